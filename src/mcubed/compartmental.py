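"""Closed-form linear mammillary PK models with zero-order infusion input.

Central-compartment concentrations for 1-, 2- and 3-compartment models are
computed by eigen-decomposition of the micro-rate-constant matrix and
superposition over dose events.  The unit-bolus response of the central
compartment is a sum of exponentials

    c(t) = (1/V1) * sum_i A_i exp(-lambda_i t),   sum_i A_i = 1,

with ``lambda_i`` the (positive) eigenvalue magnitudes and, for an
n-compartment mammillary model,

    A_i = prod_m (k_m1 - lambda_i) / prod_{j != i} (lambda_j - lambda_i)

over peripheral return constants ``k_m1``.  A zero-order infusion of rate R
and duration D started at t0 then contributes, at time t >= t0 with
tau = t - t0 and te = min(tau, D),

    (R/V1) * sum_i (A_i/lambda_i) (1 - exp(-lambda_i te))
                                  * exp(-lambda_i (tau - te)).

Nearly coincident eigenvalues are separated by a tiny relative nudge of the
micro constants; the limiting value is continuous so the perturbation is
numerically immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EIG_GAP = 1e-9


@dataclass
class DoseEvent:
    """One zero-order infusion: `amount` mg over `duration` h from `time` h."""

    time: float
    amount: float
    duration: float

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("infusion duration must be > 0")
        if self.amount < 0:
            raise ValueError("dose amount must be >= 0")

    @property
    def rate(self) -> float:
        return self.amount / self.duration


def micro_constants(params: dict) -> dict:
    """Micro rate constants from clearance-style parameters.

    ``params`` holds CL, V1 and per compartment count Q2/V2, Q3/V3 (L, L/h).
    """
    k = {"k10": params["CL"] / params["V1"]}
    if "V2" in params and params.get("V2"):
        q2 = params.get("Q2", params.get("Q"))
        k["k12"] = q2 / params["V1"]
        k["k21"] = q2 / params["V2"]
    if "V3" in params and params.get("V3"):
        k["k13"] = params["Q3"] / params["V1"]
        k["k31"] = params["Q3"] / params["V3"]
    return k


def _rate_matrix(k: dict) -> np.ndarray:
    n = 1 + ("k12" in k) + ("k13" in k)
    A = np.zeros((n, n))
    A[0, 0] = -(k["k10"] + k.get("k12", 0.0) + k.get("k13", 0.0))
    if n >= 2:
        A[0, 1] = k["k21"]
        A[1, 0] = k["k12"]
        A[1, 1] = -k["k21"]
    if n >= 3:
        A[0, 2] = k["k31"]
        A[2, 0] = k["k13"]
        A[2, 2] = -k["k31"]
    return A


def exponents_and_coefficients(params: dict):
    """Eigenvalue magnitudes and unit-bolus coefficients (lambdas, A)."""
    k = micro_constants(params)
    n = 1 + ("k12" in k) + ("k13" in k)
    if n == 1:
        return np.array([k["k10"]]), np.array([1.0])

    def _solve(kd):
        lam = np.sort(-np.linalg.eigvals(_rate_matrix(kd)).real)[::-1]
        returns = [kd[key] for key in ("k21", "k31") if key in kd]
        coefs = np.empty(n)
        for i in range(n):
            num = np.prod([km1 - lam[i] for km1 in returns])
            den = np.prod([lam[j] - lam[i] for j in range(n) if j != i])
            coefs[i] = num / den
        return lam, coefs

    lam, coefs = _solve(k)
    gaps = np.abs(np.diff(lam)) / lam[0]
    if np.any(gaps < _EIG_GAP):        # coincident eigenvalues: nudge k21/k31
        k = dict(k)
        for key, eps in (("k21", 1e-7), ("k31", 2e-7)):
            if key in k:
                k[key] *= 1.0 + eps
        lam, coefs = _solve(k)
    return lam, coefs


def concentration(params: dict, events, times) -> np.ndarray:
    """Central concentration (mg/L) at ``times`` by event superposition.

    ``events`` is a sequence of :class:`DoseEvent`; ``times`` is scalar or
    array (h).  The solution is continuous in t, including at infusion
    boundaries, and linear in the dose amounts.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    lam, coefs = exponents_and_coefficients(params)
    v1 = params["V1"]
    out = np.zeros_like(times)
    for ev in events:
        tau = times - ev.time
        active = tau > 0
        if not np.any(active):
            continue
        tau = tau[active]
        te = np.minimum(tau, ev.duration)
        contrib = np.zeros_like(tau)
        for a_i, l_i in zip(coefs, lam):
            contrib += (a_i / l_i) * (1.0 - np.exp(-l_i * te)) \
                * np.exp(-l_i * (tau - te))
        out[active] += ev.rate / v1 * contrib
    return out


def amounts_state_space(params: dict, events, times) -> np.ndarray:
    """Compartment amounts (mg) by piecewise matrix-exponential propagation.

    Independent of :func:`concentration`; used as a mass-balance and
    cross-validation oracle.  Returns an array of shape (len(times), n).
    """
    from scipy.linalg import expm

    times = np.atleast_1d(np.asarray(times, dtype=float))
    k = micro_constants(params)
    A = _rate_matrix(k)
    n = A.shape[0]
    # breakpoints: infusion starts/ends and requested times
    breaks = sorted({0.0} | {ev.time for ev in events}
                    | {ev.time + ev.duration for ev in events}
                    | set(times.tolist()))
    Ainv = np.linalg.inv(A)
    x = np.zeros(n)
    out = np.empty((len(times), n))
    t_prev = breaks[0]
    lookup = {}
    for t in breaks:
        dt = t - t_prev
        if dt > 0:
            rate = np.zeros(n)
            for ev in events:
                if ev.time <= t_prev < ev.time + ev.duration - 1e-12:
                    rate[0] += ev.rate
            eAt = expm(A * dt)
            x = eAt @ x + Ainv @ (eAt - np.eye(n)) @ rate
        lookup[t] = x.copy()
        t_prev = t
    for i, t in enumerate(times):
        out[i] = lookup[t]
    return out


def terminal_half_life(params: dict) -> float:
    """Terminal (slowest-eigenvalue) half-life in hours."""
    lam, _ = exponents_and_coefficients(params)
    return float(np.log(2.0) / np.min(lam))
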