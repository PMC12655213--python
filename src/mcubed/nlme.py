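"""Population-PK estimation by first-order conditional estimation (FOCE).

The integrated model is a one- or two-compartment IV-infusion model with
typical values TV (CL, V1, Q2, V2), multiplicative covariate effects on CL,
exponential between-subject random effects eta ~ N(0, Omega) on a
configurable subset of parameters (CL by default), and proportional
residual error with variance sigma^2 * prediction^2.

The marginal likelihood is approximated subject by subject: the
conditional mode (MAP) eta is located by a damped Newton search, the model
is linearized about it, and the residual variance is evaluated at the
conditional prediction (FOCE with interaction).  For a model whose
prediction is linear in eta with additive error the approximation is exact
and coincides with the closed-form linear-mixed-model likelihood, which is
how the machinery is validated.

All per-subject operations are vectorized across the population: the
objective for a few hundred subjects evaluates in milliseconds, which is
what makes replicated model building tractable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

VARIANCE_FLOOR = 1e-10
INNER_TOL = 1e-6
INNER_MAXITER = 60


# ---------------------------------------------------------------------------
# model types

@dataclass
class CovariateEffect:
    """One multiplicative covariate effect on a structural parameter.

    Power: TV *= (cov / reference) ** theta (continuous, reference is the
    population median).  Categorical: TV *= (1 + theta) ** cov with cov in
    {0, 1}.
    """

    target: str
    covariate: str
    kind: str                      # 'power' | 'categorical'
    theta: float = 0.0
    reference: float = 1.0

    def factor(self, cov_values: np.ndarray, theta: float | None = None):
        th = self.theta if theta is None else theta
        cov_values = np.asarray(cov_values, dtype=float)
        if self.kind == "power":
            if np.any(cov_values <= 0):
                raise ValueError(
                    f"nonpositive {self.covariate} under a power effect")
            return (cov_values / self.reference) ** th
        return (1.0 + th) ** cov_values


@dataclass
class PopModel:
    """Estimable integrated popPK model."""

    theta: dict                    # structural typical values, e.g. CL,V1,Q2,V2
    effects: list = field(default_factory=list)
    omega2: dict = field(default_factory=lambda: {"CL": 0.1})
    sigma2: float = 0.04
    residual_kind: str = "proportional"
    n_compartments: int = 2
    fixed: set = field(default_factory=set)   # parameter names held fixed

    STRUCTURAL_2CMT = ("CL", "V1", "Q2", "V2")
    STRUCTURAL_1CMT = ("CL", "V1")

    @property
    def structural_names(self):
        return self.STRUCTURAL_2CMT if self.n_compartments == 2 \
            else self.STRUCTURAL_1CMT

    @property
    def eta_params(self):
        return tuple(sorted(self.omega2))

    def validate(self):
        for name in self.structural_names:
            if self.theta.get(name, 0.0) <= 0:
                raise ValueError(f"typical value {name} must be > 0")
        if any(w < 0 for w in self.omega2.values()):
            raise ValueError("omega^2 must be >= 0")
        if self.sigma2 <= 0:
            raise ValueError("sigma^2 must be > 0")

    def copy(self):
        return replace(self, theta=dict(self.theta),
                       effects=[replace(e) for e in self.effects],
                       omega2=dict(self.omega2), fixed=set(self.fixed))


def typical_value(effects, tvpop: float, covariates) -> float:
    """Typical parameter value for one individual's covariates."""
    tv = float(tvpop)
    for eff in effects:
        tv *= float(eff.factor(np.asarray([covariates[eff.covariate]]))[0])
    return tv


def bsv_percent_cv(omega2: float) -> float:
    """Between-subject variability as %CV: 100*sqrt(exp(omega^2)-1)."""
    return 100.0 * math.sqrt(math.expm1(omega2))


@dataclass
class FitResult:
    estimates: dict
    ofv: float
    standard_errors: dict
    convergence: str
    n_iterations: int
    etas: pd.DataFrame
    model: PopModel
    n_subjects: int = 0
    n_observations: int = 0

    @property
    def converged(self):
        return self.convergence == "converged"


# ---------------------------------------------------------------------------
# vectorized dataset

class EstimationData:
    """NONMEM-style long frame unpacked into flat arrays for fast FOCE.

    Subjects are ordered by first appearance; per-subject dose events are
    padded to a common width (padding carries zero rate and never
    contributes).
    """

    def __init__(self, frame: pd.DataFrame, covariate_columns=None):
        frame = frame.reset_index(drop=True)
        ids = frame["ID"].to_numpy()
        uniq, first_pos = np.unique(ids, return_index=True)
        order = np.argsort(first_pos, kind="stable")
        self.subject_ids = uniq[order]
        self.n_subjects = len(self.subject_ids)
        id_to_idx = {sid: i for i, sid in enumerate(self.subject_ids)}

        obs = frame[frame["EVID"] == 0]
        doses = frame[frame["EVID"] == 1]
        self.obs_y = obs["DV"].to_numpy(dtype=float)
        self.obs_time = obs["TIME"].to_numpy(dtype=float)
        self.obs_subj = np.array([id_to_idx[i] for i in obs["ID"]])
        # contiguity required for segmented reductions
        seg_order = np.argsort(self.obs_subj, kind="stable")
        self.obs_y = self.obs_y[seg_order]
        self.obs_time = self.obs_time[seg_order]
        self.obs_subj = self.obs_subj[seg_order]
        self.n_obs = len(self.obs_y)
        self.counts = np.bincount(self.obs_subj, minlength=self.n_subjects)
        self.seg_starts = np.concatenate([[0], np.cumsum(self.counts)[:-1]])

        emax = max(1, int(doses.groupby("ID").size().max()) if len(doses)
                   else 1)
        self.ev_time = np.full((self.n_subjects, emax), np.inf)
        self.ev_rate = np.zeros((self.n_subjects, emax))
        self.ev_dur = np.ones((self.n_subjects, emax))
        fill = np.zeros(self.n_subjects, dtype=int)
        for sid, t, amt, rate in zip(doses["ID"], doses["TIME"],
                                     doses["AMT"], doses["RATE"]):
            i = id_to_idx[sid]
            j = fill[i]
            self.ev_time[i, j] = t
            self.ev_rate[i, j] = rate
            self.ev_dur[i, j] = amt / rate if rate > 0 else 1.0
            fill[i] += 1

        if covariate_columns is None:
            reserved = {"ID", "TIME", "AMT", "RATE", "EVID", "MDV", "DV",
                        "TAG", "STUDY"}
            covariate_columns = [
                c for c in frame.columns
                if c not in reserved and pd.api.types.is_numeric_dtype(
                    frame[c])]
        cov = frame.groupby("ID", sort=False).first()
        cov = cov.loc[self.subject_ids]
        self.covariates = cov[covariate_columns].astype(float)
        self.covariates.index.name = "ID"

    def per_subject_sum(self, values: np.ndarray) -> np.ndarray:
        """Sum an (n_obs,) array within subjects."""
        return np.add.reduceat(values, self.seg_starts)

    def median(self, column: str) -> float:
        return float(self.covariates[column].median())


def _lambdas_coefs(cl, v1, q2=None, v2=None):
    """Per-subject exponents/coefficients of the central bolus response."""
    k10 = cl / v1
    if q2 is None:
        lam = k10[:, None]
        coefs = np.ones_like(lam)
        return lam, coefs
    k12 = q2 / v1
    k21 = q2 / v2
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 1e-300))
    lam1 = 0.5 * (s + disc)
    lam2 = 0.5 * (s - disc)
    denom = np.where(np.abs(lam1 - lam2) < 1e-12, 1e-12, lam1 - lam2)
    a1 = (lam1 - k21) / denom
    a2 = (k21 - lam2) / denom
    return np.stack([lam1, lam2], axis=1), np.stack([a1, a2], axis=1)


def predict_concentrations(data: EstimationData, params: dict) -> np.ndarray:
    """Central concentration at every observation row.

    ``params`` maps structural names to per-subject arrays (S,).
    """
    cl, v1 = params["CL"], params["V1"]
    if "Q2" in params:
        lam, coefs = _lambdas_coefs(cl, v1, params["Q2"], params["V2"])
    else:
        lam, coefs = _lambdas_coefs(cl, v1)
    s_idx = data.obs_subj
    tau = data.obs_time[:, None] - data.ev_time[s_idx]       # (N, E)
    active = tau > 0
    tau = np.where(active, tau, 0.0)
    dur = data.ev_dur[s_idx]
    te = np.minimum(tau, dur)
    rate = np.where(active, data.ev_rate[s_idx], 0.0)
    conc = np.zeros(data.n_obs)
    for i in range(lam.shape[1]):
        li = lam[s_idx, i][:, None]
        ai = coefs[s_idx, i][:, None]
        contrib = rate * (ai / li) * (-np.expm1(-li * te)) \
            * np.exp(-li * (tau - te))
        conc += contrib.sum(axis=1)
    return conc / v1[s_idx]


# ---------------------------------------------------------------------------
# generic FOCE machinery (prediction function in, objective out)

def _conditional_neg2ll_parts(pred, y, sigma2, kind, floor=VARIANCE_FLOOR):
    """Per-observation -2 log density terms (residual part only)."""
    if kind == "proportional":
        v = np.maximum(sigma2 * pred * pred, floor)
    else:
        v = np.full_like(pred, max(sigma2, floor))
    resid = y - pred
    return resid * resid / v + np.log(2.0 * math.pi * v)


def _subject_g(pred_fn, etas, y, data: EstimationData, omega_inv, log_det_2pi_omega,
               sigma2, kind):
    """Vector of per-subject g(eta) = conditional NLL + eta prior."""
    pred = pred_fn(etas)
    parts = _conditional_neg2ll_parts(pred, y, sigma2, kind)
    g = 0.5 * data.per_subject_sum(parts)
    quad = 0.5 * np.einsum("si,ij,sj->s", etas, omega_inv, etas)
    return g + quad + 0.5 * log_det_2pi_omega


def map_etas(pred_fn, data: EstimationData, omega: np.ndarray,
             sigma2: float, kind: str, eta0=None,
             tol: float = INNER_TOL, maxiter: int = INNER_MAXITER):
    """Vectorized damped-Newton search for all subjects' MAP etas.

    Finite-difference gradients/Hessians in the (small) eta dimension;
    subjects failing to converge keep their best-so-far point and are
    reported in the returned mask.
    """
    k = omega.shape[0]
    omega_inv = np.linalg.inv(omega)
    ld = float(np.linalg.slogdet(2.0 * math.pi * omega)[1])
    S = data.n_subjects
    etas = np.zeros((S, k)) if eta0 is None else eta0.copy()
    y = data.obs_y
    h = 1e-4

    def g_of(e):
        return _subject_g(pred_fn, e, y, data, omega_inv, ld, sigma2, kind)

    g = g_of(etas)
    converged = np.zeros(S, dtype=bool)
    for _ in range(maxiter):
        grad = np.zeros((S, k))
        hess = np.zeros((S, k, k))
        gp = {}
        for i in range(k):
            ei = np.zeros(k)
            ei[i] = h
            gp[(i, +1)] = g_of(etas + ei)
            gp[(i, -1)] = g_of(etas - ei)
            grad[:, i] = (gp[(i, +1)] - gp[(i, -1)]) / (2 * h)
            hess[:, i, i] = (gp[(i, +1)] - 2 * g + gp[(i, -1)]) / (h * h)
        for i in range(k):
            for j in range(i + 1, k):
                eij = np.zeros(k)
                eij[i] = h
                eij[j] = h
                gpp = g_of(etas + eij)
                gmm = g_of(etas - eij)
                cross = (gpp + gmm - gp[(i, +1)] - gp[(i, -1)]
                         - gp[(j, +1)] - gp[(j, -1)] + 2 * g) / (2 * h * h)
                hess[:, i, j] = hess[:, j, i] = cross
        converged = np.abs(grad).max(axis=1) < tol
        if converged.all():
            break
        # clip Hessian eigenvalues: negative curvature would send the
        # Newton step uphill; the prior curvature is a natural floor
        vals, vecs = np.linalg.eigh(hess)
        floor = np.maximum(0.5 * np.min(np.diag(omega_inv)), 1e-3)
        vals = np.maximum(vals, floor)
        hess_pd = np.einsum("sij,sj,skj->sik", vecs, vals, vecs)
        step = np.linalg.solve(hess_pd, grad[:, :, None])[:, :, 0]
        step = np.clip(step, -2.0, 2.0)
        # backtracking: accept only improving steps, subject-wise
        scale = np.ones(S)
        improved = np.zeros(S, dtype=bool)
        trial = etas.copy()
        g_new = g.copy()
        for _bt in range(8):
            cand = etas - scale[:, None] * step
            gc = g_of(cand)
            better = (gc < g_new - 1e-14) & ~improved
            trial[better] = cand[better]
            g_new[better] = gc[better]
            improved |= better
            scale = np.where(improved, scale, scale * 0.5)
            if improved.all():
                break
        still = ~improved & ~converged
        etas, g = trial, g_new
        if not improved.any() and still.any():
            break
    hess_final = hess
    return etas, g, converged, hess_final


def foce_ofv(pred_fn, data: EstimationData, omega: np.ndarray,
             sigma2: float, kind: str = "proportional", eta0=None):
    """FOCE-with-interaction -2 log marginal likelihood.

    The model is linearized about each subject's MAP eta; the residual
    variance uses the conditional prediction.  Returns (ofv, etas,
    converged mask).
    """
    k = omega.shape[0]
    if np.all(np.diag(omega) < 1e-12):
        # degenerate population: fixed-effects-only weighted least squares
        pred = pred_fn(np.zeros((data.n_subjects, k)))
        parts = _conditional_neg2ll_parts(pred, data.obs_y, sigma2, kind)
        return float(parts.sum()), np.zeros((data.n_subjects, k)), \
            np.ones(data.n_subjects, dtype=bool)

    etas, g, conv, _ = map_etas(pred_fn, data, omega, sigma2, kind,
                                eta0=eta0)
    f = pred_fn(etas)
    # gradient of the prediction wrt eta at the mode
    h = 1e-5
    G = np.empty((data.n_obs, k))
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h
        G[:, i] = (pred_fn(etas + ei) - pred_fn(etas - ei)) / (2 * h)
    y = data.obs_y
    if kind == "proportional":
        v = np.maximum(sigma2 * f * f, VARIANCE_FLOOR)
    else:
        v = np.full_like(f, max(sigma2, VARIANCE_FLOOR))
    r = y - f + np.einsum("ni,ni->n", G, etas[data.obs_subj])

    w = 1.0 / v
    omega_inv = np.linalg.inv(omega)
    # M_s = Omega^-1 + G' W G  per subject
    GtWG = np.empty((data.n_subjects, k, k))
    GtWr = np.empty((data.n_subjects, k))
    for i in range(k):
        GtWr[:, i] = data.per_subject_sum(G[:, i] * w * r)
        for j in range(i, k):
            val = data.per_subject_sum(G[:, i] * w * G[:, j])
            GtWG[:, i, j] = GtWG[:, j, i] = val
    M = omega_inv[None] + GtWG
    sign, logdet_m = np.linalg.slogdet(M)
    logdet_omega = float(np.linalg.slogdet(omega)[1])
    logdet_c = data.per_subject_sum(np.log(v)) + logdet_omega + logdet_m
    quad_d = data.per_subject_sum(r * r * w)
    sol = np.linalg.solve(M, GtWr[:, :, None])[:, :, 0]
    quad = quad_d - np.einsum("si,si->s", GtWr, sol)
    ofv = float(np.sum(data.counts * math.log(2.0 * math.pi)
                       + logdet_c + quad))
    return ofv, etas, conv


# ---------------------------------------------------------------------------
# the popPK objective

class FOCEEngine:
    """Binds a PopModel family to a dataset for repeated evaluation."""

    def __init__(self, frame: pd.DataFrame, n_compartments: int = 2):
        self.data = EstimationData(frame)
        self.n_compartments = n_compartments
        self._eta_cache = None

    def _typical_arrays(self, model: PopModel) -> dict:
        cov = self.data.covariates
        out = {}
        for name in model.structural_names:
            tv = np.full(self.data.n_subjects, model.theta[name])
            for eff in model.effects:
                if eff.target == name:
                    tv = tv * eff.factor(cov[eff.covariate].to_numpy())
            out[name] = tv
        return out

    def make_pred_fn(self, model: PopModel):
        tv = self._typical_arrays(model)
        eta_params = model.eta_params
        data = self.data

        def pred(etas):
            params = {}
            for name, arr in tv.items():
                if name in eta_params:
                    i = eta_params.index(name)
                    params[name] = arr * np.exp(etas[:, i])
                else:
                    params[name] = arr
            return predict_concentrations(data, params)

        return pred

    def omega_matrix(self, model: PopModel) -> np.ndarray:
        return np.diag([model.omega2[p] for p in model.eta_params])

    def objective(self, model: PopModel, warm_start: bool = True) -> float:
        ofv, etas, _ = foce_ofv(
            self.make_pred_fn(model), self.data, self.omega_matrix(model),
            model.sigma2, model.residual_kind,
            eta0=self._eta_cache if warm_start else None)
        if warm_start:
            self._eta_cache = etas
        return ofv

    def etas_frame(self, model: PopModel) -> pd.DataFrame:
        _, etas, _ = foce_ofv(self.make_pred_fn(model), self.data,
                              self.omega_matrix(model), model.sigma2,
                              model.residual_kind)
        return pd.DataFrame(etas,
                            columns=[f"ETA_{p}" for p in model.eta_params],
                            index=pd.Index(self.data.subject_ids, name="ID"))


def foce_objective(model: PopModel, frame: pd.DataFrame) -> float:
    """-2 log approximate marginal likelihood of ``model`` on ``frame``."""
    engine = FOCEEngine(frame, model.n_compartments)
    return engine.objective(model, warm_start=False)


def individual_conditional_nll(model: PopModel, eta: np.ndarray,
                               subject_frame: pd.DataFrame) -> float:
    """-log conditional density of one subject's data given eta, plus the
    eta prior term."""
    data = EstimationData(subject_frame)
    if data.n_obs == 0:
        raise ValueError("subject has no observations")
    engine = FOCEEngine(subject_frame, model.n_compartments)
    pred_fn = engine.make_pred_fn(model)
    omega = engine.omega_matrix(model)
    omega_inv = np.linalg.inv(omega)
    ld = float(np.linalg.slogdet(2.0 * math.pi * omega)[1])
    eta = np.asarray(eta, dtype=float)[None, :]
    return float(_subject_g(pred_fn, eta, data.obs_y, data, omega_inv, ld,
                            model.sigma2, model.residual_kind)[0])


def map_eta(model: PopModel, subject_frame: pd.DataFrame) -> np.ndarray:
    """MAP (empirical Bayes) eta for a single subject."""
    data = EstimationData(subject_frame)
    if data.n_obs == 0:
        return np.zeros(len(model.eta_params))
    engine = FOCEEngine(subject_frame, model.n_compartments)
    etas, _, _, _ = map_etas(engine.make_pred_fn(model), engine.data,
                             engine.omega_matrix(model), model.sigma2,
                             model.residual_kind)
    return etas[0]


# ---------------------------------------------------------------------------
# population fit

def _pack(model: PopModel):
    names, values = [], []
    for p in model.structural_names:
        if p not in model.fixed:
            names.append(("theta", p))
            values.append(math.log(model.theta[p]))
    for i, eff in enumerate(model.effects):
        key = f"{eff.target}~{eff.covariate}"
        if key not in model.fixed:
            names.append(("effect", i))
            values.append(eff.theta)
    for p in model.eta_params:
        if f"omega2_{p}" not in model.fixed:
            names.append(("omega2", p))
            values.append(math.log(max(model.omega2[p], 1e-8)))
    if "sigma2" not in model.fixed:
        names.append(("sigma2", None))
        values.append(math.log(model.sigma2))
    return names, np.array(values)


def _unpack(model: PopModel, names, x) -> PopModel:
    m = model.copy()
    for (kind, key), val in zip(names, x):
        if kind == "theta":
            m.theta[key] = math.exp(min(val, 30.0))
        elif kind == "effect":
            m.effects[key].theta = val
        elif kind == "omega2":
            m.omega2[key] = math.exp(min(val, 10.0))
        else:
            m.sigma2 = math.exp(min(val, 10.0))
    return m


@dataclass
class FitConfig:
    maxiter: int = 500
    rel_tol: float = 1e-6
    grad_tol: float = 1e-3
    fd_step: float = 1e-5
    restarts: int = 3
    compute_se: bool = True


def fit_population(frame: pd.DataFrame, start: PopModel,
                   config: FitConfig | None = None) -> FitResult:
    """Maximize the FOCE approximate likelihood over all free parameters.

    Positive parameters (typical values, omega^2, sigma^2) are optimized
    on the log scale; covariate thetas are unconstrained.  Standard errors
    come from the finite-difference observed information of the objective.
    """
    config = config or FitConfig()
    start.validate()
    engine = FOCEEngine(frame, start.n_compartments)
    names, x0 = _pack(start)

    def objective(x):
        m = _unpack(start, names, x)
        try:
            val = engine.objective(m)
        except (ValueError, np.linalg.LinAlgError):
            return 1e12
        if not np.isfinite(val):
            return 1e12
        return val

    opts = {"maxiter": config.maxiter, "ftol": config.rel_tol,
            "gtol": config.grad_tol, "eps": config.fd_step}

    def run(x_init):
        res = optimize.minimize(objective, x_init, method="L-BFGS-B",
                                options=opts)
        # restart-polish: a fresh quasi-Newton memory from the incumbent
        # often escapes premature line-search termination
        for _ in range(4):
            res2 = optimize.minimize(objective, res.x, method="L-BFGS-B",
                                     options=opts)
            if res.fun - res2.fun < 0.01:
                if res2.fun < res.fun:
                    res = res2
                break
            res = res2
        return res

    best = None
    rng = np.random.default_rng(0)
    for attempt in range(1 + config.restarts):
        x_init = x0 if attempt == 0 else x0 + rng.normal(0, 0.2, len(x0))
        res = run(x_init)
        if best is None or res.fun < best.fun:
            best = res
        if np.isfinite(best.fun) and best.fun < 1e11:
            break

    model = _unpack(start, names, best.x)
    status = "converged" if best.success and best.fun < 1e11 else \
        "not_converged"
    # report a cold-start OFV so values are comparable across fits
    # (independent of the warm-start history of the optimizer)
    try:
        cold = engine.objective(model, warm_start=False)
        if np.isfinite(cold):
            best.fun = cold
    except (ValueError, np.linalg.LinAlgError):
        pass

    ses = {}
    if config.compute_se and status == "converged" and len(names):
        cov = _observed_information_cov(objective, best.x, best.fun)
        if cov is not None:
            se_packed = np.sqrt(np.maximum(np.diag(cov), 0.0))
            for (kind, key), se, xv in zip(names, se_packed, best.x):
                label = _param_label(kind, key, model)
                if kind == "effect":
                    ses[label] = se
                else:   # delta method for log-scale parameters
                    ses[label] = se * math.exp(min(xv, 30.0))

    estimates = {name: model.theta[name] for name in model.structural_names}
    for eff in model.effects:
        estimates[f"theta_{eff.covariate}"] = eff.theta
    for p, w2 in model.omega2.items():
        estimates[f"omega2_{p}"] = w2
        estimates[f"bsv_cv_{p}"] = bsv_percent_cv(w2)
        estimates[f"bsv_sqrt_omega2_{p}"] = 100.0 * math.sqrt(w2)
    estimates["sigma2"] = model.sigma2

    etas = engine.etas_frame(model)
    return FitResult(estimates=estimates, ofv=float(best.fun),
                     standard_errors=ses, convergence=status,
                     n_iterations=int(best.nit), etas=etas, model=model,
                     n_subjects=engine.data.n_subjects,
                     n_observations=engine.data.n_obs)


def _param_label(kind, key, model):
    if kind == "theta":
        return key
    if kind == "effect":
        return f"theta_{model.effects[key].covariate}"
    if kind == "omega2":
        return f"omega2_{key}"
    return "sigma2"


def _observed_information_cov(objective, x, f0, step=1e-3):
    """Covariance = 2 * inverse Hessian of the -2LL objective."""
    n = len(x)
    H = np.empty((n, n))
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = step
        fp[i] = objective(x + ei)
        fm[i] = objective(x - ei)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / step ** 2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n)
            ei[i] = step
            ej = np.zeros(n)
            ej[j] = step
            fpp = objective(x + ei + ej)
            fmm = objective(x - ei - ej)
            H[i, j] = H[j, i] = (fpp + fmm - fp[i] - fm[i] - fp[j] - fm[j]
                                 + 2 * f0) / (2 * step ** 2)
    try:
        return 2.0 * np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        return None


def gof_quantities(model: PopModel, frame: pd.DataFrame) -> pd.DataFrame:
    """Per-observation goodness-of-fit table.

    PRED: population prediction (eta = 0); IPRED: individual prediction at
    the MAP eta; CWRES: conditionally weighted residual, the FOCE residual
    decorrelated by the inverse square root of each subject's marginal
    covariance (zero-mean, unit-variance under a correct model).
    """
    engine = FOCEEngine(frame, model.n_compartments)
    data = engine.data
    pred_fn = engine.make_pred_fn(model)
    omega = engine.omega_matrix(model)
    k = omega.shape[0]
    etas, _, _, _ = map_etas(pred_fn, data, omega, model.sigma2,
                             model.residual_kind)
    f = pred_fn(etas)
    pred0 = pred_fn(np.zeros((data.n_subjects, k)))
    h = 1e-5
    G = np.empty((data.n_obs, k))
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h
        G[:, i] = (pred_fn(etas + ei) - pred_fn(etas - ei)) / (2 * h)
    if model.residual_kind == "proportional":
        v = np.maximum(model.sigma2 * f * f, VARIANCE_FLOOR)
    else:
        v = np.full_like(f, model.sigma2)
    r = data.obs_y - f + np.einsum("ni,ni->n", G, etas[data.obs_subj])
    cwres = np.empty(data.n_obs)
    for s in range(data.n_subjects):
        sl = slice(data.seg_starts[s], data.seg_starts[s] + data.counts[s])
        Gs = G[sl]
        C = Gs @ omega @ Gs.T + np.diag(v[sl])
        vals, vecs = np.linalg.eigh(C)
        inv_sqrt = vecs @ np.diag(1.0 / np.sqrt(np.maximum(vals, 1e-12))) \
            @ vecs.T
        cwres[sl] = inv_sqrt @ r[sl]
    return pd.DataFrame({
        "ID": data.subject_ids[data.obs_subj],
        "TIME": data.obs_time,
        "DV": data.obs_y,
        "PRED": pred0,
        "IPRED": f,
        "CWRES": cwres,
    })


def initial_model(frame: pd.DataFrame, n_compartments: int = 2) -> PopModel:
    """Crude naive-pooled starting values for the integrated model.

    CL from steady-state mean-concentration mass balance; volumes from
    typical vancomycin magnitudes scaled by median body weight.
    """
    obs = frame[frame["EVID"] == 0]
    doses = frame[frame["EVID"] == 1]
    per_id_rate = doses.groupby("ID").apply(
        lambda d: d["AMT"].iloc[-1] / max(np.median(np.diff(d["TIME"]))
                                          if len(d) > 1 else 12.0, 1e-6),
        include_groups=False)
    mean_conc = obs.groupby("ID")["DV"].mean()
    common = per_id_rate.index.intersection(mean_conc.index)
    cl0 = float(np.median(per_id_rate[common] / mean_conc[common]))
    cl0 = min(max(cl0, 0.5), 15.0)
    bw = float(obs["BW"].median()) if "BW" in obs else 65.0
    theta = {"CL": cl0, "V1": 0.4 * bw}
    if n_compartments == 2:
        theta.update({"Q2": 7.0, "V2": 0.7 * bw})
    return PopModel(theta=theta, omega2={"CL": 0.1}, sigma2=0.04,
                    n_compartments=n_compartments)
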