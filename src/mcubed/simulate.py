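"""Forward simulation of vancomycin concentration–time observations.

For each virtual patient this module builds the dosing schedule prescribed
by the study design (renal dose adjustment, loading dose, enough doses to
reach steady state), draws individual PK parameters from the study's
published model (typical CL from the CLcr formula, lognormal between-
subject variability), samples observation times uniformly within tagged
windows (peak / random / trough), applies residual error, censors
non-positive observations by exclusion, and emits NONMEM-style long-format
records.
"""

from __future__ import annotations

import math


import numpy as np
import pandas as pd

from .compartmental import DoseEvent, concentration, terminal_half_life
from .studies import DesignSpec, SamplingWindow, SourceModel, StudyDescriptor
from .cohort import VirtualCohort

#: steady state is operationalized as at least this many dosing intervals,
#: or five terminal half-lives, whichever is longer, before sampled doses
MIN_SS_INTERVALS = 7
SS_HALF_LIVES = 5.0

DATASET_COLUMNS = ["ID", "TIME", "AMT", "RATE", "EVID", "MDV", "DV",
                   "AGE", "BW", "CLCR", "SEX", "STUDY"]


def _dose_for_patient(clcr: float, design: DesignSpec):
    """Dose amount and interval, via the renal-adjustment table if present."""
    if not design.renal_table:
        return design.dose_mg, design.interval_h
    for band in design.renal_table:
        if band.clcr_lo <= clcr < band.clcr_hi:
            return band.dose_mg, band.interval_h
    lowest = min(design.renal_table, key=lambda b: b.clcr_lo)
    return lowest.dose_mg, lowest.interval_h


def build_dose_schedule(patient, design: DesignSpec,
                        model: SourceModel | None = None) -> list:
    """Dose events for one patient (maintenance, loading, renal bands).

    ``patient`` is a mapping with at least BW and CLCR.  When the design is
    steady-state-only the schedule is long enough that the sampled (last)
    interval is at steady state.
    """
    dose, interval = _dose_for_patient(patient["CLCR"], design)
    infusion = min(design.infusion_h, interval)
    if design.n_intervals is not None:
        n_int = design.n_intervals
    elif design.steady_state_only and model is not None:
        params = {"CL": max(model.typical_cl(patient["CLCR"]), 1e-6),
                  **model.volume_params}
        t_half = terminal_half_life(params)
        n_int = max(MIN_SS_INTERVALS,
                    math.ceil(SS_HALF_LIVES * t_half / interval))
        n_int = min(n_int, 240)
    else:
        n_int = 5
    events = []
    first = dose
    if design.loading_dose_mg is not None:
        first = design.loading_dose_mg
    elif design.loading_dose_mg_per_kg is not None:
        first = design.loading_dose_mg_per_kg * patient["BW"]
    events.append(DoseEvent(0.0, first, infusion))
    for i in range(1, n_int + 1):
        events.append(DoseEvent(i * interval, dose, infusion))
    return events


def individual_parameters(patient, model: SourceModel, rng) -> dict:
    """Individual PK parameters: typical values times exp(eta) per BSV."""
    rng = np.random.default_rng(rng)
    params = {"CL": model.typical_cl(patient["CLCR"])}
    params.update(model.volume_params)
    for name, omega2 in model.bsv.items():
        if name not in params:
            continue
        if omega2 > 0:
            params[name] = params[name] * math.exp(
                rng.normal(0.0, math.sqrt(omega2)))
    return params


DEFAULT_WINDOW_MIX = {"peak": 0.35, "random": 0.2, "trough": 0.45}
TROUGH_WIDTH_H = 0.5
PEAK_WIDTH_H = 1.0


def resolve_windows(design: DesignSpec, interval: float,
                    infusion: float) -> list:
    """Fill in default window geometry for tag-only sampling specs.

    Trough = the half hour before the next dose; peak = the hour after the
    end of infusion; random = the gap between them.  Offsets are hours
    after a dose event.  Designs with no windows at all default to
    steady-state trough sampling.
    """
    windows = design.sampling_windows or [SamplingWindow(tag="trough")]
    resolved = []
    peak_end = min(infusion + PEAK_WIDTH_H, interval)
    trough_start = max(interval - TROUGH_WIDTH_H, peak_end)
    for w in windows:
        if w.start is not None and w.end is not None:
            resolved.append(SamplingWindow(w.tag, w.start, w.end))
        elif w.tag == "peak":
            resolved.append(SamplingWindow("peak", infusion, peak_end))
        elif w.tag == "trough":
            resolved.append(SamplingWindow("trough", trough_start, interval))
        else:
            if trough_start <= peak_end:
                continue
            resolved.append(SamplingWindow("random", peak_end, trough_start))
    if not resolved:
        resolved = [SamplingWindow("trough", trough_start, interval)]
    return resolved


def _truncated_poisson_lambda(mean: float) -> float:
    """Rate of a zero-truncated Poisson with the requested mean."""
    if mean <= 1.0 + 1e-9:
        return 0.0
    lam = mean
    for _ in range(50):
        lam = mean * (1.0 - math.exp(-lam))
    return lam


def draw_n_samples(mean: float, rng) -> int:
    """Number of samples per patient: zero-truncated Poisson around mean."""
    lam = _truncated_poisson_lambda(mean)
    if lam == 0.0:
        return 1
    while True:
        n = rng.poisson(lam)
        if n >= 1:
            return int(n)


def draw_sampling_times(schedule, design: DesignSpec, n_samples: int,
                        rng) -> list:
    """Observation times, uniform within tagged windows of the last dose.

    Returns a list of (time, window_tag).  The window mix follows the
    design's declared tags weighted by the default peak/random/trough mix.
    """
    if not schedule:
        raise ValueError("empty dose schedule")
    rng = np.random.default_rng(rng)
    last = schedule[-1]
    interval = schedule[-1].time - schedule[-2].time if len(schedule) > 1 \
        else design.interval_h
    windows = resolve_windows(design, interval, last.duration)
    tags = [w.tag for w in windows]
    weights = np.array([DEFAULT_WINDOW_MIX.get(t, 0.2) for t in tags])
    weights = weights / weights.sum()
    out = []
    for _ in range(n_samples):
        w = windows[rng.choice(len(windows), p=weights)]
        t = last.time + rng.uniform(w.start, w.end)
        out.append((float(t), w.tag))
    return out


def apply_residual_error(true_conc, residual, rng):
    """Observed concentration or NaN when censored (observation <= 0).

    Proportional: y = c (1 + eps); additive: y = c + eps; combined applies
    both, with independent errors.
    """
    rng = np.random.default_rng(rng)
    c = float(true_conc)
    y = c
    if residual.kind in ("proportional", "combined") and residual.sigma2 > 0:
        y = y * (1.0 + rng.normal(0.0, math.sqrt(residual.sigma2)))
    if residual.kind == "additive" and residual.sigma2 > 0:
        y = y + rng.normal(0.0, math.sqrt(residual.sigma2))
    elif residual.kind == "combined" and residual.sigma2_add > 0:
        y = y + rng.normal(0.0, math.sqrt(residual.sigma2_add))
    if y <= 0.0:
        return float("nan")
    return float(y)


def simulate_study(cohort: VirtualCohort, study: StudyDescriptor,
                   seed) -> pd.DataFrame:
    """Simulate one study's concentration records for its virtual cohort.

    Returns a NONMEM-style fragment (dose rows EVID=1, observation rows
    EVID=0); censored (non-positive) observations are dropped.  A
    ``N_CENSORED`` attribute on the frame records how many were excluded.
    """
    rng = np.random.default_rng(seed)
    model = study.source_model
    rows = []
    n_censored = 0
    for _, patient in cohort.patients.iterrows():
        pid = int(patient["ID"])
        schedule = build_dose_schedule(patient, study.design, model)
        params = individual_parameters(patient, model, rng)
        n_samp = draw_n_samples(study.design.samples_per_patient, rng)
        times_tags = draw_sampling_times(schedule, study.design, n_samp, rng)
        obs_times = np.array([t for t, _ in times_tags])
        true_conc = concentration(params, schedule, obs_times)
        base = {"ID": pid, "AGE": patient["AGE"], "BW": patient["BW"],
                "CLCR": patient["CLCR"], "SEX": patient.get("SEX", 0),
                "STUDY": study.study_id}
        for ev in schedule:
            rows.append({**base, "TIME": ev.time, "AMT": ev.amount,
                         "RATE": ev.rate, "EVID": 1, "MDV": 1,
                         "DV": np.nan, "TAG": ""})
        for (t, tag), c in zip(times_tags, true_conc):
            y = apply_residual_error(c, model.residual, rng)
            if math.isnan(y):
                n_censored += 1
                continue
            rows.append({**base, "TIME": t, "AMT": 0.0, "RATE": 0.0,
                         "EVID": 0, "MDV": 0, "DV": y, "TAG": tag})
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(["ID", "TIME", "EVID"],
                              ascending=[True, True, False],
                              kind="stable").reset_index(drop=True)
    for label in sorted(study.disease_labels):
        frame[f"LABEL_{label}"] = 1
    frame.attrs["n_censored"] = n_censored
    return frame


def simulate_pooled(studies, cohorts, seed) -> pd.DataFrame:
    """Simulate and pool all studies into one integrated dataset.

    Patient IDs are re-assigned globally; disease-label indicator columns
    are unioned with zeros elsewhere.
    """
    from .cohort import as_seed_sequence
    seeds = as_seed_sequence(seed).spawn(len(studies))
    frames = []
    offset = 0
    n_censored = 0
    for study, cohort, s in zip(studies, cohorts, seeds):
        frag = simulate_study(cohort, study, s)
        frag["ID"] = frag["ID"] + offset
        offset += len(cohort)
        n_censored += frag.attrs["n_censored"]
        frames.append(frag)
    pooled = pd.concat(frames, ignore_index=True)
    label_cols = [c for c in pooled.columns if c.startswith("LABEL_")]
    pooled[label_cols] = pooled[label_cols].fillna(0).astype(int)
    pooled.attrs["n_censored"] = n_censored
    return pooled


def dataset_summary(dataset: pd.DataFrame) -> dict:
    obs = dataset[dataset["EVID"] == 0]
    return {"n_patients": int(dataset["ID"].nunique()),
            "n_observations": int(len(obs)),
            "n_censored": int(dataset.attrs.get("n_censored", 0))}
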