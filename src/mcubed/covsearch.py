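"""Stepwise covariate selection on the integrated popPK model.

Forward inclusion accepts, one at a time, the candidate whose addition
drops the objective function value (OFV, -2 log likelihood) by more than
3.84 (chi-square, 1 df, p < 0.05); backward elimination then removes any
covariate whose deletion raises the OFV by 6.63 or less (p > 0.01).

Disease labels are screened first against the covariate-free base model:
groups whose empirical-Bayes CL etas are significantly elevated (one-sided
Welch t-test, Bonferroni-corrected) are merged into a single 0/1
"provisional PK cluster" indicator which replaces its constituent labels
in the candidate pool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .nlme import (CovariateEffect, FitConfig, FitResult, PopModel,
                   fit_population)

FORWARD_THRESHOLD = 3.84
BACKWARD_THRESHOLD = 6.63
CLUSTER_ALPHA = 0.05
CLUSTER_MIN_GROUP = 5
CLUSTER_COLUMN = "PKCLUSTER"


@dataclass
class CandidateCovariate:
    name: str                  # dataset column (AGE, BW, CLCR, LABEL_*, ...)
    kind: str                  # 'power' | 'categorical'
    target: str = "CL"

    def effect(self, reference: float) -> CovariateEffect:
        return CovariateEffect(target=self.target, covariate=self.name,
                               kind=self.kind, theta=0.0,
                               reference=reference)


@dataclass
class SearchStep:
    step: str                  # 'forward' | 'backward'
    candidate: str
    delta_ofv: float
    decision: str              # 'added' | 'removed' | 'retained' | 'rejected'


@dataclass
class SearchTrace:
    steps: list = field(default_factory=list)
    final_model: PopModel | None = None
    final_fit: FitResult | None = None
    base_ofv: float = float("nan")
    final_ofv: float = float("nan")
    cluster_labels: list = field(default_factory=list)

    def to_json(self) -> str:
        doc = {"base_ofv": self.base_ofv, "final_ofv": self.final_ofv,
               "cluster_labels": self.cluster_labels,
               "steps": [asdict(s) for s in self.steps],
               "final_covariates": [e.covariate
                                    for e in self.final_model.effects]
               if self.final_model else []}
        return json.dumps(doc, indent=1)


def _reference_for(candidate: CandidateCovariate,
                   frame: pd.DataFrame) -> float:
    if candidate.kind != "power":
        return 1.0
    per_subject = frame[frame["EVID"] == 0].groupby("ID")[candidate.name] \
        .first()
    return float(per_subject.median())


def _fit_with(model: PopModel, frame: pd.DataFrame,
              config: FitConfig) -> FitResult | None:
    try:
        fit = fit_population(frame, model, config)
    except (ValueError, np.linalg.LinAlgError):
        return None
    return fit if fit.converged else None


def forward_step(current_fit: FitResult, candidates, frame: pd.DataFrame,
                 config: FitConfig | None = None,
                 threshold: float = FORWARD_THRESHOLD):
    """Try each remaining candidate; add the best if its OFV drop > 3.84.

    Returns (new_fit, SearchStep) on acceptance, (None, steps) otherwise;
    ties broken by larger drop then candidate name.
    """
    config = config or FitConfig(compute_se=False)
    results = []
    for cand in sorted(candidates, key=lambda c: c.name):
        model = current_fit.model.copy()
        model.effects = model.effects + [cand.effect(_reference_for(cand,
                                                                    frame))]
        fit = _fit_with(model, frame, config)
        if fit is None:
            continue
        results.append((current_fit.ofv - fit.ofv, cand, fit))
    if not results:
        return None, []
    results.sort(key=lambda t: (-t[0], t[1].name))
    best_drop, best_cand, best_fit = results[0]
    steps = [SearchStep("forward", c.name, d,
                        "added" if (c is best_cand and d > threshold)
                        else "rejected")
             for d, c, _ in results]
    if best_drop > threshold:
        return best_fit, steps
    return None, steps


def backward_step(current_fit: FitResult, frame: pd.DataFrame,
                  config: FitConfig | None = None,
                  threshold: float = BACKWARD_THRESHOLD):
    """Delete the weakest covariate if its removal raises OFV by <= 6.63.

    Returns (new_fit, SearchStep) when a covariate was removed, else
    (None, steps) with every covariate marked retained.
    """
    config = config or FitConfig(compute_se=False)
    if not current_fit.model.effects:
        return None, []
    results = []
    for i, eff in enumerate(current_fit.model.effects):
        model = current_fit.model.copy()
        del model.effects[i]
        fit = _fit_with(model, frame, config)
        if fit is None:
            continue
        rise = fit.ofv - current_fit.ofv
        results.append((rise, eff.covariate, fit))
    if not results:
        return None, []
    results.sort(key=lambda t: (t[0], t[1]))
    weakest_rise, weakest_name, weakest_fit = results[0]
    if weakest_rise <= threshold:
        steps = [SearchStep("backward", weakest_name, weakest_rise,
                            "removed")]
        return weakest_fit, steps
    steps = [SearchStep("backward", name, rise, "retained")
             for rise, name, _ in results]
    return None, steps


def build_provisional_cluster(base_fit: FitResult, frame: pd.DataFrame,
                              alpha: float = CLUSTER_ALPHA,
                              min_group: int = CLUSTER_MIN_GROUP):
    """Merge disease labels with significantly elevated CL etas.

    One-sided Welch t-test per label (group vs all others) on the
    empirical-Bayes eta_CL from the covariate-free base fit, Bonferroni
    corrected across labels.  Returns (labels, indicator Series by ID);
    empty when nothing tests elevated.
    """
    eta_col = "ETA_CL"
    if eta_col not in base_fit.etas.columns:
        raise ValueError("base fit carries no CL random effect")
    etas = base_fit.etas[eta_col]
    per_subject = frame.groupby("ID", sort=False).first()
    per_subject = per_subject.loc[etas.index]
    label_cols = [c for c in per_subject.columns if c.startswith("LABEL_")]
    m = len(label_cols)
    selected = []
    for col in label_cols:
        mask = per_subject[col].to_numpy() > 0
        if mask.sum() < min_group or (~mask).sum() < min_group:
            continue
        res = stats.ttest_ind(etas[mask], etas[~mask], equal_var=False,
                              alternative="greater")
        if res.pvalue < alpha / max(m, 1):
            selected.append(col)
    indicator = per_subject[selected].max(axis=1).astype(float) \
        if selected else pd.Series(0.0, index=per_subject.index)
    labels = [c.removeprefix("LABEL_") for c in selected]
    return labels, indicator.rename(CLUSTER_COLUMN)


def attach_cluster_column(frame: pd.DataFrame,
                          indicator: pd.Series) -> pd.DataFrame:
    out = frame.copy()
    out[CLUSTER_COLUMN] = out["ID"].map(indicator).fillna(0.0)
    return out


def default_candidates(frame: pd.DataFrame,
                       include_labels: bool = False) -> list:
    """Continuous AGE/BW/CLcr power candidates (+ per-label indicators)."""
    cands = [CandidateCovariate(name, "power")
             for name in ("AGE", "BW", "CLCR") if name in frame.columns]
    if include_labels:
        cands += [CandidateCovariate(c, "categorical")
                  for c in frame.columns if c.startswith("LABEL_")]
    return cands


def run_search(frame: pd.DataFrame, base: PopModel, candidates=None,
               config: FitConfig | None = None,
               cluster_alpha: float = CLUSTER_ALPHA) -> SearchTrace:
    """Full stepwise search with provisional-cluster construction.

    Fits the covariate-free base model, screens disease labels into a
    merged cluster indicator (which replaces the individual labels in the
    pool), then runs forward inclusion to a fixpoint followed by backward
    elimination to a fixpoint.
    """
    config = config or FitConfig(compute_se=False)
    trace = SearchTrace()
    base_fit = fit_population(frame, base, config)
    trace.base_ofv = base_fit.ofv
    if candidates is None:
        candidates = default_candidates(frame)

    labels, indicator = build_provisional_cluster(base_fit, frame,
                                                  alpha=cluster_alpha)
    trace.cluster_labels = labels
    if labels:
        frame = attach_cluster_column(frame, indicator)
        candidates = list(candidates) + [
            CandidateCovariate(CLUSTER_COLUMN, "categorical")]

    remaining = {c.name: c for c in candidates}
    current = base_fit
    while remaining:
        new_fit, steps = forward_step(current, list(remaining.values()),
                                      frame, config)
        trace.steps.extend(steps)
        if new_fit is None:
            break
        current = new_fit
        added = current.model.effects[-1].covariate
        remaining.pop(added, None)

    while current.model.effects:
        new_fit, steps = backward_step(current, frame, config)
        trace.steps.extend(steps)
        if new_fit is None:
            break
        current = new_fit

    trace.final_model = current.model
    trace.final_fit = current
    trace.final_ofv = current.ofv
    return trace
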