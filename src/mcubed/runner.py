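"""Replicated end-to-end M-cubed runs and their aggregation.

One replicate = generate virtual cohorts for every study, simulate and
pool the concentration records, fit the integrated base model, optionally
run the stepwise covariate search, and record the final estimates.  The
replicate loop derives independent child seeds from one master seed, so a
run is reproducible bit for bit, and summarizes the B estimate vectors by
their mean, standard deviation (the meta-analytic standard error),
and 5th/50th/95th percentiles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import as_seed_sequence, generate_cohorts
from .simulate import simulate_pooled, dataset_summary
from .nlme import (FitConfig, FitResult, PopModel, fit_population,
                   gof_quantities, initial_model)
from .covsearch import run_search

log = logging.getLogger("mcubed")

SUMMARY_PERCENTILES = (5.0, 50.0, 95.0)
UNRELIABLE_NONCONVERGENCE = 0.2


@dataclass
class ReplicateSummary:
    estimates: pd.DataFrame          # one row per converged replicate
    n_replicates: int
    n_converged: int
    counts: pd.DataFrame             # patients / observations / censored
    structure_counts: dict = field(default_factory=dict)
    unreliable: bool = False

    def table(self) -> pd.DataFrame:
        """Mean, SE (SD over replicates) and percentiles per parameter."""
        num = self.estimates.select_dtypes("number") \
            .drop(columns=["replicate"], errors="ignore")
        out = pd.DataFrame({"mean": num.mean(),
                            "se": num.std(ddof=1) if len(num) > 1
                            else np.nan})
        for p in SUMMARY_PERCENTILES:
            out[f"p{p:g}"] = num.quantile(p / 100.0)
        return out

    def to_json(self) -> str:
        doc = {"n_replicates": self.n_replicates,
               "n_converged": self.n_converged,
               "unreliable": self.unreliable,
               "structure_counts": self.structure_counts,
               "summary": json.loads(self.table().to_json(orient="index"))}
        return json.dumps(doc, indent=1)


def run_replicates(studies, B: int, master_seed, base: PopModel | None = None,
                   search: bool = False, fit_config: FitConfig | None = None,
                   effects=None) -> ReplicateSummary:
    """Run B independent full-pipeline replicates and aggregate.

    ``effects`` (a list of CovariateEffect templates, references resolved
    per replicate to the dataset median) fixes the covariate structure;
    ``search=True`` instead reruns the stepwise selection per replicate.
    Non-converged replicates are excluded from summaries and counted.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    fit_config = fit_config or FitConfig(compute_se=False, restarts=1)
    seeds = as_seed_sequence(master_seed).spawn(B)
    rows, counts, structures = [], [], {}
    n_converged = 0
    for b, seed in enumerate(seeds):
        ss = seed.spawn(2)
        cohorts = generate_cohorts(studies, ss[0])
        frame = simulate_pooled(studies, cohorts, ss[1])
        counts.append({"replicate": b, **dataset_summary(frame)})
        model = (base or initial_model(frame)).copy()
        try:
            if search:
                trace = run_search(frame, model, config=fit_config)
                fit = trace.final_fit
                structure = tuple(sorted(e.covariate
                                         for e in fit.model.effects))
            else:
                if effects is not None:
                    from dataclasses import replace as _rep
                    obs = frame[frame["EVID"] == 0]
                    resolved = []
                    for eff in effects:
                        ref = float(obs.groupby("ID")[eff.covariate]
                                    .first().median()) \
                            if eff.kind == "power" else 1.0
                        resolved.append(_rep(eff, reference=ref))
                    model.effects = resolved
                fit = fit_population(frame, model, fit_config)
                structure = tuple(sorted(e.covariate
                                         for e in fit.model.effects))
        except (ValueError, np.linalg.LinAlgError) as exc:
            log.warning("replicate %d failed: %s", b, exc)
            continue
        structures[structure] = structures.get(structure, 0) + 1
        if not fit.converged:
            log.info("replicate %d did not converge", b)
            continue
        n_converged += 1
        row = {"replicate": b, "ofv": fit.ofv, **fit.estimates}
        rows.append(row)
        log.info("replicate %d/%d done (OFV %.1f)", b + 1, B, fit.ofv)
    estimates = pd.DataFrame(rows)
    unreliable = (B - n_converged) / B > UNRELIABLE_NONCONVERGENCE
    return ReplicateSummary(
        estimates=estimates, n_replicates=B, n_converged=n_converged,
        counts=pd.DataFrame(counts),
        structure_counts={" + ".join(k) if k else "(none)": v
                          for k, v in structures.items()},
        unreliable=unreliable)


def gof_tables(fit: FitResult, frame: pd.DataFrame):
    """Goodness-of-fit table plus obs~pred regression summaries."""
    table = gof_quantities(fit.model, frame)
    summary = {}
    for col in ("PRED", "IPRED"):
        x = table[col].to_numpy()
        y = table["DV"].to_numpy()
        slope, intercept = np.polyfit(x, y, 1)
        summary[f"slope_obs_vs_{col.lower()}"] = float(slope)
        summary[f"intercept_obs_vs_{col.lower()}"] = float(intercept)
    summary["cwres_mean"] = float(table["CWRES"].mean())
    summary["cwres_sd"] = float(table["CWRES"].std(ddof=1))
    return table, summary


def aggregate_histograms(summary: ReplicateSummary, bins: int = 20) -> dict:
    """Plot-ready per-parameter histograms with percentile markers."""
    if summary.n_converged < 2:
        raise ValueError("need at least two converged replicates")
    out = {}
    num = summary.estimates.select_dtypes("number") \
        .drop(columns=["replicate"], errors="ignore")
    for col in num.columns:
        x = num[col].to_numpy()
        if np.allclose(x, x[0]):
            edges = np.array([x[0] - 0.5, x[0] + 0.5])
            hist = np.array([len(x)])
        else:
            hist, edges = np.histogram(x, bins=bins)
        frame = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                              "count": hist})
        frame.attrs["median"] = float(np.percentile(x, 50))
        frame.attrs["p5"] = float(np.percentile(x, 5))
        frame.attrs["p95"] = float(np.percentile(x, 95))
        out[col] = frame
    return out
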