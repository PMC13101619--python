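"""Monte-Carlo edge-recovery power study.

For a known ground-truth network and a grid of sample sizes, repeatedly
sample case-by-activity totals, run the full estimation pipeline, and score
the estimated edge set against the truth:

* sensitivity — fraction of true edges recovered;
* specificity — fraction of true non-edges correctly excluded;
* weight correlation — Pearson correlation between true and estimated
  partial correlations over the true edges.

Sensitivity is defined on the thresholded edge set (post-``tau``), because
that is the network a study would report.  With no true edges, sensitivity is
undefined and reported as NaN.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import CareNetError, EmptyMatrixError
from .inference import fit_pipeline
from .metrics import max_edges
from .preprocess import filter_activities
from .synthetic import GroundTruth, SyntheticSpec, sample_case_totals


def recovery_scores(
    estimated: dict[frozenset, float],
    gt: GroundTruth,
) -> dict[str, float]:
    """Score an estimated edge set against the ground truth.

    ``estimated`` maps unordered label pairs to estimated signed weights
    (e.g. :meth:`carenet.inference.CareNetwork.edge_weights`).
    """
    true_edges = gt.true_edges
    possible = max_edges(gt.n_activities)
    n_true = len(true_edges)
    n_nonedges = possible - n_true

    tp = sum(1 for e in estimated if e in true_edges)
    fp = len(estimated) - tp
    sensitivity = tp / n_true if n_true else float("nan")
    specificity = 1.0 - fp / n_nonedges if n_nonedges else float("nan")

    common = [e for e in true_edges if e in estimated]
    if len(common) >= 2:
        w_true = np.array([true_edges[e] for e in common])
        w_est = np.array([estimated[e] for e in common])
        if w_true.std() > 0 and w_est.std() > 0:
            weight_corr = float(np.corrcoef(w_true, w_est)[0, 1])
        else:
            weight_corr = float("nan")
    else:
        weight_corr = float("nan")
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "weight_correlation": weight_corr,
        "n_edges_est": len(estimated),
        "n_edges_true": n_true,
    }


def run_power(
    gt: GroundTruth,
    spec: SyntheticSpec,
    sizes: list[int],
    reps: int,
    lam: float = 0.05,
    tau: float = 0.15,
    seed: int = 0,
    min_prevalence: float = 0.0,
) -> pd.DataFrame:
    """One pipeline fit per (sample size, replicate); returns the raw table.

    Each replicate uses an independent, reproducible random stream derived
    from ``seed``.  Sample sizes below 10 cases per activity trigger a
    warning (estimates there are fragile by construction).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    small = [n for n in sizes if n < 10 * gt.n_activities]
    if small:
        warnings.warn(
            f"sample sizes {small} are below 10 cases per activity "
            f"({gt.n_activities} activities); recovery may be unstable",
            stacklevel=2,
        )
    rows = []
    for n in sizes:
        for rep in range(reps):
            rng = np.random.default_rng(np.random.SeedSequence((seed, n, rep)))
            m = sample_case_totals(gt, spec.with_(n_cases=int(n)), rng=rng)
            try:
                m, _ = filter_activities(m, min_prevalence=min_prevalence)
                _, net = fit_pipeline(m, lam=lam, tau=tau)
                estimated = net.edge_weights()
            except (EmptyMatrixError, CareNetError):
                estimated = {}
            scores = recovery_scores(estimated, gt)
            rows.append({"n": int(n), "rep": rep, "seed": seed, **scores})
    return pd.DataFrame(rows)


def summarize_power(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and Monte-Carlo standard error per sample size.

    The SE of a single replicate is NaN (not estimable).
    """
    if len(results) == 0:
        raise ValueError("empty results table")

    def _agg(g: pd.DataFrame) -> pd.Series:
        out = {}
        for col in ("sensitivity", "specificity", "weight_correlation"):
            vals = g[col].dropna()
            out[f"{col}_mean"] = vals.mean() if len(vals) else float("nan")
            out[f"{col}_se"] = (
                vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else float("nan")
            )
        out["n_reps"] = len(g)
        return pd.Series(out)

    summary = results.groupby("n", sort=True).apply(_agg, include_groups=False)
    summary["n_reps"] = summary["n_reps"].astype(int)
    return summary
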