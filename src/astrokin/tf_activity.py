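"""Transcription-factor activity inference by univariate linear models.

For each TF, genome-wide gene statistics y (t-values or log2FCs) are
regressed on that TF's regulon weight vector x (signed weights for targets,
zero elsewhere) with an intercept; the t-statistic of the slope (N-2 df) is
the activity score. Positive scores mean the TF's targets move with their
weights (activation); negative scores mean they move against them
(inhibition). This is the ULM convention: the t-statistic is scale-free in y
and invariant to adding a constant to all gene statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: score assigned (with capped=True) when the fit is exact and SE -> 0
SCORE_CAP = 1e6


@dataclass(frozen=True)
class TFActivity:
    tf_id: str
    score: float
    n_targets: int
    capped: bool = False

    @property
    def direction(self) -> str:
        return "activated" if self.score > 0 else "deactivated"


def ulm_score(gene_stats: pd.Series, regulons: pd.DataFrame,
              min_targets: int = 5) -> pd.DataFrame:
    """Score every TF in `regulons` against `gene_stats`.

    gene_stats: Series indexed by gene id. regulons: (source, target, weight)
    rows. TFs with fewer than min_targets covered targets, or an all-zero
    weight vector, are skipped with a warning. Returns a DataFrame
    (tf, score, n_targets, direction, capped) sorted by tf.
    """
    y = gene_stats.astype(float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 genes to fit a univariate model")
    gene_index = {g: i for i, g in enumerate(y.index)}
    yv = y.to_numpy()

    tf_ids = sorted(regulons["source"].unique())
    tf_index = {t: j for j, t in enumerate(tf_ids)}
    X = np.zeros((n, len(tf_ids)))
    counts = np.zeros(len(tf_ids), dtype=int)
    for tf, target, w in regulons[["source", "target", "weight"]].itertuples(index=False):
        gi = gene_index.get(target)
        if gi is not None:
            X[gi, tf_index[tf]] = float(w)
            counts[tf_index[tf]] += 1

    # columnwise OLS with intercept: slope, SE, t in closed form
    sx = X.sum(axis=0)
    sxx = (X ** 2).sum(axis=0)
    sxy = X.T @ yv
    sy, syy = yv.sum(), float(yv @ yv)
    ssx = sxx - sx ** 2 / n  # centered sum of squares of x
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (sxy - sx * sy / n) / ssx
        intercept = (sy - slope * sx) / n
        sse = syy - intercept * sy - slope * sxy
        sse = np.maximum(sse, 0.0)
        se = np.sqrt(sse / (n - 2) / ssx)
        t = slope / se

    rows = []
    skipped = []
    for tf in tf_ids:
        j = tf_index[tf]
        if ssx[j] == 0:  # all-zero (or constant) weight vector
            skipped.append(tf)
            continue
        if counts[j] < min_targets:
            skipped.append(tf)
            continue
        score, capped = float(t[j]), False
        if not np.isfinite(score):
            score, capped = float(np.sign(slope[j]) * SCORE_CAP), True
        elif abs(score) > SCORE_CAP:
            score, capped = float(np.sign(score) * SCORE_CAP), True
        rows.append({"tf": tf, "score": score, "n_targets": int(counts[j]),
                     "direction": "activated" if score > 0 else "deactivated",
                     "capped": capped})
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} TFs (under {min_targets} covered targets "
            f"or degenerate weights): {skipped[:5]}...", stacklevel=2)
    return pd.DataFrame(rows, columns=["tf", "score", "n_targets", "direction", "capped"])


def classify_tfs(activities: pd.DataFrame, score_min: float = 2.0
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split into activated (score >= score_min) and deactivated
    (score <= -score_min) lists, each ordered by |score| descending."""
    act = activities.loc[activities["score"] >= score_min].copy()
    deact = activities.loc[activities["score"] <= -score_min].copy()
    key = lambda df: df.reindex(
        df["score"].abs().sort_values(ascending=False, kind="mergesort").index
    ).reset_index(drop=True)
    return key(act), key(deact)
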