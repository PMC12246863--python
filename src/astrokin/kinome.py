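"""Kinome-array processing and upstream-kinase inference.

A serine/threonine peptide chip is imaged at increasing camera exposures
(10-200 ms); the per-peptide signal is the OLS slope of intensity on
exposure, scaled by 100 and log2-transformed (floored at 1 so a flat or
negative slope maps to 0). Case-vs-control log2 fold changes per peptide
feed three independent upstream-kinase scorers:

* krsa           - Z-score of the observed significant-substrate count
                   against a random-resampling null (primary scorer);
* rank_enrichment_scorer - one-sided Fisher/hypergeometric enrichment of
                   substrates among significant peptides (KEA3-style stand-in);
* substrate_shift_scorer - one-sample t of substrate LFCs against zero
                   (UKA-style stand-in).

`harmonize` converts the scorer outputs to percentile ranks and quartiles
and assigns cross-scorer confidence tiers: high when all three put a kinase
in the top quartile; medium when the primary scorer has it in the top
quartile and both others in the top two; low otherwise.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .transcriptome import percentile_rank

#: |t| cap for degenerate zero-variance substrate shifts
T_CAP = 1e6


def peptide_signal(run: pd.DataFrame) -> pd.DataFrame:
    """Per-(peptide, sample, chip) log2 signal values.

    value = log2(max(slope * 100, 1)) with slope the OLS slope of intensity
    on exposure_ms (intercept included). Negative or flat slopes floor to a
    value of 0 and are flagged.
    """
    rows = []
    for (pep, sample, chip), grp in run.groupby(["peptide", "sample", "chip"], sort=True):
        x = grp["exposure_ms"].to_numpy(dtype=float)
        if np.unique(x).size < 2:
            raise ValueError(f"peptide {pep} sample {sample}: need >= 2 distinct exposures")
        y = grp["intensity"].to_numpy(dtype=float)
        slope = np.polyfit(x, y, 1)[0]
        scaled = slope * 100.0
        flagged = scaled < 1.0
        value = float(np.log2(max(scaled, 1.0)))
        rows.append({"peptide": pep, "sample": sample,
                     "group": grp["group"].iloc[0], "chip": chip,
                     "value": value, "flagged": bool(flagged)})
    return pd.DataFrame(rows)


def peptide_lfc(values: pd.DataFrame, lfc_cut: float = 0.2) -> pd.DataFrame:
    """Per-peptide case-vs-control log2 fold changes.

    A peptide's per-sample value is its mean over chips; lfc = mean(case) -
    mean(control); significance is the strict |lfc| > lfc_cut call. Per-chip
    LFCs are retained and the chip with the highest |LFC| is identified
    (waterfall-plot convention for triplicate chips).
    """
    per_sample = values.groupby(["peptide", "sample", "group"], sort=True)["value"].mean()
    per_chip = values.groupby(["peptide", "chip", "group"], sort=True)["value"].mean()
    rows = []
    for pep in sorted(values["peptide"].unique()):
        vs = per_sample.loc[pep]
        case = vs.xs("case", level="group").to_numpy()
        ctrl = vs.xs("control", level="group").to_numpy()
        lfc = float(case.mean() - ctrl.mean())
        chip_tab = per_chip.loc[pep].unstack("group")
        chip_lfcs = (chip_tab["case"] - chip_tab["control"]).dropna()
        if len(chip_lfcs):
            max_chip = chip_lfcs.abs().sort_values(ascending=False, kind="mergesort").index[0]
            chip_map = {str(c): float(v) for c, v in chip_lfcs.items()}
        else:
            max_chip, chip_map = None, {}
        rows.append({"peptide": pep,
                     "value_case": float(case.mean()),
                     "value_control": float(ctrl.mean()),
                     "lfc": lfc,
                     "significant": bool(abs(lfc) > lfc_cut),
                     "chip_lfcs": chip_map,
                     "max_lfc_chip": max_chip})
    return pd.DataFrame(rows)


def global_phospho_test(values_case, values_control) -> tuple[float, float]:
    """Welch two-sample t-test (two-tailed) on per-sample mean log2 signals."""
    a = np.asarray(values_case, dtype=float)
    b = np.asarray(values_control, dtype=float)
    if a.std(ddof=0) == 0 and b.std(ddof=0) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def krsa(sig_peptides: set[str], chip_peptides: set[str],
         kinase_map: dict[str, set[str]], n_iter: int = 2000,
         seed: int = 0) -> pd.DataFrame:
    """Random-sampling upstream-kinase analysis.

    Observed O_k = |sig ∩ substrates(k)|. The null redraws |sig| peptides
    uniformly without replacement from the chip n_iter times;
    Z_k = (O_k - mean_null) / sd_null. A zero-variance null leaves Z missing.
    Kinases with no substrates on the chip are excluded with a note.
    """
    if not sig_peptides <= chip_peptides:
        raise ValueError("significant peptides must be a subset of the chip")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    chip = sorted(chip_peptides)
    n_chip, n_sig = len(chip), len(sig_peptides)
    rng = np.random.default_rng(seed)

    kinases = sorted(kinase_map)
    member = np.zeros((len(kinases), n_chip), dtype=bool)
    keep = []
    for i, k in enumerate(kinases):
        subs = kinase_map[k] & chip_peptides
        if not subs:
            warnings.warn(f"kinase {k} has no substrates on the chip; excluded",
                          stacklevel=2)
            continue
        member[i] = np.isin(chip, sorted(subs))
        keep.append(i)

    sig_mask = np.isin(chip, sorted(sig_peptides))
    observed = member.astype(np.int64) @ sig_mask.astype(np.int64)

    # vectorized draws: first n_sig columns of random permutations
    draw_idx = np.argsort(rng.random((n_iter, n_chip)), axis=1)[:, :n_sig]
    draws = np.zeros((n_iter, n_chip), dtype=np.int64)
    draws[np.arange(n_iter)[:, None], draw_idx] = 1
    null_counts = draws @ member.T.astype(np.int64)  # n_iter x n_kinases

    mean_null = null_counts.mean(axis=0)
    sd_null = null_counts.std(axis=0, ddof=1)
    rows = []
    for i in keep:
        z = (observed[i] - mean_null[i]) / sd_null[i] if sd_null[i] > 0 else np.nan
        rows.append({"kinase": kinases[i],
                     "n_substrates": int(member[i].sum()),
                     "observed": int(observed[i]),
                     "null_mean": float(mean_null[i]),
                     "null_sd": float(sd_null[i]),
                     "z": float(z) if np.isfinite(z) else np.nan})
    return pd.DataFrame(rows, columns=["kinase", "n_substrates", "observed",
                                       "null_mean", "null_sd", "z"])


def rank_enrichment_scorer(peptide_stats: pd.DataFrame,
                           kinase_map: dict[str, set[str]]) -> pd.DataFrame:
    """Substrate-vs-significance enrichment per kinase.

    One-sided hypergeometric upper tail of the 2x2 (significant x substrate)
    table — identical to a one-sided Fisher exact test — BH-adjusted across
    kinases.
    """
    chip = set(peptide_stats["peptide"])
    sig = set(peptide_stats.loc[peptide_stats["significant"], "peptide"])
    rows = []
    for kinase in sorted(kinase_map):
        subs = kinase_map[kinase] & chip
        if not subs:
            continue
        a = len(sig & subs)
        p = float(stats.hypergeom.sf(a - 1, len(chip), len(subs), len(sig)))
        rows.append({"kinase": kinase, "overlap": a,
                     "n_substrates": len(subs), "pvalue": min(1.0, p)})
    out = pd.DataFrame(rows, columns=["kinase", "overlap", "n_substrates", "pvalue"])
    if len(out):
        from .enrichment import bh_adjust
        out["padj"] = bh_adjust(out["pvalue"])
    else:
        out["padj"] = []
    return out


def substrate_shift_scorer(peptide_stats: pd.DataFrame,
                           kinase_map: dict[str, set[str]],
                           min_substrates: int = 3) -> pd.DataFrame:
    """One-sample t of each kinase's substrate LFCs against 0; score = |t|."""
    lfc = peptide_stats.set_index("peptide")["lfc"]
    rows = []
    for kinase in sorted(kinase_map):
        subs = sorted(kinase_map[kinase] & set(lfc.index))
        if len(subs) < min_substrates:
            continue
        vals = lfc.loc[subs].to_numpy(dtype=float)
        capped = False
        if vals.std(ddof=1) == 0:
            if vals.mean() == 0:
                t, p = 0.0, 1.0
            else:
                t, p, capped = np.sign(vals.mean()) * T_CAP, 0.0, True
        else:
            t, p = stats.ttest_1samp(vals, 0.0)
        rows.append({"kinase": kinase, "n_substrates": len(subs),
                     "mean_lfc": float(vals.mean()), "t": float(t),
                     "abs_t": float(abs(t)), "pvalue": float(p), "capped": capped})
    return pd.DataFrame(rows, columns=["kinase", "n_substrates", "mean_lfc", "t",
                                       "abs_t", "pvalue", "capped"])


def quartile_of(percentiles: np.ndarray) -> np.ndarray:
    """Quartile 4 = top: pct > 0.75 -> 4, > 0.5 -> 3, > 0.25 -> 2, else 1."""
    pct = np.asarray(percentiles, dtype=float)
    return 1 + (pct > 0.25).astype(int) + (pct > 0.5).astype(int) + (pct > 0.75).astype(int)


def confidence_tier(q_primary: int, q_second: int, q_third: int) -> str:
    """Cross-scorer tier: high iff every quartile is 4; medium iff the
    primary scorer is quartile 4 and both others at least 3; else low."""
    if q_primary == 4 and q_second == 4 and q_third == 4:
        return "high"
    if q_primary == 4 and q_second >= 3 and q_third >= 3:
        return "medium"
    return "low"


def harmonize(score_tables: dict[str, pd.Series],
              higher_is_stronger: dict[str, bool],
              primary: str | None = None) -> pd.DataFrame:
    """Merge >= 3 per-kinase score tables into a consensus table.

    Each table is oriented so higher = stronger evidence, percentile-ranked
    within itself and binned into quartiles. Confidence follows
    `confidence_tier`, with the named primary scorer (default: first table)
    in the leading role. A kinase missing from any table gets a missing
    percentile there, confidence 'low', and a flag; mean_score averages the
    available percentiles.
    """
    names = list(score_tables)
    if len(names) < 3:
        raise ValueError("harmonize needs at least 3 score tables")
    primary = primary or names[0]
    if primary not in names:
        raise ValueError(f"primary scorer {primary!r} not among tables")

    pct_tables = {}
    for name in names:
        s = score_tables[name].astype(float)
        oriented = s if higher_is_stronger[name] else -s
        pct_tables[name] = pd.Series(percentile_rank(oriented.to_numpy()),
                                     index=oriented.index)

    all_kinases = sorted(set().union(*(s.index for s in pct_tables.values())))
    others = [n for n in names if n != primary][:2]
    rows = []
    for kinase in all_kinases:
        pcts = {n: (float(pct_tables[n].get(kinase, np.nan))) for n in names}
        quarts = {n: (int(quartile_of(np.array([p]))[0]) if np.isfinite(p) else None)
                  for n, p in pcts.items()}
        missing = any(q is None for q in quarts.values())
        if missing:
            conf = "low"
        else:
            conf = confidence_tier(quarts[primary], quarts[others[0]], quarts[others[1]])
        avail = [p for p in pcts.values() if np.isfinite(p)]
        row = {"kinase": kinase, "mean_score": float(np.mean(avail)),
               "confidence": conf, "flagged_missing": missing}
        for n in names:
            row[f"{n}_pct"] = pcts[n]
            row[f"{n}_quartile"] = quarts[n]
        rows.append(row)
    return pd.DataFrame(rows)
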