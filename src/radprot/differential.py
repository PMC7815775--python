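"""Differential-protein calling from isobaric-tag (iTRAQ) reporter ratios.

Each comparison group (II, III, IV) is quantified as reporter peak-area
ratios against the pooled reference group (label 114), measured in two
technical replicates.  Following the study design this module:

* imputes a third pseudo-replicate as the arithmetic mean of the two ratios,
* tests the log2-transformed triple against 0 with a one-sample Student t
  (df = 2),
* adjusts p-values per group with Benjamini-Hochberg,
* calls a protein *up* when fold change ≥ 1.2 and adjusted P ≤ 0.1,
  *down* when fold change ≤ 0.83 and adjusted P ≤ 0.1,
* reports %CV over the two real replicates as technical-variability QC,
* checks per-group normality of the log2 ratios with a Kolmogorov-Smirnov
  test (reported, not used to gate calls).

Zero-variance replicate pairs cannot be tested (the t statistic is
undefined); they are flagged ``testable = False`` with a NaN p-value rather
than reported as spuriously significant.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

FC_UP_DEFAULT = 1.2
FC_DOWN_DEFAULT = 0.83
ALPHA_ADJ_DEFAULT = 0.1


def impute_triplicate(r1: float, r2: float) -> tuple[float, float, float]:
    """Return (r1, r2, mean) — the mean ratio serves as the missing third
    technical replicate."""
    if r1 <= 0 or r2 <= 0:
        raise ValueError("ratios must be positive")
    return (r1, r2, (r1 + r2) / 2.0)


def protein_t_test(triple: Sequence[float]) -> float:
    """Two-sided one-sample t-test of log2(ratios) against 0, df = n-1.

    Returns NaN for a zero-variance (degenerate) triple; such proteins are
    "not testable" rather than p = 0.
    """
    x = np.log2(np.asarray(triple, dtype=float))
    if x.std(ddof=1) == 0.0:
        return float("nan")
    t, p = stats.ttest_1samp(x, 0.0)
    return float(p)


def ks_normality(values: Iterable[float]) -> tuple[float, float]:
    """One-sample KS statistic of ``values`` against Normal(mean, sd) fit
    from the sample.  QC only."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 3 or not np.all(np.isfinite(x)):
        raise ValueError("need at least 3 finite values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate (constant) sample")
    stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(stat), float(p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved.

    p_(i) * m / i with a cumulative minimum from the largest p downward,
    capped at 1.  Ties are broken by stable sort on input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d sequence of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def classify(
    fold_change: float,
    p_adj: float,
    fc_up: float = FC_UP_DEFAULT,
    fc_down: float = FC_DOWN_DEFAULT,
    alpha: float = ALPHA_ADJ_DEFAULT,
) -> str:
    """'up' / 'down' / 'unchanged' per the ratio-and-adjusted-P rule."""
    if not np.isfinite(fold_change) or fold_change <= 0:
        raise ValueError("fold change must be positive and finite")
    if np.isnan(p_adj):  # not testable
        return "unchanged"
    if fold_change >= fc_up and p_adj <= alpha:
        return "up"
    if fold_change <= fc_down and p_adj <= alpha:
        return "down"
    return "unchanged"


def percent_cv(replicates: Sequence[float]) -> float:
    """100 × sample sd / mean over the technical replicates.

    Computed on the real replicates only — including the imputed mean value
    would deflate the CV artificially.
    """
    x = np.asarray(replicates, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 replicates")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("mean must be positive")
    return float(100.0 * x.std(ddof=1) / mean)


def call_differential(
    quant: pd.DataFrame,
    fc_up: float = FC_UP_DEFAULT,
    fc_down: float = FC_DOWN_DEFAULT,
    alpha: float = ALPHA_ADJ_DEFAULT,
    n_replicates: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group differential calls from a long quant table.

    Parameters
    ----------
    quant
        Columns ``protein_id, group, replicate, ratio`` (ratio vs the
        reference channel, strictly positive).

    Returns
    -------
    calls, qc
        ``calls``: one row per (protein, group) with fold_change, log2_fc,
        p_raw, p_adj, cv_percent, status, testable.  ``qc``: per group the
        number of proteins excluded for missing replicates and the KS
        normality check on the log2 fold changes.
    """
    required = {"protein_id", "group", "replicate", "ratio"}
    if not required <= set(quant.columns):
        raise ValueError(f"quant table must have columns {sorted(required)}")
    if (quant["ratio"] <= 0).any():
        raise ValueError("all ratios must be positive")
    if quant.duplicated(["protein_id", "group", "replicate"]).any():
        raise ValueError("(protein, group, replicate) must be unique")

    calls_frames = []
    qc_rows = []
    for group, sub in quant.groupby("group", sort=True):
        wide = sub.pivot(index="protein_id", columns="replicate", values="ratio")
        complete = wide.dropna()
        n_excluded = len(wide) - len(complete)
        if complete.shape[1] != n_replicates:
            raise ValueError(
                f"group {group}: expected {n_replicates} replicates, "
                f"found {complete.shape[1]}"
            )
        r = complete.to_numpy()
        fc = r.mean(axis=1)
        log2_fc = np.log2(fc)
        # vectorised one-sample t on the log2 triple (two reps + imputed mean)
        triple = np.log2(np.column_stack([r, r.mean(axis=1)]))
        m = triple.mean(axis=1)
        sd = triple.std(axis=1, ddof=1)
        n = triple.shape[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = m / (sd / np.sqrt(n))
        p_raw = 2.0 * stats.t.sf(np.abs(tstat), df=n - 1)
        degenerate = sd == 0.0
        p_raw[degenerate] = np.nan

        p_adj = np.full_like(p_raw, np.nan)
        ok = ~np.isnan(p_raw)
        if ok.any():
            p_adj[ok] = bh_adjust(p_raw[ok])

        cv = 100.0 * r[:, :n_replicates].std(axis=1, ddof=1) / r[:, :n_replicates].mean(axis=1)
        status = [classify(f, pa, fc_up, fc_down, alpha) for f, pa in zip(fc, p_adj)]
        calls_frames.append(
            pd.DataFrame(
                {
                    "protein_id": complete.index,
                    "group": group,
                    "fold_change": fc,
                    "log2_fc": log2_fc,
                    "p_raw": p_raw,
                    "p_adj": p_adj,
                    "cv_percent": cv,
                    "status": status,
                    "testable": ~degenerate,
                }
            )
        )
        try:
            ks_stat, ks_p = ks_normality(log2_fc)
        except ValueError:
            ks_stat, ks_p = float("nan"), float("nan")
        qc_rows.append(
            {
                "group": group,
                "n_tested": len(complete),
                "n_excluded_missing": n_excluded,
                "n_not_testable": int(degenerate.sum()),
                "ks_stat_log2fc": ks_stat,
                "ks_p_log2fc": ks_p,
            }
        )
    calls = pd.concat(calls_frames, ignore_index=True)
    qc = pd.DataFrame(qc_rows)
    return calls, qc


def differential_sets(calls: pd.DataFrame) -> dict[str, set[str]]:
    """Per-group set of differentially regulated proteins (status != unchanged)."""
    sig = calls[calls["status"] != "unchanged"]
    return {
        g: set(sub["protein_id"]) for g, sub in sig.groupby("group", sort=True)
    }


def venn_partition(diff_sets: Mapping[str, set]) -> dict[str, int]:
    """Exclusive region counts of the Venn partition over the given sets.

    Keys are '&'-joined sorted group labels (e.g. 'II', 'II&III',
    'II&III&IV'); 3 groups give the 7 classic regions.  Counts sum to the
    size of the union.
    """
    groups = sorted(diff_sets)
    if len(set(groups)) != len(list(diff_sets)):
        raise ValueError("group labels must be distinct")
    regions: dict[str, int] = {}
    for k in range(1, len(groups) + 1):
        for inside in combinations(groups, k):
            outside = [g for g in groups if g not in inside]
            region = set.intersection(*(set(diff_sets[g]) for g in inside))
            for g in outside:
                region -= set(diff_sets[g])
            regions["&".join(inside)] = len(region)
    return regions


def volcano_table(calls: pd.DataFrame) -> pd.DataFrame:
    """log2 fold change vs −log10 adjusted P, with status — volcano-plot data."""
    out = calls[["protein_id", "group", "log2_fc", "status"]].copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p_adj"] = -np.log10(calls["p_adj"])
    return out
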