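"""Relative qPCR quantification by the Livak–Schmittgen 2^−ΔΔCt method.

Target-gene threshold cycles (Ct) are normalised to the arithmetic mean Ct
of two reference genes (equivalent to the geometric mean of their linear
quantities), then to the mean ΔCt of the calibrator group:

    ΔCt  = Ct_target − mean(Ct_refs)
    ΔΔCt = ΔCt − mean(ΔCt | calibrator group)
    fold = 2^−ΔΔCt

Amplification efficiency is assumed perfect (factor 2 per cycle).  Reference
gene stability is validated first (Ct spread across samples); groups are
compared with a two-sample Student t-test on per-sample fold changes, with
mean ± SEM reported per group.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_CT_COLUMNS = {"sample", "group", "gene", "ct"}


def _check_ct_table(ct: pd.DataFrame) -> None:
    missing = _CT_COLUMNS - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if ct.duplicated(["sample", "gene"]).any():
        raise ValueError("(sample, gene) must be unique in the Ct table")
    if not np.all(np.isfinite(ct["ct"])) or (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be finite and positive")


def reference_stability(
    ct: pd.DataFrame,
    ref_genes: Sequence[str],
    sd_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-reference-gene Ct spread across all samples.

    A gene passes when the sample sd of its Ct is at or below the threshold
    (default 1 cycle).  Failure is reported, not fatal — the caller decides.
    """
    _check_ct_table(ct)
    rows = []
    for gene in ref_genes:
        sub = ct.loc[ct["gene"] == gene, "ct"]
        if sub.empty:
            raise ValueError(f"reference gene {gene} absent from Ct table")
        if len(sub) < 3:
            raise ValueError(f"reference gene {gene}: need ≥ 3 samples, got {len(sub)}")
        sd = float(sub.std(ddof=1))
        rows.append(
            {
                "gene": gene,
                "n": len(sub),
                "mean_ct": float(sub.mean()),
                "sd_ct": sd,
                "cv_percent": 100.0 * sd / float(sub.mean()),
                "stable": sd <= sd_threshold,
            }
        )
        if sd > sd_threshold:
            logger.warning("reference gene %s unstable: sd(Ct)=%.2f > %.2f",
                           gene, sd, sd_threshold)
    return pd.DataFrame(rows)


def ddct(
    ct: pd.DataFrame,
    target: str,
    ref_genes: Sequence[str],
    calibrator_group: str = "I",
) -> pd.DataFrame:
    """Per-sample 2^−ΔΔCt fold changes for one target gene.

    Samples missing the target or any reference gene are excluded with a log
    entry.  The calibrator is the *mean* ΔCt of the calibrator group, so the
    calibrator-group fold changes average exactly 1 on the log scale.
    """
    _check_ct_table(ct)
    wide = ct.pivot(index="sample", columns="gene", values="ct")
    groups = ct.drop_duplicates("sample").set_index("sample")["group"]
    needed = [target, *ref_genes]
    for gene in needed:
        if gene not in wide.columns:
            raise ValueError(f"gene {gene} absent from Ct table")
    complete = wide[needed].dropna()
    dropped = set(wide.index) - set(complete.index)
    for s in sorted(dropped):
        logger.info("sample %s missing %s measurements; excluded", s, target)
    if calibrator_group not in set(groups.loc[complete.index]):
        raise ValueError(f"no calibrator-group ({calibrator_group}) samples for {target}")
    dct = complete[target] - complete[list(ref_genes)].mean(axis=1)
    calibrator_mean = dct[groups.loc[complete.index] == calibrator_group].mean()
    ddct_vals = dct - calibrator_mean
    out = pd.DataFrame(
        {
            "sample": complete.index,
            "group": groups.loc[complete.index].to_numpy(),
            "gene": target,
            "delta_ct": dct.to_numpy(),
            "delta_delta_ct": ddct_vals.to_numpy(),
            "fold_change": np.power(2.0, -ddct_vals.to_numpy()),
        }
    ).reset_index(drop=True)
    return out


def group_compare(
    folds: pd.DataFrame,
    calibrator_group: str = "I",
) -> pd.DataFrame:
    """Mean ± SEM fold change per group, with Student's t vs the calibrator.

    Identical group means give p = 1 by convention; unequal means with zero
    variance in both groups are flagged degenerate (p = NaN).  Single-sample
    groups are rejected (SEM undefined).
    """
    if not {"group", "fold_change"} <= set(folds.columns):
        raise ValueError("folds table needs 'group' and 'fold_change' columns")
    cal = folds.loc[folds["group"] == calibrator_group, "fold_change"].to_numpy()
    if cal.size == 0:
        raise ValueError(f"calibrator group {calibrator_group} absent")
    rows = []
    for group, sub in folds.groupby("group", sort=True):
        x = sub["fold_change"].to_numpy()
        if x.size < 2:
            raise ValueError(f"group {group}: need ≥ 2 samples for SEM")
        degenerate = False
        if group == calibrator_group:
            p = float("nan")
        elif np.isclose(x.mean(), cal.mean()):
            p = 1.0
        elif x.std(ddof=1) == 0 and cal.std(ddof=1) == 0:
            p = float("nan")
            degenerate = True
            logger.warning("group %s vs %s: zero variance, t-test undefined",
                           group, calibrator_group)
        else:
            _, p = stats.ttest_ind(x, cal, equal_var=True)
            p = float(p)
        rows.append(
            {
                "group": group,
                "n": int(x.size),
                "mean_fold": float(x.mean()),
                "sem": float(stats.sem(x, ddof=1)),
                "p": p,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def analyze_expression(
    ct: pd.DataFrame,
    targets: Sequence[str],
    ref_genes: Sequence[str],
    calibrator_group: str = "I",
) -> pd.DataFrame:
    """Full 2^−ΔΔCt analysis for a panel of target genes.

    Returns one row per (gene, group): mean fold change, SEM, n, and the
    t-test p-value against the calibrator group.
    """
    frames = []
    for target in targets:
        folds = ddct(ct, target, ref_genes, calibrator_group)
        res = group_compare(folds, calibrator_group)
        res.insert(0, "gene", target)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
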