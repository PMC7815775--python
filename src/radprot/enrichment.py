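"""Fisher's-exact over-representation of differential proteins in annotation
terms (GMT term sets), generic over any annotation source.

The test is one-sided (over-representation): with N background proteins, K of
them in a term, and n selected (differential) proteins of which k fall in the
term, p = P(X ≥ k) for X ~ Hypergeometric(N, K, n).  The background universe
is the set of quantifiable proteins in the experiment, not the whole
proteome.  Significance is called at unadjusted p ≤ alpha (the DAVID-style
convention); a BH-adjusted column is emitted alongside for transparency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .differential import bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationTerm:
    term_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"term {self.term_id} has no members")


def fisher_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X ≥ k)."""
    if not (0 <= k <= min(n, K) and K <= N and n <= N):
        raise ValueError("inconsistent 2x2 table margins")
    return float(hypergeom.sf(k - 1, N, K, n))


def fisher_enrich(
    selected: Iterable[str],
    background: Iterable[str],
    terms: Sequence[AnnotationTerm],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of ``selected`` within each term, against
    ``background``.

    Terms are intersected with the background before testing; terms with no
    background overlap are skipped (logged).  Rows are sorted by ascending p,
    ties broken by term_id, so output is invariant to input term order.
    """
    sel = set(selected)
    bg = set(background)
    if not sel or not bg:
        raise ValueError("selected and background must be non-empty")
    if not sel <= bg:
        raise ValueError("selected proteins must be a subset of the background")
    N = len(bg)
    n = len(sel)
    rows = []
    for term in terms:
        members = term.members & bg
        K = len(members)
        if K == 0:
            logger.info("term %s has no background overlap; skipped", term.term_id)
            continue
        k = len(members & sel)
        p = fisher_pvalue(k, n, K, N)
        rows.append(
            {
                "term_id": term.term_id,
                "name": term.name,
                "overlap_k": k,
                "selected_n": n,
                "term_K": K,
                "background_N": N,
                "p": p,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "name", "overlap_k", "selected_n", "term_K",
                     "background_N", "p", "p_bh", "significant"]
        )
    out = pd.DataFrame(rows).sort_values(["p", "term_id"], kind="stable")
    out = out.reset_index(drop=True)
    out["p_bh"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p"] <= alpha
    return out


def comparative_matrix(per_group: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Term × group matrix of −log10 p — the 'comparative heat' layout used
    to display enrichment trends across dose groups."""
    import numpy as np

    frames = {}
    for group, df in per_group.items():
        frames[group] = df.set_index("term_id")["p"].apply(
            lambda p: -np.log10(p) if p > 0 else np.inf
        )
    return pd.DataFrame(frames).sort_index()
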