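"""Fisher overrepresentation of protein sets, term ranking, and set overlap.

Cluster memberships are tested against annotation term sets (GMT-style,
e.g. GO cellular-component) by the one-sided Fisher exact test — the
hypergeometric upper tail of drawing at least k term members into the query —
with BH-FDR across terms and significance at FDR < 0.05.  Term ranking uses a
combined score of significance and effect size, and 2x2 set-overlap questions
(Venn + two-sided Fisher) are answered against an explicit universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["TermMap", "OverlapResult", "fisher_ora", "rank_terms", "overlap_test"]

logger = logging.getLogger(__name__)


@dataclass
class TermMap:
    """Annotation term collection: term id -> member protein set (+ name)."""

    sets: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [t for t, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"empty term sets: {empty}")
        self.sets = {t: frozenset(s) for t, s in self.sets.items()}
        for t in self.sets:
            self.names.setdefault(t, t)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


@dataclass
class OverlapResult:
    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int
    odds_ratio: float
    pvalue: float


def fisher_ora(
    query: set[str],
    background: set[str],
    terms: TermMap,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher overrepresentation of ``query`` against each term.

    Per term: k = query hits, n = query size, K = background hits, N =
    background size; p = hypergeometric upper tail P(X >= k); fold enrichment
    (k/n)/(K/N); BH-FDR across tested terms and a significance flag at
    ``FDR < alpha``.  Terms with no background members are excluded (logged).
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    if not query:
        raise ValueError("empty query set")
    n, N = len(query), len(background)
    rows = []
    for term in sorted(terms.sets):
        members = terms.sets[term] & background
        K = len(members)
        if K == 0:
            logger.info("term %s has no background members; excluded", term)
            continue
        k = len(members & query)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N)
        rows.append(
            {
                "term": term,
                "name": terms.names.get(term, term),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "fold_enrichment": fold,
                "pvalue": p,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["fdr"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < alpha
    return out


def rank_terms(rows: pd.DataFrame, top_n: int = 4) -> pd.DataFrame:
    """Order enrichment rows by the combined FDR / fold-enrichment score.

    score = (-log10 FDR) x log2(fold enrichment); descending, ties broken by
    term id for stability; the top ``top_n`` rows are returned.
    """
    if rows.empty:
        raise ValueError("no enrichment rows to rank")
    out = rows.copy()
    fold = out["fold_enrichment"].to_numpy(float)
    # floor the FDR so a numerically zero p-value still yields a finite score
    neglog_fdr = -np.log10(np.clip(out["fdr"].to_numpy(float), 1e-300, None))
    score = np.full(fold.size, -np.inf)
    pos = fold > 0
    score[pos] = neglog_fdr[pos] * np.log2(fold[pos])
    out["combined_score"] = score
    out = out.sort_values(
        ["combined_score", "term"], ascending=[False, True], kind="stable"
    )
    return out.head(top_n).reset_index(drop=True)


def overlap_test(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> OverlapResult:
    """Venn counts and two-sided Fisher exact association of two sets.

    The 2x2 table is {A&B, A\\B, B\\A, universe\\(A|B)}; the odds ratio is the
    sample (cross-product) odds ratio.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    set_a, set_b = set(set_a), set(set_b)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("A and B must be subsets of the universe")
    both = len(set_a & set_b)
    a_only = len(set_a - set_b)
    b_only = len(set_b - set_a)
    neither = len(universe) - both - a_only - b_only
    odds, p = sps.fisher_exact(
        [[both, a_only], [b_only, neither]], alternative="two-sided"
    )
    return OverlapResult(both, a_only, b_only, neither, float(odds), float(p))
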