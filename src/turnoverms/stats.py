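"""Protein rollup, NSAF abundance, group statistics and differential tests.

This stage turns peptide-level areas into protein FA matrices and asks the
study's statistical questions: do FA distributions differ across age groups
(one-way ANOVA + Tukey, or Kruskal-Wallis + Dunn), between proteasome
complexes (two-way ANOVA complex x age), and which proteins change abundance
between treatment arms (per-protein Welch t with BH-FDR, volcano-style
classification).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .matrix import FaMatrix, make_sample_table
from .ms1 import PeptideTurnover

__all__ = [
    "ComplexDefinition",
    "StatResult",
    "PROTEASOME_COMPLEXES",
    "rollup",
    "nsaf",
    "compare_groups",
    "median_adjust",
    "complex_compare",
    "diff_abundance",
]


@dataclass(frozen=True)
class ComplexDefinition:
    """A named protein complex given by its member gene symbols."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"complex {self.name!r} has no members")


#: packaged 26S proteasome sub-complex definitions (mouse gene symbols)
PROTEASOME_COMPLEXES: dict[str, ComplexDefinition] = {
    "20S": ComplexDefinition(
        "20S",
        frozenset(
            [f"Psma{i}" for i in range(1, 8)] + [f"Psmb{i}" for i in range(1, 8)]
        ),
    ),
    "19S": ComplexDefinition(
        "19S",
        frozenset(
            [f"Psmc{i}" for i in range(1, 7)] + [f"Psmd{i}" for i in range(1, 15)]
        ),
    ),
    "catalytic": ComplexDefinition(
        "catalytic", frozenset({"Psmb1", "Psmb2", "Psmb5"})
    ),
}


@dataclass
class StatResult:
    test: str
    statistic: float
    pvalue: float
    posthoc: pd.DataFrame | None = None
    adjustment: str | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# rollup and abundance


def rollup(
    peptides: list[PeptideTurnover] | pd.DataFrame,
    sample_of: dict[str, str] | pd.Series | None = None,
    sample_meta: dict[str, dict] | None = None,
    min_replicates: int = 0,
    group_by: str = "age",
) -> FaMatrix:
    """Area-weighted peptide-to-protein rollup of fractional abundance.

    Protein FA in a sample is ``sum(I_old) / (sum(I_old) + sum(I_new))`` over
    that protein's unflagged peptides, i.e. peptides contribute in proportion
    to their chromatographic area.  ``peptides`` is either a DataFrame with
    columns ``protein, sample, i_old, i_new`` (optional ``flags``) or a list
    of :class:`PeptideTurnover` plus a ``sample_of`` map from peptide id to
    sample.  With ``min_replicates > 0``, a protein quantified in fewer than
    that many samples of a metadata group (default grouping: age) is blanked
    in that whole group.
    """
    if isinstance(peptides, pd.DataFrame):
        df = peptides.copy()
    else:
        if sample_of is None:
            raise ValueError("sample_of is required with PeptideTurnover rows")
        df = pd.DataFrame(
            {
                "protein": [p.protein for p in peptides],
                "sample": [sample_of[p.peptide_id] for p in peptides],
                "i_old": [p.i_old for p in peptides],
                "i_new": [p.i_new for p in peptides],
                "flags": [";".join(p.flags) for p in peptides],
            }
        )
    if df.empty:
        raise ValueError("no peptides to roll up")
    if "flags" in df.columns:
        df = df[df["flags"].fillna("").astype(str) == ""]
    if df.empty:
        raise ValueError("all peptides flagged; nothing to roll up")

    sums = df.groupby(["protein", "sample"])[["i_old", "i_new"]].sum()
    total = sums["i_old"] + sums["i_new"]
    fa = (sums["i_old"] / total.where(total > 0)).unstack("sample")

    records = [
        {"sample": s, **((sample_meta or {}).get(s, {}))} for s in fa.columns
    ]
    out = FaMatrix(fa, make_sample_table(records))
    if min_replicates > 0:
        meta = out.samples
        for gval in meta[group_by].dropna().unique():
            cols = meta.index[meta[group_by] == gval]
            counts = out.values[cols].notna().sum(axis=1)
            out.values.loc[counts < min_replicates, cols] = np.nan
    return out


def nsaf(spectral_counts: pd.Series, lengths: pd.Series) -> pd.Series:
    """Normalized spectral abundance factor per protein.

    NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j); the result sums to one.
    """
    counts = spectral_counts.astype(float)
    lens = lengths.reindex(counts.index).astype(float)
    if (counts < 0).any():
        raise ValueError("negative spectral count")
    if (lens <= 0).any() or lens.isna().any():
        raise ValueError("protein lengths must be positive for every protein")
    saf = counts / lens
    total = saf.sum()
    if total == 0:
        raise ValueError("all spectral counts are zero")
    return saf / total


# ---------------------------------------------------------------------------
# group comparisons


def _dunn_posthoc(groups: dict, adjust: str = "fdr_bh") -> pd.DataFrame:
    """Dunn's rank-based post-hoc z tests with tie correction."""
    labels = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], float) for g in labels])
    sizes = {g: len(groups[g]) for g in labels}
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_rank = {}
    start = 0
    for g in labels:
        mean_rank[g] = ranks[start : start + sizes[g]].mean()
        start += sizes[g]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group1": a, "group2": b, "statistic": z, "pvalue": p})
    out = pd.DataFrame(rows)
    out["adjusted_p"] = multipletests(out["pvalue"], method=adjust)[1]
    return out


def _tukey_posthoc(groups: dict, on_ranks: bool = False) -> pd.DataFrame:
    labels = list(groups)
    values = np.concatenate([np.asarray(groups[g], float) for g in labels])
    codes = np.concatenate([[g] * len(groups[g]) for g in labels])
    if on_ranks:
        values = sps.rankdata(values)
    res = pairwise_tukeyhsd(values, codes)
    frame = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    frame = frame.rename(
        columns={"meandiff": "statistic", "p-adj": "adjusted_p"}
    )
    frame["pvalue"] = frame["adjusted_p"]
    return frame[["group1", "group2", "statistic", "pvalue", "adjusted_p"]]


def _as_groups(
    m: FaMatrix | dict, by: str, values_row: str | None
) -> dict[str, np.ndarray]:
    if isinstance(m, dict):
        return {k: np.asarray(v, float) for k, v in m.items()}
    groups = {}
    for gval in sorted(m.samples[by].dropna().unique()):
        cols = m.sample_ids(**{by: gval})
        if values_row is not None:
            vals = m.values.loc[values_row, cols].to_numpy(float)
        else:
            vals = m.values[cols].to_numpy(float).ravel()
        groups[gval] = vals[np.isfinite(vals)]
    return groups


def compare_groups(
    m: FaMatrix | dict,
    by: str = "age",
    method: str = "anova",
    protein: str | None = None,
    posthoc: str | None = None,
) -> StatResult:
    """Omnibus group comparison with a pairwise post-hoc table.

    Methods: ``anova`` (one-way ANOVA, Tukey HSD post-hoc), ``kruskal``
    (Kruskal-Wallis; post-hoc Dunn with BH by default, ``posthoc="tukey_ranks"``
    for Tukey on rank-transformed data), ``welch`` / ``student`` (two-sample t
    tests, exactly two groups).  ``m`` is an :class:`FaMatrix` grouped by the
    metadata field ``by`` (one protein row if ``protein`` is given, otherwise
    all values pooled), or a plain ``{label: values}`` dict.
    """
    groups = _as_groups(m, by, protein)
    groups = {k: v for k, v in groups.items() if v.size > 0}
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    if any(v.size < 2 for v in groups.values()):
        raise ValueError("every group needs at least two observations")
    arrays = list(groups.values())

    if method == "anova":
        stat, p = sps.f_oneway(*arrays)
        table = _tukey_posthoc(groups)
        return StatResult("anova", float(stat), float(p), table, "tukey_hsd")
    if method == "kruskal":
        pooled = np.concatenate(arrays)
        if np.ptp(pooled) == 0:  # identical data: no evidence of difference
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.kruskal(*arrays)
        if posthoc == "tukey_ranks":
            table, adj = _tukey_posthoc(groups, on_ranks=True), "tukey_on_ranks"
        else:
            table, adj = _dunn_posthoc(groups), "dunn_bh"
        return StatResult("kruskal", float(stat), float(p), table, adj)
    if method in ("welch", "student"):
        if len(groups) != 2:
            raise ValueError("t tests require exactly two groups")
        a, b = arrays
        stat, p = sps.ttest_ind(a, b, equal_var=(method == "student"))
        return StatResult(method, float(stat), float(p))
    raise ValueError(f"unknown method {method!r}")


def two_way_anova(
    df: pd.DataFrame, value: str, factor_a: str, factor_b: str
) -> pd.DataFrame:
    """Type-II two-way ANOVA table (with interaction) via statsmodels OLS."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = df[[value, factor_a, factor_b]].dropna().copy()
    data.columns = ["y", "a", "b"]
    model = smf.ols("y ~ C(a) * C(b)", data=data).fit()
    return sm.stats.anova_lm(model, typ=2)


def median_adjust(m: FaMatrix, reference: object, by: str = "age") -> FaMatrix:
    """Subtract each protein's reference-group median FA from every sample.

    Centers trends on the reference age group (e.g. 12 months) so heatmaps
    show change relative to the start of the aging window.  Proteins with no
    finite value in the reference group become all-NaN (flagged out).  The
    result is a difference matrix, so downstream row z-scoring is unaffected
    by the centering choice.
    """
    ref_cols = m.sample_ids(**{by: reference})
    if not ref_cols:
        raise ValueError(f"reference group {reference!r} absent")
    ref_median = m.values[ref_cols].median(axis=1)
    values = m.values.sub(ref_median, axis=0)
    values[ref_median.isna()] = np.nan
    return FaMatrix(values, m.samples.copy(), kind="delta")


def complex_compare(
    m: FaMatrix,
    complexes: dict[str, ComplexDefinition] | None = None,
    pair: tuple[str, str] = ("19S", "20S"),
    by: str = "age",
) -> StatResult:
    """Compare pooled member FA between two complexes across age groups.

    Member FA values are pooled per complex; the omnibus test is a two-way
    ANOVA (complex x age), and per-age Welch t tests give the pairwise table.
    The sign of ``extra['mean_difference']`` is complex A minus complex B.
    """
    complexes = complexes or PROTEASOME_COMPLEXES
    name_a, name_b = pair
    rows = []
    for cname in pair:
        members = [p for p in complexes[cname].members if p in m.values.index]
        if len(members) < 2:
            raise ValueError(f"complex {cname!r} has fewer than 2 measured members")
        for sid in m.values.columns:
            for prot in members:
                val = m.values.at[prot, sid]
                if np.isfinite(val):
                    rows.append(
                        {"complex": cname, by: m.samples.at[sid, by], "fa": val}
                    )
    long = pd.DataFrame(rows)
    if long["fa"].nunique() == 1:  # degenerate: no variance anywhere
        return StatResult(
            "complex_two_way_anova", 0.0, 1.0, pd.DataFrame(),
            extra={"mean_difference": 0.0, "pair": pair},
        )
    anova = two_way_anova(long, "fa", "complex", by)
    stat = float(anova.loc["C(a)", "F"])
    p = float(anova.loc["C(a)", "PR(>F)"])

    pairwise = []
    is_a = long["complex"] == name_a
    is_b = long["complex"] == name_b
    for gval in sorted(long[by].unique()):
        in_g = long[by] == gval
        a = long.loc[is_a & in_g, "fa"]
        b = long.loc[is_b & in_g, "fa"]
        if len(a) >= 2 and len(b) >= 2:
            t, tp = sps.ttest_ind(a, b, equal_var=False)
            pairwise.append(
                {by: gval, "statistic": float(t), "pvalue": float(tp),
                 "mean_difference": float(a.mean() - b.mean())}
            )
    diff = float(long.loc[is_a, "fa"].mean() - long.loc[is_b, "fa"].mean())
    return StatResult(
        "complex_two_way_anova",
        stat,
        p,
        pd.DataFrame(pairwise),
        extra={"anova_table": anova, "mean_difference": diff, "pair": pair},
    )


def diff_abundance(
    abundance: pd.DataFrame,
    arm_a: list[str],
    arm_b: list[str],
    alpha: float = 0.05,
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Per-protein differential abundance between two arms (volcano input).

    Welch t test on log2 abundances, BH adjustment across proteins, and a
    three-way class: ``up`` (adjusted p < alpha, log2FC > 0, arm A higher),
    ``down`` (adjusted p < alpha, log2FC < 0) or ``ns``.  Zero-variance
    degenerate rows are flagged in the ``flag`` column and classed ``ns``.
    """
    if len(arm_a) < 2 or len(arm_b) < 2:
        raise ValueError("need >= 2 replicates per arm")
    log_a = np.log2(abundance[arm_a].to_numpy(float))
    log_b = np.log2(abundance[arm_b].to_numpy(float))
    log2fc = log_a.mean(axis=1) - log_b.mean(axis=1)
    flags = np.where(
        (log_a.std(axis=1) == 0) & (log_b.std(axis=1) == 0), "zero_variance", ""
    )
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # degenerate zero-variance rows are flagged and classed 'ns' below
        warnings.simplefilter("ignore", RuntimeWarning)
        tstat, pval = sps.ttest_ind(log_a, log_b, axis=1, equal_var=False)
    pval = np.where(np.isfinite(pval), pval, 1.0)
    adj = multipletests(pval, method=adjust)[1]
    cls = np.full(len(abundance), "ns", dtype=object)
    sig = (adj < alpha) & (flags == "")
    cls[sig & (log2fc > 0)] = "up"
    cls[sig & (log2fc < 0)] = "down"
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": tstat,
            "pvalue": pval,
            "adjusted_p": adj,
            "class": cls,
            "flag": flags,
        },
        index=abundance.index,
    )
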