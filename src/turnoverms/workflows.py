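"""End-to-end drivers chaining the pipeline stages.

These functions wire the stages together in the order a study runs them:
simulate (or load) -> quantify -> roll up -> adjust/z-score/cluster ->
enrich / compare.  They are what the CLI, the validation suite and the
reproduction script call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import enrich as _enrich
from . import simulate as _sim
from . import stats as _stats
from . import tmt as _tmt
from .matrix import FaMatrix
from .ms1 import CentroidSpectrum, extract_xic

__all__ = [
    "quantify_ms1_sample",
    "ms1_round_trip",
    "tmt_round_trip",
    "aging_trend_analysis",
    "cluster_enrichment",
    "inhibition_analysis",
]


def quantify_ms1_sample(
    spectra: list[CentroidSpectrum],
    species: pd.DataFrame,
    sample_id: str,
    ppm_tol: float = 10.0,
    rt_halfwidth: float = 10.0,
) -> pd.DataFrame:
    """Reconstruct XIC areas for every identified species in one run.

    Each species' theoretical isotopologue lines are integrated within
    ``+/- rt_halfwidth`` seconds of its elution apex and summed; the output
    has one row per peptide with ``i_old`` / ``i_new`` areas ready for
    :func:`turnoverms.stats.rollup`.
    """
    line_mz: list[np.ndarray] = []
    line_windows: list[np.ndarray] = []
    owner: list[int] = []
    for i, row in enumerate(species.itertuples(index=False)):
        mz = np.asarray(row.mz, dtype=float)
        line_mz.append(mz)
        win = np.tile([row.rt - rt_halfwidth, row.rt + rt_halfwidth], (mz.size, 1))
        line_windows.append(win)
        owner.extend([i] * mz.size)
    targets = np.concatenate(line_mz)
    windows = np.vstack(line_windows)
    results = extract_xic(spectra, targets, ppm_tol, target_windows=windows)

    areas = np.zeros(len(species))
    np.add.at(areas, np.asarray(owner), np.array([r.area for r in results]))
    table = species[["peptide_id", "protein", "pool"]].copy()
    table["area"] = areas
    wide = table.pivot_table(
        index=["peptide_id", "protein"], columns="pool", values="area", aggfunc="sum"
    ).reset_index()
    out = pd.DataFrame(
        {
            "peptide_id": wide["peptide_id"],
            "protein": wide["protein"],
            "sample": sample_id,
            "i_old": wide.get("old", 0.0),
            "i_new": wide.get("new", 0.0),
        }
    )
    total = out["i_old"] + out["i_new"]
    out["fa"] = out["i_old"] / total.where(total > 0)
    return out


def ms1_round_trip(
    truth: _sim.CohortTruth,
    noise_cv: float = 0.10,
    ppm_tol: float = 10.0,
    sim_trunc: float = 1e-3,
    min_replicates: int = 0,
    seed: int = 0,
    samples: list[str] | None = None,
) -> tuple[FaMatrix, FaMatrix]:
    """Simulate MS1 runs for a cohort and quantify them back to protein FA.

    Returns (estimated FaMatrix, realized-truth FaMatrix) on the same
    protein/sample grid.  Spectra are generated and quantified one sample at
    a time to bound memory.
    """
    species = _sim.species_table(
        truth.panel, truth.design.n15_enrichment, trunc=sim_trunc, seed=seed
    )
    sample_ids = list(samples) if samples is not None else list(truth.samples.index)
    peptide_frames = []
    for j, sid in enumerate(sample_ids):
        spectra = _sim.simulate_ms1_sample(
            truth, species, sid, noise_cv=noise_cv, seed=seed + 1000 + j
        )
        peptide_frames.append(
            quantify_ms1_sample(spectra, species, sid, ppm_tol=ppm_tol)
        )
    peptides = pd.concat(peptide_frames, ignore_index=True)
    meta = {
        sid: truth.samples.loc[sid].to_dict() for sid in sample_ids
    }
    estimate = _stats.rollup(
        peptides[["protein", "sample", "i_old", "i_new"]].assign(flags=""),
        sample_meta=meta,
        min_replicates=min_replicates,
    )
    truth_fa = truth.truth_matrix().subset(
        proteins=estimate.values.index, samples=sample_ids
    )
    estimate = estimate.subset(samples=sample_ids)
    return estimate, truth_fa


def tmt_round_trip(truth: _sim.CohortTruth, plexes: list[dict]) -> FaMatrix:
    """Normalize, bridge-align and compute channel FA for simulated plexes."""
    normalized = []
    for p in plexes:
        old_n, new_n = _tmt.normalize_split_pair(p["old"], p["new"])
        normalized.append({"plex": p["plex"], "old": old_n, "new": new_n})
    combined = [_tmt.combine_pools(p["old"], p["new"]) for p in normalized]
    factors = _tmt.bridge_scale(combined)
    meta = {sid: truth.samples.loc[sid].to_dict() for sid in truth.samples.index}
    pieces = []
    for p, f in zip(normalized, factors):
        old_b = _tmt.apply_bridge(p["old"], f)
        new_b = _tmt.apply_bridge(p["new"], f)
        pieces.append(_tmt.channel_fa(old_b, new_b, sample_meta=meta))
    values = pd.concat([piece.values for piece in pieces], axis=1)
    samples = pd.concat([piece.samples for piece in pieces], axis=0)
    order = [s for s in truth.samples.index if s in values.columns]
    return FaMatrix(values[order], samples.loc[order])


def aging_trend_analysis(
    fa: FaMatrix,
    reference_age: int = 12,
    k_range: tuple[int, int] = (2, 8),
    min_size: int = 10,
    seed: int = 0,
) -> dict:
    """Reference-adjusted, z-scored trend clustering of one cohort.

    Steps: subtract each protein's reference-age median FA, average replicates
    per age group, z-score rows, then k-means with silhouette-selected k.
    Returns the intermediate matrices, the fitted :class:`TrendClusterer` and
    a protein -> cluster label Series.
    """
    adjusted = _stats.median_adjust(fa, reference_age)
    profiles = FaMatrix(adjusted.values, adjusted.samples, kind="delta").group_means(
        "age"
    )
    profiles = profiles.dropna(axis=0)
    zscored = _cluster.zscore_rows(profiles)
    est = _cluster.TrendClusterer(
        k_range=k_range, min_cluster_size=min_size, random_state=seed
    ).fit(zscored.to_numpy())
    labels = pd.Series(est.labels_, index=zscored.index, name="cluster")
    return {
        "adjusted": adjusted,
        "profiles": profiles,
        "zscored": zscored,
        "clusterer": est,
        "labels": labels,
    }


def cluster_enrichment(
    labels: pd.Series,
    background: set[str],
    terms: _enrich.TermMap,
    top_n: int = 4,
) -> dict[int, pd.DataFrame]:
    """Per-cluster Fisher overrepresentation, ranked by the combined score."""
    out = {}
    for cl in sorted(labels.unique()):
        query = set(labels.index[labels == cl])
        rows = _enrich.fisher_ora(query, background, terms)
        out[int(cl)] = _enrich.rank_terms(rows, top_n=top_n)
    return out


def inhibition_analysis(
    study: _sim.InhibitionStudy, alpha: float = 0.05
) -> dict:
    """Statistics of the inhibitor arm: FA shift, volcano, overlap test.

    Welch t on pooled proteasome-subunit FA (treated vs vehicle, positive
    statistic means slower turnover under inhibition), per-protein
    differential abundance with BH-FDR, and the two-sided Fisher overlap of
    accumulated ("up") proteins with the proteasome-associated set.
    """
    sub = [g for g in study.subunits if g in study.fa.values.index]
    fa_treated = study.fa.values.loc[sub, study.treated].to_numpy().ravel()
    fa_vehicle = study.fa.values.loc[sub, study.vehicle].to_numpy().ravel()
    welch = _stats.compare_groups(
        {"marizomib": fa_treated[np.isfinite(fa_treated)],
         "vehicle": fa_vehicle[np.isfinite(fa_vehicle)]},
        method="welch",
    )
    volcano = _stats.diff_abundance(
        study.abundance, study.treated, study.vehicle, alpha=alpha
    )
    up = set(volcano.index[volcano["class"] == "up"])
    overlap = _enrich.overlap_test(
        up, set(study.substrates), set(study.abundance.index)
    )
    return {
        "welch": welch,
        "volcano": volcano,
        "up": up,
        "overlap": overlap,
        "mean_fa_shift": float(np.nanmean(fa_treated) - np.nanmean(fa_vehicle)),
    }
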