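"""Split-pool TMT reporter quantification of fractional abundance.

In the split-pool design the PSMs of one multiplexed run are divided by their
precursor label state (old = fully 14N, new = 15N-enriched) *before* reporter
quantification; each TMT channel is one animal, and the per-protein,
per-channel FA is the old-pool reporter sum over the old+new total.  Channels
are corrected for loading by total-intensity equalization, and plexes are
aligned on a shared bridge channel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .matrix import FaMatrix, make_sample_table

__all__ = [
    "ReporterMatrix",
    "normalize_total",
    "normalize_split_pair",
    "combine_pools",
    "bridge_scale",
    "apply_bridge",
    "channel_fa",
]


@dataclass
class ReporterMatrix:
    """PSM-level reporter intensities for one plex and one precursor pool.

    ``data`` columns: ``psm_id``, ``protein`` plus one column per channel.
    ``channel_map`` maps channel -> sample id (the bridge channel maps to the
    shared reference and is excluded from FA output).
    """

    data: pd.DataFrame
    channels: list[str]
    plex: str
    channel_map: dict[str, str]
    bridge: str
    pool: str  # "old" | "new"

    def __post_init__(self) -> None:
        missing = [c for c in ["protein", *self.channels] if c not in self.data.columns]
        if missing:
            raise ValueError(f"reporter table missing columns: {missing}")
        if self.bridge not in self.channels:
            raise ValueError(f"bridge channel {self.bridge!r} not among channels")
        if self.pool not in ("old", "new", "combined"):
            raise ValueError("pool must be 'old', 'new' or 'combined'")
        block = self.data[self.channels].to_numpy(dtype=float)
        if np.nanmin(block, initial=0.0) < 0:
            raise ValueError("negative reporter intensity")

    def channel_totals(self) -> pd.Series:
        return self.data[self.channels].sum()

    def protein_sums(self, channel: str | None = None) -> pd.DataFrame | pd.Series:
        grouped = self.data.groupby("protein")[self.channels].sum()
        return grouped if channel is None else grouped[channel]

    def scaled(self, factors: pd.Series | float) -> "ReporterMatrix":
        data = self.data.copy()
        data[self.channels] = data[self.channels] * factors
        return replace(self, data=data)


def _equalization_factors(totals: pd.Series) -> pd.Series:
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"channel(s) with zero total intensity: {bad}")
    return totals.mean() / totals


def normalize_total(m: ReporterMatrix) -> ReporterMatrix:
    """Equalize channel loadings within one reporter matrix.

    Each channel is divided by its own grand total and rescaled by the mean of
    the original totals, so post-normalization channel sums are equal and the
    overall intensity magnitude is preserved.
    """
    return m.scaled(_equalization_factors(m.channel_totals()))


def normalize_split_pair(
    old: ReporterMatrix, new: ReporterMatrix
) -> tuple[ReporterMatrix, ReporterMatrix]:
    """Loading-normalize an old/new pool pair with shared factors.

    A channel is one physical sample whose loading affects its 14N and 15N
    PSMs identically, so the equalization factors are computed from the
    combined (old + new) channel totals and applied to both matrices.
    """
    if old.channels != new.channels or old.plex != new.plex:
        raise ValueError("old/new matrices must describe the same plex")
    factors = _equalization_factors(old.channel_totals() + new.channel_totals())
    return old.scaled(factors), new.scaled(factors)


def combine_pools(old: ReporterMatrix, new: ReporterMatrix) -> ReporterMatrix:
    """Stack an old/new pair into one matrix (for bridge alignment)."""
    if old.channels != new.channels or old.plex != new.plex:
        raise ValueError("old/new matrices must describe the same plex")
    data = pd.concat([old.data, new.data], ignore_index=True)
    return replace(old, data=data, pool="combined")


def bridge_scale(plexes: list[ReporterMatrix]) -> list[float]:
    """Per-plex scale factors aligning bridge-channel protein aggregates.

    The first plex is the reference; each factor is the robust median, over
    proteins shared by every plex's bridge channel, of the reference bridge
    intensity divided by that plex's bridge intensity.
    """
    if not plexes:
        raise ValueError("no plexes given")
    bridges = [m.protein_sums(m.bridge) for m in plexes]
    shared = bridges[0].index
    for b in bridges[1:]:
        shared = shared.intersection(b.index)
    shared = [p for p in shared if all(b[p] > 0 for b in bridges)]
    if not shared:
        raise ValueError("no shared proteins across bridge channels")
    ref = bridges[0][shared]
    return [float(np.median(ref / b[shared])) for b in bridges]


def apply_bridge(m: ReporterMatrix, factor: float) -> ReporterMatrix:
    return m.scaled(float(factor))


def channel_fa(
    old: ReporterMatrix,
    new: ReporterMatrix,
    sample_meta: dict[str, dict] | None = None,
) -> FaMatrix:
    """Per-protein, per-channel FA from a normalized old/new matrix pair.

    FA = sum(old-pool PSM intensity) / (sum old + sum new) per protein and
    channel.  A protein absent from the old pool but present in the new pool
    has FA = 0; absent from both pools it is missing (NaN).  The bridge
    channel is the cross-plex reference and is not emitted as a sample.

    ``sample_meta`` optionally maps sample id -> metadata dict (age, sex,
    fraction, treatment, replicate).
    """
    if old.channels != new.channels:
        raise ValueError("old/new matrices must share channels")
    channels = [c for c in old.channels if c != old.bridge]
    sums_old = old.protein_sums()
    sums_new = new.protein_sums()
    proteins = sums_old.index.union(sums_new.index)
    so = sums_old.reindex(proteins, fill_value=0.0)[channels]
    sn = sums_new.reindex(proteins, fill_value=0.0)[channels]
    total = so + sn
    fa = so.where(total > 0) / total.where(total > 0)

    sample_ids = [old.channel_map[c] for c in channels]
    fa.columns = sample_ids
    records = []
    for sid in sample_ids:
        rec = {"sample": sid}
        rec.update((sample_meta or {}).get(sid, {}))
        records.append(rec)
    return FaMatrix(fa, make_sample_table(records))
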