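"""MS1 chromatogram reconstruction and old/new envelope deconvolution.

Quantification of turnover works at the MS1 level: for each identified
peptide, the pre-existing ("old": fully 14N, or 12C6-lysine) and newly
synthesized ("new": 15N-enriched, or 13C6-lysine) species are integrated from
reconstructed extracted-ion chromatograms (XICs) of their theoretical
isotopologue lines, and the fractional abundance is FA = I_old/(I_old+I_new).
When both species fall into one window, the observed envelope can instead be
deconvolved into pool fractions by non-negative least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .isotope import IsotopeEnvelope

__all__ = [
    "CentroidSpectrum",
    "XicResult",
    "MixtureFit",
    "PeptideTurnover",
    "extract_xic",
    "fit_fraction",
    "peptide_fa",
    "filter_peptides",
]

DEFAULT_PPM_TOL = 10.0
#: old/new envelopes more similar than this (cosine on the binned grid) are
#: too entangled for a stable NNLS split and get flagged.
RESOLVABILITY_COSINE = 0.99


@dataclass
class CentroidSpectrum:
    """One centroided MS1 scan: m/z and intensity arrays at a retention time."""

    scan_id: int
    rt: float  # seconds
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz/intensity length mismatch")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")


@dataclass
class XicResult:
    target_mz: float
    area: float
    n_scans: int  # scans with non-zero matched intensity
    ppm_tol: float


@dataclass
class MixtureFit:
    fraction_old: float
    scale: float
    residual: float
    flag: str | None = None


@dataclass
class PeptideTurnover:
    """Old/new integrated areas and fractional abundance of one peptide."""

    peptide_id: str
    protein: str
    i_old: float
    i_new: float
    fa: float
    residual: float = 0.0
    flags: tuple[str, ...] = ()


def extract_xic(
    spectra: list[CentroidSpectrum],
    targets: np.ndarray,
    ppm_tol: float = DEFAULT_PPM_TOL,
    rt_window: tuple[float, float] | None = None,
    target_windows: np.ndarray | None = None,
) -> list[XicResult]:
    """Integrate an XIC per target m/z over the retention-time dimension.

    For each scan inside the window, intensities of peaks within
    ``+/- ppm_tol`` of the target are summed; the chromatogram is then
    integrated by the trapezoid rule over retention time.  A target whose
    window contains a single scan contributes ``intensity x 1 s``.

    ``rt_window`` applies one (start, end) window to every target;
    ``target_windows`` (n x 2 array) gives per-target windows, which keeps the
    batched extraction cheap when thousands of species elute at known times.
    """
    if not spectra:
        raise ValueError("empty spectra list")
    if ppm_tol <= 0:
        raise ValueError("ppm tolerance must be positive")
    targets = np.atleast_1d(np.asarray(targets, dtype=float))
    n = targets.size
    rts = np.array([s.rt for s in spectra])
    if np.any(np.diff(rts) < 0):
        raise ValueError("spectra must be sorted by retention time")

    if target_windows is not None:
        windows = np.asarray(target_windows, dtype=float)
        if windows.shape != (n, 2):
            raise ValueError("target_windows must be (n_targets, 2)")
    elif rt_window is not None:
        windows = np.tile(np.asarray(rt_window, dtype=float), (n, 1))
    else:
        windows = np.tile([rts[0], rts[-1]], (n, 1))

    lo_mz = targets * (1.0 - ppm_tol * 1e-6)
    hi_mz = targets * (1.0 + ppm_tol * 1e-6)

    area = np.zeros(n)
    n_hits = np.zeros(n, dtype=int)
    n_window_scans = np.zeros(n, dtype=int)
    prev_rt = np.full(n, np.nan)
    prev_i = np.zeros(n)
    last_i = np.zeros(n)

    for spec in spectra:
        active = (windows[:, 0] <= spec.rt) & (spec.rt <= windows[:, 1])
        if not np.any(active):
            continue
        idx = np.nonzero(active)[0]
        if spec.mz.size:
            csum = np.concatenate(([0.0], np.cumsum(spec.intensity)))
            lo = np.searchsorted(spec.mz, lo_mz[idx], side="left")
            hi = np.searchsorted(spec.mz, hi_mz[idx], side="right")
            inten = csum[hi] - csum[lo]
        else:
            inten = np.zeros(idx.size)
        n_hits[idx] += inten > 0
        seen = ~np.isnan(prev_rt[idx])
        area[idx[seen]] += 0.5 * (prev_i[idx[seen]] + inten[seen]) * (
            spec.rt - prev_rt[idx[seen]]
        )
        prev_rt[idx] = spec.rt
        prev_i[idx] = inten
        last_i[idx] = inten
        n_window_scans[idx] += 1

    single = n_window_scans == 1
    area[single] = last_i[single]  # unit-width (1 s) convention
    return [
        XicResult(float(targets[i]), float(area[i]), int(n_hits[i]), ppm_tol)
        for i in range(n)
    ]


def _bin_envelope(env: IsotopeEnvelope, grid: np.ndarray, ppm_tol: float) -> np.ndarray:
    out = np.zeros(grid.size)
    for m, a in zip(env.mz, env.abundance):
        j = int(np.argmin(np.abs(grid - m)))
        if abs(grid[j] - m) <= ppm_tol * 1e-6 * m:
            out[j] += a
    return out


def fit_fraction(
    observed: np.ndarray,
    grid_mz: np.ndarray,
    env_old: IsotopeEnvelope,
    env_new: IsotopeEnvelope,
    ppm_tol: float = DEFAULT_PPM_TOL,
) -> MixtureFit:
    """Deconvolve an observed envelope into old/new pool fractions by NNLS.

    Both theoretical envelopes are binned onto the observed m/z grid at
    ``ppm_tol``; non-negative least squares finds coefficients (a_old, a_new)
    minimizing the squared error, and the old fraction is
    ``w = a_old / (a_old + a_new)``.  The residual is the L2 misfit divided by
    the L2 norm of the observation.  Fits where the binned envelopes have a
    cosine similarity above ``RESOLVABILITY_COSINE``, or fewer than two
    resolvable lines each, carry the flag ``"unresolvable"``.
    """
    observed = np.asarray(observed, dtype=float)
    grid_mz = np.asarray(grid_mz, dtype=float)
    if observed.shape != grid_mz.shape:
        raise ValueError("observed/grid length mismatch")
    if env_old.charge != env_new.charge:
        raise ValueError("old/new envelopes must share a charge state")
    norm = np.linalg.norm(observed)
    if norm == 0:
        raise ValueError("all-zero observation")

    b_old = _bin_envelope(env_old, grid_mz, ppm_tol)
    b_new = _bin_envelope(env_new, grid_mz, ppm_tol)
    flag = None
    if np.count_nonzero(b_old) < 2 or np.count_nonzero(b_new) < 2:
        flag = "unresolvable"
    else:
        denom = np.linalg.norm(b_old) * np.linalg.norm(b_new)
        if denom > 0 and float(b_old @ b_new) / denom > RESOLVABILITY_COSINE:
            flag = "unresolvable"

    design = np.column_stack([b_old, b_new])
    coef, _ = nnls(design, observed)
    total = coef.sum()
    w = float(coef[0] / total) if total > 0 else float("nan")
    residual = float(np.linalg.norm(observed - design @ coef) / norm)
    return MixtureFit(w, float(total), residual, flag)


def peptide_fa(i_old: float, i_new: float) -> float:
    """Fractional abundance FA = I_old / (I_old + I_new)."""
    if i_old < 0 or i_new < 0:
        raise ValueError("areas must be non-negative")
    total = i_old + i_new
    if total == 0:
        raise ValueError("both areas are zero; FA undefined")
    return i_old / total


def _bare_length(sequence: str) -> int:
    depth = 0
    n = 0
    for ch in sequence:
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
        elif depth == 0 and ch.isalpha():
            n += 1
    return n


def filter_peptides(
    psms: pd.DataFrame,
    min_length: int = 5,
    max_q: float = 0.01,
    digly_only: bool = False,
) -> pd.DataFrame:
    """Apply identification-quality filters to a PSM table.

    Removes peptides shorter than ``min_length`` residues and rows with
    q-value above ``max_q`` (rows without a q-value column pass).  With
    ``digly_only`` only rows carrying the +114.042927 ubiquitin-remnant
    modification (in the sequence brackets or a ``modifications`` column) are
    retained.
    """
    if "sequence" not in psms.columns:
        raise ValueError("PSM table lacks required column 'sequence'")
    if psms.empty:
        return psms.copy()
    keep = psms["sequence"].map(_bare_length) >= min_length
    if "q_value" in psms.columns:
        keep &= psms["q_value"].fillna(0.0) <= max_q
    if digly_only:
        in_seq = psms["sequence"].str.contains("114.042", regex=False)
        if "modifications" in psms.columns:
            in_seq |= (
                psms["modifications"].fillna("").str.contains("114.042", regex=False)
            )
        keep &= in_seq
    return psms.loc[keep].copy()
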