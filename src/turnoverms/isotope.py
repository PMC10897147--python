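"""Elemental compositions and isotopologue envelopes for labeled peptides.

A peptide observed by MS1 is a mixture of isotopologues whose relative
abundances follow from the elemental composition and the isotope abundances of
each element.  Metabolic labeling changes those abundances: feeding
15N-enriched chow raises the per-atom probability that a nitrogen is 15N, and
a 13C6-lysine diet replaces six carbons of each labeled lysine with pure 13C.
The envelope of a peptide species is the convolution of the per-element
isotope distributions, which this module computes exactly on the integer
"neutron shift" grid (bins of isotopologues sharing a total neutron count,
with the abundance-weighted mean mass tracked per bin).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .constants import (
    AA_FORMULAS,
    C13_MASS,
    ISOTOPES,
    LYS_C13_SHIFT,
    N15_MASS,
    PROTON_MASS,
    WATER,
    monoisotopic_mass,
)

__all__ = [
    "ElementalComposition",
    "LabelScheme",
    "Modification",
    "IsotopeEnvelope",
    "BUILTIN_MODS",
    "composition",
    "envelope",
    "mean_mass",
    "mix",
]


@dataclass(frozen=True)
class ElementalComposition:
    """Neutral-peptide elemental composition including modifications and water.

    ``fixed_mass`` collects mass contributions that do not participate in the
    natural-isotope convolution: bracketed mass deltas without a known formula,
    and isotopically pure atoms (e.g. the four 13C and one 15N of a TMT tag).
    """

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0
    fixed_mass: float = 0.0
    residues: int = 0
    lysines: int = 0

    def __post_init__(self) -> None:
        for el in "CHNOS":
            if getattr(self, el) < 0:
                raise ValueError(f"negative {el} count")
        if self.N < self.residues:
            raise ValueError("nitrogen count below residue count")

    @property
    def counts(self) -> dict[str, int]:
        return {el: getattr(self, el) for el in "CHNOS" if getattr(self, el)}

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self.counts) + self.fixed_mass


@dataclass(frozen=True)
class Modification:
    """A covalent modification: target sites plus its mass contribution.

    ``formula`` holds atoms at natural isotope abundance (they broaden the
    envelope); ``fixed_mass`` holds isotopically defined mass (pure heavy
    atoms, or the whole delta when no formula is known).
    """

    name: str
    targets: frozenset[str]  # residue letters and/or "nterm"/"cterm"
    formula: dict[str, int] | None = None
    fixed_mass: float = 0.0
    static: bool = True

    @property
    def mass(self) -> float:
        m = self.fixed_mass
        if self.formula:
            m += monoisotopic_mass(self.formula)
        return m


# TMT 10/11-plex tag: C8 H20 N O2 at natural abundance plus 4x13C and 1x15N.
_TMT_FIXED = 4 * C13_MASS + N15_MASS

BUILTIN_MODS: dict[str, Modification] = {
    "carbamidomethyl": Modification(
        "carbamidomethyl", frozenset({"C"}), {"C": 2, "H": 3, "N": 1, "O": 1}
    ),
    "tmt10": Modification(
        "tmt10", frozenset({"K", "nterm"}), {"C": 8, "H": 20, "N": 1, "O": 2}, _TMT_FIXED
    ),
    "digly": Modification(
        "digly",
        frozenset({"C", "K", "S", "T"}),
        {"C": 4, "H": 6, "N": 2, "O": 2},
        static=False,
    ),
}

_DELTA_TO_BUILTIN = [
    (57.02146, BUILTIN_MODS["carbamidomethyl"]),
    (229.1629, BUILTIN_MODS["tmt10"]),
    (114.042927, BUILTIN_MODS["digly"]),
]

_PEPTIDE_RE = re.compile(r"([A-Z])(?:\[([0-9.+-]+)\])?")


@dataclass(frozen=True)
class LabelScheme:
    """Isotope label state of one peptide species.

    variant: ``natural``, ``n15`` (15N at per-atom probability ``enrichment``)
    or ``c13lys`` (``labeled_lysines`` lysines carrying six pure 13C each).
    """

    variant: str = "natural"
    enrichment: float | None = None
    labeled_lysines: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("natural", "n15", "c13lys"):
            raise ValueError(f"unknown label variant {self.variant!r}")
        if self.variant == "n15":
            if self.enrichment is None or not 0.0 <= self.enrichment <= 1.0:
                raise ValueError("15N enrichment must lie in [0, 1]")
        if self.variant == "c13lys" and self.labeled_lysines < 0:
            raise ValueError("labeled lysine count must be >= 0")

    @classmethod
    def natural(cls) -> "LabelScheme":
        return cls("natural")

    @classmethod
    def nitrogen15(cls, enrichment: float) -> "LabelScheme":
        return cls("n15", enrichment=enrichment)

    @classmethod
    def lys_c13(cls, labeled_lysines: int) -> "LabelScheme":
        return cls("c13lys", labeled_lysines=labeled_lysines)

    @property
    def tag(self) -> str:
        if self.variant == "n15":
            return f"n15:{self.enrichment:g}"
        if self.variant == "c13lys":
            return f"c13lys:{self.labeled_lysines}"
        return "natural"


@dataclass
class IsotopeEnvelope:
    """Ordered isotopologue lines of one species at one charge state.

    ``mz`` holds m/z for ``charge >= 1`` and neutral mass for ``charge == 0``.
    Abundances are non-negative and sum to one.
    """

    mz: np.ndarray
    abundance: np.ndarray
    charge: int = 0
    label: str = "natural"

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.mz.size == 0:
            raise ValueError("empty envelope")
        if self.mz.shape != self.abundance.shape:
            raise ValueError("mz/abundance length mismatch")
        if np.any(self.abundance < 0):
            raise ValueError("negative abundance")
        if abs(self.abundance.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1 within 1e-9")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("masses must be strictly increasing")
        if self.charge < 0:
            raise ValueError("charge must be >= 0")

    @property
    def neutral_mass(self) -> np.ndarray:
        if self.charge == 0:
            return self.mz
        return self.mz * self.charge - self.charge * PROTON_MASS


def composition(
    sequence: str, mods: list[Modification] | None = None
) -> ElementalComposition:
    """Elemental composition of a neutral peptide.

    ``sequence`` uses one-letter codes, optionally with bracketed mass deltas
    attached to a residue (``K[229.1629]``).  Bracketed deltas matching a
    built-in modification (within 0.01 Da) contribute that modification's
    formula; unknown deltas are added as pure fixed mass.  ``mods`` are applied
    at every matching site (including the N terminus when targeted); a
    modification that matches no site raises, because silently dropping it
    would change the envelope the caller asked for.
    """
    if not sequence:
        raise ValueError("empty sequence")
    consumed = "".join(m.group(0) for m in _PEPTIDE_RE.finditer(sequence))
    if consumed != sequence:
        raise ValueError(f"could not parse peptide string {sequence!r}")

    counts = {el: 0 for el in "CHNOS"}
    fixed = 0.0
    residues = 0
    lysines = 0
    for m in _PEPTIDE_RE.finditer(sequence):
        aa, delta = m.group(1), m.group(2)
        if aa not in AA_FORMULAS:
            raise ValueError(f"unknown residue code {aa!r}")
        residues += 1
        lysines += aa == "K"
        for el, n in AA_FORMULAS[aa].items():
            counts[el] += n
        if delta is not None:
            dval = float(delta)
            for ref, builtin in _DELTA_TO_BUILTIN:
                if abs(dval - ref) < 0.01:
                    if builtin.formula:
                        for el, n in builtin.formula.items():
                            counts[el] += n
                    fixed += builtin.fixed_mass
                    break
            else:
                fixed += dval
    for el, n in WATER.items():
        counts[el] += n

    bare = re.sub(r"\[[0-9.+-]+\]", "", sequence)
    for mod in mods or []:
        n_sites = sum(bare.count(t) for t in mod.targets if len(t) == 1)
        n_sites += "nterm" in mod.targets
        n_sites += "cterm" in mod.targets
        if n_sites == 0:
            raise ValueError(f"modification {mod.name!r} targets no site in {bare!r}")
        if mod.formula:
            for el, n in mod.formula.items():
                counts[el] += n * n_sites
        fixed += mod.fixed_mass * n_sites

    return ElementalComposition(
        **counts, fixed_mass=fixed, residues=residues, lysines=lysines
    )


# -- convolution machinery ---------------------------------------------------
# A distribution over integer neutron shifts is a pair of arrays (a, am):
# a[s] is the probability of shift s, am[s] the probability-weighted sum of
# mass offsets (relative to the all-lightest isotopologue).  Convolution is
# exact for both, by linearity of expectation within each shift bin.


def _atom_dist(element: str, n15_p: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    isotopes = ISOTOPES[element]
    if element == "N" and n15_p is not None:
        m14, m15 = isotopes[0][0], isotopes[1][0]
        isotopes = [(m14, 1.0 - n15_p), (m15, n15_p)]
    base = isotopes[0][0]
    shifts = [int(round(m - base)) for m, _ in isotopes]
    a = np.zeros(max(shifts) + 1)
    am = np.zeros_like(a)
    for (m, p), s in zip(isotopes, shifts):
        a[s] += p
        am[s] += p * (m - base)
    return a, am


def _conv(d1, d2):
    a1, am1 = d1
    a2, am2 = d2
    return np.convolve(a1, a2), np.convolve(a1, am2) + np.convolve(am1, a2)


def _power(d, n: int):
    result = (np.array([1.0]), np.array([0.0]))
    base = d
    while n:
        if n & 1:
            result = _conv(result, base)
        base = _conv(base, base)
        n >>= 1
    return result


def envelope(
    comp: ElementalComposition,
    scheme: LabelScheme = LabelScheme.natural(),
    charge: int = 0,
    trunc: float = 1e-6,
) -> IsotopeEnvelope:
    """Isotopologue envelope of a composition under a label scheme.

    The envelope is the convolution of the per-element isotope distributions
    (binomial/multinomial in the atom counts), aggregated by total neutron
    shift.  Lines below the relative-abundance threshold ``trunc`` are dropped
    and the rest renormalized.  ``charge == 0`` returns neutral masses,
    otherwise m/z with proton mass 1.007276.
    """
    if charge < 0:
        raise ValueError("charge must be >= 0")
    if not 0.0 < trunc < 1.0:
        raise ValueError("trunc must lie in (0, 1)")

    counts = dict(comp.counts)
    fixed = comp.fixed_mass
    n15_p = scheme.enrichment if scheme.variant == "n15" else None
    if scheme.variant == "c13lys":
        if scheme.labeled_lysines > comp.lysines:
            raise ValueError(
                f"{scheme.labeled_lysines} labeled lysines but composition has "
                f"{comp.lysines}"
            )
        removed = 6 * scheme.labeled_lysines
        if counts.get("C", 0) < removed:
            raise ValueError("not enough carbons for the requested 13C6 labels")
        counts["C"] -= removed
        if counts["C"] == 0:
            counts.pop("C")
        # six pure 13C per labeled lysine: a fixed shift, no spread
        fixed += scheme.labeled_lysines * (6 * 12.0 + LYS_C13_SHIFT)

    dist = (np.array([1.0]), np.array([0.0]))
    for el, n in counts.items():
        dist = _conv(dist, _power(_atom_dist(el, n15_p), n))
    a, am = dist

    base_mass = monoisotopic_mass(counts) + fixed
    keep = a >= trunc
    if not np.any(keep):
        keep = a == a.max()
    a_kept = a[keep]
    masses = base_mass + am[keep] / a_kept
    abundance = a_kept / a_kept.sum()
    if charge >= 1:
        masses = (masses + charge * PROTON_MASS) / charge
    return IsotopeEnvelope(masses, abundance, charge=charge, label=scheme.tag)


def mean_mass(env: IsotopeEnvelope) -> float:
    """Abundance-weighted mean neutral mass in Da."""
    return float(np.sum(env.neutral_mass * env.abundance))


def mix(w: float, env_old: IsotopeEnvelope, env_new: IsotopeEnvelope) -> IsotopeEnvelope:
    """Weighted superposition ``w * old + (1 - w) * new`` on the union grid.

    Models one MS1 isolation window containing both the pre-existing and the
    newly synthesized species of a peptide.  Lines closer than 1e-9 Da (or
    m/z units) are merged.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    if env_old.charge != env_new.charge:
        raise ValueError("cannot mix envelopes with different charge states")
    mz = np.concatenate([env_old.mz, env_new.mz])
    ab = np.concatenate([w * env_old.abundance, (1.0 - w) * env_new.abundance])
    order = np.argsort(mz, kind="stable")
    mz, ab = mz[order], ab[order]
    out_mz: list[float] = []
    out_ab: list[float] = []
    for m, a in zip(mz, ab):
        if out_mz and m - out_mz[-1] < 1e-9:
            out_ab[-1] += a
        else:
            out_mz.append(m)
            out_ab.append(a)
    mz_arr = np.array(out_mz)
    ab_arr = np.array(out_ab)
    keep = ab_arr > 0
    ab_arr = ab_arr[keep] / ab_arr[keep].sum()
    label = env_old.label if env_old.label == env_new.label else (
        f"mix({w:g};{env_old.label}|{env_new.label})"
    )
    return IsotopeEnvelope(mz_arr[keep], ab_arr, charge=env_old.charge, label=label)
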