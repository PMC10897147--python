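"""Readers and writers for the pipeline's text formats, plus run configs.

Formats (all plain text, documented in the README):

* PSM table (TSV): ``sequence`` required; optional ``protein``, ``pool``,
  ``charge``, ``sample``, ``q_value``, ``modifications``.
* Spectra TSV dialect: one centroid peak per row, columns
  ``scan, rt, mz, intensity`` (mzML is supported through pyteomics when
  installed).
* Species table (TSV): per (peptide, pool) theoretical lines with ``mz`` and
  ``abundance`` as ``;``-joined floats.
* GMT annotation sets: ``term<TAB>description<TAB>member...``.
* FaMatrix CSV: ``#field,...`` metadata header block then proteins x samples.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .enrich import TermMap
from .matrix import FaMatrix
from .ms1 import CentroidSpectrum

__all__ = [
    "read_psm_table",
    "read_spectra_tsv",
    "write_spectra_tsv",
    "read_mzml",
    "read_species_table",
    "write_species_table",
    "read_gmt",
    "write_gmt",
    "read_fasta",
    "RunConfig",
    "write_results",
]

PSM_REQUIRED = ["sequence"]
SPECTRA_COLUMNS = ["scan", "rt", "mz", "intensity"]


def read_psm_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a PSM TSV; unknown columns pass through untouched."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PSM_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if "q_value" in df.columns:
        q = pd.to_numeric(df["q_value"], errors="coerce")
        bad = df.index[q.isna() & df["q_value"].notna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric q_value at data row {bad[0] + 2}")
        df["q_value"] = q
    return df


def read_spectra_tsv(path: str | Path) -> list[CentroidSpectrum]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SPECTRA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    spectra = []
    for (scan, rt), grp in df.groupby(["scan", "rt"], sort=True):
        grp = grp.sort_values("mz")
        spectra.append(
            CentroidSpectrum(
                int(scan), float(rt), grp["mz"].to_numpy(), grp["intensity"].to_numpy()
            )
        )
    spectra.sort(key=lambda s: s.rt)
    return spectra


def write_spectra_tsv(spectra: list[CentroidSpectrum], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {"scan": s.scan_id, "rt": s.rt, "mz": s.mz, "intensity": s.intensity}
        )
        for s in spectra
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.8g", lineterminator="\n"
    )


def read_mzml(path: str | Path) -> list[CentroidSpectrum]:
    """Centroid MS1 spectra from an mzML file (requires pyteomics)."""
    from pyteomics import mzml as _mzml  # optional dependency

    spectra = []
    with _mzml.MzML(str(path)) as reader:
        for i, spec in enumerate(reader):
            if spec.get("ms level") != 1:
                continue
            rt = float(
                spec["scanList"]["scan"][0]["scan start time"]
            ) * 60.0  # minutes -> seconds
            mz = np.asarray(spec["m/z array"], float)
            inten = np.asarray(spec["intensity array"], float)
            order = np.argsort(mz)
            spectra.append(CentroidSpectrum(i, rt, mz[order], inten[order]))
    spectra.sort(key=lambda s: s.rt)
    return spectra


def write_species_table(species: pd.DataFrame, path: str | Path) -> None:
    out = species.copy()
    out["mz"] = out["mz"].map(lambda a: ";".join(f"{x:.8f}" for x in a))
    out["abundance"] = out["abundance"].map(
        lambda a: ";".join(f"{x:.10g}" for x in a)
    )
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_species_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["mz"] = df["mz"].map(lambda s: np.array([float(x) for x in s.split(";")]))
    df["abundance"] = df["abundance"].map(
        lambda s: np.array([float(x) for x in s.split(";")])
    )
    return df


def read_gmt(path: str | Path) -> TermMap:
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT line needs term, description, members")
        term, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
        if term in sets:
            raise ValueError(f"{path}:{ln}: duplicate term id {term!r}")
        sets[term] = frozenset(members)
        names[term] = desc
    return TermMap(sets, names)


def write_gmt(terms: TermMap, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for term in sorted(terms.sets):
            members = "\t".join(sorted(terms.sets[term]))
            fh.write(f"{term}\t{terms.names.get(term, term)}\t{members}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by record id (standard FASTA via Biopython)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


@dataclass
class RunConfig:
    """Stage parameters of one pipeline run; round-trips through YAML."""

    seed: int
    out_dir: str = "results"
    ppm_tol: float = 10.0
    min_peptide_length: int = 5
    max_q: float = 0.01
    min_replicates: int = 3
    reference_age: int = 12
    k_range: tuple[int, int] = (2, 8)
    min_cluster_size: int = 10
    alpha: float = 0.05
    inputs: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["k_range"] = list(self.k_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["k_range"] = tuple(data.get("k_range", (2, 8)))
        return cls(**data)


def write_results(objects: dict[str, object], out_dir: str | Path) -> list[Path]:
    """Write DataFrames as CSV and plain mappings as JSON, deterministically."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in sorted(objects.items()):
        if isinstance(obj, FaMatrix):
            path = out / f"{name}.csv"
            obj.to_csv(path)
        elif isinstance(obj, pd.DataFrame):
            path = out / f"{name}.csv"
            obj.to_csv(path, lineterminator="\n")
        else:
            path = out / f"{name}.json"
            path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
        written.append(path)
    return written
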