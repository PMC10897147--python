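"""FaMatrix: proteins x samples fractional-abundance values with metadata.

Fractional abundance (FA) is the old-pool signal of a protein divided by its
total (old + new) signal in one sample.  The matrix carries per-sample
metadata (age group in months, sex, fraction, treatment, replicate) needed by
the group statistics and clustering stages.  Values are in [0, 1] or NaN.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FaMatrix", "SAMPLE_FIELDS"]

SAMPLE_FIELDS = ["age", "sex", "fraction", "treatment", "replicate"]


@dataclass
class FaMatrix:
    """Protein-by-sample FA values plus aligned sample metadata.

    ``values``: DataFrame indexed by protein, columns are sample ids.
    ``samples``: DataFrame indexed by sample id with columns ``age`` (months),
    ``sex``, ``fraction``, ``treatment``, ``replicate``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    kind: str = "fa"  # "fa": values constrained to [0, 1]; "delta": differences

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample metadata does not align with value columns")
        missing = [f for f in SAMPLE_FIELDS if f not in self.samples.columns]
        if missing:
            raise ValueError(f"sample metadata missing fields: {missing}")
        if self.kind == "fa":
            vals = self.values.to_numpy()
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
                raise ValueError("FA values must lie in [0, 1] or be missing")

    # -- convenience ---------------------------------------------------------
    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    def sample_ids(self, **criteria) -> list[str]:
        """Sample ids whose metadata match all keyword criteria."""
        mask = pd.Series(True, index=self.samples.index)
        for key, val in criteria.items():
            mask &= self.samples[key] == val
        return list(self.samples.index[mask])

    def group_means(self, by: list[str] | str = "age") -> pd.DataFrame:
        """Protein-level mean FA per metadata group (NaN-aware)."""
        if isinstance(by, str):
            by = [by]
        keys = self.samples[by].apply(lambda r: tuple(r), axis=1)
        out = {}
        for key in sorted(keys.unique()):
            cols = self.samples.index[keys == key]
            out[key if len(by) > 1 else key[0]] = self.values[cols].mean(axis=1)
        return pd.DataFrame(out)

    def subset(self, proteins=None, samples=None) -> "FaMatrix":
        vals = self.values
        meta = self.samples
        if proteins is not None:
            vals = vals.loc[[p for p in proteins if p in vals.index]]
        if samples is not None:
            vals = vals[list(samples)]
            meta = meta.loc[list(samples)]
        return FaMatrix(vals, meta, kind=self.kind)

    # -- I/O: a CSV with a '#' metadata header block -------------------------
    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            for fld in SAMPLE_FIELDS:
                row = ",".join(str(v) for v in self.samples[fld])
                fh.write(f"#{fld},{row}\n")
            self.values.to_csv(fh, index_label="protein", lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FaMatrix":
        path = Path(path)
        meta_rows: dict[str, list[str]] = {}
        body: list[str] = []
        for line in path.read_text().splitlines():
            if line.startswith("#"):
                name, _, rest = line[1:].partition(",")
                meta_rows[name] = rest.split(",") if rest else []
            else:
                body.append(line)
        values = pd.read_csv(_io.StringIO("\n".join(body)), index_col="protein")
        samples = pd.DataFrame(meta_rows, index=values.columns)
        for fld in ("age", "replicate"):
            if fld in samples:
                try:
                    samples[fld] = pd.to_numeric(samples[fld])
                except (ValueError, TypeError):
                    pass
        return cls(values, samples)


def make_sample_table(records: list[dict]) -> pd.DataFrame:
    """Build an aligned sample-metadata table from dict records with 'sample'."""
    df = pd.DataFrame(records).set_index("sample")
    for fld in SAMPLE_FIELDS:
        if fld not in df.columns:
            df[fld] = np.nan
    return df[SAMPLE_FIELDS]
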