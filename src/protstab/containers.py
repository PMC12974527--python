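"""Core in-memory containers for the turnover pipeline.

The central object is the :class:`AbundanceMatrix`: a protein x channel
intensity table plus a design table mapping each TMT channel to a chase
time point (hours) and a replicate index.  Intensities are raw (linear
scale, nonnegative); missing quantifications are ``NaN``.

A :class:`NormalizedMatrix` carries the same shape on the log2 scale,
together with a provenance record describing how it was produced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

DESIGN_COLUMNS = ("channel", "time_h", "replicate")


def _validate_design(design: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise InputError(f"design table missing columns: {missing}")
    design = design.copy()
    design["time_h"] = design["time_h"].astype(float)
    design["replicate"] = design["replicate"].astype(int)
    if design["channel"].duplicated().any():
        dup = design.loc[design["channel"].duplicated(), "channel"].tolist()
        raise InputError(f"duplicate channels in design: {dup}")
    if (design["time_h"] < 0).any():
        raise InputError("design contains negative time points")
    if design["time_h"].nunique() < 2:
        raise InputError("design must span at least 2 distinct time points")
    return design


@dataclass
class AbundanceMatrix:
    """Protein x channel intensities with a channel design.

    Parameters
    ----------
    data:
        DataFrame indexed by protein id, one column per channel, raw
        intensities (``NaN`` for missing).
    design:
        DataFrame with columns ``channel``, ``time_h``, ``replicate``.
    """

    data: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise InputError(f"duplicate protein ids: {dup[:5]}")
        if self.data.columns.duplicated().any():
            raise InputError("duplicate channel ids in intensity table")
        self.design = _validate_design(self.design)
        known = set(self.design["channel"])
        unknown = [c for c in self.data.columns if c not in known]
        if unknown:
            raise InputError(f"channels absent from design: {unknown}")
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise InputError("negative intensities are not allowed")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def channel_ids(self) -> list[str]:
        return list(self.data.columns)

    def times(self) -> pd.Series:
        """Chase time (h) for each channel column, in column order."""
        lookup = self.design.set_index("channel")["time_h"]
        return lookup.reindex(self.data.columns)

    # ---- I/O (wide TSV + design TSV) ------------------------------------
    def to_tsv(self, path: str | Path, design_path: str | Path) -> None:
        self.data.rename_axis("protein_id").to_csv(path, sep="\t")
        self.design.to_csv(design_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, design_path: str | Path) -> "AbundanceMatrix":
        data = pd.read_csv(path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t")
        return cls(data=data, design=design)


@dataclass
class NormalizedMatrix:
    """log2-scale abundances with the same layout as :class:`AbundanceMatrix`."""

    data: pd.DataFrame
    design: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.design = _validate_design(self.design)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    def times(self) -> pd.Series:
        lookup = self.design.set_index("channel")["time_h"]
        return lookup.reindex(self.data.columns)

    def copy_with(self, data: pd.DataFrame, step: dict) -> "NormalizedMatrix":
        prov = dict(self.provenance)
        steps = list(prov.get("steps", []))
        steps.append(step)
        prov["steps"] = steps
        return NormalizedMatrix(data=data, design=self.design.copy(), provenance=prov)

    def to_tsv(self, path: str | Path, design_path: str | Path | None = None,
               provenance_path: str | Path | None = None) -> None:
        self.data.rename_axis("protein_id").to_csv(path, sep="\t")
        if design_path is not None:
            self.design.to_csv(design_path, sep="\t", index=False)
        if provenance_path is not None:
            Path(provenance_path).write_text(json.dumps(self.provenance, indent=2))

    @classmethod
    def from_tsv(cls, path: str | Path, design_path: str | Path) -> "NormalizedMatrix":
        data = pd.read_csv(path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t")
        return cls(data=data, design=design)
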