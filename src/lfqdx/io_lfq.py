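"""Reading, validation and writing of LFQ intensity matrices and sample metadata.

The quantitative input is a proteins x samples table of label-free
quantification (LFQ) intensities as produced by MaxQuant-style software.
An intensity of 0 means "protein not detected in this sample"; the
analysis modules rely on that convention throughout.

Two input dialects are supported:

``plain_matrix``
    First column protein accession, remaining columns one per sample,
    numeric. Missing cells are read as 0 (not detected).
``maxquant_protein_groups``
    A MaxQuant ``proteinGroups.txt``-style tab-separated table. Only the
    ``LFQ intensity <sample>`` columns are quantitative; rows flagged as
    reverse (decoy) hits or potential contaminants are dropped.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_GROUPS = frozenset({"D", "G", "H", "N"})
VALID_TAGS = frozenset({"A", "B"})
VALID_FLUIDS = frozenset({"plasma", "urine"})

METADATA_COLUMNS = ("sample_id", "patient_id", "group", "replicate_tag", "fluid", "pair_id")


class LFQFormatError(ValueError):
    """Raised when an input table violates the LFQ matrix or metadata contract."""


@dataclass
class LFQMatrix:
    """Dense proteins x samples LFQ intensity matrix.

    Intensities are non-negative reals in arbitrary LFQ units; 0 means
    the protein was not detected in that sample.
    """

    protein_ids: list[str]
    sample_ids: list[str]
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.protein_ids = [str(p) for p in self.protein_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise LFQFormatError("intensities must be a 2-D array")
        n_prot, n_samp = self.intensities.shape
        if n_prot != len(self.protein_ids) or n_samp != len(self.sample_ids):
            raise LFQFormatError(
                f"matrix shape {self.intensities.shape} does not match id lists "
                f"({len(self.protein_ids)} proteins, {len(self.sample_ids)} samples)"
            )
        _check_unique(self.protein_ids, "protein id")
        _check_unique(self.sample_ids, "sample id")
        if self.intensities.size:
            if not np.all(np.isfinite(self.intensities)):
                raise LFQFormatError("non-finite intensity encountered")
            if np.any(self.intensities < 0):
                raise LFQFormatError("negative intensity encountered")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensities, index=self.protein_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "LFQMatrix":
        """Column subset preserving the requested order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        cols = [index[s] for s in sample_ids]
        return LFQMatrix(list(self.protein_ids), list(sample_ids), self.intensities[:, cols])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LFQMatrix):
            return NotImplemented
        return (
            self.protein_ids == other.protein_ids
            and self.sample_ids == other.sample_ids
            and self.intensities.shape == other.intensities.shape
            and bool(np.array_equal(self.intensities, other.intensities))
        )


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample annotation: which patient, disease group, replicate and fluid."""

    sample_id: str
    patient_id: str
    group: str
    replicate_tag: str
    fluid: str
    pair_id: str

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise LFQFormatError(f"unknown group label {self.group!r} (expected one of {sorted(VALID_GROUPS)})")
        if self.replicate_tag not in VALID_TAGS:
            raise LFQFormatError(f"unknown replicate tag {self.replicate_tag!r} (expected A or B)")
        if self.fluid not in VALID_FLUIDS:
            raise LFQFormatError(f"unknown fluid {self.fluid!r} (expected plasma or urine)")


def _check_unique(items: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            raise LFQFormatError(f"duplicate {what}: {item!r}")
        seen.add(item)


def _sep_for(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_lfq_table(path: str, dialect: str = "plain_matrix") -> LFQMatrix:
    """Read an LFQ intensity table from ``path``.

    Parameters
    ----------
    path:
        CSV or TSV file (separator inferred from the extension; anything
        not ``.csv`` is treated as tab-separated).
    dialect:
        ``plain_matrix`` or ``maxquant_protein_groups``.

    Returns
    -------
    LFQMatrix
        Validated matrix; protein and sample order follows the file.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if dialect == "plain_matrix":
        return _read_plain(path)
    if dialect == "maxquant_protein_groups":
        return _read_maxquant(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _coerce_numeric(frame: pd.DataFrame, where: str) -> np.ndarray:
    # float() is correctly rounded, so repr-written values round-trip
    # bit-exactly (pandas' fast to_numeric parser is not)
    def convert(cell):
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            return 0.0  # missing cell: not detected
        try:
            return float(cell)
        except (TypeError, ValueError):
            raise LFQFormatError(f"non-numeric cell in {where}: {cell!r}") from None

    return frame.map(convert).to_numpy(dtype=float)


def _read_plain(path: str) -> LFQMatrix:
    frame = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if frame.shape[1] < 1:
        raise LFQFormatError("empty table")
    protein_ids = frame.iloc[:, 0].astype(str).tolist()
    sample_ids = [str(c) for c in frame.columns[1:]]
    values = _coerce_numeric(frame.iloc[:, 1:], path)
    if values.size == 0:
        values = values.reshape(len(protein_ids), len(sample_ids))
    return LFQMatrix(protein_ids, sample_ids, values)


def _read_maxquant(path: str) -> LFQMatrix:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    lfq_prefix = "LFQ intensity "
    lfq_cols = [c for c in frame.columns if c.startswith(lfq_prefix)]
    if not lfq_cols:
        raise LFQFormatError("no 'LFQ intensity ' columns found in MaxQuant table")
    id_col = next(
        (c for c in ("Protein IDs", "Majority protein IDs") if c in frame.columns),
        frame.columns[0],
    )
    keep = pd.Series(True, index=frame.index)
    for flag_col in ("Reverse", "Potential contaminant", "Contaminant"):
        if flag_col in frame.columns:
            keep &= frame[flag_col].fillna("") != "+"
    accessions = frame[id_col].astype(str)
    keep &= ~accessions.str.startswith(("REV__", "CON__"))
    frame = frame.loc[keep]
    protein_ids = frame[id_col].astype(str).tolist()
    sample_ids = [c[len(lfq_prefix):] for c in lfq_cols]
    values = _coerce_numeric(frame[lfq_cols], path)
    if values.size == 0:
        values = values.reshape(len(protein_ids), len(sample_ids))
    return LFQMatrix(protein_ids, sample_ids, values)


def write_matrix(matrix: LFQMatrix, path: str) -> None:
    """Write ``matrix`` as a plain TSV/CSV table.

    Values are written with ``repr`` fidelity so that
    ``read_lfq_table(write_matrix(m))`` round-trips bit-exactly.
    """
    sep = _sep_for(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(["protein_id", *matrix.sample_ids]) + "\n")
        for pid, row in zip(matrix.protein_ids, matrix.intensities):
            fh.write(sep.join([pid, *(repr(float(v)) for v in row)]) + "\n")


def read_metadata(path: str) -> list[SampleMeta]:
    """Read and validate a sample-metadata table.

    Requires columns ``sample_id, patient_id, group, replicate_tag,
    fluid, pair_id``. Every pair_id must occur exactly twice, once as
    replicate A and once as B.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise LFQFormatError(f"metadata missing required columns: {missing}")
    records = [
        SampleMeta(**{c: str(frame.iloc[i][c]) for c in METADATA_COLUMNS})
        for i in range(len(frame))
    ]
    validate_metadata(records)
    return records


def validate_metadata(records: Sequence[SampleMeta]) -> None:
    _check_unique([r.sample_id for r in records], "sample id")
    by_pair: dict[str, list[SampleMeta]] = {}
    for r in records:
        by_pair.setdefault(r.pair_id, []).append(r)
    for pair_id, members in by_pair.items():
        if len(members) != 2:
            raise LFQFormatError(f"pair {pair_id!r} has {len(members)} members (expected 2)")
        tags = sorted(m.replicate_tag for m in members)
        if tags != ["A", "B"]:
            raise LFQFormatError(f"pair {pair_id!r} replicate tags are {tags} (expected one A, one B)")


def write_metadata(records: Sequence[SampleMeta], path: str) -> None:
    frame = pd.DataFrame([{c: getattr(r, c) for c in METADATA_COLUMNS} for r in records])
    frame.to_csv(path, sep=_sep_for(path), index=False)


def check_metadata_covers(matrix: LFQMatrix, records: Sequence[SampleMeta]) -> dict[str, SampleMeta]:
    """Map sample_id -> metadata, requiring every matrix sample to be annotated."""
    lookup = {r.sample_id: r for r in records}
    missing = [s for s in matrix.sample_ids if s not in lookup]
    if missing:
        raise LFQFormatError(f"samples without metadata: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    return lookup
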