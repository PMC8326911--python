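"""OTU-table input/output, validation and basic transforms.

The universal data container is :class:`OtuTable`: a dense non-negative
integer count matrix (taxa x samples) with unique taxon and sample
identifiers.  Sample grouping (e.g. "normal" / "benign" / "malignant"
tissue) is carried by :class:`GroupDesign`.

The reference on-disk format is a UTF-8 tab-separated table whose first
cell is ``#OTU_ID`` and whose rows are taxa.  A minimal reader for the
JSON dialect of the BIOM 1.0 format is also provided, since the models
only ever need a dense count matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "GroupDesign",
    "OtuTableError",
    "read_otu_tsv",
    "read_biom_json",
    "read_group_metadata",
    "write_table",
    "filter_singletons",
    "relative_abundance",
    "split_by_group",
]


class OtuTableError(ValueError):
    """Raised when a count table or metadata table violates its contract."""


@dataclass(frozen=True)
class OtuTable:
    """Dense OTU count table, taxa as rows and samples as columns.

    Parameters
    ----------
    counts
        Non-negative integer matrix of shape ``(n_taxa, n_samples)``.
    taxon_ids, sample_ids
        Unique string identifiers matching the matrix dimensions.
    """

    counts: np.ndarray
    taxon_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise OtuTableError(f"counts must be 2-D, got shape {counts.shape}")
        if not np.issubdtype(counts.dtype, np.integer):
            if np.issubdtype(counts.dtype, np.floating) and np.all(
                counts == np.floor(counts)
            ):
                counts = counts.astype(np.int64)
            else:
                bad = np.argwhere(counts != np.floor(counts))
                loc = tuple(bad[0]) if len(bad) else None
                raise OtuTableError(f"non-integer count at (taxon, sample)={loc}")
        if np.any(counts < 0):
            loc = tuple(np.argwhere(counts < 0)[0])
            raise OtuTableError(f"negative count at (taxon, sample)={loc}")
        taxa = tuple(str(t) for t in self.taxon_ids)
        samples = tuple(str(s) for s in self.sample_ids)
        if counts.shape != (len(taxa), len(samples)):
            raise OtuTableError(
                f"shape {counts.shape} does not match {len(taxa)} taxa x "
                f"{len(samples)} samples"
            )
        if len(set(taxa)) != len(taxa):
            dupes = sorted({t for t in taxa if taxa.count(t) > 1})
            raise OtuTableError(f"duplicate taxon ids: {dupes[:5]}")
        if len(set(samples)) != len(samples):
            dupes = sorted({s for s in samples if samples.count(s) > 1})
            raise OtuTableError(f"duplicate sample ids: {dupes[:5]}")
        object.__setattr__(self, "counts", np.ascontiguousarray(counts, dtype=np.int64))
        object.__setattr__(self, "taxon_ids", taxa)
        object.__setattr__(self, "sample_ids", samples)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_depths(self) -> np.ndarray:
        """Total reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def taxon_totals(self) -> np.ndarray:
        """Total reads per taxon across all samples (row sums)."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.taxon_ids), columns=list(self.sample_ids)
        )

    def select_samples(self, sample_ids: list[str] | tuple[str, ...]) -> "OtuTable":
        """Column subset (taxa rows are all retained, possibly as zero rows)."""
        index = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise OtuTableError(f"unknown sample ids: {missing[:5]}")
        cols = [index[s] for s in sample_ids]
        return OtuTable(self.counts[:, cols], self.taxon_ids, tuple(sample_ids))

    def drop_empty_taxa(self) -> "OtuTable":
        """Remove taxa whose total count is zero (structural zeros)."""
        keep = self.taxon_totals > 0
        return OtuTable(
            self.counts[keep],
            tuple(t for t, k in zip(self.taxon_ids, keep) if k),
            self.sample_ids,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.taxon_ids == other.taxon_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class GroupDesign:
    """Assignment of samples to study groups."""

    assignment: Mapping[str, str]
    group_sizes: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assignment = dict(self.assignment)
        sizes: dict[str, int] = {}
        for sample, group in assignment.items():
            if not str(group):
                raise OtuTableError(f"empty group label for sample {sample!r}")
            sizes[str(group)] = sizes.get(str(group), 0) + 1
        if self.group_sizes:
            declared = dict(self.group_sizes)
            if declared != sizes:
                raise OtuTableError(
                    f"group_sizes {declared} inconsistent with assignment {sizes}"
                )
        object.__setattr__(self, "assignment", assignment)
        object.__setattr__(self, "group_sizes", sizes)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted(self.group_sizes))

    def samples_in(self, group: str) -> tuple[str, ...]:
        return tuple(s for s, g in self.assignment.items() if g == group)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_otu_tsv(
    path: str | Path,
    orientation: Literal["taxa-rows", "samples-rows"] = "taxa-rows",
) -> OtuTable:
    """Read a tab-separated OTU table.

    The first row holds sample identifiers (first cell is the taxon-id
    header, conventionally ``#OTU_ID``); each subsequent row is one taxon.
    ``orientation="samples-rows"`` transposes the file on read so the
    returned table is always taxa x samples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, sep="\t", header=0, index_col=0, comment=None)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise OtuTableError(f"malformed table in {path}: {exc}") from exc
    if frame.shape[1] == 0:
        raise OtuTableError(f"malformed header in {path} line 1: no sample columns")
    values = frame.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        for i, row in enumerate(values):
            for j, v in enumerate(row):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise OtuTableError(
                        f"non-numeric count {v!r} at line {i + 2}, column {j + 2}"
                    ) from None
        values = values.astype(float)
    if np.any(values != np.floor(values)):
        loc = tuple(np.argwhere(values != np.floor(values))[0])
        raise OtuTableError(f"fractional count at (row, col)={loc}")
    table = OtuTable(
        values.astype(np.int64),
        tuple(str(t) for t in frame.index),
        tuple(str(s) for s in frame.columns),
    )
    if orientation == "samples-rows":
        table = OtuTable(table.counts.T, table.sample_ids, table.taxon_ids)
    elif orientation != "taxa-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return table


def write_table(table: OtuTable, path: str | Path) -> None:
    """Write an OtuTable in the reference TSV dialect (lossless round-trip)."""
    frame = table.to_frame()
    frame.index.name = "#OTU_ID"
    frame.to_csv(path, sep="\t")


def read_biom_json(path: str | Path) -> OtuTable:
    """Read a BIOM 1.0 (JSON dialect) table into an OtuTable.

    Supports both sparse and dense matrix_type; the matrix is densified.
    """
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    taxa = tuple(str(r["id"]) for r in doc["rows"])
    samples = tuple(str(c["id"]) for c in doc["columns"])
    shape = tuple(doc["shape"])
    counts = np.zeros(shape, dtype=np.int64)
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            counts[i, j] = v
    else:
        counts[:, :] = np.asarray(doc["data"])
    return OtuTable(counts, taxa, samples)


def read_group_metadata(path: str | Path) -> GroupDesign:
    """Read sample metadata TSV with columns ``sample_id`` and ``group``."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in frame.columns:
            raise OtuTableError(f"metadata {path} missing required column {col!r}")
    if frame["sample_id"].duplicated().any():
        dupes = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
        raise OtuTableError(f"duplicate sample ids in metadata: {dupes[:5]}")
    return GroupDesign(dict(zip(frame["sample_id"], frame["group"])))


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def filter_singletons(table: OtuTable) -> OtuTable:
    """Discard singleton OTUs (total count across ALL samples equal to 1).

    Globally-singleton reads are overwhelmingly likely to be sequencing
    artifacts; removing them is standard practice before neutral-model
    fitting.  Row order of the retained taxa is preserved.
    """
    totals = table.taxon_totals
    keep = totals != 1
    if not keep.any():
        warnings.warn("all taxa are singletons; returning an empty table")
    return OtuTable(
        table.counts[keep],
        tuple(t for t, k in zip(table.taxon_ids, keep) if k),
        table.sample_ids,
    )


def relative_abundance(table: OtuTable) -> np.ndarray:
    """Per-sample relative abundances (each column sums to 1)."""
    depths = table.sample_depths
    if np.any(depths == 0):
        bad = [s for s, d in zip(table.sample_ids, depths) if d == 0]
        raise OtuTableError(f"all-zero sample column(s): {bad[:5]}")
    return table.counts / depths[np.newaxis, :]


def split_by_group(table: OtuTable, design: GroupDesign) -> dict[str, OtuTable]:
    """Partition columns by group label; all taxa rows retained per part."""
    unassigned = [s for s in table.sample_ids if s not in design.assignment]
    if unassigned:
        raise OtuTableError(f"samples without group assignment: {unassigned[:5]}")
    parts: dict[str, OtuTable] = {}
    for group in design.groups:
        cols = [s for s in table.sample_ids if design.assignment[s] == group]
        if cols:
            parts[group] = table.select_samples(cols)
    return parts
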