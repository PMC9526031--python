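"""Core data structures shared across the pipeline.

The central object is :class:`ReadTable`, a dense count matrix of DNA
sequence variants across PCR-replicate units together with per-unit
metadata.  Every curation stage consumes and produces a ``ReadTable``;
replicate aggregation finally produces a :class:`SampleTable`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

UNIT_TYPES = (
    "sample",
    "blank",
    "extraction_negative",
    "pcr_negative",
    "positive_control",
)

#: unit types treated as negative controls by the contaminant rule
NEGATIVE_CONTROL_TYPES = ("extraction_negative", "pcr_negative")

UNIT_COLUMNS = (
    "unit_id",
    "sample_id",
    "individual_id",
    "group_id",
    "collection_date",
    "replicate_index",
    "unit_type",
)

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_DNA = set("ACGT")


class DietBarcoderError(ValueError):
    """Base error for invalid inputs or impossible configurations."""


def _check_dna(seq: str) -> str:
    if not seq or not set(seq) <= _DNA:
        raise DietBarcoderError(f"not an uppercase ACGT sequence: {seq!r}")
    return seq


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaxonPath:
    """A taxonomic path from kingdom down to (at most) species.

    ``names`` aligns with :data:`RANKS`; trailing ``None`` entries mean the
    path stops above that rank.
    """

    names: tuple

    def __post_init__(self):
        if len(self.names) != len(RANKS):
            raise DietBarcoderError("taxon path must have one slot per rank")
        seen_none = False
        for n in self.names:
            if n is None:
                seen_none = True
            elif seen_none:
                raise DietBarcoderError("taxon path has a gap")

    @property
    def rank(self) -> str:
        for r, n in zip(reversed(RANKS), reversed(self.names)):
            if n is not None:
                return r
        raise DietBarcoderError("empty taxon path")

    @property
    def name(self) -> str:
        return self.names[RANKS.index(self.rank)]

    def at(self, rank: str):
        return self.names[RANKS.index(rank)]

    def truncated(self, rank: str) -> "TaxonPath":
        k = RANKS.index(rank) + 1
        return TaxonPath(tuple(self.names[:k]) + (None,) * (len(RANKS) - k))

    def to_string(self) -> str:
        return ";".join(n for n in self.names if n is not None)

    @classmethod
    def from_string(cls, s: str) -> "TaxonPath":
        parts = [p for p in s.split(";") if p]
        if len(parts) > len(RANKS):
            raise DietBarcoderError(f"taxon path too deep: {s!r}")
        return cls(tuple(parts) + (None,) * (len(RANKS) - len(parts)))


def common_path(paths: Sequence[TaxonPath]) -> TaxonPath:
    """Longest shared prefix of several taxon paths (their lowest common rank)."""
    if not paths:
        raise DietBarcoderError("no paths given")
    names = []
    for i in range(len(RANKS)):
        vals = {p.names[i] for p in paths}
        if len(vals) == 1 and None not in vals:
            names.append(vals.pop())
        else:
            break
    return TaxonPath(tuple(names) + (None,) * (len(RANKS) - len(names)))


@dataclass(frozen=True)
class RefRecord:
    """One reference barcode: a sequence carrying one or more taxon labels."""

    sequence: str
    taxa: tuple  # tuple[TaxonPath, ...]
    geographic_valid: tuple = ()  # bool per species-level label

    def __post_init__(self):
        _check_dna(self.sequence)
        if not self.taxa:
            raise DietBarcoderError("reference record without taxon label")
        if not self.geographic_valid:
            object.__setattr__(self, "geographic_valid", (True,) * len(self.taxa))
        if len(self.geographic_valid) != len(self.taxa):
            raise DietBarcoderError("one validity flag per taxon label required")


@dataclass
class ReferenceDatabase:
    records: list
    scope: str = "local"  # local | global

    def __post_init__(self):
        if self.scope not in ("local", "global"):
            raise DietBarcoderError(f"unknown scope {self.scope!r}")
        seqs = [r.sequence for r in self.records]
        if len(set(seqs)) != len(seqs):
            raise DietBarcoderError("duplicate sequences in reference database")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sequences(self) -> list:
        return [r.sequence for r in self.records]

    def species_labels(self) -> list:
        out = []
        for r in self.records:
            for t in r.taxa:
                if t.rank == "species":
                    out.append(t.name)
        return out


@dataclass
class TaxonomicAssignment:
    sequence: str
    matched_db: str  # local | global | none
    identity: float
    taxon: TaxonPath | None
    label: str | None  # display label, possibly "sp. A/sp. B" joined
    assigned_rank: str | None
    demoted: str | None = None  # None | "range_mismatch" | "family_cap"

    def __post_init__(self):
        if self.matched_db not in ("local", "global", "none"):
            raise DietBarcoderError(f"bad matched_db {self.matched_db!r}")
        if self.matched_db == "none" and self.taxon is not None:
            raise DietBarcoderError("unassigned sequence with a taxon")


# ---------------------------------------------------------------------------
# read tables
# ---------------------------------------------------------------------------


def make_units(rows: Iterable[Mapping]) -> pd.DataFrame:
    """Build a unit-metadata frame (indexed by unit_id) from dict rows."""
    df = pd.DataFrame(list(rows))
    missing = [c for c in UNIT_COLUMNS if c not in df.columns]
    if missing:
        raise DietBarcoderError(f"unit metadata missing columns: {missing}")
    df = df.loc[:, list(UNIT_COLUMNS)].set_index("unit_id", drop=False)
    return df


@dataclass
class ReadTable:
    """Counts of sequence variants (rows) across PCR-replicate units (columns)."""

    sequences: list
    counts: np.ndarray
    units: pd.DataFrame
    library_id: str = "lib1"

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise DietBarcoderError("counts must be 2-D")
        if self.counts.shape != (len(self.sequences), len(self.units)):
            raise DietBarcoderError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.sequences)}, {len(self.units)})"
            )
        if np.issubdtype(self.counts.dtype, np.floating):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise DietBarcoderError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise DietBarcoderError("counts must be non-negative")
        for s in self.sequences:
            _check_dna(s)
        if len(set(self.sequences)) != len(self.sequences):
            raise DietBarcoderError("duplicate sequences in table")
        if not self.units.index.is_unique:
            raise DietBarcoderError("unit_ids not unique")
        bad = set(self.units["unit_type"]) - set(UNIT_TYPES)
        if bad:
            raise DietBarcoderError(f"unknown unit types: {bad}")

    # -- convenience views ---------------------------------------------------

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    def library_totals(self) -> np.ndarray:
        """Per-sequence read total over every unit of the library."""
        return self.counts.sum(axis=1)

    def unit_mask(self, *types: str) -> np.ndarray:
        return self.units["unit_type"].isin(types).to_numpy()

    def seq_index(self) -> dict:
        return {s: i for i, s in enumerate(self.sequences)}

    # -- transforms ----------------------------------------------------------

    def keep_sequences(self, keep: np.ndarray) -> "ReadTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return ReadTable(
            [self.sequences[i] for i in idx],
            self.counts[idx].copy(),
            self.units.copy(),
            self.library_id,
        )

    def copy(self) -> "ReadTable":
        return ReadTable(
            list(self.sequences), self.counts.copy(), self.units.copy(), self.library_id
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.sequences, name="sequence"),
            columns=self.units.index,
        )


@dataclass
class SampleTable:
    """Per-sample retained values (real-valued replicate means) by sequence/taxon."""

    values: pd.DataFrame  # rows: sequences or taxa, columns: sample_id
    samples: pd.DataFrame  # indexed by sample_id: individual_id, group_id, collection_date

    def __post_init__(self):
        if not self.values.columns.equals(self.samples.index):
            raise DietBarcoderError("sample columns and metadata index differ")
        if (self.values.to_numpy() < 0).any():
            raise DietBarcoderError("negative values in sample table")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# filter reporting
# ---------------------------------------------------------------------------


@dataclass
class StageRecord:
    stage: str
    reads_in: int
    reads_out: int
    sequences_in: int
    sequences_out: int

    @property
    def reads_removed(self) -> int:
        return self.reads_in - self.reads_out

    @property
    def sequences_removed(self) -> int:
        return self.sequences_in - self.sequences_out


@dataclass
class FilterReport:
    """Per-stage read/sequence accounting plus tag-jump diagnostics."""

    stages: list = field(default_factory=list)
    tagjump_ratio: float | None = None
    wilcoxon: tuple | None = None  # (statistic, p)
    warnings: list = field(default_factory=list)
    excluded_samples: list = field(default_factory=list)

    def add_stage(self, stage: str, before: ReadTable, after) -> StageRecord:
        reads_out = (
            after.total_reads if isinstance(after, ReadTable)
            else int(np.round(after.values.to_numpy().sum()))
        )
        n_out = (
            after.n_sequences if isinstance(after, ReadTable) else after.values.shape[0]
        )
        rec = StageRecord(
            stage, before.total_reads, reads_out, before.n_sequences, n_out
        )
        self.stages.append(rec)
        return rec

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        warnings.warn(message, stacklevel=3)

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "stage": s.stage,
                    "reads_in": s.reads_in,
                    "reads_out": s.reads_out,
                    "reads_removed": s.reads_removed,
                    "sequences_in": s.sequences_in,
                    "sequences_out": s.sequences_out,
                    "sequences_removed": s.sequences_removed,
                }
                for s in self.stages
            ],
            "tagjump_ratio": self.tagjump_ratio,
            "wilcoxon": (
                None
                if self.wilcoxon is None
                else {"statistic": self.wilcoxon[0], "p": self.wilcoxon[1]}
            ),
            "warnings": list(self.warnings),
            "excluded_samples": list(self.excluded_samples),
        }


# ---------------------------------------------------------------------------
# tag assignments
# ---------------------------------------------------------------------------


@dataclass
class TagAssignmentTable:
    """Per-unit 8-nt tag pair and primer pair used for demultiplexing."""

    rows: pd.DataFrame  # unit_id, forward_tag, reverse_tag, forward_primer, reverse_primer

    REQUIRED = ("unit_id", "forward_tag", "reverse_tag", "forward_primer", "reverse_primer")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise DietBarcoderError(f"tag table missing columns: {missing}")
        for col in ("forward_tag", "reverse_tag"):
            if not self.rows[col].str.len().eq(8).all():
                raise DietBarcoderError("tags must be exactly 8 nt")
        pairs = list(zip(self.rows["forward_tag"], self.rows["reverse_tag"]))
        if len(set(pairs)) != len(pairs):
            raise DietBarcoderError("duplicate tag pair in tag table")
        if self.rows["unit_id"].duplicated().any():
            raise DietBarcoderError("duplicate unit_id in tag table")

    def by_pair(self) -> dict:
        return {
            (r.forward_tag, r.reverse_tag): r
            for r in self.rows.itertuples(index=False)
        }
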