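"""Read accounting, identification rates, overlap summaries.

All printed percentages use pure rational arithmetic with deterministic
half-up rounding to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .abundance import SeasonCalendar
from .model import (
    RANKS,
    DietBarcoderError,
    ReadTable,
    ReferenceDatabase,
    SampleTable,
)


def percent(numerator: int, denominator: int, decimals: int = 2) -> float:
    """100 * numerator / denominator, half-up rounded."""
    if denominator == 0:
        raise DietBarcoderError("zero denominator")
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def identification_rate(total: int, identified: int) -> float:
    """Percentage of records identified, to two decimals."""
    if total <= 0:
        raise DietBarcoderError("total must be positive")
    if not 0 <= identified <= total:
        raise DietBarcoderError("identified must be in [0, total]")
    return percent(identified, total)


@dataclass
class ReadAccounting:
    total_reads: int
    host_reads: int
    assigned_reads: int
    taxa_detected: dict | None = None  # rank -> count

    def __post_init__(self):
        if not 0 <= self.host_reads <= self.total_reads:
            raise DietBarcoderError("host reads out of range")
        if not 0 <= self.assigned_reads <= self.remaining_reads:
            raise DietBarcoderError("assigned reads exceed non-host reads")

    @property
    def remaining_reads(self) -> int:
        return self.total_reads - self.host_reads

    @property
    def assigned_fraction(self) -> float:
        """Percent of non-host reads that received an assignment (2 dp)."""
        return percent(self.assigned_reads, self.remaining_reads)

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "host_reads": self.host_reads,
            "remaining_reads": self.remaining_reads,
            "assigned_reads": self.assigned_reads,
            "assigned_fraction_percent": self.assigned_fraction,
            "taxa_detected": self.taxa_detected,
        }


def read_accounting(
    table: ReadTable, assignments, host_taxa
) -> ReadAccounting:
    """Accounting over a table *before* host removal: host reads, remaining
    reads, reads assigned to a non-host taxon, and distinct taxa per rank."""
    host_taxa = set(host_taxa)
    by_seq = {a.sequence: a for a in assignments}
    totals = table.library_totals()
    host = assigned = 0
    detected = {r: set() for r in ("order", "family", "genus", "species")}
    for seq, tot in zip(table.sequences, totals):
        a = by_seq.get(seq)
        if a is None or a.taxon is None:
            continue
        names = {n for n in a.taxon.names if n} | ({a.label} if a.label else set())
        if names & host_taxa:
            host += int(tot)
            continue
        assigned += int(tot)
        for rank in detected:
            name = a.taxon.at(rank)
            if name is not None:
                detected[rank].add(name)
    return ReadAccounting(
        total_reads=table.total_reads,
        host_reads=host,
        assigned_reads=assigned,
        taxa_detected={r: len(v) for r, v in detected.items()},
    )


def refdb_summary(db: ReferenceDatabase) -> tuple:
    """(n_sequences, n_distinct_species, histogram of labels per sequence)."""
    histogram: dict = {}
    species = set()
    for rec in db.records:
        k = len(rec.taxa)
        histogram[k] = histogram.get(k, 0) + 1
        for t in rec.taxa:
            if t.rank == "species":
                species.add(t.name)
    return len(db.records), len(species), histogram


@dataclass
class MethodOverlap:
    items_edna_only: set
    items_focal_only: set
    items_shared: set

    def __post_init__(self):
        if (
            self.items_edna_only & self.items_focal_only
            or self.items_edna_only & self.items_shared
            or self.items_focal_only & self.items_shared
        ):
            raise DietBarcoderError("overlap sets must be disjoint")

    @property
    def counts(self) -> dict:
        return {
            "edna_only": len(self.items_edna_only),
            "focal_only": len(self.items_focal_only),
            "shared": len(self.items_shared),
        }


def method_overlap(edna_items, focal_items, rank: str = "species") -> MethodOverlap:
    """Partition item labels into eDNA-only / focal-only / shared.

    A multi-species barcode label ("A/B") counts as shared when any member
    species was observed; the matching observed items are shared too.
    """
    if rank not in RANKS:
        raise DietBarcoderError(f"unknown rank {rank!r}")
    edna = set(edna_items)
    focal = set(focal_items)
    shared = set()
    for e in edna:
        members = set(e.split("/")) | {e}
        if members & focal:
            shared.add(e)
            shared |= members & focal
    shared |= edna & focal
    return MethodOverlap(
        items_edna_only=edna - shared,
        items_focal_only=focal - shared,
        items_shared=shared,
    )


def seasonal_detection_rate(
    samples: SampleTable, target_taxa, calendar: SeasonCalendar
) -> pd.Series:
    """Percent of samples per season containing any retained read of a
    target taxon (two decimals)."""
    target = set(target_taxa)
    rows = samples.values.index
    hit_rows = [r for r in rows if r in target or set(str(r).split("/")) & target]
    present = (samples.values.loc[hit_rows] > 0).any(axis=0)
    seasons = [
        calendar.season_of(d) for d in samples.samples["collection_date"]
    ]
    df = pd.DataFrame({"season": seasons, "hit": present.to_numpy()})
    out = {}
    for season, grp in df.groupby("season"):
        out[season] = percent(int(grp["hit"].sum()), len(grp))
    return pd.Series(out).reindex(calendar.names).dropna()
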