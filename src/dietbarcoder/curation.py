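"""The read-curation cascade.

Stage order (enforced by :func:`run_cascade`): length filter -> minimum
library count -> denoising merge -> 97% greedy clustering -> taxonomic
assignment (local then global) -> host removal -> contaminant removal ->
tag-jump filter -> replicate aggregation.  Every stage is also callable on
its own; all ordering ties break by decreasing library abundance, then
lexicographically by sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import (
    NEGATIVE_CONTROL_TYPES,
    RANKS,
    DietBarcoderError,
    FilterReport,
    ReadTable,
    ReferenceDatabase,
    SampleTable,
    StageRecord,
    TagAssignmentTable,
    TaxonomicAssignment,
    common_path,
    make_units,
)
from .seqdist import identity, within_edit_distance

_DNA = set("ACGT")


def _abundance_order(table: ReadTable) -> list:
    """Indices in decreasing library abundance, ties lexicographic."""
    totals = table.library_totals()
    return sorted(range(table.n_sequences), key=lambda i: (-totals[i], table.sequences[i]))


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    return seq.translate(comp)[::-1]


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b)) + abs(len(a) - len(b))


def demultiplex(
    reads,
    tags: TagAssignmentTable,
    max_primer_mismatch: int = 2,
    units: pd.DataFrame | None = None,
    library_id: str = "lib1",
    report: FilterReport | None = None,
) -> ReadTable:
    """Assign tagged reads to units and collapse identical inserts.

    A read is assigned to the unique unit whose 8-nt tag pair matches
    exactly and whose two primers each match with at most
    ``max_primer_mismatch`` substitutions; anything else (including reads
    too short to contain tags and primers) is left unassigned and counted.
    ``reads`` is an iterable of Biopython ``SeqRecord`` or plain strings.
    """
    by_pair = tags.by_pair()
    counts: dict = {}
    n_total = 0
    n_unassigned = 0
    for rec in reads:
        read = str(rec.seq) if hasattr(rec, "seq") else str(rec)
        n_total += 1
        if len(read) < 16:
            n_unassigned += 1
            continue
        pair = (read[:8], _revcomp(read[-8:]))
        row = by_pair.get(pair)
        if row is None:
            n_unassigned += 1
            continue
        fp, rp = row.forward_primer, row.reverse_primer
        if len(read) < 16 + len(fp) + len(rp) + 1:
            n_unassigned += 1
            continue
        fwd_region = read[8: 8 + len(fp)]
        rev_region = _revcomp(read[-8 - len(rp): -8])
        if (
            _mismatches(fwd_region, fp) > max_primer_mismatch
            or _mismatches(rev_region, rp) > max_primer_mismatch
        ):
            n_unassigned += 1
            continue
        insert = read[8 + len(fp): -8 - len(rp)]
        if not insert or not set(insert) <= _DNA:
            n_unassigned += 1
            continue
        counts[(insert, row.unit_id)] = counts.get((insert, row.unit_id), 0) + 1

    unit_ids = list(tags.rows["unit_id"])
    if units is None:
        units = make_units(
            {
                "unit_id": u,
                "sample_id": u,
                "individual_id": "",
                "group_id": "",
                "collection_date": "",
                "replicate_index": 1,
                "unit_type": "sample",
            }
            for u in unit_ids
        )
    else:
        units = units.copy()
        missing = set(unit_ids) - set(units.index)
        if missing:
            raise DietBarcoderError(f"tag table units missing metadata: {missing}")

    seqs = sorted({s for s, _ in counts})
    seq_at = {s: i for i, s in enumerate(seqs)}
    unit_at = {u: i for i, u in enumerate(units.index)}
    mat = np.zeros((len(seqs), len(units)), dtype=np.int64)
    for (s, u), c in counts.items():
        mat[seq_at[s], unit_at[u]] = c
    table = ReadTable(seqs, mat, units, library_id)
    # deterministic row order: decreasing abundance then lexicographic
    order = _abundance_order(table)
    table = table.keep_sequences(np.array(order, dtype=int)) if seqs else table
    if report is not None:
        report.stages.append(
            StageRecord("demultiplex", n_total, table.total_reads, 0, table.n_sequences)
        )
    demultiplex.last_unassigned = n_unassigned  # simple diagnostic
    return table


# ---------------------------------------------------------------------------
# abundance/length filters
# ---------------------------------------------------------------------------


def length_filter(
    table: ReadTable, min_bp: int, max_bp: int, report: FilterReport | None = None
) -> ReadTable:
    if min_bp > max_bp:
        raise DietBarcoderError("min_bp must be <= max_bp")
    keep = np.array([min_bp <= len(s) <= max_bp for s in table.sequences], dtype=bool)
    out = table.keep_sequences(keep)
    if report is not None:
        report.add_stage("length_filter", table, out)
    return out


def min_count_filter(
    table: ReadTable, min_library_reads: int = 10, report: FilterReport | None = None
) -> ReadTable:
    """Drop sequences with fewer than ``min_library_reads`` summed over every
    unit of the library (samples and controls alike)."""
    keep = table.library_totals() >= min_library_reads
    out = table.keep_sequences(keep)
    if report is not None:
        report.add_stage("min_count_filter", table, out)
    return out


# ---------------------------------------------------------------------------
# denoising and clustering
# ---------------------------------------------------------------------------


def denoise_merge(
    table: ReadTable,
    max_mismatch: int = 1,
    child_ratio: float = 0.05,
    report: FilterReport | None = None,
) -> ReadTable:
    """Merge likely PCR/sequencing variants into their parents.

    Visiting sequences in decreasing abundance, a sequence is merged into
    the first already-retained sequence within ``max_mismatch``
    substitutions/indels whose (current) total is at least
    ``total/child_ratio``; merged counts are added per unit.
    """
    order = _abundance_order(table)
    totals = table.library_totals().astype(np.int64).copy()
    counts = table.counts.copy()
    retained: list = []
    for i in order:
        parent = None
        for j in retained:
            if (
                child_ratio > 0
                and totals[i] <= child_ratio * totals[j]
                and within_edit_distance(table.sequences[i], table.sequences[j], max_mismatch)
            ):
                parent = j
                break
        if parent is None:
            retained.append(i)
        else:
            counts[parent] += counts[i]
            totals[parent] += totals[i]
    out = ReadTable(
        [table.sequences[i] for i in retained],
        counts[retained],
        table.units.copy(),
        table.library_id,
    )
    if report is not None:
        report.add_stage("denoise_merge", table, out)
    return out


def cluster_greedy(
    table: ReadTable,
    identity_threshold: float = 0.97,
    report: FilterReport | None = None,
) -> ReadTable:
    """Greedy abundance-sorted clustering at a global-alignment identity
    threshold; cluster representative is the (first seen, hence most
    abundant) founder and per-unit counts are summed over members."""
    if not 0 < identity_threshold <= 1:
        raise DietBarcoderError("identity_threshold must be in (0, 1]")
    order = _abundance_order(table)
    reps: list = []  # founding order
    member_counts: list = []
    for i in order:
        joined = False
        for k, j in enumerate(reps):
            if table.sequences[i] == table.sequences[j] or identity(
                table.sequences[j], table.sequences[i]
            ) >= identity_threshold:
                member_counts[k] = member_counts[k] + table.counts[i]
                joined = True
                break
        if not joined:
            reps.append(i)
            member_counts.append(table.counts[i].copy())
    out = ReadTable(
        [table.sequences[j] for j in reps],
        np.array(member_counts, dtype=np.int64).reshape(len(reps), table.n_units),
        table.units.copy(),
        table.library_id,
    )
    if report is not None:
        report.add_stage("cluster_greedy", table, out)
    return out


# ---------------------------------------------------------------------------
# taxonomic assignment
# ---------------------------------------------------------------------------


def _assign_against(seq: str, db: ReferenceDatabase, threshold: float):
    best = 0.0
    hits = []
    for rec in db.records:
        ident = identity(seq, rec.sequence)
        if ident > best + 1e-12:
            best = ident
            hits = [rec]
        elif abs(ident - best) <= 1e-12 and best > 0:
            hits.append(rec)
    if best >= threshold and hits:
        return best, hits
    return best, []


def _assignment_from_hits(seq: str, db_name: str, ident: float, hits) -> TaxonomicAssignment:
    taxa = [t for rec in hits for t in rec.taxa]
    path = common_path(taxa) if len(taxa) > 1 else taxa[0]
    species = sorted({t.name for t in taxa if t.rank == "species"})
    if len(taxa) > 1 and len(species) > 1:
        label = "/".join(species)
    else:
        label = path.name
    return TaxonomicAssignment(
        sequence=seq,
        matched_db=db_name,
        identity=ident,
        taxon=path,
        label=label,
        assigned_rank=path.rank,
    )


def assign_taxonomy(
    table: ReadTable,
    local_db: ReferenceDatabase | None,
    global_db: ReferenceDatabase | None,
    threshold: float = 0.97,
) -> list:
    """Cascading assignment: best local hit >= threshold wins, otherwise best
    global hit, otherwise unassigned.  Multi-species reference labels give a
    joined label at the labels' lowest common rank; equal-identity ties
    between distinct references resolve the same way."""
    if local_db is None and global_db is None:
        raise DietBarcoderError("at least one reference database required")
    for db in (local_db, global_db):
        if db is not None and len(db) == 0:
            warnings.warn("empty reference database: everything will miss it")
    out = []
    for seq in table.sequences:
        assignment = None
        for name, db in (("local", local_db), ("global", global_db)):
            if db is None or len(db) == 0:
                continue
            ident, hits = _assign_against(seq, db, threshold)
            if hits:
                assignment = _assignment_from_hits(seq, name, ident, hits)
                break
        if assignment is None:
            assignment = TaxonomicAssignment(
                sequence=seq,
                matched_db="none",
                identity=0.0,
                taxon=None,
                label=None,
                assigned_rank=None,
            )
        out.append(assignment)
    return out


def apply_range_rules(assignments, range_table) -> list:
    """Demote species assignments whose geographic range does not fit.

    ``range_table`` maps species label -> (species_valid, genus_valid); a
    ``pandas.DataFrame`` with columns ``species, species_valid, genus_valid``
    is also accepted.  Invalid species go to genus when the genus is valid,
    else to family; missing species are treated as invalid with a warning.
    """
    if isinstance(range_table, pd.DataFrame):
        range_table = {
            r.species: (bool(r.species_valid), bool(r.genus_valid))
            for r in range_table.itertuples(index=False)
        }
    out = []
    for a in assignments:
        if a.assigned_rank != "species":
            out.append(a)
            continue
        flags = range_table.get(a.taxon.name)
        if flags is None:
            warnings.warn(f"species {a.taxon.name!r} missing from range table")
            flags = (False, False)
        sp_ok, genus_ok = flags
        if sp_ok:
            out.append(a)
            continue
        rank = "genus" if genus_ok else "family"
        path = a.taxon.truncated(rank)
        out.append(
            TaxonomicAssignment(
                sequence=a.sequence,
                matched_db=a.matched_db,
                identity=a.identity,
                taxon=path,
                label=path.name,
                assigned_rank=rank,
                demoted="range_mismatch",
            )
        )
    return out


def cap_rank(assignments, cap: str = "family") -> list:
    """Truncate assignments below ``cap`` to ``cap``."""
    if cap not in RANKS:
        raise DietBarcoderError(f"unknown rank {cap!r}")
    cap_i = RANKS.index(cap)
    out = []
    for a in assignments:
        if a.taxon is None or RANKS.index(a.assigned_rank) <= cap_i:
            out.append(a)
            continue
        path = a.taxon.truncated(cap)
        out.append(
            TaxonomicAssignment(
                sequence=a.sequence,
                matched_db=a.matched_db,
                identity=a.identity,
                taxon=path,
                label=path.name,
                assigned_rank=cap,
                demoted=a.demoted or "family_cap",
            )
        )
    return out


# ---------------------------------------------------------------------------
# artifact removal
# ---------------------------------------------------------------------------


def remove_host(
    table: ReadTable,
    assignments,
    host_taxa,
    report: FilterReport | None = None,
) -> tuple:
    """Drop sequences assigned to any host taxon, everywhere (samples and
    controls alike)."""
    report = report or FilterReport()
    host_taxa = set(host_taxa)
    by_seq = {a.sequence: a for a in assignments}
    keep = []
    for s in table.sequences:
        a = by_seq.get(s)
        is_host = False
        if a is not None and a.taxon is not None:
            names = {n for n in a.taxon.names if n} | ({a.label} if a.label else set())
            is_host = bool(names & host_taxa)
        keep.append(not is_host)
    out = table.keep_sequences(np.array(keep, dtype=bool))
    report.add_stage("remove_host", table, out)
    return out, report


def remove_contaminants(
    table: ReadTable, report: FilterReport | None = None
) -> tuple:
    """Remove sequences more abundant in extraction/PCR negatives than in
    samples, compared on per-unit relative abundance (count / unit depth)."""
    report = report or FilterReport()
    neg = table.unit_mask(*NEGATIVE_CONTROL_TYPES)
    smp = table.unit_mask("sample")
    if not neg.any():
        report.warn("no negative-control units: contaminant filter skipped")
        report.add_stage("remove_contaminants", table, table)
        return table.copy(), report
    depths = table.counts.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(depths > 0, table.counts / depths, 0.0)
    max_neg = rel[:, neg].max(axis=1) if neg.any() else np.zeros(table.n_sequences)
    max_smp = rel[:, smp].max(axis=1) if smp.any() else np.zeros(table.n_sequences)
    keep = ~(max_neg > max_smp)
    out = table.keep_sequences(keep)
    report.add_stage("remove_contaminants", table, out)
    return out, report


def tagjump_filter(
    table: ReadTable,
    quantile: float = 1.0,
    report: FilterReport | None = None,
) -> tuple:
    """Blank-based tag-jump filter.

    Leak fractions ``f = blank_count / library_total`` are pooled over all
    (sequence, blank) cells with positive counts; the library ratio ``r`` is
    the given quantile of those fractions (default: their maximum) and every
    cell with ``count < r * library_total`` of its sequence is zeroed.  A
    Wilcoxon signed-rank diagnostic comparing blank counts of
    high-abundance vs low-abundance sequence pairs is recorded.
    """
    report = report or FilterReport()
    blanks = table.unit_mask("blank")
    totals = table.library_totals().astype(float)
    if not blanks.any():
        report.warn("no blank units: tag-jump ratio set to 0")
        report.tagjump_ratio = 0.0
        report.add_stage("tagjump_filter", table, table)
        return table.copy(), report

    blank_counts = table.counts[:, blanks]
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = np.where(totals[:, None] > 0, blank_counts / totals[:, None], 0.0)
    positive = fractions[blank_counts > 0]
    r = float(np.quantile(positive, quantile)) if positive.size else 0.0
    report.tagjump_ratio = r

    # diagnostic: do more abundant sequences leak more into blanks?
    order = np.argsort(-totals, kind="stable")
    blank_tot = blank_counts.sum(axis=1)[order]
    half = len(order) // 2
    if half >= 1:
        hi, lo = blank_tot[:half], blank_tot[half: 2 * half]
        if np.any(hi != lo):
            w = sps.wilcoxon(hi, lo, zero_method="zsplit")
            report.wilcoxon = (float(w.statistic), float(w.pvalue))
        else:
            report.wilcoxon = (float("nan"), float("nan"))

    out_counts = table.counts.copy()
    if r > 0:
        threshold = r * totals[:, None]
        out_counts[out_counts < threshold] = 0
    out = ReadTable(list(table.sequences), out_counts, table.units.copy(), table.library_id)
    report.add_stage("tagjump_filter", table, out)
    return out, report


# ---------------------------------------------------------------------------
# replicate aggregation
# ---------------------------------------------------------------------------


def aggregate_replicates(
    table: ReadTable,
    min_replicates: int = 2,
    min_mean_reads: float = 5,
    report: FilterReport | None = None,
) -> SampleTable:
    """Replicate-consensus filter: per sample and sequence, the mean count
    over all replicates is retained when the sequence is nonzero in at
    least ``min_replicates`` replicates AND that mean is at least
    ``min_mean_reads``; otherwise zero.  Control units are dropped."""
    report = report or FilterReport()
    smp = table.units[table.units["unit_type"] == "sample"]
    values = {}
    meta_rows = []
    for sid, grp in smp.groupby("sample_id", sort=True):
        cols = [table.units.index.get_loc(u) for u in grp.index]
        if len(cols) < min_replicates:
            report.excluded_samples.append(sid)
            report.warn(
                f"sample {sid!r} has {len(cols)} replicate unit(s) "
                f"(< {min_replicates}): excluded"
            )
            continue
        block = table.counts[:, cols]
        present = (block > 0).sum(axis=1)
        mean = block.mean(axis=1)
        retained = np.where((present >= min_replicates) & (mean >= min_mean_reads), mean, 0.0)
        values[sid] = retained
        first = grp.iloc[0]
        meta_rows.append(
            {
                "sample_id": sid,
                "individual_id": first["individual_id"],
                "group_id": first["group_id"],
                "collection_date": first["collection_date"],
            }
        )
    if not meta_rows:
        raise DietBarcoderError("no samples with enough replicates")
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    vals = pd.DataFrame(values, index=pd.Index(table.sequences, name="sequence"))
    vals = vals.loc[:, meta.index]
    out = SampleTable(vals, meta)
    report.add_stage("aggregate_replicates", table, out)
    return out


def collapse_by_taxon(
    samples: SampleTable, assignments, drop_unassigned: bool = True
) -> SampleTable:
    """Merge sample-table rows that received identical taxon labels."""
    label = {a.sequence: a.label for a in assignments if a.label is not None}
    vals = samples.values.copy()
    keys = [label.get(s) for s in vals.index]
    if drop_unassigned:
        keep = [k is not None for k in keys]
        vals = vals.loc[keep]
        keys = [k for k in keys if k is not None]
    else:
        keys = [k if k is not None else "unassigned" for k in keys]
    grouped = vals.groupby(pd.Index(keys, name="taxon")).sum()
    return SampleTable(grouped, samples.samples.copy())


# ---------------------------------------------------------------------------
# pipeline runner
# ---------------------------------------------------------------------------


@dataclass
class CascadeParams:
    min_bp: int = 10
    max_bp: int = 220
    min_library_reads: int = 10
    denoise_max_mismatch: int = 1
    denoise_child_ratio: float = 0.05
    cluster_identity: float = 0.97
    assign_threshold: float = 0.97
    tagjump_quantile: float = 1.0
    min_replicates: int = 2
    min_mean_reads: float = 5
    host_taxa: tuple = ()
    rank_cap: str | None = None
    range_table: object = None
    skip: tuple = ()  # stage names to skip


@dataclass
class CascadeResult:
    samples: SampleTable
    taxa: SampleTable
    assignments: list
    report: FilterReport


def run_cascade(
    table: ReadTable,
    local_db: ReferenceDatabase | None,
    global_db: ReferenceDatabase | None,
    params: CascadeParams | None = None,
) -> CascadeResult:
    """Run the full curation cascade in its fixed stage order."""
    p = params or CascadeParams()
    report = FilterReport()
    skip = set(p.skip)

    if "length_filter" not in skip:
        table = length_filter(table, p.min_bp, p.max_bp, report)
    if "min_count_filter" not in skip:
        table = min_count_filter(table, p.min_library_reads, report)
    if "denoise_merge" not in skip:
        table = denoise_merge(table, p.denoise_max_mismatch, p.denoise_child_ratio, report)
    if "cluster_greedy" not in skip:
        table = cluster_greedy(table, p.cluster_identity, report)

    assignments = assign_taxonomy(table, local_db, global_db, p.assign_threshold)
    if p.range_table is not None and "range_rules" not in skip:
        assignments = apply_range_rules(assignments, p.range_table)
    if p.rank_cap is not None and "rank_cap" not in skip:
        assignments = cap_rank(assignments, p.rank_cap)
    if p.host_taxa and "remove_host" not in skip:
        table, report = remove_host(table, assignments, p.host_taxa, report)
        present = set(table.sequences)
        assignments = [a for a in assignments if a.sequence in present]
    if "remove_contaminants" not in skip:
        table, report = remove_contaminants(table, report)
    if "tagjump_filter" not in skip:
        table, report = tagjump_filter(table, p.tagjump_quantile, report)

    samples = aggregate_replicates(table, p.min_replicates, p.min_mean_reads, report)
    present = set(samples.values.index)
    assignments = [a for a in assignments if a.sequence in present]
    taxa = collapse_by_taxon(samples, assignments)
    return CascadeResult(samples=samples, taxa=taxa, assignments=assignments, report=report)
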