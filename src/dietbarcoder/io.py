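"""Plain-text readers and writers: FASTA via Biopython, TSV via pandas,
YAML for reports and simulation configs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .abundance import DietProfileMatrix, FocalLog
from .model import (
    DietBarcoderError,
    ReadTable,
    RefRecord,
    ReferenceDatabase,
    SampleTable,
    TagAssignmentTable,
    TaxonPath,
    make_units,
)

_META_COLS = ["individual_id", "group_id", "date", "season", "source", "empty"]


# -- FASTA -------------------------------------------------------------------


def write_fasta(records, path) -> None:
    """Write SeqRecords, or (id, sequence) pairs, as FASTA."""
    recs = []
    for r in records:
        if isinstance(r, SeqRecord):
            recs.append(r)
        else:
            rid, seq = r
            recs.append(SeqRecord(Seq(seq), id=str(rid), description=""))
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> list:
    return list(SeqIO.parse(str(path), "fasta"))


# -- read tables --------------------------------------------------------------


def write_read_table(table: ReadTable, counts_path, units_path) -> None:
    table.to_frame().to_csv(counts_path, sep="\t")
    table.units.to_csv(units_path, sep="\t", index=False)


def read_read_table(counts_path, units_path, library_id: str = "lib1") -> ReadTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    units = pd.read_csv(
        units_path, sep="\t", dtype={"replicate_index": int}, keep_default_na=False
    )
    units = make_units(units.to_dict("records"))
    counts = counts.loc[:, units.index]
    return ReadTable(
        list(counts.index), counts.to_numpy(dtype=np.int64), units, library_id
    )


# -- tag tables ---------------------------------------------------------------


def write_tag_table(tags: TagAssignmentTable, path) -> None:
    tags.rows.to_csv(path, sep="\t", index=False)


def read_tag_table(path) -> TagAssignmentTable:
    return TagAssignmentTable(pd.read_csv(path, sep="\t", keep_default_na=False))


# -- reference databases ------------------------------------------------------


def write_reference_db(db: ReferenceDatabase, fasta_path, taxonomy_path) -> None:
    """FASTA of sequences plus a taxonomy TSV: seq_id, taxon_path
    (semicolon-separated ranks), geographic_valid — one row per label."""
    recs = []
    rows = []
    for i, rec in enumerate(db.records):
        sid = f"ref{i + 1:04d}"
        recs.append(SeqRecord(Seq(rec.sequence), id=sid, description=""))
        for taxon, valid in zip(rec.taxa, rec.geographic_valid):
            rows.append(
                {"seq_id": sid, "taxon_path": taxon.to_string(), "geographic_valid": valid}
            )
    SeqIO.write(recs, str(fasta_path), "fasta")
    pd.DataFrame(rows).to_csv(taxonomy_path, sep="\t", index=False)


def read_reference_db(fasta_path, taxonomy_path, scope: str = "local") -> ReferenceDatabase:
    seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta_path), "fasta")}
    tax = pd.read_csv(taxonomy_path, sep="\t")
    records = []
    for sid, grp in tax.groupby("seq_id", sort=False):
        if sid not in seqs:
            raise DietBarcoderError(f"taxonomy references unknown sequence {sid!r}")
        records.append(
            RefRecord(
                seqs[sid],
                tuple(TaxonPath.from_string(s) for s in grp["taxon_path"]),
                tuple(bool(v) for v in grp["geographic_valid"]),
            )
        )
    return ReferenceDatabase(records, scope=scope)


# -- sample tables and profiles -----------------------------------------------


def write_sample_table(samples: SampleTable, values_path, meta_path) -> None:
    samples.values.to_csv(values_path, sep="\t")
    samples.samples.to_csv(meta_path, sep="\t")


def read_sample_table(values_path, meta_path) -> SampleTable:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, keep_default_na=False)
    return SampleTable(values, meta.loc[values.columns])


def write_profile(profile: DietProfileMatrix, path) -> None:
    meta = profile.meta.copy()
    meta.columns = [f"meta_{c}" for c in meta.columns]
    out = pd.concat([meta, profile.values], axis=1)
    out.insert(0, "kind", profile.kind)
    out.to_csv(path, sep="\t", index_label="row_id")


def read_profile(path) -> DietProfileMatrix:
    df = pd.read_csv(path, sep="\t", index_col="row_id", keep_default_na=False)
    kind = str(df.pop("kind").iloc[0]) if len(df) else "composition"
    meta_cols = [c for c in df.columns if c.startswith("meta_")]
    meta = df[meta_cols].copy()
    meta.columns = [c[len("meta_"):] for c in meta.columns]
    if "empty" in meta.columns:
        meta["empty"] = meta["empty"].astype(str).str.lower().isin(["true", "1"])
    values = df.drop(columns=meta_cols).astype(float)
    return DietProfileMatrix(values, meta, kind)


# -- focal logs ---------------------------------------------------------------


def write_focal_log(log: FocalLog, events_path, screenings_path) -> None:
    log.events.to_csv(events_path, sep="\t", index=False)
    log.screenings.to_csv(screenings_path, sep="\t", index=False)


def read_focal_log(events_path, screenings_path) -> FocalLog:
    events = pd.read_csv(events_path, sep="\t", keep_default_na=False)
    screenings = pd.read_csv(screenings_path, sep="\t", keep_default_na=False)
    return FocalLog(events, screenings)


# -- YAML ---------------------------------------------------------------------


def write_yaml(obj, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())
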