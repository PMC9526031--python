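"""Synthetic-data generation with known ground truth.

Everything the pipeline consumes can be generated here: reference
databases, seasonal diet compositions, triplicate read tables with planted
tag-jump/contaminant/host artifacts, tagged raw reads, and focal
observation logs.  Every generator takes an explicit integer seed and all
planted reads are recorded so recovery tests can reconcile category totals
with the grand total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import abundance as ab
from .model import (
    DietBarcoderError,
    RefRecord,
    ReferenceDatabase,
    ReadTable,
    TagAssignmentTable,
    TaxonPath,
    make_units,
)
from .seqdist import identity

_BASES = np.array(list("ACGT"))

DEFAULT_FORWARD_PRIMER = "ACGGTACCTTGGAAACGG"
DEFAULT_REVERSE_PRIMER = "TTGAGCCTTCGGAACCTA"


class GenerationError(DietBarcoderError):
    """Raised when a generator cannot satisfy its constraints."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Parameters of the data-generating process.

    ``dirichlet_concentration`` may be a scalar (symmetric), a length
    ``n_taxa`` vector shared by all seasons, or an ``n_seasons x n_taxa``
    array; all entries must be strictly positive.
    """

    n_taxa: int = 30
    n_seasons: int = 4
    n_individuals: int = 10
    samples_per_individual_season: int = 1
    replicates_per_sample: int = 3
    depth_lognormal_params: tuple = (8.0, 0.4)
    dirichlet_concentration: object = 0.3
    sample_concentration: float = 250.0
    tagjump_rate: float = 0.0
    contaminant_rate: float = 0.0
    host_read_fraction: float = 0.0
    detection_prob: object = 1.0
    rng_seed: int = 0
    indicators_per_season: int = 1
    n_blanks: int = 8
    n_extraction_negatives: int = 2
    n_pcr_negatives: int = 2
    n_positive_controls: int = 2
    n_contaminant_seqs: int = 3
    seq_len_range: tuple = (60, 120)
    library_id: str = "lib1"

    def __post_init__(self):
        if self.n_taxa < 1 or self.n_individuals < 1 or self.n_seasons < 1:
            raise DietBarcoderError("counts must be >= 1")
        if self.replicates_per_sample < 2:
            raise DietBarcoderError("replicates_per_sample must be >= 2")
        for name in ("tagjump_rate", "host_read_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise DietBarcoderError(f"{name} must be in [0, 1)")
        if self.contaminant_rate < 0:
            raise DietBarcoderError("contaminant_rate must be >= 0")
        if np.any(np.asarray(self.concentration_matrix()) <= 0):
            raise DietBarcoderError("dirichlet concentration must be positive")
        if self.indicators_per_season * self.n_seasons > self.n_taxa:
            raise DietBarcoderError("more indicator taxa than taxa")
        for p in self._detection_vector(["_probe"]):
            if not 0 <= p <= 1:
                raise DietBarcoderError("detection_prob must be in [0, 1]")

    def concentration_matrix(self) -> np.ndarray:
        a = np.asarray(self.dirichlet_concentration, dtype=float)
        if a.ndim == 0:
            return np.full((self.n_seasons, self.n_taxa), float(a))
        if a.ndim == 1:
            return np.tile(a, (self.n_seasons, 1))
        if a.shape != (self.n_seasons, self.n_taxa):
            raise DietBarcoderError("concentration matrix has wrong shape")
        return a

    def _detection_vector(self, taxa) -> np.ndarray:
        if isinstance(self.detection_prob, Mapping):
            return np.array([self.detection_prob.get(t, 1.0) for t in taxa])
        return np.full(len(taxa), float(self.detection_prob))

    def detection_vector(self, taxa) -> np.ndarray:
        return self._detection_vector(list(taxa))


@dataclass
class GroundTruth:
    """What the simulator actually did, for recovery tests."""

    taxa: list
    sequences: list  # diet barcode per taxon
    seasons: list
    season_composition: pd.DataFrame  # seasons x taxa
    per_sample_composition: pd.DataFrame  # sample_id x taxa
    sample_meta: pd.DataFrame  # sample_id -> individual_id, group_id, season, date
    planted_indicators: dict  # season -> [taxon]
    reference_db: ReferenceDatabase
    positive_taxa: list = field(default_factory=list)
    positive_composition: tuple = (0.7, 0.3)
    host_sequences: list = field(default_factory=list)
    contaminant_sequences: list = field(default_factory=list)
    planted_artifacts: dict = field(default_factory=dict)
    origin_totals: dict = field(default_factory=dict)
    origins: dict = field(default_factory=dict)  # category -> DataFrame seq x unit

    def __post_init__(self):
        for df in (self.season_composition, self.per_sample_composition):
            sums = df.to_numpy().sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise DietBarcoderError("composition rows must sum to 1")


# ---------------------------------------------------------------------------
# reference databases
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(_BASES, size=n))


def _draw_dissimilar(
    rng: np.random.Generator, n: int, seq_len_range, existing=(), max_identity=0.97,
    retries: int = 200,
) -> list:
    lo, hi = seq_len_range
    if lo < 10 or hi < lo:
        raise DietBarcoderError("implausible barcode length range")
    out = list(existing)
    for _ in range(n):
        for attempt in range(retries):
            cand = _random_seq(rng, lo, hi)
            if all(identity(cand, s) < max_identity for s in out):
                out.append(cand)
                break
        else:
            raise GenerationError(
                f"could not draw {n} pairwise-dissimilar sequences "
                f"of length {lo}-{hi}"
            )
    return out[len(existing):]


def _species_path(genus_i: int, species_i: int, family_i: int) -> TaxonPath:
    return TaxonPath(
        (
            "Plantae",
            "Streptophyta",
            "Magnoliopsida",
            f"Order{family_i // 2 + 1:02d}",
            f"Family{family_i + 1:02d}",
            f"Genus{genus_i + 1:03d}",
            f"Genus{genus_i + 1:03d} species{species_i + 1:03d}",
        )
    )


def gen_reference_db(
    n_unique: int,
    n_shared2: int,
    n_shared3: int,
    seq_len_range=(50, 120),
    seed: int = 0,
    scope: str = "local",
) -> ReferenceDatabase:
    """Reference database with a controlled sequence-sharing structure.

    ``n_shared2``/``n_shared3`` sequences carry two and three species labels
    respectively (distinct genera within one family, so the lowest common
    rank is family).  All sequences are pairwise <97% identical, so 97%
    clustering cannot merge them.
    """
    if min(n_unique, n_shared2, n_shared3) < 0:
        raise DietBarcoderError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    n_seq = n_unique + n_shared2 + n_shared3
    seqs = _draw_dissimilar(rng, n_seq, seq_len_range)
    records = []
    sp = 0  # running species counter
    fam = 0
    for i in range(n_unique):
        records.append(
            RefRecord(seqs[i], (_species_path(sp, sp, fam),))
        )
        sp += 1
        fam += 1
    for k, n_shared in ((2, n_shared2), (3, n_shared3)):
        for j in range(n_shared):
            taxa = []
            for _ in range(k):
                taxa.append(_species_path(sp, sp, fam))
                sp += 1
            fam += 1
            records.append(RefRecord(seqs[len(records)], tuple(taxa)))
    return ReferenceDatabase(records, scope=scope)


# ---------------------------------------------------------------------------
# ground-truth compositions
# ---------------------------------------------------------------------------


def gen_seasonal_profiles(cfg: SimulationConfig) -> GroundTruth:
    """Seasonal Dirichlet compositions with planted season-specific
    indicator taxa, plus per-sample compositions resampled around them."""
    rng = np.random.default_rng(cfg.rng_seed)
    calendar = ab.default_calendar(cfg.n_seasons)
    seasons = calendar.names

    db = gen_reference_db(
        cfg.n_taxa + 2, 0, 0, cfg.seq_len_range, seed=int(rng.integers(2**31))
    )
    taxa = [r.taxa[0].name for r in db.records[: cfg.n_taxa]]
    sequences = [r.sequence for r in db.records[: cfg.n_taxa]]
    positive_taxa = [r.taxa[0].name for r in db.records[cfg.n_taxa:]]

    # plant indicators: round-robin over seasons
    n_ind = cfg.indicators_per_season * cfg.n_seasons
    indicator_idx = rng.choice(cfg.n_taxa, size=n_ind, replace=False)
    planted = {
        s: [taxa[indicator_idx[i * cfg.indicators_per_season + j]] for j in range(cfg.indicators_per_season)]
        for i, s in enumerate(seasons)
    }
    indicator_season = {}
    for s, ts in planted.items():
        for t in ts:
            indicator_season[taxa.index(t)] = s

    alpha = cfg.concentration_matrix()
    comp = np.zeros((cfg.n_seasons, cfg.n_taxa))
    for i, s in enumerate(seasons):
        base = np.zeros(cfg.n_taxa)
        non_ind = [k for k in range(cfg.n_taxa) if k not in indicator_season]
        own_ind = [k for k in indicator_season if indicator_season[k] == s]
        base[non_ind] = rng.dirichlet(alpha[i, non_ind])
        ind_mass = rng.uniform(0.05, 0.12, size=len(own_ind))
        base *= 1.0 - ind_mass.sum()
        base[own_ind] = ind_mass
        comp[i] = base / base.sum()

    season_composition = pd.DataFrame(comp, index=seasons, columns=taxa)

    # samples: individuals x seasons x replicates-of-sampling
    groups = [f"grp{chr(ord('A') + g)}" for g in range(min(4, cfg.n_individuals))]
    individuals = [f"ind{i + 1:03d}" for i in range(cfg.n_individuals)]
    ind_group = {ind: groups[i % len(groups)] for i, ind in enumerate(individuals)}

    rows = []
    comps = []
    for si, season in enumerate(seasons):
        days = calendar.days_in_season(season)
        support = comp[si] > 0
        for ind in individuals:
            for j in range(cfg.samples_per_individual_season):
                sid = f"{ind}.{season}.{j + 1}"
                a = comp[si, support] * cfg.sample_concentration
                row = np.zeros(cfg.n_taxa)
                row[support] = rng.dirichlet(np.maximum(a, 1e-6))
                comps.append(row / row.sum())
                date = days[int(rng.integers(len(days)))]
                rows.append(
                    {
                        "sample_id": sid,
                        "individual_id": ind,
                        "group_id": ind_group[ind],
                        "season": season,
                        "collection_date": date.isoformat(),
                    }
                )
    sample_meta = pd.DataFrame(rows).set_index("sample_id", drop=False)
    per_sample = pd.DataFrame(
        np.array(comps), index=sample_meta.index, columns=taxa
    )

    return GroundTruth(
        taxa=taxa,
        sequences=sequences,
        seasons=list(seasons),
        season_composition=season_composition,
        per_sample_composition=per_sample,
        sample_meta=sample_meta,
        planted_indicators=planted,
        reference_db=db,
        positive_taxa=positive_taxa,
    )


# ---------------------------------------------------------------------------
# read tables
# ---------------------------------------------------------------------------


def _jump_reads(rng, mat: np.ndarray, rate: float) -> tuple:
    """Move reads between units: each read leaks with probability ``rate``
    to a uniformly chosen other unit.  Returns (depleted_source, jumped)."""
    n_seq, n_units = mat.shape
    jumped = np.zeros_like(mat)
    if rate <= 0 or n_units < 2:
        return mat, jumped
    moved = rng.binomial(mat, rate)
    src = mat - moved
    for s, u in zip(*np.nonzero(moved)):
        p = np.full(n_units, 1.0 / (n_units - 1))
        p[u] = 0.0
        jumped[s] += rng.multinomial(moved[s, u], p)
    return src, jumped


def gen_read_table(truth: GroundTruth, cfg: SimulationConfig) -> tuple:
    """Simulate one library: triplicate sample wells plus control wells,
    with multinomial diet reads and planted artifact reads.

    Returns ``(table, truth)`` where ``truth`` has been updated in place
    with planted-artifact records, per-category origin matrices, and
    category totals that reconcile with the table's grand total.
    """
    rng = np.random.default_rng(cfg.rng_seed + 1)
    mu, sigma = cfg.depth_lognormal_params

    unit_rows = []
    for sid, m in truth.sample_meta.iterrows():
        for r in range(1, cfg.replicates_per_sample + 1):
            unit_rows.append(
                {
                    "unit_id": f"{sid}.r{r}",
                    "sample_id": sid,
                    "individual_id": m["individual_id"],
                    "group_id": m["group_id"],
                    "collection_date": m["collection_date"],
                    "replicate_index": r,
                    "unit_type": "sample",
                }
            )

    def control(unit_type: str, short: str, n: int):
        for i in range(1, n + 1):
            unit_rows.append(
                {
                    "unit_id": f"{short}{i:02d}",
                    "sample_id": f"{short}{i:02d}",
                    "individual_id": "control",
                    "group_id": "control",
                    "collection_date": "",
                    "replicate_index": 1,
                    "unit_type": unit_type,
                }
            )

    control("blank", "blank", cfg.n_blanks)
    control("extraction_negative", "extneg", cfg.n_extraction_negatives)
    control("pcr_negative", "pcrneg", cfg.n_pcr_negatives)
    control("positive_control", "poscon", cfg.n_positive_controls)

    units = make_units(unit_rows)
    n_units = len(units)
    unit_ids = list(units.index)
    is_sample = (units["unit_type"] == "sample").to_numpy()
    is_positive = (units["unit_type"] == "positive_control").to_numpy()
    is_negative = units["unit_type"].isin(
        ["extraction_negative", "pcr_negative"]
    ).to_numpy()

    # sequence rows: diet, positive-control taxa, host, contaminants
    pos_records = [
        r for r in truth.reference_db.records
        if r.taxa[0].name in truth.positive_taxa
    ]
    pos_seqs = [r.sequence for r in pos_records]
    host_seqs = []
    contam_seqs = []
    taken = list(truth.sequences) + pos_seqs
    if cfg.host_read_fraction > 0:
        host_seqs = _draw_dissimilar(
            rng, 2, cfg.seq_len_range, existing=taken
        )
        taken += host_seqs
    if cfg.contaminant_rate > 0:
        contam_seqs = _draw_dissimilar(
            rng, cfg.n_contaminant_seqs, cfg.seq_len_range, existing=taken
        )
    sequences = list(truth.sequences) + pos_seqs + host_seqs + contam_seqs
    n_seq = len(sequences)
    seq_at = {s: i for i, s in enumerate(sequences)}

    composition = np.zeros((n_seq, n_units), dtype=np.int64)
    host = np.zeros_like(composition)
    contaminant = np.zeros_like(composition)

    sample_comp = truth.per_sample_composition.to_numpy()
    sid_row = {sid: i for i, sid in enumerate(truth.per_sample_composition.index)}

    for u, (uid, m) in enumerate(units.iterrows()):
        if m["unit_type"] == "sample":
            depth = int(np.round(rng.lognormal(mu, sigma)))
            if depth == 0:
                continue
            n_host = rng.binomial(depth, cfg.host_read_fraction)
            if n_host:
                split = rng.binomial(n_host, 0.9)  # vervet vs human
                host[seq_at[host_seqs[0]], u] = split
                host[seq_at[host_seqs[1]], u] = n_host - split
            diet = rng.multinomial(depth - n_host, sample_comp[sid_row[m["sample_id"]]])
            composition[: len(truth.sequences), u] += diet
        elif m["unit_type"] == "positive_control":
            depth = int(np.round(rng.lognormal(mu, sigma)))
            if depth == 0:
                continue
            mix = rng.multinomial(depth, np.asarray(truth.positive_composition))
            for seq, c in zip(pos_seqs, mix):
                composition[seq_at[seq], u] = c

    if contam_seqs:
        inject = is_sample | is_negative
        lam = np.where(inject, cfg.contaminant_rate, 0.0)
        for seq in contam_seqs:
            contaminant[seq_at[seq]] = rng.poisson(lam)

    composition, jumped_c = _jump_reads(rng, composition, cfg.tagjump_rate)
    host, jumped_h = _jump_reads(rng, host, cfg.tagjump_rate)
    tagjump = jumped_c + jumped_h

    counts = composition + host + tagjump + contaminant
    table = ReadTable(sequences, counts, units, cfg.library_id)

    def cells(mat):
        return [
            (unit_ids[u], sequences[s], int(mat[s, u]))
            for s, u in zip(*np.nonzero(mat))
        ]

    truth.host_sequences = host_seqs
    truth.contaminant_sequences = contam_seqs
    truth.planted_artifacts = {
        "tagjump": cells(tagjump),
        "contaminant": cells(contaminant),
        "host": cells(host),
    }
    truth.origin_totals = {
        "composition": int(composition.sum()),
        "host": int(host.sum()),
        "tagjump": int(tagjump.sum()),
        "contaminant": int(contaminant.sum()),
    }
    truth.origins = {
        name: pd.DataFrame(mat, index=sequences, columns=unit_ids)
        for name, mat in (
            ("composition", composition),
            ("host", host),
            ("tagjump", tagjump),
            ("contaminant", contaminant),
        )
    }
    return table, truth


# ---------------------------------------------------------------------------
# tagged raw reads
# ---------------------------------------------------------------------------


def gen_tag_table(
    unit_ids,
    seed: int = 0,
    forward_primer: str = DEFAULT_FORWARD_PRIMER,
    reverse_primer: str = DEFAULT_REVERSE_PRIMER,
) -> TagAssignmentTable:
    """Unique random 8-nt tag pairs for every unit."""
    rng = np.random.default_rng(seed)
    pairs = set()
    rows = []
    for uid in unit_ids:
        for _ in range(1000):
            pair = (
                "".join(rng.choice(_BASES, size=8)),
                "".join(rng.choice(_BASES, size=8)),
            )
            if pair not in pairs:
                pairs.add(pair)
                break
        else:  # pragma: no cover
            raise GenerationError("could not draw unique tag pairs")
        rows.append(
            {
                "unit_id": uid,
                "forward_tag": pair[0],
                "reverse_tag": pair[1],
                "forward_primer": forward_primer,
                "reverse_primer": reverse_primer,
            }
        )
    return TagAssignmentTable(pd.DataFrame(rows))


def _mutate(rng, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < error_rate:
            chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    return "".join(chars)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def gen_raw_reads(
    table: ReadTable,
    tags: TagAssignmentTable,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list:
    """One FASTA record per read: tag + primer + insert + rc(primer) + rc(tag).

    Substitution errors at ``error_rate`` per base are confined to the two
    primer regions, so demultiplexing mismatch logic is exercised without
    corrupting tags or inserts.
    """
    rng = np.random.default_rng(seed)
    by_unit = {r.unit_id: r for r in tags.rows.itertuples(index=False)}
    missing = set(table.units.index) - set(by_unit)
    if missing:
        raise DietBarcoderError(f"units without tag assignment: {sorted(missing)[:5]}")
    records = []
    i = 0
    for u, uid in enumerate(table.units.index):
        t = by_unit[uid]
        for s, seq in enumerate(table.sequences):
            for _ in range(int(table.counts[s, u])):
                fp = _mutate(rng, t.forward_primer, error_rate)
                rp = _mutate(rng, t.reverse_primer, error_rate)
                read = (
                    t.forward_tag + fp + seq + _revcomp(rp) + _revcomp(t.reverse_tag)
                )
                records.append(
                    SeqRecord(Seq(read), id=f"read{i:07d}", description="")
                )
                i += 1
    return records


# ---------------------------------------------------------------------------
# focal logs
# ---------------------------------------------------------------------------


def gen_focal_log(
    truth: GroundTruth,
    cfg: SimulationConfig,
    days_per_season: int = 20,
    follows_per_day: int = 3,
    feeding_prob: float = 0.6,
    level_map: Mapping | None = None,
) -> ab.FocalLog:
    """Observation log: 10 screenings per 20-min focal follow; feeding events
    drawn from the day's season composition, thinned per-taxon by
    ``detection_prob``, and recorded at an item-specific taxon level
    (random species/genus/broad mix unless ``level_map`` pins it)."""
    rng = np.random.default_rng(cfg.rng_seed + 2)
    calendar = ab.default_calendar(cfg.n_seasons)
    detect = cfg.detection_vector(truth.taxa)
    # item-specific observer resolution
    if level_map is None:
        levels = rng.choice(
            ["species", "genus", "broad"], size=len(truth.taxa), p=[0.7, 0.2, 0.1]
        )
    else:
        levels = [level_map.get(t, "species") for t in truth.taxa]
    individuals = sorted(truth.sample_meta["individual_id"].unique())

    def recorded(taxon_i: int) -> tuple:
        lvl = levels[taxon_i]
        name = truth.taxa[taxon_i]
        if lvl == "species":
            return name, "species"
        if lvl == "genus":
            return name.split()[0], "genus"
        return "undetermined plant", "broad"

    events = []
    screenings = []
    for si, season in enumerate(truth.seasons):
        days = calendar.days_in_season(season)
        picks = sorted(rng.choice(len(days), size=min(days_per_season, len(days)), replace=False))
        comp = truth.season_composition.loc[season].to_numpy()
        for di in picks:
            date = days[di].isoformat()
            n_follows = follows_per_day
            screenings.append({"date": date, "count": 10 * n_follows})
            for _ in range(n_follows):
                ind = individuals[int(rng.integers(len(individuals)))]
                for _ in range(10):  # instantaneous points per follow
                    if rng.random() >= feeding_prob:
                        continue
                    k = int(rng.choice(len(comp), p=comp))
                    if rng.random() >= detect[k]:
                        continue
                    item, lvl = recorded(k)
                    events.append(
                        {"date": date, "individual_id": ind, "item": item, "level": lvl}
                    )
    ev = pd.DataFrame(events, columns=["date", "individual_id", "item", "level"])
    sc = pd.DataFrame(screenings, columns=["date", "count"])
    return ab.FocalLog(ev, sc)
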