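"""Synthetic small-RNA FASTQ libraries with known ground truth.

Emulates the statistical structure of pooled plasma-EV small-RNA libraries:
a mixture over ncRNA classes with class-specific insert-length laws (miRNA
inserts around 18–24 nt; YRNA/tRNA fragments around 29–34 nt), 3'-adapter
ligation into a fixed-length read, and the six filtering artifact categories
at configurable rates.  Every read carries a planted category and, for clean
reads, a source reference — the oracle the filtering and quantification
stages are validated against.

By default artifact reads are *unambiguous by construction*: each artifact is
built so that it can only satisfy its own category's rule (e.g. poly reads
contain no adapter-5' run, too-short inserts are 10–16 nt of mixed bases), so
a filtering pass recovers the planted counts exactly.  ``ambiguous=True``
relaxes those guards for robustness testing.

Sequencing errors are not modelled; reads are template-perfect and quality
strings only encode the clean/inferior-quality distinction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .qcfilter import (
    DEFAULT_ADAPTER3,
    DEFAULT_ADAPTER5,
    QualityConfig,
    find_adapter3,
    is_poly_repeat,
    _has_adapter5_run,
)
from .refdb import Catalog, ReferenceRecord

ARTIFACT_CATEGORIES = (
    "adapter3_null",
    "insert_null",
    "adapter5_contaminant",
    "inferior_quality",
    "too_short",
    "poly_repeat",
)

#: Class mixture of the default library: YRNA-fragment dominated with a
#: substantial miRNA component, minor tRNA/rRNA/snRNA/snoRNA/piRNA mass —
#: the composition profile typical of NSCLC plasma-EV small-RNA pools.
DEFAULT_CLASS_WEIGHTS: dict[str, float] = {
    "miRNA": 0.30,
    "YRNA": 0.51,
    "tRNA": 0.011,
    "rRNA": 0.05,
    "snRNA": 0.03,
    "snoRNA": 0.019,
    "piRNA": 0.08,
}

#: Default artifact rates, matching the magnitude of a real EV library's
#: filtering statistics (~93% clean).
DEFAULT_ARTIFACT_RATES: dict[str, float] = {
    "adapter3_null": 0.0191,
    "insert_null": 0.0098,
    "adapter5_contaminant": 0.0006,
    "inferior_quality": 0.0049,
    "too_short": 0.0356,
    "poly_repeat": 0.0002,
}


@dataclass(frozen=True)
class ClassInsertLaw:
    """Insert-length law for one RNA class.

    mode="offset": insert length = reference length + Δ, Δ drawn from
    ``values`` with ``probs``; negative Δ trims the 3' end, positive Δ
    extends into the precursor context 3' of the mature sequence (capped at
    the context boundary when no precursor is linked).  Models isomiR end
    heterogeneity around a mature miRNA.

    mode="fragment": insert = 5'-anchored prefix of the reference of
    absolute length drawn from ``values``/``probs`` (capped at the reference
    length).  Models degradation-fragment classes (YRNA/tRNA/rRNA/... pieces
    of a longer transcript).
    """

    mode: str
    values: tuple[int, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.mode not in ("offset", "fragment"):
            raise ValueError(f"unknown insert-law mode {self.mode!r}")
        if len(self.values) != len(self.probs) or not self.values:
            raise ValueError("values and probs must be non-empty and equal-length")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("probs must sum to 1")


#: Per-class laws; fragment-length peaks follow the class-specific size
#: distributions seen in plasma-EV libraries (YRNA/tRNA 29–34 nt,
#: rRNA 20–32 nt, snRNA 19–24 nt, snoRNA ~27 nt, piRNA fragments 20–22 nt).
DEFAULT_INSERT_LAWS: dict[str, ClassInsertLaw] = {
    "miRNA": ClassInsertLaw("offset", (-2, -1, 0, 1, 2), (0.1, 0.2, 0.4, 0.2, 0.1)),
    "YRNA": ClassInsertLaw(
        "fragment", (29, 30, 31, 32, 33, 34), (0.05, 0.1, 0.2, 0.4, 0.15, 0.1)
    ),
    "tRNA": ClassInsertLaw(
        "fragment", (29, 30, 31, 32, 33, 34), (0.1, 0.2, 0.3, 0.2, 0.1, 0.1)
    ),
    "rRNA": ClassInsertLaw(
        "fragment", tuple(range(20, 33)), tuple([1 / 13] * 13)
    ),
    "snRNA": ClassInsertLaw(
        "fragment", (19, 20, 21, 22, 23, 24), (0.1, 0.2, 0.25, 0.25, 0.1, 0.1)
    ),
    "snoRNA": ClassInsertLaw(
        "fragment", (25, 26, 27, 28, 29), (0.1, 0.25, 0.3, 0.25, 0.1)
    ),
    "piRNA": ClassInsertLaw("fragment", (20, 21, 22), (0.3, 0.4, 0.3)),
}


@dataclass
class SimulationConfig:
    """Knobs of one simulated library."""

    library_size: int = 100_000
    seed: int = 0
    class_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    insert_laws: dict[str, ClassInsertLaw] = field(
        default_factory=lambda: dict(DEFAULT_INSERT_LAWS)
    )
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    artifact_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARTIFACT_RATES)
    )
    read_length: int = 50
    ambiguous: bool = False
    quality_cfg: QualityConfig = field(default_factory=QualityConfig)

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        bad = set(self.artifact_rates) - set(ARTIFACT_CATEGORIES)
        if bad:
            raise ValueError(f"unknown artifact categories {sorted(bad)}")
        total = sum(self.artifact_rates.values())
        if total > 1.0 + 1e-12 or any(r < 0 for r in self.artifact_rates.values()):
            raise ValueError("artifact rates must be nonnegative and sum to <= 1")
        if not self.class_weights or sum(self.class_weights.values()) <= 0:
            raise ValueError("class weights must have positive total mass")

    @property
    def clean_rate(self) -> float:
        return 1.0 - sum(self.artifact_rates.get(c, 0.0) for c in ARTIFACT_CATEGORIES)


@dataclass
class GroundTruth:
    """Planted labels of a simulated library."""

    read_categories: list[tuple[str, str]]  # (read_id, category)
    read_sources: dict[str, str]  # read_id -> reference id (clean reads only)
    copy_counts: dict[str, int]  # reference id -> clean-read copies
    inserts: dict[str, str]  # read_id -> true insert (clean reads only)

    def category_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, cat in self.read_categories:
            out[cat] = out.get(cat, 0) + 1
        return out

    def confirmable_mirna_counts(
        self, catalog: Catalog, max_len_diff: int = 4
    ) -> dict[str, int]:
        """Planted copies per miRNA that satisfy the confirmation rule.

        Only reads whose insert contains the entire mature sequence with a
        length difference within ``max_len_diff`` nt can ever be confirmed
        by quantification; 3'-trimmed isomiRs are planted but, by design,
        excluded from miRNA calls.  This is the exact oracle for
        quantification recovery.
        """
        out: dict[str, int] = {}
        for rid, src in self.read_sources.items():
            rec = catalog.get(src)
            if rec.rna_class != "miRNA":
                continue
            insert = self.inserts[rid]
            if rec.seq in insert and abs(len(insert) - len(rec.seq)) <= max_len_diff:
                out[src] = out.get(src, 0) + 1
        return out

    def write_tsv(self, path: str | Path) -> None:
        srcs = self.read_sources
        with open(path, "w") as fh:
            fh.write("read_id\tcategory\tsource_id\n")
            for rid, cat in self.read_categories:
                fh.write(f"{rid}\t{cat}\t{srcs.get(rid, '.')}\n")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _quality_string(rng: np.random.Generator, length: int, clean: bool) -> str:
    if clean:
        # every base >= Q30
        scores = rng.integers(30, 41, size=length)
    else:
        # mean well below Q20
        scores = rng.integers(2, 18, size=length)
    return "".join(chr(33 + int(s)) for s in scores)


def _clean_insert(
    rng: np.random.Generator, record: ReferenceRecord, catalog: Catalog, law: ClassInsertLaw
) -> str:
    choice = int(rng.choice(len(law.values), p=law.probs))
    if law.mode == "fragment":
        length = min(law.values[choice], len(record.seq))
        return record.seq[:length]
    delta = law.values[choice]
    if delta <= 0:
        return record.seq[: max(1, len(record.seq) + delta)]
    ctx = catalog.precursor_of(record)
    if ctx is None:
        return record.seq
    off = catalog.mature_offset(record)
    end = min(off + len(record.seq) + delta, len(ctx))
    return ctx[off:end]


class _ArtifactFactory:
    """Builds artifact reads; unambiguous mode guards each category's rule."""

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng

    def _pad_to_length(self, core: str) -> str:
        n = self.cfg.read_length - len(core)
        if n <= 0:
            return core[: self.cfg.read_length]
        return core + _random_seq(self.rng, n)

    def _wrap_insert(self, insert: str) -> str:
        """insert + 3' adapter + random padding, adapter junction guaranteed
        to be the first adapter occurrence in unambiguous mode."""
        cfg = self.cfg
        for _ in range(200):
            read = self._pad_to_length(insert + cfg.adapter3)
            if cfg.ambiguous:
                return read
            if find_adapter3(read, cfg.adapter3, cfg.quality_cfg.adapter_min_overlap) == len(insert):
                return read
            # adapter prefix occurred inside the insert or padding; re-pad is
            # pointless if the collision is in the insert itself
            if find_adapter3(
                insert, cfg.adapter3, cfg.quality_cfg.adapter_min_overlap
            ) >= 0:
                raise ValueError(
                    "insert contains the 3' adapter prefix; cannot build an "
                    "unambiguous read"
                )
        raise RuntimeError("failed to wrap insert without spurious adapter hit")

    def _mixed_insert(self, length: int) -> str:
        """Random insert free of adapter hits, 5'-adapter runs and poly runs."""
        cfg = self.cfg
        for _ in range(500):
            ins = _random_seq(self.rng, length)
            if cfg.ambiguous:
                return ins
            if find_adapter3(ins, cfg.adapter3, cfg.quality_cfg.adapter_min_overlap) >= 0:
                continue
            if _has_adapter5_run(ins, cfg.adapter5, cfg.quality_cfg.adapter5_min_run):
                continue
            if is_poly_repeat(ins, cfg.quality_cfg.poly_fraction):
                continue
            return ins
        raise RuntimeError("failed to build a mixed insert")

    def build(self, category: str) -> tuple[str, str]:
        cfg, rng = self.cfg, self.rng
        L = cfg.read_length
        if category == "adapter3_null":
            for _ in range(500):
                read = _random_seq(rng, L)
                if find_adapter3(read, cfg.adapter3, cfg.quality_cfg.adapter_min_overlap) < 0:
                    return read, _quality_string(rng, L, clean=True)
            raise RuntimeError("failed to build adapter3_null read")
        if category == "insert_null":
            read = self._pad_to_length(cfg.adapter3)
            return read, _quality_string(rng, L, clean=True)
        if category == "adapter5_contaminant":
            run = cfg.quality_cfg.adapter5_min_run + 2
            ins = cfg.adapter5[:run] + self._mixed_insert(10)
            read = self._wrap_insert(ins)
            return read, _quality_string(rng, L, clean=True)
        if category == "inferior_quality":
            ins = self._mixed_insert(22)
            read = self._wrap_insert(ins)
            qual = _quality_string(rng, len(ins), clean=False) + _quality_string(
                rng, L - len(ins), clean=True
            )
            return read, qual
        if category == "too_short":
            length = int(rng.integers(10, cfg.quality_cfg.min_insert_len))
            ins = self._mixed_insert(length)
            read = self._wrap_insert(ins)
            return read, _quality_string(rng, L, clean=True)
        if category == "poly_repeat":
            base = "ACGT"[int(rng.integers(0, 4))]
            ins = base * 20
            # a homopolymer can collide with the adapters only if they carry
            # long runs themselves; the defaults do not
            read = self._wrap_insert(ins)
            return read, _quality_string(rng, L, clean=True)
        raise ValueError(f"unknown artifact category {category!r}")


def _check_clean_insert(insert: str, cfg: SimulationConfig) -> None:
    q = cfg.quality_cfg
    if not (q.min_insert_len <= len(insert) <= q.max_insert_len):
        raise ValueError(
            f"clean insert of {len(insert)} nt outside the "
            f"{q.min_insert_len}–{q.max_insert_len} window"
        )
    if not cfg.ambiguous:
        if find_adapter3(insert, cfg.adapter3, q.adapter_min_overlap) >= 0:
            raise ValueError("reference-derived insert contains the 3' adapter prefix")
        if _has_adapter5_run(insert, cfg.adapter5, q.adapter5_min_run):
            raise ValueError("reference-derived insert contains a 5'-adapter run")
        if is_poly_repeat(insert, q.poly_fraction):
            raise ValueError("reference-derived insert is a poly repeat")


def _per_record_rates(
    config: SimulationConfig, catalog: Catalog
) -> tuple[list[ReferenceRecord], np.ndarray]:
    """Expected clean-read share of each catalog record.

    Class mass is split uniformly among the records of that class; classes
    with weight but no records are an error when total clean mass > 0.
    """
    weights = config.class_weights
    wsum = sum(weights.values())
    recs: list[ReferenceRecord] = []
    shares: list[float] = []
    for cls, w in weights.items():
        if w <= 0:
            continue
        members = catalog.by_class(cls)
        if not members:
            raise ValueError(f"class {cls!r} has weight but no catalog records")
        for rec in members:
            recs.append(rec)
            shares.append(w / wsum / len(members))
    if not recs:
        raise ValueError("no catalog records receive clean-read mass")
    return recs, np.asarray(shares)


def simulate_library(
    config: SimulationConfig, catalog: Catalog
) -> tuple[list[tuple[str, str, str]], GroundTruth]:
    """Simulate one library; returns FASTQ tuples ``(id, seq, qual)`` + truth.

    Deterministic for a fixed config (seed included): the same config yields
    byte-identical records.
    """
    rng = np.random.default_rng(config.seed)
    n = config.library_size
    cats = list(ARTIFACT_CATEGORIES) + ["clean"]
    probs = np.array(
        [config.artifact_rates.get(c, 0.0) for c in ARTIFACT_CATEGORIES]
        + [config.clean_rate]
    )
    counts = rng.multinomial(n, probs)
    category_of_read = np.repeat(np.arange(len(cats)), counts)
    rng.shuffle(category_of_read)

    n_clean = int(counts[-1])
    if n_clean > 0 and len(catalog) == 0:
        raise ValueError("empty catalog but nonzero clean-read mass")
    if n_clean > 0:
        recs, shares = _per_record_rates(config, catalog)
        rec_counts = rng.multinomial(n_clean, shares)
        source_pool = np.repeat(np.arange(len(recs)), rec_counts)
        rng.shuffle(source_pool)
    else:
        recs, rec_counts, source_pool = [], np.array([], dtype=int), np.array([], dtype=int)

    factory = _ArtifactFactory(config, rng)
    records: list[tuple[str, str, str]] = []
    read_categories: list[tuple[str, str]] = []
    read_sources: dict[str, str] = {}
    inserts: dict[str, str] = {}
    copy_counts: dict[str, int] = {}
    clean_i = 0
    for i, cat_idx in enumerate(category_of_read):
        rid = f"read_{i:07d}"
        cat = cats[cat_idx]
        if cat == "clean":
            rec = recs[int(source_pool[clean_i])]
            clean_i += 1
            law = config.insert_laws[rec.rna_class]
            insert = _clean_insert(rng, rec, catalog, law)
            _check_clean_insert(insert, config)
            seq = factory._wrap_insert(insert)
            qual = _quality_string(rng, config.read_length, clean=True)
            read_sources[rid] = rec.id
            inserts[rid] = insert
            copy_counts[rec.id] = copy_counts.get(rec.id, 0) + 1
        else:
            seq, qual = factory.build(cat)
        records.append((rid, seq, qual))
        read_categories.append((rid, cat))

    truth = GroundTruth(read_categories, read_sources, copy_counts, inserts)
    assert sum(truth.category_counts().values()) == n
    return records, truth


def write_fastq(records: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def simulate_two_group(
    config: SimulationConfig,
    catalog: Catalog,
    fold_change_map: Mapping[str, float],
    seed_a: int,
    seed_b: int,
) -> tuple[
    list[tuple[str, str, str]],
    GroundTruth,
    list[tuple[str, str, str]],
    GroundTruth,
    dict[str, float],
]:
    """Two libraries sharing a catalog, with planted per-feature fold changes.

    Group A follows ``config``; group B multiplies the expected clean copy
    count of each feature in ``fold_change_map`` by its fold change.  To keep
    the "expected B = expected A x FC" contract exact, per-feature clean
    counts are drawn independently (Poisson) rather than under a fixed-total
    multinomial, so each library's total is Poisson-distributed around the
    target size.  Returns (records_a, truth_a, records_b, truth_b,
    planted_log2fc) with planted log2 fold changes for every catalog feature
    (0 where unchanged).
    """
    for fid, fc in fold_change_map.items():
        if fc <= 0:
            raise ValueError(f"fold change for {fid!r} must be > 0, got {fc}")
        catalog.get(fid)  # KeyError if unknown

    planted = {rec.id: 0.0 for rec in catalog}
    planted.update({fid: math.log2(fc) for fid, fc in fold_change_map.items()})

    out = []
    for seed, scale_map in ((seed_a, None), (seed_b, fold_change_map)):
        rng = np.random.default_rng(seed)
        recs, shares = _per_record_rates(config, catalog)
        lam = shares * config.library_size * config.clean_rate
        if scale_map:
            lam = lam.copy()
            for j, rec in enumerate(recs):
                if rec.id in scale_map:
                    lam[j] *= scale_map[rec.id]
        rec_counts = rng.poisson(lam)
        art_counts = rng.multinomial(
            config.library_size,
            np.array(
                [config.artifact_rates.get(c, 0.0) for c in ARTIFACT_CATEGORIES]
                + [config.clean_rate]
            ),
        )[:-1]

        factory = _ArtifactFactory(config, rng)
        records: list[tuple[str, str, str]] = []
        read_categories: list[tuple[str, str]] = []
        read_sources: dict[str, str] = {}
        inserts: dict[str, str] = {}
        copy_counts: dict[str, int] = {}
        i = 0
        for cat, cnt in zip(ARTIFACT_CATEGORIES, art_counts):
            for _ in range(int(cnt)):
                rid = f"read_{i:07d}"
                seq, qual = factory.build(cat)
                records.append((rid, seq, qual))
                read_categories.append((rid, cat))
                i += 1
        for j, rec in enumerate(recs):
            law = config.insert_laws[rec.rna_class]
            for _ in range(int(rec_counts[j])):
                rid = f"read_{i:07d}"
                insert = _clean_insert(rng, rec, catalog, law)
                _check_clean_insert(insert, config)
                seq = factory._wrap_insert(insert)
                records.append((rid, seq, _quality_string(rng, config.read_length, True)))
                read_categories.append((rid, "clean"))
                read_sources[rid] = rec.id
                inserts[rid] = insert
                copy_counts[rec.id] = copy_counts.get(rec.id, 0) + 1
                i += 1
        out.append((records, GroundTruth(read_categories, read_sources, copy_counts, inserts)))

    (records_a, truth_a), (records_b, truth_b) = out
    return records_a, truth_a, records_b, truth_b, planted


# 5'-end 32-mer of hY4 and its antisense counterpart, the two YRNA fragments
# dominating NSCLC plasma-EV libraries.
HY4F = "AGTTCTGATAACCCACTACCATCGGACCAGCC"
HY4RF = "GGCTGGTCCGATGGTAGTGGGTTATCAGAACT"

_DEFAULT_REF_LENGTHS = {
    "YRNA": 96,
    "tRNA": 73,
    "rRNA": 120,
    "snRNA": 106,
    "snoRNA": 80,
    "piRNA": 30,
}


def _guarded_seq(
    rng: np.random.Generator,
    length: int,
    cfg: SimulationConfig,
    check_prefix_lengths: Sequence[int] = (),
) -> str:
    """Random reference free of adapter collisions/poly runs (all prefixes)."""
    q = cfg.quality_cfg
    for _ in range(1000):
        s = _random_seq(rng, length)
        if find_adapter3(s, cfg.adapter3, q.adapter_min_overlap) >= 0:
            continue
        if _has_adapter5_run(s, cfg.adapter5, q.adapter5_min_run):
            continue
        if any(is_poly_repeat(s[:k], q.poly_fraction) for k in check_prefix_lengths):
            continue
        return s
    raise RuntimeError("failed to build a guarded reference sequence")


def make_synthetic_catalog(
    seed: int = 0,
    n_mirna: int = 20,
    n_per_fragment_class: int = 4,
    include_hy4: bool = True,
    config: SimulationConfig | None = None,
) -> Catalog:
    """Build a fully synthetic reference catalog suitable for simulation.

    Records are random sequences screened so that every insert the default
    insert laws can derive from them survives filtering (no spurious adapter
    hits, no poly runs); miRNA matures (22 nt) come with synthetic precursor
    contexts (20 nt flanks) so templated 3' extensions exist.  Loci are
    synthetic hg19-style placements for the chromosome-abundance summary.
    When ``include_hy4`` is set, a synthetic full-length hY4 stand-in whose
    5' end is the canonical 32-nt hY4F fragment is added to the YRNA class.
    """
    from .refdb import Locus  # local import to avoid cycle at module load

    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    records: list[ReferenceRecord] = []
    precursors: dict[str, str] = {}
    chrom_cycle = [f"chr{c}" for c in (2, 3, 6, 7, 8, 1, 12, 17)]
    pos = 1_000_000

    def next_locus(length: int) -> Locus:
        nonlocal pos
        chrom = chrom_cycle[len(records) % len(chrom_cycle)]
        start = pos
        pos += 50_000
        return Locus(chrom, start, start + length, "+")

    for i in range(n_mirna):
        for _ in range(1000):
            flank5 = _random_seq(rng, 20)
            mature = _guarded_seq(rng, 22, cfg, check_prefix_lengths=range(20, 23))
            flank3 = _random_seq(rng, 20)
            hairpin = flank5 + mature + flank3
            # extensions into the precursor must stay clean too
            ext = [mature + flank3[:k] for k in (1, 2)]
            q = cfg.quality_cfg
            if any(
                find_adapter3(e, cfg.adapter3, q.adapter_min_overlap) >= 0
                or _has_adapter5_run(e, cfg.adapter5, q.adapter5_min_run)
                or is_poly_repeat(e, q.poly_fraction)
                for e in ext
            ):
                continue
            if hairpin.count(mature) != 1:
                continue
            break
        else:
            raise RuntimeError("failed to build miRNA record")
        mid = f"syn-miR-{i + 1}"
        pid = f"syn-mir-{i + 1}"
        precursors[pid] = hairpin
        records.append(
            ReferenceRecord(mid, mature, "miRNA", precursor_id=pid, locus=next_locus(22))
        )

    for cls, ref_len in _DEFAULT_REF_LENGTHS.items():
        law = DEFAULT_INSERT_LAWS[cls]
        lengths = [min(v, ref_len) for v in law.values]
        for i in range(n_per_fragment_class):
            seq = _guarded_seq(rng, ref_len, cfg, check_prefix_lengths=lengths)
            records.append(
                ReferenceRecord(f"syn-{cls}-{i + 1}", seq, cls, locus=next_locus(ref_len))
            )

    if include_hy4:
        law = DEFAULT_INSERT_LAWS["YRNA"]
        q = cfg.quality_cfg
        for _ in range(1000):
            tail = _random_seq(rng, _DEFAULT_REF_LENGTHS["YRNA"] - len(HY4F))
            full = HY4F + tail
            if find_adapter3(full, cfg.adapter3, q.adapter_min_overlap) >= 0:
                continue
            if _has_adapter5_run(full, cfg.adapter5, q.adapter5_min_run):
                continue
            if any(is_poly_repeat(full[:k], q.poly_fraction) for k in law.values):
                continue
            break
        else:
            raise RuntimeError("failed to build hY4 stand-in")
        records.append(
            ReferenceRecord(
                "hY4-synthetic",
                HY4F + tail,
                "YRNA",
                locus=Locus("chr7", 148_000_000, 148_000_000 + 96, "+"),
            )
        )

    return Catalog(records=records, precursor_seqs=precursors)
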