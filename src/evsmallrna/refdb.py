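"""Reference catalogs of small non-coding RNAs and core sequence utilities.

A :class:`Catalog` is the annotation universe of the pipeline: mature small-RNA
sequences (miRNA, YRNA, tRNA, rRNA, snRNA, snoRNA, piRNA) with class labels,
optional precursor links and optional genomic loci.  It plays the role that
miRBase/Rfam/piRNABank dumps play in a production run, in a neutral
FASTA + TSV (+ optional BED, + optional precursor FASTA) format.

All sequences are held in DNA space: U is converted to T at load time so that
catalog entries compare directly against sequenced reads.  Loci are 0-based,
half-open, BED-native.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

RNA_CLASSES = ("miRNA", "YRNA", "tRNA", "rRNA", "snRNA", "snoRNA", "piRNA")

#: Default priority for resolving equal-score multi-class hits; "other" is
#: implicit last.  miRNA first mirrors the downstream focus on miRNA calls.
DEFAULT_CLASS_PRIORITY = list(RNA_CLASSES)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_SEQ = set("ACGTN")


class CatalogError(ValueError):
    """Raised for malformed catalog inputs (duplicate ids, bad classes...)."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA sequence over {A,C,G,T,N}.

    An involution: ``reverse_complement(reverse_complement(x)) == x``.
    """
    bad = set(seq) - _VALID_SEQ
    if bad:
        raise ValueError(f"invalid nucleotide(s) {sorted(bad)} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T); validate the alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID_SEQ
    if bad:
        raise CatalogError(f"sequence contains invalid character(s) {sorted(bad)}")
    return s


@dataclass(frozen=True)
class Locus:
    """Genomic interval, 0-based half-open, as in BED."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise CatalogError(f"locus end {self.end} <= start {self.start}")
        if self.strand not in ("+", "-"):
            raise CatalogError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class ReferenceRecord:
    """One mature small-RNA reference sequence with its class annotation."""

    id: str
    seq: str
    rna_class: str
    precursor_id: str | None = None
    locus: Locus | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise CatalogError(f"record {self.id!r} has empty sequence")
        if self.rna_class not in RNA_CLASSES:
            raise CatalogError(
                f"record {self.id!r}: unknown rna_class {self.rna_class!r}"
            )
        if self.rna_class == "miRNA" and not self.precursor_id:
            raise CatalogError(f"miRNA record {self.id!r} lacks a precursor_id")


@dataclass
class Catalog:
    """A validated collection of reference records plus class priority.

    ``precursor_seqs`` maps precursor ids to their (DNA-space) sequences;
    miRNA reads with templated extensions align within this context.
    """

    records: list[ReferenceRecord]
    class_priority: list[str] = field(default_factory=lambda: list(DEFAULT_CLASS_PRIORITY))
    precursor_seqs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise CatalogError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
        present = {r.rna_class for r in self.records}
        missing = present - set(self.class_priority)
        if missing:
            raise CatalogError(f"class_priority omits classes {sorted(missing)}")
        # A linked precursor must contain its mature sequence when the
        # precursor sequence is supplied.
        for rec in self.records:
            if rec.precursor_id and rec.precursor_id in self.precursor_seqs:
                if rec.seq not in self.precursor_seqs[rec.precursor_id]:
                    raise CatalogError(
                        f"mature {rec.id!r} not found within precursor "
                        f"{rec.precursor_id!r}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, record_id: str) -> ReferenceRecord:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise KeyError(record_id)

    def by_class(self, rna_class: str) -> list[ReferenceRecord]:
        return [r for r in self.records if r.rna_class == rna_class]

    def precursor_of(self, record: ReferenceRecord) -> str | None:
        """Precursor sequence for a record, if linked and loaded."""
        if record.precursor_id is None:
            return None
        return self.precursor_seqs.get(record.precursor_id)

    def mature_offset(self, record: ReferenceRecord) -> int | None:
        """0-based offset of the mature sequence within its precursor."""
        ctx = self.precursor_of(record)
        if ctx is None:
            return None
        return ctx.find(record.seq)


def load_catalog(
    fasta_path: str | Path,
    metadata_path: str | Path,
    precursor_fasta: str | Path | None = None,
    class_priority: Sequence[str] | None = None,
) -> Catalog:
    """Load and validate a reference catalog.

    Parameters
    ----------
    fasta_path
        FASTA of mature reference sequences (RNA or DNA alphabet).
    metadata_path
        Tab-delimited table with header columns
        ``id  rna_class  precursor_id  chrom  start  end  strand``;
        empty/``.`` fields mean "absent".  Every FASTA record must have a
        metadata row and vice versa.
    precursor_fasta
        Optional FASTA of precursor sequences, keyed by the ids referenced
        in the ``precursor_id`` column.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise CatalogError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = normalize_sequence(str(rec.seq))

    records: list[ReferenceRecord] = []
    seen_meta: set[str] = set()
    with open(metadata_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"id", "rna_class"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise CatalogError("metadata must have at least 'id' and 'rna_class' columns")
        for row in reader:
            rid = row["id"]
            if rid in seen_meta:
                raise CatalogError(f"duplicate metadata id {rid!r}")
            seen_meta.add(rid)
            if rid not in seqs:
                raise CatalogError(f"metadata id {rid!r} has no FASTA record")
            locus = None
            chrom = (row.get("chrom") or "").strip()
            if chrom and chrom != ".":
                locus = Locus(
                    chrom=chrom,
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=(row.get("strand") or "+").strip() or "+",
                )
            precursor = (row.get("precursor_id") or "").strip()
            records.append(
                ReferenceRecord(
                    id=rid,
                    seq=seqs[rid],
                    rna_class=row["rna_class"].strip(),
                    precursor_id=precursor if precursor and precursor != "." else None,
                    locus=locus,
                )
            )
    missing = set(seqs) - seen_meta
    if missing:
        raise CatalogError(f"FASTA ids without metadata rows: {sorted(missing)}")

    precursors: dict[str, str] = {}
    if precursor_fasta is not None:
        for rec in SeqIO.parse(str(precursor_fasta), "fasta"):
            if rec.id in precursors:
                raise CatalogError(f"duplicate precursor id {rec.id!r}")
            precursors[rec.id] = normalize_sequence(str(rec.seq))

    priority = list(class_priority) if class_priority else list(DEFAULT_CLASS_PRIORITY)
    return Catalog(records=records, class_priority=priority, precursor_seqs=precursors)


def write_loci_bed(catalog: Catalog, bed_path: str | Path) -> None:
    """Write the genomic loci of all placed records as BED6."""
    with open(bed_path, "w") as fh:
        for rec in catalog:
            if rec.locus is None:
                continue
            loc = rec.locus
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{rec.id}\t0\t{loc.strand}\n"
            )


def read_loci_bed(bed_path: str | Path) -> dict[str, Locus]:
    """Read a BED6 file into a record-id → Locus map."""
    loci: dict[str, Locus] = {}
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise CatalogError(f"BED line has fewer than 4 fields: {line!r}")
            strand = fields[5] if len(fields) >= 6 else "+"
            loci[fields[3]] = Locus(fields[0], int(fields[1]), int(fields[2]), strand)
    return loci


def locate_fragment(fragment: str, record: ReferenceRecord) -> list[tuple[int, str]]:
    """All exact occurrences of ``fragment`` (either strand) in ``record.seq``.

    Returns 0-based ``(offset, strand)`` pairs, '+' for the fragment itself
    and '-' for its reverse complement, sorted by offset then strand.  N never
    matches anything, which :func:`_find_all` guarantees by requiring exact
    character equality.
    """
    if not fragment or not record.seq:
        raise ValueError("fragment and record sequence must be non-empty")
    hits = [(off, "+") for off in _find_all(record.seq, fragment)]
    rc = reverse_complement(fragment)
    hits += [(off, "-") for off in _find_all(record.seq, rc)]
    return sorted(hits)


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) exact occurrences; 'N' matches nothing."""
    if "N" in needle or "N" in haystack:
        # str.find would treat N as an ordinary character and let N==N match;
        # scan manually so N never matches.
        n, m = len(haystack), len(needle)
        out = []
        for i in range(n - m + 1):
            window = haystack[i : i + m]
            if "N" in window or "N" in needle:
                continue
            if window == needle:
                out.append(i)
        return out
    out = []
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1
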