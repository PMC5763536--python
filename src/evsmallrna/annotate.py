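"""Tag collapsing, bounded-mismatch alignment and ncRNA class annotation.

Clean inserts are collapsed to unique *tags* (sequence + copy count), matched
against the catalog with a bounded number of substitutions on either strand,
and uniquely aligned tags are assigned an ncRNA class by priority.  The
matcher is a dictionary/Hamming scan over the catalog's reference sequences
(for miRNA, the precursor context when available, so templated end extensions
still align): the analysis only needs feature- and class-level assignment,
not genome-wide placement.

Downstream summaries (class composition, per-class length distributions in
RPM, per-chromosome binned abundance) use uniquely aligned tags only;
multi-mapped tags are excluded, unmatched tags are "other".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .refdb import Catalog, Locus, ReferenceRecord, reverse_complement

MIN_TAG_LEN = 17
MAX_TAG_LEN = 45


@dataclass(frozen=True)
class Tag:
    """A unique clean insert sequence with its copy count."""

    seq: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("tag count must be >= 1")
        if not (MIN_TAG_LEN <= len(self.seq) <= MAX_TAG_LEN):
            raise ValueError(
                f"tag length {len(self.seq)} outside {MIN_TAG_LEN}–{MAX_TAG_LEN} nt"
            )


@dataclass(frozen=True)
class Hit:
    """One placement of a tag within a reference record's context."""

    reference_id: str
    offset: int  # 0-based within the alignment context (precursor for miRNA)
    strand: str  # '+': tag as-is; '-': reverse complement matched
    mismatches: int


@dataclass
class AnnotatedTag:
    tag: Tag
    hits: list[Hit] = field(default_factory=list)
    unique: bool = False
    rna_class: str = "other"

    @property
    def best_hit(self) -> Hit | None:
        return self.hits[0] if self.unique else None


def collapse_reads(clean_inserts: Iterable[str]) -> list[Tag]:
    """Collapse clean inserts into unique tags, lexicographic order.

    Copy counts are conserved: sum(tag.count) == number of input inserts.
    """
    counts = Counter(clean_inserts)
    return [Tag(seq, n) for seq, n in sorted(counts.items())]


def _alignment_targets(catalog: Catalog) -> list[tuple[str, str, list[tuple[ReferenceRecord, int]]]]:
    """(context_id, context_seq, [(owner_record, mature_offset_in_context)]).

    miRNA records sharing a precursor share one context so a tag spanning it
    yields one placement, attributed afterwards to the best-overlapping
    mature.  Records without a precursor context are their own context.
    """
    by_context: dict[str, tuple[str, list[tuple[ReferenceRecord, int]]]] = {}
    for rec in catalog:
        ctx = catalog.precursor_of(rec)
        if ctx is not None:
            cid = f"pre:{rec.precursor_id}"
            off = catalog.mature_offset(rec)
            seq = ctx
        else:
            cid = f"rec:{rec.id}"
            off = 0
            seq = rec.seq
        if cid not in by_context:
            by_context[cid] = (seq, [])
        by_context[cid][1].append((rec, off))
    return [(cid, seq, owners) for cid, (seq, owners) in by_context.items()]


def _hamming_positions(text: str, pattern: str, max_mm: int) -> list[tuple[int, int]]:
    """All (offset, mismatches) placements of pattern in text with <= max_mm
    substitutions.  'N' on either side counts as a mismatch."""
    n, m = len(text), len(pattern)
    out = []
    for i in range(n - m + 1):
        mm = 0
        for a, b in zip(text[i : i + m], pattern):
            if a != b or a == "N":
                mm += 1
                if mm > max_mm:
                    break
        else:
            out.append((i, mm))
    return out


def _attribute(
    owners: Sequence[tuple[ReferenceRecord, int]], offset: int, tag_len: int
) -> list[ReferenceRecord]:
    """Owning record(s) of a context placement: maximal overlap with the
    mature interval; ties keep all (the tag becomes multi-mapped)."""
    if len(owners) == 1:
        return [owners[0][0]]
    best: list[ReferenceRecord] = []
    best_ov = -1
    for rec, moff in owners:
        ov = min(offset + tag_len, moff + len(rec.seq)) - max(offset, moff)
        if ov > best_ov:
            best, best_ov = [rec], ov
        elif ov == best_ov:
            best.append(rec)
    return best


def align_tags(
    tags: Sequence[Tag], catalog: Catalog, max_mismatches: int = 0
) -> list[AnnotatedTag]:
    """Match every tag against the catalog with bounded substitutions.

    Both strands are searched.  A tag is *unique* iff exactly one placement
    achieves the minimal mismatch count; all worse placements are dropped
    from ``hits``.  Tags with no placement stay class "other".
    """
    if max_mismatches not in (0, 1, 2):
        raise ValueError("max_mismatches must be 0, 1 or 2")
    targets = _alignment_targets(catalog)
    out: list[AnnotatedTag] = []
    for tag in tags:
        rc = reverse_complement(tag.seq)
        hits: list[Hit] = []
        for _cid, ctx_seq, owners in targets:
            for strand, query in (("+", tag.seq), ("-", rc)):
                for off, mm in _hamming_positions(ctx_seq, query, max_mismatches):
                    for rec in _attribute(owners, off, len(tag.seq)):
                        hits.append(Hit(rec.id, off, strand, mm))
        if hits:
            best_mm = min(h.mismatches for h in hits)
            best = [h for h in hits if h.mismatches == best_mm]
            out.append(AnnotatedTag(tag, hits=best, unique=len(best) == 1))
        else:
            out.append(AnnotatedTag(tag, hits=[], unique=False))
    return out


def assign_classes(
    annotated: Sequence[AnnotatedTag], catalog: Catalog
) -> list[AnnotatedTag]:
    """Set ``rna_class`` per tag.

    Unique tags take the class of their single best hit.  Tags whose
    equal-score best hits span several records keep unique=False but are
    still labelled: the highest-priority class among the best hits wins,
    so composition's "other" stays reserved for unmatched tags.
    """
    cls_of = {rec.id: rec.rna_class for rec in catalog}
    rank = {c: i for i, c in enumerate(catalog.class_priority)}
    for at in annotated:
        if not at.hits:
            at.rna_class = "other"
            continue
        classes = {cls_of[h.reference_id] for h in at.hits}
        at.rna_class = min(classes, key=lambda c: rank.get(c, len(rank)))
    return list(annotated)


def class_composition(
    annotated: Sequence[AnnotatedTag], clean_reads: int
) -> dict[str, float]:
    """Copy-weighted class percentages over unique + unmatched tags.

    Multi-mapped tags are excluded (only uniquely aligned reads are
    annotated); unmatched tags count as "other".  Percentages sum to 100.
    """
    if clean_reads <= 0:
        raise ValueError("clean_reads must be positive")
    weights: dict[str, int] = {}
    for at in annotated:
        if at.unique or not at.hits:
            cls = at.rna_class
            weights[cls] = weights.get(cls, 0) + at.tag.count
    total = sum(weights.values())
    if total == 0:
        return {}
    return {cls: 100.0 * n / total for cls, n in sorted(weights.items())}


def length_distribution(
    annotated: Sequence[AnnotatedTag], rna_class: str, clean_reads: int
) -> dict[int, float]:
    """RPM by insert length (17–45 nt) for one class, unique tags only."""
    if clean_reads <= 0:
        raise ValueError("clean_reads must be positive")
    dist = {ell: 0.0 for ell in range(MIN_TAG_LEN, MAX_TAG_LEN + 1)}
    for at in annotated:
        if at.unique and at.rna_class == rna_class:
            dist[len(at.tag.seq)] += at.tag.count / clean_reads * 1e6
    return dist


def chromosome_abundance(
    annotated: Sequence[AnnotatedTag],
    loci: Mapping[str, Locus],
    bin_size: int,
    clean_reads: int,
) -> dict[tuple[str, int], float]:
    """RPM per (chromosome, bin) from unique tags' genomic starts.

    The genomic start of a hit is the locus start plus the hit offset on a
    '+' locus, and the locus end minus offset minus tag length on a '-'
    locus.  Hits on references without a locus accumulate under
    ``("unplaced", 0)``.  Total RPM over bins equals the unique-tag RPM sum.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if clean_reads <= 0:
        raise ValueError("clean_reads must be positive")
    table: dict[tuple[str, int], float] = {}
    for at in annotated:
        if not at.unique:
            continue
        hit = at.hits[0]
        rpm = at.tag.count / clean_reads * 1e6
        locus = loci.get(hit.reference_id)
        if locus is None:
            key = ("unplaced", 0)
        elif locus.strand == "+":
            start = locus.start + hit.offset
            key = (locus.chrom, start // bin_size)
        else:
            start = locus.end - hit.offset - len(at.tag.seq)
            key = (locus.chrom, max(start, 0) // bin_size)
        table[key] = table.get(key, 0.0) + rpm
    return table


def write_annotation_tsv(annotated: Sequence[AnnotatedTag], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "tag\tcount\trna_class\treference_id\toffset\tstrand\tmismatches\tunique\n"
        )
        for at in annotated:
            if at.hits:
                h = at.hits[0]
                ref, off, strand, mm = h.reference_id, h.offset, h.strand, h.mismatches
            else:
                ref, off, strand, mm = ".", -1, ".", -1
            fh.write(
                f"{at.tag.seq}\t{at.tag.count}\t{at.rna_class}\t{ref}\t{off}\t"
                f"{strand}\t{mm}\t{int(at.unique)}\n"
            )


def write_collapsed_fasta(tags: Sequence[Tag], path: str | Path) -> None:
    """Collapsed tags in the ``seq_<n>_x<count>`` header dialect."""
    with open(path, "w") as fh:
        for i, tag in enumerate(tags, start=1):
            fh.write(f">seq_{i}_x{tag.count}\n{tag.seq}\n")


def read_collapsed_fasta(path: str | Path) -> list[Tag]:
    from Bio import SeqIO

    tags = []
    for rec in SeqIO.parse(str(path), "fasta"):
        count = int(rec.id.rsplit("_x", 1)[1])
        tags.append(Tag(str(rec.seq).upper(), count))
    return tags
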