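"""miRNA confirmation, isomiR collapsing, copy-number filtering and RPM.

A tag is *confirmed* as a read of a mature miRNA when it contains the entire
mature reference sequence and its length differs from the mature by at most
4 nt.  Confirmed tags derived from the same end (identical 5' start within
the same precursor) whose pairwise length discrepancy is below 3 nt are
isomiRs of one underlying species and are merged into a single call; calls
with fewer than 10 total copies are discarded as likely sequencing error.
Retained calls are normalised as RPM — mapped reads per million clean reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotate import AnnotatedTag, Tag
from .refdb import Catalog, ReferenceRecord

DEFAULT_MIN_COPIES = 10
MAX_MATURE_LEN_DIFF = 4  # "length difference within 4 nt"
MAX_ISOMIR_DISCREPANCY = 2  # "length discrepancy below 3 nt" => <= 2


@dataclass
class MirnaCall:
    """One quantified miRNA species (representative tag + merged isomiRs)."""

    mirna_id: str
    member_tags: list[tuple[str, int]]  # (tag sequence, copy count)
    representative: str

    @property
    def total_count(self) -> int:
        return sum(n for _, n in self.member_tags)


def confirm_tag(tag: Tag, mature_record: ReferenceRecord) -> bool:
    """True iff the tag contains the full mature sequence and the length
    difference is within 4 nt."""
    return (
        mature_record.seq in tag.seq
        and abs(len(tag.seq) - len(mature_record.seq)) <= MAX_MATURE_LEN_DIFF
    )


def collapse_isomirs(
    tags_with_offsets: Sequence[tuple[Tag, str, int]],
) -> list[list[tuple[Tag, str, int]]]:
    """Group (tag, precursor_id, five_prime_offset) triples into isomiR sets.

    Tags merge iff they share precursor and 5' offset and every pairwise
    length discrepancy is <= 2 nt.  Within one (precursor, offset) anchor the
    tags are clustered greedily by ascending length: a tag joins the current
    group while it stays within 2 nt of the group's shortest member,
    otherwise it opens a new group.  Deterministic and order-independent
    (input order never matters; sorting is by (length, sequence)).
    """
    by_anchor: dict[tuple[str, int], list[tuple[Tag, str, int]]] = {}
    for item in tags_with_offsets:
        _, pid, off = item
        by_anchor.setdefault((pid, off), []).append(item)

    groups: list[list[tuple[Tag, str, int]]] = []
    for key in sorted(by_anchor):
        members = sorted(by_anchor[key], key=lambda t: (len(t[0].seq), t[0].seq))
        current: list[tuple[Tag, str, int]] = []
        for item in members:
            if current and len(item[0].seq) - len(current[0][0].seq) > MAX_ISOMIR_DISCREPANCY:
                groups.append(current)
                current = []
            current.append(item)
        if current:
            groups.append(current)
    return groups


def _representative(members: Sequence[tuple[Tag, str, int]]) -> str:
    """Most abundant member sequence; ties → lexicographically smallest."""
    best = min(members, key=lambda t: (-t[0].count, t[0].seq))
    return best[0].seq


def quantify_mirnas(
    annotated: Sequence[AnnotatedTag],
    catalog: Catalog,
    min_copies: int = DEFAULT_MIN_COPIES,
) -> list[MirnaCall]:
    """Full miRNA quantification over annotated tags.

    Uniquely aligned miRNA-class tags are confirmed against their mature
    record, isomiR-collapsed per (precursor, 5' offset), the per-call copy
    filter applied after merging, and each call named by its mature record.
    """
    confirmed: list[tuple[Tag, str, int]] = []
    mature_of_anchor: dict[tuple[str, int], str] = {}
    for at in annotated:
        if not at.unique or at.rna_class != "miRNA":
            continue
        hit = at.hits[0]
        rec = catalog.get(hit.reference_id)
        if hit.strand != "+" or not confirm_tag(at.tag, rec):
            continue
        pid = rec.precursor_id or rec.id
        confirmed.append((at.tag, pid, hit.offset))
        mature_of_anchor.setdefault((pid, hit.offset), rec.id)

    calls: list[MirnaCall] = []
    for group in collapse_isomirs(confirmed):
        _, pid, off = group[0]
        mid = mature_of_anchor[(pid, off)]
        calls.append(
            MirnaCall(
                mirna_id=mid,
                member_tags=[(t.seq, t.count) for t, _, _ in group],
                representative=_representative(group),
            )
        )
    calls = apply_min_copies(calls, min_copies)
    # several groups may share a mature id (different 5' offsets after
    # trimming); keep them distinct by suffixing the offset variant
    seen: dict[str, int] = {}
    for call in calls:
        k = seen.get(call.mirna_id, 0)
        seen[call.mirna_id] = k + 1
        if k:
            call.mirna_id = f"{call.mirna_id}.v{k + 1}"
    return calls


def apply_min_copies(
    calls: Sequence[MirnaCall], min_copies: int = DEFAULT_MIN_COPIES
) -> list[MirnaCall]:
    """Drop calls with total_count < min_copies (post-merge)."""
    return [c for c in calls if c.total_count >= min_copies]


def rpm_normalize(count: float, clean_reads: int) -> float:
    """Reads per million clean reads."""
    if clean_reads <= 0:
        raise ValueError("clean_reads must be positive")
    if count < 0:
        raise ValueError("count must be nonnegative")
    return count / clean_reads * 1e6


@dataclass
class ExpressionMatrix:
    """Feature × group RPM matrix with per-group clean-read denominators."""

    counts: pd.DataFrame  # integer counts, features × groups
    clean_reads: dict[str, int]

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.clean_reads)
        if missing:
            raise ValueError(f"groups without clean-read totals: {sorted(missing)}")

    @property
    def rpm(self) -> pd.DataFrame:
        denom = pd.Series(self.clean_reads, dtype=float)
        return self.counts / denom[self.counts.columns] * 1e6

    def write_tsv(self, rpm_path: str | Path, counts_path: str | Path | None = None) -> None:
        rpm = self.rpm.copy()
        rpm.index.name = "feature"
        rpm.to_csv(rpm_path, sep="\t", float_format="%.6g")
        if counts_path is not None:
            c = self.counts.copy()
            c.index.name = "feature"
            c.to_csv(counts_path, sep="\t")


def expression_matrix(
    calls_by_group: Mapping[str, Sequence[MirnaCall]],
    clean_reads_by_group: Mapping[str, int],
) -> ExpressionMatrix:
    """Assemble per-group miRNA calls into one count/RPM matrix.

    Features absent from a group get count 0 (they may simply have fallen
    under that group's copy filter).
    """
    features = sorted({c.mirna_id for calls in calls_by_group.values() for c in calls})
    groups = list(calls_by_group)
    data = pd.DataFrame(0, index=features, columns=groups, dtype=int)
    for grp, calls in calls_by_group.items():
        for call in calls:
            data.loc[call.mirna_id, grp] = call.total_count
    return ExpressionMatrix(counts=data, clean_reads=dict(clean_reads_by_group))
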