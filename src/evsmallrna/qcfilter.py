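"""Raw-read filtering: six rejection categories, adapter trimming, clean inserts.

Small-RNA libraries sequence short inserts ligated between a 5' and a 3'
adapter; a fixed-length sequencer read therefore runs through the insert into
the 3' adapter.  Filtering classifies every raw read into exactly one of six
rejection categories or "clean", in a fixed precedence order:

1. ``adapter3_null``        — no 3' adapter found (ligation failure);
2. ``insert_null``          — 3' adapter at position 0 (adapter dimer);
3. ``adapter5_contaminant`` — insert carries a run of the 5' adapter;
4. ``inferior_quality``     — mean insert Phred below the quality floor;
5. ``too_short``            — trimmed insert shorter than 17 nt;
6. ``poly_repeat``          — insert dominated by a single base (or N);

else the read is clean and its trimmed insert (17–45 nt window enforced
downstream) enters the analysis.  The categories are disjoint and exhaustive,
so their counts always sum to the library total.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

CATEGORIES = (
    "adapter3_null",
    "insert_null",
    "adapter5_contaminant",
    "inferior_quality",
    "too_short",
    "poly_repeat",
    "clean",
)

# Illumina TruSeq small-RNA adapters; defaults only, every entry point takes
# explicit adapter arguments.
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"


@dataclass(frozen=True)
class QualityConfig:
    """Filtering thresholds.

    min_insert_len / max_insert_len
        Clean-insert window in nt; shorter inserts are rejected as
        ``too_short``, longer ones are kept here and truncated out of the
        analysis at the mapping stage.
    min_mean_quality
        Mean Phred score floor for the insert; below it the read is
        ``inferior_quality``.
    poly_fraction
        A single base (or N) making up at least this fraction of the insert
        marks a ``poly_repeat``.
    adapter_min_overlap
        Minimum exact overlap with the 3'-adapter prefix required to call the
        adapter (full adapter or a terminal prefix of at least this length).
    adapter5_min_run
        Minimum run of consecutive 5'-adapter bases inside the insert that
        flags a contaminant.
    """

    min_insert_len: int = 17
    max_insert_len: int = 45
    min_mean_quality: float = 20.0
    poly_fraction: float = 0.8
    adapter_min_overlap: int = 6
    adapter5_min_run: int = 10


@dataclass
class FilterReport:
    """Per-category read counts for one library (Table-3-style)."""

    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CATEGORIES})

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def clean_reads(self) -> int:
        return self.counts["clean"]

    def percentages(self) -> dict[str, float]:
        total = self.total_reads
        if total == 0:
            return {c: 0.0 for c in CATEGORIES}
        return {c: 100.0 * n / total for c, n in self.counts.items()}

    def to_rows(self) -> list[tuple[str, int, float]]:
        """(category, count, percent) rows, total first."""
        pct = self.percentages()
        rows = [("total_reads", self.total_reads, 100.0 if self.total_reads else 0.0)]
        rows += [(c, self.counts[c], pct[c]) for c in CATEGORIES]
        return rows

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("category\tcount\tpercent\n")
            for cat, n, pct in self.to_rows():
                fh.write(f"{cat}\t{n}\t{pct:.4f}\n")


def find_adapter3(read: str, adapter3: str, min_overlap: int = 6) -> int:
    """Leftmost start of the 3' adapter in ``read``; -1 when absent.

    The adapter is called at the first exact occurrence of the full adapter
    sequence, or of a terminal adapter prefix of length >= ``min_overlap``
    reaching the read end (the insert may leave fewer than len(adapter)
    cycles).
    """
    i = read.find(adapter3)
    if i >= 0:
        return i
    # terminal partial adapter: prefix of the adapter flush with the read end
    max_partial = min(len(adapter3) - 1, len(read))
    for k in range(max_partial, min_overlap - 1, -1):
        if read.endswith(adapter3[:k]):
            return len(read) - k
    return -1


def mean_phred(qual: str) -> float:
    if not qual:
        return 0.0
    return sum(ord(c) - 33 for c in qual) / len(qual)


def is_poly_repeat(insert: str, poly_fraction: float = 0.8) -> bool:
    if not insert:
        return False
    top = max(insert.count(b) for b in "ACGTN")
    return top / len(insert) >= poly_fraction


def _has_adapter5_run(insert: str, adapter5: str, min_run: int) -> bool:
    if len(insert) < min_run:
        return False
    for start in range(len(adapter5) - min_run + 1):
        if adapter5[start : start + min_run] in insert:
            return True
    return False


def classify_read(
    read: str,
    qual: str,
    adapter3: str = DEFAULT_ADAPTER3,
    adapter5: str = DEFAULT_ADAPTER5,
    quality_cfg: QualityConfig | None = None,
) -> tuple[str, str | None]:
    """Classify one raw read; returns ``(category, trimmed_insert_or_None)``.

    The insert is returned only for clean reads.  Precedence is fixed (see
    module docstring) so each read lands in exactly one category.
    """
    if len(read) != len(qual):
        raise ValueError(
            f"read/quality length mismatch ({len(read)} vs {len(qual)})"
        )
    cfg = quality_cfg or QualityConfig()
    read = read.upper()

    pos = find_adapter3(read, adapter3, cfg.adapter_min_overlap)
    if pos < 0:
        return "adapter3_null", None
    if pos == 0:
        return "insert_null", None
    insert, iqual = read[:pos], qual[:pos]
    if _has_adapter5_run(insert, adapter5, cfg.adapter5_min_run):
        return "adapter5_contaminant", None
    if mean_phred(iqual) < cfg.min_mean_quality:
        return "inferior_quality", None
    if len(insert) < cfg.min_insert_len:
        return "too_short", None
    if is_poly_repeat(insert, cfg.poly_fraction):
        return "poly_repeat", None
    return "clean", insert


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, seq, qual) from a FASTQ file, plain or gzipped."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError(f"malformed FASTQ record at index {idx} in {path}")
            if len(seq) != len(qual):
                raise ValueError(
                    f"FASTQ record {idx}: sequence/quality length mismatch"
                )
            yield header[1:].split()[0], seq, qual
            idx += 1


def filter_reads(
    reads: Iterable[tuple[str, str, str]],
    adapter3: str = DEFAULT_ADAPTER3,
    adapter5: str = DEFAULT_ADAPTER5,
    quality_cfg: QualityConfig | None = None,
) -> tuple[list[str], FilterReport, list[tuple[str, str]]]:
    """Filter an iterable of (id, seq, qual); core of :func:`filter_library`.

    Returns (clean_inserts, report, per_read_categories).
    """
    cfg = quality_cfg or QualityConfig()
    report = FilterReport()
    clean: list[str] = []
    per_read: list[tuple[str, str]] = []
    for rid, seq, qual in reads:
        category, insert = classify_read(seq, qual, adapter3, adapter5, cfg)
        report.counts[category] += 1
        per_read.append((rid, category))
        if insert is not None:
            clean.append(insert)
    return clean, report, per_read


def filter_library(
    fastq_path: str | Path,
    adapter3: str = DEFAULT_ADAPTER3,
    adapter5: str = DEFAULT_ADAPTER5,
    quality_cfg: QualityConfig | None = None,
) -> tuple[list[str], FilterReport]:
    """Filter a FASTQ library; returns clean inserts and the filter report."""
    clean, report, _ = filter_reads(
        _iter_fastq(fastq_path), adapter3, adapter5, quality_cfg
    )
    return clean, report
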