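"""End-to-end orchestration: filter → annotate → quantify → DE, with manifest.

The pipeline takes one FASTQ per group (typically two pooled libraries),
runs every stage with a single parameter set, and writes all tabular outputs
plus a plain-text run manifest into the output directory.  All stages are
deterministic, so identical inputs and parameters give byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .annotate import (
    align_tags,
    assign_classes,
    chromosome_abundance,
    class_composition,
    collapse_reads,
    length_distribution,
    write_annotation_tsv,
    write_collapsed_fasta,
)
from .diffexp import DEConfig, cumulative_frequency, differential_expression, heatmap_matrix, pearson_correlation, write_de_tsv
from .mirquant import expression_matrix, quantify_mirnas
from .qcfilter import DEFAULT_ADAPTER3, DEFAULT_ADAPTER5, QualityConfig, filter_library
from .refdb import Catalog, load_catalog, read_loci_bed


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class PipelineConfig:
    fastq_by_group: dict[str, str]  # group label -> FASTQ path
    catalog_fasta: str
    catalog_metadata: str
    precursor_fasta: str | None = None
    loci_bed: str | None = None
    outdir: str = "evsmallrna_out"
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    quality: QualityConfig = field(default_factory=QualityConfig)
    max_mismatches: int = 0
    min_copies: int = 10
    de: DEConfig = field(default_factory=DEConfig)
    bin_size: int = 1_000_000
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Flat ``key = value`` config; fastq entries as ``fastq.<group>``."""
        kv: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                kv[key.strip()] = val.strip()
        fastqs = {
            k.split(".", 1)[1]: v for k, v in kv.items() if k.startswith("fastq.")
        }
        de = DEConfig(
            dispersion=float(kv.get("dispersion", 0.1)),
            alpha_p=float(kv.get("alpha_p", 0.05)),
            alpha_fdr=float(kv.get("alpha_fdr", 0.05)),
            min_abs_log2fc=float(kv.get("min_abs_log2fc", 1.0)),
            pseudo=float(kv.get("pseudo", 0.1)),
        )
        return cls(
            fastq_by_group=fastqs,
            catalog_fasta=kv["catalog_fasta"],
            catalog_metadata=kv["catalog_metadata"],
            precursor_fasta=kv.get("precursor_fasta") or None,
            loci_bed=kv.get("loci_bed") or None,
            outdir=kv.get("outdir", "evsmallrna_out"),
            adapter3=kv.get("adapter3", DEFAULT_ADAPTER3),
            adapter5=kv.get("adapter5", DEFAULT_ADAPTER5),
            max_mismatches=int(kv.get("max_mismatches", 0)),
            min_copies=int(kv.get("min_copies", 10)),
            de=de,
            bin_size=int(kv.get("bin_size", 1_000_000)),
            seed=int(kv.get("seed", 0)),
        )

    def manifest_items(self) -> list[tuple[str, str]]:
        items = [
            ("evsmallrna_version", __version__),
            ("seed", str(self.seed)),
            ("adapter3", self.adapter3),
            ("adapter5", self.adapter5),
            ("max_mismatches", str(self.max_mismatches)),
            ("min_copies", str(self.min_copies)),
            ("dispersion", str(self.de.dispersion)),
            ("alpha_p", str(self.de.alpha_p)),
            ("alpha_fdr", str(self.de.alpha_fdr)),
            ("min_abs_log2fc", str(self.de.min_abs_log2fc)),
            ("pseudo", str(self.de.pseudo)),
            ("bin_size", str(self.bin_size)),
            ("min_insert_len", str(self.quality.min_insert_len)),
            ("max_insert_len", str(self.quality.max_insert_len)),
            ("min_mean_quality", str(self.quality.min_mean_quality)),
            ("poly_fraction", str(self.quality.poly_fraction)),
            ("adapter_min_overlap", str(self.quality.adapter_min_overlap)),
            ("adapter5_min_run", str(self.quality.adapter5_min_run)),
        ]
        for grp in sorted(self.fastq_by_group):
            items.append((f"fastq.{grp}", str(self.fastq_by_group[grp])))
        return items


def _log(stage: str, msg: str) -> None:
    print(f"[evsmallrna:{stage}] {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write all outputs; returns the output file map."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    try:
        catalog = load_catalog(
            config.catalog_fasta, config.catalog_metadata, config.precursor_fasta
        )
    except Exception as exc:
        raise PipelineError(f"stage=load_catalog: {exc}") from exc
    loci = {rec.id: rec.locus for rec in catalog if rec.locus is not None}
    if config.loci_bed:
        loci.update(read_loci_bed(config.loci_bed))

    calls_by_group = {}
    clean_by_group = {}
    groups = sorted(config.fastq_by_group)
    for grp in groups:
        fq = config.fastq_by_group[grp]
        try:
            clean, report = filter_library(
                fq, config.adapter3, config.adapter5, config.quality
            )
        except Exception as exc:
            raise PipelineError(f"stage=qcfilter group={grp}: {exc}") from exc
        _log("qcfilter", f"group {grp}: {report.clean_reads}/{report.total_reads} clean")
        p = out / f"filter_report.{grp}.tsv"
        report.write_tsv(p)
        outputs[f"filter_report.{grp}"] = p

        try:
            tags = collapse_reads(clean)
            annotated = assign_classes(
                align_tags(tags, catalog, config.max_mismatches), catalog
            )
        except Exception as exc:
            raise PipelineError(f"stage=annotate group={grp}: {exc}") from exc
        _log("annotate", f"group {grp}: {len(tags)} tags, "
                         f"{sum(a.unique for a in annotated)} unique")
        p = out / f"tags.{grp}.fasta"
        write_collapsed_fasta(tags, p)
        outputs[f"tags.{grp}"] = p
        p = out / f"annotation.{grp}.tsv"
        write_annotation_tsv(annotated, p)
        outputs[f"annotation.{grp}"] = p

        clean_reads = report.clean_reads
        clean_by_group[grp] = clean_reads
        if clean_reads > 0:
            comp = class_composition(annotated, clean_reads)
            p = out / f"composition.{grp}.tsv"
            with open(p, "w") as fh:
                fh.write("rna_class\tpercent\n")
                for cls, pct in comp.items():
                    fh.write(f"{cls}\t{pct:.4f}\n")
            outputs[f"composition.{grp}"] = p

            p = out / f"length_distribution.{grp}.tsv"
            classes = sorted({a.rna_class for a in annotated if a.unique})
            with open(p, "w") as fh:
                fh.write("rna_class\tlength\trpm\n")
                for cls in classes:
                    for ell, rpm in length_distribution(annotated, cls, clean_reads).items():
                        fh.write(f"{cls}\t{ell}\t{rpm:.6g}\n")
            outputs[f"length_distribution.{grp}"] = p

            bins = chromosome_abundance(annotated, loci, config.bin_size, clean_reads)
            p = out / f"chromosome_abundance.{grp}.tsv"
            with open(p, "w") as fh:
                fh.write("chrom\tbin_start\trpm\n")
                for (chrom, b), rpm in sorted(bins.items()):
                    fh.write(f"{chrom}\t{b * config.bin_size}\t{rpm:.6g}\n")
            outputs[f"chromosome_abundance.{grp}"] = p

        try:
            calls_by_group[grp] = quantify_mirnas(annotated, catalog, config.min_copies)
        except Exception as exc:
            raise PipelineError(f"stage=mirquant group={grp}: {exc}") from exc
        _log("mirquant", f"group {grp}: {len(calls_by_group[grp])} miRNA calls")

    expr = expression_matrix(calls_by_group, clean_by_group)
    p = out / "expression_rpm.tsv"
    expr.write_tsv(p, out / "expression_counts.tsv")
    outputs["expression_rpm"] = p
    outputs["expression_counts"] = out / "expression_counts.tsv"

    if len(groups) >= 2 and len(expr.counts):
        ga, gb = groups[0], groups[1]
        try:
            results = differential_expression(expr, ga, gb, config.de)
        except Exception as exc:
            raise PipelineError(f"stage=diffexp: {exc}") from exc
        p = out / "de_results.tsv"
        write_de_tsv(results, p)
        outputs["de_results"] = p

        hm = heatmap_matrix(expr, config.de.pseudo)
        p = out / "heatmap_matrix.tsv"
        hm.index.name = "feature"
        hm.to_csv(p, sep="\t", float_format="%.6g")
        outputs["heatmap_matrix"] = p

        rpm = expr.rpm
        mean_rpm = rpm.mean(axis=1)
        if len(mean_rpm):
            x, f, frac = cumulative_frequency(mean_rpm.to_list(), config.de.pseudo)
            p = out / "cumulative_frequency.tsv"
            with open(p, "w") as fh:
                fh.write(f"# fraction_below_1_rpm\t{frac:.6g}\n")
                fh.write("log2_rpm\tcumulative_fraction\n")
                for xi, fi in zip(x, f):
                    fh.write(f"{xi:.6g}\t{fi:.6g}\n")
            outputs["cumulative_frequency"] = p
        if len(rpm) >= 2 and rpm[ga].nunique() > 1 and rpm[gb].nunique() > 1:
            r = pearson_correlation(rpm[ga], rpm[gb])
            p = out / "correlation.tsv"
            with open(p, "w") as fh:
                fh.write("group_a\tgroup_b\tpearson_r\n")
                fh.write(f"{ga}\t{gb}\t{r:.6g}\n")
            outputs["correlation"] = p

    manifest = out / "manifest.txt"
    with open(manifest, "w") as fh:
        for k, v in config.manifest_items():
            fh.write(f"{k} = {v}\n")
    outputs["manifest"] = manifest
    return outputs


def checksum_outputs(outputs: dict[str, Path]) -> dict[str, str]:
    """SHA-256 of every output file, keyed by output name."""
    return {
        name: hashlib.sha256(path.read_bytes()).hexdigest()
        for name, path in sorted(outputs.items())
    }


def make_report(outdir: str | Path) -> str:
    """Human-readable run summary from an existing output directory."""
    out = Path(outdir)
    if not out.is_dir():
        raise FileNotFoundError(f"output directory {out} does not exist")
    lines: list[str] = ["# evsmallrna run report", ""]

    reports = sorted(out.glob("filter_report.*.tsv"))
    if not reports:
        raise FileNotFoundError("no filter_report.*.tsv found")
    for p in reports:
        grp = p.name.split(".")[1]
        lines.append(f"## Filtering — group {grp}")
        lines += [line.rstrip("\n") for line in open(p)]
        lines.append("")
    for p in sorted(out.glob("composition.*.tsv")):
        grp = p.name.split(".")[1]
        lines.append(f"## Class composition — group {grp}")
        lines += [line.rstrip("\n") for line in open(p)]
        lines.append("")

    de = out / "de_results.tsv"
    lines.append("## Differential expression")
    if de.exists():
        up = down = total = 0
        with open(de) as fh:
            next(fh)
            for line in fh:
                f = line.rstrip("\n").split("\t")
                total += 1
                if f[-1] == "1":
                    if float(f[5]) > 0:
                        up += 1
                    else:
                        down += 1
        lines.append(f"features tested\t{total}")
        lines.append(f"significant up\t{up}")
        lines.append(f"significant down\t{down}")
    else:
        lines.append("features tested\t0")
        lines.append("significant up\t0")
        lines.append("significant down\t0")
    lines.append("")
    return "\n".join(lines)
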