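import pytest

from evsmallrna.qcfilter import filter_reads
from evsmallrna.simulate import SimulationConfig, make_synthetic_catalog, simulate_library


@pytest.fixture(scope="session")
def catalog():
    return make_synthetic_catalog(seed=1)


@pytest.fixture(scope="session")
def small_library(catalog):
    """A 20k-read simulated library with its ground truth and filter output."""
    cfg = SimulationConfig(library_size=20_000, seed=7)
    records, truth = simulate_library(cfg, catalog)
    clean, report, per_read = filter_reads(records)
    return {
        "config": cfg,
        "records": records,
        "truth": truth,
        "clean": clean,
        "report": report,
        "per_read": per_read,
    }


@pytest.fixture
def catalog_files(tmp_path, catalog):
    """The session catalog written out as FASTA + metadata (+ precursors)."""
    fasta = tmp_path / "catalog.fasta"
    meta = tmp_path / "catalog.tsv"
    pre = tmp_path / "precursors.fasta"
    with open(fasta, "w") as fh:
        for rec in catalog:
            fh.write(f">{rec.id}\n{rec.seq}\n")
    with open(meta, "w") as fh:
        fh.write("id\trna_class\tprecursor_id\tchrom\tstart\tend\tstrand\n")
        for rec in catalog:
            loc = rec.locus
            locf = (
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.strand}"
                if loc
                else ".\t.\t.\t."
            )
            fh.write(f"{rec.id}\t{rec.rna_class}\t{rec.precursor_id or '.'}\t{locf}\n")
    with open(pre, "w") as fh:
        for pid, seq in catalog.precursor_seqs.items():
            fh.write(f">{pid}\n{seq}\n")
    return {"fasta": fasta, "metadata": meta, "precursors": pre}
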