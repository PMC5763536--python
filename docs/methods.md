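# Methods

## Setting and model

The package analyses single-end small-RNA sequencing of pooled plasma
extracellular-vesicle (EV) libraries: per study group, RNA from many donors
is pooled into a single library, sequenced deeply, and groups are compared
feature by feature. The analysis has four computational stages — read
filtering, annotation, miRNA quantification, and differential expression —
plus a simulator that generates libraries with known ground truth, which is
how the pipeline is validated in the absence of raw patient data.

## Read filtering

A small-RNA read is insert + 3′ adapter + downstream cycles. Each raw read
is assigned exactly one label, evaluated in fixed precedence order:

1. `adapter3_null` — no 3′ adapter. Adapter detection is an exact match of
   the full adapter anywhere in the read, or of a terminal adapter prefix of
   at least 6 nt (`adapter_min_overlap`) flush with the read end. Exact
   matching with a declared minimum overlap keeps the rule deterministic and
   unit-testable; an error-tolerant matcher can be substituted behind the
   same interface.
2. `insert_null` — adapter at position 0 (adapter dimer).
3. `adapter5_contaminant` — the insert contains ≥ 10 consecutive bases of
   the 5′ adapter (`adapter5_min_run`).
4. `inferior_quality` — mean Phred of the insert < 20 (`min_mean_quality`).
5. `too_short` — insert < 17 nt.
6. `poly_repeat` — one base (or N) makes up ≥ 80% of the insert
   (`poly_fraction`).

Otherwise the read is clean and contributes its trimmed insert. The
categories are disjoint and exhaustive by construction, so counts sum to the
library total on any input — the central conservation invariant of the
stage. The quality floor, poly threshold and 5′-run length are conventions
declared here (the category names alone do not pin them down); all are
configurable, and the defaults are what the tests and simulator assume.

The insert window is 17–45 nt: shorter inserts are rejected here; longer
inserts (impossible at the default 50-cycle read length with 6 nt minimum
adapter overlap) would simply fail to align downstream.

## Reference catalogs and alignment

The catalog is a neutral stand-in for miRBase/Rfam/piRNA databases: mature
sequences with class labels (miRNA, YRNA, tRNA, rRNA, snRNA, snoRNA, piRNA),
optional precursor links, optional genomic loci (BED, 0-based half-open).
All sequences are normalised to DNA space (U→T) at load; N never matches
anything.

Clean inserts are collapsed to unique tags with copy counts (lexicographic
order, counts conserved). Tags are matched against catalog sequences with at
most 0–2 substitutions on either strand — a dictionary/bounded-Hamming
matcher rather than a genome-wide FM-index aligner, because the analysis
needs feature- and class-level assignment only. For miRNA records with a
linked precursor, the match runs within the precursor context so templated
3′ extensions (isomiRs) still align; the placement is attributed to the
best-overlapping mature record.

A tag is *uniquely aligned* iff exactly one placement attains the minimal
mismatch count; ties at the best score make the tag multi-mapped. Only
unique tags enter the summaries (composition, length distributions,
chromosome bins) and quantification; unmatched tags are "other". When the
equal-score best hits of a multi-mapped tag span several classes, the label
is resolved by the class priority (default miRNA > YRNA > tRNA > rRNA >
snRNA > snoRNA > piRNA), but the tag remains excluded from unique-only
summaries. The tie rule (ties ⇒ non-unique) is a declared design choice.

Genomic abundance assigns each unique tag's copies to the bin containing its
hit's genomic start (locus start + offset on `+` loci, locus end − offset −
tag length on `−` loci); hits on un-placed references accumulate under
"unplaced". Abundance is RPM: copies / clean reads × 10⁶.

## miRNA quantification

A tag is a confirmed read of a mature miRNA iff it **contains the entire
mature sequence** and its length differs by at most 4 nt ("within 4 nt" read
as ≤ 4). Confirmed tags with the same precursor and identical 5′ offset
whose pairwise length discrepancy is below 3 nt (≤ 2) are isomiRs of one
species and merge into a single call (counts summed; representative = most
abundant member, ties to the lexicographically smallest sequence). 5′-end
identity is positional — the precursor offset of the alignment — not a
sequence-prefix comparison. Within one anchor, grouping is greedy by
ascending length, which is deterministic and order-independent. Calls with
fewer than 10 copies are removed *after* merging (the pre/post-merge order
is not dictated by the rule's wording; post-merge is this package's declared
choice). Retained calls are normalised as RPM.

Consequence worth noting: 3′-*trimmed* isomiRs can never be confirmed (the
mature is not contained in them), so planted trimmed variants are excluded
from calls by design. The simulator's ground truth therefore exposes
`confirmable_mirna_counts()` — the copies that satisfy the containment rule
— and quantification recovers those exactly on unambiguous libraries.

## Differential expression

With one pooled library per group there are no replicates, so dispersion
cannot be estimated from the data. The test is a conditional two-sided exact
negative-binomial test with an explicit dispersion φ:

- counts are scaled to the geometric-mean library size with round-half-even
  (a fixed, testable surrogate for more elaborate normalisations);
- conditional on the scaled total s = a′ + b′, outcome x ∈ {0..s} has weight
  P(x)·P(s−x) under independent NB(mean s/2, Var = μ + φμ²);
- p = total conditional probability of outcomes no more probable than the
  observed one (probability-mass criterion, with a 1e−12 relative tolerance
  to absorb floating ties such as the exact mirror outcome); p ∈ (0, 1].

φ = 0 reduces to the conditional binomial exact test (Poisson limit). The
default φ = 0.1 (biological CV ≈ 0.32, a conventional magnitude for human
samples) is an assumption, not an estimate, and every DE result is reported
conditional on it. The implementation agrees with a brute-force enumeration
to < 1e−10 for all totals ≤ 50, and with edgeR's `exactTest` at a common
dispersion to ~4 decimals on spot checks.

Multiple testing uses Benjamini–Hochberg step-up (q(i) = min over j ≥ i of
p(j)·n/j). Significance requires P < 0.05, FDR < 0.05 and |log₂FC| ≥ 1.
Descriptive outputs: M = log₂((rpm_B+0.1)/(rpm_A+0.1)) and A = mean of the
log₂(rpm+0.1) values (the 0.1 pseudo-count is the same moderate cutoff used
for the heatmap and is configurable); the heatmap matrix log₂(RPM + 0.1)
after dropping features below 1 RPM in **all** groups; the ECDF of
log₂(RPM + 0.1) with the fraction of features below 1 RPM; Pearson
correlation of the two groups' RPM vectors (raw scale by default, log
switchable — both conventions exist in practice).

### Statistical behaviour and the depth needed for recovery

Because the conditional NB spread grows linearly with the total while a
fixed fold change displaces the observed split linearly too, the exact test
has a **depth-independent p-value floor** for a given fold change and φ: for
a 4-fold change at φ = 0.1 the floor is ≈ 0.0032. With 200 changed features
among 2000, the best attainable BH q for the block is then ≈ 0.032 — below
the 0.05 threshold, but with little headroom. Validation of fold-change
recovery therefore uses *deep* features, expected count 2000 per feature
(≈ 50 RPM at a 40M-read library, the abundance range where pooled-library DE
calls are credible); at that depth counting noise is negligible, recovery
power is stably ~100% and the mean recovered M is 2.00. At expected counts
near 100 the whole block sits on the BH knife-edge and recovery is
unreliable — an intrinsic property of unreplicated exact-test DE worth
knowing before trusting marginal calls on shallow features.

Type-I error is calibrated by construction (the conditioning distribution is
exactly the null sampling distribution): 2000 null NB pairs at φ = 0.1 give
a rejection fraction of ~0.05 at nominal 0.05, slightly conservative from
discreteness.

## qPCR module

Relative expression is 2^−ΔCt, ΔCt = Ct(target) − Ct(control), against a
spike-in (cel-miR-39) or endogenous (U6) control. It is invariant to adding
a constant to both Cts and monotone in each. Group comparison is a two-sided
unpaired t test — pooled-variance Student or Welch — with the
variance-equality choice caller-supplied or auto-selected by a two-sided
F-ratio test at 0.05.

## Simulator: what it emulates and what it does not

`simulate_library` draws a category per read (multinomial over artifact
rates, remainder clean), a source reference per clean read (class weights
split uniformly within a class), and an insert per source: miRNAs use a
±2 nt 3′ offset law around the mature (extensions templated from the
precursor), fragment classes use 5′-anchored prefixes with class-specific
length laws (YRNA/tRNA 29–34 nt peaking at 32, rRNA 20–32, snRNA 19–24,
snoRNA ~27, piRNA 20–22). Default class weights are EV-plasma-like: YRNA
0.51, miRNA 0.30, with minor classes making up the rest. Default artifact
rates total ~7% (clean ≈ 93%). Reads are insert + 3′ adapter + random
padding at 50 cycles, Phred+33; clean reads get all bases ≥ Q30, planted
inferior-quality reads mean Q < 20.

In the default *unambiguous* mode every artifact read is constructed so it
can only satisfy its own category's rule and every reference-derived insert
is screened against spurious adapter hits, 5′-adapter runs and poly
composition — so a filtering pass recovers the planted labels exactly, and
recovery tests have a crisp oracle. `ambiguous=True` drops those guards for
robustness testing. One `numpy` Generator seeded from a single integer
drives each library; identical configs give byte-identical FASTQ.

`simulate_two_group` plants per-feature fold changes by drawing clean copy
counts per feature independently (Poisson around scaled expectations) rather
than under a fixed-total multinomial: renormalising would contaminate every
feature's expectation and break the "expected B = expected A × FC" contract.
Library totals are therefore Poisson-distributed around the target size.
Planting balanced up/down changes keeps the clean-read denominators
comparable; an all-up planting of any size shifts every RPM (and hence M) by
the log of the library-total ratio.

Not emulated: sequencing errors (substitutions/indels), PCR duplication,
ligation bias, multi-mapping across homologous references (synthetic
references are random and effectively unique), and real hg19 coordinates
(loci are synthetic placements; the packaged hY4 stand-in is the canonical
32-nt 5′ fragment joined to a synthetic tail, labelled `hY4-synthetic`).
Passing recovery tests therefore demonstrates the correctness of the
pipeline's logic under its own stated rules, not robustness to real-data
noise sources.

## Numerical and degenerate-input conventions

- RPM requires clean_reads > 0; composition and ECDF reject empty input.
- p-values are clamped to (0, 1]; BH rejects p outside (0, 1].
- Zero scaled total in the exact test ⇒ p = 1 (no information).
- Identical constant groups in the t test ⇒ t = 0, p = 1.
- Tag collapse, isomiR grouping and all output tables are deterministically
  ordered, making whole-pipeline reruns byte-identical.

## Problem sizes used in validation

Filter/annotation/quantification recovery uses 100 000-read libraries
(20 000 in the shared test fixture); exact-test enumeration covers all
totals ≤ 50 at φ ∈ {0, 0.1, 0.5}; calibration and recovery use 2000
features (200 changed at 4-fold, expected count 2000); the end-to-end
determinism check runs the full pipeline twice on ~15 000-read two-group
libraries. These sizes give binomial/Poisson error bars comfortably inside
the asserted tolerances.
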