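# Methods

## The WHA model

WHA (window-based HERV alignment) treats each reference region — a HERV
provirus or a host gene — as a sequence of *L*-nt windows and asks, per
sample, whether aligned reads from the target cell population cover enough
consecutive windows deeply enough to indicate genuine locus transcription
rather than scattered multi-mapping noise.

Window partition. `[0, region_length)` is tiled left to right with windows
of length *L*; the terminal window is retained even when shorter, so window
lengths always sum exactly to the region length and window counts are
reproducible. *L* defaults to 100 nt and is recorded in every output; it is
a free parameter of the method rather than a constant of nature, so it is
configurable per run.

Read filters. Two per-read predicates are applied before any counting, in
either order (they commute):

* **cell-type (barcode) filter** — only reads whose 16-nt cell barcode is
  annotated as the target type (monocytes, label `Mono`) count; barcodes
  missing from the annotation are dropped with a warning tally.
* **identity filter** — a read is kept iff
  `100 * matches / aligned_length > 99.0`. The comparison is strict: a
  100-nt read with one mismatch (exactly 99.0%) is rejected. Identity is
  computed on the primary alignment only, by comparing the aligned query to
  the catalog reference sequence (falling back to the NM tag when the
  catalog carries no sequence). Duplicates are not removed.

Depth. A window's depth is the *mean per-base coverage*: total aligned bases
overlapping the window divided by window length, computed by exact interval
overlap (difference-array + cumulative sum, so depth conservation
`Σ depth_w · len_w = total aligned bases` holds exactly). Reads spanning a
boundary contribute their overlapping bases to each window. "Depth" in the
decision rule is taken as this mean; reads-per-window counting would be an
alternative aggregation, which is why the aggregation is stated explicitly
here and fixed in code.

Decision rule. With thresholds `D_min = 3`, `W_min = 9`, `WSS_min = 100`:

* usable window: `depth_w >= D_min` (boundary inclusive);
* locus depth: mean of `depth_w` over usable windows (0 when none) — the
  least arbitrary per-locus aggregate, since it averages exactly the windows
  that define the call;
* **positive**: `n_usable >= W_min` and `locus_depth >= D_min` and (when the
  WSS gate is on) `WSS = 100`; otherwise **negative**. Nine usable windows
  correspond to an extended (≥ ~900 nt at the default *L*) expressed
  transcript; eight or fewer leave the locus negative.

WSS. The window-similarity score is defined operationally as the percentage
of *covered* windows (depth > 0) in which every retained read matches the
reference base-for-base inside the window; a region with no covered window
scores 100 vacuously so the depth/window rules alone decide. The gate has
two modes: `strict` (default; retention requires 100%) and `off`. With
100-nt reads the strict >99% identity filter already discards any read
carrying a mismatch, making the gate redundant; it becomes meaningful for
longer reads, where sub-1% error still passes the identity filter but can
mark individual windows imperfect.

## Cohort analysis

Pangenome filter: a locus survives iff negative in *every* healthy control
and positive in ≥ 1 patient sample. Set arithmetic between two patient
groups counts loci positive in ≥ 1 sample of A and none of B (unique to A),
vice versa, and positive in at least one of each (shared).

Comparisons: per-locus two-sided Welch t-tests (unequal variances — the
robust default of the R ecosystem this mirrors) on usable-window counts or
locus depth; host genes across ≥ 3 cohorts use one-way ANOVA followed by
Tukey's HSD (studentized-range adjusted pairwise p-values, via statsmodels).
Significance is raw p < 0.05 by default; Benjamini–Hochberg adjustment is an
opt-in flag (`correction="bh"`), since the default mirrors the
raw-p workflow this pipeline reproduces. Samples in which a locus is
negative are excluded from that locus's comparison by default (comparisons
are over expressing samples; `positive_only=False` includes the zeros).
Degenerate inputs follow explicit contracts: both groups constant and equal
→ t = 0, p = 1; constant but different → ±∞, p = 0; all ANOVA groups one
constant → F = 0, p = 1, all pairs non-significant.

## The synthetic cohort generator

The generator stands in for controlled-access single-cell cohorts. It
emulates: a multi-locus reference (random i.i.d. ACGT sequences — real HERV
homology/multi-mapping structure is deliberately *not* modelled), per-sample
monocyte reads over a contiguous block of exactly `n_covered_windows`
windows at controlled depth, sequencing substitution errors (i.i.d. per
base), non-monocyte decoy reads on expressed *and* silent loci (so the
barcode filter is consequential — without it, silent loci would be called
positive), and a ground-truth manifest of intended per-(sample, locus)
states.

Coverage model. Within each covered window the read count is Poisson with
mean `depth · window_len / read_len` and each read lies wholly inside its
window (start uniform over the admissible range), so expected mean coverage
per covered window equals `depth` exactly and uncovered windows receive no
reads at all. Reads are therefore never split across the block edge, at the
cost of slightly blockier coverage than fragment-level sampling would give.
The `exact` model instead emits `round(depth)` window-spanning reads —
noise-free coverage used for exact classifier/ground-truth agreement checks.
The default substitution rate is 0.001 per base (high-quality short-read
scale); under the strict identity filter it thins effective coverage by
~10% for 100-nt reads, which the preset depths absorb.

What passing tests do **not** show about real data: alignment ambiguity
between homologous HERV loci, UMI duplication, ambient RNA and doublets,
cell-annotation errors, and library-size variation are all absent. Results
on the synthetic cohort validate the scoring/filtering/statistics machinery,
not the upstream alignment behaviour on real HERV references.

Default preset (31 controls, 11 acute, 12 PASC; 50 HERV loci of 2.5 kb, 5
host genes of 3.2 kb; 150 barcodes/sample at 40% monocyte; decoys over 10
windows at depth 4). Expression topology, chosen once to mirror the target
study's shape at desk scale: HERV001–003 expressed in all PASC samples and
HERV004–006 in most, all six *amplified* — 22 windows at depth 9 in PASC
versus 12 windows at depth 6 in expressing acute samples (Δwindows = 10,
Δdepth = 3); HERV007–012 expressed at identical baseline in subsets of both
patient groups (the null loci for false-positive measurement); HERV013–017
PASC-only; HERV018–022 acute-only; HERV023–050 silent everywhere; host
genes expressed in every sample with JAKMIP2/SPINK1/DPYSL3 amplified in
PASC. Baseline depth 6 keeps the per-window usable probability ≈ 0.91 after
identity-filter thinning, so intended-positive calls are robust but not
deterministic under Poisson noise.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere except inside SAM records
  (handled by pysam). Strand is stored but ignored for coverage.
* All randomness flows from one `numpy.random.default_rng(seed)` per
  simulation in a fixed traversal order, so identical seeds give
  byte-identical FASTA/BED/SAM/TSV outputs.
* Missing profiles for catalog regions score as all-zero (negative) rather
  than erroring, with a log line, so partial ingests degrade loudly but
  gracefully.
* Regions with fewer than two expressing samples in either group are skipped
  by group comparisons rather than tested at n = 1.
* The replicate studies (`hervwha.study`) run the in-memory pipeline path —
  identical read records and scoring code as the SAM path, which a test
  verifies, minus file I/O — with 200 replicates of the full default preset
  for the amplification power study.

## Known limitations

* The WSS definition here is an operational stand-in for the original
  window-similarity score, whose exact formula is external to this package;
  the gate is configurable (`strict`/`off`) and recorded in output metadata.
* Whether per-window "depth" should be mean coverage or a read count, and
  how multi-mapping reads across homologous loci should be apportioned, are
  configuration-sensitive choices of the upstream aligner; this package
  fixes the former (mean) and takes alignments as given.
* The generator does not emit 10x R1/R2 FASTQ chemistry; SAM with a CB
  barcode tag is its alignment-level interface.
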