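# Methods

## Scope and data model

The package analyses strand-resolved, single-nucleotide maps of UV-induced
cyclobutane pyrimidine dimers (CPDs).  A lesion spans a dinucleotide of two
adjacent pyrimidines (TT, TC, CT, CC) on one strand and is keyed throughout
by the genomic position of the 5'-most base of that dinucleotide *on the
damaged strand* (0-based; on the minus strand the 5'-most base has the
higher coordinate).  All intervals are half-open.  For a gene, the
transcribed strand (TS) is the strand opposite the annotated mRNA strand;
the non-transcribed strand (NTS) is the mRNA-coding strand itself.

## Lesion calling from read 5' ends

CPD-seq-type libraries cleave immediately 3' of the dimer on the damaged
strand, so the read begins just downstream of the lesion on the opposite
strand.  The default convention: for a read on `+` with 5' end p, the
lesion dinucleotide occupies genomic (p−2, p−1) on the minus strand and is
stored at p−1; for a read on `-` at p it occupies (p+1, p+2) on the plus
strand, stored at p+1.  Reads whose inferred dinucleotide is not a
dipyrimidine, falls off the chromosome, or contains an ambiguous base are
discarded and tallied by reason.  Because published pipelines differ in
dialect, the offset and the same/opposite-strand relation are arguments.
Duplicate reads are kept by default — at single-base resolution, recurrence
at a lesion hotspot is signal rather than PCR duplication — and collapsing
is opt-in, as is a mapping-quality cutoff (default 0, i.e. alignments are
accepted as given); both choices are visible in the QC tally rather than
silently imposed.

## Fractions remaining and the two scalings

The core estimator pools lesion counts over genes per bin and takes one
ratio F = N_t/N_0 per bin and strand role.  Pooling (rather than averaging
per-gene ratios) is the default because per-gene counts are sparse at
realistic depth and per-gene ratios are unstable; a per-gene-mean mode is
available behind a flag for sensitivity analyses.  Bins with a zero 0 hr
count are reported as undefined (NaN), never as 0.

Two rescalings address library-yield variability:

* **Gel scaling** multiplies every regional fraction by
  s = F_gel / (N_t/N_0 genome-wide), so the genome-wide scaled fraction
  equals the bulk alkaline-gel measurement exactly.
* **Intergenic-median scaling** divides a test profile by the median of the
  12 flank-bin test/reference ratios (3 upstream + 3 downstream bins × two
  strand roles), making the median intergenic ratio exactly 1.  It requires
  every reference flank bin to be defined and positive.

The log2 TS/NTS asymmetry cancels any common scale factor, so it is
reported for both scaled and unscaled profiles interchangeably.

## Metagene geometry

Each gene contributes 12 bins in transcription orientation: three 167 bp
flank bins flush upstream of the TSS, six body sextiles over [TSS, TES),
and three 167 bp flank bins flush downstream of the TES.  When the body
length is not divisible by 6, the leftover base pairs go one at a time to
the first body bins (in transcription orientation) — deterministic and
exactly partitioning the body.  Flank bins are taken regardless of overlap
with neighbouring genes; genes with a body shorter than the bin count are
excluded and logged.  Flanks abut the TSS/TES with no 1 bp offset.
Organellar or plasmid contigs can be excluded via a denylist argument.

Single-nucleotide TSS profiles pool counts per offset (−200..+1000 by
default) across genes, mirroring minus-strand genes.  Smoothing applies a
centered moving average of odd width (default 11 nt; 1 disables) to the
pooled 0 hr and timepoint counts *before* the ratio — smoothing counts
rather than ratios keeps offsets with sparse denominators stable and
defined.  A nucleosome-dyad overlay reports mean dyad coverage per offset.

Gene×bin matrices carry per-gene fractions (per-gene denominators) or
test−reference differences; rows are ordered by descending transcription
rate, ascending expression log2 fold-change, or SRAT-first (then by rate),
with genes missing the covariate placed last and logged.  Matrices export
as TSV and as CDT text for tree-view heatmap browsers.

The SRAT contrast takes per-gene difference cells on the NTS (TS as
control), reports group means per body bin, and attaches a nonparametric
bootstrap CI (resampling genes within groups; 1000 draws, seeded).  The
bootstrap is this package's addition — bar-level uncertainty for such
contrasts is often left unstated — and its coverage is verified against
normal theory in the tests.

## Alkaline-gel quantitation

Ladder calibration interpolates log10(length) linearly in migration
distance (standard electrophoretic mobility), extrapolating end segments
with a warning.  Treating stain intensity as mass-proportional, the
number-average fragment length is Ln = ΣI / Σ(I/L); each T4 endonuclease V
cut adds one molecule end, so CPDs/kb = 1/Ln(+enzyme) − 1/Ln(−enzyme).
Negative estimates are floored at 0 with a warning, never silently.
Percent repair at t is 100×(1 − D(t)/D(0)), per matched replicate, with
mean ± SEM (sd/√n).  Between-group comparisons use a two-sided t-test,
Welch by default (a pooled-variance Student variant is available); two
constant equal groups return t = 0, p = 1 by convention.

## The simulator

The generator emulates the full study: a random genome (default two 100 kb
chromosomes, ~38% GC), ~100 packed non-overlapping genes (0.5–2.5 kb,
≥200 bp intergenic), uniform strands, covariates, a SRAT flag on a fixed
fraction of genes (default 0.1, mirroring the few-hundred-in-5000 scale of
annotated polyA SRAT genes), and nucleosome dyads at +60 bp from each TSS
then every 165 bp through the gene body.

* **Induction**: every dipyrimidine site on either strand independently
  carries a lesion with probability per dinucleotide (defaults TT 0.10,
  TC 0.05, CT 0.05, CC 0.02 — the qualitative TT > TC≈CT > CC yield order,
  giving ~0.015 lesions/bp/strand, a high-UVC-dose regime that keeps desk-
  scale counts informative).
* **Repair**: survival to time t is exp(−k(x,s)t) with
  k = m_nuc·k_gg·g_gg + k_tc·g_tc·[TS of a gene] + k_anti·g_anti·[NTS of a
  SRAT gene].  m_nuc = 1 − a·c(x) slows global-genome repair in
  nucleosomes; c(x) is 1 at a dyad, 0 at the linker midpoint, cosine-
  interpolated, with amplitude a (default 0.5) and repeat 165 bp exposed as
  parameters because the periodic pattern is observed but not
  parameterized in the literature this emulates.  Rate defaults: k_gg =
  0.2/h, k_tc = 0.6/h, k_anti = 0.3/h.  Genotype multipliers
  (g_gg, g_tc, g_anti): WT (1,1,0); set2 (1, 0.4, 1); rad16 (0,1,0);
  rad16set2 (0, 0.4, 1); rad26 (1,0,0).  γ_tc = 0.4 encodes that loss of
  Set2/H3K36me impairs but does not abolish TC-NER; k_anti's magnitude is
  not constrained by published quantification, so it is a documented
  default with no claim of fidelity.  Survival uniforms are drawn in a
  t-independent order from the seed, so timepoints are nested (monotone
  decay per seed).
* **Depth**: observed counts are binomial thinnings with success
  probability min(1, depth/total), default expected depth 2×10⁵.
* **Bulk curve**: fraction remaining from true totals, with optional
  truncated-Gaussian replicate noise on the fraction scale (plumbing for
  SEM statistics only).
* **Gel lanes**: Poisson fragmentation of 50 kb molecules at a given cut
  density, binned into a migration profile via the same log-linear
  mobility law the calibrator inverts — an independent oracle for the
  number-average pipeline.

What the simulator deliberately does **not** model: read-level sequencing
(FASTQ, alignment error), 6-4 photoproducts, replication and cell-cycle
effects, transcription-level heterogeneity of TC-NER within a gene, histone
exchange, and chromatin changes between genotypes.  Passing tests therefore
demonstrate correctness of the estimators and the direction/recoverability
of the programmed effects, not biological fidelity of any particular rate.

## Problem sizes and numerical choices in the checks

* Directional contrasts (WT vs set2 asymmetry; rad16set2 vs rad16 NTS
  rescue): default study conditions (200 kb, ~100 genes, depth 2×10⁵,
  t = 2 h), three independent seeds; every body bin is required to move in
  the predicted direction, which at these counts is a ≥5σ margin per bin.
* Rate recovery: −ln(F)/t against k_gg (intergenic) and k_gg+k_tc (TS
  bodies) within 10%, depth 10⁵, ten seeds.  This scenario sets the
  nucleosome amplitude to 0 so the body rate is exactly k_gg+k_tc and the
  pooled estimator is unbiased (with modulation on, the recovered body rate
  is mean(m_nuc)·k_gg + k_tc by construction).
* Nucleosome periodicity: the autocorrelation peak of the NTS TSS profile
  is a noisy lag estimator; the check uses 2000 genes on a 4.6 Mb
  chromosome (yeast-genome scale) so the peak-lag sampling error is ~1 bp
  against the 165±5 bp acceptance window, and requires the periodicity to
  vanish when global-genome repair is off (rad16), where the profile is
  flat by construction.
* t-test calibration: 10,000 Gaussian-null simulations with 10 replicates
  per group.  Welch's test is intentionally conservative at n ≤ 5 (type-I
  ≈ 0.035 at n = 3); calibration to the nominal 5% level is a
  moderate-replicate property and is checked there.
* Scaling "exactness" is asserted at machine precision (a few ulp): IEEE
  double rounding makes x·(g/x) = g and median(r/m) = 1 exact only to
  ~1e-16 relative.

## Known limitations

* Lesion-calling dialects vary between published pipelines; only the
  documented default is verified against hand-worked examples, and other
  dialects are supported but unvalidated.
* Genes in the generator never overlap, so the per-position "covering
  gene" is unique; real annotations with overlapping transcripts would
  need a precedence rule the package does not define.
* The gel model ignores lane-to-lane mobility distortion and background
  subtraction; densitometry profiles are assumed pre-corrected.
* Bootstrap CIs assume genes are exchangeable within groups; spatial
  correlation along chromosomes is not modelled.
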