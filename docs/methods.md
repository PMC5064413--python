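# Methods

## Scope and model

`circuitscan` reconstructs a cell's core transcriptional regulatory
circuitry (CRC) from peak-level occupancy of Mediator (MED1), Cohesin
(SMC1A) and the Cohesin loader NIPBL, together with TF peak sets, a genome
sequence, a PWM collection, a chromatin-state segmentation and pathway gene
sets.  It starts from called peaks in BED: read alignment, signal-track
generation and peak calling are out of scope, as are expression-based
activity filters, super-enhancer calling and enhancer–promoter loop
prediction.

All coordinates are 0-based half-open; GTF input (1-based closed) is
converted on read.  Two intervals overlap when they share at least one base
(`a.start < b.end and b.start < a.end`); abutting intervals merge because
they are contiguous in base space.  Chromosome names are matched verbatim.

## Co-occupancy analyses

The substrate is a binary occupancy matrix: rows are the merged union of all
input peak sets (no splitting at set boundaries), columns regulators,
`M[r,c] = 1` iff union region `r` overlaps a peak of regulator `c`.  Binary
membership rather than read densities is used deliberately: it requires no
signal files and reproduces the qualitative structure of interest (the
MED1/NIPBL axis against CTCF, and the split Cohesin population).

PCA centers columns but does not variance-scale them (all variables share
the 0/1 scale; scaling is available via a flag).  Components come from an
SVD; the sign of each component is fixed by forcing the lexicographically
smallest regulator to a non-negative variable coordinate.  Variable
coordinates are Pearson correlations between each column and the region
scores of each component.  Per-regulator densities of member-region scores
on component 1 use a Gaussian KDE on a common 512-point grid, rescaled to a
maximum of exactly 1.  A density is called **bimodal** when two local maxima,
each reaching at least 30% of the curve maximum, are separated by a valley
at least 20% below both — the 30% floor keeps minor KDE ripples and small
satellite populations from counting as a split distribution.

Pairwise correlations between occupancy columns are Pearson's R with the
two-sided p-value from the t transform at n−2 degrees of freedom.
"Percentage of overlap" statistics count regions of the query set with ≥1 bp
intersection (asymmetric by design; a base-pair Jaccard mode exists but is
not the default) — chosen because the TF ranking asks what fraction of each
cofactor's regions a TF covers.  The colocalization matrix is ordered by
average-linkage hierarchical clustering at distance 1 − Pearson correlation
between matrix rows; linkage and distance are recorded in the output header.

State-overlap profiles are base-pair ratios: for each ChromHMM state, the
fraction of the regulator's occupied bases in that state; bases outside any
segment fall under a reserved `unannotated` label, so ratios always sum to 1.

## Motif enrichment

PWMs are read from a HOCOMOCO-style plain text format (rows = positions,
columns A C G T, counts or frequencies) with a pseudocount (default 0.8 per
cell) added before row normalization.  Scanning scores every window of the
MED1∩SMC1A∩NIPBL co-occupied regions on both strands with log2 odds against
an i.i.d. background estimated from the background regions.  Log-odds are
discretized to 1e-3, which lets the score distribution of a PWM under the
background be computed *exactly* by dynamic programming over positions; the
hit threshold is a quantile of that distribution.

The default threshold quantile is 0.9999.  A looser, more conventional
0.995 was evaluated and rejected: with regions of a few hundred bp, each
region contributes ~600 window tests (both strands), so a per-window tail of
5e-3 saturates the per-region hit indicator (background per-region rates
above 0.9 for every motif) and destroys the contrast the region-level
binomial test depends on.  At 0.9999 the per-region background rate sits
near 5–10% and planted motifs separate from decoys by dozens of orders of
magnitude.  The quantile is a config parameter.

Enrichment is a per-region binomial hit-rate test: `h` of `n_t` target
regions contain ≥1 hit; the background rate `b` is the hit fraction among
background regions, floored at `1/(2·n_bg)` to avoid zero; p is the upper
binomial tail `P(X ≥ h)`.  The transparent binomial form was preferred over
a lognormal affinity statistic because it is exact, testable by direct
summation, and matches a "most frequent motifs" ranking.  Background
regions default to the target regions shuffled to random non-target
positions of matched lengths (seeded); a user-supplied background BED is
also accepted.  Motifs are ranked by ascending p, ties by descending hits
then motif id.

## Circuitry construction

TFs are ranked by the mean fraction of MED1, SMC1A and NIPBL regions their
peaks overlap; the top k (default 20) is cross-referenced with the TF
symbols of the top-k enriched motifs.  Symbol matching is case-insensitive
through a small alias table (e.g. ERa ↔ ESR1) shipped as data, since motif
databases often annotate protein names while peak sets carry gene symbols.
A TF present only in the motif list — with no ChIP peaks — cannot become a
candidate: ChIP evidence is required on both sides of the cross-reference.

Each candidate gene gets a regulatory window from 10 kb upstream of the TSS
(strand-aware, clamped at 0) through the end of the gene.  Edge A → B is
drawn when ≥1 peak of A overlaps B's window; edges are unweighted but carry
the peak count as metadata.  A self-edge marks autoregulation.  **Leading
candidates** require the conjunction: autoregulatory AND own window
overlapped by the MED1∩SMC1A∩NIPBL co-occupied set.  Externally motivated
additions (e.g. a pioneer-factor family member observed across all cell
lines) can be listed in the config as `manual_candidates`; they are reported
flagged `"manual"` and never produced by the automated filter.

## Peak-to-gene assignment and pathway enrichment

A peak is assigned to the gene whose regulatory window contains the peak
midpoint (ties: nearest TSS); peaks in no window fall back to the nearest
TSS within 50 kb; anything further is unassigned.  The window-then-nearest
rule and the 50 kb cap are this package's choices (annotation conventions
differ between tools); both live in config and are echoed into output
provenance.  The default universe is all genes in the annotation file.

Pathway enrichment is the one-sided hypergeometric test (equivalent to
Fisher's exact test for enrichment), computed in log space via scipy, with
Benjamini–Hochberg adjustment across tested pathways and significance tiers
at raw p < 0.05 / 0.01 / 0.001.

## Synthetic data generator

The generator emulates the statistical structure of cofactor ChIP-Seq in a
cancer cell line with a single seeded random stream (numpy PCG64); every
stochastic choice is drawn in a documented order, so bundles are
byte-reproducible.  Defaults (the reference scenario): 2 chromosomes × 1 Mb
of i.i.d. sequence at GC 0.41; 60 genes of 2–4 kb; 200 cofactor sites; 3
circuitry TFs (all autoregulatory) and 27 decoy TFs; 3 planted and 30 decoy
motifs of length 9; co-occupancy probability q = 0.8; CTCF-associated
fraction of Cohesin peaks 0.4; motif plant rates 0.6 (target) and 0.05
(background); log-normal peak widths (median 400 bp, σ = 0.25) resembling
typical ChIP-Seq peaks.

Key structural choices:

* Each cofactor site carries all three of MED1/SMC1A/NIPBL with probability
  q, otherwise exactly one.  Each cofactor additionally receives solo noise
  peaks at rate (2/3)(1−q) per site, modelling factor-specific binding and
  ChIP noise; this rate is tied to q so that the fraction of one cofactor's
  peaks co-occupied by another equals q in expectation, and vanishes in the
  q = 1 limit.
* A disjoint CTCF site population, a subset of which carries SMC1A, sized so
  the configured fraction of all SMC1A peaks is CTCF-associated.  CTCF sites
  are kept ≥2 kb from cofactor sites.
* A forced co-occupied site sits at every circuitry gene's TSS; circuitry
  genes are chosen with pairwise-disjoint regulatory windows (the generator
  errors out advising a larger chromosome if that is impossible).  Each
  circuitry TF gets peaks at cofactor sites at the target plant rate, a
  guaranteed peak in every circuitry gene's window (its own only if
  autoregulatory), and its consensus written into the genome under each of
  its peaks plus random background placements; placements overwritten by a
  later overlapping plant are dropped from the truth record.
* Decoy motifs map to TF symbols with no peak set, as in a real
  motif-database cross-reference where most motifs lack matching ChIP data
  in a given cell line.  Decoy consensi are rejection-sampled to lie ≥3
  mismatches from every planted consensus on either strand at alignment
  offsets up to ±3 — a near-copy of a planted motif would be genuinely
  enriched and is not a decoy.
* The state segmentation tiles each chromosome exactly: 1_TssA at
  promoters, 9_EnhA1 at cofactor sites, 5_Tx over gene bodies, 18_Quies
  elsewhere (including CTCF-only sites, which the profiles then correctly
  separate from the active states).

What the generator does **not** model: repeats and local sequence
composition, read-level noise, peak-strength variation correlated with
occupancy, dinucleotide background structure, and 3D enhancer–promoter
contacts.  Passing recovery tests therefore demonstrates correctness of the
inference machinery under the planted statistical structure, not performance
on real ChIP-Seq with its messier backgrounds.

## Null calibration of pathway enrichment

The type-I-error simulation draws target genes uniformly from the universe
and measures the fraction of pathways with p < 0.05.  Because the
hypergeometric test is discrete, its attained level is strictly below the
nominal 0.05 and depends on the design; sizes were chosen by computing the
attained level analytically: a universe of 10,000 genes, 60 pathways of 200
genes and 1,500 target genes attains 0.048, close enough to nominal for a
meaningful calibration check.  Small designs (e.g. pathways of 50 in a
2,000-gene universe) attain only ~0.02 and would misleadingly suggest
miscalibration.

## Problem sizes and numerical choices

Tests and the acceptance script run on the reference scenario above
(2 Mb genome, 200 cofactor sites, 33 PWMs) and a reduced bundle (400 kb, 60
sites) for unit tests; these sizes give stable recovery statistics across
seeds while keeping a full 20-seed study to a couple of minutes.  Score
discretization is 1e-3 in log2-odds units; scanning applies a half-step
tolerance when comparing to the threshold so discretized sums never miss by
floating-point error.  Degenerate inputs are defined errors: empty query
sets for overlap fractions, zero-variance columns for correlations
(zero-variance PCA columns warn and zero their coordinates), overlapping
segmentation intervals, and invalid hypergeometric parameters all raise
with explicit messages.

## Known limitations

Real-data quantities that depend on specific datasets (correlation
magnitudes, overlap percentages, motif p-values, pathway identities) are
data-dependent and not reproduced here; the package asserts structural and
statistical properties instead.  The binomial enrichment treats regions as
exchangeable and ignores region length variation beyond the length-matched
background; the peak-to-gene rule is intentionally simple (no
expression-aware assignment); and the interval algebra assumes peaks are
trustworthy as called.
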