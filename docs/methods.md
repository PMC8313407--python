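# Methods

This note documents the models, conventions and numerical choices behind
`ecrscan`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Coordinates and interval algebra

All internal coordinates are 0-based half-open; GTF (1-based inclusive) is
converted at the I/O boundary and BED is native. "Overlap" means at least
one shared base in half-open arithmetic. The distance between disjoint
intervals is `start(downstream) − end(upstream)`, so abutting intervals
have distance 0. Two exceptions are deliberate:

- Exon merging before intron subtraction coalesces abutting exons
  (`min_overlap=0`), since a zero-length "intron" between book-ended exons
  is meaningless.
- Splice-site and editing-site coordinates are treated as points. The gap
  between editing sites is the difference of their positions (sites at 100
  and 150 have gap 50 and share a cluster at max gap 50), and the distance
  from a splice-site coordinate to a CLIP peak is the number of bases to
  the nearer peak edge (0 inside the peak).

Strand "." is accepted only for repeat, SNP and CLIP inputs; editing and
UTR logic require an explicit strand.

## Editing discovery

The editing frequency at a site folds sequencing errors into the
reference: on the sense strand the edit count is G and the reference is
A+T+C; antisense, edit is C and reference is T+A+G; frequency is
edit/(reference+edit), 0 when no reads. Missing (site, sample)
observations are zeros — the pileup table is authoritative, which
reproduces the recovery of sites absent from per-sample caller output
without needing the alignments.

The cascade: (1) keep non-SNP sites with caller pass, caller score ≥ 0.5,
coverage ≥ 10 and frequency in [0.05, 0.95] in at least one ADAR-WT
sample; (2) re-extract counts across all samples and keep sites where the
three samples of at least one treatment have all frequencies ≥ 0.05, at
least two ≥ 0.10, and all read counts ≥ 10; (3) re-cluster at max gap 50
and keep only clusters with ≥ 5 sites (dropping the other clusters'
sites). Clustering is a single left-to-right scan whose output equals the
transitive closure of the pairwise gap relation; the test suite checks
this against an O(n²) union-find oracle.

A cluster's canonical interval is [first site, last site + 1). ECRs pad
each cluster by 1,000 nt (clamped at 0), then merge intervals overlapping
by ≥ 1 bp — so clusters separated by exactly 2,000 nt produce abutting,
unmerged ECRs, the boundary reading of "group clusters < 2,000 bp apart".

Pooled editing is always Σedit/Σreads over the group — per site per
treatment across all days, or per ECR per treatment day-wise — never a
mean of per-sample ratios. Groups with zero pooled reads report 0 with a
flag. The ≥ 10-reads-in-all-samples rule is a display filter only and
never alters the retained-site set.

## Annotation services

Introns are derived per gene from principal (APPRIS-flagged, detected by
an "appris" substring in the transcript attributes) transcripts: exons
merged, subtracted from the union span of the principal transcripts.
Using the principal span rather than the GTF gene record keeps introns
from leaking past annotated transcripts. Ordinals follow transcript
orientation. Feature assignment uses the fixed priority CDS > 3′UTR >
5′UTR > exon > intron > gene > intergenic; ties within a category are
broken by larger overlap, then lexicographic gene id, making output
independent of track order. Upstream-3′UTR distances consider UTRs of
both strands (a (+) UTR must end at or before the query start; a (−) UTR
must start at or after the query end) and report the nearer candidate,
since intergenic clusters carry no strand of their own.

## Splicing statistics

Relative splice-site use pools replicate counts within a condition, then
divides the summed counts of introns touching a site by the cluster
total; start-site uses and end-site uses each sum to 1 by construction.
Fold changes are reported KO/CTRL. The differential test is a
likelihood-ratio G-test (`G = 2 Σ O ln(O/E)`, df = #introns − 1) on
pooled intron-count vectors of the two arms, BH-adjusted across clusters;
it is an explicit stand-in for the external differential-splicing model —
when a per-cluster significance file is supplied it takes precedence.
Single-intron clusters are excluded; a zero-total arm yields p = NA.

## Differential expression

All three feature classes (genes, introns, ECRs) are normalized against
gene-level library sizes corrected by TMM factors: reference sample by
upper-quartile count fraction closest to the mean; M and A computed on
features nonzero in both sample and reference; 30% M-tails and 5% A-tails
trimmed by rank; factor = 2^(precision-weighted mean M) with asymptotic
binomial precision weights; factors rescaled to geometric mean 1.
log2-cpm adds 0.5 to counts before the log (a standard stabilizer; the
exact constant is a free choice here). Mean-log2-cpm filters are 0.5 /
1.0 / 4.5 for genes / introns / ECRs, boundary inclusive.

Testing fits per-feature treatment-group means by OLS on log2-cpm and
moderates the residual variance toward the global mean with fixed prior
df d₀ = 4: s²_post = (d₀·s̄² + d·s²)/(d₀+d). This is a deliberately
simplified form of empirical-Bayes moderation; it does not reproduce the
precision weights or estimated prior of a full voom/limma fit, and an
external DE engine can be substituted at this seam for real data. The t reference
uses a Satterthwaite-matched df of (d₀+d)²/d rather than d₀+d: the prior
term of the shrunken variance behaves as a constant, so (d₀+d)²/d is the
effective chi-square df that keeps null p-values uniform (verified by
simulation in the test suite; with d = 4 this gives df 16). "Regulated"
means |log2FC| ≥ 1 and BH-adjusted p ≤ 0.05, adjusted per feature class.
Per-day pairwise comparisons are contrasts within the all-treatment
design (each genotype×day triplet an independent condition).

The 2×2 factorial interaction is the double difference
(DKO − ADAR) − (hnRNPC − CTRL) of genotype group means on one day, with
the same moderation, BH-adjusted across the ISG set only. The ISG set is
an input list of feature ids: on real data it would come from an
IFN-α-vs-untreated contrast, but the synthetic design has no IFN-α arm,
so the generator emits its planted ISG list as that input. The factorial
fit is unweighted; no sample-level quality weights are estimated.

Decoupling is Δ = log2FC(intron) − log2FC(gene) per intron;
"differentially regulated introns" for that display are |fold| ≥ 4 and
adjusted p ≤ 0.01 in any per-day comparison. rpkm is
count·10⁹/(lib·factor·length); an ECR is "expressed" when its
per-condition mean rpkm is ≥ 4 in every condition.

## Structure metrics and ligand calls

From a dot-bracket string: total length is the string length; mismatch
fraction is count('.')/length — terminal-loop dots included, exactly as
the count-of-dots formula implies; longest helix is the longest run of
stacked pairs contiguous on both strands (a 1-nt bulge on either strand
breaks the run). Ligand criteria are length > 300 nt (strict), mismatch
fraction < 0.2 (strict), helix ≥ 37 bp (inclusive); the combined flag
defaults to "any" — the inclusive reading of the criteria — with "all"
exposed and the choice recorded in output metadata. Folding itself is out
of scope; records may come from any folding engine or the generator.

## eCLIP enrichment

Per family and strand, p = (reads + pc)/(total + pc·n_families) with a
Laplace pseudocount (default 1) on both libraries; FE = p_eclip/p_input;
RIC = p_eclip·log2 FE. Log base 2 matches the package's conventions;
rankings are invariant to the base, which output metadata records.
Library totals default to the per-strand sum of family reads (making
fractions sum to 1); explicit totals columns are honoured when present.

## Synthetic data: what it emulates, and what it does not

The generator plants the statistical structure the analyses assume, under
the study design (CTRL/hnRNPC/ADAR/DKO × days 3–5 × 3 replicates):

- Toy genome: annotation-only (no FASTA; no stage downstream of
  alignment needs sequence), 60 genes of 10 kb with 4 exons by default,
  one principal transcript each, Alu-like repeats covering ~30% of
  intronic bases (30% as inverted, opposite-strand copies; 20% non-Alu),
  kept ≥ 350 bp from intron edges so canonical splice sites stay
  repeat-free.
- Editing: 30 clusters of 5–12 sites (gaps 5–45 nt) placed in introns /
  3′UTRs / intergenic space at 60/20/20%, genotype frequencies 0.30
  (ADAR-WT) and 0.05 (ADAR-KO), coverage Poisson around 100×, edited
  counts binomial, per-base sequencing errors at 0.005 folded into the
  references, plus planted decoys (singletons, low-frequency sites,
  caller failures) that the cascade must remove. SNP positions are
  disjoint from planted sites.
- Counts: negative-binomial (gamma–Poisson, Var = m + φm², φ = 0.05)
  with per-sample log-normal library-size multipliers (σ = 0.15) so
  factor recovery is testable. Planted classes: decoupled introns
  (log2FC 3 in hnRNPC-deficient arms, gene effect 0),
  transcription-driven genes (log2FC 2 on gene and introns alike), ISGs
  (main effects 1 + interaction 2 in DKO only).
- Splicing: two-intron clusters sharing a 5′ site; the planted subset
  shifts the cryptic 3′ site (inside an intronic Alu) from 20% to 60%
  relative use in hnRNPC-deficient arms; ~150 reads per cluster per
  sample.
- Structures: hairpins assembled from helix runs, symmetric interior
  loops and a terminal loop, with truth metrics by arithmetic.

Deliberately not emulated: read-level artifacts (mapping ambiguity in
repeats, positional coverage bias, strand bleed-through), realistic Alu
sequence content, splice-site motifs, correlated gene–intron noise, batch
or day effects, and the mean–variance trend of real RNA-seq. Passing
tests therefore demonstrate that the algorithms implement their
definitions correctly and recover planted signals at realistic depths —
not that upstream callers are reliable on real alignments.

## Determinism and output conventions

All randomness flows from a single seed through per-stage
`numpy.random.default_rng([seed, stage])` streams; identical spec + seed
gives byte-identical files. Output tables carry the parameter set and
seed in a header comment, format numbers to 6 significant digits and use
'.' for missing values; the run log echoes the resolved configuration
with every parameter exactly once. Problem sizes used by the acceptance
script (60-gene genome, 2,000-feature calibration matrices, 1,000
recovery sites, 500 ISGs) are the package's default study conditions and
complete in seconds on one CPU.

## Known limitations

- The DE model is a simplified moderation; per-feature statistics on
  real data will differ in detail from a voom/limma run even though the
  calibration targets (uniform null, FDR control, unbiased log2FC) are
  met by simulation.
- The G-test ignores between-replicate overdispersion (counts are pooled
  within arms); on real data the external caller's per-cluster
  significance should be supplied and takes precedence.
- `map_to_features` and repeat classification are O(queries × track)
  linear scans — adequate for the toy genome and typical cluster counts,
  not engineered for genome-scale tracks.
- The upstream-3′UTR distance uses the UTR interval edge, not the
  transcript end, when annotations overlap other genes' exons.
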