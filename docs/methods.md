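# Methods

`sexchromtk` implements the sequence-analysis machinery used to
characterize a mammalian sex-chromosome system from short-read depth,
Hi-C contacts, assembly comparison, self-alignment, X/Y alignment and
tissue expression. Every stage is exercised end-to-end against a
synthetic genome with planted ground truth. This note records the models,
the parameter choices that matter, and the limits of what the synthetic
tests demonstrate.

## Sex-linkage calling from depth ratios

**Model.** X-differentiated (X-Div) sequence is diploid in females and
haploid in males; Y-differentiated (Y-Div) sequence is male-only;
autosomes and pseudoautosomal regions (PARs) are diploid in both sexes.
After normalizing each sex's 5-kb window depth by its modal ("peak")
depth, the female/male ratio sits near 2 on X-Div, near 0 on Y-Div and
near 1 elsewhere.

**Decision rule.** Scaffolds longer than 10 kb with > 60% of usable
windows at ratio in [1.5, 2.5] are X-linked, in [0.0, 0.3] Y-linked.
Band endpoints are treated as inclusive (the prose rule "between 1.5 and
2.5" does not fix this; closed intervals are the conservative reading and
are configurable). A pseudocount of 0.05 on normalized depths keeps Y
ratios finite where female depth is ~0, and ratios are capped at 10.

**Peak normalization** uses the histogram mode (1x bins, restricted to
bins above 0.25x the track maximum to skip zero-inflation, the peak being
the mean depth inside the modal bin) rather than the mean, because
hemizygous sequence skews the mean downward. With a strong GC bias the
depth mode legitimately broadens; peak accuracy to within ~1x is all the
ratio stage needs, since identical biases in both sexes cancel in the
ratio.

**PAR delineation** is automated (run-length analysis) rather than the
by-eye inspection typical of practice: windows in the diploid band
[0.75, 1.25] are smoothed by a 5-window majority vote and maximal runs of
at least 10 windows (50 kb) are reported. On clean simulations the
recovered boundary is within one window (5 kb) of truth.

## Hi-C assignment of unplaced scaffolds

Under the standard assumption that intra-chromosomal contact frequency
exceeds inter-chromosomal contact frequency, an unplaced scaffold is
assigned to a chromosome when its bin-pair interaction strengths with
that chromosome are stochastically greater than with *every* competitor
chromosome — one one-sided Wilcoxon rank-sum test per competitor, all
significant at alpha (default 0.05). A PAR candidate is tested against a
chromosome *pair* (the X and Y it would bridge): its interactions with
both are pooled into one sample by default; a stricter per-chromosome AND
rule is available (`pooled=False`).

Choices worth noting:

* No multiple-testing correction across competitors: the all-competitor
  conjunction is already conservative (each additional competitor can
  only remove assignments).
* Raw strengths are accepted without matrix balancing; the test is
  rank-based, so decisions are invariant under any global rescaling.
* The Wilcoxon p-value is computed by exact enumeration when the pooled
  sample is tie-free with n+m <= 16, otherwise by the normal
  approximation with tie and continuity corrections (scipy). The
  asymptotic path agrees with exact enumeration to < 0.01 on tie-free
  samples of 8 vs 8.
* Competitor sets contain anchored chromosomes only.

## Gap-closure auditing

Each maximal N-run in the older assembly is audited against the newer
one via its 500-bp flanks: gaps under 5 bp or within 200 bp of a
scaffold end are excluded; both flanks mapping (aligning rate > 0.70) to
one scaffold with consistent orientation and order and no N in the
intervening span means closed; flanks on two scaffolds means a
trans-scaffold break; everything else is open. Orientation/order
consistency is required for "closed" so that inversion breakpoints are
not counted as closures, and intervening spans beyond 1 Mb (configurable)
are treated as spurious hits and left open.

The built-in flank mapper indexes the new assembly with exact k-mers
(default k = 21, every position), groups seed hits by (scaffold, strand,
diagonal), and extends the best candidates with banded infix alignment
(edlib). The aligning rate is defined as (flank length − edit distance) /
flank length. Seed length 21 is chosen so that a 500-bp flank at ~10%
divergence almost always retains at least one exact seed (the chance of
no clean k-mer stretch is roughly exp(−L(1−p)^k); at k = 31 that failure
rate is ~15%, at k = 21 it is < 1%), while random 21-mer collisions are
negligible at the genome sizes this convenience mapper is intended for.
Production-scale audits should supply external hit tables from a real
aligner; the mapper exists so synthetic scenarios are self-contained.

## Ampliconic regions

Three independent evidence channels, then a union:

1. **Palindromes** — inverted self-alignment hits on one sequence,
   chained when co-linear within 2 kb on both arms; kept when arm-vs-arm
   identity >= 98%, both arms >= 8 kb, spacer <= 500 kb and repeat
   content of the span < 80%. Overlapping calls are deduplicated in
   favour of the longer arm.
2. **Tandem arrays** — 5-kb windows (2-kb overlap) of the repeat-masked
   sex-linked sequence supported by a non-self self-hit covering > 50% of
   the window at > 99% identity; candidate windows merged, merged length
   >= 10 kb. A hit whose target overlaps the window itself never supports
   it (the trivial self-match carries no amplification evidence).
3. **Depth excess** — non-PAR sex-linked windows whose GC-corrected male
   depth is >= the autosomal level ( >= , not >: a two-copy collapse sits
   exactly at the autosomal level), repeat content < 80%. This channel is
   the only one that sees amplicons collapsed during assembly.

GC correction is binned-median scaling: windows are grouped in GC bins of
0.01, each value is multiplied by (global median / bin median), and bins
with fewer than 20 windows inherit the nearest populated bin's factor.
This matches regression-style corrections in expectation for this use
and is easy to verify. The autosomal reference level is the mean of
corrected autosomal windows (median via flag).

Genes with > 80% of their length inside the merged region set are called
ampliconic; olfactory and vomeronasal receptor names (OR*/OLFR*/V1R/V2R/
VMN* patterns, case-insensitive) are excluded because those families
amplify genome-wide rather than sex-specifically. For genes in hemizygous
regions a copy-number estimate is attached: median corrected depth over
the gene divided by half the autosomal level, rounded. It is labelled an
estimate; it only reflects copies collapsed in the assembly.

## Strata dating

X/Y identity is computed in 1-kb windows along the X from alignment
segments (matched bases / aligned columns intersecting the window; with
only per-segment identities available, mismatches are spread uniformly
along the segment — an approximation stated in the output types). X/Y
segments whose Y span aligns *strictly* better (higher identity AND
longer alignment, ties keep) to autosome/PAR sequence are filtered out
as likely paralogous alignment; Y-span correspondence requires 50%
reciprocal overlap.

Divergence per stratum is estimated from concatenated valid columns
(non-gap, non-N, unmasked — coding and repeat masks are supplied as
column masks and combined as a union) under Jukes–Cantor:
`d = -(3/4) ln(1 - (4/3) p)`. The 95% CI is a percentile bootstrap over
columns (default B = 1,000, seeded); replicates hitting the p >= 3/4
saturation ceiling are discarded and counted.

**Rate model.** With male-to-female mutation-rate ratio alpha and female
rate mu_f, per-year rates are A: (1+alpha)/2 mu_f, X: (2+alpha)/3 mu_f,
Y: alpha mu_f, so X/Y divergence accumulates at
`r = (2+4 alpha)/(3+3 alpha)` times the autosomal rate; r is strictly
increasing in alpha, bounded in (2/3, 4/3), and 1 at alpha = 1. Stratum
age is `T = d / mu_XY` with `mu_XY = r * mu_AA`. At the monotreme
literature values alpha = 2.95 and mu_AA = 7e-9/site/year this gives
mu_XY = 8.15e-9/site/year. Stratum interval definitions are inputs;
calling stratum boundaries (gametolog phylogenies, synteny inspection)
is out of scope.

## Tissue specificity

tau = sum_i (1 − x_i / max_j x_j) / (n − 1) over n >= 2 tissues, on
linear TPM after averaging replicates per tissue (log2(x+1) optional).
tau is scale-invariant, 0 for uniform expression, 1 for single-tissue
expression, undefined (NaN) for all-zero profiles. A gene is called
tissue-specific when tau >= 0.8 (configurable; the threshold is a
convention, not a derived quantity) and the named tissue is the unique
maximum; ties for the top tissue are non-specific.

## The synthetic scenario

`simulate.ScenarioConfig` defines the study conditions; the defaults are
the conditions every recovery test runs under and are deliberately
scaled down from a real genome so the whole suite runs on one CPU in
minutes:

* 4 autosomes of 200 kb; X1 = 60-kb PAR + 180 kb X-Div; Y1 = the same
  PAR + Y-Div derived from the X-Div ancestor + 60 kb Y-specific
  sequence; unplaced scaffolds: a second 60-kb PAR, a 50-kb X-Div
  fragment and a 60-kb autosomal fragment.
* Three strata of 60 kb at divergences 0.30 / 0.10 / 0.03: the Y copy of
  each stratum carries JC-style substitutions at probability
  (3/4)(1 − e^(−4d/3)), i.e. the planted d is the total X/Y divergence.
* Depth: negative-binomial 5-kb window totals, mean 30x for a diploid
  window, size parameter 150 (~8% CV, realistic for 30x WGS window
  means); female Y depth floored at 0.02x of the mean (contamination
  floor so ratio denominators are finite); GC varies sinusoidally and
  multiplies depth by 1 − 1.2 (GC − 0.42), giving the correction stage a
  real signal to remove.
* Hi-C at 10-kb resolution (bin counts per profile comparable to 100-kb
  bins on real chromosomes): power-law intra-chromosomal decay, flat
  trans baseline, 3x enrichment between unplaced scaffolds and their
  true chromosome(s), lognormal noise (sigma 0.4). No balancing — the
  consumer is rank-based.
* Amplicons: one true palindrome (10-kb arms, 98.5% identity) plus a
  repeat-covered decoy that must be rejected; a 6 x 5-kb tandem array at
  99.5% pairwise copy identity (each copy mutated from a master at half
  the target divergence); a 20-kb 6-fold collapsed region realized in
  depth only.
* Gaps: 10 closed / 5 open / 5 trans / 2 excluded, built by copying
  flank context out of the new assembly; "open" gaps get a downstream
  flank that does not exist in the new assembly.
* Expression: 6 tissues x 2 replicates, 60 genes, 12 planted
  testis-specific (high testis, ~0–2 TPM elsewhere).

Determinism: every stage draws from its own `SeedSequence` child of the
scenario seed, so outputs are byte-identical across runs and independent
of the order stages are invoked in.

**What the synthetic tests do not show.** The generator has no indels in
X/Y alignments (segments are gapless), no read-level artifacts
(mappability, duplicates, reference bias), no Hi-C ligation noise or
balancing structure, no repeat-driven mismapping, and substitutions are
strictly JC-uniform. Perfect recovery on these scenarios validates the
decision rules and their thresholds, not robustness to real-data
artifacts; on real data the depth bands, the Hi-C significance level and
the mapper are the knobs to revisit.

## Numerical details

* All coordinates 0-based half-open; 1-based conversions confined to I/O.
* Inverted alignment targets are stored on the forward strand with a
  strand flag, keeping one coordinate system for palindrome chaining.
* Missing window values are NaN in memory and `NA` on disk; they are
  excluded from classification denominators, identity windows and GC
  bins.
* JC69 is refused at p >= 0.75 (saturation); the bootstrap discards and
  counts saturated replicates rather than clipping them.
* Tie-breaking: flank-mapper hits by (matches, aligning rate, scaffold
  name, leftmost coordinate); top-tissue ties make a gene non-specific;
  identity ties never drop an X/Y segment in the paralogy filter.
* Problem sizes in the test suite (10-kb bootstrap alignments, 100-trial
  coverage runs, 2.5-Mb autosomes for CLT/GC checks, 20-replicate power
  runs) were chosen so each statistical assertion has the sample size its
  nominal tolerance needs.
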