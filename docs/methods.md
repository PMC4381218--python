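# Methods

`dyeswap` implements the classical analysis chain for two-color spotted
cDNA microarrays hybridized in a dye-swap design: per-spot quality
filtering, background subtraction, intensity-dependent and spatial lowess
normalization, per-gene replicate-spot t statistics, fold-change calling,
cross-condition comparison, two Gene Ontology category statistics, and the
standard-curve arithmetic used to validate array results by qPCR.  A
synthetic experiment generator with planted ground truth drives all
testing.  This note records the model, the defaults and why, and the
choices made where the procedure admitted more than one reading.

## Spot filtering and expression ratios

Each spot carries, per channel, a median foreground intensity I, a median
background B, and their standard deviations SI and SB.  A spot is kept
when, in *both* channels, the signal-to-background ratio satisfies
I/B ≥ 3 and the contrast satisfies (I − B)/(SI + SB) ≥ 0.6, the scanner
has not flagged it, and the background-subtracted intensity is positive
(the log ratio is otherwise undefined; such a spot would in any case have
non-positive contrast).  Degenerate denominators are resolved toward the
information they carry: a zero background passes the ratio criterion iff
I > 0 (the ratio is infinite), and a zero SI + SB passes the contrast
criterion iff I − B > 0.  After spot filtering, any gene left with fewer
than three high-quality spots on a slide is dropped from that slide
entirely; a gene must clear this bar on *both* slides of a dye-swap pair
to be analyzable in that condition.

Surviving spots are transformed to MA coordinates:
A = (log2(I₁ − B₁) + log2(I₂ − B₂))/2 and M = log2 of the
background-subtracted test/control ratio, with the test channel resolved
from the slide's recorded dye orientation (ch2 = Cy5 carries the test
sample on the first slide of a pair, ch1 on the swap slide).  Resolving
orientation here, rather than sign-flipping later, makes the two slides'
M values directly poolable and makes test/control relabeling an exact
antisymmetry of the whole pipeline (verified to the last bit in tests).

## Normalization

Intensity-dependent dye bias is removed by robust lowess of M on A
(tricube-weighted local linear fit, span 0.3, 3 robustifying iterations —
standard MA-normalization practice; all three are configurable).  The fit
is subtracted in three sequential passes: whole slide, then within each
of the 12 meta-row groups, then within each of the 4 meta-column groups.
The alternative reading — one fit per each of the 48 print blocks — is
available as `mode="blocks"`; the marginal (12 + 4) reading is the
default.  A fitting group with fewer than 20 spots retains the global
correction only, to avoid overfitting tiny groups.  Normalization never
changes spot membership, only M.

The stage is idempotent by construction: M is always recomputed from the
stored raw values, so re-running the stage on its own output cannot
double-correct (re-application reproduces the output exactly).

What normalization can and cannot do: the smooth injected bias b(A) and
the spatial offsets are removed to a ~2% residual on noise-free data, but
the per-spot noise floor is untouched — on noisy data the post-
normalization median |M| converges to the noise median, not to zero.
Efficacy is therefore measured on noise-free bias-carrying slides, and
the absence of spurious signal (≥95% of genes moved by < 0.05 in mean M)
on bias-free noisy slides.

## Differential expression

For each gene of a condition, the orientation-aligned M values of the two
slides are pooled (up to 12 spots: 6 per slide) and tested against zero
with a plain one-sample two-sided Student t test, df = n − 1.  Replicate
spots are treated as exchangeable across the two slides (no slide random
effect) and no variance moderation or multiple-testing adjustment is
applied — the statistic is deliberately the textbook one.  Zero-variance
vectors cannot support a t statistic; by documented convention they
report p = 0 when the repeated value is nonzero and p = 1 when it is
zero, with a degeneracy flag.

Fold changes use the sign-magnitude convention: mean log2 ER m maps to
2^m for m ≥ 0 and −2^(−m) for m < 0, so strong down-regulation reads,
e.g., −74.54 rather than 0.013.  The mapping is exactly invertible and is
round-trip-tested.  A gene is called differentially expressed when
p < 0.01 **and** |FC| ≥ 1.5; both thresholds are exposed, and setting
`fc_threshold=1.0` recovers the p-only rule, since reported DEG counts in
this field sometimes apply only the p criterion.

Two conditions' DEG lists are compared as a Venn partition over the genes
analyzable in *both* conditions; DEGs analyzable in only one condition
cannot be classified as shared-or-specific and are reported separately
rather than silently assigned.  Shared DEGs carry both fold changes and a
same-direction flag.

## Category statistics

Two complementary statistics summarize Gene Ontology categories, both
computed against the background of genes that survived QC in the
condition at hand (enrichment must condition on what was analyzable, not
on the full printed platform):

1. **Over-representation**: the 2×2 table DEG/non-DEG × in/out of
   category, evaluated by the chi-square test with Yates continuity
   correction (df = 1); for a 2×2 table this equals
   N·(max(|ad − bc| − N/2, 0))² divided by the product of the margins,
   the clip at zero being what the continuity correction means.  A table
   with a zero margin carries no information and reports p = 1 with a
   degeneracy flag.
2. **Rank-class statistic**: up- and down-regulated genes are ranked
   separately by |log2 ER| (rank 1 = strongest, average ranks on ties)
   and member ranks are compared with non-member ranks by a two-sample
   Student t test — a normal-approximation analogue of a rank-sum test.
   "Compare the sums of ranked genes by a t test" admits several
   readings; this one (two-sample t on ranks, directional lists built
   separately) is the closest literal one, and a permutation oracle in
   the test suite guards that its significance calls match a 10,000-draw
   permutation test of the mean-rank difference.  The statistic depends
   on the expression values only through their ranks (tested under
   monotone transforms).

Category-level effect sizes are reported as the arithmetic mean
sign-magnitude FC of member DEGs, with a bidirectional flag when members
change in both directions (opposite signs cancel in the mean).  A
Benjamini–Hochberg option across categories exists behind a flag, off by
default — the headline statistics are per-category.

## qPCR arithmetic

Quantification is absolute: Ct = slope·log10(copies) + intercept is
fitted by least squares to a plasmid dilution series (≥3 points spanning
≥2 decades), the triplicate-mean Ct of each sample converts to copies
through the curve, target copies are normalized to 18S rRNA copies of the
same sample, and the fold change is the ratio of treated to control group
means of the normalized values, mapped to sign-magnitude.  Triplicates
are averaged on the Ct scale before conversion (convention; the
alternative — averaging copies — differs only at large well-to-well
spread).  Curve quality gates: r² > 0.99 and efficiency
10^(−1/slope) − 1 > 0.99; slope −3.3219 is perfect doubling.  Reference
stability is the percent difference of group-mean reference Cts against
a 7% gate; violating it warns (the check is diagnostic) rather than
fails.  An efficiency-corrected ddCt alternative, (1 + E)^(−Ct) in place
of curve copies, sits behind `method="ddct"`.  Fold changes are computed
per sample and then averaged per group, and a constant Ct shift applied
to a whole run cancels exactly through the reference and control
normalization (a tested invariant).

## The synthetic experiment generator

The generator emulates a 1818-clone immunochip-style platform, six
replicate spots per clone scattered over a 12 × 4 meta-grid, annotated
with nine functional categories of fixed sizes (immune response 236,
cell communication 291, signal transduction 245, receptor activity 126,
apoptosis 120, cell cycle 76, protein catabolism 90, protein folding 70,
oxidative stress 39; overlaps allowed).  Four conditions ({slow, fast}
muscle × {24 h, 72 h} of an inflammatory challenge vs saline control)
are each hybridized as one dye-swap pair — 8 slides by default.  The
physical layout of the real platform is not public; the scattered layout
is an emulation chosen to exercise the spatial normalization, not a
reconstruction.

Per spot, log2 channel intensities are baseline(gene) ± log2FC/2 plus
iid Gaussian noise of SD 0.3/√2 per channel (per-spot log-ratio SD 0.3,
a typical replicate-spot spread for this platform class).  Baselines are
uniform on log2 ∈ [11, 21] (~3 decades of intensity).  The Cy5 channel
additionally receives 0.5·sin(A/2) of smooth dye bias plus per-meta-row
(SD 0.15) and per-meta-column (SD 0.10) offsets drawn fresh per slide,
so both normalization passes have real structure to remove.  Foreground
medians are 2^l + B with background B ~ N(100, 10) clipped to ±40%;
because the stored background is subtracted exactly downstream, the
model keeps the expression signal recoverable while still exercising
the subtraction path.  SI = 0.05·I and SB = 0.1·B place every regular
spot safely inside both quality criteria, while a planted fraction
(default 8%) of spots is built to fail exactly one criterion (I/B = 2.5,
contrast = 0.3, or a scanner flag), giving the filter a planted truth it
must reproduce exactly.  Planted differential genes (default 5% of
clones at |log2 FC| = 1.25, random sign) are over-sampled (50%) from the
immune-response category so the enrichment statistics also have a
planted positive.  Biological pooling (3 fish per RNA pool) is modeled
implicitly as the reduced variance of one pooled expression level per
condition — the hybridizations never see individual fish.

What the generator does *not* emulate: spatial correlation of background,
print-order effects, cross-hybridization, heavy-tailed spot noise, and
per-fish biological replication.  Passing tests therefore demonstrate
the correctness and calibration of the arithmetic under the stated
model, not robustness to every artifact of real scans.

qPCR simulation: per-gene curves with slope −3.3219 + N(0, 0.01) and
intercept U(34, 38); six-point tenfold dilution series with 0.05 Ct of
well noise (keeping r² > 0.99 and efficiency within the >0.99 gate);
target genes at ~10⁴ copies shifted by the planted log2 FC in the
treated group, 18S at ~10⁷ copies in both groups, comfortably inside the
7% Ct stability gate.

## Numerical and reproducibility choices

* All randomness flows from one `numpy.random.default_rng(seed)` per
  generator call; identical (config, seed) reproduce every file.
* Lowess fits come from `statsmodels`' robust lowess evaluated at the
  input points in input order; a fitting group with fewer than two
  distinct A values falls back to its mean.
* Pipeline outputs are written with a fixed `%.6g` float format and
  LF newlines, making repeat runs byte-identical; the run manifest
  records seed, thresholds and stage counts but not the output path.
* The t-test p value is computed from the t survival function; the test
  suite checks it against a direct incomplete-beta evaluation to 1e-10,
  and the Yates statistic against the closed 2×2 formula to 1e-12.
* Default problem sizes in the test suite: full platform width (1818
  clones) wherever a criterion depends on scale (calibration, recovery,
  CLT bounds), and 100–150-clone experiments for structural and
  orchestration checks.

## Known limitations

* The rank-class statistic is one defensible reading of an
  under-specified procedure; an unstandardized rank-sum variant would
  differ in small samples (the permutation guard bounds the damage).
* No between-slide scale or quantile normalization is performed
  (deliberately — the procedure normalizes within slides only), so
  slide-level scale differences propagate into the pooled variance.
* Plain per-gene t tests at n = 12 with no moderation are noisy for
  genes with unluckily small sample variance; this is faithful to the
  procedure, not optimal practice by today's standards (limma-style
  shrinkage would dominate).
* The 2×2 chi-square treats genes as independent; replicate spots of a
  gene are collapsed first, but co-regulation between genes is ignored,
  as is the GO DAG (categories come flat from the annotation file).
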