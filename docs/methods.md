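# Methods

## The analysis problem

In vivo biotin identification (iBioID) tags proteins within ~10–50 nm of a
promiscuous biotin ligase (BirA*) fused to a bait protein. With three
release-site baits expressed in dopamine neurons (the central RIM fragment
RIM^PPCP^, ELKS2β, and Ca_V_β4) and soluble BirA-tdTomato as an axonal
reference, the mass-spectrometry readout is a table of spectral (peptide)
counts per protein × condition × biological repeat, with repeats grouped
into mass-spectrometry sessions. The analysis asks which proteins are
*enriched* near the baits relative to the general axonal proteome, how the
three baits' neighborhoods overlap, which ontology categories they cover,
and how dopamine-neuron knockouts of RIM or Synaptotagmin-1 reshape the
result. A companion imaging assay quantifies a candidate protein's
intensity in TH⁺ synaptosomes with and without the release-site marker
Bassoon.

## Enrichment statistic

For each protein, bait condition and session:

1. counts are averaged over the session's repeats (absence = 0);
2. a session average of exactly 0 is imputed to 0.5 peptides — a floor that
   also absorbs single singleton detections such as (1, 0), whose plain
   mean already equals 0.5;
3. the session fold change is the bait session average divided by the
   BirA-tdTomato session average (both post-imputation, hence > 0);
4. session fold changes are averaged, unweighted, into the final FC;
   single-session datasets use the session FC directly;
5. log₂FC is taken after the averaging, and a protein is a *hit* at
   threshold t if FC ≥ t (inclusive), with t ∈ {1.5, 2.0, 2.5} and 2.0 the
   primary threshold.

Imputation is applied at the session-average level to numerator and
denominator alike; this single rule covers both "zero session average" and
"zero in the denominator" cases consistently. A protein with no peptide in
any of the four conditions of a genotype is excluded from that genotype's
result entirely rather than being reported at FC = 0.5/0.5 = 1.

Mitochondrial proteins (a versioned inventory such as MitoCarta is supplied
as a plain gene list) and hard contaminants (the endogenously biotinylated
carboxylases PC and PCCA, neutravidin, IgG) are removed before enrichment;
mitochondrial removal can be disabled (`keep_mito`) for analyses that
deliberately retain them. Gene symbols are matched after uppercasing and
stripping whitespace, with an optional user-supplied synonym map applied
first — cross-species symbol reconciliation is data, not code.

Per-bait summary counts ("identified / log₂FC>0 / hits") define
"identified" as ≥1 peptide in that bait condition across its repeats. This
is the only definition under which the per-bait totals can differ between
baits, which they do in practice; it is recorded here because the
convention is not otherwise derivable from the outputs.

No per-protein significance test is computed: the method is a pure
fold-change threshold, and the package deliberately keeps it that way.
Consequences of that choice are quantified with the synthetic generator
(below).

## Overlap, categories, panels

Hits at one threshold are partitioned into the 7 exclusive regions of the
three-bait Venn diagram; the partition also records, per protein, the
largest FC over the baits in which it is a hit and that bait's identity
(the quantity the original display scales circle area by — area is scaled
linearly with max FC in exports, and the raw value is always exported so
the scaling stays cosmetic). Bait-encoding genes are flagged in the
partition but not removed from it; they *are* excluded from annotation
fractions and category means, and additionally each bait's own gene is
excluded from its own bait's category mean (self-biotinylation would
otherwise dominate it).

Annotation tables map gene symbols to hierarchical cellular-component
paths (e.g. synapse / presynapse / active zone). Paths are not mutually
exclusive and membership at a level is prefix matching, so an ancestor
level always contains every descendant level's genes. Category summaries
report mean ± SEM (sample SD/√n) of log₂FC over all *detected* annotated
proteins — not only hits — per genotype and bait.

Genotype effects on category means are tested with a factorial two-way
ANOVA (genotype × bait, interaction included), computed via OLS with
Type II sums of squares; on balanced designs this equals the textbook
decomposition, and the test suite verifies F statistics against an
independent brute-force sums-of-squares oracle to 10⁻⁸. Post-hoc
comparisons are per-bait two-sample t-tests of each mutant against
control, Bonferroni-adjusted by the number of comparisons actually
performed (mutant genotypes × baits); empty or singleton cells are skipped
and flagged, and shrink the Bonferroni family accordingly.

Control-vs-mutant overlap is |control ∩ mutant| / |control| on hit sets
from the same threshold. Curated gene panels (e.g. Parkinson's-associated
genes) are reported per gene × bait × genotype with an above/below
threshold flag; genes absent from a dataset are reported as not detected,
never as an imputed FC. The network export is simply hits ∩
synaptic-annotated, written one symbol per line for an external
protein-interaction tool; edge retrieval and clustering are out of scope.

## Synthetic count generator

The generator is the test bed for the whole pipeline; it emulates the
design, not the chemistry. Counts are negative binomial (Gamma–Poisson;
variance μ + αμ²) with a single global dispersion α, around

μ[p, cond] = baseline[p] × enrichment[p, cond] × session factor,

with log-normal baselines, a planted release-site subset enriched in the
three bait conditions, a self-bait spike (each bait's own gene, own
condition only), mitochondrial and fixed-contaminant background, per-record
detection dropout (post-hoc zeroing), and an optional log-normal session
factor (default off) for testing that session-wise FC normalization cancels
it. Genotype multipliers m ∈ [0, 1] interpolate the planted effect as
1 + (enrichment_factor − 1)·m, so m = 1 reproduces control and m = 0
removes the enrichment without planting depletion.

Defaults (one choice, stated with units):

| parameter | default | meaning |
|---|---|---|
| n_proteins | 1500 | detectable proteome size |
| frac_release_site | 0.05 | planted enriched fraction |
| frac_mito | 0.15 | mitochondrial background fraction |
| baseline_log_mean / sd | 3.7 / 0.45 | ln-scale abundance (≈13–90 peptides/repeat) |
| dispersion | 0.01 | NB overdispersion α |
| enrichment_factor | 8 | planted fold enrichment in bait conditions |
| self_bait_factor | 20 | extra spike for the bait's own gene |
| dropout_prob | 0.005 | per-record detection failure |
| n_sessions × repeats | 2 × 2 (control), 1 × 2 (mutants) | acquisition design |
| RIM-KO multipliers | 0.15 (RIM bait), 0.02 (others) | partial self-rescue by the RIM fragment bait |

The sample-size design mirrors the real acquisition (four control repeats
in two sessions; two mutant repeats in one session). The abundance/noise
regime was fixed by a recovery experiment run before the tests were
frozen: because a bare fold-change threshold has no per-protein error
control, the planted-effect recovery property (sensitivity ≥ 0.9 and
false-discovery proportion ≤ 0.1 for the union hit set at the 2.0
threshold) only holds when background proteins are measured well. The
defaults above put essentially all proteins in that regime (tail
probability of a 2-fold ratio excursion ≲ 10⁻³ per protein × bait). What
passing tests therefore show is that the pipeline recovers a planted
8-fold effect in well-measured data; they do not show that the
fold-change threshold controls errors for weakly detected proteins (a few
counts per repeat), where imputation and ratio noise dominate — on real
low-count data the hit lists near the threshold should be read as
candidates, not discoveries. Other real-data features the generator does
not emulate: correlated abundances between related proteins, batch
effects beyond a scalar session factor, and peptide-to-protein inference
ambiguity.

## Imaging module

Each channel (TH, Bassoon, target) is binarized at an Otsu threshold
computed over a 256-bin histogram; the implementation takes the lowest bin
edge attaining the maximal between-class variance (ties, which arise when
the cut moves across empty bins, resolve to the lowest bin within a 10⁻¹²
relative tolerance) and is verified in tests against an exhaustive-search
oracle and against scikit-image. Particles are 8-connected components
(connectivity configurable), gated by area in µm² with closed intervals —
0.2–1 for TH, 0.15–2 for Bassoon and the target channel — with pixel area
= pixel_size², no sub-pixel correction. Pixel size must always be supplied
(synthetic scenes default to 0.138 µm/px).

TH⁺ ROIs are classed Bassoon⁺ if they share ≥1 pixel with a detected
Bassoon ROI, otherwise Bassoon⁻ if their mean Bassoon intensity is below
1× the image-wide Bassoon mean, otherwise EXCLUDED; the three classes
partition the TH ROIs. A symmetric intensity-only rule (positive = above
the same cutoff, nothing excluded) is available as a config switch since
the overlap rule is a design choice, not an established convention. Group
target intensities are compared with an unpaired two-tailed pooled t-test
and a two-sample KS test on per-ROI means.

The synthetic image generator places Gaussian spots (σ = 2 px) with a
minimum separation of 6σ, co-locates Bassoon spots on a configured
fraction of TH particles, draws target amplitudes N(50, 10) plus a planted
shift for Bassoon⁺ particles, and adds Gaussian read noise on a uniform
background, clipped at zero. The end-to-end null calibration (no planted
shift, 500 images) keeps the t-test's empirical false-positive rate at
α = 0.05 within 0.05 ± 0.02. The 2-D single-plane analysis is the minimal
faithful reading of the assay; z-stacks, deconvolution, and sub-pixel
colocalization are out of scope.

## Problem sizes and determinism

Default test and acceptance problem sizes — 500–1500 simulated proteins,
10 recovery seeds, 5–10 genotype panels, 100–500 synthetic images of
256×256 px with 100–150 particles — were chosen so the full suite runs in
about a minute on one core while leaving every asserted property
comfortably away from its Monte-Carlo noise floor. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; equal
config + seed reproduces byte-identical datasets, and the full-pipeline
runner writes a manifest with sha256 checksums plus a JSON-lines log from
which every filtered record and imputed session mean can be counted.

## Known limitations

- The fold-change threshold is the method under study, not a recommended
  inference procedure; see the generator section for what recovery results
  do and do not mean.
- Whether mutant-genotype histogram-style summaries should retain
  mitochondrial proteins is ambiguous in the source convention; both
  readings are computable via `keep_mito`.
- Annotation-dependent quantities are functions of the supplied annotation
  export and are not comparable across annotation releases.
- The ANOVA uses Type II sums of squares on near-balanced data; strongly
  unbalanced category tables would make the main-effect decomposition
  order-dependent under other conventions.
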