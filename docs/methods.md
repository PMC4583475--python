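# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `bittermap`, and what passing its tests does and does
not demonstrate about real data.

## Genotype model and copy number

Genotypes are unordered allele pairs per subject and coding site. Whole
gene deletions at the CNV-capable loci (*TAS2R43*, *TAS2R45* by default)
interact with SNP calls: one deleted chromosome makes a subject hemizygous
(single-allele calls at every site of the gene), two make the gene's sites
missing. Copy number is called from multiplex-PCR product patterns by a
three-row decision table — spanning product only → 0 copies, internal
products only → 2, both → 1, neither → assay failure (raised, never
silently imputed).

Hardy–Weinberg departures are tested with the exact conditional test
(two-sided by probability mass, enumerating heterozygote counts given the
allele counts). With 48 subjects the asymptotic χ² test would be
anticonservative; the exact test's rejection rate under random mating is
verified at the nominal 5% over 1,000 replicate simulated sites.

## Haplotype phasing

Phasing is multinomial EM under random mating. A *scope* is phased
jointly: the sites of one gene, or — for long-range haplotypes — one
multi-allelic marker per gene whose alleles are gene-haplotype names, the
deletion being an ordinary allele state. Each diploid subject contributes
the set of diplotype resolutions compatible with its genotypes (2^(h−1)
for h heterozygous markers); hemizygous subjects contribute a single
chromosome; subjects missing a scope contribute nothing. The E step
weights resolutions by f_i·f_j (doubled for heterozygous pairs), the M
step re-estimates frequencies from expected chromosome counts; the
likelihood is non-decreasing and iteration stops when its gain falls below
1e-8 (500 iterations cap, non-convergence flagged on the result, not
raised). Ten seeded restarts (uniform + Dirichlet initialisations) guard
against local maxima, though at the ≤6 haplotypes per gene typical of
this receptor family the likelihood is effectively unimodal. Reported
phases are maximum-posterior diplotypes with their posterior probability;
low-posterior phases are reported as-is (no external-reference
resolution step). This is a deliberate, deterministic stand-in for
coalescent-prior Bayesian phasing: at these scope sizes the difference is
negligible and reproducibility is exact. Haplotypes are named by
descending frequency (H1 most common; ties broken lexicographically on
the allele vector; the pure-deletion haplotype keeps the deletion symbol;
long-range haplotypes use the H-LR prefix).

Phasing accuracy is summarised as the fraction of subjects whose inferred
unordered haplotype pair differs from the simulated truth — at ≤4-site
scopes this diplotype error is the natural switch-error summary (a single
switch changes the whole diplotype).

## Linkage disequilibrium and blocks

For a k×l gamete table, D′ = Σᵢⱼ pᵢqⱼ·|D′ᵢⱼ| (frequency-weighted), and
r² = χ²/(N·min(k−1, l−1)), the squared Cramér's-V analogue; both reduce
to the classical biallelic D′ and r². Significance uses a Monte-Carlo χ²
independence test with margins fixed (10,000 seeded tables by default) —
valid for sparse multi-allelic tables at n = 48.

Blocks follow the four-gamete rule: after collapsing each unit to major
allele vs rest, a pair shows recombination evidence iff all four gametes
reach the 5% frequency cutoff. Blocks are maximal contiguous runs, grown
greedily left to right, in which **no within-run pair** (not adjacent
only) shows evidence; monomorphic units extend runs. Manual overrides
(unit → forced block label) are applied after the algorithm and win over
it, covering the hand-adjustment cases where single genes straddle
boundaries; the final partition is the contiguous runs of equal labels.

## Psychophysics

Detection follows the 4-AFC model P(correct) = γ + (1−γ)·F((x−μ)·β) with
γ = 0.25, x = log₁₀ concentration and F the logistic; recognition uses
γ = 0. Fits maximise the Bernoulli likelihood per subject × compound ×
repetition (pooled-repetition fits optional) with L-BFGS-B from five
deterministic starts, ties broken by likelihood then smaller slope. The
reported threshold is 10^μ — the midpoint of the non-guessing component
(P = 0.625 detection, 0.5 recognition), the ISO-13301-consistent default;
the criterion point is configurable. μ outside the tested range sets a
low/high censor flag (all-correct and at-chance series therefore censor
rather than error), and censored cells are excluded listwise downstream.
Fitting is done on log concentration.

Intensity ratings (percent of gLMS scale length) are fitted by least
squares to a three-parameter saturating logistic (floor 0, ceiling ≤110%)
and inverted at the fixed label positions weak 6, moderate 17, strong
34.7 and very strong 52.5% of scale; inversions above the fitted ceiling
are undefined (censored), and solutions outside the tested range carry a
censor flag. Inverted concentrations are non-decreasing in the label
order by monotonicity of the curve.

Peirce's criterion uses Gould's iterative computation of the squared
deviation ratio x²(N, k) (one unknown quantity); the number of doubtful
observations k is raised while at least k observations exceed the
criterion, and deviations are measured against the full sample's mean and
SD, per the classical procedure. It is applied per compound × measure to
log₁₀ thresholds across subject × repetition cells.

## Association

The response is log₁₀ concentration (thresholds are log-normal). Genotype
is a categorical between-subject factor (classes below the 0.05 sample
frequency dropped, their subjects excluded for that unit); subjects are
random intercepts with repetitions nested inside. The genotype test is
the containment-degrees-of-freedom F:

F = MS(genotype) / MS(subject within genotype), df = (k−1, n_subj−k),

computed directly from the nested sums of squares; for balanced data it
equals the one-way ANOVA on subject means, and it equals the type-I
nested OLS decomposition in general (both identities are tested). Its
type-I error is calibrated to 0.05 ± 0.02 over 1,000 null replicates.

The experiment-wide SNP threshold is the α-quantile (default 5%) of the
permutation distribution of the per-permutation minimum p, permuting
subject phenotype vectors as units — this preserves LD among sites and
the repetition structure, so the family-wise error is held at α under the
observed dependence (duplicating a SNP leaves the threshold unchanged;
for independent SNPs it matches the Šidák closed form, also offered as a
fast alternative). Gene- and block-level scans use Bonferroni.

## Receptor function

Corrections are applied in the fixed order: (1) each well's response is
its own baseline ratio ΔF/F = (F−F₀)/F₀, absorbing well-to-well loading
differences and making the pipeline exactly invariant to detector gain;
(2) the mean empty-vector ΔF/F matched on (day, compound, concentration)
is subtracted, removing receptor-independent artefacts (empty-vector
wells are exactly mean-centred by construction); (3) responses are scaled
by grand-mean/day-mean of the positive control, equalising day gains.
Days with non-positive control means are dropped; wells without a matched
negative-control group are dropped.

The activation threshold is the lowest concentration whose corrected
responses exceed the matched empty-vector wells: a one-way ANOVA gate
across concentration groups plus control at α = 0.05, then per-
concentration Welch comparisons with Bonferroni m = number of tested
concentrations (the contrast structure is a package choice; the direction
must be positive). Concentrations above a per-compound artefact-free
ceiling (3×10⁻⁴ M by default) are excluded throughout.

Hill fits minimise least squares over (log EC₅₀, A, n) with EC₅₀ bounded
to [c_min/10, c_max·10], n ∈ [0.5, 4] (freely fitted, not pinned to 1)
and A ≥ 0, from five EC₅₀ starts; bound-pinned or non-convergent fits are
flagged and treated as not activated, as are constructs with no called
threshold.

## Integration

Alleles are classed within a compound by activation-threshold ratio to
the best allele: ≤3× sensitive, ≤30× intermediate, else insensitive;
never-activated alleles are nonfunctional (boundaries configurable). An
allele is *phenotype-explanatory* iff its threshold is at or below the
top of the subjects' recognition range. For linkage-phase summaries,
sensitivity is judged within each gene (its own lowest-threshold class):
the published masking argument counts "a high-sensitivity allele of at
least one gene", which is a per-gene notion — a gene's best allele can be
10× the other gene's and still be that gene's sensitive allele.

Per-subject dosage is the number of carried long-range-haplotype copies
bearing ≥1 sensitive allele. Phase mode over the common (≥5%) LRHs:
*repulsion* when every LRH carries exactly one implicated gene's
sensitive allele (dosage saturates at two copies for everyone, masking
association); *coupling* when sensitive alleles co-reside on some LRHs
while others carry none (dosage spreads 0–2 and association shows);
*single_locus* when only one gene is implicated; *mixed* otherwise.

The causal filter intersects (a) genes in experiment-wide-significant
blocks, (b) the compound's responsiveness inventory (an editable config
table), and (c) explanatory alleles: all three → causal; in a significant
block and responsive but not explanatory → linked passenger;
non-responsive genes riding a block that holds a responsive gene are also
linked passengers, while blocks with no responsive gene stay unexplained;
responsive + explanatory without any association → phase-masked. The
report is a pure function of its inputs.

## The synthetic generator

The generator is the package's model of the study conditions, not a
tuning knob. The default scenario fixes: 48 diploid subjects; 25 genes on
chromosomes 5, 7 and 12 in six multi-gene LD blocks plus singleton genes;
per-block long-range haplotype pools — in particular the four common
TAS2R31–42 haplotypes at 0.30/0.22/0.20/0.16 with the deletion (TAS2R43),
truncation (TAS2R46-H2) and sensitive-allele arrangements that put the
grosheimin-relevant alleles in coupling and the absinthin-relevant
alleles in repulsion phase; receptor dose–response parameters taken from
the published per-allele thresholds, EC₅₀s and amplitudes; 12-step
ratio-1.5 concentration series from the published starting
concentrations, in triplicate, 4-AFC guess rate 0.25; and six-day plate
designs on a 1–3–10 half-log grid (10⁻⁹–3×10⁻⁴ M).

Chromosomes are drawn i.i.d. from the block pools (random mating); the
residual pool mass becomes rare haplotypes made by mutating a pool
haplotype at one random site, keeping allele sets closed. Within-block
pools are four-gamete-consistent by construction (a perfect-phylogeny
arrangement), so block boundaries arise only between blocks; because
blocks are independent, the generator deliberately has no cross-block LD
decay, and region-wide mean LD is therefore lower than in the real
cluster even though within-block LD is high.

A subject's latent log₁₀ recognition threshold is a per-compound affine
link applied to the best (lowest) activation threshold among carried
functional alleles, plus N(0, 0.12) subject noise; subjects with no
functional allele fall back to a compound-specific nonresponder
threshold. The link offsets/slopes were calibrated once so the published
receptor thresholds map onto the published phenotype modes and ranges
(e.g. grosheimin 1.0×10⁻⁶ M → the 9.9×10⁻⁶ M mode, nonresponders inside
the 5.0×10⁻⁵ M series end; absinthin perception sits below in-vitro
activation, hence its negative offset). Detection sits 0.2 log₁₀ units
below recognition. Intensity is a saturating logistic with a per-subject
ceiling (85 ± 5%, clipped to [60, 100]) and truncated Gaussian rating
noise (SD 4), clipped to [0, 100]; the published narrowing of the
strong-intensity distribution relative to recognition emerges from
ceiling saturation plus censoring of inversions beyond the tested range,
not from an extra parameter. The yes/no recognition question is simulated
at every step by default (`recognition_mode="all"`); the variant where it
is asked only after a correct 4-AFC choice is supported
(`"chosen"`).

Plate wells draw a lognormal baseline F₀ (CV 10%), a per-day
multiplicative gain N(1, 0.12), and relative response noise SD 0.003; the
receptor signal follows the allele's Hill curve once its activation
threshold is crossed and stays at baseline below it — the printed
activation threshold is a detectability statement, and anchoring the
evoked signal at it is what lets the statistical threshold call reproduce
the printed values rather than drift with assay noise. Empty-vector wells
(3 per day × concentration) carry only the receptor-independent artefact
term (zero within the artefact-free range), positive-control wells (4 per
day) a unit response. All randomness flows from one integer seed through
per-operation, per-compound tagged streams, so every stage is
byte-reproducible and independently re-seedable.

What the synthetic data do **not** emulate: population structure and
relatedness, genotyping error, cross-block LD decay, adaptive staircase
designs, lapse rates, session/carry-over effects, kinetic fluorescence
traces, or expression-level variation. Passing tests therefore
demonstrates that the statistical machinery is correct and calibrated
under the study's declared generative structure — not that the pipeline
is robust to those unmodelled features of real data.

## Problem sizes used in tests and the acceptance script

Simulation sizes are chosen for Monte-Carlo stability at desk scale:
1,000 replicates for type-I-error and HWE calibration; 200 subjects for
phasing-error and block-structure checks (block recovery is a structural
property; at n = 48 single boundary gametes sit near the 5% cutoff);
200 seeded plate replicates per receptor for EC₅₀ recovery; 4,000
permutations for the experiment-wide threshold; 50 paired replicates for
the coupling-vs-repulsion contrast, which uses latent thresholds plus
replicate noise as the phenotype (the full trial-simulation →
psychometric-refit path is exercised separately; using it inside the
paired contrast would only add fitting noise to both arms).

## Known limitations

* The EM phasing carries no coalescent prior; with many rare haplotypes
  in small samples a Bayesian phaser would be more accurate.
* The containment F test assumes genotype constant within subject and a
  single random intercept; it does not handle crossed random effects or
  covariates (the study design has none).
* Peirce rejection is applied to log thresholds marginally per measure;
  correlated measures are not jointly screened.
* The four-gamete partition is order-dependent by construction (greedy
  maximal runs); equal-evidence tie cases can differ from
  confidence-interval-based block definitions.
* Phase-mode labels are defined for common haplotypes only; rare
  haplotypes affect dosage fractions but not the mode call.
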