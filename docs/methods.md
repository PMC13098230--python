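# Methods

## Scope and model

The package implements the analysis chain of a paired FMT intervention
study: each patient contributes a baseline and a post-treatment (~week 4)
stool sample, a fixed donor provides a pool of reference samples, and
patients are labelled responder (R) or non-responder (NR) from clinical
indices. Three data layers are analysed jointly — genus-level relative
abundances (compositional), absolutely quantified metabolite concentrations,
and clinical inflammation markers — and the central quantity is the degree
to which the baseline host–microbe–metabolite correlation structure is
replaced after treatment ("rewiring", measured as edge persistence).

## Synthetic cohort generator

The generator is first-class, tested code: it defines the study conditions
under which every downstream stage is validated.

**Marginals.** Taxon abundances are drawn on a log scale,
x ~ N(μᵢ, noise_sd²), with community means μᵢ spread linearly from +3 to −3
(an abundant-to-rare gradient), and closed to relative abundances by a
softmax *after* all signals are planted. Metabolites are log-normal with
means spread from 3.5 to 0.5 (log concentration in panel units), no closure
— mirroring an absolutely quantified LC-MS/MS panel. Clinical markers (CRP
in mg/dL, fecal calprotectin in µg/g, a composite disease-activity score)
are log-normal with half the feature noise.

**Response features** (`n_response_taxa = n_response_metabolites = 6` of
40 taxa / 30 metabolites). On the log scale, selected features are shifted
by `effect_size × noise_sd` (default 2.0 × 1.0; sign random per feature) in
all patient baselines relative to donors; responders' post samples return to
the donor mean, non-responders' post samples stay at the baseline mean. The
2σ default represents the strong, screenable shifts such studies report;
weaker shifts (≤ 1.5σ) are only partially recoverable at the screen's
α = 0.05 / BH thresholds and can be explored via the config.

**Planted edges.** Designated node pairs (clinical–taxon,
clinical–metabolite, taxon–metabolite; never metabolite–metabolite or
clinical–clinical) share a per-sample latent factor g: each endpoint's
latent value is μ + sd·(s·ℓ·g + √(1−ℓ²)·e) with loading ℓ = `latent_loading`
(default 0.92) and edge sign s ∈ {−1, +1}. This yields a pair correlation of
ℓ² ≈ 0.85 on the latent scale while keeping each marginal's variance
unchanged — essential because an additive latent factor would inflate a
taxon's log-variance, let it dominate the compositional closure denominator,
and leak spurious edges across the whole network. Baseline edges (default
15) are realized only in baseline samples, post edges (default 20) only in
post samples; `planted_persistence_fraction` (default 0.07, the
order of magnitude such studies report) of baseline edges recur in the post
set with identical pair and sign. Within a context every node carries at
most one planted edge, so each association is driven by a single factor.

**Dominance skew** (`dysbiosis_skew`, default 0). When positive, patient
baseline and non-responder post log-abundances are multiplied by
(1 + skew) before closure — a sample-wise sharpening that concentrates mass
on dominant taxa, pushing rare taxa below the counting limit (lower observed
richness, Chao1, ACE) and raising Simpson dominance. It is a whole-community
distortion: with it enabled, *every* taxon differs in distribution between
donors and baselines, so it is kept off in screening-recovery experiments,
whose ground truth is the planted per-feature shifts.

**What the generator does not emulate:** read-level sequencing error and
zero-inflation beyond finite-depth rounding, patient-specific donors'
engraftment dynamics, longitudinal drift, covariate structure (age, diet),
or realistic taxon-taxon ecological interactions. Passing recovery tests
therefore demonstrates correctness of the statistical machinery under the
declared generative model, not performance on real cohorts.

**Clinical trajectories.** `generate_trajectories` draws Mayo subscores (UC)
or CDAI/SES-CD (CD) per patient: responders satisfy the week-4 response
definition and reach week-14 clinical remission (about two-thirds also
endoscopic remission); non-responders violate the response definition, and
their CRP/calprotectin do not decline. Outcome labels are derived by running
the generated scores through the clinical classifiers, never assigned
directly, so labels and scores cannot disagree.

## Clinical outcome rules

Boundary semantics follow the printed inequalities exactly: response
requires a partial-Mayo drop ≥ 2 *and* rectal-bleeding drop ≥ 1 (UC) or a
CDAI drop ≥ 100 (CD, inclusive); remission is partial Mayo < 3 (strict) or
CDAI < 150 (strict); endoscopic remission is Mayo endoscopic ≤ 1 or
SES-CD ≤ 2. The packaged outcome table (`data/reported_outcomes.csv`)
transcribes a published 30-patient table; its CD rows list only the 11
patients retained through follow-up (all responders), which is why CD counts
from the table are surfaced but not treated as a reference quantity.

## Diversity

Computed on counts. When only relative abundances exist (the generator's
native output), a documented pseudo-count rescaling multiplies by a nominal
library size (default 50 000) and rounds; abundances below half a count drop
to zero, emulating finite depth. Estimator choices: Chao1 is the
bias-corrected form; ACE uses the standard rare-class cutoff of 10 and falls
back to Chao1 when the coverage estimate is zero (all rare individuals
singletons); Shannon is in nats; Simpson is reported as dominance D = Σp²
(with 1−D exposed) so that dysbiosis reads as higher D. No rarefaction is
applied.

## Response screen

Criterion (i) uses BH-adjusted q < α on baseline-vs-donor tests; the
adjustment is applied within feature class, since taxa and metabolites form
separate test families. Criterion (ii) — "shift to donor levels" — is
operationalized as non-significance vs donors *plus* a directionality guard
(responder-post mean moved from the baseline mean toward the donor mean,
overshoot allowed): non-significance alone would be satisfied by any
high-variance feature. Criterion (iii) — "persistence of baseline levels" —
is non-significance of NR-post vs baseline (the literal reading); the
stricter alternative (NR-post still significantly different from donors) is
available as `crit3_vs_donor=True`. Cohorts without non-responders make
criterion (iii) vacuously true and the result is flagged. Default tests:
Mann–Whitney for taxa (rank-based, robust to compositionality and zeros),
Welch t-test on log values for metabolites. α = 0.05 throughout.

Criteria (ii) and (iii) are *acceptance-of-null* criteria at α = 0.05, so
even a perfectly restored feature fails each with ~5% probability; together
with BH power this caps attainable sensitivity around 0.9 under the default
conditions.

## Networks and persistence

Spearman ρ is the Pearson correlation of mid-ranks (tie-aware); two-sided p
uses the t approximation with n−2 df, or exact permutation enumeration for
n ≤ 7. Taxon features are prevalence-filtered (≥ 60% nonzero, inclusive)
before testing; all cross- and within-class pairs are tested except
clinical–clinical (clinical indices are mutually dependent by construction;
a switch re-enables them). Edges require |ρ| > 0.6 (strict) and p < 0.05;
edge p-values are deliberately not multiplicity-adjusted — the threshold
pair is a per-edge inclusion rule, not a family-wise claim — with a BH
option available. Constant features are skipped and recorded.

Edge persistence = |baseline edges recurring in post| / |baseline edges|,
computed after symmetrically excluding metabolite–metabolite pairs from
both networks; matching is on the unordered node pair and, by default, the
correlation sign. An empty eligible baseline edge set leaves the fraction
undefined (NaN, flagged). Baseline networks pool all patients' baseline
samples and post networks pool all post samples by default (a
responders-only switch exists), since pooling is the only option that keeps
both networks at equal n.

At n = 30 samples the |ρ| > 0.6, p < 0.05 rule admits a few marginal chance
edges per network (|ρ| barely above 0.6); these inflate both edge counts
slightly and bias the recovered persistence a little below the planted value
because chance edges rarely recur. Recovery experiments therefore compare
the recovered fraction to the planted one within ±0.15.

## Multivariate

PCA: SVD of centered (optionally unit-variance scaled) data; loadings
orthonormal; component signs fixed so the largest-magnitude loading is
positive; zero-variance features are dropped under scaling and reported.
PLS-DA: NIPALS PLS of the 0/1-coded class (centered) on centered/UV-scaled
features (Pareto scaling available); VIPⱼ = √(p·Σₖ w²ⱼₖ·SSYₖ/ΣSSY), which
satisfies mean(VIP²) = 1 exactly; VIP > 0.9 (strict) flags discriminative
features. Q²Y = 1 − PRESS/TSS from stratified 7-fold cross-validation with a
seeded partition; fold counts shrink automatically for small classes.
Multi-class PLS-DA is out of scope.

## Problem sizes and determinism

Recovery experiments use cohorts of 30 patients (networks; 30 baseline + 30
post samples) or 20 patients with 10 donors (screening; 10 per responder
stratum), averaged over 20 seeds (50 for the global-null FDR check) — sizes
at which the statistical properties stabilize while a full run stays in the
tens of seconds. All randomness flows from a single integer seed through
`numpy.random.default_rng`/`SeedSequence`; identical config and seed
reproduce byte-identical tables, networks and reports.

## Known limitations

- The screen compares responders' post samples to the pooled donor group,
  not each patient to their own donor (a per-donor pairing hook exists in
  the metadata but is not the default analysis path).
- Compositional effects are handled by rank statistics and prevalence
  filtering, not by log-ratio transforms; strongly coupled communities could
  still induce spurious negative taxon-taxon edges.
- Edge persistence is a binary pair-recurrence measure; it does not test
  whether correlation *strengths* changed.
- The dominance-skew dysbiosis model changes the whole composition at once
  and is unsuitable as ground truth for per-feature differential-abundance
  claims.
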