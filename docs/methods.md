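# Methods

## The analysis

`nemafauna` analyzes soil nematode community succession around localized
enrichment hotspots — the canonical case being the soil beneath a
decomposing vertebrate carcass, sampled repeatedly over roughly a year at
two depths: 0–30 cm composite cores and the 0–1 cm *interface* layer in
direct contact with the remains. Communities are tables of taxon densities
(nematodes per 100 cm³ soil) at mixed taxonomic rank (genus, family, or
order), with each taxon annotated by trophic group (bacterivore,
fungivore, herbivore, omnivore, predator) and colonizer–persister (cp)
class 1–5, the r-to-K life-history scale. Trophic initial + cp class gives
the functional guild (B1, F2, P2, …); cp-1 is an exclusively
bacterial-feeding designation, enforced at the type level.

The pipeline computes, per stratum and treatment arm:

1. **Alpha diversity** — total abundance, richness (count of taxa with
   positive abundance at their recorded ranks; no rank collapsing, no
   rarefaction — densities are not read counts), and Shannon
   H′ = −Σ pᵢ ln pᵢ (natural log by default, base configurable).
2. **Composition and faunal profile** — relative abundance by trophic
   group and cp class (descriptive; herbivores included), and the weighted
   enrichment/basal/structure components

       e = 3.2·N(B1) + 0.8·N(F2)
       b = 0.8·(N(B2) + N(F2))
       s = 1.8·N(cp3) + 3.2·N(cp4) + 5.0·N(cp5) + 0.8·N(P2)

   over non-herbivore guilds, giving the Enrichment Index
   EI = 100·e/(e+b) and Structure Index SI = 100·s/(s+b). Weights follow
   the standard faunal-analysis scheme (cp-1 = 3.2, cp-2 = 0.8,
   cp-3 = 1.8, cp-4 = 3.2, cp-5 = 5.0; F2 in both e and b; P2 in s) and
   are override-able. Conventions for degenerate communities: EI is
   undefined (NaN) when e + b = 0; SI = 0 whenever s = 0, including
   s = b = 0, so a pure cp-1 bacterivore bloom sits at the enriched corner
   (EI, SI) = (100, 0) rather than an indeterminate point. Trajectories
   are computed on per-day group means (matching how such figures are
   drawn), with per-sample profiles available for dispersion.
3. **Indicator screening** — per taxon, per day, against the paired
   control mean at the same day (default; a pooled-control mode exists
   because "the mean abundance in the control soils" is ambiguous for
   unpaired data): *enrichment* requires impacted mean ≥ 5 and
   impacted > control × scale; *suppression* requires control mean ≥ 5 and
   impacted < control / scale; scale is 10 for B1 opportunists and 2 for
   everything else. Both clauses bind at the same sampling day. Days
   without a control mean (interface days before interface controls
   existed) are unevaluable, not zero-control — treating them as zero
   would manufacture spurious enrichment. Flagged taxa fall into four
   categories: `b1_enrichment` (any enrichment flag on a B1 taxon),
   `suppression_then_enrichment` (suppression before the first
   late-skeletonization day, 153 by default, followed by enrichment after
   the earliest suppressed day), `suppression_only`, `non_b1_enrichment`,
   else `none`. The screening is deterministic thresholding by design; no
   p-values are attached.
4. **Statistics** — two-way fixed-effects ANOVA (treatment × day, day
   categorical, Type II SS via statsmodels; types coincide on the balanced
   6+6 design, and Type II is the predictable choice if user data are
   unbalanced), per-day paired t-tests (pairing by site), and RDA on
   Euclidean distances: column-centered community matrix projected on the
   group-membership design, canonical axes from the SVD of the fitted
   values, reporting weighted-average and linear-combination site scores,
   stage centroids, and per-group axis SDs (ellipse radii). No chord or
   Hellinger pre-transformation by default (Euclidean means raw centered
   abundances); a transform hook exists. Per-day t-tests are reported
   uncorrected, matching standard practice for this design; a Holm option
   exists but defaults off. Axis signs are fixed (first nonzero loading
   positive) for reproducible outputs.

## The synthetic study

`simulate.generate_succession` draws a full study: 6 impacted sites with
paired controls, the 12-day stage calendar (placement day 0 through late
skeletonization day 317), cores throughout, interface impacted samples
from day 15 and interface controls from day 40. Each taxon follows an
archetype with a piecewise-constant per-day response multiplier on the
impacted arm (controls are always ×1) — piecewise-constant because the
analysis only ever observes sampling days, so continuous kinetics would
add parameters without adding testable structure. Interface samples
amplify the *multiplier* (×10 enrichment side, ÷10 suppression side), not
the baseline: the hotspot exaggerates responses, not resident densities.

The default 20-taxon community plants: two B1 bloom opportunists (one
broad, folds ramping 12→100→25 over days 15–110 and peaking at day 40;
one narrow early bloom), cp-2 suppression-then-enrichment generalists
(B2/F2, suppressed ÷4 through decay with a ÷16 trough at day 40, enriched
×4 from day 153), one high-baseline suppression-only fungivore (the
dominant resident, baseline 60 per 100 cm³), late-enriching K-selected
taxa (an omnivore order and predators, some with a decay-phase dip below
the detection-floor), and neutral taxa at baselines either ≤ 3 or ≥ 12.
That split is deliberate: a neutral baseline near the screening floor of 5
turns the control-floor clause into a coin flip across 6 replicate sites,
so flag specificity would measure the rule's knife edge rather than the
community. Counts are gamma-Poisson with Var = μ + 0.05 μ² — overdispersed
relative to Poisson because replicate carcass sites vary far more than
sampling error; 0.05 was set by a z-margin analysis (planted effects ≥
~2.5 SE inside their thresholds at n = 6, neutral taxa ≥ ~2.5 SE outside)
so that recovery is reliable without being trivial. The full study design
(20 taxa × 240 samples) simulates in well under a second, so no scaling down is
needed anywhere in the tests.

Ground truth (expected flag windows and category per taxon per stratum) is
derived analytically from the noise-free expectations using the published
screening constants restated inside the generator — the generator never
imports the screening configuration, so recovery tests compare two
independent routes to the same answer.

What the simulator does *not* emulate: spatial structure and between-site
covariance (sites are independent), taxon–taxon interactions (responses
are marginal multipliers), detection/extraction efficiency, and
within-stage kinetics. Passing recovery tests therefore shows the
screening and indices behave correctly under the designed signal and
realistic replicate noise; it does not validate the ecological model
itself against field data.

## Numerical choices and degenerate inputs

- EI/SI are clamped to [0, 100] to absorb last-ulp float roundoff.
- All-zero samples: richness 0, H′ = 0, flagged degenerate; empty
  communities give undefined (NaN) composition fractions.
- ANOVA: zero residual SS → `perfect_fit` flag with p → 0 for terms with
  positive SS; constant response → `degenerate` flag with F = 0. Empty
  cells raise with a pointer toward an additive model.
- Paired t with zero-variance differences: p = 0 if the mean difference is
  nonzero (every pair moved identically), else p = 1; n = 1 is an error.
- RDA keeps at most min(groups − 1, taxa) axes with singular values above
  1e-10 of the largest; a single group yields constrained proportion 0 and
  no axes.
- Missing design cells are absent samples, never zero-abundance samples,
  at every layer (reader, group means, screening, validation report).
- Stage lookup is exact-day by default; `interval` mode (latest calendar
  day ≤ query) exists for joining sensor streams recorded between
  sampling days.

## Limitations

- Channel Index, Maturity Index, and metabolic footprints are out of
  scope, as are PERMANOVA/db-RDA and IndVal-style permutation indicator
  statistics.
- Whether richness should apply a detection floor above zero is unknowable
  from density tables; abundance > 0 is the implemented convention.
- The O3 guild weight is the uniform cp-3 weight 1.8; published weighting
  schemes do not print a separate value for it.
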