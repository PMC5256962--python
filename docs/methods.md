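# Methods

## Model

Each protein *l* is analyzed independently within a fraction (pellet or
supernatant). The response is the quantile-normalized log10 Protein
Abundance Index across a balanced layout of 2 substrates × 2 incubation
times × r replicates (r = 3 by default):

y\*ᵢⱼₖₗ = μₗ + αₗSᵢ + βₗTⱼ + γₗ(S·T)ᵢⱼ + εᵢⱼₖₗ,  ε ~ N(0, σₗ²)

with treatment coding: the reference substrate and time get S = 0 and
T = 0, so α > 0 means higher levels on the non-reference substrate and
γ > 0 means levels that increase faster (or decrease slower) there. All
effects are log10 fold changes.

### Censoring

Non-detects are encoded as exact 0 in the linear-scale matrix. The
censoring threshold of protein *l* is cₗ = min of its positive response
values. Following the replacement rule, a zero in a (substrate, time)
cell that has at least one detected replicate is replaced by cₗ and
flagged `censored-replaced`; a cell whose replicates are all zero keeps
the value 0 and is flagged `all-zero-cell`. In the likelihood both
kinds are treated as left-censored at cₗ: a literal 0 on this scale
would be a fabricated low measurement (detected normalized values sit
around 5–9 log10 units), and a censored likelihood is the only coherent
treatment of a non-detect. The distinction between the two flags is
kept because it separates the quantitative regime from the
presence/absence regime (below).

### Fitting

A data-augmentation Gibbs sampler: latent values for censored
observations are drawn from N(xᵢᵝ, σ²) truncated above at cₗ (exact
rejection sampling — plain rejection near the bulk, Robert's
exponential envelope in the tail); coefficients are drawn from their
conditional multivariate normal under an improper flat prior; σ² from
its conditional inverse-gamma with an IG(a = 0.001, b = 0.001) prior.
Defaults: 11,000 iterations, 1,000 burn-in, no thinning, per-protein
seed derived deterministically from the master seed and protein index
(so results are independent of fitting order). The inner loop is
compiled with numba; a protein costs ~15 ms, which keeps a
500-protein × 10-seed experiment within minutes on one CPU.

Point estimates are posterior means. The two-sided p-value per
coefficient uses the add-one tail estimator
p = min(1, 2·min(1+#{draws ≤ 0}, 1+#{draws ≥ 0})/(N+1)),
which cannot be exactly zero; with 10,000 kept draws the floor is
≈ 2·10⁻⁴. Under a flat prior and no censoring the posterior of each
coefficient is the scaled-t sampling distribution of the least-squares
estimate, so these posterior p-values are calibrated; the test suite
verifies near-uniformity of null p-values under ~20% censoring as well.

### Convergence screening

Every fitted protein is screened with the Heidelberger–Welch diagnostic
on the α, β, γ and σ² chains; failure on any chain discards the protein
from inference (recorded in a discard log). The diagnostic:

1. *Stationarity* — Cramér–von Mises statistic on the standardized
   cumulative sums, normalized by the spectral density at frequency
   zero; S(0) is estimated by a Yule–Walker autoregressive fit with the
   order chosen by AIC (Levinson–Durbin recursion), evaluated as
   σ²ₚ/(1−Σφ)². If the test rejects at level α = 0.05, the first 10% of
   iterations is discarded and the test repeated, up to 50%. S(0) is
   re-estimated from the second half of each retained window; estimating
   it once from the full chain lets strongly trending chains pass at the
   later windows, because the near-unit-root AR fit inflates S(0) enough
   to mask the trend.
2. *Halfwidth* — 1.96·√(S(0)/n)/|mean| ≤ eps with eps = 0.1 on the
   retained window. A zero-variance chain passes both parts vacuously.

Two consequences are worth knowing. First, the halfwidth test rejects
any chain whose posterior mean is near zero (the relative precision is
unattainable), so null proteins are discarded at a substantial rate;
this costs power but cannot create false positives, and the empirical
FDR checks run on the screened pipeline exactly as used. Second, the
diagnostic is a local check: a chain that drifts into a flat region of
the posterior and mixes there can pass.

### The presence/absence regime

When an entire design cell is non-detect, the likelihood for that
cell's mean flattens as it decreases below cₗ, and with a flat prior
the posterior is improper in one coefficient direction: the chain
drifts toward large magnitudes. This is not a sampler defect — it is
how "present on one substrate, absent on the other" contrasts manifest
in a censored model, and it is the regime that produces the very large
log10 fold changes (|Δ| ≈ 3–8) such studies report. The generator
produces these effects via detection-limit crossings and records them
as qualitative; the fit table exposes `n_all_zero` so downstream
analyses can separate the regimes. Quantitative parameter-recovery
claims (bias, RMSE) are made only for proteins with no all-zero cell.

## Preprocessing

log10 transform of detected values (values in (0, 1] are rejected:
they would collide with the non-detect sentinel 0; realistic XIC areas
are ≫ 1). Quantile normalization maps each sample's detected values
onto the mean-of-order-statistics reference of its fraction group,
evaluating the reference by linear interpolation at each sample's
quantile positions when detected counts differ; ties receive the
average of their mapped values; non-detects are untouched and excluded
from the reference (they are modelled as censored, not as observed
minima). Known limitation: when a large share of proteins carries real
substrate effects, the detected-set composition differs between
substrate groups and quantile normalization transfers part of that
composition shift into every protein (≈0.1 log10 units in an
all-non-null stress test). At the study-like 90%-null composition the
distortion is negligible. For this reason the parameter-recovery
experiments (which need all proteins non-null) feed log10 responses to
the model directly.

## Identification and quantification

Target/decoy FDR is estimated as #decoys/#targets above a score cutoff,
capped at 1. Validation picks the largest (lowest-cutoff) score set
whose estimate stays at or below the threshold, first over peptides
(best PSM score per peptide, default 5%), then over proteins (best
retained-peptide score, decoy proteins as the null population, default
1%). Retention-time alignment fits a monotone piecewise-linear map
through shared-peptide anchors (median RT per sequence per sample;
isotonic regression enforces monotonicity; terminal segments
extrapolate linearly). Identification transfer requires a unique
candidate within both the m/z (ppm) and RT tolerances; ambiguous peaks
stay unidentified. The PAI of a protein in a sample is the mean of its
three largest per-peptide areas (mean of 1–2 if fewer; 0 if none);
per-peptide area is the maximum over that peptide's features, and only
single-protein peptides are quantified to avoid double counting.

## Inference and reporting

BH step-up adjustment is applied per coefficient family — substrate
(α) and interaction (γ) — within each fraction, across proteins,
matching per-effect reporting; time main effects are fitted but not
FDR-reported unless requested. Significance is q ≤ 0.01, inclusive. A
protein is significant if either reported coefficient passes.
Significant proteins are classified pellet-only / supernatant-only /
both. Supernatant calls pass a lysis filter: retained if the
localization class is cellulosome, secreted or cell wall, or the
cellulosomal flag is set, or the protein is a CAZyme with an
extracytoplasmic localization; unannotated proteins are conservatively
flagged lysis-derived. GO profile ratios compare the percentage of each
term among the GO annotations of significant proteins with the
percentage among all annotations; terms can be dropped when fewer than
3 significant proteins carry them.

## Synthetic data

The generator emulates the study's statistical structure: a balanced
2 × 2 × 3 design in two fractions; ~1000 proteins; baselines
μ ~ U(5, 9) log10 units (so detected normalized values are far from
the 0 sentinel); residual σ = 0.15; 90% of proteins null; non-null
substrate effects N(0, 0.3²) (time and interaction effect scales are
configurable, default 0); a per-protein detection limit at the 0.2
quantile of the protein's own latent values (~20% non-detects, rate
monotone in the quantile); and a rare (1%) presence/absence class whose
detection limit is placed between the substrate group means. Peptide
tables are built from a fixed per-protein peptide panel with
log-normal relative intensities scaled so the top-3 mean reproduces the
matrix value exactly at zero dispersion, with retention times drawn
from a per-sample monotone warp of a common latent RT. PSM lists are a
mixture of correct matches and null-distribution matches with known
labels. What the generator does not emulate: correlated peptide
interference, retention-time-dependent intensity bias, shared peptides,
charge-state splitting, or any spectrum-level structure — so passing
tests certify the statistical pipeline, not raw-data processing.

Within-protein peptide-intensity dispersion is not constrained by the
study design; the defaults (log10 relative-intensity sd 0.5,
multiplicative dispersion 0.25) are free parameters chosen to look like
typical XIC data.

## Problem sizes

The shipped experiments use desk-scale sizes chosen as reasonable
operating points: FDR control averages 10 seeds × 500 proteins;
parameter recovery uses 200 proteins at 3 and 6 replicates; the
Tobit/least-squares agreement check uses 50 proteins; the
Heidelberger–Welch calibration uses 200 chains of length 5000; the
demonstration pipeline fixture has 60 proteins with a 3000-iteration
chain. The per-protein sampler always runs the full 11,000-iteration
default unless a config says otherwise.

## Numerical notes and edge cases

- All observations zero → protein unfittable, listed in the discard log
  as "no detections"; every observation censored → flagged unconverged.
- Design matrices are validated for balance and full rank; exactly two
  substrate and two time levels are required.
- Ties in quantile normalization are averaged, making the mapping
  order-invariant; a sample with no detected values is left untouched
  with a warning.
- The decoy FDR estimate is undefined with no targets above the cutoff
  (raised as an error); D/T is capped at 1.
- Degradation-yield reconstructions below zero are clipped to zero with
  a warning (mass-balance inconsistency). Degree of polymerization is
  returned both raw and rounded to the nearest 10 (reporting style).
- Genome-copy constants default to 650 g/mol/bp, Avogadro 6.022·10²³
  and a 4,068,724 bp genome; these reproduce the reference value of
  227,703 copies/ng and are overridable — the exact constants behind
  that published value are not printed anywhere, so the defaults are
  reverse-engineered and documented as such.
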