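# lfqtobit

Label-free quantitative proteomics inference for two-condition,
two-time-point fermentation studies, built around a per-protein
left-censored (Tobit) regression fitted by Gibbs sampling.

The package targets shotgun-proteomics comparisons of a cellulolytic
bacterium grown on two cellulosic substrates, sampled at two incubation
times in pellet and supernatant fractions, but the machinery is generic:
any balanced 2 × 2 × r layout with intensity-based quantification and
zeros encoding non-detects fits the model.

## What it computes

1. **Quantification** — peptide-spectrum matches are validated against a
   target/decoy score list (peptide FDR 5%, protein FDR 1%, best-peptide
   protein scores); identified peptides shared between samples anchor a
   monotone piecewise-linear retention-time alignment; identifications
   are transferred to unidentified peaks within m/z and RT tolerances;
   each protein's abundance in a sample is the Protein Abundance Index
   (PAI), the mean XIC area of its three most intense peptides.
2. **Preprocessing** — log10 transform and quantile normalization of the
   detected values, separately per fraction; non-detects stay exact 0
   behind a detect mask.
3. **Censored model** — for protein *l* with normalized log10 abundance
   *y\*ᵢⱼₖₗ* under substrate *Sᵢ*, time *Tⱼ*, replicate *k*:

   *y\*ᵢⱼₖₗ = μₗ + αₗSᵢ + βₗTⱼ + γₗ(S·T)ᵢⱼ + εᵢⱼₖₗ*, ε ~ N(0, σₗ²)

   Zeros are left-censored at the protein's censoring threshold *cₗ*
   (its minimum positive value). The model is fitted by a
   data-augmentation Gibbs sampler (flat prior on coefficients,
   IG(0.001, 0.001) on σ²; 11,000 iterations, 1,000 burn-in). Chains
   failing the Heidelberger–Welch convergence diagnostic are discarded.
4. **Inference** — two-sided posterior tail p-values per coefficient,
   Benjamini–Hochberg adjustment per coefficient family (substrate;
   interaction) within each fraction, significance at q ≤ 0.01, a
   pellet/supernatant/both classification of significant proteins, and a
   lysis filter that keeps only plausibly extracellular proteins among
   supernatant calls.
5. **Materials module** — the closed-form substrate/fermentation
   quantities used around the proteomics workflow: X-ray crystallinity
   index (100·Σ|U−A|/Σ|C−A|), cellulose degree of polymerization
   (peak molar mass / 519 Da), genome copies per ng DNA, metabolite
   concentration ratios, and the carbon-balance degradation yield.
6. **Synthetic data** — a generator for designs, abundance matrices,
   peptide tables and PSM score lists with known ground truth, used by
   the test suite to check FDR control, parameter recovery and
   calibration end to end.

## Worked example

```python
import lfqtobit as L
from lfqtobit.config import SimConfig
from lfqtobit.tobit import fit_all_proteins
from lfqtobit.report import add_q_values, call_significant

cfg = SimConfig(n_proteins=100, seed=42, fractions=("pellet",),
                effect_null_fraction=0.8, alpha_sd=0.5)
design = L.simulate_design(cfg)                    # 12 samples, 2x2x3
matrix, truth = L.simulate_abundance(design, cfg)  # PAI matrix + ground truth
normalized = L.quantile_normalize(L.log10_transform(matrix))
fits, discards = fit_all_proteins(normalized, design, "pellet", master_seed=42)
effects = call_significant(add_q_values(fits), q_threshold=0.01)
print(fits["protein_id"].nunique(), len(discards))
```

prints `48 52`: 48 proteins pass the convergence screen, 52 are
discarded (mostly via the halfwidth test, which rejects chains whose
posterior mean is indistinguishable from zero at the requested relative
precision). The strongest substrate effect in this run is

```
protein_id  estimate  p_value  q_value
    P00035 -1.126860 0.000400 0.019198
```

an estimated log10 fold change of −1.13 (13-fold lower on the second
substrate) whose q-value of 0.019 still misses the 1% FDR bar — with
only ~50 tested proteins and a finite-chain p-value floor of
2/(N+1) ≈ 2·10⁻⁴, the Benjamini–Hochberg step-up at 1% is deliberately
conservative.

The materials helpers are one-liners:

```python
>>> round(L.genome_copies(1.0))          # copies per ng of DNA
227703
>>> L.degree_of_polymerization(503430.0) # (rounded to nearest 10, raw)
(970, 970.0)
```

A command-line interface mirrors the library
(`lfqtobit simulate|quantify|normalize|fit|report|materials|run`); a
full configuration-driven run is

```sh
lfqtobit run --config configs/smoke.yaml --outdir smoke_out
```

which writes every intermediate table, a discard log and a manifest
recording seed and parameters (reruns are bit-identical).

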