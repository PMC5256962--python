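"""Configuration objects for simulation and pipeline runs.

Both configs are plain dataclasses that can be round-tripped through a
single YAML file (see :func:`load_pipeline_config`).  Every tunable of the
pipeline lives here so that a run is fully determined by one config plus a
master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml


@dataclass
class SimConfig:
    """Parameters of the synthetic label-free quantification experiment.

    The default layout mirrors a 2 substrates x 2 time points x 3 replicates
    x 2 fractions batch-fermentation study with ~1000 quantified proteins.
    Effects are expressed in log10 units; baselines are log10 XIC areas
    (large, so every detected normalized value stays well above zero).

    Parameters
    ----------
    n_proteins
        Number of simulated proteins.
    substrates, times
        Level labels; the first entry of each is the reference level of the
        design coding (substrate effect > 0 means higher level on the
        non-reference substrate).
    n_replicates
        Biological replicates per substrate x time cell.
    fractions
        Sample fraction labels (e.g. pellet / supernatant).
    effect_null_fraction
        Proportion of proteins with all effect coefficients equal to zero.
    alpha_sd, beta_sd, gamma_sd
        Standard deviations (log10 units) of the substrate, time and
        interaction effects drawn for non-null proteins.  A value of 0
        pins the corresponding coefficient at zero.
    noise_sd
        Residual standard deviation sigma (log10 units).
    baseline_low, baseline_high
        Range of the uniform baseline mu (log10 units).
    detection_quantile
        Per-protein non-detect rule: values whose log10 abundance falls
        below this empirical quantile of the protein's own latent values
        are reported as 0.  Set to 0 to disable.
    detection_limit
        Absolute detection limit (log10 units) applied to every protein;
        overrides ``detection_quantile`` when not None.
    qualitative_fraction
        Proportion of proteins whose substrate effect is expressed as a
        presence/absence pattern: the detection limit is placed between
        the two substrate group means so one group is entirely non-detect.
    peptides_per_protein
        Mean of the (shifted Poisson) peptide count per protein.
    peptide_dispersion
        Log10-scale multiplicative dispersion of per-sample peptide areas.
    rt_warp_magnitude
        Size of the per-sample monotone retention-time distortion; 0 gives
        the identity warp.
    n_correct_psms, n_incorrect_psms, n_decoy_psms
        Sizes of the simulated PSM score populations.
    correct_score_mean, null_score_mean, score_sd
        Normal score-distribution parameters for correct matches and for
        the null (incorrect target / decoy) population.
    seed
        Master seed for all simulate_* operations.
    """

    n_proteins: int = 1000
    substrates: Sequence[str] = ("Whatman", "Tissue")
    times: Sequence[str] = ("46h", "70h")
    n_replicates: int = 3
    fractions: Sequence[str] = ("pellet", "supernatant")
    effect_null_fraction: float = 0.9
    alpha_sd: float = 0.3
    beta_sd: float = 0.0
    gamma_sd: float = 0.0
    noise_sd: float = 0.15
    baseline_low: float = 5.0
    baseline_high: float = 9.0
    detection_quantile: float = 0.2
    detection_limit: float | None = None
    qualitative_fraction: float = 0.01
    peptides_per_protein: float = 4.0
    peptide_dispersion: float = 0.25
    rt_warp_magnitude: float = 0.05
    n_correct_psms: int = 800
    n_incorrect_psms: int = 200
    n_decoy_psms: int = 200
    correct_score_mean: float = 30.0
    null_score_mean: float = 15.0
    score_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if len(self.substrates) < 1 or len(self.times) < 1 or len(self.fractions) < 1:
            raise ValueError("substrates, times and fractions need >= 1 level each")
        for name in ("effect_null_fraction", "detection_quantile", "qualitative_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.baseline_high < self.baseline_low:
            raise ValueError("baseline range inverted")


@dataclass
class MCMCConfig:
    """Gibbs sampler settings for the censored regression."""

    iterations: int = 11_000
    burnin: int = 1_000
    prior_a: float = 0.001
    prior_b: float = 0.001

    def __post_init__(self) -> None:
        if not 0 <= self.burnin < self.iterations:
            raise ValueError("need 0 <= burnin < iterations")


@dataclass
class HWConfig:
    """Heidelberger-Welch screening settings."""

    alpha: float = 0.05
    eps: float = 0.1


@dataclass
class PipelineConfig:
    """Everything needed to run the full pipeline reproducibly."""

    outdir: str = "lfqtobit_out"
    seed: int = 1
    sim: SimConfig = field(default_factory=SimConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    hw: HWConfig = field(default_factory=HWConfig)
    q_threshold: float = 0.01
    peptide_level: bool = False
    # optional external inputs; when set, the corresponding simulation
    # stage is skipped and the tables are read from disk instead
    design_path: str | None = None
    abundance_path: str | None = None
    annotation_path: str | None = None
    peptide_fdr: float = 0.05
    protein_fdr: float = 0.01
    rt_tol: float = 1.0
    mz_tol_ppm: float = 10.0
    include_time_effects: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a :class:`PipelineConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = SimConfig(**raw.pop("sim", {}))
    mcmc = MCMCConfig(**raw.pop("mcmc", {}))
    hw = HWConfig(**raw.pop("hw", {}))
    return PipelineConfig(sim=sim, mcmc=mcmc, hw=hw, **raw)


def save_pipeline_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
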