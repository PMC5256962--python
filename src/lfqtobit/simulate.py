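"""Synthetic label-free quantification data with known ground truth.

The generator emulates the statistical structure of a two-substrate,
two-time-point batch fermentation proteomics study: a balanced
2 x 2 x 3 design measured in two fractions, ~1000 quantified proteins,
log10-scale substrate/time/interaction effects, and non-detects encoded
as literal zeros in the linear-scale abundance matrix.  Rare large
"presence/absence" contrasts are produced by detection-limit crossings
rather than by literal coefficients, matching how such fold changes
arise under left-censoring.

Every operation is deterministic given ``config.seed``.
"""

from __future__ import annotations

import itertools
import string

import numpy as np
import pandas as pd

from .config import SimConfig
from .containers import DESIGN_COLUMNS, FEATURE_COLUMNS, AbundanceMatrix, GroundTruth

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

__all__ = [
    "simulate_design",
    "simulate_abundance",
    "simulate_peptides",
    "simulate_psms",
]


def simulate_design(config: SimConfig) -> pd.DataFrame:
    """Build the balanced experimental-design table.

    One row per (substrate, time, replicate, fraction) with a unique
    sample identifier.  Purely combinatorial, hence the same for any seed.
    """
    rows = []
    for sub, time, rep, frac in itertools.product(
        config.substrates, config.times, range(1, config.n_replicates + 1), config.fractions
    ):
        rows.append(
            {
                "sample_id": f"{sub}_{time}_r{rep}_{frac}",
                "substrate": sub,
                "time": time,
                "replicate": rep,
                "fraction": frac,
            }
        )
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def _design_indicators(design: pd.DataFrame, config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """0/1 substrate and time indicators (first config level = reference)."""
    if len(config.substrates) != 2 or len(config.times) != 2:
        raise ValueError("the generative model needs exactly 2 substrates and 2 times")
    s = (design["substrate"] == config.substrates[1]).to_numpy(dtype=float)
    t = (design["time"] == config.times[1]).to_numpy(dtype=float)
    return s, t


def simulate_abundance(
    design: pd.DataFrame, config: SimConfig
) -> tuple[AbundanceMatrix, GroundTruth]:
    """Draw a linear-scale abundance matrix from the censored linear model.

    Latent log10 abundance of protein ``l`` in sample ``(i, j, k)`` is
    ``mu_l + alpha_l*S_i + beta_l*T_j + gamma_l*S_i*T_j + eps`` with
    ``eps ~ N(0, sigma^2)``; the linear-scale value is ``10**latent``
    unless the latent value falls below the protein's detection limit,
    in which case the entry is reported as 0 (non-detect).
    """
    if config.noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng([config.seed, 1])
    s_ind, t_ind = _design_indicators(design, config)
    n_samples = len(design)
    n = config.n_proteins

    mu = rng.uniform(config.baseline_low, config.baseline_high, size=n)
    is_null = rng.random(n) < config.effect_null_fraction
    n_qual = int(round(config.qualitative_fraction * n))
    qualitative = np.zeros(n, dtype=bool)
    non_null_idx = np.flatnonzero(~is_null)
    if n_qual > 0 and len(non_null_idx) > 0:
        qual_idx = rng.choice(non_null_idx, size=min(n_qual, len(non_null_idx)), replace=False)
        qualitative[qual_idx] = True

    def draw_effect(sd: float) -> np.ndarray:
        eff = np.zeros(n)
        if sd > 0:
            eff[~is_null] = rng.normal(0.0, sd, size=(~is_null).sum())
        return eff

    alpha = draw_effect(config.alpha_sd)
    beta = draw_effect(config.beta_sd)
    gamma = draw_effect(config.gamma_sd)
    # presence/absence proteins: a moderate substrate shift whose lower
    # group is pushed entirely below the detection limit
    alpha[qualitative] = rng.choice([-1.0, 1.0], size=qualitative.sum()) * rng.uniform(
        0.4, 0.8, size=qualitative.sum()
    )

    eps = rng.normal(0.0, config.noise_sd, size=(n, n_samples))
    latent = (
        mu[:, None]
        + alpha[:, None] * s_ind[None, :]
        + beta[:, None] * t_ind[None, :]
        + gamma[:, None] * s_ind[None, :] * t_ind[None, :]
        + eps
    )

    if config.detection_limit is not None:
        limit = np.full(n, float(config.detection_limit))
    elif config.detection_quantile > 0:
        limit = np.quantile(latent, config.detection_quantile, axis=1)
    else:
        limit = np.full(n, -np.inf)
    # qualitative proteins: limit at the midpoint of the substrate group means
    limit[qualitative] = np.maximum(
        limit[qualitative], mu[qualitative] + alpha[qualitative] / 2.0
    )

    detected = latent >= limit[:, None]
    values = np.where(detected, np.power(10.0, latent), 0.0)

    protein_ids = [f"P{i:05d}" for i in range(n)]
    matrix = AbundanceMatrix(
        values=pd.DataFrame(values, index=protein_ids, columns=design["sample_id"].tolist()),
        sample_fractions=pd.Series(
            design["fraction"].to_numpy(), index=design["sample_id"].to_numpy()
        ),
    )
    truth = GroundTruth(
        pd.DataFrame(
            {
                "protein_id": protein_ids,
                "mu": mu,
                "alpha": alpha,
                "beta": beta,
                "gamma": gamma,
                "sigma": config.noise_sd,
                "detection_limit": limit,
                "alpha_null": (alpha == 0) & ~qualitative,
                "beta_null": beta == 0,
                "gamma_null": gamma == 0,
                "qualitative": qualitative,
            }
        )
    )
    return matrix, truth


def _peptide_sequences(rng: np.random.Generator, count: int) -> list[str]:
    seqs: set[str] = set()
    out = []
    while len(out) < count:
        length = int(rng.integers(8, 16))
        seq = "".join(rng.choice(_AA, size=length))
        if seq not in seqs:
            seqs.add(seq)
            out.append(seq)
    return out


def simulate_peptides(
    abundance: AbundanceMatrix, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand an abundance matrix into per-sample peptide feature rows.

    Each protein carries a fixed panel of peptides with a per-peptide
    relative-intensity profile; in every sample where the protein is
    detected, areas are scaled so the mean of the top ``min(3, n)``
    peptides recovers the matrix value, then multiplied by a log10-scale
    dispersion term.  Retention times are a per-sample monotone warp of a
    common latent RT.

    Returns
    -------
    features, peptide_truth
        ``features`` follows the standard feature schema; ``peptide_truth``
        records the per-peptide latent retention time and m/z.
    """
    rng = np.random.default_rng([config.seed, 2])
    proteins = abundance.values.index.to_list()
    samples = abundance.values.columns.to_list()

    n_pep = 1 + rng.poisson(max(config.peptides_per_protein - 1.0, 0.0), size=len(proteins))
    total = int(n_pep.sum())
    seqs = _peptide_sequences(rng, total)
    meta_rows = []
    pos = 0
    rel_intensity = []
    for pid, k in zip(proteins, n_pep):
        rel = np.power(10.0, rng.normal(0.0, 0.5, size=k))
        rel_intensity.append(rel)
        for j in range(k):
            meta_rows.append(
                {
                    "peptide": seqs[pos + j],
                    "protein_id": pid,
                    "mz": float(rng.uniform(300.0, 1500.0)),
                    "latent_rt": float(rng.uniform(5.0, 120.0)),
                }
            )
        pos += k
    peptide_truth = pd.DataFrame(meta_rows, columns=["peptide", "protein_id", "mz", "latent_rt"])

    w = config.rt_warp_magnitude
    rt_max = 125.0
    warps = {}
    for s in samples:
        shift = w * rng.normal(0.0, 5.0)
        scale = 1.0 + w * rng.uniform(-0.3, 0.3)
        curve = w * rng.uniform(0.0, 0.5)
        warps[s] = (shift, scale, curve)

    values = abundance.values.to_numpy()
    rows = []
    for i, pid in enumerate(proteins):
        rel = rel_intensity[i]
        top_mean = np.mean(np.sort(rel)[::-1][: min(3, len(rel))])
        block = peptide_truth.iloc[
            peptide_truth.index[peptide_truth["protein_id"] == pid]
        ]
        for j, s in enumerate(samples):
            pai = values[i, j]
            if pai <= 0:
                continue
            scalef = pai / top_mean
            noise = (
                np.power(10.0, rng.normal(0.0, config.peptide_dispersion, size=len(rel)))
                if config.peptide_dispersion > 0
                else np.ones(len(rel))
            )
            shift, scale, curve = warps[s]
            for (_, meta), r, nz in zip(block.iterrows(), rel, noise):
                rt = meta["latent_rt"]
                rows.append(
                    {
                        "sample_id": s,
                        "peptide": meta["peptide"],
                        "protein_id": pid,
                        "mz": meta["mz"],
                        "rt": shift + scale * rt + curve * rt * rt / rt_max,
                        "area": r * scalef * nz,
                    }
                )
    features = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    return features, peptide_truth


def simulate_psms(config: SimConfig) -> pd.DataFrame:
    """Simulate a labelled PSM score list for target-decoy FDR exercises.

    Targets are a mixture of correct matches (high-score population) and
    incorrect matches drawn from the same null distribution as the decoys;
    the ``is_correct`` column records the true class of every record.
    """
    rng = np.random.default_rng([config.seed, 3])
    n_c, n_i, n_d = config.n_correct_psms, config.n_incorrect_psms, config.n_decoy_psms
    scores = np.concatenate(
        [
            rng.normal(config.correct_score_mean, config.score_sd, size=n_c),
            rng.normal(config.null_score_mean, config.score_sd, size=n_i),
            rng.normal(config.null_score_mean, config.score_sd, size=n_d),
        ]
    )
    is_decoy = np.concatenate([np.zeros(n_c + n_i, dtype=bool), np.ones(n_d, dtype=bool)])
    is_correct = np.concatenate(
        [np.ones(n_c, dtype=bool), np.zeros(n_i + n_d, dtype=bool)]
    )
    n = n_c + n_i + n_d
    peptides = [f"SYNPEP{i:06d}" for i in range(n)]
    proteins = [
        ("DECOY_" if d else "") + f"P{rng.integers(0, max(config.n_proteins, 1)):05d}"
        for d in is_decoy
    ]
    return pd.DataFrame(
        {
            "spectrum_id": [f"spec{i:06d}" for i in range(n)],
            "peptide": peptides,
            "protein_id": proteins,
            "score": scores,
            "is_decoy": is_decoy,
            "is_correct": is_correct,
            "sample_id": "S01",
        }
    )
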