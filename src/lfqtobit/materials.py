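"""Substrate characterization and fermentation bookkeeping computations.

Small, closed-form quantities used around the proteomics pipeline:
X-ray-diffraction crystallinity index against amorphous/crystalline
standards, cellulose degree of polymerization from the tricarbanilate
peak molar mass, genome-copy equivalents of extracted DNA, metabolite
concentration ratios, and the carbon mass-balance degradation yield of
batch microcosms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Diffractogram",
    "MaterialConstants",
    "CarbonPools",
    "crystallinity_index",
    "degree_of_polymerization",
    "genome_copies",
    "metabolite_ratios",
    "degradation_yield",
]

#: molar mass of one tricarbanilated anhydroglucose unit (Da)
TRICARBANILATE_UNIT_DA = 519.0


@dataclass
class Diffractogram:
    """Sample (U), amorphous (A) and crystalline (C) intensities on one 2-theta grid."""

    two_theta: np.ndarray
    sample: np.ndarray
    amorphous: np.ndarray
    crystalline: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.two_theta)
        for name in ("sample", "amorphous", "crystalline"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n:
                raise ValueError("U, A and C must share the 2-theta grid")
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite intensities in {name}")
            setattr(self, name, arr)


@dataclass
class MaterialConstants:
    """Physical constants of the genome-copy computation.

    The defaults (650 g/mol per base pair, Avogadro 6.022e23, genome
    length 4,068,724 bp) reproduce the reference value of 227,703 genome
    copies per ng of DNA; all are overridable.
    """

    bp_molar_mass: float = 650.0  # g/mol per bp
    avogadro: float = 6.022e23  # 1/mol
    genome_length_bp: float = 4_068_724.0
    tricarbanilate_unit: float = TRICARBANILATE_UNIT_DA

    def __post_init__(self) -> None:
        for name in ("bp_molar_mass", "avogadro", "genome_length_bp", "tricarbanilate_unit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CarbonPools:
    """Carbon masses (mg) in a microcosm at one time point."""

    substrate: float
    doc: float
    dic: float
    co2_gas: float
    sampled: float = 0.0

    def __post_init__(self) -> None:
        for name in ("substrate", "doc", "dic", "co2_gas", "sampled"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> float:
        return self.substrate + self.doc + self.dic + self.co2_gas + self.sampled


def crystallinity_index(d: Diffractogram) -> float:
    """Crystallinity index (%) = 100 * sum|U - A| / sum|C - A| over the grid."""
    denom = np.abs(d.crystalline - d.amorphous).sum()
    if denom == 0:
        raise ValueError("crystalline and amorphous standards coincide; CI undefined")
    return float(100.0 * np.abs(d.sample - d.amorphous).sum() / denom)


def degree_of_polymerization(
    peak_molar_mass: float, unit_mass: float = TRICARBANILATE_UNIT_DA
) -> tuple[int, float]:
    """Cellulose DP from the tricarbanilate peak molar mass.

    DP = peak MW / unit mass (519 Da for the tricarbanilated
    anhydroglucose unit).  Returns the value rounded to the nearest 10
    (reporting convention) together with the raw ratio.
    """
    if peak_molar_mass <= 0:
        raise ValueError("peak molar mass must be positive")
    raw = peak_molar_mass / unit_mass
    return int(round(raw / 10.0) * 10), raw


def genome_copies(dna_mass_ng: float, constants: MaterialConstants | None = None) -> float:
    """Genome-copy equivalents of a DNA mass in ng.

    copies = mass / (genome length * bp molar mass / Avogadro).
    """
    if dna_mass_ng < 0:
        raise ValueError("DNA mass must be non-negative")
    c = constants or MaterialConstants()
    genome_mass_ng = c.genome_length_bp * c.bp_molar_mass / c.avogadro * 1e9
    return dna_mass_ng / genome_mass_ng


def metabolite_ratios(series: pd.DataFrame) -> pd.DataFrame:
    """Acetate-to-lactate and acetate-to-ethanol concentration ratios over time.

    ``series`` needs columns time, acetate, ethanol, lactate on a common
    time grid (strictly increasing).  Ratios with a zero denominator are
    NaN and flagged undefined rather than set to 0.
    """
    required = {"time", "acetate", "ethanol", "lactate"}
    if not required.issubset(series.columns):
        raise ValueError(f"series needs columns {sorted(required)}")
    t = series["time"].to_numpy(dtype=float)
    if (np.diff(t) <= 0).any():
        raise ValueError("time points must be strictly increasing")
    if (series[["acetate", "ethanol", "lactate"]].to_numpy() < 0).any():
        raise ValueError("concentrations must be non-negative")

    def ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)

    ac = series["acetate"].to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "time": t,
            "acetate_to_lactate": ratio(ac, series["lactate"].to_numpy(dtype=float)),
            "acetate_to_ethanol": ratio(ac, series["ethanol"].to_numpy(dtype=float)),
        }
    )
    out["undefined"] = out[["acetate_to_lactate", "acetate_to_ethanol"]].isna().any(axis=1)
    return out


def degradation_yield(
    initial: CarbonPools,
    final: CarbonPools,
    sampling_option: int = 1,
    sampled_substrate_carbon: float = 0.0,
) -> tuple[float, float]:
    """Substrate degradation yield (%) from the carbon mass balance.

    The final substrate carbon is reconstructed by conservation: total
    carbon is identical at both time points, so final substrate = initial
    total - (DOC + DIC + CO2 + sampled) at the final time point.  Under
    option 1 no substrate particles were removed with the liquid-phase
    samples; under option 2 particles at the initial concentration were
    sampled, adding ``sampled_substrate_carbon`` mg to the sampled pool.
    Yield = 100 * (initial substrate - final substrate) / initial substrate.

    Returns (yield percent, reconstructed final substrate carbon in mg);
    a negative reconstruction is clipped to 0 with a warning since it
    signals a mass-balance inconsistency.
    """
    if sampling_option not in (1, 2):
        raise ValueError("sampling_option must be 1 or 2")
    if initial.substrate <= 0:
        raise ValueError("initial substrate carbon must be positive")
    sampled = final.sampled + (sampled_substrate_carbon if sampling_option == 2 else 0.0)
    final_substrate = initial.total - (final.doc + final.dic + final.co2_gas + sampled)
    if final_substrate < 0:
        import warnings

        warnings.warn("reconstructed substrate carbon < 0; clipped (mass-balance inconsistency)")
        final_substrate = 0.0
    yield_pct = 100.0 * (initial.substrate - final_substrate) / initial.substrate
    return yield_pct, final_substrate
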