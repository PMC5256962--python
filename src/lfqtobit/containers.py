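"""In-memory containers shared across pipeline stages.

Tabular data is held in pandas DataFrames with fixed, documented column
sets; the small dataclasses here bundle a table with the metadata that
must travel with it (fraction labels, detect masks, censor thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: column order of the experimental-design table
DESIGN_COLUMNS = ["sample_id", "substrate", "time", "replicate", "fraction"]

#: column order of the peptide-feature table
FEATURE_COLUMNS = ["sample_id", "peptide", "protein_id", "mz", "rt", "area"]

#: column order of the PSM table
PSM_COLUMNS = ["spectrum_id", "peptide", "protein_id", "score", "is_decoy", "sample_id"]

COEFFICIENTS = ("mu", "alpha", "beta", "gamma")


@dataclass
class AbundanceMatrix:
    """Proteins x samples PAI values on the linear scale; 0 = non-detect."""

    values: pd.DataFrame  # index: protein_id, columns: sample_id
    sample_fractions: pd.Series  # sample_id -> fraction label

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("PAI values must be non-negative")
        missing = set(self.values.columns) - set(self.sample_fractions.index)
        if missing:
            raise ValueError(f"samples without fraction label: {sorted(missing)}")

    def fraction_samples(self, fraction: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_fractions[s] == fraction]


@dataclass
class NormalizedMatrix:
    """log10-scale matrix with an explicit detect mask.

    Non-detects are carried as exact 0 in ``values`` and as False in
    ``detected``; detected entries are finite log10 abundances.
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    sample_fractions: pd.Series

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        d = self.detected.to_numpy(dtype=bool)
        if not np.isfinite(v[d]).all():
            raise ValueError("detected entries must be finite")
        if (v[~d] != 0).any():
            raise ValueError("non-detect entries must be exactly 0")

    def fraction_samples(self, fraction: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_fractions[s] == fraction]


# observation flags of the censoring rule
OBSERVED = "observed"
CENSORED = "censored-replaced"
ALL_ZERO = "all-zero-cell"


@dataclass
class CensoredResponse:
    """Per-protein model response after the censoring rule.

    ``y`` is the response with zeros in partially detected cells replaced
    by the threshold; ``y_star`` the raw vector; ``flags`` one of
    {observed, censored-replaced, all-zero-cell} per observation.  In the
    likelihood every non-detect (both flag kinds) is treated as
    left-censored at ``threshold``.
    """

    y: np.ndarray
    y_star: np.ndarray
    flags: np.ndarray  # dtype object/str
    threshold: float

    @property
    def censored_mask(self) -> np.ndarray:
        return self.flags != OBSERVED

    @property
    def n_censored(self) -> int:
        return int(self.censored_mask.sum())


@dataclass
class TobitPosterior:
    """Retained MCMC draws for one protein.

    ``draws`` has one column per entry of ``columns``; sigma2 draws are on
    the squared log10 scale.
    """

    draws: np.ndarray  # (n_kept, 5)
    columns: tuple = (*COEFFICIENTS, "sigma2")
    iterations: int = 0
    burnin: int = 0
    seed: int = 0
    n_censored: int = 0
    threshold: float = np.nan
    converged: bool = True

    def chain(self, name: str) -> np.ndarray:
        return self.draws[:, self.columns.index(name)]


@dataclass
class GroundTruth:
    """True generative parameters of a synthetic dataset (one row per protein)."""

    table: pd.DataFrame

    COLUMNS = [
        "protein_id", "mu", "alpha", "beta", "gamma", "sigma",
        "detection_limit", "alpha_null", "beta_null", "gamma_null", "qualitative",
    ]

    def __post_init__(self) -> None:
        if list(self.table.columns) != self.COLUMNS:
            raise ValueError("unexpected ground-truth schema")
        t = self.table
        for coef in ("alpha", "beta", "gamma"):
            # a quantitative coefficient is flagged null iff it is exactly 0
            quant = ~t["qualitative"]
            if not (t.loc[quant, f"{coef}_null"] == (t.loc[quant, coef] == 0)).all():
                raise ValueError("null flags inconsistent with coefficients")
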