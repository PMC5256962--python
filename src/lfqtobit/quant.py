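"""Identification filtering, retention-time alignment and PAI computation.

The quantification strategy follows the classic XIC workflow: peptide
spectrum matches are validated against a target/decoy score list at a
peptide-level FDR, protein identifications at a protein-level FDR (best
peptide score per protein); identified peptides shared between samples
act as anchors for a monotone piecewise-linear retention-time alignment;
validated identifications are transferred to unidentified peaks within
m/z and RT tolerances; and each protein's abundance in a sample is the
Protein Abundance Index (PAI) -- the mean XIC area of its three most
intense peptides.

Quantification uses unique (single-protein) peptides only, and the
per-peptide area within a sample is the maximum over that peptide's
features, which is robust to split chromatographic features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .containers import AbundanceMatrix

__all__ = [
    "estimate_decoy_fdr",
    "filter_identifications",
    "align_retention_times",
    "transfer_identifications",
    "compute_pai",
    "assemble_abundance",
]


def estimate_decoy_fdr(psms: pd.DataFrame, cutoff: float) -> float:
    """Decoy-based FDR estimate at a score cutoff: ``#decoys / #targets``, capped at 1.

    Raises
    ------
    ValueError
        If no target PSM scores at or above the cutoff (estimate undefined).
    """
    above = psms[psms["score"] >= cutoff]
    n_targets = int((~above["is_decoy"]).sum())
    if n_targets == 0:
        raise ValueError("no target PSMs at or above cutoff; FDR undefined")
    n_decoys = int(above["is_decoy"].sum())
    return min(1.0, n_decoys / n_targets)


def _largest_passing_set(scores: np.ndarray, is_decoy: np.ndarray, threshold: float) -> float:
    """Lowest score cutoff whose decoy-estimated FDR is <= threshold.

    Returns ``inf`` when no cutoff passes (nothing retained).
    """
    order = np.argsort(-scores, kind="stable")
    s, d = scores[order], is_decoy[order]
    n_dec = np.cumsum(d)
    n_tar = np.cumsum(~d)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_tar > 0, np.minimum(1.0, n_dec / np.maximum(n_tar, 1)), np.inf)
    passing = np.flatnonzero(fdr <= threshold)
    if len(passing) == 0:
        return np.inf
    return float(s[passing[-1]])


def filter_identifications(
    psms: pd.DataFrame, peptide_fdr: float = 0.05, protein_fdr: float = 0.01
) -> tuple[pd.DataFrame, set[str]]:
    """Two-stage target/decoy validation of identifications.

    Peptides are scored by their best PSM and retained at the largest
    cutoff set with decoy-estimated FDR <= ``peptide_fdr``; proteins are
    scored by their best retained peptide and filtered at ``protein_fdr``.
    Decoy records are excluded from both outputs.

    Returns
    -------
    validated_peptides
        PSM-level table restricted to validated target peptides.
    validated_proteins
        Set of validated target protein ids.
    """
    if len(psms) == 0:
        return psms.copy(), set()
    pep = (
        psms.groupby("peptide")
        .agg(score=("score", "max"), is_decoy=("is_decoy", "any"))
        .reset_index()
    )
    pep_cut = _largest_passing_set(
        pep["score"].to_numpy(), pep["is_decoy"].to_numpy(dtype=bool), peptide_fdr
    )
    valid_pep = pep[pep["score"] >= pep_cut]

    prot = (
        psms[psms["peptide"].isin(valid_pep["peptide"])]
        .groupby("protein_id")
        .agg(score=("score", "max"), is_decoy=("is_decoy", "any"))
        .reset_index()
    )
    if len(prot) == 0:
        return psms.iloc[0:0].copy(), set()
    prot_cut = _largest_passing_set(
        prot["score"].to_numpy(), prot["is_decoy"].to_numpy(dtype=bool), protein_fdr
    )
    valid_prot = set(prot.loc[(prot["score"] >= prot_cut) & ~prot["is_decoy"], "protein_id"])

    keep_pep = set(valid_pep.loc[~valid_pep["is_decoy"], "peptide"])
    out = psms[
        psms["peptide"].isin(keep_pep)
        & psms["protein_id"].isin(valid_prot)
        & ~psms["is_decoy"]
    ].copy()
    return out, valid_prot


@dataclass
class RTWarp:
    """Monotone piecewise-linear retention-time map with linear extrapolation."""

    x: np.ndarray  # anchor RTs in the sample being aligned (sorted)
    y: np.ndarray  # corresponding reference RTs (non-decreasing)

    def __call__(self, rt: np.ndarray | float) -> np.ndarray | float:
        rt = np.asarray(rt, dtype=float)
        out = np.interp(rt, self.x, self.y)
        # linear extrapolation from the terminal segments
        if len(self.x) >= 2:
            lo = rt < self.x[0]
            hi = rt > self.x[-1]
            slope_lo = self._slope(0)
            slope_hi = self._slope(-2)
            out = np.where(lo, self.y[0] + (rt - self.x[0]) * slope_lo, out)
            out = np.where(hi, self.y[-1] + (rt - self.x[-1]) * slope_hi, out)
        return out if out.ndim else float(out)

    def _slope(self, i: int) -> float:
        dx = self.x[i + 1] - self.x[i]
        return (self.y[i + 1] - self.y[i]) / dx if dx > 0 else 1.0


def _identity_warp(rt):
    return rt


def align_retention_times(
    reference: pd.DataFrame, other: pd.DataFrame
) -> tuple[Callable, pd.DataFrame]:
    """Align one sample's retention times onto a reference sample.

    Anchors are peptide sequences identified in both samples (median RT
    per sequence per sample).  A monotone piecewise-linear map is fitted
    through the anchor pairs (isotonic regression enforces monotonicity)
    and applied to every feature of ``other``.

    With fewer than 2 anchors the alignment is skipped with a warning and
    the identity map is returned.
    """
    ref_ids = reference.dropna(subset=["peptide"])
    oth_ids = other.dropna(subset=["peptide"])
    ref_rt = ref_ids.groupby("peptide")["rt"].median()
    oth_rt = oth_ids.groupby("peptide")["rt"].median()
    shared = ref_rt.index.intersection(oth_rt.index)
    if len(shared) < 2:
        warnings.warn("fewer than 2 shared anchor peptides; returning identity map")
        return _identity_warp, other.copy()
    x = oth_rt[shared].to_numpy()
    y = ref_rt[shared].to_numpy()
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    iso = IsotonicRegression(increasing=True)
    y_fit = iso.fit_transform(x, y)
    # collapse duplicated anchor positions to a single knot
    xu, idx = np.unique(x, return_index=True)
    warp = RTWarp(x=xu, y=y_fit[idx])
    aligned = other.copy()
    aligned["rt"] = warp(aligned["rt"].to_numpy())
    return warp, aligned


def transfer_identifications(
    features: pd.DataFrame,
    validated: pd.DataFrame,
    rt_tol: float = 1.0,
    mz_tol_ppm: float = 10.0,
) -> pd.DataFrame:
    """Propagate validated identifications to unidentified aligned peaks.

    An unidentified peak inherits the peptide/protein of a validated
    identification when it lies within both tolerances of exactly one
    candidate peptide; peaks matching two or more distinct peptides stay
    unidentified (ambiguity rule).

    ``validated`` needs columns peptide, protein_id, mz, rt (reference
    retention-time scale, i.e. after alignment).
    """
    cand = (
        validated.groupby("peptide")
        .agg(protein_id=("protein_id", "first"), mz=("mz", "median"), rt=("rt", "median"))
        .reset_index()
        .sort_values("mz", kind="stable")
        .reset_index(drop=True)
    )
    cmz = cand["mz"].to_numpy()
    crt = cand["rt"].to_numpy()
    out = features.copy()
    unident = out["peptide"].isna()
    for i in np.flatnonzero(unident.to_numpy()):
        mz = out.iat[i, out.columns.get_loc("mz")]
        rt = out.iat[i, out.columns.get_loc("rt")]
        tol = mz * mz_tol_ppm * 1e-6
        lo = np.searchsorted(cmz, mz - tol, side="left")
        hi = np.searchsorted(cmz, mz + tol, side="right")
        hits = [j for j in range(lo, hi) if abs(crt[j] - rt) <= rt_tol]
        if len(hits) == 1:
            j = hits[0]
            out.iat[i, out.columns.get_loc("peptide")] = cand.at[j, "peptide"]
            out.iat[i, out.columns.get_loc("protein_id")] = cand.at[j, "protein_id"]
    return out


def compute_pai(features: pd.DataFrame) -> float:
    """Protein Abundance Index of one protein in one sample.

    Mean XIC area of the three most intense peptides (per-peptide area =
    max over that peptide's features); with 1-2 peptides, the mean of
    those; with none, 0 (non-detect).
    """
    if len(features) == 0:
        return 0.0
    if features["protein_id"].nunique() > 1 or features["sample_id"].nunique() > 1:
        raise ValueError("features must share one protein id and one sample id")
    areas = features.groupby("peptide")["area"].max().to_numpy()
    if (areas < 0).any():
        raise ValueError("negative XIC area")
    top = np.sort(areas)[::-1][: min(3, len(areas))]
    return float(np.mean(top))


def assemble_abundance(
    features: pd.DataFrame, design: pd.DataFrame
) -> AbundanceMatrix:
    """Build the proteins x samples PAI matrix from identified features.

    Shared peptides (sequences assigned to more than one protein across
    the table) are dropped before quantification to avoid double
    counting; samples with no features for a protein get 0.
    """
    ident = features.dropna(subset=["peptide", "protein_id"])
    n_prot = ident.groupby("peptide")["protein_id"].nunique()
    unique_peps = n_prot[n_prot == 1].index
    ident = ident[ident["peptide"].isin(unique_peps)]
    if (ident["area"] < 0).any():
        raise ValueError("negative XIC area")

    per_pep = (
        ident.groupby(["protein_id", "sample_id", "peptide"])["area"].max().reset_index()
    )

    def top3_mean(a: pd.Series) -> float:
        arr = np.sort(a.to_numpy())[::-1]
        return float(arr[: min(3, len(arr))].mean())

    pai = (
        per_pep.groupby(["protein_id", "sample_id"])["area"].apply(top3_mean).unstack(fill_value=0.0)
    )
    samples = design["sample_id"].tolist()
    pai = pai.reindex(columns=samples, fill_value=0.0)
    return AbundanceMatrix(
        values=pai,
        sample_fractions=pd.Series(
            design["fraction"].to_numpy(), index=design["sample_id"].to_numpy()
        ),
    )
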