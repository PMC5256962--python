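"""log10 transform and within-fraction quantile normalization.

Non-detects (zeros) never enter the transform or the reference
distribution: downstream they are modelled as left-censored rather than
as observed minima, so normalization only redistributes the detected
values.  Pellet and supernatant samples are normalized separately, as
the two fractions are analyzed separately throughout the pipeline.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, NormalizedMatrix

__all__ = ["log10_transform", "quantile_normalize"]


def log10_transform(matrix: AbundanceMatrix) -> NormalizedMatrix:
    """Replace detected entries by log10(value); zeros stay 0 and are masked.

    Values in (0, 1] would map to <= 0 and collide with the non-detect
    sentinel, so they are rejected.  Realistic XIC areas are orders of
    magnitude above 1.
    """
    v = matrix.values.to_numpy(dtype=float)
    detected = v > 0
    if ((v > 0) & (v <= 1.0)).any():
        raise ValueError(
            "abundances in (0, 1] map to log10 <= 0 and collide with the "
            "non-detect sentinel 0"
        )
    out = np.zeros_like(v)
    out[detected] = np.log10(v[detected])
    return NormalizedMatrix(
        values=pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        detected=pd.DataFrame(
            detected, index=matrix.values.index, columns=matrix.values.columns
        ),
        sample_fractions=matrix.sample_fractions,
    )


def _reference_distribution(columns: list[np.ndarray], m: int) -> np.ndarray:
    """Mean-of-order-statistics reference evaluated on an m-point quantile grid."""
    grid = (np.arange(m) + 0.5) / m
    acc = np.zeros(m)
    for col in columns:
        srt = np.sort(col)
        pos = (np.arange(len(srt)) + 0.5) / len(srt)
        acc += np.interp(grid, pos, srt)
    return acc / len(columns)


def _map_sample(values: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Map one sample's detected values onto the reference distribution.

    The k-th order statistic maps to the reference quantile function at
    position (k - 0.5)/n; tied input values receive the average of their
    mapped values so the result is order-invariant.
    """
    n = len(values)
    order = np.argsort(values, kind="stable")
    pos = (np.arange(n) + 0.5) / n
    grid = (np.arange(len(ref)) + 0.5) / len(ref)
    mapped_sorted = np.interp(pos, grid, ref)
    out = np.empty(n)
    out[order] = mapped_sorted
    # average mapped values over ties
    srt_vals = values[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and srt_vals[j + 1] == srt_vals[i]:
            j += 1
        if j > i:
            out[order[i : j + 1]] = mapped_sorted[i : j + 1].mean()
        i = j + 1
    return out


def quantile_normalize(matrix: NormalizedMatrix) -> NormalizedMatrix:
    """Quantile-normalize detected values within each fraction group.

    Each sample's detected values are mapped onto the group's
    mean-of-order-statistics reference distribution; with unequal
    detected counts the reference is evaluated by linear interpolation at
    each sample's quantile positions.  Non-detects are untouched.  A
    sample with no detected values is left as is with a warning.
    """
    values = matrix.values.copy()
    detected = matrix.detected
    for fraction in pd.unique(matrix.sample_fractions):
        samples = matrix.fraction_samples(fraction)
        if len(samples) < 2:
            raise ValueError(f"fraction {fraction!r} needs >= 2 samples")
        cols, live = [], []
        for s in samples:
            mask = detected[s].to_numpy()
            if mask.sum() == 0:
                warnings.warn(f"sample {s!r} has no detected values; left untouched")
                continue
            cols.append(values[s].to_numpy()[mask])
            live.append(s)
        if not cols:
            continue
        m = max(len(c) for c in cols)
        ref = _reference_distribution(cols, m)
        for s, col in zip(live, cols):
            mask = detected[s].to_numpy()
            mapped = _map_sample(col, ref)
            new = values[s].to_numpy()
            new[mask] = mapped
            values[s] = new
    return NormalizedMatrix(
        values=values, detected=detected.copy(), sample_fractions=matrix.sample_fractions
    )
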