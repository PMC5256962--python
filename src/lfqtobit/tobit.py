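"""Per-protein left-censored (Tobit) linear regression fitted by Gibbs sampling.

The response is the normalized log10 abundance of one protein across a
balanced 2 substrates x 2 time points x r replicates layout; the linear
predictor has an intercept, a substrate indicator S, a time indicator T
and their interaction S*T.  Non-detects are left-censored at the
protein's censoring threshold c, defined as the minimum positive value
of its raw response vector.

The sampler uses data augmentation: latent values for censored
observations are drawn from the model's conditional normal truncated
above at c; the coefficient vector is then drawn from its conditional
multivariate normal under a flat prior; and sigma^2 from its conditional
inverse-gamma (IG(a, b) prior, a = b = 0.001 by default).  Chains are
reproducible from a per-protein seed derived from the master seed and
the protein index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit

from .config import HWConfig, MCMCConfig
from .containers import (
    ALL_ZERO,
    CENSORED,
    COEFFICIENTS,
    OBSERVED,
    CensoredResponse,
    NormalizedMatrix,
    TobitPosterior,
)
from .diagnostics import heidelberger_welch

__all__ = [
    "build_design_matrix",
    "apply_censoring_rule",
    "gibbs_tobit",
    "summarize_posterior",
    "fit_all_proteins",
    "derive_protein_seed",
]

#: chains screened by the convergence diagnostic
SCREENED_CHAINS = ("alpha", "beta", "gamma", "sigma2")


def build_design_matrix(
    design: pd.DataFrame,
    substrate_reference: str | None = None,
    time_reference: str | None = None,
) -> np.ndarray:
    """Treatment-coded design matrix (intercept, S, T, S*T) for one fraction.

    The reference substrate gets S = 0 (by default the first level in
    order of appearance), so a positive substrate coefficient means
    higher levels on the non-reference substrate; likewise for time.
    Requires exactly two substrates and two time levels.
    """
    substrates = list(pd.unique(design["substrate"]))
    times = list(pd.unique(design["time"]))
    if len(substrates) != 2 or len(times) != 2:
        raise ValueError("design must have exactly 2 substrates and 2 times")
    sub_ref = substrates[0] if substrate_reference is None else substrate_reference
    time_ref = times[0] if time_reference is None else time_reference
    if sub_ref not in substrates or time_ref not in times:
        raise ValueError("reference level not present in the design")
    counts = design.groupby(["substrate", "time"]).size()
    if counts.nunique() != 1:
        raise ValueError("design is unbalanced")
    s = (design["substrate"] != sub_ref).to_numpy(dtype=float)
    t = (design["time"] != time_ref).to_numpy(dtype=float)
    return np.column_stack([np.ones(len(design)), s, t, s * t])


def apply_censoring_rule(y_star: np.ndarray, design: pd.DataFrame) -> CensoredResponse:
    """Apply the minimum-positive-value censoring rule to one protein.

    The censoring threshold c is the minimum positive entry of the raw
    response.  A zero in a (substrate, time) cell with at least one
    detected replicate is replaced by c and flagged censored-replaced; a
    cell whose replicates are all zero keeps the value 0 and is flagged
    all-zero (the likelihood treats both kinds as left-censored at c).

    Raises
    ------
    ValueError
        If every observation is zero (threshold undefined, not fittable).
    """
    y_star = np.asarray(y_star, dtype=float)
    if len(y_star) != len(design):
        raise ValueError("response and design length mismatch")
    positive = y_star > 0
    if not positive.any():
        raise ValueError("all observations are non-detects; protein not fittable")
    c = float(y_star[positive].min())
    flags = np.full(len(y_star), OBSERVED, dtype=object)
    y = y_star.copy()
    cells = design.groupby(["substrate", "time"], sort=False).indices
    for idx in cells.values():
        idx = np.asarray(idx)
        zeros = idx[y_star[idx] == 0]
        if len(zeros) == 0:
            continue
        if len(zeros) == len(idx):
            flags[zeros] = ALL_ZERO
        else:
            flags[zeros] = CENSORED
            y[zeros] = c
    return CensoredResponse(y=y, y_star=y_star, flags=flags, threshold=c)


@njit(cache=True)
def _trunc_std_lower(a):
    # standard normal conditioned on >= a (Robert's exponential rejection
    # for far tails, plain rejection otherwise)
    if a < 0.45:
        while True:
            v = np.random.standard_normal()
            if v >= a:
                return v
    lam = 0.5 * (a + np.sqrt(a * a + 4.0))
    while True:
        v = a + np.random.exponential() / lam
        d = v - lam
        if np.random.random() <= np.exp(-0.5 * d * d):
            return v


@njit(cache=True)
def _gibbs_kernel(y, cens, c, X, A, L, a0, b0, n_iter, burnin, seed, out):
    np.random.seed(seed)
    n, p = X.shape
    z = y.copy()
    beta = A @ z
    ssr = 0.0
    for i in range(n):
        m = 0.0
        for j in range(p):
            m += X[i, j] * beta[j]
        d = z[i] - m
        ssr += d * d
    sig2 = ssr / max(n - p, 1)
    if sig2 < 1e-8:
        sig2 = 1e-8
    eps = np.empty(p)
    keep = 0
    for it in range(n_iter):
        sig = np.sqrt(sig2)
        # latent censored values: x ~ N(m, sig^2) | x <= c
        for i in range(n):
            if cens[i]:
                m = 0.0
                for j in range(p):
                    m += X[i, j] * beta[j]
                v = _trunc_std_lower((m - c) / sig)
                z[i] = m - sig * v
        # coefficients | z, sig2 (flat prior)
        bhat = A @ z
        for j in range(p):
            eps[j] = np.random.standard_normal()
        beta = bhat + sig * (L @ eps)
        # sig2 | beta, z  ~ IG(a0 + n/2, b0 + SSR/2)
        ssr = 0.0
        for i in range(n):
            m = 0.0
            for j in range(p):
                m += X[i, j] * beta[j]
            d = z[i] - m
            ssr += d * d
        g = np.random.gamma(a0 + 0.5 * n, 1.0)
        sig2 = (b0 + 0.5 * ssr) / g
        if it >= burnin:
            for j in range(p):
                out[keep, j] = beta[j]
            out[keep, p] = sig2
            keep += 1


def gibbs_tobit(
    response: CensoredResponse,
    X: np.ndarray,
    mcmc: MCMCConfig | None = None,
    seed: int = 0,
) -> TobitPosterior:
    """Fit the censored regression for one protein by data augmentation.

    Requires at least one uncensored observation and a full-rank design.
    With every observation censored the model is non-identifiable and the
    returned posterior is flagged unconverged (no draws).
    """
    mcmc = mcmc or MCMCConfig()
    cens = response.censored_mask
    n_kept = mcmc.iterations - mcmc.burnin
    if (~cens).sum() == 0:
        return TobitPosterior(
            draws=np.empty((0, 5)),
            iterations=mcmc.iterations,
            burnin=mcmc.burnin,
            seed=seed,
            n_censored=response.n_censored,
            threshold=response.threshold,
            converged=False,
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    xtx_inv = np.linalg.inv(X.T @ X)
    A = xtx_inv @ X.T
    L = np.linalg.cholesky(xtx_inv)
    # censored entries start at the threshold for initialization
    y0 = response.y.copy()
    y0[cens] = response.threshold
    out = np.empty((n_kept, X.shape[1] + 1))
    _gibbs_kernel(
        np.ascontiguousarray(y0),
        np.ascontiguousarray(cens),
        float(response.threshold),
        np.ascontiguousarray(X, dtype=np.float64),
        np.ascontiguousarray(A),
        np.ascontiguousarray(L),
        float(mcmc.prior_a),
        float(mcmc.prior_b),
        int(mcmc.iterations),
        int(mcmc.burnin),
        int(seed),
        out,
    )
    return TobitPosterior(
        draws=out,
        iterations=mcmc.iterations,
        burnin=mcmc.burnin,
        seed=seed,
        n_censored=response.n_censored,
        threshold=response.threshold,
        converged=True,
    )


def summarize_posterior(posterior: TobitPosterior) -> pd.DataFrame:
    """Posterior means and two-sided tail p-values per coefficient.

    The p-value uses the add-one tail estimator
    ``p = min(1, 2 * min((1 + #{draws <= 0}), (1 + #{draws >= 0})) / (N + 1))``
    which cannot be exactly zero in a finite chain.
    """
    if not posterior.converged or len(posterior.draws) == 0:
        raise ValueError("cannot summarize an unconverged posterior")
    n = len(posterior.draws)
    rows = []
    for coef in COEFFICIENTS:
        draws = posterior.chain(coef)
        lo = (1 + int((draws <= 0).sum())) / (n + 1)
        hi = (1 + int((draws >= 0).sum())) / (n + 1)
        rows.append(
            {
                "coefficient": coef,
                "estimate": float(draws.mean()),
                "p_value": min(1.0, 2.0 * min(lo, hi)),
            }
        )
    return pd.DataFrame(rows)


def derive_protein_seed(master_seed: int, index: int) -> int:
    """Stable per-protein seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def fit_all_proteins(
    matrix: NormalizedMatrix,
    design: pd.DataFrame,
    fraction: str,
    mcmc: MCMCConfig | None = None,
    hw: HWConfig | None = None,
    master_seed: int = 0,
    substrate_reference: str | None = None,
    time_reference: str | None = None,
    screen: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Censoring rule -> Gibbs fit -> convergence screen for every protein.

    Proteins failing the Heidelberger-Welch diagnostic on any screened
    chain (substrate, time, interaction effects and sigma^2) are excluded
    from inference and listed in the discard log; so are proteins with no
    detected value.  ``screen=False`` skips the diagnostic (useful for
    calibration studies of the raw posterior p-values).

    Returns
    -------
    fits
        One row per retained protein x coefficient with columns protein_id,
        fraction, coefficient, estimate, p_value, n_censored, threshold.
    discards
        One row per excluded protein with the reason.
    """
    mcmc = mcmc or MCMCConfig()
    hw = hw or HWConfig()
    sub = design[design["fraction"] == fraction].reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError(f"no samples in fraction {fraction!r}")
    X = build_design_matrix(sub, substrate_reference, time_reference)
    samples = sub["sample_id"].tolist()
    values = matrix.values[samples].to_numpy()

    fit_rows, discard_rows = [], []
    for i, pid in enumerate(matrix.values.index):
        y_star = values[i]
        if not (y_star != 0).any():
            discard_rows.append({"protein_id": pid, "fraction": fraction, "reason": "no detections"})
            continue
        response = apply_censoring_rule(y_star, sub)
        seed = derive_protein_seed(master_seed, i)
        posterior = gibbs_tobit(response, X, mcmc=mcmc, seed=seed)
        if not posterior.converged:
            discard_rows.append(
                {"protein_id": pid, "fraction": fraction, "reason": "all observations censored"}
            )
            continue
        failed = (
            [
                name
                for name in SCREENED_CHAINS
                if not heidelberger_welch(posterior.chain(name), alpha=hw.alpha, eps=hw.eps).passed
            ]
            if screen
            else []
        )
        if failed:
            discard_rows.append(
                {
                    "protein_id": pid,
                    "fraction": fraction,
                    "reason": "hw-failed: " + ",".join(failed),
                }
            )
            continue
        summary = summarize_posterior(posterior)
        n_all_zero = int((response.flags == ALL_ZERO).sum())
        for _, row in summary.iterrows():
            fit_rows.append(
                {
                    "protein_id": pid,
                    "fraction": fraction,
                    "coefficient": row["coefficient"],
                    "estimate": row["estimate"],
                    "p_value": row["p_value"],
                    "n_censored": posterior.n_censored,
                    "n_all_zero": n_all_zero,
                    "threshold": posterior.threshold,
                }
            )
    fits = pd.DataFrame(
        fit_rows,
        columns=[
            "protein_id", "fraction", "coefficient", "estimate",
            "p_value", "n_censored", "n_all_zero", "threshold",
        ],
    )
    discards = pd.DataFrame(discard_rows, columns=["protein_id", "fraction", "reason"])
    return fits, discards
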