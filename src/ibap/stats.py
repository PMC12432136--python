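"""Shared statistical helpers: rank correlations, bootstrap CIs, BH-FDR."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_fdr", "spearman_test", "rank_corr_rows", "percentile_ci"]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs propagate)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _standardized_ranks(a: np.ndarray) -> np.ndarray:
    """Midranks along the last axis, centered and scaled to unit norm."""
    r = stats.rankdata(a, axis=-1)
    r = r - r.mean(axis=-1, keepdims=True)
    norm = np.linalg.norm(r, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return r / norm


def rank_corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Spearman correlation of two equal-shape 2-D arrays.

    Ties are handled by midranks.  Rows with zero variance give NaN.
    """
    return np.einsum("...i,...i->...", _standardized_ranks(a), _standardized_ranks(b))


def percentile_ci(samples: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    alpha = (1.0 - level) / 2.0
    lo, hi = np.nanquantile(samples, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def spearman_test(
    x,
    y,
    n_boot: int = 10_000,
    seed: int | None = 0,
    ci_level: float = 0.95,
):
    """Spearman rho with two-sided p and a percentile-bootstrap CI.

    Bootstrap resamples subjects (paired), vectorized; returns
    ``(rho, p, (lo, hi), n)``.  With ``n_boot=0`` the CI is ``(nan, nan)``.
    Constant inputs give ``rho = nan``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan, (np.nan, np.nan), n
    rho, p = stats.spearmanr(x, y)
    if n_boot <= 0:
        return float(rho), float(p), (np.nan, np.nan), n
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    rho_b = rank_corr_rows(x[idx], y[idx])
    return float(rho), float(p), percentile_ci(rho_b, ci_level), n
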