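"""Deviation-summary PCA and environment/outcome associations.

PC1 of the subjects x regions deviation-score matrix serves as the global
deviation summary; it is correlated with environment and behavior variables
and entered into the GA x SES moderation regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr, percentile_ci, spearman_test
from .synthetic import SES_CODES

__all__ = ["PCSummary", "ModerationResult", "pc1_summary", "env_outcome_correlations",
           "moderation_ga_ses"]


@dataclass
class PCSummary:
    scores: pd.Series  # PC1 score per subject (centered)
    loadings: pd.Series  # unit-norm loading per region, sign: mean loading > 0
    explained_variance_ratio: np.ndarray
    center: pd.Series  # per-region column means removed before the SVD


def pc1_summary(score_matrix: pd.DataFrame, standardize: bool = False) -> PCSummary:
    """First principal component of the deviation-score matrix.

    Columns are centered (not scaled by default: deviation scores already
    share the (0, 1) scale); missing-region columns are dropped.  The sign
    convention (mean loading > 0) makes output deterministic across
    linear-algebra backends.
    """
    X = score_matrix.dropna(axis=1, how="all").dropna(axis=0)
    center = X.mean(axis=0)
    M = X.to_numpy(dtype=float) - center.to_numpy()
    if standardize:
        sd = M.std(axis=0, ddof=1)
        M = M / sd
    if not np.any(M):
        raise ValueError("rank-0 matrix: no variance to decompose")
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    if Vt[0].mean() < 0:
        Vt[0] = -Vt[0]
        U[:, 0] = -U[:, 0]
    ev = S**2
    return PCSummary(
        scores=pd.Series(U[:, 0] * S[0], index=X.index, name="pc1"),
        loadings=pd.Series(Vt[0], index=X.columns, name="pc1_loading"),
        explained_variance_ratio=ev / ev.sum(),
        center=center,
    )


def env_outcome_correlations(
    pc: PCSummary,
    variables: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Spearman of PC1 scores against each variable column.

    BH-FDR runs across the variables tested in this one call; each row gets a
    percentile-bootstrap 95% CI.  Constant variables give missing rows.
    """
    rows = []
    for name in variables.columns:
        v = variables[name].reindex(pc.scores.index)
        if v.dtype == object:
            v = v.map(SES_CODES) if set(v.dropna()) <= set(SES_CODES) else v
        rho, p, ci, n = spearman_test(pc.scores, pd.to_numeric(v), n_boot=n_boot, seed=seed)
        rows.append({"variable": name, "rho": rho, "p": p, "ci_lo": ci[0], "ci_hi": ci[1], "n": n})
    out = pd.DataFrame(rows).set_index("variable")
    out["p_fdr"] = bh_fdr(out["p"])
    return out


@dataclass
class ModerationResult:
    params: pd.Series  # intercept, ga, ses, ga_x_ses
    bse: pd.Series
    interaction_p_one_sided: float
    interaction_p_two_sided: float
    interaction_ci: tuple  # bootstrap 95% CI of the interaction coefficient
    conditional_effects: pd.DataFrame  # per SES level: effect of GA, se, p
    n: int
    alternative: str
    seed: int


def moderation_ga_ses(
    pc1_scores: pd.Series,
    ga: pd.Series,
    ses: pd.Series,
    alternative: str = "less",
    n_boot: int = 5_000,
    seed: int = 0,
) -> ModerationResult:
    """OLS moderation model ``PC1 ~ GA + SES + GA x SES`` (raw predictors).

    SES is ordinal-coded low = 1, middle = 2, high = 3 (labels or numeric
    codes accepted).  The interaction is tested one-sided (``alternative``
    gives the hypothesized sign; 'less' = higher SES weakens the GA effect).
    Conditional effects of GA are evaluated at each observed SES level as
    ``beta_GA + code * beta_int`` with pointwise one-sided tests, and the
    interaction gets a subject-resampling percentile-bootstrap CI.
    """
    if alternative not in ("less", "greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    ses = ses.map(SES_CODES).fillna(pd.to_numeric(ses, errors="coerce")) if ses.dtype == object else ses
    df = pd.DataFrame({"pc1": pc1_scores, "ga": ga, "ses": ses}).dropna()
    levels = np.sort(df["ses"].unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 SES levels for a moderation model")
    y = df["pc1"].to_numpy(dtype=float)
    X = np.column_stack(
        [
            np.ones(len(df)),
            df["ga"].to_numpy(dtype=float),
            df["ses"].to_numpy(dtype=float),
            (df["ga"] * df["ses"]).to_numpy(dtype=float),
        ]
    )
    names = ["intercept", "ga", "ses", "ga_x_ses"]
    beta, cov, dof = _ols(X, y)
    se = np.sqrt(np.diag(cov))
    t_int = beta[3] / se[3]
    p_two = 2.0 * sps.t.sf(abs(t_int), dof)
    if alternative == "two-sided":
        p_one = p_two
    elif alternative == "less":
        p_one = sps.t.cdf(t_int, dof)
    else:
        p_one = sps.t.sf(t_int, dof)

    # conditional effect of GA at each observed SES level: c' beta with
    # c = [0, 1, 0, code]
    rows = []
    for code in levels:
        c = np.array([0.0, 1.0, 0.0, float(code)])
        eff = float(c @ beta)
        eff_se = float(np.sqrt(c @ cov @ c))
        t = eff / eff_se
        rows.append(
            {
                "ses_code": float(code),
                "effect": eff,
                "se": eff_se,
                "p_two_sided": 2.0 * float(sps.t.sf(abs(t), dof)),
                "p_one_sided": float(sps.t.sf(t, dof)),  # H1: GA effect > 0
            }
        )
    cond = pd.DataFrame(rows).set_index("ses_code")

    # percentile bootstrap over subjects for the interaction coefficient
    n = len(df)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                boot[b] = np.linalg.lstsq(X[idx], y[idx], rcond=None)[0][3]
            except np.linalg.LinAlgError:
                boot[b] = np.nan
        ci = percentile_ci(boot)
    else:
        ci = (np.nan, np.nan)

    return ModerationResult(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        interaction_p_one_sided=float(p_one),
        interaction_p_two_sided=float(p_two),
        interaction_ci=ci,
        conditional_effects=cond,
        n=n,
        alternative=alternative,
        seed=seed,
    )


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - k
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    return beta, sigma2 * XtX_inv, dof
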