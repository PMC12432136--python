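"""Group-average dysmaturation versus individual heterogeneity.

Contrasts the classical group-difference analysis (per-region OLS with age
and sex covariates, BH-FDR across regions) with per-region extranormal
overlap percentages and cross-subject similarity of binarized deviation
profiles.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .normative import DeviationProfile
from .stats import bh_fdr, rank_corr_rows

log = logging.getLogger(__name__)

__all__ = [
    "group_average_dysmaturation",
    "overlap_percentages",
    "binarize_profiles",
    "profile_similarity",
]


def group_average_dysmaturation(
    data: pd.DataFrame,
    measure: str = "CTh",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region OLS of value on group, correcting for age and sex.

    Model: ``value ~ intercept + group(preterm) + age + sex``; BH-FDR across
    the regions tested.  Returns a region-indexed frame with ``beta_group``,
    ``p``, ``p_fdr`` and ``significant``.
    """
    d = data[data["measure"] == measure]
    groups = set(d["group"].unique())
    if not {"term", "preterm"} <= groups:
        raise ValueError("both term and preterm groups are required")
    if d[["age", "sex", "group", "value"]].isna().any().any():
        raise ValueError("missing covariates or values")

    rows = []
    for region, dr in d.groupby("region", observed=True):
        X = np.column_stack(
            [
                (dr["group"] == "preterm").to_numpy(dtype=float),
                dr["age"].to_numpy(dtype=float),
                (dr["sex"] == "M").to_numpy(dtype=float),
            ]
        )
        X = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"collinear design in region {region!r}")
        fit = sm.OLS(dr["value"].to_numpy(dtype=float), X).fit()
        rows.append({"region": region, "beta_group": fit.params[1], "p": fit.pvalues[1]})
    out = pd.DataFrame(rows).set_index("region")
    out["p_fdr"] = bh_fdr(out["p"])
    out["significant"] = out["p_fdr"] < alpha
    return out


def overlap_percentages(
    profiles: DeviationProfile,
    groups: pd.Series | None = None,
    directions: tuple = ("infra", "supra", "either"),
    timepoint=None,
) -> pd.DataFrame:
    """Percentage of subjects extranormal per (region, group, direction).

    ``groups`` maps subject_id -> group label; omit it to treat all subjects
    as one group.  Missing-score subjects are excluded from both numerator
    and denominator of the affected region.
    """
    labels = profiles.label_matrix(timepoint=timepoint)
    if labels.empty:
        raise ValueError("empty profile set")
    if groups is None:
        groups = pd.Series("all", index=labels.index)
    groups = groups.reindex(labels.index)

    rows = []
    for gname, idx in labels.groupby(groups).groups.items():
        sub = labels.loc[idx]
        if sub.empty:
            raise ValueError(f"empty group {gname!r}")
        for region in sub.columns:
            col = sub[region]
            present = col != "missing"
            denom = int(present.sum())
            for direction in directions:
                if direction == "either":
                    num = int(col.isin(["infra", "supra"]).sum())
                else:
                    num = int((col == direction).sum())
                pct = 100.0 * num / denom if denom else np.nan
                rows.append(
                    {
                        "region": region,
                        "group": gname,
                        "direction": direction,
                        "pct": pct,
                        "n": denom,
                    }
                )
    return pd.DataFrame(rows)


def binarize_profiles(profiles, timepoint=None, measure=None) -> pd.DataFrame:
    """Subjects x regions binary matrix: 1 = extranormal (infra or supra).

    Accepts a :class:`DeviationProfile` or an already-binary matrix
    (idempotent).  Excluded (missing) regions are dropped column-wise when
    every subject misses them, otherwise encoded as NaN.
    """
    if isinstance(profiles, pd.DataFrame):
        arr = profiles.to_numpy(dtype=float)
        return pd.DataFrame(
            (arr != 0).astype(float), index=profiles.index, columns=profiles.columns
        )
    labels = profiles.label_matrix(timepoint=timepoint, measure=measure)
    binary = labels.isin(["infra", "supra"]).astype(float)
    binary[labels == "missing"] = np.nan
    all_missing = binary.isna().all(axis=0)
    return binary.loc[:, ~all_missing]


def profile_similarity(binary: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise Spearman similarity of binary profiles, plus per-subject means.

    Ties are midranked, so on 0/1 data Spearman coincides with the phi
    coefficient.  Zero-variance rows (all-normal subjects) yield NaN entries
    and are excluded from the per-subject means; the diagonal is excluded.
    """
    mat = binary.to_numpy(dtype=float)
    variable = np.nanstd(mat, axis=1) > 0
    if variable.sum() < 2:
        raise ValueError("need >= 2 subjects with non-constant binary profiles")
    n_flat = int((~variable).sum())
    if n_flat:
        log.info("%d all-normal subjects excluded from similarity means", n_flat)

    n = mat.shape[0]
    sim = np.full((n, n), np.nan)
    idx = np.where(variable)[0]
    r = rank_corr_rows(mat[idx][:, None, :], mat[idx][None, :, :])
    sim[np.ix_(idx, idx)] = r
    np.fill_diagonal(sim, np.nan)
    simdf = pd.DataFrame(sim, index=binary.index, columns=binary.index)
    means = simdf.mean(axis=1, skipna=True)
    means[~variable] = np.nan
    return simdf, means
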