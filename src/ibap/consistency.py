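"""Extent and anatomical-location consistency of deviation profiles.

Extent: Spearman correlation of per-subject extranormal counts with
gestational age, with percentile-bootstrap CIs and BH-FDR across the tested
set, plus GA-threshold subgrouping of overlap percentages.

Location: two-timepoint persistence of extranormal deviations and per-region
ICC(3,1) of continuous deviation scores.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .heterogeneity import overlap_percentages
from .normative import DeviationProfile
from .stats import bh_fdr, spearman_test

log = logging.getLogger(__name__)

__all__ = [
    "extent_vs_ga",
    "ga_subgroup_overlap",
    "select_longitudinal_extranormal",
    "persistence_fraction",
    "regional_icc",
    "icc_table",
]

CLINICAL_BINS = ((-np.inf, 28.0), (28.0, 32.0), (32.0, np.inf))


def extent_vs_ga(
    profiles: DeviationProfile,
    ga: pd.Series,
    directions: tuple = ("infra", "supra"),
    timepoint=1,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Spearman of per-subject extranormal counts against GA, per direction.

    BH adjustment runs across the directions tested in this one call (the
    figure-equivalent analysis family).  Constant counts give missing rows.
    """
    counts = profiles.counts()
    counts = counts[counts["timepoint"] == timepoint].set_index("subject_id")
    ga = ga.reindex(counts.index)
    if ga.notna().sum() < 10:
        raise ValueError("need >= 10 subjects with GA")
    rows = []
    for direction in directions:
        col = {"infra": "n_infra", "supra": "n_supra", "either": "n_extranormal"}[direction]
        rho, p, ci, n = spearman_test(counts[col], ga, n_boot=n_boot, seed=seed)
        if not np.isfinite(rho):
            warnings.warn(f"constant {col}; rho undefined")
        rows.append(
            {"direction": direction, "rho": rho, "p": p, "ci_lo": ci[0], "ci_hi": ci[1], "n": n}
        )
    out = pd.DataFrame(rows).set_index("direction")
    out["p_fdr"] = bh_fdr(out["p"])
    return out


def ga_subgroup_overlap(
    profiles: DeviationProfile,
    ga: pd.Series,
    scheme: str = "cut30",
    timepoint=1,
) -> pd.DataFrame:
    """Overlap percentages per GA subgroup.

    ``scheme='cut30'`` splits earlier (GA <= 30) vs later birth (GA > 30);
    ``scheme='clinical'`` uses the {<=28, 28-32, >32} partition.  Empty bins
    are skipped with a warning.  Adds the per-subgroup maximum overlap.
    """
    labels = profiles.label_matrix(timepoint=timepoint)
    ga = ga.reindex(labels.index)
    if scheme == "cut30":
        bins = pd.Series(np.where(ga <= 30.0, "ga<=30", "ga>30"), index=labels.index)
    elif scheme == "clinical":
        def _bin(g):
            if g <= 28.0:
                return "ga<=28"
            return "28<ga<=32" if g <= 32.0 else "ga>32"

        bins = ga.map(_bin)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    frames = []
    for name in bins.dropna().unique():
        members = bins[bins == name].index
        if len(members) == 0:
            warnings.warn(f"empty GA bin {name!r}; skipped")
            continue
        sub = DeviationProfile(
            table=profiles.table[profiles.table["subject_id"].isin(members)],
            lower=profiles.lower,
            upper=profiles.upper,
            regions=profiles.regions,
        )
        tab = overlap_percentages(sub, timepoint=timepoint)
        tab["group"] = name
        tab["max_pct_in_group"] = tab.groupby("direction")["pct"].transform("max")
        frames.append(tab)
    if not frames:
        raise ValueError("all GA bins empty")
    return pd.concat(frames, ignore_index=True)


def select_longitudinal_extranormal(
    profiles: DeviationProfile,
    t1=1,
    t2=2,
    measure: str | None = None,
) -> pd.DataFrame:
    """(subject, region) pairs extranormal at >= 1 of the two timepoints.

    Subjects missing either timepoint are excluded (logged).  Returns one row
    per selected pair with the direction label at each timepoint.
    """
    l1 = profiles.label_matrix(timepoint=t1, measure=measure)
    l2 = profiles.label_matrix(timepoint=t2, measure=measure)
    common = l1.index.intersection(l2.index)
    dropped = len(l1.index.union(l2.index)) - len(common)
    if dropped:
        log.info("%d subjects missing one timepoint; excluded from persistence", dropped)
    l1, l2 = l1.loc[common], l2.loc[common]
    extr = l1.isin(["infra", "supra"]) | l2.isin(["infra", "supra"])
    subj, reg = np.where(extr.to_numpy())
    return pd.DataFrame(
        {
            "subject_id": l1.index.to_numpy()[subj],
            "region": l1.columns.to_numpy()[reg],
            "label_t1": l1.to_numpy()[subj, reg],
            "label_t2": l2.to_numpy()[subj, reg],
        }
    )


def persistence_fraction(pairs: pd.DataFrame, direction: str) -> float:
    """Percent of pairs extranormal in ``direction`` at t1 that stay so at t2.

    Direction flips (infra -> supra) count as not maintained.  Empty
    denominator returns NaN with a warning.
    """
    at_t1 = pairs[pairs["label_t1"] == direction]
    if at_t1.empty:
        warnings.warn(f"no pairs {direction!r} at t1; persistence undefined")
        return np.nan
    kept = (at_t1["label_t2"] == direction).sum()
    return 100.0 * float(kept) / float(len(at_t1))


def regional_icc(
    scores_t1: pd.Series,
    scores_t2: pd.Series,
    min_subjects: int = 5,
) -> dict:
    """ICC(3,1): two-way mixed, single rater, consistency, k = 2 timepoints.

    Computed from the two-way ANOVA mean squares:
    ``(MS_subjects - MS_error) / (MS_subjects + (k - 1) * MS_error)``,
    with the F-test ``MS_subjects / MS_error`` on (n-1, (n-1)(k-1)) df.
    Zero between-subject variance is reported as ICC = 0 with a flag.
    """
    joined = pd.concat([scores_t1, scores_t2], axis=1, keys=["t1", "t2"]).dropna()
    n = len(joined)
    if n < min_subjects:
        raise ValueError(f"need >= {min_subjects} complete subjects (got {n})")
    Y = joined.to_numpy(dtype=float)  # (n, 2)
    k = Y.shape[1]
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    time_means = Y.mean(axis=0)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_time = n * np.sum((time_means - grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_time
    ms_subj = ss_subj / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))

    flagged = False
    if ms_subj <= 0 or (ms_subj + (k - 1) * ms_err) <= 0:
        icc, p, flagged = 0.0, np.nan, True
    else:
        icc = (ms_subj - ms_err) / (ms_subj + (k - 1) * ms_err)
        if ms_err <= 0:
            p = 0.0
        else:
            f = ms_subj / ms_err
            p = float(sps.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return {"icc": float(icc), "p": p, "n": n, "flagged": flagged}


def icc_table(
    profiles: DeviationProfile,
    t1=1,
    t2=2,
    measure: str | None = None,
    selected_only: bool = False,
    min_subjects: int = 5,
) -> pd.DataFrame:
    """Per-region ICC(3,1) of deviation scores across the two timepoints.

    By default all longitudinal subjects enter; ``selected_only=True``
    restricts each region to subjects extranormal there at >= 1 timepoint.
    """
    s1 = profiles.score_matrix(timepoint=t1, measure=measure)
    s2 = profiles.score_matrix(timepoint=t2, measure=measure)
    common = s1.index.intersection(s2.index)
    s1, s2 = s1.loc[common], s2.loc[common]
    selected = None
    if selected_only:
        selected = select_longitudinal_extranormal(profiles, t1=t1, t2=t2, measure=measure)
    rows = []
    for region in s1.columns:
        a, b = s1[region], s2[region]
        if selected is not None:
            keep = selected.loc[selected["region"] == region, "subject_id"]
            a, b = a.loc[a.index.isin(keep)], b.loc[b.index.isin(keep)]
        try:
            res = regional_icc(a, b, min_subjects=min_subjects)
        except ValueError:
            res = {"icc": np.nan, "p": np.nan, "n": int(min(a.notna().sum(), b.notna().sum())), "flagged": True}
        res["region"] = region
        rows.append(res)
    return pd.DataFrame(rows).set_index("region")[["icc", "p", "n", "flagged"]]
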