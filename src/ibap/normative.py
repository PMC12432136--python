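"""Normative reference charts and percentile deviation scoring.

Per (region, sex) the chart is a sinh-arcsinh distribution whose location is
quadratic in log-age, whose log-scale is linear in log-age, and whose skewness
is constant; per study an additive location offset is adapted on term-born
subjects only.  A subject's deviation score for a region is the chart CDF
evaluated at the (offset-corrected) observed value — a percentile in (0, 1).
Scores below 0.05 are labelled infranormal, above 0.95 supranormal (strict
inequalities; exact boundary ties are normal).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .regions import DK34_REGIONS, SEXES
from .shash import shash_cdf, shash_nll, shash_ppf

log = logging.getLogger(__name__)

__all__ = [
    "ChartParams",
    "NormativeChart",
    "DeviationProfile",
    "age_in_days",
    "fit_reference_charts",
    "adapt_study_offset",
    "compute_deviation_scores",
    "classify_extranormal",
]

#: default extranormal thresholds (5th / 95th percentile)
LOWER_THRESHOLD = 0.05
UPPER_THRESHOLD = 0.95

#: conception-to-birth offset assumed for postnatal ages given in years
_TERM_GESTATION_DAYS = 280.0
_DAYS_PER_YEAR = 365.25


def age_in_days(age, unit: str = "years") -> np.ndarray:
    """Map an age column onto the single internal axis: days since conception.

    ``unit='weeks'`` means postmenstrual weeks (neonatal regime);
    ``unit='years'`` means postnatal years, offset by a 40-week gestation.
    """
    age = np.asarray(age, dtype=float)
    if unit == "weeks":
        return age * 7.0
    if unit == "years":
        return _TERM_GESTATION_DAYS + age * _DAYS_PER_YEAR
    raise ValueError(f"unknown age unit {unit!r} (expected 'weeks' or 'years')")


def _ages_from_table(data: pd.DataFrame) -> np.ndarray:
    unit = data["age_unit"] if "age_unit" in data.columns else "years"
    if np.isscalar(unit) or isinstance(unit, str):
        return age_in_days(data["age"].to_numpy(), str(unit))
    out = np.empty(len(data), dtype=float)
    for u in pd.unique(unit):
        m = (unit == u).to_numpy()
        out[m] = age_in_days(data["age"].to_numpy()[m], str(u))
    return out


@dataclass
class ChartParams:
    """Fitted coefficients for one (region, sex) stratum.

    ``mu`` are polynomial coefficients of the location on the standardized
    log-age axis (low order first), ``log_sigma`` likewise for the log-scale,
    ``nu`` is the constant skewness.
    """

    mu: np.ndarray
    log_sigma: np.ndarray
    nu: float
    converged: bool = True
    nll: float = np.nan


def _design(t: np.ndarray, df: int) -> np.ndarray:
    return np.vander(t, N=df, increasing=True)


def _poly_eval_linear_ext(coef: np.ndarray, t: np.ndarray, t_lo: float, t_hi: float) -> np.ndarray:
    """Evaluate a polynomial, extending linearly beyond [t_lo, t_hi]."""
    t = np.asarray(t, dtype=float)
    tc = np.clip(t, t_lo, t_hi)
    val = np.polynomial.polynomial.polyval(tc, coef)
    deriv = np.polynomial.polynomial.polyval(tc, np.polynomial.polynomial.polyder(coef))
    return val + deriv * (t - tc)


@dataclass
class NormativeChart:
    """Per-region, per-sex distributional parameters over age, plus study offsets."""

    measure: str
    params: dict = field(default_factory=dict)  # (region, sex) -> ChartParams
    study_offsets: dict = field(default_factory=dict)  # study -> float
    age_center: float = 0.0  # on log(days since conception)
    age_scale: float = 1.0
    support: tuple = (0.0, 0.0)  # (min, max) age in days seen at fit time
    excluded: frozenset = frozenset()
    support_tolerance: float = 0.02  # fraction of support width tolerated beyond the edges
    regions: tuple = DK34_REGIONS

    # ---- parameter curves -------------------------------------------------
    def _t(self, age_days: np.ndarray) -> np.ndarray:
        return (np.log(np.asarray(age_days, dtype=float)) - self.age_center) / self.age_scale

    def _t_bounds(self) -> tuple[float, float]:
        lo, hi = self.support
        return float(self._t(np.array([lo]))[0]), float(self._t(np.array([hi]))[0])

    def curves(self, region: str, sex: str, age_days) -> tuple[np.ndarray, np.ndarray, float]:
        """(mu, sigma, nu) at the given ages; linear extension outside support."""
        cp = self.params[(region, sex)]
        t = self._t(np.atleast_1d(age_days))
        t_lo, t_hi = self._t_bounds()
        mu = _poly_eval_linear_ext(cp.mu, t, t_lo, t_hi)
        sigma = np.exp(_poly_eval_linear_ext(cp.log_sigma, t, t_lo, t_hi))
        return mu, sigma, cp.nu

    def check_support(self, age_days: np.ndarray, subjects=None) -> None:
        lo, hi = self.support
        tol = self.support_tolerance * (hi - lo)
        age_days = np.asarray(age_days, dtype=float)
        bad = (age_days < lo - tol) | (age_days > hi + tol)
        if np.any(bad):
            who = ""
            if subjects is not None:
                who = ": " + ", ".join(map(str, pd.unique(np.asarray(subjects)[bad])[:5]))
            raise ValueError(
                f"ages outside chart support [{lo:.1f}, {hi:.1f}] days "
                f"(tolerance {tol:.1f}){who}"
            )

    def offset(self, study: str, on_unknown: str = "error") -> float:
        if study in self.study_offsets:
            return self.study_offsets[study]
        if on_unknown == "zero":
            warnings.warn(f"no adapted offset for study {study!r}; using 0", stacklevel=2)
            return 0.0
        raise KeyError(f"no adapted offset for study {study!r}")

    def cdf(self, region, sex, age_days, value, study=None, on_unknown_study="error"):
        u = 0.0 if study is None else self.offset(study, on_unknown_study)
        mu, sigma, nu = self.curves(region, sex, age_days)
        return shash_cdf(np.asarray(value, dtype=float) - u, mu, sigma, nu)

    def quantile(self, region, sex, age_days, p, study=None, on_unknown_study="error"):
        u = 0.0 if study is None else self.offset(study, on_unknown_study)
        mu, sigma, nu = self.curves(region, sex, age_days)
        return shash_ppf(p, mu, sigma, nu) + u

    # ---- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "age_center": self.age_center,
            "age_scale": self.age_scale,
            "support": list(self.support),
            "support_tolerance": self.support_tolerance,
            "excluded": sorted(self.excluded),
            "regions": list(self.regions),
            "study_offsets": dict(self.study_offsets),
            "params": {
                f"{r}|{s}": {
                    "mu": cp.mu.tolist(),
                    "log_sigma": cp.log_sigma.tolist(),
                    "nu": cp.nu,
                    "converged": bool(cp.converged),
                }
                for (r, s), cp in self.params.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeChart":
        params = {}
        for key, cp in d["params"].items():
            r, s = key.split("|")
            params[(r, s)] = ChartParams(
                mu=np.asarray(cp["mu"], dtype=float),
                log_sigma=np.asarray(cp["log_sigma"], dtype=float),
                nu=float(cp["nu"]),
                converged=bool(cp["converged"]),
            )
        return cls(
            measure=d["measure"],
            params=params,
            study_offsets={k: float(v) for k, v in d["study_offsets"].items()},
            age_center=float(d["age_center"]),
            age_scale=float(d["age_scale"]),
            support=tuple(d["support"]),
            excluded=frozenset(d["excluded"]),
            support_tolerance=float(d["support_tolerance"]),
            regions=tuple(d["regions"]),
        )

    @classmethod
    def from_json(cls, path) -> "NormativeChart":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _fit_stratum(
    x: np.ndarray,
    t: np.ndarray,
    df_location: int,
    df_scale: int,
    fix_nu: float | None,
    n_restarts: int,
    rng: np.random.Generator,
) -> ChartParams:
    """Maximum-likelihood fit of one (region, sex) stratum.

    Deterministic start from OLS, followed by random restarts; best NLL wins.
    """
    B = _design(t, df_location)
    b0, *_ = np.linalg.lstsq(B, x, rcond=None)
    resid = x - B @ b0
    s0 = max(float(np.std(resid)), 1e-6)

    free_nu = fix_nu is None

    def unpack(theta):
        mu = B @ theta[:df_location]
        log_sigma = _design(t, df_scale) @ theta[df_location:df_location + df_scale]
        nu = theta[-1] if free_nu else fix_nu
        return mu, np.exp(np.clip(log_sigma, -30.0, 30.0)), nu

    # weak ridge on the shape and scale-slope coefficients: stabilizes the
    # tails at modest stratum sizes without visibly biasing the centiles
    tau_nu, tau_slope = 0.15, 0.1

    def nll(theta):
        mu, sigma, nu = unpack(theta)
        with np.errstate(over="ignore", invalid="ignore"):
            val = shash_nll(x, mu, sigma, nu)
        if free_nu:
            val += 0.5 * (nu / tau_nu) ** 2
        val += 0.5 * float(np.sum((theta[df_location + 1:df_location + df_scale] / tau_slope) ** 2))
        return val if np.isfinite(val) else 1e12

    start = np.concatenate(
        [b0, [np.log(s0)], np.zeros(df_scale - 1), [0.0] if free_nu else []]
    )
    starts = [start]
    for _ in range(n_restarts):
        jitter = rng.normal(scale=0.1, size=start.size)
        jitter[:df_location] *= s0  # perturb location coefs on the data scale
        starts.append(start + jitter)

    best = None
    for s in starts:
        res = minimize(nll, s, method="L-BFGS-B", options={"maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    mu_c = best.x[:df_location]
    ls_c = best.x[df_location:df_location + df_scale].copy()
    # residual-df correction of the ML scale (analog of SSR/(n-p) vs SSR/n),
    # counting every estimated parameter
    n = x.size
    k_total = df_location + df_scale + int(free_nu)
    if n > k_total:
        ls_c[0] += 0.5 * np.log(n / (n - k_total))
    nu = float(best.x[-1]) if free_nu else float(fix_nu)
    converged = bool(best.success) and np.isfinite(best.fun)
    return ChartParams(mu=mu_c, log_sigma=ls_c, nu=nu, converged=converged, nll=float(best.fun))


def fit_reference_charts(
    data: pd.DataFrame,
    measure: str = "CTh",
    family: str = "shash",
    df_location: int = 3,
    df_scale: int = 2,
    n_restarts: int = 3,
    seed: int = 0,
    exclude_regions=(),
    min_per_sex: int = 20,
) -> NormativeChart:
    """Fit per-region, per-sex normative charts on term-born data.

    ``family='shash'`` fits location, scale and skewness; ``family='gaussian'``
    fixes ``nu = 0`` (and with ``df_scale=1`` reduces to homoscedastic OLS).
    Non-convergent regions are flagged and added to the exclusion mask.
    """
    if family not in ("shash", "gaussian"):
        raise ValueError(f"unknown family {family!r}")
    fix_nu = 0.0 if family == "gaussian" else None

    d = data[(data["group"] == "term") & (data["measure"] == measure)]
    if d.empty:
        raise ValueError("no term-born rows for this measure")
    for sex in SEXES:
        n = d.loc[d["sex"] == sex, "subject_id"].nunique()
        if n == 0:
            raise ValueError(f"empty sex stratum {sex!r}: charts are stratified by sex")
        if n < min_per_sex:
            raise ValueError(f"only {n} term subjects with sex={sex}; need >= {min_per_sex}")

    age_days = _ages_from_table(d)
    la = np.log(age_days)
    center, scale = float(np.mean(la)), float(np.std(la))
    if scale < 1e-9:
        scale = 1.0  # single-age designs: location/scale become intercept-only
    chart = NormativeChart(
        measure=measure,
        age_center=center,
        age_scale=scale,
        support=(float(age_days.min()), float(age_days.max())),
        excluded=frozenset(exclude_regions),
    )

    rng = np.random.default_rng(seed)
    t_all = (la - center) / scale
    excluded = set(exclude_regions)
    regions = [r for r in pd.unique(d["region"]) if r not in excluded]
    for region in regions:
        for sex in SEXES:
            m = ((d["region"] == region) & (d["sex"] == sex)).to_numpy()
            x = d.loc[m, "value"].to_numpy(dtype=float)
            t = t_all[m]
            if np.linalg.matrix_rank(_design(t, df_location)) < df_location:
                raise ValueError(f"singular age design for region {region!r}, sex {sex!r}")
            cp = _fit_stratum(x, t, df_location, df_scale, fix_nu, n_restarts, rng)
            chart.params[(region, sex)] = cp
            if not cp.converged:
                excluded.add(region)
                log.warning("region %s (%s) did not converge; excluded", region, sex)
    chart.excluded = frozenset(excluded)
    return chart


def adapt_study_offset(
    chart: NormativeChart,
    data: pd.DataFrame,
    study: str,
    min_subjects: int = 10,
) -> NormativeChart:
    """Register an additive location offset for one study.

    The offset is the median of term-born residuals on the location scale;
    preterm subjects never enter the estimate.
    """
    d = data[(data["study"] == study) & (data["measure"] == chart.measure)]
    if d.empty:
        raise ValueError(f"no rows for study {study!r}")
    term = d[d["group"] == "term"]
    if term.empty:
        raise ValueError("offset requires term-born data")
    if term["subject_id"].nunique() < min_subjects:
        raise ValueError(
            f"only {term['subject_id'].nunique()} term subjects in study {study!r}; "
            f"need >= {min_subjects}"
        )
    age_days = _ages_from_table(term)
    chart.check_support(age_days, term["subject_id"].to_numpy())
    resid = np.empty(len(term), dtype=float)
    values = term["value"].to_numpy(dtype=float)
    for (region, sex), idx in term.groupby(["region", "sex"], observed=True).indices.items():
        if region in chart.excluded or (region, sex) not in chart.params:
            resid[idx] = np.nan
            continue
        mu, _, _ = chart.curves(region, sex, age_days[idx])
        resid[idx] = values[idx] - mu
    u = float(np.nanmedian(resid))
    new = replace(chart, study_offsets=dict(chart.study_offsets))
    new.study_offsets[study] = u
    return new


# ---------------------------------------------------------------------------
# deviation profiles
# ---------------------------------------------------------------------------

LABELS = ("infra", "normal", "supra", "missing")


@dataclass
class DeviationProfile:
    """Tidy per-(subject, timepoint, measure, region) deviation scores.

    ``table`` columns: subject_id, timepoint, measure, region, score, label.
    Scores lie in (0, 1); excluded-region scores are NaN with label 'missing'.
    """

    table: pd.DataFrame
    lower: float = LOWER_THRESHOLD
    upper: float = UPPER_THRESHOLD
    regions: tuple = DK34_REGIONS

    def score_matrix(self, measure: str | None = None, timepoint=None) -> pd.DataFrame:
        """Subjects x regions wide matrix of deviation scores."""
        t = self._subset(measure, timepoint)
        mat = t.pivot_table(index="subject_id", columns="region", values="score")
        cols = [r for r in self.regions if r in mat.columns]
        return mat[cols]

    def label_matrix(self, measure: str | None = None, timepoint=None) -> pd.DataFrame:
        t = self._subset(measure, timepoint)
        mat = t.pivot(index="subject_id", columns="region", values="label")
        cols = [r for r in self.regions if r in mat.columns]
        return mat[cols]

    def counts(self) -> pd.DataFrame:
        """Per (subject, timepoint, measure): n_infra, n_supra, n_extranormal."""
        t = self.table
        g = t.groupby(["subject_id", "timepoint", "measure"], observed=True)["label"]
        out = pd.DataFrame(
            {
                "n_infra": g.apply(lambda s: int((s == "infra").sum())),
                "n_supra": g.apply(lambda s: int((s == "supra").sum())),
            }
        )
        out["n_extranormal"] = out["n_infra"] + out["n_supra"]
        return out.reset_index()

    def _subset(self, measure, timepoint) -> pd.DataFrame:
        t = self.table
        if measure is not None:
            t = t[t["measure"] == measure]
        if timepoint is not None:
            t = t[t["timepoint"] == timepoint]
        return t

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compute_deviation_scores(
    chart: NormativeChart,
    data: pd.DataFrame,
    on_unknown_study: str = "error",
) -> DeviationProfile:
    """Convert observed values to chart-CDF deviation scores.

    Excluded regions yield NaN scores.  Raises if a subject's age falls beyond
    the chart support tolerance or (configurably) if a study has no offset.
    """
    d = data[data["measure"] == chart.measure].copy()
    if d.empty:
        raise ValueError(f"no rows for measure {chart.measure!r}")
    age_days = _ages_from_table(d)
    chart.check_support(age_days, d["subject_id"].to_numpy())

    scores = np.full(len(d), np.nan)
    values = d["value"].to_numpy(dtype=float)
    for (region, sex, study), idx in d.groupby(
        ["region", "sex", "study"], observed=True
    ).indices.items():
        if region in chart.excluded or (region, sex) not in chart.params:
            continue
        s = chart.cdf(region, sex, age_days[idx], values[idx], study, on_unknown_study)
        scores[idx] = np.clip(s, 1e-12, 1.0 - 1e-12)

    table = pd.DataFrame(
        {
            "subject_id": d["subject_id"].to_numpy(),
            "timepoint": d["timepoint"].to_numpy() if "timepoint" in d else 1,
            "measure": chart.measure,
            "region": d["region"].to_numpy(),
            "score": scores,
        }
    )
    profile = DeviationProfile(table=table, regions=chart.regions)
    return classify_extranormal(profile)


def classify_extranormal(
    profile: DeviationProfile,
    lower: float = LOWER_THRESHOLD,
    upper: float = UPPER_THRESHOLD,
) -> DeviationProfile:
    """Attach {infra, normal, supra, missing} labels (strict thresholds)."""
    if not (0.0 < lower < upper < 1.0):
        raise ValueError("need 0 < lower < upper < 1")
    s = profile.table["score"]
    label = np.where(s < lower, "infra", np.where(s > upper, "supra", "normal"))
    label = np.where(s.isna(), "missing", label)
    out = profile.table.copy()
    out["label"] = label
    return DeviationProfile(table=out, lower=lower, upper=upper, regions=profile.regions)
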