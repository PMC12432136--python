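"""Multi-cohort synthetic data generator with recorded ground truth.

Generates morphometry tables (term + preterm, one or two timepoints), a
gene x region expression matrix with marker-gene sets, and parcel centroids,
with every generating parameter recorded in a :class:`GroundTruth` so that
downstream stages can be tested by parameter recovery:

* term subjects are drawn from a known normative chart family;
* each preterm subject receives ``K ~ Poisson(lam0 + lam1 * max(0, 40 - GA))``
  target regions, sampled with probability proportional to the softmax of a
  GA-interpolated mixture of latent cell-type maps, and placed in the chart's
  own tails via its quantile function;
* at a second timepoint targets persist with a known probability;
* SES injects a global value shift ``a*ses + b*ses*(40 - GA)`` and cognition
  is coupled to the subject's mean deviation score.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy.special import ndtr, ndtri

from .normative import ChartParams, NormativeChart, age_in_days, compute_deviation_scores
from .regions import CELL_TYPES, DK34_REGIONS, N_REGIONS, SEXES
from .spatial_null import ParcelGeometry, fibonacci_sphere

log = logging.getLogger(__name__)

__all__ = [
    "GroundTruth",
    "SyntheticBundle",
    "default_truth",
    "simulate_cohort",
    "simulate_expression",
    "simulate_outcomes",
]

SES_LEVELS = ("low", "middle", "high")
SES_CODES = {"low": 1, "middle": 2, "high": 3}


@dataclass
class GroundTruth:
    """All generating parameters of a synthetic bundle."""

    chart: NormativeChart
    geometry: ParcelGeometry
    latent_maps: dict  # cell type -> (n_regions,) standardized abundance map
    lam0: float = 0.5
    lam1: float = 0.8
    placement_weights: dict = field(default_factory=dict)  # cell type -> (w0, ga_slope)
    placement_concentration: float = 2.0
    persistence_prob: float = 0.85
    score_autocorr: float | None = None  # t1-t2 Gaussian-copula corr of body scores;
    # None ties it to persistence_prob (one knob for longitudinal stability)
    direction_mix: float = 0.5  # probability a target deviation is supranormal
    ses_main: float = 0.0  # 'a': value shift per SES code
    ses_ga_interaction: float = 0.0  # 'b': value shift per SES code per week before 40
    cognition_coupling: float = 0.0
    cognition_noise_sd: float = 10.0
    seed: int = 0
    region_names: tuple = DK34_REGIONS

    def __post_init__(self):
        if self.lam0 < 0 or self.lam1 < 0:
            raise ValueError("lam0 and lam1 must be nonnegative")
        if not 0.0 <= self.persistence_prob <= 1.0:
            raise ValueError("persistence_prob must lie in [0, 1]")
        if not 0.0 <= self.direction_mix <= 1.0:
            raise ValueError("direction_mix must lie in [0, 1]")
        if self.placement_weights:
            total = sum(w for w, _ in self.placement_weights.values())
            if total <= 0:
                raise ValueError("mixing weights must have positive sum")
            self.placement_weights = {
                ct: (w / total, s) for ct, (w, s) in self.placement_weights.items()
            }

    def extranormal_rate(self, ga_weeks) -> np.ndarray:
        """lambda(GA) = lam0 + lam1 * max(0, 40 - GA); Poisson mean of targets."""
        ga = np.asarray(ga_weeks, dtype=float)
        return self.lam0 + self.lam1 * np.maximum(0.0, 40.0 - ga)

    def placement_probs(self, ga_weeks: float) -> np.ndarray:
        """Region sampling probabilities: softmax of the GA-interpolated map mixture."""
        if not self.placement_weights:
            return np.full(N_REGIONS, 1.0 / N_REGIONS)
        w = np.array(
            [
                max(w0 + slope * max(0.0, 40.0 - ga_weeks), 0.0)
                for w0, slope in self.placement_weights.values()
            ]
        )
        if w.sum() <= 0:
            return np.full(N_REGIONS, 1.0 / N_REGIONS)
        w = w / w.sum()
        maps = np.stack([self.latent_maps[ct] for ct in self.placement_weights])
        mix = w @ maps
        e = np.exp(self.placement_concentration * (mix - mix.max()))
        return e / e.sum()

    def to_json(self, path) -> None:
        d = {
            "chart": self.chart.to_dict(),
            "geometry": self.geometry.to_frame().to_dict(orient="list"),
            "latent_maps": {k: np.asarray(v).tolist() for k, v in self.latent_maps.items()},
            "lam0": self.lam0,
            "lam1": self.lam1,
            "placement_weights": {k: list(v) for k, v in self.placement_weights.items()},
            "placement_concentration": self.placement_concentration,
            "persistence_prob": self.persistence_prob,
            "direction_mix": self.direction_mix,
            "ses_main": self.ses_main,
            "ses_ga_interaction": self.ses_ga_interaction,
            "cognition_coupling": self.cognition_coupling,
            "cognition_noise_sd": self.cognition_noise_sd,
            "seed": self.seed,
            "region_names": list(self.region_names),
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


@dataclass
class SyntheticBundle:
    """Morphometry + expression + geometry + the truth that generated them."""

    morphometry: pd.DataFrame
    truth: GroundTruth
    injections: pd.DataFrame  # ground-truth target regions per subject/timepoint
    expression: pd.DataFrame | None = None
    marker_sets: dict | None = None

    @property
    def centroids(self) -> ParcelGeometry:
        return self.truth.geometry

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.morphometry.to_csv(out / "morphometry.csv", index=False)
        self.injections.to_csv(out / "injections.csv", index=False)
        self.centroids.to_csv(out / "centroids.csv")
        self.truth.to_json(out / "truth.json")
        if self.expression is not None:
            self.expression.to_csv(out / "expression.csv")
        if self.marker_sets is not None:
            with open(out / "marker_sets.json", "w") as fh:
                json.dump(self.marker_sets, fh, indent=1)


# ---------------------------------------------------------------------------
# ground-truth factory
# ---------------------------------------------------------------------------

def _truth_chart(
    rng: np.random.Generator,
    age_range: tuple[float, float],
    age_unit: str,
    measure: str,
    study: str,
    study_offset: float,
) -> NormativeChart:
    lo, hi = age_in_days(np.asarray(age_range, dtype=float), age_unit)
    la_lo, la_hi = np.log(lo), np.log(hi)
    center = 0.5 * (la_lo + la_hi)
    scale = max((la_hi - la_lo) / (2.0 * np.sqrt(3.0)), 1e-3)  # sd of U(log lo, log hi)
    chart = NormativeChart(
        measure=measure,
        age_center=center,
        age_scale=scale,
        support=(float(lo), float(hi)),
        study_offsets={study: study_offset},
    )
    for region in DK34_REGIONS:
        base = rng.uniform(1.8, 3.2)  # mm-scale regional means
        for sex in SEXES:
            b0 = base + rng.normal(0.0, 0.05)
            b1 = rng.normal(0.0, 0.05)
            b2 = rng.normal(0.0, 0.02)
            c0 = np.log(rng.uniform(0.08, 0.16))
            c1 = rng.normal(0.0, 0.05)
            nu = rng.normal(0.0, 0.10)
            chart.params[(region, sex)] = ChartParams(
                mu=np.array([b0, b1, b2]), log_sigma=np.array([c0, c1]), nu=float(nu)
            )
    return chart


def _latent_cell_maps(
    rng: np.random.Generator, geometry: ParcelGeometry, length_scale: float
) -> dict:
    """Spatially autocorrelated latent maps: Gaussian kernel on chord distance."""
    X = geometry.xyz
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2)
    K = np.exp(-d2 / (2.0 * length_scale**2)) + 1e-8 * np.eye(len(geometry))
    L = np.linalg.cholesky(K)
    raw = L @ rng.normal(size=(len(geometry), len(CELL_TYPES)))
    # orthogonalize across cell types: linear combinations of GP draws stay
    # spatially smooth, and zero pairwise correlation keeps placement-recovery
    # tests well-posed (no chance collinearity between latent maps)
    raw = raw - raw.mean(axis=0)
    Q, _ = np.linalg.qr(raw)
    signs = np.sign(np.einsum("ij,ij->j", Q, raw))
    Q = Q * np.where(signs == 0, 1.0, signs)
    maps = {}
    for i, ct in enumerate(CELL_TYPES):
        m = Q[:, i] - Q[:, i].mean()
        maps[ct] = m / m.std()
    return maps


#: default placement mixture: OPC/astro/endo weight grows toward earlier birth,
#: mature oligodendrocytes weight grows toward term
DEFAULT_PLACEMENT = {
    "opc": (0.15, 0.03),
    "astro": (0.15, 0.03),
    "endo": (0.15, 0.03),
    "oligo": (0.55, -0.035),
}


def default_truth(
    seed: int = 0,
    age_range: tuple[float, float] = (24.0, 30.0),
    age_unit: str = "years",
    measure: str = "CTh",
    study: str = "synth",
    study_offset: float = 0.0,
    length_scale: float = 0.6,
    **overrides,
) -> GroundTruth:
    """Build a complete ground truth: chart, geometry, latent maps, effect laws."""
    ss = np.random.SeedSequence(seed)
    rng_chart, rng_geo, rng_maps = (np.random.default_rng(s) for s in ss.spawn(3))
    chart = _truth_chart(rng_chart, age_range, age_unit, measure, study, study_offset)
    geometry = fibonacci_sphere(N_REGIONS, seed=int(rng_geo.integers(2**31)))
    latent = _latent_cell_maps(rng_maps, geometry, length_scale)
    kw = dict(placement_weights=dict(DEFAULT_PLACEMENT))
    kw.update(overrides)
    return GroundTruth(chart=chart, geometry=geometry, latent_maps=latent, seed=seed, **kw)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    truth: GroundTruth,
    n_term: int,
    n_preterm: int,
    n_timepoints: int = 1,
    age_range: tuple[float, float] | None = None,
    age_unit: str = "years",
    study: str = "synth",
    preterm_ga_range: tuple[float, float] = (24.0, 36.9),
    followup_gap: float | None = None,
    obs_noise_sd: float = 0.0,
    min_term_per_sex: int = 20,
    seed: int | None = None,
) -> SyntheticBundle:
    """Simulate a term + preterm cohort from the ground truth.

    Tail placement uses the chart's own quantile function: target-region CDF
    values are drawn uniformly from (0, 0.05) or (0.95, 1), every other value
    uniformly from (0, 1), so the generating model is exactly calibrated.
    """
    if n_timepoints not in (1, 2):
        raise ValueError("n_timepoints must be 1 or 2")
    if obs_noise_sd < 0:
        raise ValueError("obs_noise_sd must be nonnegative")
    n_per_sex = {s: (n_term + i) // 2 for i, s in enumerate(SEXES)}
    if n_term > 0 and min(n_per_sex.values()) == 0:
        raise ValueError("empty sex stratum among term subjects")
    if n_term > 0 and min(n_per_sex.values()) < min_term_per_sex:
        raise ValueError(
            f"need >= {min_term_per_sex} term subjects per sex for fittable charts "
            f"(got {min(n_per_sex.values())}); lower min_term_per_sex to override"
        )
    if age_range is None:
        lo, hi = truth.chart.support
        if age_unit == "weeks":
            age_range = (lo / 7.0, hi / 7.0)
        else:
            age_range = ((lo - 280.0) / 365.25, (hi - 280.0) / 365.25)
    if followup_gap is None:
        followup_gap = 2.0 if age_unit == "years" else 2.0  # years or weeks

    base_seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence((base_seed, 101)))
    chart = truth.chart
    offset = chart.study_offsets.get(study, 0.0)
    regions = list(truth.region_names)

    subjects = []
    for i in range(n_term):
        subjects.append((f"T{i + 1:04d}", "term", SEXES[i % 2]))
    for i in range(n_preterm):
        subjects.append((f"P{i + 1:04d}", "preterm", SEXES[i % 2]))

    rows = []
    inj_rows = []
    age_lo = min(age_range)
    age_hi = max(age_range)
    if n_timepoints == 2:
        # keep follow-up ages inside the chart support
        age_hi = max(age_lo + 1e-6, age_hi - followup_gap)
    for sid, group, sex in subjects:
        age1 = rng.uniform(age_lo, age_hi)
        if group == "term":
            ga = rng.uniform(37.0, 42.0)
            targets = np.empty(0, dtype=int)
        else:
            ga = rng.uniform(*preterm_ga_range)
            k = int(rng.poisson(truth.extranormal_rate(ga)))
            if k > N_REGIONS:
                log.warning("subject %s: K=%d > %d target regions; clipped", sid, k, N_REGIONS)
                k = N_REGIONS
            probs = truth.placement_probs(ga)
            targets = rng.choice(N_REGIONS, size=k, replace=False, p=probs) if k else np.empty(0, dtype=int)
        directions = {
            int(r): ("supra" if rng.uniform() < truth.direction_mix else "infra") for r in targets
        }
        retained = {int(r): (rng.uniform() < truth.persistence_prob) for r in targets}
        r_auto = (
            truth.persistence_prob if truth.score_autocorr is None else truth.score_autocorr
        )

        p_prev: dict[int, float] = {}
        for tp in range(1, n_timepoints + 1):
            age = age1 if tp == 1 else age1 + followup_gap
            age_days = age_in_days(age, age_unit)
            for j, region in enumerate(regions):
                is_target = j in directions and (tp == 1 or retained[j])
                if is_target:
                    if directions[j] == "supra":
                        p = rng.uniform(0.95, 1.0)
                    else:
                        p = rng.uniform(0.0, 0.05)
                elif tp == 1 or j in directions:
                    # fresh body draw (dropped targets resolve independently)
                    p = rng.uniform(0.0, 1.0)
                else:
                    # within-subject stability: Gaussian copula on the t1 draw
                    # keeps the marginal exactly uniform
                    z1 = ndtri(p_prev[j])
                    z2 = r_auto * z1 + np.sqrt(1.0 - r_auto**2) * rng.normal()
                    p = float(ndtr(z2))
                p = min(max(p, 1e-12), 1.0 - 1e-12)
                if tp == 1:
                    p_prev[j] = p
                value = float(np.asarray(chart.quantile(region, sex, age_days, p)).item()) + offset
                if obs_noise_sd > 0:
                    value += rng.normal(0.0, obs_noise_sd)
                rows.append(
                    (sid, study, tp, age, age_unit, sex, group, ga, region, chart.measure, value)
                )
                if is_target:
                    inj_rows.append((sid, tp, region, directions[j]))

    morph = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "study", "timepoint", "age", "age_unit", "sex",
            "group", "ga_weeks", "region", "measure", "value",
        ],
    )
    for col in ("ses", "piri", "cognition"):
        morph[col] = np.nan
    injections = pd.DataFrame(inj_rows, columns=["subject_id", "timepoint", "region", "direction"])
    return SyntheticBundle(morphometry=morph, truth=truth, injections=injections)


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

_GENE_PREFIX = {
    "astro": "AST", "endo": "END", "micro": "MIC", "neuro-ex": "NEX",
    "neuro-in": "NIN", "oligo": "OLG", "opc": "OPC", "per": "PER",
}


def simulate_expression(
    truth: GroundTruth,
    genes_per_type: int = 10,
    noise_sd: float = 0.5,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Marker genes = the cell type's latent regional map plus i.i.d. noise."""
    if genes_per_type < 2:
        raise ValueError("genes_per_type must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    base_seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence((base_seed, 202)))
    rows, ids, marker_sets = [], [], {}
    for ct in CELL_TYPES:
        latent = truth.latent_maps[ct]
        genes = [f"{_GENE_PREFIX[ct]}{i + 1:03d}" for i in range(genes_per_type)]
        marker_sets[ct] = genes
        for g in genes:
            rows.append(latent + rng.normal(0.0, noise_sd, size=latent.size))
            ids.append(g)
    expr = pd.DataFrame(np.asarray(rows), index=ids, columns=list(truth.region_names))
    expr.index.name = "gene"
    return expr, marker_sets


# ---------------------------------------------------------------------------
# outcome simulation
# ---------------------------------------------------------------------------

def simulate_outcomes(
    bundle: SyntheticBundle,
    truth: GroundTruth | None = None,
    ses_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    seed: int | None = None,
) -> SyntheticBundle:
    """Fill SES, PIRI and cognition; inject the SES x GA value shift.

    The SES-dependent shift ``a*code + b*code*(40 - GA)`` is applied to the
    values of preterm subjects only (term subjects train the charts and must
    stay unshifted), before cognition is computed from the resulting mean
    deviation score under the generating chart.
    """
    truth = bundle.truth if truth is None else truth
    base_seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence((base_seed, 303)))
    morph = bundle.morphometry.copy()

    meta = morph.drop_duplicates("subject_id")[["subject_id", "group", "ga_weeks"]]
    ses_label = rng.choice(len(SES_LEVELS), size=len(meta), p=np.asarray(ses_probs))
    ses = pd.Series([SES_LEVELS[i] for i in ses_label], index=meta["subject_id"].to_numpy())
    code = ses.map(SES_CODES)
    piri_p = np.clip(0.75 - 0.2 * (code.to_numpy() - 1), 0.05, 0.95)
    piri = pd.Series(rng.binomial(8, piri_p), index=ses.index)

    morph["ses"] = morph["subject_id"].map(ses)
    morph["piri"] = morph["subject_id"].map(piri)

    shift = (
        truth.ses_main * code
        + truth.ses_ga_interaction
        * code
        * np.maximum(0.0, 40.0 - meta.set_index("subject_id")["ga_weeks"])
    )
    shift[meta.set_index("subject_id")["group"] == "term"] = 0.0
    morph["value"] = morph["value"] + morph["subject_id"].map(shift).to_numpy()

    # cognition couples to the subject's mean deviation score under the truth chart
    t1 = morph[morph["timepoint"] == 1]
    profile = compute_deviation_scores(truth.chart, t1, on_unknown_study="zero")
    summary = profile.table.groupby("subject_id")["score"].mean()
    z = (summary - summary.mean()) / summary.std()
    cognition = (
        100.0
        + truth.cognition_coupling * z
        + rng.normal(0.0, truth.cognition_noise_sd, size=len(z))
    )
    morph["cognition"] = morph["subject_id"].map(cognition)

    return SyntheticBundle(
        morphometry=morph,
        truth=truth,
        injections=bundle.injections,
        expression=bundle.expression,
        marker_sets=bundle.marker_sets,
    )
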