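"""Pipeline driver: ties all stages together and writes a run manifest.

Stage order: simulate (optional) -> fit -> adapt -> score -> heterogeneity ->
consistency -> cellmaps -> spin -> plasticity.  Every output file is a text
format and is checksummed into ``manifest.json``; rerunning with the same
config and seed reproduces the outputs bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cell_maps import aggregate_marker_sets, normalize_genes
from .config import RunConfig
from .consistency import extent_vs_ga, ga_subgroup_overlap, icc_table, persistence_fraction, \
    select_longitudinal_extranormal
from .heterogeneity import binarize_profiles, group_average_dysmaturation, overlap_percentages, \
    profile_similarity
from .io import read_expression, read_marker_sets, read_morphometry, write_json
from .normative import adapt_study_offset, classify_extranormal, compute_deviation_scores, \
    fit_reference_charts
from .plasticity import env_outcome_correlations, moderation_ga_ses, pc1_summary
from .spatial_null import ParcelGeometry, build_spin_schedule, cell_alignment_vs_ga, \
    subject_cellmap_correlations
from .synthetic import default_truth, simulate_cohort, simulate_expression, simulate_outcomes

log = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": [],
        "outputs": {},
    }
    stage = "init"
    try:
        ss = np.random.SeedSequence(config.seed)
        seeds = {
            name: int(s.generate_state(1)[0] % (2**31))
            for name, s in zip(
                ["simulate", "fit", "spin", "boot", "moderation"], ss.spawn(5)
            )
        }
        manifest["stage_seeds"] = seeds

        # ---- inputs / simulation ------------------------------------------
        stage = "simulate"
        if config.morphometry is None:
            truth = default_truth(seed=seeds["simulate"], measure=config.measure)
            bundle = simulate_cohort(
                truth, config.n_term, config.n_preterm, n_timepoints=config.n_timepoints
            )
            expr, markers = simulate_expression(truth)
            bundle.expression, bundle.marker_sets = expr, markers
            bundle = simulate_outcomes(bundle, truth)
            bundle.write(out / "synthetic")
            morph = bundle.morphometry
            geom = bundle.centroids
            for f in (out / "synthetic").glob("*"):
                manifest["outputs"][f"synthetic/{f.name}"] = _sha256(f)
        else:
            morph = read_morphometry(config.morphometry)
            expr = read_expression(config.expression) if config.expression else None
            markers = read_marker_sets(config.marker_sets) if config.marker_sets else None
            geom = ParcelGeometry.from_csv(config.centroids) if config.centroids else None
        manifest["stages"].append(stage)

        # ---- normative charts ---------------------------------------------
        stage = "fit"
        chart = fit_reference_charts(
            morph,
            measure=config.measure,
            seed=seeds["fit"],
            exclude_regions=config.exclude_regions,
        )
        for study in sorted(morph["study"].unique()):
            term = morph[(morph["study"] == study) & (morph["group"] == "term")]
            if term.empty:
                log.warning("study %s has no term subjects; offset skipped", study)
                continue
            chart = adapt_study_offset(chart, morph, study)
        chart.to_json(out / "chart.json")
        manifest["stages"].append(stage)

        stage = "score"
        profiles = compute_deviation_scores(chart, morph)
        profiles = classify_extranormal(
            profiles, lower=config.lower_threshold, upper=config.upper_threshold
        )
        profiles.to_csv(out / "deviation_profiles.csv")
        manifest["stages"].append(stage)

        meta = morph.drop_duplicates("subject_id").set_index("subject_id")
        preterm_ids = meta.index[meta["group"] == "preterm"]
        pre_tab = profiles.table[profiles.table["subject_id"].isin(preterm_ids)]
        pre_profiles = type(profiles)(
            table=pre_tab, lower=profiles.lower, upper=profiles.upper, regions=profiles.regions
        )

        # ---- heterogeneity ------------------------------------------------
        stage = "heterogeneity"
        gad = group_average_dysmaturation(morph[morph["timepoint"] == 1], config.measure)
        gad.to_csv(out / "group_average.csv")
        overlap = overlap_percentages(profiles, groups=meta["group"], timepoint=1)
        overlap.to_csv(out / "overlap.csv", index=False)
        binary = binarize_profiles(pre_profiles, timepoint=1)
        sim, sim_means = profile_similarity(binary)
        sim.to_csv(out / "similarity_matrix.csv")
        sim_means.rename("mean_similarity").to_csv(out / "similarity_means.csv")
        manifest["stages"].append(stage)

        # ---- consistency --------------------------------------------------
        stage = "consistency"
        ga = meta.loc[preterm_ids, "ga_weeks"]
        extent = extent_vs_ga(pre_profiles, ga, n_boot=config.n_boot_ci, seed=seeds["boot"])
        extent.to_csv(out / "extent_vs_ga.csv")
        subgroups = ga_subgroup_overlap(pre_profiles, ga)
        subgroups.to_csv(out / "ga_subgroup_overlap.csv", index=False)
        if config.n_timepoints == 2:
            pairs = select_longitudinal_extranormal(pre_profiles)
            persistence = pd.DataFrame(
                {
                    "direction": ["infra", "supra"],
                    "pct_maintained": [
                        persistence_fraction(pairs, "infra"),
                        persistence_fraction(pairs, "supra"),
                    ],
                }
            )
            persistence.to_csv(out / "persistence.csv", index=False)
            icc = icc_table(pre_profiles)
            icc.to_csv(out / "icc.csv")
        manifest["stages"].append(stage)

        # ---- cell maps and spin tests -------------------------------------
        if expr is not None and markers is not None and geom is not None:
            stage = "cellmaps"
            maps = aggregate_marker_sets(normalize_genes(expr), markers)
            maps.to_csv(out / "cell_maps.csv")
            manifest["stages"].append(stage)

            stage = "spin"
            included = [r for r in geom.regions if r not in set(config.exclude_regions)]
            idx = [list(geom.regions).index(r) for r in included]
            geom_inc = ParcelGeometry(tuple(included), geom.xyz[idx])
            schedule = build_spin_schedule(geom_inc, n_spins=config.n_spins, seed=seeds["spin"])
            scores_t1 = pre_profiles.score_matrix(timepoint=1).dropna(axis=1, how="all").dropna()
            rho, p_spin = subject_cellmap_correlations(scores_t1, maps, schedule)
            rho.to_csv(out / "cellmap_rho.csv")
            p_spin.to_csv(out / "cellmap_pspin.csv")
            alignment = cell_alignment_vs_ga(rho, ga, n_boot=config.n_boot_ci, seed=seeds["boot"])
            alignment.to_csv(out / "cell_alignment_vs_ga.csv")
            manifest["stages"].append(stage)

        # ---- plasticity / outcomes ----------------------------------------
        stage = "plasticity"
        scores_t1 = pre_profiles.score_matrix(timepoint=1).dropna(axis=1, how="all").dropna()
        pc = pc1_summary(scores_t1)
        pc.scores.to_csv(out / "pc1_scores.csv")
        pc.loadings.to_csv(out / "pc1_loadings.csv")
        env_cols = [c for c in ("ses", "piri", "cognition") if c in meta.columns]
        env = meta.loc[:, env_cols].copy() if env_cols else pd.DataFrame(index=meta.index)
        counts = pre_profiles.counts()
        counts = counts[counts["timepoint"] == 1].set_index("subject_id")
        env["n_infranormal"] = counts["n_infra"]
        env["mean_deviation"] = scores_t1.mean(axis=1)
        if not env.dropna(how="all").empty:
            corr = env_outcome_correlations(pc, env, n_boot=config.n_boot_ci, seed=seeds["boot"])
            corr.to_csv(out / "env_correlations.csv")
        if "ses" in meta.columns and meta.loc[preterm_ids, "ses"].notna().any():
            mod = moderation_ga_ses(
                pc.scores,
                ga,
                meta.loc[preterm_ids, "ses"],
                n_boot=config.n_boot_moderation,
                seed=seeds["moderation"],
            )
            write_json(
                {
                    "params": mod.params.to_dict(),
                    "bse": mod.bse.to_dict(),
                    "interaction_p_one_sided": mod.interaction_p_one_sided,
                    "interaction_p_two_sided": mod.interaction_p_two_sided,
                    "interaction_ci": list(mod.interaction_ci),
                    "conditional_effects": mod.conditional_effects.reset_index().to_dict(
                        orient="records"
                    ),
                    "n": mod.n,
                    "alternative": mod.alternative,
                    "seed": mod.seed,
                },
                out / "moderation.json",
            )
        manifest["stages"].append(stage)

        for f in sorted(out.glob("*")):
            if f.is_file() and f.name != "manifest.json":
                manifest["outputs"][f.name] = _sha256(f)
        write_json(manifest, out / "manifest.json")
        return manifest
    except Exception as exc:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for f in out.glob("*"):
            if f.is_file():
                shutil.move(str(f), failed / f.name)
        log.error("pipeline failed at stage %r; partial outputs moved to %s", stage, failed)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
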