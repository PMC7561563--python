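"""End-to-end analysis: filter -> aggregate -> turnover -> trajectory
models -> ordination -> variance partitioning -> report bundle.

Driven by a :class:`PipelineConfig` (loadable from YAML/JSON); all
randomness (permutation tests) flows from the configured seed, so a
rerun with the same config is numerically identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datamodel import (
    CommunityMatrix,
    SiteTable,
    TraitTable,
    aggregate_group,
    filter_aspen_associated,
    read_community_table,
    read_site_table,
    read_trait_table,
)
from .ordination import (
    community_to_hellinger,
    marginal_permutation_test,
    ordination_scores,
    partial_rda,
)
from .simulate import SimulationParams, simulate_study
from .trajectories import (
    ModelSpec,
    fit_trajectory,
    interaction_lrt,
    prepare_model_frame,
    residual_time_diagnostics,
    specialist_generalist_model,
    within_time_contrasts,
)
from .turnover import turnover_rates, write_turnover_csv
from .varpart import varpart3

log = logging.getLogger("saprosucc")

DEFAULT_GROUPS = (
    "specialist", "generalist", "fungivore",
    "wood_feeder", "predator", "omnivore_saprophage",
)


@dataclass
class PipelineConfig:
    community: str | None = None
    traits: str | None = None
    sites: str | None = None
    preset: str | None = None  # 'aspen-study' to simulate inputs
    groups: tuple = DEFAULT_GROUPS
    n_perm: int = 1000
    seed: int = 0
    label_threshold: float = 0.2
    contrast_adjust: str | None = None
    make_figures: bool = True
    outdir: str = "results"

    def __post_init__(self):
        if not self.groups:
            raise ValueError("groups must be non-empty")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        data["groups"] = tuple(data.get("groups", DEFAULT_GROUPS))
        return cls(**data)


def _json_default(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return None if np.isnan(x) else float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (pd.Series,)):
        return x.to_dict()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _dump(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default, sort_keys=True)


def load_inputs(config: PipelineConfig):
    """Read or simulate the three study tables."""
    if config.preset:
        if config.preset != "aspen-study":
            raise ValueError(f"unknown preset {config.preset!r}")
        study = simulate_study(SimulationParams.aspen_study(), seed=config.seed)
        return study.community, study.traits, study.sites
    if not (config.community and config.traits and config.sites):
        raise ValueError("either a preset or all three input paths required")
    return (
        read_community_table(config.community),
        read_trait_table(config.traits),
        read_site_table(config.sites),
    )


def group_model_report(
    matrix: CommunityMatrix,
    traits: TraitTable,
    sites: SiteTable,
    group: str,
    adjust: str | None = None,
) -> dict:
    """Fit all four trajectory models for one functional group."""
    series = aggregate_group(matrix, traits, group)
    records = turnover_rates(matrix, traits, group)
    report: dict = {"group": group, "models": {}}
    for response in ("richness", "abundance", "Gp", "Lp"):
        spec = ModelSpec.for_response(response)
        src = series if response in ("richness", "abundance") else records
        frame = prepare_model_frame(src, sites, response)
        full = fit_trajectory(frame, spec, interaction=True)
        reduced = fit_trajectory(frame, spec, interaction=False)
        chi2, df, p = interaction_lrt(full, reduced)
        contrasts = within_time_contrasts(full, adjust=adjust)
        _, diag = residual_time_diagnostics(full)
        report["models"][response] = {
            "structure": full.structure,
            "messages": full.messages,
            "coefficients": {
                k: {"estimate": float(v),
                    "se": float(np.sqrt(full.cov.loc[k, k]))}
                for k, v in full.params.items()
            },
            "dispersion": full.dispersion,
            "loglik": full.llf,
            "n_obs": full.n_obs,
            "interaction_lrt": {"chi2": chi2, "df": df, "p": p},
            "contrasts": [
                dict(time=str(c.time), estimate=c.estimate, se=c.se,
                     z=c.z, p=c.p)
                for c in contrasts
            ],
            "predictions": full.predictions.to_dict(orient="records"),
            "lag1_residual_correlation": diag["lag1_pooled"],
        }
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Returns a dict of in-memory results keyed by stage; files are
    written under ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results: dict = {}
    try:
        log.info("saprosucc %s seed=%d", __version__, config.seed)
        stage = "inputs"
        community, traits, sites = load_inputs(config)
        stage = "filter"
        matrix = filter_aspen_associated(community, traits)
        log.info(
            "aspen-associated matrix: %d traps x %d years x %d species, "
            "%d individuals", matrix.n_traps, matrix.n_years,
            matrix.n_species, matrix.total_abundance,
        )
        results["matrix"] = matrix

        stage = "turnover"
        turnover_all = pd.concat(
            [turnover_rates(matrix, traits, g) for g in config.groups],
            ignore_index=True,
        )
        write_turnover_csv(turnover_all, out / "turnover.csv")
        results["turnover"] = turnover_all

        stage = "models"
        reports = {}
        for g in config.groups:
            rep = group_model_report(
                matrix, traits, sites, g, adjust=config.contrast_adjust
            )
            for resp, m in rep["models"].items():
                for msg in m["messages"]:
                    log.info("%s/%s: %s", g, resp, msg)
            _dump(rep, out / f"model_report_{g}.json")
            reports[g] = rep
        results["model_reports"] = reports

        stage = "specialist_generalist"
        frames = {
            g: prepare_model_frame(
                aggregate_group(matrix, traits, g), sites, "abundance"
            )
            for g in ("specialist", "generalist")
        }
        fit3, three_way, folds = specialist_generalist_model(
            frames, response="abundance", years=(1, 2)
        )
        sg = {
            "three_way": dict(term=str(three_way.time),
                              estimate=three_way.estimate, se=three_way.se,
                              z=three_way.z, p=three_way.p),
            "fold_changes": folds.to_dict(orient="records"),
            "structure": fit3.structure,
        }
        _dump(sg, out / "specialist_generalist.json")
        results["specialist_generalist"] = sg

        stage = "ordination"
        hel = community_to_hellinger(matrix, sites)
        design = hel.samples.copy()
        design["year"] = design["year"].astype(str)
        terms = ["year", "environment", "year:environment"]
        rda = partial_rda(hel, design, terms, condition=["landscape"])
        perm_tests = {}
        for i, term in enumerate(terms):
            res = marginal_permutation_test(
                hel, design, terms, condition=["landscape"], term=term,
                n_perm=config.n_perm, seed=config.seed + i,
            )
            perm_tests[term] = dict(
                F=res.f, df_num=res.df_num, df_den=res.df_den,
                p=res.p, n_perm=res.n_perm, seed=res.seed,
            )
        scores = ordination_scores(
            rda, scaling=2, label_threshold=config.label_threshold,
            centroid_factors=["environment", "year"],
        )
        scores.to_csv(out / "ordination_scores.csv", index=False)
        _dump(
            {
                "eigenvalues": rda.eigenvalues,
                "unconstrained_eigenvalues": rda.unconstrained_eigenvalues,
                "total_variance": rda.total_variance,
                "r2": rda.r2, "adj_r2": rda.adj_r2,
                "rank": rda.rank, "n": rda.n,
                "terms": terms, "condition": ["landscape"],
                "permutation_tests": perm_tests,
            },
            out / "rda_summary.json",
        )
        results["rda"] = rda
        results["permutation_tests"] = perm_tests
        results["scores"] = scores

        stage = "varpart"
        vp = varpart3(hel, design)
        _dump(
            {
                "subset_adj_r2": vp.subset_adj_r2,
                "subset_r2": vp.subset_r2,
                "fractions": vp.fractions(),
                "percent": vp.as_percent(),
                "n": vp.n,
                "dropped_rows": vp.dropped_rows,
            },
            out / "varpart.json",
        )
        results["varpart"] = vp

        if config.make_figures:
            stage = "figures"
            from . import plots
            for g in config.groups:
                series = aggregate_group(matrix, traits, g)
                records = turnover_rates(matrix, traits, g)
                for response in ("richness", "abundance", "Gp", "Lp"):
                    spec = ModelSpec.for_response(response)
                    src = series if response in ("richness", "abundance") else records
                    frame = prepare_model_frame(src, sites, response)
                    fit = fit_trajectory(frame, spec, interaction=True)
                    plots.plot_trajectory(
                        fit, out / f"fig_{response}_{g}.png",
                        title=f"{g}: {response}",
                    )
            plots.plot_triplot(
                scores, out / "fig_triplot.png",
                label_threshold=config.label_threshold,
            )
            plots.plot_venn(vp, out / "fig_venn.png")
        log.info("pipeline complete")
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return results
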