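"""End-to-end orchestration of the clonal-trial evaluation.

One call runs the full chain on a trial table and a climate table
(measured or simulated): mixed-model fits per site and across sites,
genetic parameters and composite clone ranks, type-B correlation
matrices, GGE biplot views, the multivariate regression tree on climate,
trait-climate correlation and Mantel tables, and the realised-gain
report.  Every artifact is a CSV/JSON file under the output directory,
written deterministically so a rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import gge_biplot, mrt
from .env_stats import (
    mantel_report,
    regression_table,
    site_year_trait_means,
    spearman_matrix,
)
from .genetic_parameters import (
    composite_rank,
    gain_report,
    gain_table,
    summarize_fit,
    type_b_correlation,
)
from .synthetic_trial import (
    SimulationParams,
    TrialDesign,
    default_climate_profiles,
    simulate_climate,
    simulate_trial,
)
from .trial_io import (
    read_climate_csv,
    read_trial_csv,
    write_climate_csv,
    write_trial_csv,
)
from .variance_components import (
    blup_table,
    components_table,
    fit_all_random,
    fit_multi_site,
    fit_single_site,
    variance_proportions,
)
from .worked_example import replay_gains


@dataclass
class PipelineConfig:
    """Settings for one full run; see the analysis drivers for examples."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    trial_csv: str | None = None  # if None, simulate
    climate_csv: str | None = None
    simulate: bool = True
    n_clones: int = 32
    target_traits: list = field(
        default_factory=lambda: [("height", 5), ("dbh", 9), ("volume", 5)]
    )
    rank_trait_ages: list = field(default_factory=lambda: [1, 2, 3, 4, 5])
    blocks: str = "fixed"
    use_plot_means: bool = False
    gge_scaling: str = "env_sd"
    gge_svp: str = "genotype_focused"
    mrt_min_leaf: int = 5
    mrt_max_size: int = 8
    mantel_permutations: int = 999

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw["target_traits"] = [tuple(t) for t in raw.get("target_traits", [])] or None
        kwargs = {k: v for k, v in raw.items() if v is not None}
        return cls(**kwargs)


def _write_csv(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a manifest mapping artifact names to paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    stage = "input"
    try:
        if config.trial_csv:
            data = read_trial_csv(config.trial_csv)
            design = None
        else:
            design = TrialDesign.reference(n_clones=config.n_clones,
                                           ages=(1, 2, 3, 4, 5, 6, 7, 8, 9))
            params = SimulationParams.reference(seed=int(rng.integers(2**31 - 1)))
            data, _truth = simulate_trial(design, params)
            write_trial_csv(data, out / "trial.csv")
        if config.climate_csv:
            climate = read_climate_csv(config.climate_csv)
        else:
            years = range(2010, 2015)
            climate = simulate_climate(
                sorted(data["site"].unique()),
                years,
                default_climate_profiles(),
                seed=int(rng.integers(2**31 - 1)),
            )
            write_climate_csv(climate, out / "climate.csv")

        planting_year = design.planting_year if design is not None else 2009
        sites = sorted(data["site"].unique())

        # --- mixed-model fits -------------------------------------------
        stage = "variance_components"
        fits_single, fits_multi, prop_rows = [], [], []
        present = set(zip(data["trait"], data["age"]))
        targets = [t for t in config.target_traits if tuple(t) in present]
        for trait, age in targets:
            for s in sites:
                fits_single.append(fit_single_site(data, trait, age, s))
            fits_multi.append(fit_multi_site(data, trait, age, blocks=config.blocks))
            ar = fit_all_random(data, trait, age)
            props = variance_proportions(ar)
            prop_rows.append({"trait": trait, "age": age, **props})
        _write_csv(components_table(fits_single + fits_multi),
                   out / "variance_components.csv")
        _write_csv(pd.DataFrame(prop_rows), out / "variance_proportions.csv")

        # --- genetic parameters -----------------------------------------
        stage = "genetic_parameters"
        summaries = [summarize_fit(data, f) for f in fits_single + fits_multi]
        _write_csv(pd.DataFrame([asdict(s) for s in summaries]),
                   out / "genetic_parameters.csv")

        # --- BLUPs and composite ranks ----------------------------------
        stage = "blups"
        blups = blup_table(fits_single + fits_multi)
        _write_csv(blups.sort_values(["trait", "age", "site", "clone"]),
                   out / "blups.csv")
        rank_frames = []
        for trait in sorted({t for t, _a in targets}):
            ages = sorted(
                a for (tt, a) in present
                if tt == trait and a in config.rank_trait_ages
            )
            multi_fits = [
                fit_multi_site(data, trait, a, blocks=config.blocks)
                for a in ages
            ]
            tab = blup_table(multi_fits)
            ranks = composite_rank(tab, trait)
            ranks.insert(0, "trait", trait)
            rank_frames.append(ranks)
        _write_csv(pd.concat(rank_frames, ignore_index=True),
                   out / "composite_ranks.csv")

        # --- type-B correlation matrices --------------------------------
        stage = "type_b"
        rb_rows = []
        rb_matrices = {}
        for trait, age in targets:
            mat = pd.DataFrame(1.0, index=sites, columns=sites)
            for s1, s2 in itertools.combinations(sites, 2):
                pair = data[data["site"].isin([s1, s2])]
                f = fit_multi_site(pair, trait, age, blocks=config.blocks)
                rb = type_b_correlation(
                    f.components.sigma_c2, f.components.sigma_cs2
                )
                mat.loc[s1, s2] = mat.loc[s2, s1] = rb
                rb_rows.append({"trait": trait, "age": age, "site1": s1,
                                "site2": s2, "r_b": rb})
            rb_matrices[trait] = mat
        _write_csv(pd.DataFrame(rb_rows), out / "type_b_correlations.csv")

        # --- GGE biplot views -------------------------------------------
        stage = "gge"
        gge_meta = {}
        coord_frames, view_frames = [], []
        for trait, age in targets:
            tab = blup_table([f for f in fits_single
                              if f.trait == trait and f.age == age])
            gem = gge_biplot.build_ge_matrix(tab, trait, age)
            model = gge_biplot.fit_gge(
                gem, scaling=config.gge_scaling, svp=config.gge_svp
            )
            coords = gge_biplot.coordinates_table(model)
            coords.insert(0, "trait", trait)
            coord_frames.append(coords)
            www = gge_biplot.which_won_where(model)
            ms = gge_biplot.mean_vs_stability(model)
            dr = gge_biplot.discrimination_representativeness(model)
            rk = gge_biplot.rank_genotypes(model)
            view = ms.merge(rk, on="genotype")
            view.insert(0, "trait", trait)
            view["winner_of"] = view["genotype"].map(
                lambda g: ",".join(sorted(www["sectors"].get(g, []))) or ""
            )
            view_frames.append(view)
            gge_meta[trait] = {
                "age": age,
                "pct_explained_pc1": float(model.pct_explained[0]),
                "pct_explained_pc2": float(model.pct_explained[1]),
                "winners": www["winners"],
                "hull_vertices": www["vertices"],
                "environment_metrics": dr.to_dict(orient="records"),
                "imputed_cells": [list(c) for c in gem.imputed],
                "dropped_genotypes": gem.dropped_genotypes,
                "scaling": config.gge_scaling,
                "svp": config.gge_svp,
            }
        _write_csv(pd.concat(coord_frames, ignore_index=True),
                   out / "gge_coordinates.csv")
        _write_csv(pd.concat(view_frames, ignore_index=True),
                   out / "gge_views.csv")
        (out / "gge_settings.json").write_text(
            json.dumps(gge_meta, indent=2, sort_keys=True) + "\n"
        )

        # --- MRT on climate ---------------------------------------------
        stage = "mrt"
        X, Y = build_mrt_frame(data, climate, planting_year)
        Ystd, _means, _sds = mrt.standardize_responses(Y)
        control = mrt.MrtControl(min_leaf=config.mrt_min_leaf,
                                 max_size=config.mrt_max_size)
        tree = mrt.grow_tree(X, Ystd, control)
        pruned, cp = mrt.cv_prune(
            tree, X, Ystd, folds=10, seed=int(rng.integers(2**31 - 1))
        )
        (out / "mrt_rules.txt").write_text(pruned.rules_text() + "\n")
        (out / "mrt_tree.json").write_text(
            json.dumps(pruned.root.to_dict(), indent=2) + "\n"
        )
        _write_csv(cp, out / "mrt_complexity.csv")

        # --- climate correlations and Mantel ----------------------------
        stage = "env_stats"
        tv = site_year_trait_means(data, planting_year)
        tv = tv[tv["year"].isin(climate["year"].unique())]
        corr = spearman_matrix(tv, climate)
        reg = regression_table(tv, climate)
        _write_csv(corr.merge(reg, on=["trait", "variable"]),
                   out / "climate_correlations.csv")
        mant = mantel_report(
            rb_matrices, climate,
            n_perm=config.mantel_permutations,
            seed=int(rng.integers(2**31 - 1)),
        )
        _write_csv(mant, out / "mantel.csv")

        # --- gain report -------------------------------------------------
        stage = "gains"
        reports = [gain_report(data, f) for f in fits_single + fits_multi]
        _write_csv(gain_table(reports), out / "gains.csv")

        # --- manifest ----------------------------------------------------
        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "settings": {k: (list(map(list, v)) if k == "target_traits" else v)
                         for k, v in asdict(config).items()},
            "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return manifest


def build_mrt_frame(data: pd.DataFrame, climate: pd.DataFrame, planting_year: int):
    """Observational unit for the regression tree: one row per
    (clone, site, year) with the three growth responses averaged over
    trees, joined to that site-year's climate."""
    wide = (
        data.groupby(["site", "clone", "age", "trait"])["value"]
        .mean()
        .unstack("trait")
        .reset_index()
    )
    resp = [t for t in ("height", "dbh", "volume") if t in wide.columns]
    wide = wide.dropna(subset=resp)
    wide["year"] = wide["age"].astype(int) + int(planting_year)
    merged = wide.merge(climate, on=["site", "year"], how="inner")
    if merged.empty:
        raise ValueError("no overlap between growth years and climate years")
    from .trial_io import CLIMATE_VARIABLES

    X = merged[CLIMATE_VARIABLES].reset_index(drop=True)
    Y = merged[resp].reset_index(drop=True)
    return X, Y


def replay_gain_table() -> pd.DataFrame:
    """Recompute the published worked-example gains from printed inputs."""
    return replay_gains()
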