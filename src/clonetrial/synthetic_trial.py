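"""Synthetic clonal-trial and climate generators with known ground truth.

The generator draws data from the same mixed model the estimation side
fits: for each trait and age,

    value = mu(trait, age) + site + block + clone + clone-by-site + residual

with one clone effect per (trait, clone) shared across ages (growth at
successive ages carries the same genetic signal; an option draws per-age
effects instead), one clone-by-site effect per (trait, clone, site), block
effects per (trait, site, block), and an independent residual per
tree-age.  True effect draws are returned alongside the table so recovery
studies can compare estimates against truth.

Whole trees (all their ages jointly) are dropped by the mortality model,
matching how field losses occur.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trial_io import (
    CLIMATE_VARIABLES,
    TRAITS,
    TRIAL_COLUMNS,
    validate_climate,
    validate_trial,
)


@dataclass
class TrialDesign:
    """Field layout: sites, blocks, plot sizes, clones, measurement ages."""

    site_ids: list
    blocks_per_site: dict
    ramets_per_plot: dict
    clone_ids: list
    ages: list
    planting_year: int = 2009

    def __post_init__(self):
        if not self.site_ids or not self.clone_ids or not self.ages:
            raise ValueError("empty design")
        if len(set(self.clone_ids)) != len(self.clone_ids):
            raise ValueError("clone_ids must be unique")
        if list(self.ages) != sorted(set(int(a) for a in self.ages)):
            raise ValueError("ages must be strictly increasing positive integers")
        if any(int(a) <= 0 for a in self.ages):
            raise ValueError("ages must be positive")
        for s in self.site_ids:
            if self.blocks_per_site.get(s, 0) < 1:
                raise ValueError(f"blocks_per_site[{s!r}] must be >= 1")
            if self.ramets_per_plot.get(s, 0) < 1:
                raise ValueError(f"ramets_per_plot[{s!r}] must be >= 1")

    @classmethod
    def reference(cls, n_clones: int = 32, ages=(1, 2, 3, 4, 5)) -> "TrialDesign":
        """The three-site layout of the motivating trial series: one site
        with single-tree plots in six blocks, one with two-tree plots in
        five blocks, one with two-tree plots in four blocks."""
        return cls(
            site_ids=["LY", "NY", "TS"],
            blocks_per_site={"LY": 6, "NY": 5, "TS": 4},
            ramets_per_plot={"LY": 1, "NY": 2, "TS": 2},
            clone_ids=[f"C{i + 1:02d}" for i in range(n_clones)],
            ages=list(ages),
            planting_year=2009,
        )


def _per_trait(value, trait):
    """Allow scalar parameters or per-trait maps."""
    if isinstance(value, dict):
        return float(value[trait])
    return float(value)


@dataclass
class SimulationParams:
    """Ground-truth generating parameters.

    Variances may be scalars (shared across traits) or per-trait maps;
    ``trait_means`` maps (trait, age) to the population mean.
    """

    trait_means: dict
    site_effects: dict = field(default_factory=dict)  # (site, trait, age) -> shift
    block_sd: float | dict = 0.0
    sigma_c2: float | dict = 1.0
    sigma_cs2: float | dict = 0.0
    sigma_e2: float | dict = 1.0
    survival_rate: float = 1.0
    seed: int = 0
    per_age_clone_effects: bool = False

    def __post_init__(self):
        for name in ("sigma_c2", "sigma_cs2"):
            v = getattr(self, name)
            vals = v.values() if isinstance(v, dict) else [v]
            if any(x < 0 for x in vals):
                raise ValueError(f"{name} must be nonnegative")
        # sigma_e2 == 0 is admitted for degenerate/diagnostic draws; the
        # estimation side needs residual variation, the generator does not.
        v = self.sigma_e2
        vals = v.values() if isinstance(v, dict) else [v]
        if any(x < 0 for x in vals):
            raise ValueError("sigma_e2 must be nonnegative")
        if not (0 < self.survival_rate <= 1):
            raise ValueError("survival_rate must lie in (0, 1]")
        v = self.block_sd
        vals = v.values() if isinstance(v, dict) else [v]
        if any(x < 0 for x in vals):
            raise ValueError("block_sd must be nonnegative")

    @classmethod
    def reference(cls, seed: int = 0) -> "SimulationParams":
        """Defaults emulating the observed scale of the trial series:
        5-year height ~8 m growing ~1.7 m/yr, DBH reaching ~12 cm at 9 yr,
        clone repeatabilities in the 0.3-0.8 range, ~85% survival."""
        means = {}
        for age in range(1, 10):
            if age <= 5:
                means[("height", age)] = 1.5 + 1.6 * age
                means[("volume", age)] = 0.002 + 0.006 * age
            means[("dbh", age)] = 1.4 * age
        site_effects = {}
        for (trait, age) in means:
            scale = {"height": 1.0, "dbh": 1.2, "volume": 0.004}[trait]
            for site, shift in (("LY", 0.5), ("NY", -0.2), ("TS", -0.4)):
                site_effects[(site, trait, age)] = shift * scale
        return cls(
            trait_means=means,
            site_effects=site_effects,
            block_sd={"height": 0.15, "dbh": 0.25, "volume": 0.0015},
            sigma_c2={"height": 0.25, "dbh": 0.6, "volume": 2.5e-5},
            sigma_cs2={"height": 0.12, "dbh": 0.3, "volume": 1.2e-5},
            sigma_e2={"height": 0.8, "dbh": 2.0, "volume": 8.0e-5},
            survival_rate=0.85,
            seed=seed,
        )


def simulate_trial(design: TrialDesign, params: SimulationParams, traits=None):
    """Draw a complete trial table from the generating mixed model.

    Returns ``(dataset, truth)`` where ``dataset`` is a validated long
    table and ``truth`` maps effect kinds (``clone``, ``clone_site``,
    ``block``) to DataFrames of the realised draws.  Mortality is applied
    afterwards when ``params.survival_rate < 1``.
    """
    rng = np.random.default_rng(params.seed)
    if traits is None:
        traits = sorted({t for (t, _a) in params.trait_means})
        traits = [t for t in TRAITS if t in traits]
    unknown = set(traits) - set(TRAITS)
    if unknown:
        raise ValueError(f"unknown traits: {sorted(unknown)}")

    clone_truth, cs_truth, block_truth = [], [], []
    rows = []
    for trait in traits:
        sc = np.sqrt(_per_trait(params.sigma_c2, trait))
        scs = np.sqrt(_per_trait(params.sigma_cs2, trait))
        se = np.sqrt(_per_trait(params.sigma_e2, trait))
        sb = _per_trait(params.block_sd, trait)

        ages_t = sorted(a for (t, a) in params.trait_means if t == trait)
        if not ages_t:
            continue
        if params.per_age_clone_effects:
            c_eff = {
                (c, a): rng.normal(0.0, sc)
                for c in design.clone_ids
                for a in ages_t
            }
        else:
            draw = {c: rng.normal(0.0, sc) for c in design.clone_ids}
            c_eff = {(c, a): draw[c] for c in design.clone_ids for a in ages_t}
        cs_eff = {
            (c, s): rng.normal(0.0, scs)
            for c in design.clone_ids
            for s in design.site_ids
        }
        b_eff = {
            (s, b): rng.normal(0.0, sb) if sb > 0 else 0.0
            for s in design.site_ids
            for b in range(1, design.blocks_per_site[s] + 1)
        }

        for c in design.clone_ids:
            clone_truth.extend(
                {"trait": trait, "clone": c, "age": a, "effect": c_eff[(c, a)]}
                for a in ages_t
            )
            cs_truth.extend(
                {"trait": trait, "clone": c, "site": s, "effect": cs_eff[(c, s)]}
                for s in design.site_ids
            )
        block_truth.extend(
            {"trait": trait, "site": s, "block": b, "effect": e}
            for (s, b), e in b_eff.items()
        )

        for s in design.site_ids:
            for b in range(1, design.blocks_per_site[s] + 1):
                for c in design.clone_ids:
                    for k in range(1, design.ramets_per_plot[s] + 1):
                        resid = rng.normal(0.0, se, size=len(ages_t))
                        for a, e in zip(ages_t, resid):
                            mu = params.trait_means[(trait, a)]
                            site_shift = params.site_effects.get((s, trait, a), 0.0)
                            val = (
                                mu
                                + site_shift
                                + b_eff[(s, b)]
                                + c_eff[(c, a)]
                                + cs_eff[(c, s)]
                                + e
                            )
                            rows.append((s, f"B{b}", c, f"R{k}", a, trait, val))

    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    # Values are model draws and can stray below zero at small means; the
    # data contract requires nonnegative measurements.
    df["value"] = df["value"].clip(lower=0.0)
    df = validate_trial(df)
    truth = {
        "clone": pd.DataFrame(clone_truth),
        "clone_site": pd.DataFrame(cs_truth),
        "block": pd.DataFrame(block_truth),
    }
    if params.survival_rate < 1.0:
        df = apply_mortality(
            df, params.survival_rate, seed=int(rng.integers(0, 2**31 - 1))
        )
    return df, truth


def apply_mortality(dataset: pd.DataFrame, survival_rate: float, seed: int):
    """Retain each tree (all its ages and traits jointly) independently
    with probability ``survival_rate``.

    Emits a warning if any (clone, site) combination loses every tree.
    """
    if not (0 < survival_rate <= 1):
        raise ValueError("survival_rate must lie in (0, 1]")
    dataset = validate_trial(dataset)
    if survival_rate == 1.0:
        return dataset
    rng = np.random.default_rng(seed)
    trees = dataset[["site", "block", "clone", "ramet"]].drop_duplicates()
    keep_mask = rng.random(len(trees)) < survival_rate
    kept = trees[keep_mask]
    out = dataset.merge(kept, on=["site", "block", "clone", "ramet"], how="inner")

    before = set(map(tuple, dataset[["site", "clone"]].drop_duplicates().to_numpy()))
    after = set(map(tuple, out[["site", "clone"]].drop_duplicates().to_numpy()))
    lost = sorted(before - after)
    if lost:
        warnings.warn(
            f"mortality removed every tree for {len(lost)} (site, clone) "
            f"combinations, e.g. {lost[0]}",
            stacklevel=2,
        )
    return out.reset_index(drop=True)


#: Site climate profiles (mean, sd) loosely shaped on warm-temperate
#: continental China: a low-elevation humid site, a transitional site, and
#: a cooler, more continental highland site.
def default_climate_profiles():
    base = {
        "LY": {"MAT": 14.2, "MWMT": 26.8, "MCMT": 0.6, "MAP": 640.0, "PAS": 12.0,
               "NFFD": 225.0, "EMT": -14.0, "EXT": 41.0, "Eref": 1050.0,
               "CMD": 560.0, "RH": 63.0,
               "DD_lt_0": 120.0, "DD_gt_5": 4400.0, "DD_lt_18": 1900.0,
               "DD_gt_18": 900.0},
        "NY": {"MAT": 15.0, "MWMT": 27.4, "MCMT": 1.8, "MAP": 810.0, "PAS": 8.0,
               "NFFD": 235.0, "EMT": -12.0, "EXT": 40.0, "Eref": 980.0,
               "CMD": 430.0, "RH": 68.0,
               "DD_lt_0": 80.0, "DD_gt_5": 4700.0, "DD_lt_18": 1700.0,
               "DD_gt_18": 1000.0},
        "TS": {"MAT": 10.9, "MWMT": 22.8, "MCMT": -2.2, "MAP": 520.0, "PAS": 30.0,
               "NFFD": 195.0, "EMT": -19.0, "EXT": 36.0, "Eref": 870.0,
               "CMD": 380.0, "RH": 60.0,
               "DD_lt_0": 260.0, "DD_gt_5": 3400.0, "DD_lt_18": 2700.0,
               "DD_gt_18": 420.0},
    }
    sds = {"MAT": 0.5, "MWMT": 0.8, "MCMT": 1.0, "MAP": 80.0, "PAS": 6.0,
           "NFFD": 8.0, "EMT": 2.0, "EXT": 1.2, "Eref": 40.0, "CMD": 60.0,
           "RH": 3.0, "DD_lt_0": 40.0, "DD_gt_5": 150.0, "DD_lt_18": 120.0,
           "DD_gt_18": 90.0}
    profiles = {}
    for site, means in base.items():
        profiles[site] = {v: (means[v], sds[v]) for v in means}
    return profiles


def simulate_climate(site_ids, years, profiles, seed: int) -> pd.DataFrame:
    """Draw a per-(site, year) climate table from site profiles.

    ``profiles[site][variable] = (mean, sd)`` for every variable except
    TD and AHM, which are derived for internal consistency:
    TD = MWMT - MCMT and AHM = (MAT + 10) / (MAP / 1000).
    """
    rng = np.random.default_rng(seed)
    rows = []
    derived = {"TD", "AHM"}
    for s in site_ids:
        if s not in profiles:
            raise ValueError(f"missing climate profile for site {s!r}")
        prof = profiles[s]
        missing = set(CLIMATE_VARIABLES) - derived - set(prof)
        if missing:
            raise ValueError(f"profile for {s!r} missing variables {sorted(missing)}")
        for y in years:
            row = {"site": s, "year": int(y)}
            for v in CLIMATE_VARIABLES:
                if v in derived:
                    continue
                mean, sd = prof[v]
                row[v] = rng.normal(mean, sd) if sd > 0 else float(mean)
            row["TD"] = row["MWMT"] - row["MCMT"]
            row["MAP"] = max(row["MAP"], 0.0)
            row["RH"] = float(np.clip(row["RH"], 0.0, 100.0))
            row["AHM"] = (row["MAT"] + 10.0) / max(row["MAP"], 1.0) * 1000.0
            rows.append(row)
    return validate_climate(pd.DataFrame(rows))
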