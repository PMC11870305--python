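"""Mixed-model fits for clonal trials: variance components and clone BLUPs.

Three model families are provided, matching how multi-environment clonal
trials are routinely analysed:

* single-site: value = mu + block (fixed) + clone (random) + residual
* multi-site:  value = mu + site (fixed) + block-within-site (fixed)
  + clone (random) + clone-by-site (random) + residual
* all-random:  value = mu + site + clone + site-by-clone + residual, every
  term random, used for reporting the proportion of phenotypic variance
  attributable to environment, genetics, and G-by-E.

Blocks-within-site in the multi-site model default to fixed (mirroring the
single-site model); a ``blocks="random"`` switch treats them as a variance
component instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._reml import RandomFactor, reml_fit
from .trial_io import validate_trial

#: Site label marking across-site (multi-site) BLUPs in a BLUP table.
ALL_SITES = "ALL"


@dataclass
class VarianceComponents:
    sigma_c2: float
    sigma_e2: float
    sigma_cs2: float | None = None
    extra: dict = field(default_factory=dict)  # e.g. site/block variances
    loglik: float = float("nan")
    converged: bool = True
    n_iter: int = 0

    def as_dict(self) -> dict:
        d = {"sigma_c2": self.sigma_c2, "sigma_e2": self.sigma_e2}
        if self.sigma_cs2 is not None:
            d["sigma_cs2"] = self.sigma_cs2
        d.update(self.extra)
        return d


@dataclass
class FitResult:
    model_tag: str  # single_site | multi_site | all_random
    trait: str
    age: int
    fixed_effects: dict
    components: VarianceComponents
    blups: pd.DataFrame  # columns: clone, site, trait, age, blup
    interaction_blups: pd.DataFrame | None = None  # clone, site, blup
    n_obs: int = 0
    site: str | None = None


def _subset(data: pd.DataFrame, trait: str, age: int, site: str | None = None):
    data = validate_trial(data)
    mask = (data["trait"] == trait) & (data["age"] == int(age))
    if site is not None:
        mask &= data["site"] == str(site)
    sub = data.loc[mask]
    if sub.empty:
        raise ValueError(f"no observations for trait={trait!r} age={age}"
                         + (f" site={site!r}" if site else ""))
    return sub.reset_index(drop=True)


def _codes(series: pd.Series) -> RandomFactor:
    cat = pd.Categorical(series)
    return RandomFactor(series.name, np.asarray(cat.codes), list(cat.categories))


def _dummies(series: pd.Series, prefix: str):
    """Treatment-coded dummies (first level dropped)."""
    cat = pd.Categorical(series)
    levels = list(cat.categories)
    cols = []
    names = []
    for lev in levels[1:]:
        cols.append((cat == lev).astype(float))
        names.append(f"{prefix}[{lev}]")
    return cols, names


def fit_single_site(data: pd.DataFrame, trait: str, age: int, site: str) -> FitResult:
    """REML fit of the single-site clone model at one trait-age.

    value = mu + block (fixed) + clone (random, sigma_c^2) + residual.
    The clone variance is constrained nonnegative; a boundary solution is
    reported as exactly 0 with all clone BLUPs 0.
    """
    sub = _subset(data, trait, age, site)
    if sub["clone"].nunique() < 2:
        raise ValueError("single-site fit needs at least 2 clones")
    if len(sub) < 3:
        raise ValueError("single-site fit needs at least 3 observations")

    y = sub["value"].to_numpy(dtype=float)
    cols = [np.ones(len(sub))]
    names = ["mu"]
    bcols, bnames = _dummies(sub["block"], "block")
    cols += bcols
    names += bnames
    X = np.column_stack(cols)
    clone = _codes(sub["clone"])
    fit = reml_fit(y, X, [clone], beta_names=names)

    comp = VarianceComponents(
        sigma_c2=fit.variances["clone"],
        sigma_e2=fit.variances["residual"],
        loglik=fit.loglik,
        converged=fit.converged,
        n_iter=fit.n_iter,
    )
    blups = pd.DataFrame(
        {
            "clone": fit.blup_levels["clone"],
            "site": str(site),
            "trait": trait,
            "age": int(age),
            "blup": fit.blups["clone"],
        }
    )
    return FitResult(
        model_tag="single_site",
        trait=trait,
        age=int(age),
        fixed_effects=fit.beta,
        components=comp,
        blups=blups,
        n_obs=len(sub),
        site=str(site),
    )


def fit_multi_site(
    data: pd.DataFrame, trait: str, age: int, blocks: str = "fixed"
) -> FitResult:
    """REML fit of the multi-site clone model at one trait-age.

    value = mu + site + block-within-site + clone + clone-by-site + residual
    with clone and clone-by-site random.  Returns across-site clone BLUPs
    (site = ``ALL``) plus per-cell predictions clone + clone-by-site in
    ``interaction_blups``.  Clones observed at a single site are retained;
    their unobserved interaction cells simply shrink to zero.
    """
    if blocks not in ("fixed", "random"):
        raise ValueError("blocks must be 'fixed' or 'random'")
    sub = _subset(data, trait, age)
    n_sites = sub["site"].nunique()
    if n_sites < 2:
        raise ValueError(
            "multi-site fit needs >=2 sites; use fit_single_site for one site"
        )
    multi_site_clones = (
        sub.groupby("clone")["site"].nunique().ge(2).sum()
    )
    if multi_site_clones < 2:
        raise ValueError("need >=2 clones observed at >=2 sites")

    y = sub["value"].to_numpy(dtype=float)
    cols = [np.ones(len(sub))]
    names = ["mu"]
    scols, snames = _dummies(sub["site"], "site")
    cols += scols
    names += snames
    site_block = sub["site"].str.cat(sub["block"], sep=":")
    site_block.name = "site_block"
    factors = []
    if blocks == "fixed":
        # block-within-site: drop one block per site to keep full rank
        for s in sorted(sub["site"].unique()):
            at_s = sub["site"] == s
            blocks_s = sorted(sub.loc[at_s, "block"].unique())
            for b in blocks_s[1:]:
                cols.append((at_s & (sub["block"] == b)).astype(float).to_numpy())
                names.append(f"block[{s}:{b}]")
    else:
        factors.append(_codes(site_block))
    X = np.column_stack(cols)

    clone = _codes(sub["clone"])
    cs = sub["clone"].str.cat(sub["site"], sep=":")
    cs.name = "clone_site"
    factors = [clone, _codes(cs)] + factors
    fit = reml_fit(y, X, factors, beta_names=names)

    comp = VarianceComponents(
        sigma_c2=fit.variances["clone"],
        sigma_cs2=fit.variances["clone_site"],
        sigma_e2=fit.variances["residual"],
        extra=(
            {"sigma_b2": fit.variances["site_block"]} if blocks == "random" else {}
        ),
        loglik=fit.loglik,
        converged=fit.converged,
        n_iter=fit.n_iter,
    )
    blups = pd.DataFrame(
        {
            "clone": fit.blup_levels["clone"],
            "site": ALL_SITES,
            "trait": trait,
            "age": int(age),
            "blup": fit.blups["clone"],
        }
    )
    # Per-cell predictions: clone main effect + interaction deviation for
    # every (clone, site) combination; unobserved cells get interaction 0.
    clone_effect = dict(zip(fit.blup_levels["clone"], fit.blups["clone"]))
    cs_effect = dict(zip(fit.blup_levels["clone_site"], fit.blups["clone_site"]))
    rows = []
    for c in fit.blup_levels["clone"]:
        for s in sorted(sub["site"].unique()):
            rows.append(
                {
                    "clone": c,
                    "site": s,
                    "trait": trait,
                    "age": int(age),
                    "blup": clone_effect[c] + cs_effect.get(f"{c}:{s}", 0.0),
                }
            )
    inter = pd.DataFrame(rows)
    return FitResult(
        model_tag="multi_site",
        trait=trait,
        age=int(age),
        fixed_effects=fit.beta,
        components=comp,
        blups=blups,
        interaction_blups=inter,
        n_obs=len(sub),
    )


def fit_all_random(data: pd.DataFrame, trait: str, age: int) -> FitResult:
    """All-random decomposition: site, clone, site-by-clone, residual.

    Used to report each term's share of the phenotypic variance; the
    proportions of the four components sum to one.  Block structure is
    deliberately absorbed into the residual so that the decomposition has
    exactly the environment / genetics / G-by-E / error reading.
    """
    sub = _subset(data, trait, age)
    if sub["site"].nunique() < 2:
        raise ValueError("all-random decomposition needs >=2 sites")
    if sub["clone"].nunique() < 2:
        raise ValueError("all-random decomposition needs >=2 clones")
    y = sub["value"].to_numpy(dtype=float)
    X = np.ones((len(sub), 1))
    cs = sub["site"].str.cat(sub["clone"], sep=":")
    cs.name = "site_clone"
    site = sub["site"].copy()
    site.name = "site"
    factors = [_codes(site), _codes(sub["clone"]), _codes(cs)]
    fit = reml_fit(y, X, factors, beta_names=["mu"])
    comp = VarianceComponents(
        sigma_c2=fit.variances["clone"],
        sigma_cs2=fit.variances["site_clone"],
        sigma_e2=fit.variances["residual"],
        extra={"sigma_s2": fit.variances["site"]},
        loglik=fit.loglik,
        converged=fit.converged,
        n_iter=fit.n_iter,
    )
    blups = pd.DataFrame(
        {
            "clone": fit.blup_levels["clone"],
            "site": ALL_SITES,
            "trait": trait,
            "age": int(age),
            "blup": fit.blups["clone"],
        }
    )
    return FitResult(
        model_tag="all_random",
        trait=trait,
        age=int(age),
        fixed_effects=fit.beta,
        components=comp,
        blups=blups,
        n_obs=len(sub),
    )


def variance_proportions(fit: FitResult) -> dict:
    """Shares of total variance for an all-random fit (sum to 1)."""
    if fit.model_tag != "all_random":
        raise ValueError("proportions are defined for all_random fits")
    c = fit.components
    parts = {
        "site": c.extra["sigma_s2"],
        "clone": c.sigma_c2,
        "site_clone": c.sigma_cs2,
        "residual": c.sigma_e2,
    }
    total = sum(parts.values())
    if total <= 0:
        raise ValueError("degenerate fit: total variance is zero")
    return {k: v / total for k, v in parts.items()}


def anova_components_balanced(
    data: pd.DataFrame, trait: str, age: int, site: str
) -> VarianceComponents:
    """Method-of-moments components from expected mean squares.

    Oracle for the single-site model on perfectly balanced layouts (every
    clone in every block with the same number of ramets).  With c clones,
    b blocks and r ramets per plot:

        sigma_e^2 = MSE,   sigma_c^2 = (MS_clone - MSE) / (b * r)

    where MS_clone and MSE come from the two-way (clone + block) ANOVA
    without interaction.  Raises on unbalanced input.
    """
    sub = _subset(data, trait, age, site)
    counts = sub.groupby(["clone", "block"]).size()
    clones = sub["clone"].unique()
    blocks = sub["block"].unique()
    if len(counts) != len(clones) * len(blocks) or counts.nunique() != 1:
        raise ValueError("anova_components_balanced requires a balanced layout")
    r = int(counts.iloc[0])
    c, b = len(clones), len(blocks)
    n = len(sub)
    y = sub["value"].to_numpy(dtype=float)
    grand = y.mean()
    clone_means = sub.groupby("clone")["value"].mean()
    block_means = sub.groupby("block")["value"].mean()

    ss_clone = b * r * float(((clone_means - grand) ** 2).sum())
    ss_block = c * r * float(((block_means - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_err = ss_total - ss_clone - ss_block
    df_clone = c - 1
    df_err = n - c - b + 1
    ms_clone = ss_clone / df_clone
    mse = ss_err / df_err
    sigma_e2 = mse
    sigma_c2 = (ms_clone - mse) / (b * r)
    return VarianceComponents(sigma_c2=float(sigma_c2), sigma_e2=float(sigma_e2))


def components_table(fits: list[FitResult]) -> pd.DataFrame:
    """Flat CSV-ready table of variance components across fits."""
    rows = []
    for f in fits:
        row = {
            "model": f.model_tag,
            "trait": f.trait,
            "age": f.age,
            "site": f.site if f.site is not None else ALL_SITES,
            "n_obs": f.n_obs,
            "converged": f.components.converged,
            "loglik": f.components.loglik,
        }
        row.update(f.components.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def blup_table(fits: list[FitResult]) -> pd.DataFrame:
    """Concatenate BLUP tables from several fits (one row per key)."""
    tab = pd.concat([f.blups for f in fits], ignore_index=True)
    if tab.duplicated(subset=["clone", "site", "trait", "age"]).any():
        raise ValueError("duplicate BLUP keys across fits")
    return tab
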