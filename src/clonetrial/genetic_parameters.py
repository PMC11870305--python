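"""Scalar genetic statistics for clonal trials.

Coefficients of variation, clonal repeatability on a mean basis, type-B
genetic correlations between environments, expected genetic gain from
clone selection, and the membership-function composite ranking used to
combine multi-year BLUPs into a single selection index.

Notation: sigma_c^2 is the clone (genetic) variance, sigma_cs^2 the
clone-by-site interaction variance, sigma_e^2 the residual; K is the
harmonic mean number of replicates per clone; S, B, N are the numbers of
sites, blocks, and trees per plot entering the mean-basis repeatability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variance_components import ALL_SITES, FitResult


@dataclass
class GeneticSummary:
    trait: str
    age: int
    site: str  # site id or ALL
    cv_pct: float
    gcv_pct: float
    ecv_pct: float
    repeatability: float
    n_clones: int


@dataclass
class GainReport:
    trait: str
    age: int
    site: str
    selected_clone: str
    sel_mean: float
    pop_mean: float
    repeatability: float
    gain_pct: float


def variation_coefficients(values, sigma_g2: float, sigma_e2: float):
    """(CV%, GCV%, ECV%) for one trait-age.

    CV uses the sample standard deviation of the phenotype values; GCV and
    ECV put the square roots of the supplied genetic and residual variance
    components over the same phenotypic mean.  All three in percent.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need >=2 values")
    if sigma_g2 < 0 or sigma_e2 < 0:
        raise ValueError("variance components must be nonnegative")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("phenotypic mean must be positive")
    cv = values.std(ddof=1) / mean * 100.0
    gcv = np.sqrt(sigma_g2) / mean * 100.0
    ecv = np.sqrt(sigma_e2) / mean * 100.0
    return float(cv), float(gcv), float(ecv)


def harmonic_K(replicate_counts) -> float:
    """Harmonic mean of per-clone replicate counts."""
    counts = np.asarray(list(replicate_counts), dtype=float)
    if counts.size == 0:
        raise ValueError("empty replicate counts")
    if (counts < 1).any():
        raise ValueError("replicate counts must be >= 1")
    return float(counts.size / np.sum(1.0 / counts))


def repeatability_single(sigma_c2: float, sigma_e2: float, K: float) -> float:
    """Mean-basis clonal repeatability R = sigma_c^2 / (sigma_c^2 + sigma_e^2/K)."""
    if K <= 0:
        raise ValueError("K must be positive")
    if sigma_c2 < 0 or sigma_e2 < 0:
        raise ValueError("variances must be nonnegative")
    denom = sigma_c2 + sigma_e2 / K
    if denom <= 0:
        raise ValueError("repeatability undefined when all variances are zero")
    return float(sigma_c2 / denom)


def repeatability_multi(
    sigma_c2: float, sigma_sc2: float, sigma_e2: float, S: float, B: float, N: float
) -> float:
    """Across-site mean-basis repeatability.

    R = sigma_c^2 / (sigma_c^2 + sigma_sc^2/S + sigma_e^2/(S*B*N)),
    with S sites, B blocks per site, and N trees per plot; B and N may be
    real-valued (harmonic/arithmetic means under unbalanced layouts).
    Non-decreasing in each of S, B, N.
    """
    if min(S, B, N) < 1:
        raise ValueError("S, B, N must be >= 1")
    if min(sigma_c2, sigma_sc2, sigma_e2) < 0:
        raise ValueError("variances must be nonnegative")
    denom = sigma_c2 + sigma_sc2 / S + sigma_e2 / (S * B * N)
    if denom <= 0:
        raise ValueError("repeatability undefined: zero denominator")
    return float(sigma_c2 / denom)


def type_b_correlation(sigma_c2: float, sigma_cs2: float) -> float:
    """Type-B genetic correlation r_b = sigma_c^2 / (sigma_c^2 + sigma_cs^2).

    Near 1: clone rankings agree across environments (weak G-by-E); near
    0: strong G-by-E.  Undefined when both variances are zero.
    """
    if sigma_c2 < 0 or sigma_cs2 < 0:
        raise ValueError("variances must be nonnegative")
    denom = sigma_c2 + sigma_cs2
    if denom <= 0:
        raise ValueError("type-B correlation undefined when both variances are 0")
    return float(sigma_c2 / denom)


def genetic_gain(sel_mean: float, pop_mean: float, repeatability: float) -> float:
    """Expected genetic gain from selection, in percent.

    gain% = 100 * (selected mean - population mean) * R / population mean,
    i.e. the selection differential regressed through the repeatability
    and expressed relative to the population mean.
    """
    if pop_mean <= 0:
        raise ValueError("population mean must be positive")
    if not (0 <= repeatability <= 1):
        raise ValueError("repeatability must lie in [0, 1]")
    return float(100.0 * (sel_mean - pop_mean) * repeatability / pop_mean)


def membership_normalize(values):
    """Min-max (membership function) normalisation to [0, 1].

    Affine-invariant; requires at least two distinct values.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need >=2 values")
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ValueError("membership normalisation undefined for constant input")
    return (values - lo) / (hi - lo)


def composite_rank(blups: pd.DataFrame, trait: str, site: str = ALL_SITES):
    """Composite multi-year ranking of clones for one trait.

    For each age, clone BLUPs are membership-normalised to [0, 1]; the sum
    across ages is the comprehensive evaluation index, ranked descending
    (rank 1 = best), ties broken by clone identifier.  Ages where every
    clone has the same BLUP carry no information and are skipped with a
    warning.

    Returns a DataFrame (clone, score, rank) sorted by rank.
    """
    sub = blups[(blups["trait"] == trait) & (blups["site"] == site)]
    if sub.empty:
        raise ValueError(f"no BLUPs for trait={trait!r} site={site!r}")
    mat = sub.pivot_table(index="clone", columns="age", values="blup")
    if mat.isna().any().any():
        raise ValueError("BLUP table must cover every clone at every age")
    if len(mat) < 2:
        raise ValueError("composite ranking needs >=2 clones")
    scores = pd.Series(0.0, index=mat.index)
    for age in mat.columns:
        col = mat[age].to_numpy()
        if np.ptp(col) == 0:
            warnings.warn(
                f"all BLUPs equal at age {age}; year skipped in composite rank",
                stacklevel=2,
            )
            continue
        scores += membership_normalize(col)
    out = scores.rename("score").reset_index()
    out = out.sort_values(["score", "clone"], ascending=[False, True]).reset_index(
        drop=True
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def replicate_counts(data: pd.DataFrame, trait: str, age: int, site: str):
    """Surviving replicates (blocks x ramets) per clone at one site-age."""
    sub = data[
        (data["trait"] == trait)
        & (data["age"] == int(age))
        & (data["site"] == str(site))
    ]
    if sub.empty:
        raise ValueError("no observations for the requested site-age")
    return sub.groupby("clone").size()


def multi_site_design_numbers(data: pd.DataFrame, trait: str, age: int):
    """(S, B, N) entering the multi-site repeatability.

    S is the site count; B the arithmetic mean number of blocks per site;
    N the harmonic mean number of trees per (site, block, clone) plot.
    """
    sub = data[(data["trait"] == trait) & (data["age"] == int(age))]
    if sub.empty:
        raise ValueError("no observations for the requested trait-age")
    S = sub["site"].nunique()
    B = float(sub.groupby("site")["block"].nunique().mean())
    plot_sizes = sub.groupby(["site", "block", "clone"]).size()
    N = harmonic_K(plot_sizes.to_numpy())
    return float(S), B, N


def summarize_fit(data: pd.DataFrame, fit: FitResult) -> GeneticSummary:
    """CVs and repeatability from one mixed-model fit plus its data."""
    sub = data[(data["trait"] == fit.trait) & (data["age"] == fit.age)]
    if fit.model_tag == "single_site":
        sub = sub[sub["site"] == fit.site]
        K = harmonic_K(sub.groupby("clone").size().to_numpy())
        R = repeatability_single(fit.components.sigma_c2, fit.components.sigma_e2, K)
        site = fit.site
    else:
        S, B, N = multi_site_design_numbers(data, fit.trait, fit.age)
        R = repeatability_multi(
            fit.components.sigma_c2,
            fit.components.sigma_cs2 or 0.0,
            fit.components.sigma_e2,
            S,
            B,
            N,
        )
        site = ALL_SITES
    cv, gcv, ecv = variation_coefficients(
        sub["value"].to_numpy(),
        fit.components.sigma_c2,
        fit.components.sigma_e2,
    )
    return GeneticSummary(
        trait=fit.trait,
        age=fit.age,
        site=site,
        cv_pct=cv,
        gcv_pct=gcv,
        ecv_pct=ecv,
        repeatability=R,
        n_clones=int(sub["clone"].nunique()),
    )


def gain_report(
    data: pd.DataFrame, fit: FitResult, selected_clone: str | None = None
) -> GainReport:
    """Realised-gain row for the best (or a chosen) clone under one fit.

    The selected clone defaults to the top-BLUP clone; the selected and
    population means are plain means over the trees entering the fit.
    """
    summary = summarize_fit(data, fit)
    sub = data[(data["trait"] == fit.trait) & (data["age"] == fit.age)]
    if fit.model_tag == "single_site":
        sub = sub[sub["site"] == fit.site]
    if selected_clone is None:
        best = fit.blups.sort_values(["blup", "clone"], ascending=[False, True])
        selected_clone = str(best.iloc[0]["clone"])
    sel = sub[sub["clone"] == selected_clone]
    if sel.empty:
        raise ValueError(f"selected clone {selected_clone!r} not in data")
    sel_mean = float(sel["value"].mean())
    pop_mean = float(sub["value"].mean())
    return GainReport(
        trait=fit.trait,
        age=fit.age,
        site=summary.site,
        selected_clone=selected_clone,
        sel_mean=sel_mean,
        pop_mean=pop_mean,
        repeatability=summary.repeatability,
        gain_pct=genetic_gain(sel_mean, pop_mean, summary.repeatability),
    )


def gain_table(reports) -> pd.DataFrame:
    """Gain-report CSV: one row per (trait, age, site) selection."""
    return pd.DataFrame(
        [
            {
                "trait": r.trait,
                "age": r.age,
                "site": r.site,
                "selected_clone": r.selected_clone,
                "sel_mean": r.sel_mean,
                "pop_mean": r.pop_mean,
                "repeatability": r.repeatability,
                "gain_pct": r.gain_pct,
            }
            for r in reports
        ]
    )
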