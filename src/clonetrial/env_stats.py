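"""Trait-climate association and Mantel attribution of G-by-E drivers.

Two layers of analysis:

* direct association between site-year trait means and bioclimatic
  variables (Spearman rank correlation and simple linear regression);
* attribution of genotype-by-environment interaction to climate: the
  mean absolute between-site difference of each climate variable is
  correlated (Mantel permutation test) with the between-site G-by-E
  dissimilarity 1 - r_b, where r_b is the type-B genetic correlation.

With only three sites a Mantel p-value has floor 1/6 (six relabelings);
a warning recommends >=5 labels for calibrated inference.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trial_io import CLIMATE_VARIABLES, validate_climate


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None


def spearman_matrix(
    trait_values: pd.DataFrame, climate: pd.DataFrame, traits=None, variables=None
) -> pd.DataFrame:
    """Spearman rho and p for every (trait, climate variable) pair.

    ``trait_values`` carries columns (site, year, trait, value) of
    site-year trait means; rows are joined to the climate table on
    (site, year).  Average ranks handle ties; p is the two-sided
    t-approximation.  Pairs with a constant vector are reported with
    missing rho/p.
    """
    climate = validate_climate(climate)
    merged = trait_values.merge(climate, on=["site", "year"], how="inner")
    if merged.empty:
        raise ValueError("no overlapping (site, year) rows between traits and climate")
    traits = traits or sorted(trait_values["trait"].unique())
    variables = variables or CLIMATE_VARIABLES
    rows = []
    for t in traits:
        sub = merged[merged["trait"] == t]
        for v in variables:
            x = sub["value"].to_numpy(dtype=float)
            y = sub[v].to_numpy(dtype=float)
            if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append({"trait": t, "variable": v, "rho": np.nan, "p": np.nan,
                             "n": len(x)})
                continue
            rho, p = stats.spearmanr(x, y)
            rows.append({"trait": t, "variable": v, "rho": float(rho),
                         "p": float(p), "n": len(x)})
    return pd.DataFrame(rows)


def simple_regression(x, y):
    """Ordinary least squares of y on x: (slope, intercept, R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need >=3 points")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def regression_table(
    trait_values: pd.DataFrame, climate: pd.DataFrame, traits=None, variables=None
) -> pd.DataFrame:
    """Slope, intercept and R^2 of each trait on each climate variable."""
    climate = validate_climate(climate)
    merged = trait_values.merge(climate, on=["site", "year"], how="inner")
    traits = traits or sorted(trait_values["trait"].unique())
    variables = variables or CLIMATE_VARIABLES
    rows = []
    for t in traits:
        sub = merged[merged["trait"] == t]
        for v in variables:
            slope, intercept, r2 = simple_regression(
                sub[v].to_numpy(), sub["value"].to_numpy()
            )
            rows.append({"trait": t, "variable": v, "slope": slope,
                         "intercept": intercept, "r2": r2})
    return pd.DataFrame(rows)


def _check_square(mat: pd.DataFrame, name: str):
    if list(mat.index) != list(mat.columns):
        raise ValueError(f"{name}: labels on rows and columns differ")
    a = mat.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError(f"{name}: matrix not symmetric")
    if not np.allclose(np.diag(a), 0.0, atol=1e-10):
        raise ValueError(f"{name}: diagonal not zero")
    return a


def env_change_matrix(climate: pd.DataFrame, variable: str, years=None) -> pd.DataFrame:
    """Between-site change in one climate variable.

    Entry (s1, s2) is the mean over years of |value(s1, y) - value(s2, y)|
    — the annual absolute difference averaged over the study window.
    Symmetric with zero diagonal; a pseudometric for single-year input.
    """
    climate = validate_climate(climate)
    if years is not None:
        climate = climate[climate["year"].isin(list(years))]
    wide = climate.pivot_table(index="year", columns="site", values=variable)
    na = wide.isna()
    if na.any().any():
        year = na.index[na.any(axis=1)][0]
        site = na.columns[na.loc[year]][0]
        raise ValueError(f"missing climate cell (year, site) = ({year}, {site})")
    sites = list(wide.columns)
    out = pd.DataFrame(0.0, index=sites, columns=sites)
    for s1, s2 in itertools.combinations(sites, 2):
        d = float(np.mean(np.abs(wide[s1] - wide[s2])))
        out.loc[s1, s2] = out.loc[s2, s1] = d
    return out


def typeb_distance_matrix(rb: pd.DataFrame) -> pd.DataFrame:
    """G-by-E dissimilarity 1 - r_b from a pairwise type-B correlation table.

    ``rb`` is a symmetric site x site table with unit diagonal (r_b of a
    site with itself is 1).  Larger output entries mean stronger G-by-E
    between the pair.
    """
    a = rb.to_numpy(dtype=float)
    if list(rb.index) != list(rb.columns):
        raise ValueError("labels on rows and columns differ")
    off = a[~np.eye(len(a), dtype=bool)]
    if np.any((off < 0) | (off > 1)):
        raise ValueError("type-B correlations must lie in [0, 1]")
    out = 1.0 - a
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=rb.index, columns=rb.columns)


def _upper(a: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(a.shape[0], k=1)
    return a[iu]


def mantel_test(
    A: pd.DataFrame, B: pd.DataFrame, n_perm: int = 999, seed: int | None = 0
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    r is the Pearson correlation of the off-diagonal upper triangles; the
    two-sided p-value counts joint row/column relabelings of B with
    |r*| >= |r|, with the +1 correction.  For <=5 labels all relabelings
    are enumerated exactly.
    """
    a = _check_square(A, "A")
    b = _check_square(B, "B")
    if list(A.index) != list(B.index):
        raise ValueError("matrices must share the same labels in the same order")
    m = a.shape[0]
    if m < 3:
        raise ValueError("need >=3 labels")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if m == 3:
        warnings.warn(
            "with 3 labels the Mantel p-value has floor 1/6; "
            "use >=5 labels for calibrated inference",
            stacklevel=2,
        )
    va = _upper(a)
    vb = _upper(b)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("zero-variance distance triangle")
    r_obs = float(np.corrcoef(va, vb)[0, 1])

    def r_perm(perm):
        bp = b[np.ix_(perm, perm)]
        return float(np.corrcoef(va, _upper(bp))[0, 1])

    if m <= 5:
        perms = [p for p in itertools.permutations(range(m))]
        rs = np.array([r_perm(np.asarray(p)) for p in perms])
        n_used = len(perms) - 1  # identity excluded from the random draws
        count = int(np.sum(np.abs(rs[1:]) >= abs(r_obs) - 1e-12))
        p = (count + 1) / (n_used + 1)
        return MantelResult(r=r_obs, p=float(p), n_perm=n_used, seed=seed)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(m)
        if abs(r_perm(perm)) >= abs(r_obs) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm, seed=seed)


def mantel_report(
    rb_matrices: dict,
    climate: pd.DataFrame,
    variables=None,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Mantel r and p of each trait's G-by-E pattern against each variable.

    ``rb_matrices`` maps trait -> site x site type-B correlation table.
    Both the dissimilarity form (1 - r_b, primary: positive r means the
    variable's change tracks stronger G-by-E) and the raw-r_b form are
    reported.
    """
    variables = variables or CLIMATE_VARIABLES
    rows = []
    for trait, rb in rb_matrices.items():
        dist = typeb_distance_matrix(rb)
        raw = rb.copy()
        raw_arr = raw.to_numpy(dtype=float).copy()
        np.fill_diagonal(raw_arr, 0.0)
        raw = pd.DataFrame(raw_arr, index=rb.index, columns=rb.columns)
        for v in variables:
            env = env_change_matrix(climate, v)
            env = env.loc[dist.index, dist.index]
            res = mantel_test(env, dist, n_perm=n_perm, seed=seed)
            res_raw = mantel_test(env, raw, n_perm=n_perm, seed=seed)
            rows.append(
                {
                    "trait": trait,
                    "variable": v,
                    "r_dissimilarity": res.r,
                    "p_dissimilarity": res.p,
                    "r_raw_rb": res_raw.r,
                    "p_raw_rb": res_raw.p,
                    "n_perm": res.n_perm,
                }
            )
    return pd.DataFrame(rows)


def site_year_trait_means(
    data: pd.DataFrame, planting_year: int
) -> pd.DataFrame:
    """Site-year mean of each trait's annual measurement.

    Tree age a maps to calendar year ``planting_year + a``; returns
    columns (site, year, trait, value) ready for the climate join.
    """
    out = (
        data.groupby(["site", "age", "trait"])["value"].mean().reset_index()
    )
    out["year"] = out["age"].astype(int) + int(planting_year)
    return out[["site", "year", "trait", "value"]]
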