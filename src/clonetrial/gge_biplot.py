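"""BLUP-GGE biplot engine: SVD of the environment-centered clone table.

A genotype-by-environment (G+GE) table of per-site clone BLUPs is
environment-centered (optionally scaled by each environment's standard
deviation) and decomposed by SVD.  The first two principal components
carry the genotype main effect plus the genotype-by-environment signal;
the classic biplot views are computed from them:

* discrimination vs representativeness of test environments,
* which-won-where (convex-hull sectors and per-environment winners),
* mean vs stability along the average-environment axis (AEA),
* genotype ranking against the ideal genotype.

Singular-value partitioning (SVP) controls which side of the biplot
carries the singular values for display.  All rankings and winners are
computed from the SVP-invariant rank-2 inner-product geometry, so the SVP
mode affects exported coordinates only, never a selection decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull


@dataclass
class GeMatrix:
    """Genotype x environment value table with an imputation record."""

    values: pd.DataFrame  # index: genotype ids, columns: environment ids
    imputed: list = field(default_factory=list)  # (genotype, environment)
    dropped_genotypes: list = field(default_factory=list)


@dataclass
class GgeModel:
    centering: str  # "env_centered"
    scaling: str  # "none" | "env_sd"
    svp: str  # "genotype_focused" | "environment_focused" | "symmetric"
    genotypes: list
    environments: list
    genotype_scores: np.ndarray  # (g, 2) display coordinates per svp
    environment_scores: np.ndarray  # (e, 2)
    singular_values: np.ndarray  # all, nonincreasing
    pct_explained: np.ndarray  # per PC, sums to 100
    u2: np.ndarray = None  # (g, 2) left singular vectors
    v2: np.ndarray = None  # (e, 2) right singular vectors
    processed: np.ndarray = None  # centered/scaled matrix

    # SVP-invariant internal coordinates (genotype-focused convention);
    # their inner products reproduce the rank-2 reconstruction.
    @property
    def g_internal(self) -> np.ndarray:
        return self.u2 * self.singular_values[:2]

    @property
    def e_internal(self) -> np.ndarray:
        return self.v2

    def rank2(self) -> np.ndarray:
        return self.g_internal @ self.e_internal.T


_SVP_MODES = ("genotype_focused", "environment_focused", "symmetric")


def build_ge_matrix(
    blups: pd.DataFrame,
    trait: str,
    age: int,
    min_environments: int = 2,
) -> GeMatrix:
    """Assemble the genotype x environment table from per-site BLUPs.

    Genotypes present in fewer than ``min_environments`` environments are
    dropped (and reported); remaining missing cells are imputed with the
    environment's mean over observed genotypes, which after centering is
    a neutral zero, and flagged.
    """
    sub = blups[(blups["trait"] == trait) & (blups["age"] == int(age))]
    sub = sub[sub["site"] != "ALL"]
    if sub.empty:
        raise ValueError(f"no per-site BLUPs for trait={trait!r} age={age}")
    mat = sub.pivot_table(index="clone", columns="site", values="blup")
    if mat.shape[1] < 2:
        raise ValueError("need >=2 environments")
    never = mat.index[mat.notna().sum(axis=1) == 0].tolist()
    if never:
        raise ValueError(f"genotypes observed nowhere: {never}")
    present = mat.notna().sum(axis=1)
    dropped = mat.index[present < min_environments].tolist()
    mat = mat.loc[present >= min_environments]
    if mat.shape[0] < 3:
        raise ValueError("need >=3 genotypes after filtering")
    imputed = [
        (g, e) for g in mat.index for e in mat.columns if pd.isna(mat.at[g, e])
    ]
    mat = mat.fillna(mat.mean(axis=0))
    return GeMatrix(values=mat, imputed=imputed, dropped_genotypes=dropped)


def fit_gge(
    matrix: GeMatrix | pd.DataFrame,
    scaling: str = "env_sd",
    svp: str = "genotype_focused",
) -> GgeModel:
    """Environment-centered (optionally SD-scaled) SVD of the G+GE table.

    Each environment's mean is subtracted (G+GE centering); with
    ``scaling="env_sd"`` each centered column is divided by its sample
    standard deviation.  Scores for PCs 1-2 are scaled by the singular
    values according to the SVP mode; the percentage of G+GE variation
    explained by PC k is 100 * lambda_k^2 / sum lambda^2.
    """
    if svp not in _SVP_MODES:
        raise ValueError(f"svp must be one of {_SVP_MODES}")
    if scaling not in ("none", "env_sd"):
        raise ValueError("scaling must be 'none' or 'env_sd'")
    values = matrix.values if isinstance(matrix, GeMatrix) else matrix
    if isinstance(values, pd.DataFrame):
        genotypes = list(values.index)
        environments = list(values.columns)
        M = values.to_numpy(dtype=float)
    else:
        M = np.asarray(values, dtype=float)
        genotypes = [f"G{i + 1}" for i in range(M.shape[0])]
        environments = [f"E{j + 1}" for j in range(M.shape[1])]
    if M.shape[0] < 3 or M.shape[1] < 2:
        raise ValueError("need >=3 genotypes and >=2 environments")

    P = M - M.mean(axis=0, keepdims=True)
    if scaling == "env_sd":
        sd = P.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [environments[j] for j in np.where(sd == 0)[0]]
            raise ValueError(f"zero-variance environments under env_sd scaling: {bad}")
        P = P / sd

    U, lam, Vt = np.linalg.svd(P, full_matrices=False)
    V = Vt.T
    # Deterministic sign: make the largest-magnitude loading of each PC's
    # environment vector positive.
    for k in range(len(lam)):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
            U[:, k] = -U[:, k]
    energy = np.sum(lam**2)
    pct = 100.0 * lam**2 / energy if energy > 0 else np.zeros_like(lam)

    l2 = lam[:2]
    if svp == "genotype_focused":
        g_scores = U[:, :2] * l2
        e_scores = V[:, :2]
    elif svp == "environment_focused":
        g_scores = U[:, :2]
        e_scores = V[:, :2] * l2
    else:
        root = np.sqrt(l2)
        g_scores = U[:, :2] * root
        e_scores = V[:, :2] * root

    return GgeModel(
        centering="env_centered",
        scaling=scaling,
        svp=svp,
        genotypes=genotypes,
        environments=environments,
        genotype_scores=g_scores,
        environment_scores=e_scores,
        singular_values=lam,
        pct_explained=pct,
        u2=U[:, :2],
        v2=V[:, :2],
        processed=P,
    )


def _aea_unit(model: GgeModel) -> np.ndarray:
    """Unit vector of the average-environment axis (internal coordinates)."""
    mean_env = model.e_internal.mean(axis=0)
    norm = np.linalg.norm(mean_env)
    if norm < 1e-12:
        raise ValueError("average environment vector is ~0; AEA undefined")
    return mean_env / norm


def which_won_where(model: GgeModel) -> dict:
    """Convex-hull sectors and the winning genotype per environment.

    The hull of genotype points partitions the biplot into sectors by
    perpendiculars from the origin to the hull edges; each environment's
    winner is the hull-vertex genotype maximising the rank-2 inner
    product with that environment — the genotype predicted best there.
    """
    G = model.g_internal
    E = model.e_internal
    if np.allclose(G, G[0], atol=1e-12):
        raise ValueError("all genotype scores identical; hull degenerate")
    try:
        hull = ConvexHull(G)
        vertices = [model.genotypes[i] for i in hull.vertices]
        vertex_idx = list(hull.vertices)
    except Exception:  # collinear points: hull = extreme pair
        d = G - G.mean(axis=0)
        proj = d @ (d[np.argmax(np.linalg.norm(d, axis=1))] / max(
            np.linalg.norm(d[np.argmax(np.linalg.norm(d, axis=1))]), 1e-12))
        vertex_idx = [int(np.argmin(proj)), int(np.argmax(proj))]
        vertices = [model.genotypes[i] for i in vertex_idx]

    scores = E @ G.T  # (e, g) rank-2 predicted values
    winners = {}
    for j, env in enumerate(model.environments):
        order = np.lexsort((model.genotypes, -scores[j]))
        winners[env] = model.genotypes[int(order[0])]

    # Sector membership: environments grouped by their winning vertex.
    sectors = {}
    for env, w in winners.items():
        sectors.setdefault(w, []).append(env)
    return {"vertices": vertices, "vertex_idx": vertex_idx,
            "winners": winners, "sectors": sectors}


def mean_vs_stability(model: GgeModel) -> pd.DataFrame:
    """Mean performance and instability per genotype.

    Mean projection: genotype score onto the AEA unit vector (larger =
    higher predicted mean across environments).  Stability: unsigned
    perpendicular distance to the AEA (smaller = more stable).
    """
    a = _aea_unit(model)
    G = model.g_internal
    proj = G @ a
    perp = G - np.outer(proj, a)
    dist = np.linalg.norm(perp, axis=1)
    return pd.DataFrame(
        {
            "genotype": model.genotypes,
            "mean_projection": proj,
            "stability_distance": dist,
        }
    )


def discrimination_representativeness(model: GgeModel) -> pd.DataFrame:
    """Per-environment vector length (discrimination) and angle to the AEA
    in degrees (representativeness; smaller = more representative).

    Computed on the display coordinates (environment-focused SVP is the
    conventional choice for this view)."""
    a_disp = model.environment_scores.mean(axis=0)
    norm_a = np.linalg.norm(a_disp)
    if norm_a < 1e-12:
        raise ValueError("average environment vector is ~0; AEA undefined")
    a_disp = a_disp / norm_a
    E = model.environment_scores
    lengths = np.linalg.norm(E, axis=1)
    if np.any(lengths < 1e-12):
        raise ValueError("zero-length environment vector")
    cosang = np.clip(E @ a_disp / lengths, -1.0, 1.0)
    angles = np.degrees(np.arccos(cosang))
    return pd.DataFrame(
        {
            "environment": model.environments,
            "vector_length": lengths,
            "angle_to_aea_deg": angles,
        }
    )


def rank_genotypes(model: GgeModel) -> pd.DataFrame:
    """Rank genotypes by distance to the ideal genotype.

    The ideal genotype sits on the AEA at the maximum observed mean
    projection (highest mean, zero instability); genotypes are ranked by
    ascending Euclidean distance to it, ties broken by genotype id.
    """
    a = _aea_unit(model)
    G = model.g_internal
    proj = G @ a
    ideal = a * proj.max()
    dist = np.linalg.norm(G - ideal, axis=1)
    out = pd.DataFrame({"genotype": model.genotypes, "distance_to_ideal": dist})
    out = out.sort_values(["distance_to_ideal", "genotype"]).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def coordinates_table(model: GgeModel) -> pd.DataFrame:
    """Display coordinates CSV: entity, kind, PC1, PC2."""
    rows = [
        {"entity": g, "kind": "genotype",
         "PC1": model.genotype_scores[i, 0], "PC2": model.genotype_scores[i, 1]}
        for i, g in enumerate(model.genotypes)
    ] + [
        {"entity": e, "kind": "environment",
         "PC1": model.environment_scores[j, 0], "PC2": model.environment_scores[j, 1]}
        for j, e in enumerate(model.environments)
    ]
    return pd.DataFrame(rows)
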