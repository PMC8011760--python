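"""Lightweight weighted co-expression analysis.

The workflow mirrors the classic weighted network recipe: power adjacency
|r|^beta on Pearson correlations, topological overlap similarity, average-
linkage clustering of 1-TOM with a static tree cut, module eigengenes as
first principal components, top-edge export and hypergeometric term
enrichment. The static cut (instead of a dynamic hybrid cut) keeps module
detection deterministic and dependency-free; the cut height and minimum
module size are exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

__all__ = [
    "CoexprModule",
    "EnrichmentResult",
    "adjacency",
    "tom_similarity",
    "detect_modules",
    "eigengene",
    "top_edges",
    "hypergeom_enrich",
]

UNASSIGNED = "unassigned"


@dataclass
class CoexprModule:
    id: str
    members: list[str]
    eigengene: np.ndarray | None = None
    explained_variance: float | None = None
    hub_rank: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k_hits: int
    n_module: int
    K_annotated: int
    N_population: int
    p: float
    significant: bool


def adjacency(expr: pd.DataFrame, beta: float = 6.0) -> pd.DataFrame:
    """Signed-absolute power adjacency a_ij = |pearson(i, j)|^beta.

    ``expr`` is features x samples. Zero-variance features are excluded
    with a warning naming them; the diagonal is exactly 1.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sd = expr.std(axis=1)
    constant = list(expr.index[sd == 0])
    if constant:
        warnings.warn(f"excluding zero-variance features: {constant}")
        expr = expr.drop(index=constant)
    x = expr.to_numpy(dtype=float)
    r = np.corrcoef(x)
    a = np.abs(np.clip(r, -1, 1)) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a weighted adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    k = row sums minus the diagonal and the shared-neighbour sum taken over
    u distinct from i and j; TOM_ii = 1.
    """
    a = adj.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T):
        raise ValueError("adjacency must be square symmetric")
    k = a.sum(axis=1) - np.diag(a)
    shared = a @ a - a * np.diag(a)[None, :] - a * np.diag(a)[:, None]
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def detect_modules(tom: pd.DataFrame, min_module_size: int = 10,
                   cut_height: float = 0.9,
                   expr: pd.DataFrame | None = None) -> list[CoexprModule]:
    """Average-linkage clustering of 1-TOM with a static cut.

    Weighted-TOM dissimilarities concentrate near 1 even for related
    features (a power-6 adjacency shrinks moderate correlations hard), so
    the default static cut sits at 0.9; lower it for denser networks.

    Clusters below ``min_module_size`` are pooled into "unassigned".
    Modules are labelled M1, M2, ... by decreasing size; if ``expr`` is
    given, eigengenes and explained variances are filled in.
    """
    d = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)
    if len(tom) < 2:
        labels = np.ones(len(tom), dtype=int)
    else:
        z = hierarchy.linkage(squareform(d, checks=False), method="average")
        labels = hierarchy.fcluster(z, t=cut_height, criterion="distance")
    ids = np.asarray(tom.index)
    clusters: dict[int, list[str]] = {}
    for lab, fid in zip(labels, ids):
        clusters.setdefault(int(lab), []).append(str(fid))
    real = sorted((m for m in clusters.values() if len(m) >= min_module_size),
                  key=lambda m: (-len(m), m[0]))
    modules = [CoexprModule(f"M{i + 1}", members) for i, members in enumerate(real)]
    leftovers = sorted(f for m in clusters.values() if len(m) < min_module_size
                       for f in m)
    if leftovers:
        modules.append(CoexprModule(UNASSIGNED, leftovers))
    if expr is not None:
        for mod in modules:
            if mod.id == UNASSIGNED or len(mod.members) < 2:
                continue
            vec, ev = eigengene(expr.loc[mod.members])
            mod.eigengene, mod.explained_variance = vec, ev
    return modules


def eigengene(expr_submatrix: pd.DataFrame) -> tuple[np.ndarray, float]:
    """First principal component of standardized member profiles.

    Returns a unit-norm per-sample vector whose sign is fixed so the mean
    correlation with member profiles is non-negative, plus the fraction of
    variance it explains.
    """
    if expr_submatrix.shape[0] < 2 or expr_submatrix.shape[1] < 2:
        raise ValueError("need >= 2 members and >= 2 samples")
    x = expr_submatrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).all():
        raise ValueError("constant submatrix has no principal component")
    x = x[sd > 0]
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    vec = vt[0]
    corr = z @ vec / (np.linalg.norm(z, axis=1) * np.linalg.norm(vec))
    if corr.mean() < 0:
        vec = -vec
    vec = vec / np.linalg.norm(vec)
    explained = float(s[0] ** 2 / np.sum(s**2))
    return vec, explained


def top_edges(adj: pd.DataFrame, module: CoexprModule | list[str],
              k: int = 50) -> list[tuple[str, str, float]]:
    """The k heaviest intramodular edges, with deterministic tie-breaks.

    Edges are sorted by descending weight then lexicographic (id_i, id_j);
    the module's ``hub_rank`` (intramodular degree within this edge set) is
    refreshed when a :class:`CoexprModule` is passed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    members = module.members if isinstance(module, CoexprModule) else list(module)
    members = [m for m in members if m in adj.index]
    if len(members) < 2:
        return []
    edges = []
    for i, j in combinations(sorted(members), 2):
        edges.append((i, j, float(adj.at[i, j])))
    edges.sort(key=lambda e: (-e[2], e[0], e[1]))
    picked = edges[:k]
    if isinstance(module, CoexprModule):
        degree: dict[str, int] = {}
        for i, j, _ in picked:
            degree[i] = degree.get(i, 0) + 1
            degree[j] = degree.get(j, 0) + 1
        module.hub_rank = degree
    return picked


def hypergeom_enrich(module_members, term_map, population,
                     alpha: float = 0.05) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation per term.

    ``term_map`` maps term -> annotated features (or a two-column DataFrame
    of feature, term pairs). p = P(X >= k) for k hits among n module members
    drawn from a population of N with K annotated; terms with K = 0 are
    skipped. Significance is the uncorrected p < alpha rule.
    """
    population = set(population)
    module = set(module_members)
    if not module <= population:
        raise ValueError("module members must be a subset of the population")
    if isinstance(term_map, pd.DataFrame):
        feature_col, term_col = term_map.columns[:2]
        mapping: dict[str, set] = {}
        for _, row in term_map.iterrows():
            mapping.setdefault(str(row[term_col]), set()).add(str(row[feature_col]))
        term_map = mapping
    N, n = len(population), len(module)
    results = []
    for term in sorted(term_map):
        annotated = set(term_map[term]) & population
        K = len(annotated)
        if K == 0:
            continue
        k = len(annotated & module)
        p = float(hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(term, k, n, K, N, p, p < alpha))
    results.sort(key=lambda r: (r.p, r.term))
    return results
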