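"""Weighted co-occurrence network, module detection and connectivity.

Adjacency is the soft-thresholded correlation ``a_ij = |tau_ij|^beta``;
beta comes from the scale-free topology criterion (smallest exponent
whose connectivity distribution fits log p(k) ~ -gamma log k with
R^2 at or above a target) unless fixed by configuration.  Taxa are
clustered by average linkage on 1 - TOM, where TOM is the topological
overlap

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

and modules are the dendrogram branches selected by a static cut with
small branches merged into their nearest module by mean TOM.
Intramodular connectivity (sum of within-module edge weights) ranks
taxa; the per-module maximum is the hub.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

__all__ = [
    "ScaleFreeFit",
    "NetworkModel",
    "select_beta",
    "adjacency",
    "topological_overlap",
    "cut_modules",
    "intramodular_connectivity",
    "hubs",
    "edge_list",
    "build_network",
    "dendrogram_to_newick",
]

#: module labels by decreasing size, echoing the usual color convention;
#: "unassigned" is reserved for leftovers and never used for a real module
MODULE_PALETTE = (
    "blue", "grey", "orange", "yellow", "green", "black", "brown", "red",
    "pink", "purple", "cyan", "magenta", "salmon", "tan", "gold", "plum",
)


@dataclass(frozen=True)
class ScaleFreeFit:
    beta: int
    r_squared: float
    slope: float
    mean_k: float


@dataclass
class NetworkModel:
    beta: int
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    dendrogram: np.ndarray                      # scipy linkage matrix
    modules: pd.Series                          # taxon -> label
    connectivity: pd.Series                     # taxon -> intramodular k
    fits: list[ScaleFreeFit] = field(default_factory=list)


def _abs_tau(tau: pd.DataFrame) -> np.ndarray:
    A = np.abs(tau.to_numpy(dtype=float))
    A[~np.isfinite(A)] = 0.0  # undefined-tau pairs carry no edge
    np.fill_diagonal(A, 0.0)
    return A


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of log10 p(k) vs log10 k over equal-width k bins."""
    k = np.asarray(k, dtype=float)
    if np.allclose(k, k[0]):
        raise ValueError("all connectivities equal; scale-free fit undefined")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        mean_k = members.mean()
        dens = members.size / k.size
        if mean_k > 0 and dens > 0:
            xs.append(math.log10(mean_k))
            ys.append(math.log10(dens))
    if len(xs) < 2:
        raise ValueError("too few occupied bins for a scale-free fit")
    fit = linregress(xs, ys)
    return float(fit.rvalue ** 2), float(fit.slope)


def select_beta(tau: pd.DataFrame,
                candidates=range(1, 31),
                r2_target: float = 0.8,
                n_bins: int = 10) -> tuple[int, list[ScaleFreeFit]]:
    """Smallest beta meeting the scale-free criterion (R^2, negative slope).

    Falls back to the argmax-R^2 candidate with a warning when no
    candidate reaches the target.
    """
    A0 = _abs_tau(tau)
    fits: list[ScaleFreeFit] = []
    for beta in candidates:
        k = (A0 ** beta).sum(axis=1)
        try:
            r2, slope = scale_free_fit(k, n_bins=n_bins)
        except ValueError:
            continue
        fits.append(ScaleFreeFit(int(beta), r2, slope, float(k.mean())))
    if not fits:
        raise ValueError("no scale-free fit could be computed for any beta")
    for f in fits:
        if f.r_squared >= r2_target and f.slope < 0:
            return f.beta, fits
    # fallback: the best negative-slope fit (a positive slope contradicts
    # the criterion); only when no slope is negative take the raw argmax
    decaying = [f for f in fits if f.slope < 0]
    best = max(decaying or fits, key=lambda f: f.r_squared)
    warnings.warn(
        f"no candidate beta reached R^2 >= {r2_target} with negative slope; "
        f"falling back to beta={best.beta} (R^2={best.r_squared:.3f})")
    return best.beta, fits


def adjacency(tau: pd.DataFrame, beta: int) -> pd.DataFrame:
    """``a_ij = |tau_ij|^beta`` with zero diagonal; NaN tau -> 0."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    A = _abs_tau(tau) ** beta
    return pd.DataFrame(A, index=tau.index, columns=tau.columns)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij); diag 1."""
    A = adj.to_numpy(dtype=float)
    k = A.sum(axis=1)
    numerator = A @ A + A
    denominator = np.minimum.outer(k, k) + 1.0 - A
    T = numerator / denominator
    np.fill_diagonal(T, 1.0)
    return pd.DataFrame(np.clip(T, 0.0, 1.0), index=adj.index, columns=adj.columns)


def _branches_at(Z: np.ndarray, height: float) -> np.ndarray:
    return fcluster(Z, t=height, criterion="distance")


def _modularity(A: np.ndarray, labels: np.ndarray) -> float:
    """Newman weighted modularity of a hard partition on adjacency A."""
    two_m = A.sum()
    if two_m == 0:
        return 0.0
    k = A.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += A[np.ix_(idx, idx)].sum() / two_m - (k[idx].sum() / two_m) ** 2
    return float(q)


def cut_modules(Z: np.ndarray, tom: pd.DataFrame,
                min_size: int = 5,
                cut_height: float | None = None) -> pd.Series:
    """Extract modules from the dendrogram branches.

    With an explicit ``cut_height`` the tree is cut statically there.
    By default every inter-merge height is scanned and the cut whose
    branch partition maximises weighted modularity on the TOM graph is
    chosen (ties break toward the higher cut) — a deterministic
    simplification of dynamic branch cutting.  Branches below
    ``min_size`` are merged into the module with the highest mean TOM
    to their members, or labeled ``"unassigned"`` when no module exists.
    Labels are color names ordered by decreasing module size.
    """
    n = len(tom)
    if min_size > n:
        raise ValueError(f"min_size={min_size} exceeds the {n} taxa available")
    T = tom.to_numpy()
    W = T - np.diag(np.diag(T))  # self-similarity carries no edge weight
    heights = np.sort(np.unique(Z[:, 2]))
    if cut_height is not None:
        cuts = [float(cut_height)]
    else:
        mids = (heights[:-1] + heights[1:]) / 2.0
        cuts = list(mids) + [float(heights[-1]) + 1.0]

    best = None
    for h in cuts:
        labels = _branches_at(Z, h)
        if len(np.unique(labels)) > max(2 * n // min_size, 8):
            continue  # far too fragmented to be a useful partition
        key = (_modularity(W, labels), h)
        if best is None or key > best[0]:
            best = (key, labels)
    if best is None:  # every scanned cut was fragmented; fall back to 2 branches
        labels = _branches_at(Z, float(heights[-1]) - 1e-12)
    else:
        _, labels = best
    sizes = np.bincount(labels)
    big = {b for b in np.unique(labels) if sizes[b] >= min_size}

    ids = np.asarray(tom.index)
    T = tom.to_numpy()
    member_lists = {b: np.flatnonzero(labels == b) for b in np.unique(labels)}

    # order real modules by size desc, then by lexicographically smallest member
    real = sorted(big, key=lambda b: (-len(member_lists[b]),
                                      str(min(ids[member_lists[b]]))))
    name_of = {b: (MODULE_PALETTE[i] if i < len(MODULE_PALETTE)
                   else f"module{i + 1}") for i, b in enumerate(real)}

    assigned = pd.Series("unassigned", index=tom.index, dtype=object)
    for b in real:
        assigned.iloc[member_lists[b]] = name_of[b]
    for b in member_lists:
        if b in big:
            continue
        idx = member_lists[b]
        best_module, best_sim = None, 0.0
        for m in real:
            sim = float(T[np.ix_(idx, member_lists[m])].mean())
            if sim > best_sim:
                best_module, best_sim = m, sim
        if best_module is not None:
            assigned.iloc[idx] = name_of[best_module]
    return assigned


def intramodular_connectivity(adj: pd.DataFrame, modules: pd.Series) -> pd.Series:
    """k_i = sum of adjacency to same-module taxa."""
    A = adj.to_numpy()
    labels = modules.reindex(adj.index).to_numpy()
    same = labels[:, None] == labels[None, :]
    k = (A * same).sum(axis=1)
    return pd.Series(k, index=adj.index, name="intramodular_k")


def hubs(connectivity: pd.Series, modules: pd.Series,
         fraction: float = 0.10) -> pd.DataFrame:
    """Top-``fraction`` taxa by intramodular k per module (hub = rank 1).

    Ties break toward the lexicographically smaller taxon id.
    """
    rows = []
    for label in sorted(modules.unique()):
        if label == "unassigned":
            continue
        members = modules.index[modules == label]
        n_top = max(1, math.ceil(fraction * len(members)))
        ranked = sorted(members, key=lambda t: (-connectivity[t], str(t)))
        for rank, taxon in enumerate(ranked[:n_top], start=1):
            rows.append({"module": label, "taxon": taxon, "rank": rank,
                         "intramodular_k": float(connectivity[taxon]),
                         "is_hub": rank == 1})
    return pd.DataFrame(rows)


def edge_list(adj: pd.DataFrame, modules: pd.Series,
              threshold: float = 0.2) -> pd.DataFrame:
    """Within-module edges with weight strictly above the view threshold."""
    A = adj.to_numpy()
    ids = np.asarray(adj.index)
    labels = modules.reindex(adj.index).to_numpy()
    iu = np.triu_indices(len(ids), k=1)
    same = labels[iu[0]] == labels[iu[1]]
    keep = same & (A[iu] > threshold) & (labels[iu[0]] != "unassigned")
    return pd.DataFrame({
        "source": ids[iu[0]][keep],
        "target": ids[iu[1]][keep],
        "weight": A[iu][keep],
        "module": labels[iu[0]][keep],
    })


def build_network(tau: pd.DataFrame, beta: int | str = "auto",
                  min_size: int = 5, cut_height: float | None = None,
                  r2_target: float = 0.8) -> NetworkModel:
    """Tau matrix -> adjacency -> TOM -> dendrogram -> modules -> k."""
    fits: list[ScaleFreeFit] = []
    if beta == "auto":
        beta, fits = select_beta(tau, r2_target=r2_target)
    beta = int(beta)
    adj = adjacency(tau, beta)
    tom = topological_overlap(adj)
    dist = 1.0 - tom.to_numpy()
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    modules = cut_modules(Z, tom, min_size=min_size, cut_height=cut_height)
    k = intramodular_connectivity(adj, modules)
    return NetworkModel(beta, adj, tom, Z, modules, k, fits)


def dendrogram_to_newick(Z: np.ndarray, ids) -> str:
    """Render a scipy linkage matrix as a Newick string with branch heights."""
    ids = list(ids)
    n = len(ids)
    clusters: dict[int, tuple[str, float]] = {
        i: (str(ids[i]).replace(" ", "_"), 0.0) for i in range(n)}
    for step, (left, right, height, _) in enumerate(Z):
        ln, lh = clusters.pop(int(left))
        rn, rh = clusters.pop(int(right))
        node = f"({ln}:{height - lh:.6f},{rn}:{height - rh:.6f})"
        clusters[n + step] = (node, float(height))
    (root, _), = clusters.values()
    return root + ";"
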