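"""The NetMoss module-shift scoring algorithm.

Given a health-state and a disease-state correlation network over the
same taxa, the score of a taxon measures how strongly it drives the
re-organization of network modules between the two states:

1. correlations c are mapped to similarities s = (1 + c) / 2 in [0, 1];
2. a soft threshold beta (chosen for approximate scale-free topology,
   as in weighted gene co-expression analysis) gives the weighted
   adjacency a = s^beta;
3. the topological overlap w_ij = (l_ij + a_ij) / (min{k_i, k_j} + 1 - a_ij)
   with l_ij = sum_u a_iu a_uj and k_i = sum_u a_iu turns shared
   neighborhoods into a similarity, and d = 1 - w into a distance;
4. average-linkage clustering of d yields a module partition per state;
   crossing the two partitions yields K intersection modules — the
   units that remain identifiable across states;
5. per node, the mean distance to each intersection module is computed
   in both states (N x K matrices), their difference is the
   differential module distance DeltaD, and the NetMoss score contrasts
   DeltaD summed over the node's health-side neighboring modules
   against its disease-side neighboring modules.

A node whose module membership is stable scores near zero; a node that
migrates between modules moves away from its old neighborhood and
towards a new one simultaneously, and both terms push its score up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .integrate import IntegratedNetwork, align_taxa, pool_correlations, unweighted_pool
from .io import CorrelationNetwork

__all__ = [
    "ModulePartition",
    "IntersectionModules",
    "TomDistance",
    "NetMossResult",
    "linear_transform",
    "pick_soft_threshold",
    "scale_free_fit",
    "weighted_adjacency",
    "connection_strength",
    "topological_overlap",
    "detect_modules",
    "intersect_partitions",
    "module_mean_distance",
    "netmoss_scores",
    "run_netmoss",
]

DEFAULT_BETAS = tuple(range(1, 21))
SCALE_FREE_R2_TARGET = 0.8


# ---------------------------------------------------------------------------
# elementwise transforms


def linear_transform(c: np.ndarray) -> np.ndarray:
    """Map correlations in [-1, 1] to similarities s = (1 + c) / 2 in [0, 1]."""
    c = np.asarray(c, dtype=float)
    if np.abs(c).max(initial=0.0) > 1 + 1e-9:
        raise ValueError("correlations outside [-1, 1]")
    return (1.0 + np.clip(c, -1.0, 1.0)) / 2.0


def weighted_adjacency(s: np.ndarray, beta: float) -> np.ndarray:
    """Soft-thresholded adjacency a = |s|^beta with zeroed diagonal."""
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    s = np.asarray(s, dtype=float)
    if s.min(initial=0.0) < -1e-12 or s.max(initial=0.0) > 1 + 1e-12:
        raise ValueError("similarities outside [0, 1]")
    a = np.abs(s) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def scale_free_fit(a: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index of a weighted adjacency.

    Bins the connectivities k_i = sum_j a_ij, regresses log10 frequency
    on log10 mean connectivity per bin, and returns R^2 when the slope
    is negative (heavy-tailed, scale-free-like) and 0 otherwise.
    """
    k = a.sum(axis=1)
    k = k[k > 0]
    if k.size < 4 or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_p = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        log_k.append(np.log10(members.mean()))
        log_p.append(np.log10(members.size / k.size))
    if len(log_k) < 3:
        return 0.0
    log_k, log_p = np.asarray(log_k), np.asarray(log_p)
    if np.ptp(log_k) == 0:
        return 0.0
    slope, _ = np.polyfit(log_k, log_p, 1)
    r = np.corrcoef(log_k, log_p)[0, 1]
    r2 = float(r * r)
    return r2 if slope < 0 else 0.0


def pick_soft_threshold(
    s: np.ndarray,
    candidate_betas: Sequence[int] = DEFAULT_BETAS,
    r2_target: float = SCALE_FREE_R2_TARGET,
) -> int:
    """Choose the smallest beta whose adjacency reaches the scale-free fit target.

    Falls back to the best-fitting candidate (with a warning) when no
    candidate reaches ``r2_target``.
    """
    s = np.asarray(s, dtype=float)
    if s.shape[0] < 4:
        raise ValueError(f"need >= 4 nodes to fit a soft threshold, got {s.shape[0]}")
    if len(candidate_betas) == 0:
        raise ValueError("empty candidate list")
    fits = []
    for beta in candidate_betas:
        fits.append(scale_free_fit(weighted_adjacency(s, beta)))
        if fits[-1] >= r2_target:
            return int(beta)
    best = int(np.argmax(fits))
    warnings.warn(
        f"no candidate beta reached scale-free fit {r2_target}; "
        f"using beta={candidate_betas[best]} (fit {fits[best]:.3f})",
        stacklevel=2,
    )
    return int(candidate_betas[best])


# ---------------------------------------------------------------------------
# topology


def connection_strength(a: np.ndarray, partition: "ModulePartition | None" = None) -> np.ndarray:
    """Total connection of each node, optionally module-signed.

    Without a partition this is the plain row sum k_i = sum_j a_ij.
    With one, connections inside the node's own module count positively
    and connections to other modules negatively, so hub nodes of
    well-separated modules score highest.
    """
    a = np.asarray(a, dtype=float)
    if partition is None:
        return a.sum(axis=1)
    labels = np.asarray(partition.labels)
    if labels.shape[0] != a.shape[0]:
        raise ValueError("partition does not cover all nodes")
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, True)
    return (np.where(same, a, 0.0)).sum(axis=1) - (np.where(~same, a, 0.0)).sum(axis=1)


def topological_overlap(a: np.ndarray) -> "TomDistance":
    """Topological overlap similarity and its distance.

    w_ij = (l_ij + a_ij) / (min{k_i, k_j} + 1 - a_ij) where
    l_ij = sum_u a_iu a_uj counts shared-neighbor connectivity and
    k_i = sum_u a_iu is the node connectivity.  The diagonal is set to
    overlap 1 (distance 0 to self); a fully isolated pair has overlap 0.
    """
    a = np.asarray(a, dtype=float)
    if not np.allclose(a, a.T, atol=1e-10, rtol=0):
        raise ValueError("adjacency must be symmetric")
    if np.abs(np.diag(a)).max(initial=0.0) > 1e-12:
        raise ValueError("adjacency diagonal must be zero")
    if a.min(initial=0.0) < -1e-12 or a.max(initial=0.0) > 1 + 1e-12:
        raise ValueError("adjacency entries outside [0, 1]")
    k = a.sum(axis=1)
    # l_ij excludes u in {i, j}: full product sum minus the u=i and u=j terms
    # (a_ii = a_jj = 0 already removes them from the matrix product).
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = (l + a) / denom
    omega = np.where(denom > 0, omega, 0.0)
    # numerically the ratio can poke a hair above 1; clamp
    omega = np.clip((omega + omega.T) / 2, 0.0, 1.0)
    np.fill_diagonal(omega, 1.0)
    return TomDistance(omega=omega, dist=1.0 - omega, strength=k)


@dataclass
class TomDistance:
    """Topological overlap matrix, its distance 1 - omega, and node strengths."""

    omega: np.ndarray
    dist: np.ndarray
    strength: np.ndarray


# ---------------------------------------------------------------------------
# modules


@dataclass
class ModulePartition:
    """Node -> module assignment from clustering a distance matrix."""

    labels: np.ndarray  # integer module label per node
    nodes: list[str] = field(default_factory=list)

    @property
    def modules(self) -> list[np.ndarray]:
        """Node-index sets, one per module, in label order."""
        return [np.flatnonzero(self.labels == m) for m in np.unique(self.labels)]

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.labels))


def detect_modules(
    dist: np.ndarray,
    min_module_size: int = 5,
    cut_fraction: float = 0.99,
) -> ModulePartition:
    """Partition nodes by average-linkage clustering of a distance matrix.

    The dendrogram is cut at ``cut_fraction`` of its maximum merge
    height; clusters smaller than ``min_module_size`` are then merged
    into their nearest cluster by average inter-cluster distance until
    every module is large enough (or only one remains).  When all merge
    heights coincide the matrix carries no module structure and a
    single module is returned.  Fully deterministic.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if n < 2:
        return ModulePartition(labels=np.zeros(max(n, 0), dtype=int))
    if n < min_module_size:
        warnings.warn(
            f"{n} nodes < min_module_size={min_module_size}; single module",
            stacklevel=2,
        )
        return ModulePartition(labels=np.zeros(n, dtype=int))
    condensed = squareform(np.clip((dist + dist.T) / 2, 0.0, None), checks=False)
    link = hierarchy.linkage(condensed, method="average")
    heights = link[:, 2]
    if np.ptp(heights) < 1e-12:
        return ModulePartition(labels=np.zeros(n, dtype=int))
    cut = cut_fraction * heights.max()
    labels = hierarchy.fcluster(link, t=cut, criterion="distance")
    labels = np.asarray(labels, dtype=int)

    # merge undersized clusters into their nearest neighbor cluster
    def mean_between(m1: np.ndarray, m2: np.ndarray) -> float:
        return float(dist[np.ix_(m1, m2)].mean())

    while True:
        uniq, counts = np.unique(labels, return_counts=True)
        if len(uniq) <= 1:
            break
        small = uniq[counts < min_module_size]
        if small.size == 0:
            break
        # absorb the smallest cluster first; ties -> lowest label
        order = np.lexsort((small, counts[np.isin(uniq, small)]))
        victim = small[order[0]]
        members = np.flatnonzero(labels == victim)
        others = [m for m in uniq if m != victim]
        nearest = min(others, key=lambda m: (mean_between(members, np.flatnonzero(labels == m)), m))
        labels[members] = nearest

    # relabel 0..M-1 in order of first appearance
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap)
    return ModulePartition(labels=np.array([remap[lab] for lab in labels], dtype=int))


@dataclass
class IntersectionModules:
    """Nonempty pairwise intersections of a health and a disease partition."""

    cells: list[np.ndarray]  # node-index sets
    health_module: list[int]  # parent health module per cell
    disease_module: list[int]  # parent disease module per cell

    @property
    def K(self) -> int:
        return len(self.cells)

    def cell_of_node(self, n_nodes: int) -> np.ndarray:
        out = np.full(n_nodes, -1, dtype=int)
        for idx, cell in enumerate(self.cells):
            out[cell] = idx
        return out


def intersect_partitions(
    p_health: ModulePartition, p_disease: ModulePartition
) -> IntersectionModules:
    """Cross two partitions of the same node set into intersection cells.

    K, the number of nonempty cells, is at most the product of the two
    module counts.
    """
    if len(p_health.labels) != len(p_disease.labels):
        raise ValueError("partitions cover different node sets")
    cells, hmods, dmods = [], [], []
    for h in np.unique(p_health.labels):
        for d in np.unique(p_disease.labels):
            members = np.flatnonzero((p_health.labels == h) & (p_disease.labels == d))
            if members.size:
                cells.append(members)
                hmods.append(int(h))
                dmods.append(int(d))
    return IntersectionModules(cells=cells, health_module=hmods, disease_module=dmods)


def module_mean_distance(dist: np.ndarray, cells: IntersectionModules) -> np.ndarray:
    """N x K matrix of each node's mean distance to each intersection cell.

    The node itself is excluded when it belongs to the cell; a cell that
    is exactly the singleton {i} contributes 0 for node i.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    out = np.zeros((n, cells.K))
    for k, cell in enumerate(cells.cells):
        sums = dist[:, cell].sum(axis=1)
        sizes = np.full(n, cell.size, dtype=float)
        in_cell = np.zeros(n, dtype=bool)
        in_cell[cell] = True
        # self-distance is 0 on the diagonal, so the sum needs no correction
        sizes[in_cell] -= 1
        with np.errstate(invalid="ignore", divide="ignore"):
            col = np.where(sizes > 0, sums / np.where(sizes > 0, sizes, 1.0), 0.0)
        out[:, k] = col
    return out


# ---------------------------------------------------------------------------
# scoring


@dataclass
class NetMossResult:
    """Per-taxon module-shift scores and the artifacts behind them."""

    taxa: list[str]
    d_mod_health: np.ndarray
    d_mod_disease: np.ndarray
    delta_d: np.ndarray
    raw_scores: np.ndarray
    scores: np.ndarray
    p_health: ModulePartition
    p_disease: ModulePartition
    cells: IntersectionModules
    beta: int | None = None
    threshold: float | None = None

    @property
    def flagged(self) -> list[str]:
        if self.threshold is None:
            return []
        return [t for t, s in zip(self.taxa, self.scores) if s > self.threshold]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "taxon": self.taxa,
                "raw_score": self.raw_scores,
                "score": self.scores,
                "module_health": self.p_health.labels,
                "module_disease": self.p_disease.labels,
            }
        )
        if self.threshold is not None:
            frame["flagged"] = self.scores > self.threshold
        return frame.set_index("taxon")


def netmoss_scores(
    d_mod_health: np.ndarray,
    d_mod_disease: np.ndarray,
    cells: IntersectionModules,
    p_health: ModulePartition,
    p_disease: ModulePartition,
    taxa: Sequence[str] | None = None,
    neighbor_mode: Literal["same_module", "other_modules"] = "same_module",
    beta: int | None = None,
    threshold: float | None = None,
) -> NetMossResult:
    """Score each node's contribution to the health -> disease module shift.

    DeltaD = d_mod_disease - d_mod_health, and for node i

        NMSS(i) = sum_{cells j in NeighborsA(i)} DeltaD[i, j]
                - sum_{cells l in NeighborsB(i)} DeltaD[i, l]

    where NeighborsA(i) are the intersection cells inside node i's
    health-network module and NeighborsB(i) those inside its
    disease-network module, each excluding i's own cell.  A migrating
    node's distance to its old (health-side) neighborhood grows while
    its distance to its new (disease-side) neighborhood shrinks, so
    both terms push |NMSS| up.  ``neighbor_mode="other_modules"``
    instead takes the cells *outside* the respective parent module.
    Reported scores are |NMSS| min-max normalized to [0, 1].
    """
    d_mod_health = np.asarray(d_mod_health, dtype=float)
    d_mod_disease = np.asarray(d_mod_disease, dtype=float)
    if d_mod_health.shape != d_mod_disease.shape:
        raise ValueError("distance matrices differ in shape")
    n, K = d_mod_health.shape
    if K != cells.K:
        raise ValueError("cell count does not match matrix columns")
    delta = d_mod_disease - d_mod_health
    if taxa is None:
        taxa = [str(i) for i in range(n)]

    raw = np.zeros(n)
    if K == 1:
        warnings.warn("single intersection cell; all scores are 0", stacklevel=2)
    else:
        cell_of = cells.cell_of_node(n)
        h_parent = np.asarray(cells.health_module)
        d_parent = np.asarray(cells.disease_module)
        for i in range(n):
            own = cell_of[i]
            in_h = h_parent == p_health.labels[i]
            in_d = d_parent == p_disease.labels[i]
            if neighbor_mode == "same_module":
                mask_a, mask_b = in_h.copy(), in_d.copy()
            elif neighbor_mode == "other_modules":
                mask_a, mask_b = ~in_h, ~in_d
            else:
                raise ValueError(f"unknown neighbor_mode: {neighbor_mode!r}")
            mask_a[own] = False
            mask_b[own] = False
            raw[i] = delta[i, mask_a].sum() - delta[i, mask_b].sum()

    mag = np.abs(raw)
    span = mag.max() - mag.min()
    scores = (mag - mag.min()) / span if span > 0 else np.zeros(n)
    return NetMossResult(
        taxa=list(taxa),
        d_mod_health=d_mod_health,
        d_mod_disease=d_mod_disease,
        delta_d=delta,
        raw_scores=raw,
        scores=scores,
        p_health=p_health,
        p_disease=p_disease,
        cells=cells,
        beta=beta,
        threshold=threshold,
    )


def run_netmoss(
    case_nets: Sequence[CorrelationNetwork],
    control_nets: Sequence[CorrelationNetwork],
    beta: int | Literal["auto"] = "auto",
    min_module_size: int = 5,
    weighting: Literal["univariate", "unweighted"] = "univariate",
    neighbor_mode: Literal["same_module", "other_modules"] = "same_module",
    threshold: float | None = None,
    candidate_betas: Sequence[int] = DEFAULT_BETAS,
) -> NetMossResult:
    """Full pipeline from per-study networks to NetMoss scores.

    Control networks define the health state A and case networks the
    disease state B.  Both groups are aligned onto the shared taxon
    union, pooled per group, transformed, soft-thresholded with a
    single shared beta (fit on the health matrix so the two topological
    overlap matrices are comparable), clustered into modules, crossed,
    and scored.  Deterministic given the inputs.
    """
    if len(case_nets) == 0 or len(control_nets) == 0:
        raise ValueError("need at least one network per group")
    aligned = align_taxa(list(control_nets) + list(case_nets))
    control_aligned = aligned[: len(control_nets)]
    case_aligned = aligned[len(control_nets):]
    pool = pool_correlations if weighting == "univariate" else unweighted_pool
    health = pool(control_aligned)
    disease = pool(case_aligned)
    return run_netmoss_from_matrices(
        health,
        disease,
        beta=beta,
        min_module_size=min_module_size,
        neighbor_mode=neighbor_mode,
        threshold=threshold,
        candidate_betas=candidate_betas,
    )


def run_netmoss_from_matrices(
    health: CorrelationNetwork | IntegratedNetwork,
    disease: CorrelationNetwork | IntegratedNetwork,
    beta: int | Literal["auto"] = "auto",
    min_module_size: int = 5,
    neighbor_mode: Literal["same_module", "other_modules"] = "same_module",
    threshold: float | None = None,
    candidate_betas: Sequence[int] = DEFAULT_BETAS,
) -> NetMossResult:
    """Run the scoring stages on two already-integrated correlation matrices."""
    taxa = list(health.corr.index)
    if list(disease.corr.index) != taxa:
        raise ValueError("health and disease matrices must share one taxon set")
    s_health = linear_transform(health.corr.to_numpy(dtype=float))
    s_disease = linear_transform(disease.corr.to_numpy(dtype=float))
    if beta == "auto":
        beta_val = pick_soft_threshold(s_health, candidate_betas)
    else:
        beta_val = int(beta)
    a_health = weighted_adjacency(s_health, beta_val)
    a_disease = weighted_adjacency(s_disease, beta_val)
    tom_health = topological_overlap(a_health)
    tom_disease = topological_overlap(a_disease)
    p_health = detect_modules(tom_health.dist, min_module_size=min_module_size)
    p_disease = detect_modules(tom_disease.dist, min_module_size=min_module_size)
    cells = intersect_partitions(p_health, p_disease)
    d_mod_health = module_mean_distance(tom_health.dist, cells)
    d_mod_disease = module_mean_distance(tom_disease.dist, cells)
    return netmoss_scores(
        d_mod_health,
        d_mod_disease,
        cells,
        p_health,
        p_disease,
        taxa=taxa,
        neighbor_mode=neighbor_mode,
        beta=beta_val,
        threshold=threshold,
    )
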