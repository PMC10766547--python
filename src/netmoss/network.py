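"""Per-study co-occurrence networks and threshold-dependent topology.

A co-occurrence network is the taxon-taxon correlation matrix of an
abundance table.  The default estimator is Spearman rank correlation —
monotone associations are what microbiome co-abundance analyses usually
target — with Pearson and a plugin hook for externally computed
matrices (e.g. from a compositional estimator) as alternatives.  All
downstream steps consume only a generic correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .io import AbundanceTable, CorrelationNetwork

__all__ = [
    "TopologyProfile",
    "build_correlation_network",
    "topology_profile",
    "network_distance",
]

CorrMethod = Union[Literal["spearman", "pearson"], Callable[[np.ndarray], np.ndarray]]


@dataclass
class TopologyProfile:
    """Edge counts and average degrees of a network across hard thresholds."""

    thresholds: list[float]
    edge_counts: list[int]
    average_degrees: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "edges": self.edge_counts,
                "average_degree": self.average_degrees,
            }
        )


def build_correlation_network(
    table: AbundanceTable,
    method: CorrMethod = "spearman",
) -> CorrelationNetwork:
    """Estimate the taxon-taxon correlation matrix of one study.

    Constant (zero-variance) taxa cannot carry a correlation; they are
    assigned correlation 0 to every other taxon, with a warning.
    ``method`` may also be a callable mapping the taxa x samples value
    matrix to a square correlation matrix, which allows plugging in any
    external estimator.
    """
    values = table.data.to_numpy(dtype=float)
    n_taxa, n_samples = values.shape
    if n_samples < 3:
        raise ValueError(f"need >= 3 samples to estimate correlations, got {n_samples}")
    if n_taxa < 2:
        raise ValueError(f"need >= 2 taxa, got {n_taxa}")

    constant = values.std(axis=1) == 0
    if callable(method):
        corr = np.asarray(method(values), dtype=float)
        if corr.shape != (n_taxa, n_taxa):
            raise ValueError(
                f"plugin estimator returned shape {corr.shape}, expected {(n_taxa, n_taxa)}"
            )
    elif method == "spearman":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", stats.ConstantInputWarning)
            corr = stats.spearmanr(values, axis=1).statistic
        if np.ndim(corr) == 0:  # scipy collapses the 2-variable case to a scalar
            corr = np.array([[1.0, float(corr)], [float(corr), 1.0]])
    elif method == "pearson":
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(values)
    else:
        raise ValueError(f"unknown correlation method: {method!r}")

    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant taxa assigned correlation 0", stacklevel=2
        )
        corr[constant, :] = 0.0
        corr[:, constant] = 0.0
    corr = np.nan_to_num(corr, nan=0.0)
    corr = np.clip((corr + corr.T) / 2, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    frame = pd.DataFrame(corr, index=table.taxa, columns=table.taxa)
    return CorrelationNetwork(frame, n=n_samples, study_id=table.study_id, group=table.group)


def topology_profile(
    net: CorrelationNetwork,
    thresholds: Sequence[float],
) -> TopologyProfile:
    """Count edges with |corr| >= t for each threshold t.

    The average degree is ``2 * edges / n_taxa``.  Edge counts are
    non-increasing in the threshold.
    """
    thresholds = sorted(float(t) for t in thresholds)
    if thresholds and not (0 <= thresholds[0] and thresholds[-1] <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    values = np.abs(net.values)
    n = values.shape[0]
    iu = np.triu_indices(n, k=1)
    upper = values[iu]
    edge_counts = [int((upper >= t).sum()) for t in thresholds]
    average_degrees = [2 * e / n for e in edge_counts]
    return TopologyProfile(thresholds, edge_counts, average_degrees)


def network_distance(a, b) -> float:
    """Mean absolute difference of aligned upper-triangle correlations.

    Taxa are aligned on the union of the two label sets; a pair absent
    from one network contributes that network's fill value 0.  The
    metric is symmetric, zero iff the aligned matrices agree, and
    insensitive to taxon count (it is a mean, not a sum).
    """
    taxa_a, taxa_b = list(a.corr.index), list(b.corr.index)
    union = sorted(set(taxa_a) | set(taxa_b))
    if not union:
        raise ValueError("networks share no taxa and have none to align")
    mat_a = a.corr.reindex(index=union, columns=union).fillna(0.0).to_numpy(dtype=float)
    mat_b = b.corr.reindex(index=union, columns=union).fillna(0.0).to_numpy(dtype=float)
    iu = np.triu_indices(len(union), k=1)
    if len(iu[0]) == 0:
        return 0.0
    return float(np.abs(mat_a[iu] - mat_b[iu]).mean())
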