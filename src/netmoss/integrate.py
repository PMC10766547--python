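"""Inverse-variance ("univariate") weighted integration of correlation networks.

Each taxon-pair correlation r_i from study i carries a conditional
deviation v_i = (1 - r_i^2) / (n_i - 1) (Hedges-Olkin); its weight is
w_i = 1 / v_i, and the pooled correlation is the w-weighted mean of the
per-study correlations.  Larger studies and stronger correlations get
larger weights, so a big cohort dominates a small one on every pair —
this is what makes the pooled network robust to between-study batch
effects.  Weighting is per pair ("univariate"): r varies across pairs,
so each co-abundance variable is pooled with its own weights.

Taxa missing from a study are aligned in with correlation 0; by default
the study still contributes that 0 with the weight of r = 0, namely
n - 1 (``skip_missing=True`` excludes such pairs instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import CorrelationNetwork

__all__ = [
    "IntegratedNetwork",
    "align_taxa",
    "conditional_deviation",
    "pool_correlations",
    "unweighted_pool",
    "study_contribution",
    "enumerate_subset_integrations",
]

#: Floor for the conditional deviation at r = +/-1, where the raw
#: formula gives v = 0 and hence an infinite weight.
EPS_V = 1e-12

_MAX_SUBSET_STUDIES = 20


@dataclass
class IntegratedNetwork:
    """Pooled correlation network with per-study weights and contributions.

    ``weights[s]`` is the taxa x taxa weight matrix of study ``s`` and
    ``contributions`` the per-study share of total weight (sums to 1).
    """

    pooled: pd.DataFrame
    study_ids: list[str]
    weights: dict[str, pd.DataFrame]
    contributions: pd.Series
    group: Literal["case", "control", ""] = ""

    @property
    def taxa(self) -> list[str]:
        return list(self.pooled.index)

    @property
    def corr(self) -> pd.DataFrame:
        """Alias so integrated networks drop into network-level functions."""
        return self.pooled

    @property
    def values(self) -> np.ndarray:
        return self.pooled.to_numpy(dtype=float)

    @property
    def k_studies(self) -> int:
        return len(self.study_ids)


def align_taxa(networks: Sequence[CorrelationNetwork]) -> list[CorrelationNetwork]:
    """Reindex every network onto the sorted union of all taxa.

    Pairs absent from a study get correlation 0 there ("bacteria
    without interaction"); the diagonal stays 1.
    """
    if len(networks) == 0:
        raise ValueError("no networks to align")
    union = sorted(set().union(*(net.corr.index for net in networks)))
    aligned = []
    for net in networks:
        frame = net.corr.reindex(index=union, columns=union).fillna(0.0)
        mat = frame.to_numpy(dtype=float)
        np.fill_diagonal(mat, 1.0)
        aligned.append(
            CorrelationNetwork(
                pd.DataFrame(mat, index=union, columns=union),
                n=net.n,
                study_id=net.study_id,
                group=net.group,
            )
        )
    return aligned


def conditional_deviation(r, n: int):
    """Hedges-Olkin conditional deviation v = (1 - r^2) / (n - 1).

    Accepts a scalar or array ``r``.  At r = +/-1 the raw value is 0
    (infinite weight); it is floored at ``EPS_V`` to keep pooling
    finite while preserving the dominance of perfect correlations.
    """
    if n < 2:
        raise ValueError(f"conditional deviation needs n >= 2, got n={n}")
    r = np.asarray(r, dtype=float)
    if np.abs(r).max(initial=0.0) > 1 + 1e-12:
        raise ValueError("correlation outside [-1, 1]")
    v = (1.0 - np.square(np.clip(r, -1.0, 1.0))) / (n - 1)
    v = np.maximum(v, EPS_V)
    return float(v) if v.ndim == 0 else v


def _study_ids(networks: Sequence[CorrelationNetwork]) -> list[str]:
    ids = [net.study_id or f"study{i + 1}" for i, net in enumerate(networks)]
    if len(set(ids)) != len(ids):
        ids = [f"{sid}#{i + 1}" for i, sid in enumerate(ids)]
    return ids


def pool_correlations(
    networks: Sequence[CorrelationNetwork],
    skip_missing: bool = False,
    group: Literal["case", "control", ""] = "",
) -> IntegratedNetwork:
    """Pool aligned networks into one by per-pair inverse-variance weighting.

    ``rho = sum_i w_i r_i / sum_i w_i`` per taxon pair, with
    ``w_i = (n_i - 1) / (1 - r_i^2)``.  With ``skip_missing`` a study
    contributes nothing on pairs it was zero-filled for (both taxa must
    be native to the study for the pair to count).
    """
    if len(networks) == 0:
        raise ValueError("no networks to pool")
    taxa = list(networks[0].corr.index)
    for net in networks[1:]:
        if list(net.corr.index) != taxa:
            raise ValueError("networks are not aligned; call align_taxa first")
    ids = _study_ids(networks)
    n_taxa = len(taxa)

    num = np.zeros((n_taxa, n_taxa))
    den = np.zeros((n_taxa, n_taxa))
    weights: dict[str, pd.DataFrame] = {}
    for sid, net in zip(ids, networks):
        r = net.values
        w = 1.0 / conditional_deviation(r, net.n)
        if skip_missing:
            # zero-filled taxa are recognized as all-zero off-diagonal rows
            off = r.copy()
            np.fill_diagonal(off, 0.0)
            native = off.any(axis=0) | off.any(axis=1)
            mask = np.outer(native, native)
            w = np.where(mask, w, 0.0)
        num += w * r
        den += w
        weights[sid] = pd.DataFrame(w, index=taxa, columns=taxa)

    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    pooled = np.clip((pooled + pooled.T) / 2, -1.0, 1.0)
    np.fill_diagonal(pooled, 1.0)

    total = sum(float(_offdiag_sum(w.to_numpy())) for w in weights.values())
    contributions = pd.Series(
        {sid: float(_offdiag_sum(w.to_numpy())) / total for sid, w in weights.items()}
    )
    return IntegratedNetwork(
        pooled=pd.DataFrame(pooled, index=taxa, columns=taxa),
        study_ids=ids,
        weights=weights,
        contributions=contributions,
        group=group,
    )


def _offdiag_sum(mat: np.ndarray) -> float:
    return float(mat.sum() - np.trace(mat))


def unweighted_pool(
    networks: Sequence[CorrelationNetwork],
    group: Literal["case", "control", ""] = "",
) -> IntegratedNetwork:
    """Baseline integration: plain mean of the aligned matrices (all weights 1)."""
    if len(networks) == 0:
        raise ValueError("no networks to pool")
    taxa = list(networks[0].corr.index)
    for net in networks[1:]:
        if list(net.corr.index) != taxa:
            raise ValueError("networks are not aligned; call align_taxa first")
    ids = _study_ids(networks)
    pooled = np.mean([net.values for net in networks], axis=0)
    pooled = np.clip((pooled + pooled.T) / 2, -1.0, 1.0)
    np.fill_diagonal(pooled, 1.0)
    ones = pd.DataFrame(1.0, index=taxa, columns=taxa)
    k = len(networks)
    return IntegratedNetwork(
        pooled=pd.DataFrame(pooled, index=taxa, columns=taxa),
        study_ids=ids,
        weights={sid: ones.copy() for sid in ids},
        contributions=pd.Series({sid: 1.0 / k for sid in ids}),
        group=group,
    )


def study_contribution(integrated: IntegratedNetwork) -> pd.Series:
    """Per-study share of the total pooling weight (fractions sum to 1).

    This is the only quantity in the pooling equation that measures how
    hard a study pulls on the pooled correlations; a larger cohort (or
    stronger correlations) means a larger share.
    """
    return integrated.contributions.copy()


def enumerate_subset_integrations(
    networks: Sequence[CorrelationNetwork],
    skip_missing: bool = False,
) -> dict[tuple[str, ...], IntegratedNetwork]:
    """Integrate every non-empty subset of the studies (2^k - 1 networks).

    Keys are tuples of study ids.  Networks are aligned on the global
    taxon union first so all subset integrations share one taxon set.
    """
    k = len(networks)
    if k == 0:
        raise ValueError("no networks given")
    if k > _MAX_SUBSET_STUDIES:
        raise ValueError(f"refusing subset enumeration for k={k} > {_MAX_SUBSET_STUDIES}")
    aligned = align_taxa(networks)
    ids = _study_ids(aligned)
    out: dict[tuple[str, ...], IntegratedNetwork] = {}
    for size in range(1, k + 1):
        for idx in combinations(range(k), size):
            subset = [aligned[i] for i in idx]
            out[tuple(ids[i] for i in idx)] = pool_correlations(subset, skip_missing=skip_missing)
    return out
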