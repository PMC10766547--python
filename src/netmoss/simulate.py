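"""Block-modular correlation-matrix simulator with planted module migrations.

The generator builds a "health" correlation matrix from block-diagonal
modules and perturbs it into a paired "disease" matrix in which a known
subset of submodules migrates from a source module to a target module.
The migrated set is the ground truth that scoring methods are
benchmarked against.

Module blocks follow the Gram-matrix construction
``Sigma_k = rho_k (U_k^T U_k) + (1 - rho_k) I`` where the columns of
``U_k`` are random unit vectors in ``R^{M_k}``.  Vectors are drawn from
the positive orthant of the sphere, so within-module correlations are
positive — taxa inside a module co-occur cooperatively, while ties
between modules are zero.  ``rho_k`` caps the within-module correlation
and ``M_k`` sets its spread (``M_k = 1`` gives exactly ``rho_k``
everywhere; larger spans push typical values lower).

Noise rows are graded: submodule ``k`` of the perturbed module receives
magnitude ``eps_k`` interpolated linearly between ``noise_min`` and
``noise_max``, so weakly and strongly disturbed submodules coexist in
one simulated pair, as in real dysbiosis where taxa are not all hit
equally.  Migrating submodules apply their noise *directionally* —
weakening ties to the module they leave and strengthening ties to the
module they join — while non-migrating submodules of the same module
receive the same magnitudes with random signs (incoherent disturbance
that does not move them anywhere).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AbundanceTable, CorrelationNetwork

__all__ = [
    "SimulationSpec",
    "SimulatedPair",
    "unit_vectors",
    "make_module_block",
    "assemble_matrix",
    "make_noise_matrix",
    "repair_psd",
    "perturb",
    "simulate_pair",
    "sample_abundances",
]

_PSD_FLOOR = 1e-8


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated health/disease matrix pair.

    Defaults describe the standard two-module benchmark: 120 taxa in an
    80-taxon target module and a 40-submodule source module, 75% of
    whose submodules (30 of 40) migrate under graded noise spanning
    0.2–0.8.  Each submodule is a single taxon.
    """

    n_taxa: int = 120
    module_sizes: tuple[int, ...] = (80, 40)
    module_max_corr: tuple[float, ...] = (0.8, 0.8)
    module_span: tuple[int, ...] = (5, 5)
    noise_span: int = 10
    noise_min: float = 0.2
    noise_max: float = 0.8
    migrate_fraction: float = 0.75
    source_module: int = -1
    target_module: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_taxa:
            raise ValueError(
                f"modules hold {sum(self.module_sizes)} taxa > n_taxa={self.n_taxa}"
            )
        if len(self.module_max_corr) != len(self.module_sizes):
            raise ValueError("module_max_corr and module_sizes lengths differ")
        if len(self.module_span) != len(self.module_sizes):
            raise ValueError("module_span and module_sizes lengths differ")
        if not all(0 < r < 1 for r in self.module_max_corr):
            raise ValueError("module_max_corr values must lie in (0, 1)")
        if not all(g >= 1 for g in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if not all(m >= 1 for m in self.module_span):
            raise ValueError("module spans must be positive")
        if self.noise_min > self.noise_max:
            raise ValueError("noise_min must not exceed noise_max")
        if self.noise_min < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if not 0 <= self.migrate_fraction <= 1:
            raise ValueError("migrate_fraction must lie in [0, 1]")

    def taxa(self) -> list[str]:
        width = len(str(self.n_taxa))
        return [f"taxon_{i + 1:0{width}d}" for i in range(self.n_taxa)]

    def module_indices(self) -> list[np.ndarray]:
        """Taxon index ranges of each module, in block order."""
        out, start = [], 0
        for g in self.module_sizes:
            out.append(np.arange(start, start + g))
            start += g
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationSpec":
        raw = json.loads(Path(path).read_text())
        for key in ("module_sizes", "module_max_corr", "module_span"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SimulatedPair:
    """A control/case correlation-matrix pair with its ground truth."""

    control_corr: pd.DataFrame
    case_corr: pd.DataFrame
    migrated: list[str]
    spec: SimulationSpec

    @property
    def labels(self) -> np.ndarray:
        """Boolean migration label per taxon, in matrix order."""
        migrated = set(self.migrated)
        return np.array([t in migrated for t in self.control_corr.index])

    def control_network(self, n: int = 100) -> CorrelationNetwork:
        return CorrelationNetwork(self.control_corr.copy(), n=n, group="control")

    def case_network(self, n: int = 100) -> CorrelationNetwork:
        return CorrelationNetwork(self.case_corr.copy(), n=n, group="case")


def unit_vectors(m: int, count: int, seed, positive: bool = True) -> np.ndarray:
    """Draw ``count`` random unit vectors in R^m as an m x count matrix.

    Gaussian draws normalized to length 1; with ``positive`` (the
    default) coordinates are reflected into the positive orthant so all
    pairwise inner products are non-negative.
    """
    rng = _as_rng(seed)
    u = rng.standard_normal((m, count))
    if positive:
        u = np.abs(u)
    norms = np.linalg.norm(u, axis=0)
    norms[norms == 0] = 1.0
    return u / norms


def make_module_block(g: int, rho: float, m: int, seed) -> np.ndarray:
    """One g x g module block rho (U^T U) + (1 - rho) I with unit diagonal.

    Off-diagonal entries are bounded by rho in magnitude (Cauchy-Schwarz
    on unit vectors); with ``m = 1`` they equal rho exactly.
    """
    if g < 1:
        raise ValueError("module size must be >= 1")
    if not 0 < rho < 1:
        raise ValueError(f"rho must lie in (0, 1), got {rho}")
    u = unit_vectors(m, g, seed)
    block = rho * (u.T @ u) + (1.0 - rho) * np.eye(g)
    np.fill_diagonal(block, 1.0)
    return block


def assemble_matrix(blocks: Sequence[np.ndarray], n_taxa: int) -> np.ndarray:
    """Place module blocks on the diagonal of an n x n matrix, zeros outside.

    Taxa beyond the blocks stay as isolated singletons (diagonal 1).
    """
    total = sum(b.shape[0] for b in blocks)
    if total > n_taxa:
        raise ValueError(f"blocks hold {total} taxa > n_taxa={n_taxa}")
    out = np.zeros((n_taxa, n_taxa))
    start = 0
    for b in blocks:
        g = b.shape[0]
        out[start : start + g, start : start + g] = b
        start += g
    np.fill_diagonal(out, 1.0)
    return out


def make_noise_matrix(
    r: int, c: int, m: int, eps1: float, epsr: float, seed
) -> np.ndarray:
    """Graded r x c noise: row k scaled by eps_k linear between eps1 and epsr.

    The unscaled values are inner products of random unit vectors from
    R^m, so ``m`` controls the spread of noise magnitudes within a row.
    """
    if r < 1 or c < 1:
        raise ValueError("noise matrix dimensions must be positive")
    if r > c:
        raise ValueError(f"need r <= c to select noise rows, got r={r}, c={c}")
    rng = _as_rng(seed)
    u = unit_vectors(m, c, rng)
    gram = u.T @ u
    if r == 1:
        eps = np.array([eps1])
    else:
        eps = eps1 + (np.arange(r) / (r - 1)) * (epsr - eps1)
    return eps[:, None] * gram[:r, :]


def repair_psd(matrix: np.ndarray, floor: float = _PSD_FLOOR) -> np.ndarray:
    """Project a symmetric matrix to the nearest valid correlation matrix.

    Eigenvalues are clipped at ``floor``, the matrix is rebuilt and
    rescaled to unit diagonal.  Idempotent up to numerical tolerance.
    """
    matrix = np.asarray(matrix, dtype=float)
    sym = (matrix + matrix.T) / 2
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= floor:
        out = sym.copy()
    else:
        vals = np.clip(vals, floor, None)
        out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    out = np.clip((out + out.T) / 2, -1.0, 1.0)
    np.fill_diagonal(out, 1.0)
    return out


def _build_control(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    blocks = [
        make_module_block(g, rho, m, rng)
        for g, rho, m in zip(spec.module_sizes, spec.module_max_corr, spec.module_span)
    ]
    return repair_psd(assemble_matrix(blocks, spec.n_taxa))


def perturb(control: np.ndarray, spec: SimulationSpec, seed=None) -> SimulatedPair:
    """Perturb a control matrix so chosen submodules migrate between modules.

    ``round(migrate_fraction * g_source)`` submodules of the source
    module are selected at random.  Each submodule row of the source
    module gets a graded noise row; migrating rows apply it
    directionally (ties to remaining source members weakened, ties to
    every target member strengthened), non-migrating rows apply the
    same magnitudes with random signs across all their ties.  The
    result is clipped to [-1, 1] and PSD-repaired; the control matrix
    is returned untouched.
    """
    rng = _as_rng(spec.seed if seed is None else seed)
    control = np.asarray(control, dtype=float)
    if control.shape != (spec.n_taxa, spec.n_taxa):
        raise ValueError(
            f"control shape {control.shape} does not match n_taxa={spec.n_taxa}"
        )
    modules = spec.module_indices()
    src = modules[spec.source_module]
    tgt = modules[spec.target_module]
    if src is tgt or np.array_equal(src, tgt):
        raise ValueError("source and target modules must differ")
    n_mig = round(spec.migrate_fraction * len(src))
    taxa = spec.taxa()
    if spec.migrate_fraction == 0:
        # no transition event: the pair is the control against itself
        return SimulatedPair(
            control_corr=pd.DataFrame(control, index=taxa, columns=taxa),
            case_corr=pd.DataFrame(repair_psd(control), index=taxa, columns=taxa),
            migrated=[],
            spec=spec,
        )
    if n_mig == 0:
        raise ValueError(
            f"migrate_fraction={spec.migrate_fraction} selects zero of "
            f"{len(src)} submodules"
        )
    migrated_idx = np.sort(rng.choice(src, size=n_mig, replace=False))
    migrated_set = set(migrated_idx.tolist())
    stay = np.array([i for i in src if i not in migrated_set], dtype=int)

    noise = make_noise_matrix(
        r=len(src),
        c=spec.n_taxa,
        m=spec.noise_span,
        eps1=spec.noise_min,
        epsr=spec.noise_max,
        seed=rng,
    )
    case = control.copy()
    for k, i in enumerate(src):
        s = np.abs(noise[k])
        if i in migrated_set:
            if stay.size:
                case[i, stay] -= s[stay]
                case[stay, i] = case[i, stay]
            case[i, tgt] += s[tgt]
            case[tgt, i] = case[i, tgt]
        else:
            cols = np.concatenate([np.setdiff1d(src, [i]), tgt])
            signs = rng.choice([-1.0, 1.0], size=cols.size)
            case[i, cols] += signs * s[cols]
            case[cols, i] = case[i, cols]
    case = repair_psd(np.clip(case, -1.0, 1.0))

    return SimulatedPair(
        control_corr=pd.DataFrame(control, index=taxa, columns=taxa),
        case_corr=pd.DataFrame(case, index=taxa, columns=taxa),
        migrated=[taxa[i] for i in migrated_idx],
        spec=spec,
    )


def simulate_pair(spec: SimulationSpec | None = None, seed: int | None = None) -> SimulatedPair:
    """Build the control matrix for ``spec`` and perturb it into a pair.

    ``seed`` overrides ``spec.seed``; identical spec and seed give a
    bit-identical pair.
    """
    if spec is None:
        spec = SimulationSpec()
    rng = _as_rng(spec.seed if seed is None else seed)
    control = _build_control(spec, rng)
    return perturb(control, spec, seed=rng)


def sample_abundances(
    corr: np.ndarray | pd.DataFrame,
    n_samples: int,
    seed,
    study_id: str = "",
    group: str = "",
) -> AbundanceTable:
    """Draw a relative-abundance table whose taxa co-vary like ``corr``.

    Samples are logistic-normal compositions: multivariate normal draws
    with the given correlation, exponentiated and renormalized per
    sample.  The empirical rank correlation of a large sample matches
    the sign pattern of the target.
    """
    frame = None
    if isinstance(corr, pd.DataFrame):
        frame = corr
        corr = corr.to_numpy(dtype=float)
    corr = np.asarray(corr, dtype=float)
    vals, vecs = np.linalg.eigh((corr + corr.T) / 2)
    if vals.min() < -1e-8:
        raise ValueError(f"correlation matrix is not PSD (min eigenvalue {vals.min():.3g})")
    rng = _as_rng(seed)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = root @ rng.standard_normal((corr.shape[0], n_samples))
    x = np.exp(z)
    x /= x.sum(axis=0)
    n = corr.shape[0]
    width = len(str(n))
    taxa = list(frame.index) if frame is not None else [f"taxon_{i + 1:0{width}d}" for i in range(n)]
    samples = [f"sample_{j + 1:0{len(str(n_samples))}d}" for j in range(n_samples)]
    return AbundanceTable(
        pd.DataFrame(x, index=taxa, columns=samples),
        study_id=study_id,
        group=group,
    )
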