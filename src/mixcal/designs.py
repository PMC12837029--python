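"""Mixture design generation and space-filling diagnostics.

Three samplers (Monte Carlo, Latin hypercube, Sobol) plus a classical
multilevel full-factorial generator, all operating on a :class:`DesignSpace`
of per-analyte concentration bounds.  Designs carry both the physical
(µg/mL) and the coded (unit-hypercube) view; uniformity metrics are always
computed in coded space so they are scale-free.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

__all__ = [
    "DesignSpace",
    "DesignMatrix",
    "UniformityReport",
    "factorial_calibration_design",
    "monte_carlo_design",
    "latin_hypercube_design",
    "sobol_design",
    "min_pairwise_distance",
    "grid_coverage",
    "uniformity_report",
    "write_design_csv",
    "read_design_csv",
]


@dataclass(frozen=True)
class DesignSpace:
    """Ordered per-variable concentration bounds (µg/mL)."""

    variables: tuple[tuple[str, float, float], ...]

    def __init__(self, variables: Sequence[tuple[str, float, float]]):
        variables = tuple((str(n), float(lo), float(hi)) for n, lo, hi in variables)
        if not variables:
            raise ValueError("DesignSpace needs at least one variable")
        for name, lo, hi in variables:
            if not lo < hi:
                raise ValueError(f"variable {name!r}: lower bound {lo} must be < upper {hi}")
        names = [v[0] for v in variables]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")
        object.__setattr__(self, "variables", variables)

    @property
    def names(self) -> list[str]:
        return [v[0] for v in self.variables]

    @property
    def lower(self) -> np.ndarray:
        return np.array([v[1] for v in self.variables])

    @property
    def upper(self) -> np.ndarray:
        return np.array([v[2] for v in self.variables])

    @property
    def ndim(self) -> int:
        return len(self.variables)

    def to_physical(self, coded: np.ndarray) -> np.ndarray:
        """Map coded [0,1]^d coordinates to physical µg/mL."""
        coded = np.atleast_2d(np.asarray(coded, dtype=float))
        return self.lower + coded * (self.upper - self.lower)

    def to_coded(self, physical: np.ndarray) -> np.ndarray:
        physical = np.atleast_2d(np.asarray(physical, dtype=float))
        return (physical - self.lower) / (self.upper - self.lower)


@dataclass(frozen=True)
class DesignMatrix:
    """A set of sampled mixture points with physical and coded views."""

    space: DesignSpace
    coded: np.ndarray  # n x d in [0,1]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        coded = np.atleast_2d(np.asarray(self.coded, dtype=float))
        if coded.shape[0] < 1:
            raise ValueError("design must contain at least one point")
        if coded.shape[1] != self.space.ndim:
            raise ValueError("coded matrix width does not match design space dimension")
        if np.any(coded < -1e-12) or np.any(coded > 1 + 1e-12):
            raise ValueError("coded points must lie in the unit hypercube")
        object.__setattr__(self, "coded", coded)

    @property
    def points(self) -> np.ndarray:
        """Physical concentrations, µg/mL."""
        return self.space.to_physical(self.coded)

    @property
    def n(self) -> int:
        return self.coded.shape[0]

    @property
    def ndim(self) -> int:
        return self.coded.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=self.space.names)


@dataclass(frozen=True)
class UniformityReport:
    min_pairwise_distance: float
    grid_coverage_percent: float
    grid_resolution: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def factorial_calibration_design(
    space: DesignSpace, levels: Sequence[float] = (-2, -1, 0, 1, 2)
) -> DesignMatrix:
    """Full factorial over equally spaced coded levels.

    The lowest level maps to each variable's lower bound and the highest to
    its upper bound; intermediate levels interpolate linearly.  Five levels
    on a 2-variable space gives the classical 25-mixture training design.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size < 2 or levels.size % 2 == 0:
        raise ValueError("need an odd number (>= 3) of coded levels")
    diffs = np.diff(levels)
    if np.any(diffs <= 0):
        raise ValueError("levels must be strictly increasing")
    if not np.allclose(diffs, diffs[0]):
        raise ValueError("levels must be equally spaced")
    unit = (levels - levels[0]) / (levels[-1] - levels[0])  # -> [0, 1]
    grids = np.meshgrid(*([unit] * space.ndim), indexing="ij")
    coded = np.column_stack([g.ravel() for g in grids])
    prov = {"sampler": "factorial", "levels": list(map(float, levels))}
    return DesignMatrix(space, coded, prov)


def monte_carlo_design(n: int, space: DesignSpace, seed: int | None = None) -> DesignMatrix:
    """Independent uniform draws: x = x_min + r * (x_max - x_min)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    coded = rng.random((n, space.ndim))
    prov = {"sampler": "mc", "seed": seed, "n": n}
    return DesignMatrix(space, coded, prov)


def latin_hypercube_design(n: int, space: DesignSpace, seed: int | None = None) -> DesignMatrix:
    """Stratified sampling: per variable, x = x_min + ((k - r)/N) * (x_max - x_min).

    k runs over a random permutation of 1..N so each of the N equal-width
    strata holds exactly one point; r is a fresh uniform draw per stratum.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    coded = np.empty((n, space.ndim))
    for j in range(space.ndim):
        k = rng.permutation(n) + 1  # stratum indices 1..N
        r = rng.random(n)
        coded[:, j] = (k - r) / n
    prov = {"sampler": "lhs", "seed": seed, "n": n}
    return DesignMatrix(space, coded, prov)


# ---------------------------------------------------------------------------
# Sobol sequence via direction numbers (Joe-Kuo primitive-polynomial table,
# dimensions 1-10; dimension 1 is the van der Corput sequence in base 2).
# Each row: (degree s, coefficient int a, initial m_1..m_s).
_SOBOL_TABLE: list[tuple[int, int, tuple[int, ...]]] = [
    (1, 0, (1,)),            # dim 1
    (1, 0, (1,)),            # dim 2
    (2, 1, (1, 3)),          # dim 3
    (3, 1, (1, 3, 1)),       # dim 4
    (3, 2, (1, 1, 1)),       # dim 5
    (4, 1, (1, 1, 3, 3)),    # dim 6
    (4, 4, (1, 3, 5, 13)),   # dim 7
    (5, 2, (1, 1, 5, 5, 17)),  # dim 8
    (5, 4, (1, 1, 5, 5, 5)),   # dim 9
    (5, 7, (1, 1, 7, 11, 19)),  # dim 10
]
_SOBOL_BITS = 32
SOBOL_MAX_DIM = len(_SOBOL_TABLE)


def sobol_direction_integers(dim: int, nbits: int = _SOBOL_BITS) -> np.ndarray:
    """Direction integers V[k] (scaled by 2**nbits) for one dimension (1-based)."""
    if not 1 <= dim <= SOBOL_MAX_DIM:
        raise ValueError(f"Sobol dimension {dim} exceeds the bundled table (d <= {SOBOL_MAX_DIM})")
    s, a, m_init = _SOBOL_TABLE[dim - 1]
    v = np.zeros(nbits, dtype=np.uint64)
    if dim == 1:
        for k in range(nbits):
            v[k] = np.uint64(1) << np.uint64(nbits - k - 1)
        return v
    m = list(m_init)
    for k in range(s, nbits):
        new = m[k - s] ^ (m[k - s] << s)
        for i in range(1, s):
            if (a >> (s - 1 - i)) & 1:
                new ^= m[k - i] << i
        m.append(new)
    for k in range(nbits):
        v[k] = np.uint64(m[k]) << np.uint64(nbits - k - 1)
    return v


def _sobol_points(n: int, d: int, skip_zero: bool) -> np.ndarray:
    """First n points in Gray-code order, optionally skipping the origin."""
    vs = [sobol_direction_integers(j + 1) for j in range(d)]
    total = n + (1 if skip_zero else 0)
    x = np.zeros(d, dtype=np.uint64)
    out = np.empty((total, d))
    out[0] = 0.0
    for i in range(1, total):
        c = 0  # rightmost zero bit of i-1
        val = i - 1
        while val & 1:
            val >>= 1
            c += 1
        for j in range(d):
            x[j] ^= vs[j][c]
        out[i] = x / float(1 << _SOBOL_BITS)
    return out[1:] if skip_zero else out


def sobol_design(
    n: int,
    space: DesignSpace,
    skip_zero: bool = True,
    scramble: bool = False,
    seed: int | None = None,
) -> DesignMatrix:
    """Deterministic low-discrepancy design from the Sobol sequence.

    Points are generated by XOR of direction integers in Gray-code order.
    The index-0 point (the all-lower-bound corner) is skipped by default;
    ``scramble=True`` applies a seeded random digital shift per dimension.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    coded = _sobol_points(n, space.ndim, skip_zero)
    if scramble:
        rng = np.random.default_rng(seed)
        shift = rng.integers(0, 1 << _SOBOL_BITS, size=space.ndim, dtype=np.uint64)
        ints = (coded * float(1 << _SOBOL_BITS)).astype(np.uint64)
        coded = (ints ^ shift) / float(1 << _SOBOL_BITS)
    prov = {
        "sampler": "sobol",
        "n": n,
        "skip_zero": bool(skip_zero),
        "scramble": bool(scramble),
        "seed": seed if scramble else None,
    }
    return DesignMatrix(space, coded, prov)


# ---------------------------------------------------------------------------
# Uniformity metrics (coded space).

def min_pairwise_distance(design: DesignMatrix) -> float:
    """Smallest Euclidean distance between any two coded points."""
    if design.n < 2:
        raise ValueError("need at least two points for a pairwise distance")
    return float(pdist(design.coded).min())


def grid_coverage(design: DesignMatrix, cells_per_dim: int = 10) -> float:
    """Percent of cells of a cells_per_dim^d grid occupied by >= 1 point.

    Points on the upper boundary are assigned to the last cell.
    """
    if cells_per_dim < 1:
        raise ValueError("cells_per_dim must be >= 1")
    idx = np.floor(design.coded * cells_per_dim).astype(int)
    idx = np.clip(idx, 0, cells_per_dim - 1)
    occupied = len({tuple(row) for row in idx})
    return 100.0 * occupied / cells_per_dim**design.ndim


def uniformity_report(design: DesignMatrix, cells_per_dim: int = 10) -> UniformityReport:
    return UniformityReport(
        min_pairwise_distance=min_pairwise_distance(design),
        grid_coverage_percent=grid_coverage(design, cells_per_dim),
        grid_resolution=cells_per_dim,
    )


# ---------------------------------------------------------------------------
# I/O: CSV of physical concentrations plus a JSON sidecar with provenance.

def write_design_csv(design: DesignMatrix, path: str, sidecar: bool = True) -> None:
    design.to_frame().to_csv(path, index=False)
    if sidecar:
        meta = {
            "provenance": design.provenance,
            "bounds": {n: [lo, hi] for n, lo, hi in design.space.variables},
            "coded": design.coded.tolist(),
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)


def read_design_csv(path: str, space: DesignSpace | None = None) -> DesignMatrix:
    df = pd.read_csv(path)
    if space is None:
        try:
            with open(str(path) + ".json") as fh:
                meta = json.load(fh)
            space = DesignSpace([(n, lo, hi) for n, (lo, hi) in meta["bounds"].items()])
            prov = meta.get("provenance", {})
        except FileNotFoundError:
            space = DesignSpace([(c, df[c].min(), df[c].max()) for c in df.columns])
            prov = {"sampler": "unknown"}
    else:
        prov = {"sampler": "unknown"}
    coded = space.to_coded(df[space.names].to_numpy())
    return DesignMatrix(space, np.clip(coded, 0.0, 1.0), prov)
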