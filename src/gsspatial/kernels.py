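"""Distance matrices, parametric spatial correlation kernels, and the
marker-based additive relationship matrix.

Spatial dependence among plot errors is modeled as a random field whose
correlation decays with center-to-center distance.  Three families are
supported:

* power:      ``rho(d) = theta ** d`` with ``0 < theta < 1`` — the
  continuous-distance generalization of the AR(1) structure;
* gaussian:   ``rho(d) = exp(-d**2 / phi**2)`` with ``phi > 0``;
* spherical:  ``rho(d) = 1 - 1.5 (d/phi) + 0.5 (d/phi)**3`` for
  ``d <= phi`` and exactly 0 beyond ``phi``.

The decay parameter (``theta`` or ``phi``) is called the standardizing
parameter: the larger it is, the slower the decay.  Distance can be the
full planar (isotropic) distance or only its Range- or Column-wise
component (directional correlation, a special case of anisotropy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trial import MarkerMatrix, PlotDimension, TrialTable

__all__ = [
    "DistanceMatrix",
    "SpatialKernel",
    "GenomicKinship",
    "FAMILIES",
    "DIRECTIONS",
    "distance_matrix",
    "spatial_correlation",
    "vanraden_kinship",
    "parameter_grid",
]

FAMILIES = ("power", "gaussian", "spherical")
DIRECTIONS = ("isotropic", "range", "column")

#: eigenvalues above this (negative) bound count as numerically PSD
_PSD_TOL = 1e-8


@dataclass
class DistanceMatrix:
    """Symmetric plot-to-plot distances in meters."""

    entries: np.ndarray
    direction: str
    plot_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")

    @property
    def max_distance(self) -> float:
        return float(self.entries.max())

    @property
    def min_nonzero(self) -> float:
        off = self.entries[self.entries > 0]
        return float(off.min()) if off.size else 0.0


@dataclass
class SpatialKernel:
    """A correlation structure realized as a plot x plot matrix."""

    family: str
    direction: str
    param: float
    matrix: np.ndarray
    plot_ids: np.ndarray

    @property
    def label(self) -> str:
        return f"{self.family}-{self.direction}({self.param:g})"

    def submatrix(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Cross-correlation block between two plot index sets."""
        return self.matrix[np.ix_(rows, cols)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.plot_ids, columns=self.plot_ids)


@dataclass
class GenomicKinship:
    """Additive genomic relationship matrix over an ordered genotype list."""

    genotypes: np.ndarray
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        self.matrix = np.asarray(self.matrix, dtype=float)
        g = len(self.genotypes)
        if self.matrix.shape != (g, g):
            raise ValueError("kinship matrix shape must match genotype list")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")

    @classmethod
    def identity(cls, genotypes) -> "GenomicKinship":
        """Identity relationship (unrelated genotypes, label-only kinship)."""
        genotypes = np.asarray(genotypes)
        return cls(genotypes, np.eye(len(genotypes)))

    def index_of(self, labels) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genotypes)}
        try:
            return np.array([lookup[g] for g in labels], dtype=int)
        except KeyError as e:
            raise KeyError(f"genotype {e.args[0]!r} absent from kinship") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.genotypes, columns=self.genotypes)


def distance_matrix(t: TrialTable, dim: PlotDimension, direction: str = "isotropic") -> DistanceMatrix:
    """Center-to-center distances between all plot pairs.

    Range distance is ``|delta range| * width_m`` and column distance
    ``|delta col| * length_m``; the isotropic distance between diagonal
    plots is the hypotenuse of the two components.  Directional matrices
    use only their own component.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    r = t.data["range_idx"].to_numpy(dtype=float)
    c = t.data["col_idx"].to_numpy(dtype=float)
    dr = np.abs(r[:, None] - r[None, :]) * dim.width_m
    dc = np.abs(c[:, None] - c[None, :]) * dim.length_m
    if direction == "range":
        d = dr
    elif direction == "column":
        d = dc
    else:
        d = np.hypot(dr, dc)
    return DistanceMatrix(d, direction, t.plot_ids.copy())


def _power(d: np.ndarray, theta: float) -> np.ndarray:
    if not 0.0 < theta < 1.0:
        raise ValueError(f"power parameter must be in (0, 1), got {theta}")
    return theta ** d


def _gaussian(d: np.ndarray, phi: float) -> np.ndarray:
    if phi <= 0:
        raise ValueError(f"gaussian parameter must be positive, got {phi}")
    return np.exp(-(d ** 2) / phi ** 2)


def _spherical(d: np.ndarray, phi: float) -> np.ndarray:
    if phi <= 0:
        raise ValueError(f"spherical parameter must be positive, got {phi}")
    x = d / phi
    out = 1.0 - 1.5 * x + 0.5 * x ** 3
    out[d > phi] = 0.0
    return out


_KERNELS = {"power": _power, "gaussian": _gaussian, "spherical": _spherical}


def spatial_correlation(d: DistanceMatrix, family: str, param: float) -> SpatialKernel:
    """Apply a correlation family entrywise to a distance matrix.

    The result has unit diagonal and entries in [0, 1], non-increasing in
    distance.  If the matrix is numerically indefinite (possible for
    directional structures, which repeat values across plots sharing a
    Range or Column) a diagonal jitter is added and the diagonal is
    renormalized to 1.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    mat = _KERNELS[family](d.entries, float(param))
    np.fill_diagonal(mat, 1.0)
    mat = _repair_psd(mat)
    return SpatialKernel(family, d.direction, float(param), mat, d.plot_ids.copy())


def _repair_psd(mat: np.ndarray) -> np.ndarray:
    lam_min = float(np.linalg.eigvalsh(mat)[0])
    if lam_min >= -_PSD_TOL:
        return mat
    delta = abs(lam_min) + _PSD_TOL
    mat = mat + delta * np.eye(mat.shape[0])
    # renormalize to a correlation matrix (unit diagonal)
    mat /= 1.0 + delta
    np.fill_diagonal(mat, 1.0)
    return mat


def vanraden_kinship(m: MarkerMatrix, maf_min: float = 0.01) -> GenomicKinship:
    """Additive relationship matrix from SNP dosages (VanRaden method 1).

    Markers with minor allele frequency at or below ``maf_min`` are
    discarded; missing dosages are mean-imputed per marker; dosages are
    centered by twice the allele frequency and
    ``K = W W' / (2 * sum_j p_j (1 - p_j))``.
    """
    x = m.dosages.copy()
    col_mean = np.nanmean(x, axis=0)
    nan_r, nan_c = np.where(np.isnan(x))
    x[nan_r, nan_c] = col_mean[nan_c]
    p = x.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = maf > maf_min
    if not keep.any():
        raise ValueError(f"no marker passes the MAF > {maf_min:g} filter")
    x, p = x[:, keep], p[keep]
    w = x - 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    k = (w @ w.T) / denom
    return GenomicKinship(m.genotypes.copy(), (k + k.T) / 2.0)


def parameter_grid(family: str, d: DistanceMatrix, n: int = 10,
                   grid: list[float] | None = None) -> list[float]:
    """Default standardizing-parameter grid for a kernel family.

    Power uses theta in {0.1, ..., 0.9}; gaussian and spherical use ``n``
    log-spaced values between the smallest nonzero and the largest
    distance in ``d``.  A user-supplied ``grid`` overrides the default.
    """
    if grid is not None:
        return [float(v) for v in grid]
    if family == "power":
        return [round(0.1 * i, 1) for i in range(1, 10)]
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    lo, hi = d.min_nonzero, d.max_distance
    if lo <= 0 or hi <= lo:
        return [max(hi, 1.0)]
    return list(np.geomspace(lo, hi, n))
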