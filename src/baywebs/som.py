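"""Kohonen self-organizing maps for community patterning.

Abundance tables (samples x taxa) are reduced to common taxa, min-max scaled,
and projected onto a 2-D lattice of units by a batch SOM.  Map size follows
the 5*sqrt(N) heuristic, with the final grid picked by minimizing topographic
then quantization error over candidate grids.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

__all__ = [
    "KohonenSOM",
    "SOMConfig",
    "filter_common_taxa",
    "minmax_scale",
    "propose_grids",
    "train_som",
    "select_grid",
    "quantization_error",
    "topographic_error",
    "u_matrix",
    "component_planes",
]


def filter_common_taxa(
    table: pd.DataFrame,
    threshold: float = 0.05,
    occasion_level: str | int | None = "season",
) -> pd.DataFrame:
    """Keep taxa reaching ``threshold`` relative abundance on >=1 sampling occasion.

    A sampling occasion pools the samples sharing one level of the row index
    (by default a level named ``season``); if no such level exists each sample
    is its own occasion.  All-zero taxa are always dropped.  The sample set is
    never changed.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if table.empty:
        raise ValueError("empty abundance table")

    level = None
    if occasion_level is not None and isinstance(table.index, pd.MultiIndex):
        if occasion_level in (table.index.names or []):
            level = occasion_level
    if level is not None:
        occasion_totals = table.groupby(level=level).sum()
    else:
        occasion_totals = table

    grand = occasion_totals.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = occasion_totals.div(grand.replace(0, np.nan), axis=0)
    keep = (rel >= threshold).any(axis=0) & (table.sum(axis=0) > 0)
    if not keep.any():
        raise ValueError(
            "common-taxon filter removed every taxon; lower the threshold"
        )
    return table.loc[:, keep]


def minmax_scale(table):
    """Scale each taxon (column) to [0, 1]; constant columns map to 0.

    Accepts a DataFrame or 2-D array and returns the same type.  Idempotent:
    applying it twice gives the same result as once.
    """
    is_frame = isinstance(table, pd.DataFrame)
    x = np.asarray(table, dtype=float)
    if x.size == 0:
        raise ValueError("empty table")
    lo = x.min(axis=0)
    rng = x.max(axis=0) - lo
    rng_safe = np.where(rng > 0, rng, 1.0)
    scaled = (x - lo) / rng_safe
    scaled[:, rng == 0] = 0.0
    if is_frame:
        return pd.DataFrame(scaled, index=table.index, columns=table.columns)
    return scaled


def propose_grids(
    n_samples: int,
    bracket: tuple[float, float] = (0.5, 1.5),
    max_aspect: float = 3.0,
) -> list[tuple[int, int]]:
    """Candidate (rows, cols) grids around the 5*sqrt(N) unit-count heuristic.

    Unit counts are kept within ``bracket`` times the heuristic and never
    exceed the number of samples; each count contributes its most nearly
    square factorization (rows >= 2, aspect ratio <= ``max_aspect``).
    Candidates are ranked by closeness to the heuristic.  When no count
    qualifies (tiny datasets) the minimal 2x2 grid is returned.
    """
    if n_samples < 4:
        raise ValueError(f"need at least 4 samples, got {n_samples}")
    target = 5.0 * math.sqrt(n_samples)
    lo = bracket[0] * target
    hi = min(bracket[1] * target, float(n_samples))

    candidates: list[tuple[float, tuple[int, int]]] = []
    for count in range(4, n_samples + 1):
        if not lo <= count <= hi:
            continue
        best = None
        for rows in range(2, int(math.isqrt(count)) + 1):
            if count % rows:
                continue
            cols = count // rows
            if cols / rows > max_aspect:
                continue
            if best is None or cols - rows < best[1] - best[0]:
                best = (rows, cols)
        if best is not None:
            candidates.append((abs(count - target), best))
    if not candidates:
        return [(2, 2)]
    candidates.sort(key=lambda t: (t[0], t[1]))
    return [grid for _, grid in candidates]


@dataclass
class SOMConfig:
    """Training schedule for the batch SOM (SOM-Toolbox-style defaults)."""

    grid: tuple[int, int] = (6, 6)
    ordering_epochs: int = 100
    tuning_epochs: int = 400
    ordering_radius: tuple[float, float] | None = None  # default max(grid)/2 -> 1
    tuning_radius: tuple[float, float] = (1.0, 0.5)
    init: str = "linear"
    seed: int = 0

    def __post_init__(self):
        rows, cols = self.grid
        if rows < 2 or cols < 2:
            raise ValueError("grid must be at least 2x2")
        for phase in (self.ordering_radius, self.tuning_radius):
            if phase is not None:
                a, b = phase
                if a <= 0 or b <= 0 or b > a:
                    raise ValueError(
                        "radius schedule must be positive and non-increasing"
                    )

    def estimator(self) -> "KohonenSOM":
        return KohonenSOM(
            n_rows=self.grid[0],
            n_cols=self.grid[1],
            ordering_epochs=self.ordering_epochs,
            tuning_epochs=self.tuning_epochs,
            ordering_radius=self.ordering_radius,
            tuning_radius=self.tuning_radius,
            init=self.init,
            random_state=self.seed,
        )


class KohonenSOM(BaseEstimator):
    """Batch self-organizing map on a rectangular lattice.

    Training runs two phases (ordering, tuning) with a Gaussian neighbourhood
    whose radius decays linearly within each phase.  Codebooks are updated as
    neighbourhood-weighted means of the mapped samples, so each codebook
    component stays within the [min, max] of the corresponding data column.
    Linear initialization spans the two leading principal directions of the
    data, which makes the fit deterministic; ``random_state`` only matters for
    ``init='random'``.

    Parameters
    ----------
    n_rows, n_cols : lattice shape (>= 2 each).
    ordering_epochs, tuning_epochs : batch epochs per phase.
    ordering_radius : (start, end) neighbourhood radius of the ordering phase;
        defaults to (max(n_rows, n_cols)/2, 1).
    tuning_radius : (start, end) radius of the tuning phase.
    init : 'linear' (PCA plane) or 'random' (uniform within column ranges).
    random_state : seed for random initialization.

    Attributes
    ----------
    codebook_ : (n_units, n_features) weight vectors.
    grid_coordinates_ : (n_units, 2) integer (row, col) lattice positions;
        unit index runs top-to-bottom then left-to-right.
    quantization_error_, topographic_error_ : errors on the training data.
    """

    def __init__(
        self,
        n_rows: int = 6,
        n_cols: int = 6,
        ordering_epochs: int = 100,
        tuning_epochs: int = 400,
        ordering_radius: tuple[float, float] | None = None,
        tuning_radius: tuple[float, float] = (1.0, 0.5),
        init: str = "linear",
        random_state: int | None = None,
    ):
        self.n_rows = n_rows
        self.n_cols = n_cols
        self.ordering_epochs = ordering_epochs
        self.tuning_epochs = tuning_epochs
        self.ordering_radius = ordering_radius
        self.tuning_radius = tuning_radius
        self.init = init
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    @property
    def n_units(self) -> int:
        return self.n_rows * self.n_cols

    def _grid_coords(self) -> np.ndarray:
        rows, cols = np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )
        return np.column_stack([rows.ravel(), cols.ravel()])

    @staticmethod
    def _validate_X(X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim != 2 or x.shape[0] == 0:
            raise ValueError("X must be a non-empty 2-D array")
        if not np.isfinite(x).all():
            raise ValueError("X contains non-finite values")
        return x

    def _init_codebook(self, x: np.ndarray) -> np.ndarray:
        n, d = x.shape
        if self.init == "random":
            rng = np.random.default_rng(self.random_state)
            lo, hi = x.min(axis=0), x.max(axis=0)
            return rng.uniform(lo, hi, size=(self.n_units, d))
        if self.init != "linear":
            raise ValueError(f"unknown init {self.init!r}")
        mean = x.mean(axis=0)
        xc = x - mean
        # deterministic PCA plane; sign fixed by the largest-loading component
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        dirs = np.zeros((2, d))
        scale = np.zeros(2)
        for i in range(min(2, len(s))):
            v = vt[i]
            j = np.argmax(np.abs(v))
            if v[j] < 0:
                v = -v
            dirs[i] = v
            scale[i] = s[i] / math.sqrt(max(n - 1, 1))
        a = np.linspace(-1.0, 1.0, self.n_rows) if self.n_rows > 1 else np.zeros(1)
        b = np.linspace(-1.0, 1.0, self.n_cols) if self.n_cols > 1 else np.zeros(1)
        aa, bb = np.meshgrid(a, b, indexing="ij")
        code = (
            mean
            + aa.ravel()[:, None] * scale[0] * dirs[0]
            + bb.ravel()[:, None] * scale[1] * dirs[1]
        )
        return code

    def _radius_schedule(self) -> np.ndarray:
        start0 = (
            max(self.n_rows, self.n_cols) / 2.0
            if self.ordering_radius is None
            else self.ordering_radius[0]
        )
        end0 = 1.0 if self.ordering_radius is None else self.ordering_radius[1]
        phases = [
            (start0, end0, self.ordering_epochs),
            (self.tuning_radius[0], self.tuning_radius[1], self.tuning_epochs),
        ]
        out = []
        for start, end, n in phases:
            if n > 0:
                out.append(np.linspace(start, end, n))
        return np.concatenate(out) if out else np.array([])

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None):
        x = self._validate_X(X)
        if x.shape[0] < self.n_units:
            warnings.warn(
                f"training {self.n_units} units on only {x.shape[0]} samples; "
                "some units will stay empty",
                stacklevel=2,
            )
        coords = self._grid_coords().astype(float)
        grid_d2 = cdist(coords, coords, "sqeuclidean")
        codebook = self._init_codebook(x)

        for sigma in self._radius_schedule():
            d2 = cdist(x, codebook, "sqeuclidean")
            bmu = np.argmin(d2, axis=1)
            h = np.exp(-grid_d2 / (2.0 * sigma * sigma))
            w = h[:, bmu]  # (n_units, n_samples)
            denom = w.sum(axis=1)
            active = denom > 1e-300
            codebook[active] = (w @ x)[active] / denom[active, None]

        self.codebook_ = codebook
        self.grid_coordinates_ = self._grid_coords()
        self.n_features_in_ = x.shape[1]
        self.n_samples_ = x.shape[0]
        self.quantization_error_ = quantization_error(self, x)
        self.topographic_error_ = topographic_error(self, x)
        return self

    def transform(self, X) -> np.ndarray:
        """Euclidean distances from each sample to every unit codebook."""
        x = self._validate_X(X)
        if x.shape[1] != self.codebook_.shape[1]:
            raise ValueError("feature dimension mismatch")
        return cdist(x, self.codebook_)

    def predict(self, X) -> np.ndarray:
        """Best-matching-unit index for each sample."""
        return np.argmin(self.transform(X), axis=1)


def train_som(matrix, config: SOMConfig | None = None) -> KohonenSOM:
    """Fit a batch SOM on a scaled samples x taxa matrix."""
    config = config or SOMConfig()
    return config.estimator().fit(np.asarray(matrix, dtype=float))


def quantization_error(som: KohonenSOM, matrix) -> float:
    """Mean Euclidean distance from each sample to its best matching unit."""
    d = som.transform(matrix)
    return float(np.min(d, axis=1).mean())


def topographic_error(som: KohonenSOM, matrix) -> float:
    """Fraction of samples whose two best units are not lattice-adjacent.

    Adjacency is the 8-neighbourhood of the rectangular lattice (Chebyshev
    distance 1).
    """
    d = som.transform(matrix)
    if d.shape[1] < 2:
        raise ValueError("need at least two units for topographic error")
    order = np.argsort(d, axis=1, kind="stable")
    first, second = order[:, 0], order[:, 1]
    c = som.grid_coordinates_
    cheb = np.abs(c[first] - c[second]).max(axis=1)
    return float(np.mean(cheb > 1))


def select_grid(
    matrix,
    candidates: list[tuple[int, int]],
    config: SOMConfig | None = None,
) -> tuple[KohonenSOM, pd.DataFrame]:
    """Train every candidate grid and keep the (TE, QE)-lexicographic minimizer.

    Returns the winning fitted map and the full QE/TE table for the sweep.
    """
    if not candidates:
        raise ValueError("no candidate grids")
    base = config or SOMConfig()
    rows = []
    best = None
    for grid in candidates:
        cfg = SOMConfig(
            grid=grid,
            ordering_epochs=base.ordering_epochs,
            tuning_epochs=base.tuning_epochs,
            ordering_radius=base.ordering_radius,
            tuning_radius=base.tuning_radius,
            init=base.init,
            seed=base.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            som = train_som(matrix, cfg)
        key = (som.topographic_error_, som.quantization_error_)
        rows.append(
            {
                "rows": grid[0],
                "cols": grid[1],
                "units": grid[0] * grid[1],
                "qe": som.quantization_error_,
                "te": som.topographic_error_,
            }
        )
        if best is None or key < best[0]:
            best = (key, som)
    return best[1], pd.DataFrame(rows)


def u_matrix(som: KohonenSOM) -> np.ndarray:
    """Mean distance from each unit codebook to its lattice neighbours."""
    coords = som.grid_coordinates_
    code = som.codebook_
    out = np.zeros(len(code))
    cheb = np.abs(coords[:, None, :] - coords[None, :, :]).max(axis=2)
    dist = cdist(code, code)
    for u in range(len(code)):
        nbr = (cheb[u] == 1)
        out[u] = dist[u, nbr].mean() if nbr.any() else 0.0
    return out.reshape(som.n_rows, som.n_cols)


def component_planes(som: KohonenSOM, names=None) -> dict:
    """Codebook slice per taxon, reshaped to the lattice."""
    d = som.codebook_.shape[1]
    names = list(names) if names is not None else list(range(d))
    if len(names) != d:
        raise ValueError("one name per codebook dimension required")
    return {
        name: som.codebook_[:, j].reshape(som.n_rows, som.n_cols)
        for j, name in enumerate(names)
    }
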