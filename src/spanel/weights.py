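"""Spatial contiguity weights.

A spatial weight matrix ``W`` codifies which regions are neighbours of
which.  Row-standardised (each nonempty row summing to one), ``W @ x`` is
the simple average of ``x`` over each region's contiguous neighbours — the
"spatial lag" used both for spatially lagged covariates and for the
spatial-error / spatial-lag disturbance processes.

Weights here are binary contiguity before standardisation (no distance
decay).  Islands — units with no neighbour — are kept with an all-zero row
and flagged with a warning rather than dropped, so a balanced panel stays
balanced.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp

__all__ = [
    "SpatialWeights",
    "WeightsFormatError",
    "build_lattice_weights",
    "reorder_weights",
    "row_standardize",
    "spatial_lag",
    "eigenvalues",
    "read_gal",
    "write_gal",
]


class WeightsFormatError(ValueError):
    """Malformed GAL file or inconsistent neighbour structure."""


@dataclass
class SpatialWeights:
    """Neighbour lists plus per-pair nonnegative weights.

    Parameters
    ----------
    neighbors
        Per-unit integer arrays of neighbour indices.
    values
        Per-unit weight arrays aligned with ``neighbors``.
    ids
        Unit labels, aligned with panel region ids (strings).
    standardized
        True when every nonempty row sums to one.
    degrees
        Row sums of the *pre-standardisation* matrix; retained after
        standardisation because the spectrum is computed through a
        similarity transform that needs them.
    """

    neighbors: list
    values: list
    ids: list
    standardized: bool = False
    degrees: np.ndarray | None = None
    _spectrum: np.ndarray | None = field(default=None, repr=False, compare=False)
    _csr: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.neighbors)
        if n < 2:
            raise ValueError("a spatial weights matrix needs at least 2 units")
        if len(self.values) != n or len(self.ids) != n:
            raise ValueError("neighbors, values and ids must have equal length")
        self.neighbors = [np.asarray(a, dtype=np.intp) for a in self.neighbors]
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        self.ids = [str(i) for i in self.ids]
        if len(set(self.ids)) != n:
            raise ValueError("unit ids must be unique")
        for i, (nb, v) in enumerate(zip(self.neighbors, self.values)):
            if nb.shape != v.shape:
                raise ValueError(f"unit {self.ids[i]}: neighbor/value length mismatch")
            if nb.size and (nb.min() < 0 or nb.max() >= n):
                raise ValueError(f"unit {self.ids[i]}: neighbor index out of range")
            if np.any(nb == i):
                raise ValueError(f"unit {self.ids[i]}: self-neighbour (nonzero diagonal)")
            if nb.size != np.unique(nb).size:
                raise ValueError(f"unit {self.ids[i]}: duplicated neighbour")
            if np.any(v < 0):
                raise ValueError(f"unit {self.ids[i]}: negative weight")
        pairs = {(i, int(j)) for i, nb in enumerate(self.neighbors) for j in nb}
        for i, j in pairs:
            if (j, i) not in pairs:
                raise ValueError(
                    f"asymmetric adjacency: {self.ids[i]} lists {self.ids[j]} "
                    "but not conversely"
                )
        if self.degrees is None:
            self.degrees = np.array([v.sum() for v in self.values])
        else:
            self.degrees = np.asarray(self.degrees, dtype=float)

    @property
    def n(self) -> int:
        return len(self.neighbors)

    @property
    def island_mask(self) -> np.ndarray:
        """Boolean mask of units with no neighbours."""
        return np.array([nb.size == 0 for nb in self.neighbors])

    def sparse(self) -> sp.csr_matrix:
        """The weight matrix as CSR (cached)."""
        if self._csr is None:
            indptr = np.zeros(self.n + 1, dtype=np.intp)
            indptr[1:] = np.cumsum([nb.size for nb in self.neighbors])
            indices = (
                np.concatenate(self.neighbors)
                if indptr[-1]
                else np.empty(0, dtype=np.intp)
            )
            data = (
                np.concatenate(self.values) if indptr[-1] else np.empty(0, dtype=float)
            )
            self._csr = sp.csr_matrix((data, indices, indptr), shape=(self.n, self.n))
        return self._csr

    def dense(self) -> np.ndarray:
        return self.sparse().toarray()


def build_lattice_weights(rows: int, cols: int, scheme: str = "rook") -> SpatialWeights:
    """Binary contiguity on a ``rows x cols`` grid.

    ``rook`` links edge-sharing cells, ``queen`` additionally links
    corner-sharing cells.  Unit ids are ``"r{i}c{j}"`` in row-major order.
    The result is unstandardised.
    """
    if rows < 1 or cols < 1:
        raise ValueError("lattice dimensions must be positive")
    if rows * cols < 2:
        raise ValueError("lattice must contain at least 2 cells")
    if scheme not in ("rook", "queen"):
        raise ValueError(f"unknown contiguity scheme {scheme!r}")
    if scheme == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    neighbors, values, ids = [], [], []
    for i in range(rows):
        for j in range(cols):
            nb = [
                (i + di) * cols + (j + dj)
                for di, dj in offsets
                if 0 <= i + di < rows and 0 <= j + dj < cols
            ]
            nb.sort()
            neighbors.append(np.array(nb, dtype=np.intp))
            values.append(np.ones(len(nb)))
            ids.append(f"r{i}c{j}")
    return SpatialWeights(neighbors, values, ids)


def subset_weights(w: SpatialWeights, keep: int) -> SpatialWeights:
    """Restrict to the first ``keep`` units, dropping dangling edges.

    Used to trim a rectangular lattice to an exact region count (e.g. a
    61x60 grid trimmed to 3,659 units).
    """
    if not 2 <= keep <= w.n:
        raise ValueError("keep must be in [2, n]")
    neighbors, values = [], []
    for i in range(keep):
        mask = w.neighbors[i] < keep
        neighbors.append(w.neighbors[i][mask])
        values.append(w.values[i][mask])
    return SpatialWeights(neighbors, values, w.ids[:keep], standardized=False)


def reorder_weights(w: SpatialWeights, ids: list) -> SpatialWeights:
    """Permute units to the given id order (e.g. a panel's region order)."""
    ids = [str(i) for i in ids]
    if sorted(ids) != sorted(w.ids):
        missing = sorted(set(ids) ^ set(w.ids))
        raise ValueError(f"id sets differ between weights and target order: {missing[:5]}")
    old_index = {uid: i for i, uid in enumerate(w.ids)}
    perm = [old_index[uid] for uid in ids]  # new position -> old position
    new_pos = np.empty(w.n, dtype=np.intp)
    new_pos[perm] = np.arange(w.n)
    neighbors, values = [], []
    for old in perm:
        order = np.argsort(new_pos[w.neighbors[old]])
        neighbors.append(new_pos[w.neighbors[old]][order])
        values.append(w.values[old][order])
    return SpatialWeights(
        neighbors,
        values,
        ids,
        standardized=w.standardized,
        degrees=w.degrees[perm] if w.degrees is not None else None,
    )


def row_standardize(w: SpatialWeights) -> SpatialWeights:
    """Divide each nonempty row by its sum so spatial lags are neighbour means.

    Island rows are left all-zero (a warning is emitted); the
    pre-standardisation row sums are retained for the spectrum computation.
    """
    degrees = np.array([v.sum() for v in w.values]) if not w.standardized else w.degrees
    if not np.any(degrees > 0):
        raise ValueError("cannot standardize: every unit is an island")
    n_islands = int(np.sum(degrees == 0))
    if n_islands:
        warnings.warn(
            f"{n_islands} island unit(s) kept with all-zero rows",
            UserWarning,
            stacklevel=2,
        )
    values = []
    for v, d in zip(w.values, degrees):
        values.append(v / d if d > 0 else v.copy())
    return SpatialWeights(
        [nb.copy() for nb in w.neighbors],
        values,
        list(w.ids),
        standardized=True,
        degrees=degrees,
    )


def spatial_lag(w: SpatialWeights, x: np.ndarray) -> np.ndarray:
    """Neighbour average ``W @ x`` for a row-standardised ``w``.

    Island rows return 0 with a warning.
    """
    if not w.standardized:
        raise ValueError("spatial_lag requires a row-standardised weights matrix")
    x = np.asarray(x, dtype=float)
    if x.shape[0] != w.n:
        raise ValueError(f"vector length {x.shape[0]} != number of units {w.n}")
    islands = w.island_mask
    if islands.any():
        warnings.warn(
            f"{int(islands.sum())} island unit(s): lag set to 0",
            UserWarning,
            stacklevel=2,
        )
    return w.sparse() @ x


def eigenvalues(w: SpatialWeights) -> np.ndarray:
    """Real spectrum of the row-standardised matrix, ascending (cached).

    ``D^{-1}A`` with ``A`` symmetric is similar to the symmetric
    ``D^{-1/2} A D^{-1/2}``, so the eigenvalues are real and are computed
    with a symmetric eigensolver; islands contribute zeros.  Falls back to
    the general solver for non-symmetric ``A`` (checking the imaginary
    parts vanish).  Feeds the log-determinant term of the spatial ML
    likelihoods.
    """
    if not w.standardized:
        raise ValueError("eigenvalues are defined on the row-standardised matrix")
    if w._spectrum is not None:
        return w._spectrum
    d = w.degrees
    keep = d > 0
    # reconstruct pre-standardisation A on the non-island block
    A = w.sparse().toarray()
    A = A * d[:, None]
    A = A[np.ix_(keep, keep)]
    dk = d[keep]
    if np.allclose(A, A.T, atol=1e-12):
        scale = 1.0 / np.sqrt(dk)
        S = scale[:, None] * A * scale[None, :]
        vals = scipy.linalg.eigh(S, eigvals_only=True)
    else:
        ev = scipy.linalg.eigvals(A / dk[:, None])
        if np.abs(ev.imag).max(initial=0.0) > 1e-8:
            raise FloatingPointError("spectrum has non-negligible imaginary parts")
        vals = np.sort(ev.real)
    if vals.size and vals.max() > 1 + 1e-8:
        raise FloatingPointError("largest eigenvalue exceeds 1 for standardised W")
    full = np.zeros(w.n)
    full[: vals.size] = vals
    full = np.sort(full)
    w._spectrum = full
    return full


def read_gal(path) -> SpatialWeights:
    """Read a GAL-format contiguity file.

    Format: a header line with the unit count, then for each unit a line
    ``<id> <k>`` followed by a line with its ``k`` neighbour ids.  The
    result is unstandardised binary contiguity.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise WeightsFormatError(f"{path}: empty file")
    header = lines[0].split()
    # tolerate the 4-token variant "0 n file key"
    try:
        n = int(header[1] if len(header) == 4 else header[0])
    except (ValueError, IndexError):
        raise WeightsFormatError(f"{path}: line 1: malformed header {lines[0]!r}")
    ids: list[str] = []
    raw: dict[str, list[str]] = {}
    lineno = 1
    for _ in range(n):
        if lineno >= len(lines):
            raise WeightsFormatError(f"{path}: truncated after line {lineno}")
        head = lines[lineno].split()
        if len(head) != 2:
            raise WeightsFormatError(
                f"{path}: line {lineno + 1}: expected '<id> <count>', got {lines[lineno]!r}"
            )
        uid, k_str = head
        try:
            k = int(k_str)
        except ValueError:
            raise WeightsFormatError(
                f"{path}: line {lineno + 1}: neighbour count {k_str!r} is not an integer"
            )
        if uid in raw:
            raise WeightsFormatError(f"{path}: line {lineno + 1}: duplicate id {uid!r}")
        lineno += 1
        if k > 0:
            if lineno >= len(lines):
                raise WeightsFormatError(f"{path}: truncated after line {lineno}")
            nbrs = lines[lineno].split()
            if len(nbrs) != k:
                raise WeightsFormatError(
                    f"{path}: line {lineno + 1}: expected {k} neighbour ids, "
                    f"got {len(nbrs)}"
                )
            lineno += 1
        else:
            nbrs = []
        ids.append(uid)
        raw[uid] = nbrs
    index = {uid: i for i, uid in enumerate(ids)}
    neighbors, values = [], []
    for uid in ids:
        nb = []
        for other in raw[uid]:
            if other not in index:
                raise WeightsFormatError(
                    f"{path}: unit {uid!r} references unknown id {other!r}"
                )
            nb.append(index[other])
        nb = np.array(sorted(nb), dtype=np.intp)
        neighbors.append(nb)
        values.append(np.ones(nb.size))
    for uid in ids:
        i = index[uid]
        for j in neighbors[i]:
            if i not in neighbors[j]:
                raise WeightsFormatError(
                    f"{path}: asymmetric adjacency: {uid!r} lists "
                    f"{ids[j]!r} but not conversely"
                )
    return SpatialWeights(neighbors, values, ids)


def write_gal(w: SpatialWeights, path) -> None:
    """Write the neighbour structure (not the weight values) as GAL text."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{w.n}\n")
        for i, uid in enumerate(w.ids):
            nb = w.neighbors[i]
            fh.write(f"{uid} {nb.size}\n")
            if nb.size:
                fh.write(" ".join(w.ids[j] for j in nb) + "\n")
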