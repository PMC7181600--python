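"""Morphospace construction: parameter table → Gower distances → PCoA.

The per-specimen network descriptors (nine variables: N, K, D, C, L, H,
S-module count, Q-module count, Q_max; parcellation is excluded) are
log-transformed, converted to pairwise Gower distances (mean of per-column
range-normalized absolute differences) and ordinated by classical
multidimensional scaling (principal coordinates analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .netparams import NetworkParams

#: the nine ordination variables, in table order
PCOA_VARIABLES = ("N", "K", "D", "C", "L", "H", "n_S_modules", "n_Q_modules", "Q_max")

LOG_EPS = 1e-6  # offset for variables that can be exactly 0 (C, Q_max)


def build_param_table(params: dict[str, NetworkParams]) -> pd.DataFrame:
    """Specimen × nine-variable table from per-specimen descriptors."""
    rows = {}
    for sid, p in params.items():
        d = p.as_dict()
        missing = [v for v in PCOA_VARIABLES if d.get(v) is None]
        if missing:
            raise ValueError(f"{sid}: missing module-based parameters {missing}")
        rows[sid] = {v: d[v] for v in PCOA_VARIABLES}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(PCOA_VARIABLES))


def log_transform(table: pd.DataFrame, eps: float = LOG_EPS) -> pd.DataFrame:
    """Natural log of every column; zeros are offset by ``eps`` with a warning."""
    out = table.astype(float).copy()
    if (out.to_numpy() < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    zero_cols = out.columns[(out == 0).any(axis=0)].tolist()
    if zero_cols:
        warnings.warn(
            f"zero values in columns {zero_cols}: using log(x + {eps:g})",
            stacklevel=2,
        )
        out[zero_cols] = out[zero_cols] + eps
    return np.log(out)


def gower_distance(table: pd.DataFrame) -> pd.DataFrame:
    """Gower distance: d_ij = (1/p) Σ_v |x_iv - x_jv| / range_v.

    Zero-range columns contribute 0 to every pair (with a warning), keeping
    the distance defined when a descriptor is constant across specimens.
    """
    x = table.to_numpy(dtype=float)
    n, p = x.shape
    ranges = x.max(axis=0) - x.min(axis=0)
    zero = ranges == 0
    if zero.any():
        warnings.warn(
            f"zero-range columns contribute 0 to Gower distance: "
            f"{list(table.columns[zero])}",
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, ranges)
    d = np.zeros((n, n))
    for v in range(p):
        if zero[v]:
            continue
        col = x[:, v]
        d += np.abs(col[:, None] - col[None, :]) / safe[v]
    d /= p
    return pd.DataFrame(d, index=table.index, columns=table.index)


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame        # specimens × PCo axes
    eigenvalues: np.ndarray          # positive eigenvalues, non-increasing
    variance_fractions: np.ndarray   # shares of the positive-eigenvalue sum
    negative_eigenvalue_magnitude: float


class GowerPCoA:
    """Classical scaling (PCoA) of a distance matrix, sklearn-style.

    Double-centers -0.5 * J D^2 J, eigendecomposes, and keeps axes with
    positive eigenvalues; coordinates are eigenvectors scaled by the square
    root of their eigenvalue. Negative eigenvalues (possible for non-
    Euclidean distances such as Gower) are dropped by default; a Lingoes or
    Cailliez correction can be requested instead.

    Parameters
    ----------
    correction : {"none", "lingoes", "cailliez"}
        Treatment of negative eigenvalues.
    eig_tol : float
        Eigenvalues with absolute value below ``eig_tol * max(|eig|)`` are
        treated as zero.
    """

    def __init__(self, correction: str = "none", eig_tol: float = 1e-10):
        self.correction = correction
        self.eig_tol = eig_tol

    def get_params(self, deep: bool = True) -> dict:
        return {"correction": self.correction, "eig_tol": self.eig_tol}

    def set_params(self, **params) -> "GowerPCoA":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, dist: pd.DataFrame | np.ndarray) -> "GowerPCoA":
        d = np.asarray(dist, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError(f"distance matrix must be square, got {d.shape}")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        index = (dist.index if isinstance(dist, pd.DataFrame)
                 else pd.RangeIndex(d.shape[0]))
        n = d.shape[0]
        if self.correction == "cailliez":
            d = _cailliez(d)
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d ** 2) @ j
        if self.correction == "lingoes":
            evals = np.linalg.eigvalsh((b + b.T) / 2)
            c = max(0.0, -evals.min())
            if c > 0:
                d2 = d ** 2 + 2 * c
                np.fill_diagonal(d2, 0.0)
                b = -0.5 * j @ d2 @ j
        evals, evecs = np.linalg.eigh((b + b.T) / 2)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        tol = self.eig_tol * max(np.abs(evals).max(), 1.0)
        pos = evals > tol
        neg_mag = float(-evals[evals < -tol].sum()) if (evals < -tol).any() else 0.0
        lam = evals[pos]
        coords = evecs[:, pos] * np.sqrt(lam)
        # deterministic sign: largest-|loading| entry of each axis positive
        for a in range(coords.shape[1]):
            i = int(np.argmax(np.abs(coords[:, a])))
            if coords[i, a] < 0:
                coords[:, a] = -coords[:, a]
        cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
        self.coordinates_ = pd.DataFrame(coords, index=index, columns=cols)
        self.eigenvalues_ = lam
        self.variance_fractions_ = lam / lam.sum() if lam.size else lam
        self.negative_eigenvalue_magnitude_ = neg_mag
        return self

    def fit_transform(self, dist) -> pd.DataFrame:
        return self.fit(dist).coordinates_

    @property
    def result_(self) -> PcoaResult:
        return PcoaResult(
            coordinates=self.coordinates_,
            eigenvalues=self.eigenvalues_,
            variance_fractions=self.variance_fractions_,
            negative_eigenvalue_magnitude=self.negative_eigenvalue_magnitude_,
        )


def _cailliez(d: np.ndarray) -> np.ndarray:
    """Smallest additive constant making the distances Euclidean."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    del1 = -0.5 * j @ (d ** 2) @ j
    del2 = -0.5 * j @ d @ j
    top = np.hstack([np.zeros((n, n)), 2 * del1])
    bot = np.hstack([-np.eye(n), -4 * del2])
    c = float(np.max(np.real(np.linalg.eigvals(np.vstack([top, bot])))))
    if c > 0:
        d = d + c
        np.fill_diagonal(d, 0.0)
    return d


def pcoa(dist: pd.DataFrame | np.ndarray, correction: str = "none") -> PcoaResult:
    """Function wrapper over :class:`GowerPCoA`."""
    return GowerPCoA(correction=correction).fit(dist).result_
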