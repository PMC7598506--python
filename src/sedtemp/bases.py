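"""Penalized spline bases for the additive mixed models.

Three basis families are built here, each exposing a design-matrix block,
a symmetric positive semidefinite penalty, and an evaluation rule for new
data:

* :class:`CyclicCubicBasis` — a periodic cubic regression spline on
  evenly spaced knots (used for day-of-year seasonality, period 366 so
  leap years wrap). Value, first- and second-derivative continuity hold
  at the wrap point and the penalty is the integrated squared second
  derivative expressed through the natural-spline tridiagonal system.
  The sum-to-zero identifiability constraint is absorbed by a null-space
  reparameterisation, after which the penalty is full rank: at infinite
  smoothing the term vanishes entirely.
* :class:`ThinPlateBasis1D` — low-rank thin-plate regression spline with
  radial kernel |r|^3/12 and a linear null space, rank-reduced by eigen-
  truncation of the (polynomial-projected) kernel matrix at the knots.
* :class:`ThinPlateBasis2D` — the two-dimensional analogue with kernel
  r^2 log(r)/(8 pi) and polynomial null space {1, x, y}, used for the
  residential-location smooth.

Thin-plate terms drop the polynomial intercept column and are column
centred over the training data, which makes every basis function
orthogonal to the model intercept while leaving the (unpenalized)
polynomial null space intact.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg

__all__ = [
    "CyclicCubicBasis",
    "ThinPlateBasis1D",
    "ThinPlateBasis2D",
    "SmoothBasis",
]


def _null_space_transform(constraint: np.ndarray) -> np.ndarray:
    """Orthonormal basis Z of the null space of a single row constraint."""
    c = constraint.reshape(-1, 1)
    q, _ = np.linalg.qr(c, mode="complete")
    return q[:, 1:]


@dataclasses.dataclass
class SmoothBasis:
    """Common container for a built smooth block.

    Attributes
    ----------
    design : (n, q) array — training design block, constraints applied.
    penalty : (q, q) array — PSD penalty, scaled to unit spectral norm.
    penalty_rank : rank of the penalty.
    null_dim : dimension of the unpenalized (polynomial) null space
        remaining in the block after constraint absorption.
    penalty_logdet : log pseudo-determinant of the scaled penalty.
    """

    design: np.ndarray
    penalty: np.ndarray
    penalty_rank: int
    null_dim: int
    penalty_logdet: float

    def transform(self, *values) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


def _finalize_penalty(S: np.ndarray) -> tuple[np.ndarray, int, float]:
    """Symmetrise, scale to unit spectral norm, return (S, rank, logdet+)."""
    S = (S + S.T) / 2.0
    eigvals = scipy.linalg.eigvalsh(S)
    scale = eigvals.max()
    if scale <= 0:
        raise ValueError("penalty has no positive eigenvalues")
    S = S / scale
    eigvals = eigvals / scale
    tol = eigvals.max() * len(eigvals) * np.finfo(float).eps * 10
    pos = eigvals[eigvals > tol]
    return S, len(pos), float(np.log(pos).sum())


# ---------------------------------------------------------------------------
# Cyclic cubic regression spline
# ---------------------------------------------------------------------------

class CyclicCubicBasis(SmoothBasis):
    """Periodic cubic regression spline on [lower, upper].

    ``k`` knots are spaced evenly over the period; the k-th knot is
    identified with the first, leaving k-1 free knot values, of which one
    more is absorbed by the sum-to-zero constraint (k-2 coefficients,
    matching the convention that EDF <= k-2 for a cyclic smooth).
    """

    def __init__(self, x, k: int = 10, lower: float = 1.0, upper: float = 366.0):
        if k < 4:
            raise ValueError(f"cyclic basis needs k >= 4, got {k}")
        x = np.asarray(x, dtype=float)
        self.k = int(k)
        self.lower = float(lower)
        self.upper = float(upper)
        self.period = self.upper - self.lower
        self.knots = np.linspace(self.lower, self.upper, self.k)
        h = np.diff(self.knots)  # k-1 interval widths (cyclic, all equal here)
        m = self.k - 1  # free knot values before constraint

        B = np.zeros((m, m))
        D = np.zeros((m, m))
        for i in range(m):
            ip = (i + 1) % m
            im = (i - 1) % m
            h_i = h[i]
            h_im = h[im]
            B[i, i] = (h_im + h_i) / 3.0
            B[i, ip] += h_i / 6.0
            B[i, im] += h_im / 6.0
            D[i, i] = -(1.0 / h_im + 1.0 / h_i)
            D[i, ip] += 1.0 / h_i
            D[i, im] += 1.0 / h_im
        self._h = h
        self._BinvD = np.linalg.solve(B, D)
        S_raw = D.T @ self._BinvD  # integrated squared second derivative

        X_raw = self._raw_design(x)
        constraint = X_raw.sum(axis=0)
        self._Z = _null_space_transform(constraint)
        design = X_raw @ self._Z
        S, rank, logdet = _finalize_penalty(self._Z.T @ S_raw @ self._Z)
        super().__init__(design, S, rank, null_dim=0, penalty_logdet=logdet)

    def _raw_design(self, x) -> np.ndarray:
        """Interpolating design in the k-1 free knot values."""
        x = np.asarray(x, dtype=float)
        m = self.k - 1
        # wrap into [lower, upper)
        xw = self.lower + np.mod(x - self.lower, self.period)
        j = np.clip(np.searchsorted(self.knots, xw, side="right") - 1, 0, m - 1)
        h = self._h[j]
        x0 = self.knots[j]
        x1 = self.knots[j + 1]
        a_minus = (x1 - xw) / h
        a_plus = (xw - x0) / h
        c_minus = ((x1 - xw) ** 3 / h - h * (x1 - xw)) / 6.0
        c_plus = ((xw - x0) ** 3 / h - h * (xw - x0)) / 6.0
        n = len(xw)
        A_f = np.zeros((n, m))
        A_m = np.zeros((n, m))
        rows = np.arange(n)
        np.add.at(A_f, (rows, j), a_minus)
        np.add.at(A_f, (rows, (j + 1) % m), a_plus)
        np.add.at(A_m, (rows, j), c_minus)
        np.add.at(A_m, (rows, (j + 1) % m), c_plus)
        return A_f + A_m @ self._BinvD

    def transform(self, x) -> np.ndarray:
        return self._raw_design(x) @ self._Z


# ---------------------------------------------------------------------------
# Thin plate regression splines
# ---------------------------------------------------------------------------

def _tps_kernel_1d(r: np.ndarray) -> np.ndarray:
    return np.abs(r) ** 3 / 12.0


def _tps_kernel_2d(r: np.ndarray) -> np.ndarray:
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * np.log(r[nz]) / (8.0 * np.pi)
    return out


def _subsample_knots(points: np.ndarray, max_knots: int) -> np.ndarray:
    """Deterministic thinning of unique rows to at most max_knots."""
    uniq = np.unique(points, axis=0)
    if len(uniq) <= max_knots:
        return uniq
    idx = np.linspace(0, len(uniq) - 1, max_knots).round().astype(int)
    return uniq[np.unique(idx)]


class _ThinPlateBase(SmoothBasis):
    """Shared eigen-truncation machinery for 1-D and 2-D thin plate bases."""

    _dim: int

    def __init__(self, points: np.ndarray, k: int, max_knots: int):
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if points.shape[1] != self._dim:
            points = points.T
        n_poly = self._dim + 1  # {1, x} or {1, x, y}
        uniq = np.unique(points, axis=0)
        if len(uniq) < k:
            k = max(len(uniq), n_poly + 1)
        self.k = int(k)
        # standardise coordinates for kernel conditioning
        self._shift = points.mean(axis=0)
        self._scale = points.std(axis=0)
        self._scale[self._scale == 0] = 1.0
        z = (points - self._shift) / self._scale
        self.knots = _subsample_knots(z, max_knots)

        E = self._kernel(self._pairwise(self.knots, self.knots))
        T = self._poly(self.knots)  # (K, n_poly)
        q_poly, _ = np.linalg.qr(T, mode="complete")
        Z_T = q_poly[:, n_poly:]  # null space of T'
        E_proj = Z_T.T @ E @ Z_T
        E_proj = (E_proj + E_proj.T) / 2.0
        eigvals, eigvecs = scipy.linalg.eigh(E_proj)
        order = np.argsort(eigvals)[::-1]
        q_wing = min(self.k - n_poly, len(eigvals))
        take = order[:q_wing]
        lam = np.clip(eigvals[take], 0.0, None)
        self._wing = Z_T @ eigvecs[:, take]  # (K, q_wing)

        wing_design = self._kernel(self._pairwise(z, self.knots)) @ self._wing
        # rescale wing columns to unit RMS (absorbed into the penalty) so
        # the design block is well conditioned next to the other terms
        rms = np.sqrt((wing_design**2).mean(axis=0))
        self._col_scale = np.where(rms > 0, rms, 1.0)
        wing_design = wing_design / self._col_scale
        null_design = self._poly(z)[:, 1:]  # drop intercept
        raw = np.hstack([wing_design, null_design])
        self._col_means = raw.mean(axis=0)
        design = raw - self._col_means

        S_raw = np.zeros((raw.shape[1], raw.shape[1]))
        S_raw[:q_wing, :q_wing] = np.diag(lam / self._col_scale**2)
        S, rank, logdet = _finalize_penalty(S_raw)
        super().__init__(design, S, rank, null_dim=self._dim, penalty_logdet=logdet)

    def _pairwise(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        diff = a[:, None, :] - b[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def _poly(self, z: np.ndarray) -> np.ndarray:
        return np.hstack([np.ones((len(z), 1)), z])

    def _kernel(self, r: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def transform(self, *values) -> np.ndarray:
        pts = np.column_stack([np.asarray(v, dtype=float) for v in values])
        z = (pts - self._shift) / self._scale
        wing = self._kernel(self._pairwise(z, self.knots)) @ self._wing / self._col_scale
        raw = np.hstack([wing, self._poly(z)[:, 1:]])
        return raw - self._col_means


class ThinPlateBasis1D(_ThinPlateBase):
    """Low-rank thin plate regression spline in one covariate.

    Kernel |r|^3/12 with linear null space; ``k`` counts the basis
    dimension before the intercept is absorbed, so the block carries
    k-1 coefficients of which one (the linear direction) is unpenalized.
    """

    _dim = 1

    def __init__(self, x, k: int = 10, max_knots: int = 200):
        super().__init__(np.asarray(x, dtype=float).reshape(-1, 1), k, max_knots)

    def _kernel(self, r):
        return _tps_kernel_1d(r)


class ThinPlateBasis2D(_ThinPlateBase):
    """Low-rank thin plate regression spline on the plane.

    Kernel r^2 log(r)/(8 pi) with null space {1, x, y}; after absorbing
    the intercept the block carries k-1 coefficients of which two (the
    plane directions) are unpenalized.
    """

    _dim = 2

    def __init__(self, x, y, k: int = 30, max_knots: int = 300):
        pts = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
        uniq = np.unique(pts, axis=0)
        if len(uniq) >= 3:
            # guard against collinear-only locations
            spread = np.linalg.svd(uniq - uniq.mean(0), compute_uv=False)
            if spread[1] <= 1e-12 * max(spread[0], 1.0):
                import warnings

                warnings.warn(
                    "locations are collinear; 2-D thin plate smooth degrades to 1-D",
                    stacklevel=2,
                )
        super().__init__(pts, k, max_knots)

    def _kernel(self, r):
        return _tps_kernel_2d(r)
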