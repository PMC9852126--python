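"""Penalized spline bases: cubic, natural cubic, cyclic cubic, tensor product.

Each basis evaluates to a design matrix and carries one or more wiggliness
penalty matrices ``S`` such that, for a coefficient vector ``beta``, the
quadratic form ``beta' S beta`` equals the integrated squared second
derivative of the represented function over the knot range (one period for
cyclic bases).

The natural and cyclic bases use the cardinal (value-at-knot)
parameterization: coefficient ``beta_j`` is the function value at knot
``x_j`` and the basis function set is implied by natural / periodic cubic
spline interpolation.  This makes the C2-continuity constraints implicit and
yields the exact penalty ``S = D' B^{-1} D`` from the tridiagonal
interpolation system.  The plain (non-natural) cubic basis is a clamped
B-spline basis with the penalty computed by exact Gauss-Legendre quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space, solve

from .exceptions import (
    DegenerateCovariateError,
    HemogamWarning,
    InvalidKnotsError,
)

__all__ = [
    "KnotVector",
    "SmoothBasis",
    "make_knots",
    "cubic_basis",
    "cyclic_cubic_basis",
    "tensor_smooth",
    "apply_centering",
    "adaptive_penalty",
    "penalty_matrix",
]


@dataclass(frozen=True)
class KnotVector:
    """Strictly increasing knot locations plus the rule that produced them."""

    values: np.ndarray
    placement_rule: str = "explicit"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or len(v) < 4:
            raise InvalidKnotsError(f"need at least 4 knots, got {len(v)}")
        if not np.all(np.diff(v) > 0):
            raise InvalidKnotsError("knots must be strictly increasing")

    def __len__(self):
        return len(self.values)


def make_knots(x_values, n_knots: int, rule: str = "quantile") -> KnotVector:
    """Place ``n_knots`` knots over the range of ``x_values``.

    ``rule='quantile'`` puts knots at the empirical quantiles at
    probabilities 0, 1/(k-1), ..., 1 (so the minimum and maximum are always
    knots and each inter-knot segment holds roughly the same number of
    observations).  ``rule='uniform'`` spaces knots evenly over
    [min, max].  Tied quantiles are collapsed with a warning.
    """
    x = np.asarray(x_values, dtype=float)
    if n_knots < 4:
        raise InvalidKnotsError("n_knots must be at least 4")
    if len(np.unique(x)) < 2:
        raise DegenerateCovariateError("covariate has fewer than 2 distinct values")
    if rule == "quantile":
        probs = np.linspace(0.0, 1.0, n_knots)
        k = np.quantile(x, probs)
        uk = np.unique(k)
        if len(uk) < len(k):
            warnings.warn(
                f"collapsed {len(k) - len(uk)} duplicate quantile knots "
                f"(heavily tied covariate); basis dimension reduced",
                HemogamWarning,
                stacklevel=2,
            )
            k = uk
        if len(k) < 4:
            raise DegenerateCovariateError(
                "fewer than 4 distinct quantile knots; covariate too discrete"
            )
    elif rule == "uniform":
        k = np.linspace(x.min(), x.max(), n_knots)
    else:
        raise ValueError(f"unknown knot placement rule: {rule!r}")
    return KnotVector(values=k, placement_rule=rule)


# ---------------------------------------------------------------------------
# Core basis classes
# ---------------------------------------------------------------------------


@dataclass
class SmoothBasis:
    """An evaluable spline basis with its penalty matrices.

    Attributes
    ----------
    kind : str
        One of ``cubic``, ``natural_cubic``, ``cyclic_cubic``, ``tensor``.
    n_basis : int
        Number of basis functions (after any constraint).
    penalties : list of ndarray
        Square PSD matrices, one per smoothing parameter.
    adaptive_order : int
        Number of penalty sub-bases (1 = ordinary smooth).
    """

    kind: str
    n_basis: int
    penalties: list = field(default_factory=list)
    knots: KnotVector | None = None
    adaptive_order: int = 1
    centered: bool = False

    # subclasses implement design(); SmoothBasis itself is abstract
    def design(self, x, deriv: int = 0) -> np.ndarray:
        raise NotImplementedError

    @property
    def period(self):
        return None


def _locate(knots: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Segment index j with knots[j] <= x < knots[j+1], clipped to valid."""
    j = np.searchsorted(knots, x, side="right") - 1
    return np.clip(j, 0, len(knots) - 2)


def _hermite_parts(x, knots, j, deriv):
    """Cardinal-spline segment weights (a-, a+, c-, c+) or their derivatives."""
    h = knots[j + 1] - knots[j]
    dl = x - knots[j]
    dr = knots[j + 1] - x
    if deriv == 0:
        am, ap = dr / h, dl / h
        cm = (dr**3 / h - h * dr) / 6.0
        cp = (dl**3 / h - h * dl) / 6.0
    elif deriv == 1:
        am, ap = -1.0 / h, 1.0 / h
        am = np.broadcast_to(am, x.shape).copy()
        ap = np.broadcast_to(ap, x.shape).copy()
        cm = (h - 3.0 * dr**2 / h) / 6.0
        cp = (3.0 * dl**2 / h - h) / 6.0
    elif deriv == 2:
        am = np.zeros_like(x)
        ap = np.zeros_like(x)
        cm = dr / h
        cp = dl / h
    else:
        raise ValueError("deriv must be 0, 1 or 2")
    return am, ap, cm, cp


class NaturalCubicBasis(SmoothBasis):
    """Cardinal natural cubic spline basis: beta_j = f(knot_j).

    The second and third derivatives vanish at the outer knots, so the
    function is linear beyond them; evaluation outside the knot range
    extrapolates that linear tail.
    """

    def __init__(self, knots: KnotVector):
        xk = knots.values
        k = len(xk)
        h = np.diff(xk)
        # tridiagonal system B delta_int = D beta for interior 2nd derivatives
        B = np.zeros((k - 2, k - 2))
        D = np.zeros((k - 2, k))
        for i in range(k - 2):
            B[i, i] = (h[i] + h[i + 1]) / 3.0
            if i + 1 < k - 2:
                B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
            D[i, i] = 1.0 / h[i]
            D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
            D[i, i + 2] = 1.0 / h[i + 1]
        F = solve(B, D, assume_a="pos")
        S = D.T @ F
        S = (S + S.T) / 2.0
        self._F_full = np.zeros((k, k))
        self._F_full[1:-1] = F  # delta_1 = delta_k = 0 (natural constraint)
        super().__init__(
            kind="natural_cubic", n_basis=k, penalties=[S], knots=knots
        )

    def design(self, x, deriv: int = 0) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        xk = self.knots.values
        k = len(xk)
        lo, hi = xk[0], xk[-1]
        inside = np.clip(x, lo, hi)
        j = _locate(xk, inside)
        am, ap, cm, cp = _hermite_parts(inside, xk, j, deriv)
        X = cm[:, None] * self._F_full[j] + cp[:, None] * self._F_full[j + 1]
        rows = np.arange(len(x))
        X[rows, j] += am
        X[rows, j + 1] += ap
        # linear extrapolation beyond the outer knots
        out_lo = x < lo
        out_hi = x > hi
        if out_lo.any() or out_hi.any():
            if deriv == 0:
                d1 = self.design(np.array([lo, hi]), deriv=1)
                for mask, xb, drow in ((out_lo, lo, d1[0]), (out_hi, hi, d1[1])):
                    if mask.any():
                        X[mask] += (x[mask] - xb)[:, None] * drow
            elif deriv == 1:
                d1 = self.design(np.array([lo, hi]), deriv=1)
                X[out_lo] = d1[0]
                X[out_hi] = d1[1]
            else:
                X[out_lo] = 0.0
                X[out_hi] = 0.0
        return X


class CyclicCubicBasis(SmoothBasis):
    """Cardinal cyclic cubic spline basis on the period [knot_0, knot_last].

    The first and last knot are identified, giving ``len(knots) - 1``
    basis functions; the function and its first two derivatives are
    continuous across the period boundary.  Inputs are wrapped modulo the
    period, so out-of-range covariate values are never an error.
    """

    def __init__(self, knots: KnotVector):
        xk = knots.values
        m = len(xk) - 1  # effective knots / basis dimension
        h = np.diff(xk)  # m segment lengths
        B = np.zeros((m, m))
        D = np.zeros((m, m))
        for i in range(m):
            im1 = (i - 1) % m
            ip1 = (i + 1) % m
            hm = h[im1]
            hi = h[i]
            B[i, i] += (hm + hi) / 3.0
            B[i, ip1] += hi / 6.0
            B[i, im1] += hm / 6.0
            D[i, i] += -1.0 / hm - 1.0 / hi
            D[i, ip1] += 1.0 / hi
            D[i, im1] += 1.0 / hm
        B = (B + B.T) / 2.0
        F = solve(B, D, assume_a="pos")
        S = D.T @ F
        S = (S + S.T) / 2.0
        self._F = F
        super().__init__(
            kind="cyclic_cubic", n_basis=m, penalties=[S], knots=knots
        )

    @property
    def period(self):
        xk = self.knots.values
        return float(xk[-1] - xk[0])

    def design(self, x, deriv: int = 0) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        xk = self.knots.values
        m = self.n_basis
        lo = xk[0]
        per = self.period
        xr = lo + np.mod(x - lo, per)
        j = _locate(xk, xr)
        j = np.minimum(j, m - 1)
        am, ap, cm, cp = _hermite_parts(xr, xk, j, deriv)
        jr = (j + 1) % m
        X = cm[:, None] * self._F[j] + cp[:, None] * self._F[jr]
        rows = np.arange(len(x))
        X[rows, j] += am
        X[rows, jr] += ap
        return X


class CubicBSplineBasis(SmoothBasis):
    """Unconstrained C2 piecewise-cubic basis (clamped B-splines).

    Spans every piecewise cubic with C2 continuity at the interior knots;
    dimension ``n_knots + 2``.  Out-of-range evaluation clamps to the
    boundary value with a warning (the unconstrained cubic has no natural
    linear tail to extrapolate).
    """

    def __init__(self, knots: KnotVector):
        xk = knots.values
        self._t = np.r_[[xk[0]] * 3, xk, [xk[-1]] * 3]
        p = len(xk) + 2
        self._p = p
        S = _quadrature_penalty(self, xk)
        super().__init__(kind="cubic", n_basis=p, penalties=[S], knots=knots)

    def design(self, x, deriv: int = 0) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        xk = self._t[3], self._t[-4]
        if (x < xk[0]).any() or (x > xk[1]).any():
            warnings.warn(
                "covariate values outside the knot range of a non-natural "
                "cubic basis were clamped to the boundary",
                HemogamWarning,
                stacklevel=2,
            )
            x = np.clip(x, xk[0], xk[1])
        spl = BSpline(self._t, np.eye(self._p), 3, extrapolate=False)
        if deriv:
            spl = spl.derivative(deriv)
        X = spl(x)
        return np.nan_to_num(X, copy=False)


def _gauss_points(a, b, n):
    """Gauss-Legendre nodes/weights on [a, b]."""
    z, w = np.polynomial.legendre.leggauss(n)
    mid, half = (a + b) / 2.0, (b - a) / 2.0
    return mid + half * z, half * w


def _quadrature_penalty(basis, breakpoints, weight=None, npts=6):
    """S[i,j] = integral of w(x) * B_i''(x) * B_j''(x) dx, piecewise Gauss.

    Exact for the piecewise-polynomial integrands that arise here (second
    derivatives are at most quadratic per segment, weights piecewise linear).
    """
    p = basis._p if hasattr(basis, "_p") else basis.n_basis
    S = np.zeros((p, p))
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        if b <= a:
            continue
        xq, wq = _gauss_points(a, b, npts)
        D2 = basis.design(xq, deriv=2)
        wts = wq if weight is None else wq * weight(xq)
        S += (D2 * wts[:, None]).T @ D2
    return (S + S.T) / 2.0


def cubic_basis(knots: KnotVector, natural: bool = True) -> SmoothBasis:
    """Cubic spline basis on the given knots.

    ``natural=True`` returns the natural cubic basis (linear beyond the
    outer knots, where the 2nd and 3rd derivatives are pinned to zero);
    ``natural=False`` returns the full unconstrained C2 cubic span.
    """
    if natural:
        return NaturalCubicBasis(knots)
    return CubicBSplineBasis(knots)


def cyclic_cubic_basis(knots: KnotVector) -> SmoothBasis:
    """Cyclic cubic spline basis; first and last knot identified."""
    return CyclicCubicBasis(knots)


# ---------------------------------------------------------------------------
# Tensor products
# ---------------------------------------------------------------------------


class TensorBasis(SmoothBasis):
    """Tensor-product smooth of two marginal bases.

    Columns are ordered x-major: column ``i * n_y + j`` is the product of
    marginal basis functions ``b_i(x) * c_j(y)``.  Two penalties are carried
    (row-wise and column-wise marginal roughness, Kronecker-embedded as
    ``S_x (x) I`` and ``I (x) S_y``), each with its own smoothing parameter.
    """

    def __init__(self, margin_x: SmoothBasis, margin_y: SmoothBasis):
        self.margin_x = margin_x
        self.margin_y = margin_y
        nx, ny = margin_x.n_basis, margin_y.n_basis
        Sx = sum(margin_x.penalties)
        Sy = sum(margin_y.penalties)
        pen = [np.kron(Sx, np.eye(ny)), np.kron(np.eye(nx), Sy)]
        super().__init__(kind="tensor", n_basis=nx * ny, penalties=pen)

    def design(self, xy, deriv: int = 0) -> np.ndarray:
        if deriv:
            raise NotImplementedError("tensor derivatives are not needed/exposed")
        xy = np.asarray(xy, dtype=float)
        Ax = self.margin_x.design(xy[:, 0])
        Ay = self.margin_y.design(xy[:, 1])
        return np.einsum("ni,nj->nij", Ax, Ay).reshape(len(xy), -1)


def tensor_smooth(margin_x: SmoothBasis, margin_y: SmoothBasis) -> SmoothBasis:
    """Tensor-product interaction smooth with two marginal-roughness penalties."""
    return TensorBasis(margin_x, margin_y)


# ---------------------------------------------------------------------------
# Constraints and adaptive penalties
# ---------------------------------------------------------------------------


class CenteredBasis(SmoothBasis):
    """Reparameterized basis whose fitted smooth sums to zero over the data.

    Absorbing the sum-to-zero identifiability constraint reduces the
    dimension by one and makes the model intercept the mean of the response
    (so the intercept of a pulse-pressure model is the mean pulse pressure).
    """

    def __init__(self, inner: SmoothBasis, x_values):
        self.inner = inner
        c = inner.design(np.asarray(x_values)).sum(axis=0)
        Z = null_space(c[None, :])  # (p, p-1), orthonormal
        self._Z = Z
        pen = [(Z.T @ S @ Z + (Z.T @ S @ Z).T) / 2.0 for S in inner.penalties]
        super().__init__(
            kind=inner.kind,
            n_basis=inner.n_basis - 1,
            penalties=pen,
            knots=inner.knots,
            adaptive_order=inner.adaptive_order,
            centered=True,
        )

    @property
    def period(self):
        return self.inner.period

    def design(self, x, deriv: int = 0) -> np.ndarray:
        return self.inner.design(x, deriv=deriv) @ self._Z


def apply_centering(basis: SmoothBasis, x_values) -> SmoothBasis:
    """Impose the sum-to-zero constraint over the supplied covariate values."""
    return CenteredBasis(basis, x_values)


def _tent_weights(lo, hi, n_bumps):
    """Piecewise-linear partition of unity: n_bumps tents over [lo, hi]."""
    nodes = np.linspace(lo, hi, n_bumps)

    def make(m):
        def w(x):
            out = np.zeros_like(x)
            if m > 0:
                left = (x - nodes[m - 1]) / (nodes[m] - nodes[m - 1])
                sel = (x >= nodes[m - 1]) & (x <= nodes[m])
                out[sel] = left[sel]
            else:
                out[x <= nodes[0]] = 1.0
            if m < n_bumps - 1:
                right = (nodes[m + 1] - x) / (nodes[m + 1] - nodes[m])
                sel = (x > nodes[m]) & (x <= nodes[m + 1])
                out[sel] = right[sel]
            else:
                out[x >= nodes[-1]] = 1.0
            return out

        return w

    return [make(m) for m in range(n_bumps)], nodes


def adaptive_penalty(basis: SmoothBasis, n_penalty_bases: int) -> SmoothBasis:
    """Split the curvature penalty into locally weighted sub-penalties.

    Each sub-penalty integrates f''(x)^2 against a tent-shaped weight over a
    sub-range of the covariate; REML can then assign a different smoothing
    parameter per region, letting the smooth be stiff where the signal is
    flat and flexible across sharp transitions.  The tents form a partition
    of unity, so the equal-weight sum of the sub-penalties is the ordinary
    penalty.
    """
    if n_penalty_bases == 1:
        return basis
    if n_penalty_bases < 1:
        raise ValueError("n_penalty_bases must be >= 1")
    if basis.kind not in ("cubic", "natural_cubic", "cyclic_cubic"):
        raise ValueError("adaptive penalties require a univariate basis")
    xk = basis.knots.values
    weights, nodes = _tent_weights(xk[0], xk[-1], n_penalty_bases)
    brk = np.unique(np.concatenate([xk, nodes]))
    pens = [_quadrature_penalty(basis, brk, weight=w) for w in weights]
    import copy

    out = copy.copy(basis)
    out.penalties = pens
    out.adaptive_order = n_penalty_bases
    return out


def penalty_matrix(basis: SmoothBasis) -> np.ndarray:
    """Total curvature penalty of a basis (sum over penalty components)."""
    return sum(basis.penalties)
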