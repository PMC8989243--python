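"""Basis systems, Gram matrices, and coordinate representations of functional data.

A scalar-on-function regression treats each predictor curve ``X^j`` as an
element of a Hilbert space ``H_j`` of square-integrable functions on a compact
interval.  At the sample level every ``H_j`` is spanned by a finite basis
``{b_1^j, ..., b_m^j}`` and a curve is represented by its coordinate vector.
Inner products then become quadratic forms with the Gram matrix

    (G_j)_{ik} = \\int b_i^j(t) b_k^j(t) dt ,

and the roughness of a coefficient function is measured through the
second-derivative Gram matrix ``(B_j)'' = [ \\int (b_i^j)'' (b_k^j)'' ]``.

This module builds B-spline and Fourier bases (plus user-supplied callable
bases for testing and extensions), computes the Gram matrices by Gauss-Legendre
quadrature, projects discretely observed curves onto a basis by least squares,
and provides centering and empirical covariance computations in coordinates.
Time grids may differ across subjects and predictors: projection is per curve,
so all downstream computation sees only coordinates.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline

__all__ = [
    "BasisSystem",
    "BlockStructure",
    "CoordinateVector",
    "FunctionalDataset",
    "build_basis",
    "build_custom_basis",
    "gram_matrix",
    "second_derivative_gram",
    "project_curve",
    "center_dataset",
    "inner_product",
    "empirical_covariance_coords",
]

_GL_NODES = 10  # Gauss-Legendre nodes per quadrature subinterval


# ---------------------------------------------------------------------------
# basis systems
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BasisSystem:
    """A set of ``m`` basis functions on a closed interval with its Gram data.

    Attributes
    ----------
    kind : {"bspline", "fourier", "custom"}
    m : number of basis functions.
    domain : (a, b) closed interval, in original time units.
    order : B-spline order (degree + 1); ignored for other kinds.
    gram : (m, m) Gram matrix of pairwise L2 inner products.
    d2gram : (m, m) Gram matrix of the second derivatives.
    """

    kind: str
    m: int
    domain: tuple[float, float]
    order: int | None = None
    gram: np.ndarray = field(default=None, repr=False, compare=False)
    d2gram: np.ndarray = field(default=None, repr=False, compare=False)
    _funcs: tuple = field(default=None, repr=False, compare=False)
    _d2funcs: tuple = field(default=None, repr=False, compare=False)

    # -- evaluation --------------------------------------------------------
    def evaluate(self, t, deriv: int = 0) -> np.ndarray:
        """Evaluate all basis functions (or a derivative) at times ``t``.

        Returns an array of shape ``(len(t), m)``.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        a, b = self.domain
        if np.any(t < a - 1e-12) or np.any(t > b + 1e-12):
            raise ValueError(
                f"evaluation times outside basis domain [{a}, {b}]"
            )
        t = np.clip(t, a, b)
        if self.kind == "bspline":
            return self._eval_bspline(t, deriv)
        if self.kind == "fourier":
            return self._eval_fourier(t, deriv)
        if self.kind == "custom":
            funcs = self._funcs if deriv == 0 else self._d2funcs
            if deriv not in (0, 2) or funcs is None:
                raise ValueError("custom basis supports deriv in {0, 2} only")
            return np.column_stack([np.broadcast_to(f(t), t.shape) for f in funcs])
        raise ValueError(f"unknown basis kind {self.kind!r}")

    def _knots(self) -> np.ndarray:
        a, b = self.domain
        k = self.order - 1  # spline degree
        n_interior = self.m - self.order
        interior = np.linspace(a, b, n_interior + 2)[1:-1]
        return np.concatenate([np.full(k + 1, a), interior, np.full(k + 1, b)])

    def _eval_bspline(self, t: np.ndarray, deriv: int) -> np.ndarray:
        k = self.order - 1
        if deriv > k:
            return np.zeros((t.size, self.m))
        spl = BSpline(self._knots(), np.eye(self.m), k, extrapolate=True)
        return spl(t, nu=deriv)

    def _eval_fourier(self, t: np.ndarray, deriv: int) -> np.ndarray:
        a, b = self.domain
        length = b - a
        out = np.empty((t.size, self.m))
        # constant term, normalized so the system is orthonormal on [a, b]
        out[:, 0] = (1.0 / np.sqrt(length)) if deriv == 0 else 0.0
        amp = np.sqrt(2.0 / length)
        for pair in range(1, (self.m - 1) // 2 + 1):
            w = 2.0 * np.pi * pair / length
            phase = w * (t - a)
            s, c = np.sin(phase), np.cos(phase)
            if deriv == 0:
                ds, dc = s, c
            elif deriv == 1:
                ds, dc = w * c, -w * s
            elif deriv == 2:
                ds, dc = -w * w * s, -w * w * c
            else:
                raise ValueError("fourier derivatives supported up to order 2")
            out[:, 2 * pair - 1] = amp * ds
            out[:, 2 * pair] = amp * dc
        return out

    def quadrature_breakpoints(self) -> np.ndarray:
        """Subinterval edges on which the integrands are smooth."""
        a, b = self.domain
        if self.kind == "bspline":
            k = self.order - 1
            knots = self._knots()
            return np.unique(knots[k: len(knots) - k])
        if self.kind == "fourier":
            return np.linspace(a, b, 4 * self.m + 1)
        return np.linspace(a, b, max(4 * self.m, 40) + 1)


def _quad_gram(basis: BasisSystem, deriv: int) -> np.ndarray:
    """Gram matrix of ``deriv``-th derivatives via per-subinterval Gauss-Legendre."""
    nodes, weights = leggauss(_GL_NODES)
    edges = basis.quadrature_breakpoints()
    gram = np.zeros((basis.m, basis.m))
    for lo, hi in zip(edges[:-1], edges[1:]):
        half = 0.5 * (hi - lo)
        t = lo + half * (nodes + 1.0)
        e = basis.evaluate(t, deriv=deriv)
        gram += half * (e.T * weights) @ e
    return 0.5 * (gram + gram.T)


def build_basis(kind: str, m: int, domain: Sequence[float], order: int = 4) -> BasisSystem:
    """Construct a B-spline or Fourier basis with populated Gram matrices.

    Parameters
    ----------
    kind : {"bspline", "fourier"}
    m : number of basis functions.  B-splines require ``m >= order``;
        Fourier requires odd ``m`` (constant plus sine/cosine pairs).
    domain : (a, b) with a < b.
    order : B-spline order (degree + 1), default 4 (cubic).
    """
    a, b = float(domain[0]), float(domain[1])
    if not a < b:
        raise ValueError(f"degenerate domain [{a}, {b}]: need a < b")
    if kind == "bspline":
        if order < 1:
            raise ValueError("bspline order must be >= 1")
        if m < order:
            raise ValueError(f"bspline with order {order} needs m >= {order}, got {m}")
    elif kind == "fourier":
        if m < 1 or m % 2 == 0:
            raise ValueError(f"fourier basis needs odd m >= 1, got {m}")
        order = None
    else:
        raise ValueError(f"unknown basis kind {kind!r}")
    basis = BasisSystem(kind=kind, m=m, domain=(a, b), order=order)
    gram = _quad_gram(basis, deriv=0)
    if kind == "bspline" and order <= 2:
        d2 = np.zeros((m, m))  # a.e. zero second derivative
    else:
        d2 = _quad_gram(basis, deriv=2)
    return replace(basis, gram=gram, d2gram=d2)


def build_custom_basis(
    funcs: Sequence[Callable],
    domain: Sequence[float],
    d2funcs: Sequence[Callable] | None = None,
) -> BasisSystem:
    """Basis from arbitrary callables (second derivatives optional).

    Gram matrices are computed with the same quadrature as the built-in kinds;
    callables must be smooth on the subintervals reported by
    :meth:`BasisSystem.quadrature_breakpoints`.
    """
    a, b = float(domain[0]), float(domain[1])
    if not a < b:
        raise ValueError(f"degenerate domain [{a}, {b}]: need a < b")
    basis = BasisSystem(
        kind="custom", m=len(funcs), domain=(a, b),
        _funcs=tuple(funcs), _d2funcs=tuple(d2funcs) if d2funcs else None,
    )
    gram = _quad_gram(basis, deriv=0)
    d2 = _quad_gram(basis, deriv=2) if d2funcs else None
    return replace(basis, gram=gram, d2gram=d2)


def gram_matrix(basis: BasisSystem) -> np.ndarray:
    """Gram matrix of pairwise L2 inner products of the basis functions."""
    if basis.gram is not None:
        return basis.gram
    return _quad_gram(basis, deriv=0)


def second_derivative_gram(basis: BasisSystem) -> np.ndarray:
    """Gram matrix of the second derivatives (curvature penalty kernel)."""
    if basis.d2gram is not None:
        return basis.d2gram
    return _quad_gram(basis, deriv=2)


# ---------------------------------------------------------------------------
# block bookkeeping and coordinate vectors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockStructure:
    """Contiguous per-predictor block layout of a stacked coordinate vector."""

    m_list: tuple[int, ...]

    @property
    def p(self) -> int:
        return len(self.m_list)

    @property
    def M(self) -> int:
        return int(sum(self.m_list))

    @functools.cached_property
    def offsets(self) -> tuple[int, ...]:
        out = [0]
        for m in self.m_list:
            out.append(out[-1] + m)
        return tuple(out)

    def block_slice(self, j: int) -> slice:
        off = self.offsets
        return slice(off[j], off[j + 1])

    @functools.cached_property
    def _slices(self) -> tuple[slice, ...]:
        return tuple(self.block_slice(j) for j in range(self.p))

    def slices(self) -> tuple[slice, ...]:
        return self._slices


@dataclass
class CoordinateVector:
    """A stacked block coefficient vector with its basis tag.

    ``tag="B"`` means coordinates in the original basis; ``tag="C"`` in the
    per-predictor Karhunen-Loeve orthonormal basis, where the H-inner product
    is the plain Euclidean dot product.
    """

    values: np.ndarray
    structure: BlockStructure
    tag: str = "B"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.structure.M:
            raise ValueError(
                f"coordinate vector length {self.values.size} != total basis size "
                f"{self.structure.M}"
            )

    def block(self, j: int) -> np.ndarray:
        return self.values[self.structure.block_slice(j)]

    def block_norms(self, grams: Sequence[np.ndarray] | None = None) -> np.ndarray:
        """Per-block H-norms; in tag C (or with grams=None) Euclidean norms."""
        out = np.empty(self.structure.p)
        for j, sl in enumerate(self.structure.slices()):
            b = self.values[sl]
            if grams is None:
                out[j] = np.linalg.norm(b)
            else:
                out[j] = np.sqrt(max(b @ grams[j] @ b, 0.0))
        return out


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

@dataclass
class FunctionalDataset:
    """n x p curves reduced to a stacked M x n coordinate matrix plus response.

    ``coords`` has ``M = sum(m_j)`` rows grouped contiguously by predictor and
    one column per subject; ``tag`` records whether coordinates refer to the
    original basis ("B") or the orthonormalized one ("C").
    """

    bases: list[BasisSystem]
    coords: np.ndarray
    response: np.ndarray
    centered: bool = False
    x_means: np.ndarray | None = None
    y_mean: float = 0.0
    tag: str = "B"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.response = np.asarray(self.response, dtype=float).ravel()
        if self.coords.shape != (self.structure.M, self.n):
            raise ValueError(
                f"coords shape {self.coords.shape} inconsistent with "
                f"M={self.structure.M}, n={self.n}"
            )

    @property
    def n(self) -> int:
        return self.response.size

    @property
    def p(self) -> int:
        return len(self.bases)

    @property
    def structure(self) -> BlockStructure:
        return BlockStructure(tuple(b.m for b in self.bases))

    def gram_blocks(self) -> list[np.ndarray]:
        if self.tag == "C":
            return [np.eye(b.m) for b in self.bases]
        return [b.gram for b in self.bases]

    def block_coords(self, j: int) -> np.ndarray:
        return self.coords[self.structure.block_slice(j), :]


def project_curve(times, values, basis: BasisSystem) -> np.ndarray:
    """Least-squares projection of one observed curve onto a basis.

    Exact (to round-off) when the observed values sample a member of the span.
    Raises when there are fewer observation points than basis functions.
    """
    times = np.asarray(times, dtype=float).ravel()
    values = np.asarray(values, dtype=float).ravel()
    if times.size != values.size:
        raise ValueError("times and values must have equal length")
    if times.size < basis.m:
        raise ValueError(
            f"curve with {times.size} points is rank-deficient for m={basis.m} "
            "basis functions"
        )
    design = basis.evaluate(times)
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    return coef


def dataset_from_curves(
    curves: np.ndarray | Sequence,
    response,
    bases: Sequence[BasisSystem],
    times=None,
) -> FunctionalDataset:
    """Assemble a dataset by projecting each (subject, predictor) curve.

    ``curves`` is ``(n, p, n_obs)`` with shared ``times`` of length ``n_obs``,
    or a nested sequence ``curves[i][j] = (times_ij, values_ij)`` for
    unbalanced designs.
    """
    bases = list(bases)
    p = len(bases)
    if times is not None:
        curves = np.asarray(curves, dtype=float)
        n = curves.shape[0]
        # shared grid: one pseudo-inverse per predictor basis
        coords = np.empty((sum(b.m for b in bases), n))
        off = 0
        for j, basis in enumerate(bases):
            design = basis.evaluate(np.asarray(times, dtype=float))
            sol, *_ = np.linalg.lstsq(design, curves[:, j, :].T, rcond=None)
            coords[off: off + basis.m, :] = sol
            off += basis.m
    else:
        n = len(curves)
        coords = np.empty((sum(b.m for b in bases), n))
        for i in range(n):
            if len(curves[i]) != p:
                raise ValueError(f"subject {i} has {len(curves[i])} of {p} predictors")
            off = 0
            for j, basis in enumerate(bases):
                t_ij, v_ij = curves[i][j]
                try:
                    coords[off: off + basis.m, i] = project_curve(t_ij, v_ij, basis)
                except ValueError as exc:
                    raise ValueError(
                        f"projection failed for subject {i}, predictor {j}: {exc}"
                    ) from exc
                off += basis.m
    return FunctionalDataset(bases=bases, coords=coords, response=np.asarray(response, float))


def center_dataset(dataset: FunctionalDataset) -> FunctionalDataset:
    """Center coordinates and response, storing the means for prediction.

    Equivalent to right-multiplying the coordinate matrix by
    ``Q = I - n^{-1} 1 1^T``; applying it twice is a no-op.
    """
    if dataset.centered:
        return dataset
    if dataset.n < 2:
        raise ValueError("centering requires n >= 2")
    x_means = dataset.coords.mean(axis=1)
    y_mean = float(dataset.response.mean())
    return FunctionalDataset(
        bases=dataset.bases,
        coords=dataset.coords - x_means[:, None],
        response=dataset.response - y_mean,
        centered=True,
        x_means=x_means,
        y_mean=y_mean,
        tag=dataset.tag,
    )


def inner_product(f: CoordinateVector, g: CoordinateVector,
                  dataset: FunctionalDataset | None = None,
                  bases: Sequence[BasisSystem] | None = None) -> float:
    """H-inner product of two functions given by coordinates.

    In tag B this is ``[f]^T G [g]`` with the block-diagonal Gram matrix; in
    the orthonormal tag C it reduces to the plain dot product.
    """
    if f.tag != g.tag or f.structure != g.structure:
        raise ValueError("coordinate vectors have mismatched basis tag or blocks")
    if f.tag == "C":
        return float(f.values @ g.values)
    if bases is None:
        if dataset is None:
            raise ValueError("tag-B inner product needs the dataset or bases")
        bases = dataset.bases
    total = 0.0
    for j, sl in enumerate(f.structure.slices()):
        total += f.values[sl] @ bases[j].gram @ g.values[sl]
    return float(total)


def empirical_covariance_coords(dataset: FunctionalDataset):
    """Coordinate representations of the empirical covariances.

    Returns ``(gamma_xx, gamma_yx)`` where ``gamma_xx = n^{-1} [X~][X~]^T G``
    is the M x M coordinate matrix of the empirical covariance operator of X
    and ``gamma_yx = n^{-1} Y^T [X~]^T G`` the length-M covariance with Y.
    Centers internally if needed.
    """
    if dataset.n < 2:
        raise ValueError("empirical covariance requires n >= 2")
    ds = center_dataset(dataset)
    G = _block_diag([g for g in ds.gram_blocks()])
    xt = ds.coords
    gamma_xx = (xt @ xt.T) @ G / ds.n
    gamma_yx = (ds.response @ xt.T) @ G / ds.n
    return gamma_xx, gamma_yx


def _block_diag(blocks: Sequence[np.ndarray]) -> np.ndarray:
    sizes = [b.shape[0] for b in blocks]
    out = np.zeros((sum(sizes), sum(sizes)))
    off = 0
    for b in blocks:
        k = b.shape[0]
        out[off: off + k, off: off + k] = b
        off += k
    return out
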