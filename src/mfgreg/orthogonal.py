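"""Per-predictor Karhunen-Loeve orthonormalization of the basis system.

For each predictor ``j`` the empirical covariance operator of ``X^j`` is
eigendecomposed through the symmetric matrix

    S_j = n^{-1} (G_j)^{1/2} [X~^j] [X~^j]^T (G_j)^{1/2} ,

whose eigenvectors ``v_k`` give coordinates ``[phi_k^j]_B = (G_j)^{-1/2} v_k``
of orthonormal eigenfunctions.  In the new basis ``C_j = {phi_k^j}`` the
H-inner product is the Euclidean dot product and the empirical covariance is
diagonal with the eigenvalues, which makes the ADMM updates closed-form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import BasisSystem, CoordinateVector, FunctionalDataset, _block_diag

__all__ = [
    "KLTransform",
    "kl_orthogonalize",
    "to_orthonormal",
    "from_orthonormal",
    "d2gram_orthonormal",
]

_EIG_FLOOR = 1e-12  # relative eigenvalue floor for the Gram square root


def _sym_sqrt_pair(G: np.ndarray, label: str) -> tuple[np.ndarray, np.ndarray]:
    """(G^{1/2}, G^{-1/2}) via symmetric eigendecomposition with a floor."""
    w, V = np.linalg.eigh(0.5 * (G + G.T))
    floor = _EIG_FLOOR * w[-1]
    if w[-1] <= 0 or w[0] < -1e-8 * w[-1]:
        raise ValueError(f"Gram matrix for predictor {label} is not positive definite")
    w = np.maximum(w, floor)
    sq = (V * np.sqrt(w)) @ V.T
    isq = (V / np.sqrt(w)) @ V.T
    return sq, isq


def _fix_signs(V: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Deterministic sign convention: first entry exceeding tol is positive."""
    V = V.copy()
    for k in range(V.shape[1]):
        col = V[:, k]
        nz = np.flatnonzero(np.abs(col) > tol)
        if nz.size and col[nz[0]] < 0:
            V[:, k] = -col
    return V


@dataclass
class KLTransform:
    """Per-predictor orthonormalizing change of basis.

    ``phi[j]`` holds the m x m matrix whose columns are the B-coordinates of
    the orthonormal eigenfunctions; ``eigenvalues[j]`` the nonincreasing KL
    eigenvalues; ``ginvsqrt[j]`` the symmetric inverse square root of G_j.
    """

    phi: list[np.ndarray]
    eigenvalues: list[np.ndarray]
    ginvsqrt: list[np.ndarray]

    @property
    def p(self) -> int:
        return len(self.phi)


def kl_orthogonalize(dataset: FunctionalDataset) -> KLTransform:
    """Eigendecompose each predictor's empirical covariance (dataset must be centered)."""
    if not dataset.centered:
        raise ValueError("kl_orthogonalize requires a centered dataset")
    phi, eigs, ginv = [], [], []
    for j, basis in enumerate(dataset.bases):
        sq, isq = _sym_sqrt_pair(basis.gram, str(j))
        Z = sq @ dataset.block_coords(j)
        S = (Z @ Z.T) / dataset.n
        w, V = np.linalg.eigh(0.5 * (S + S.T))
        idx = np.argsort(w, kind="stable")[::-1]  # nonincreasing, stable ties
        w, V = w[idx], _fix_signs(V[:, idx])
        phi.append(isq @ V)
        eigs.append(np.maximum(w, 0.0) if w.min() > -1e-10 * max(w.max(), 1) else w)
        ginv.append(isq)
    return KLTransform(phi=phi, eigenvalues=eigs, ginvsqrt=ginv)


def to_orthonormal(dataset: FunctionalDataset, transform: KLTransform) -> FunctionalDataset:
    """Change coordinates to the orthonormal KL basis: ``[X]_C = Phi^T G [X]_B``."""
    if dataset.tag != "B":
        raise ValueError("dataset is already in orthonormal coordinates")
    if transform.p != dataset.p:
        raise ValueError("transform and dataset have mismatched predictor counts")
    coords_c = np.empty_like(dataset.coords)
    for j, sl in enumerate(dataset.structure.slices()):
        A = transform.phi[j].T @ dataset.bases[j].gram
        coords_c[sl, :] = A @ dataset.coords[sl, :]
    x_means = None
    if dataset.x_means is not None:
        x_means = np.empty_like(dataset.x_means)
        for j, sl in enumerate(dataset.structure.slices()):
            x_means[sl] = transform.phi[j].T @ dataset.bases[j].gram @ dataset.x_means[sl]
    return FunctionalDataset(
        bases=dataset.bases,
        coords=coords_c,
        response=dataset.response,
        centered=dataset.centered,
        x_means=x_means,
        y_mean=dataset.y_mean,
        tag="C",
    )


def from_orthonormal(beta_c: CoordinateVector, transform: KLTransform) -> CoordinateVector:
    """Map C-coordinates back to the original basis: ``[beta]_B = Phi [beta]_C`` per block."""
    if beta_c.tag != "C":
        raise ValueError("expected tag-C coordinates")
    out = np.empty_like(beta_c.values)
    for j, sl in enumerate(beta_c.structure.slices()):
        out[sl] = transform.phi[j] @ beta_c.values[sl]
    return CoordinateVector(values=out, structure=beta_c.structure, tag="B")


def d2gram_orthonormal(transform: KLTransform, bases: list[BasisSystem]) -> np.ndarray:
    """Second-derivative Gram matrix G'' in the orthonormal basis.

    Since ``Phi_j^{-1} = Phi_j^T G_j`` (orthonormality), the j-th block
    ``(Phi_j)^{-1}(G_j)^{-1}(B_j)''((G_j)^{-1}(Phi_j)^{-1})^T`` simplifies to
    ``Phi_j^T (B_j)'' Phi_j``; block-diagonal, symmetric PSD.
    """
    blocks = []
    for j, basis in enumerate(bases):
        if basis.d2gram is None:
            raise ValueError(f"basis for predictor {j} has no second-derivative Gram")
        B2 = basis.d2gram
        blk = transform.phi[j].T @ B2 @ transform.phi[j]
        blocks.append(0.5 * (blk + blk.T))
    return _block_diag(blocks)
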