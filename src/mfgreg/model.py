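"""User-facing estimator: fit/predict with either solver and cross-validation.

``fit`` accepts the regularization weight ``lambda_`` on the per-sample (E_n)
scale for both solvers; the GMD objective carries no 1/n factor, so the weight
is multiplied by the training size internally when GMD is used.  This makes a
fit at one ``lambda_`` comparable across solvers: both minimize the same
functional objective and return the same active set up to solver tolerances.

Cross-validation follows the tuning recipe of the method: for every
``(alpha, lambda_der)`` on a user net, a data-driven lambda grid is built on
the full training data (for ADMM, log-spaced between slightly below the
smallest and slightly above the largest block norm of the ridge estimate; for
GMD, from the KKT-derived lambda_max downward), each fold is solved along the
grid with warm starts, and the mean validation squared error selects the
winning triple, at which the model is refit on all data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .admm import ADMMConfig, ADMMFactor, admm_fit, objective_value
from .basis import (
    BasisSystem,
    BlockStructure,
    CoordinateVector,
    FunctionalDataset,
    center_dataset,
    project_curve,
)
from .gmd import (
    GMDConfig,
    GMDWorkspace,
    build_lambda_grid_gmd,
    gmd_fit,
    gmd_fit_path,
)
from .orthogonal import (
    d2gram_orthonormal,
    from_orthonormal,
    kl_orthogonalize,
    to_orthonormal,
)

__all__ = ["SparseFit", "CVResult", "build_lambda_grid_admm", "fit", "predict",
           "predict_coords", "cross_validate", "extract_coefficients",
           "select_num_basis"]


@dataclass
class SparseFit:
    """A fitted sparse scalar-on-function regression model.

    ``beta_b`` holds the coefficient functions in the original basis (used for
    interpretation and prediction); blocks outside ``active_set`` are exactly
    zero.  ``lambda_`` is on the per-sample (E_n) scale regardless of solver.
    """

    beta_b: CoordinateVector
    active_set: list[int]
    lambda_: float
    alpha: float
    lambda_der: float
    solver: str
    bases: list[BasisSystem]
    y_mean: float
    x_means: np.ndarray
    beta_c: CoordinateVector | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return len(self.bases)


def build_lambda_grid_admm(dataset: FunctionalDataset, n_points: int = 100,
                           rho: float = 1.0, lambda_der: float = 0.0,
                           d2gram=None, lo_factor: float = 0.9,
                           hi_factor: float = 1.1) -> np.ndarray:
    """Decreasing lambda grid bracketing the ridge estimate's block norms.

    The ridge estimate is the first ADMM beta-update with ``gamma = U = 0``;
    the grid is log-spaced on ``[lo_factor * min_norm, hi_factor * max_norm]``
    of its per-block norms, so the largest lambda zeroes every block and the
    smallest keeps all of them.
    """
    ds = center_dataset(dataset)
    if ds.tag != "C":
        klt = kl_orthogonalize(ds)
        ds = to_orthonormal(ds, klt)
        if lambda_der > 0 and d2gram is None:
            d2gram = d2gram_orthonormal(klt, dataset.bases)
    factor = ADMMFactor(ds, d2gram, lambda_der, rho)
    ridge = factor.beta_update(np.zeros(ds.structure.M), np.zeros(ds.structure.M))
    norms = np.array([np.linalg.norm(ridge[sl]) for sl in ds.structure.slices()])
    if norms.max() <= 1e-14:
        raise ValueError("degenerate lambda grid: all ridge block norms are zero")
    lo = max(lo_factor * norms[norms > 1e-14].min(), 1e-12)
    hi = hi_factor * norms.max()
    # the ridge block norms only bound the first thresholding pass; the exact
    # all-zero boundary is the KKT threshold max_j ||Z_j Y|| / n — raise the
    # grid top to it so the largest lambda provably empties the active set
    zy = ds.coords @ ds.response
    kkt_top = max(np.linalg.norm(zy[sl]) for sl in ds.structure.slices()) / ds.n
    hi = max(hi, 1.01 * kkt_top)
    return np.geomspace(hi, lo, n_points)


def _prepare(dataset: FunctionalDataset):
    ds = center_dataset(dataset)
    klt = kl_orthogonalize(ds)
    ds_c = to_orthonormal(ds, klt)
    return ds, klt, ds_c


def fit(dataset: FunctionalDataset, solver: str = "gmd", lambda_: float = 0.0,
        alpha: float = 0.0, lambda_der: float = 0.0, config=None) -> SparseFit:
    """Fit MFG-LASSO (alpha=0) / MFG-Elastic-Net at one parameter triple."""
    if solver not in ("admm", "gmd"):
        raise ValueError(f"unknown solver {solver!r}")
    ds = center_dataset(dataset)
    # user-facing lambda_ and lambda_der are per-sample weights; the solvers'
    # raw updates carry the curvature matrix without a 1/n factor
    if solver == "admm":
        ds_b, klt, ds_c = _prepare(ds)
        d2c = d2gram_orthonormal(klt, ds_b.bases) if lambda_der > 0 else None
        res = admm_fit(ds_c, lambda_, alpha, lambda_der * ds.n, d2gram=d2c,
                       config=config or ADMMConfig())
        beta_b = from_orthonormal(res.gamma, klt)
        for j in range(ds.p):
            if j not in res.active_set:
                beta_b.values[ds.structure.block_slice(j)] = 0.0
        diag = {"iterations": res.iterations, "converged": res.converged,
                "primal_residual": res.primal_residual,
                "dual_residual": res.dual_residual, "objective": res.objective}
        beta_c = res.gamma
        active = res.active_set
    else:
        res = gmd_fit(ds, lambda_ * ds.n, alpha, lambda_der * ds.n,
                      config=config or GMDConfig())
        beta_b = res.beta
        beta_c = None
        active = res.active_set
        diag = {"sweeps": res.sweeps, "converged": res.converged,
                "kkt_violations": res.kkt_violations,
                "objective_gmd_scale": res.objective,
                "objective": res.objective / ds.n}
    return SparseFit(
        beta_b=beta_b, active_set=active, lambda_=lambda_, alpha=alpha,
        lambda_der=lambda_der, solver=solver, bases=list(ds.bases),
        y_mean=ds.y_mean, x_means=ds.x_means, beta_c=beta_c, diagnostics=diag,
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_coords(fit_: SparseFit, coords_b: np.ndarray) -> np.ndarray:
    """Predict from raw (uncentered) B-coordinates, one column per subject:
    ``yhat = y_mean + sum_j ([x^j] - xbar^j)^T G_j [beta^j]``."""
    coords_b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    struct = fit_.beta_b.structure
    if coords_b.shape[0] != struct.M:
        raise ValueError(f"coordinate matrix has {coords_b.shape[0]} rows, expected {struct.M}")
    gb = np.empty(struct.M)
    for j, sl in enumerate(struct.slices()):
        gb[sl] = fit_.bases[j].gram @ fit_.beta_b.values[sl]
    centered = coords_b - fit_.x_means[:, None]
    return fit_.y_mean + centered.T @ gb


def predict(fit_: SparseFit, new_curves, times=None) -> np.ndarray:
    """Predict responses for new subjects' curves.

    ``new_curves`` is ``(n_new, p, n_obs)`` with a shared ``times`` grid, or a
    nested ``new_curves[i][j] = (times_ij, values_ij)``; every subject must
    supply every predictor.
    """
    struct = fit_.beta_b.structure
    if times is not None:
        arr = np.asarray(new_curves, dtype=float)
        if arr.ndim == 2:  # single subject
            arr = arr[None]
        n_new = arr.shape[0]
        coords = np.empty((struct.M, n_new))
        for j, basis in enumerate(fit_.bases):
            design = basis.evaluate(np.asarray(times, dtype=float))
            sol, *_ = np.linalg.lstsq(design, arr[:, j, :].T, rcond=None)
            coords[struct.block_slice(j), :] = sol
    else:
        n_new = len(new_curves)
        coords = np.empty((struct.M, n_new))
        for i in range(n_new):
            if len(new_curves[i]) != fit_.p:
                raise ValueError(
                    f"subject {i} supplies {len(new_curves[i])} of {fit_.p} predictors")
            for j, basis in enumerate(fit_.bases):
                t_ij, v_ij = new_curves[i][j]
                try:
                    coords[struct.block_slice(j), i] = project_curve(t_ij, v_ij, basis)
                except ValueError as exc:
                    raise ValueError(
                        f"subject {i}, predictor {j}: {exc}") from exc
    return predict_coords(fit_, coords)


def extract_coefficients(fit_: SparseFit, eval_times) -> np.ndarray:
    """Sample the p coefficient functions at ``eval_times`` -> (p, len(times))."""
    t = np.asarray(eval_times, dtype=float)
    out = np.empty((fit_.p, t.size))
    for j, basis in enumerate(fit_.bases):
        block = fit_.beta_b.block(j)
        out[j] = basis.evaluate(t) @ block
    return out


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Cross-validation error surface over the (alpha, lambda_der, lambda) net."""

    error_surface: dict            # (alpha, lambda_der, lambda) -> (mean MSE, fold SD)
    best: tuple[float, float, float]
    k: int
    seed: int
    best_fit: SparseFit
    solver: str

    def best_mse(self) -> float:
        return self.error_surface[self.best][0]


def _fold_assignment(n: int, k: int, seed: int, groups=None) -> np.ndarray:
    """Deterministic subject-level folds with sizes differing by <= 1.

    With ``groups`` (one label per record), all records sharing a label are
    assigned to the same fold — for designs where a subject contributes
    several records.
    """
    rng = np.random.default_rng(seed)
    if groups is None:
        idx = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        folds[idx] = np.arange(n) % k
        return folds
    groups = np.asarray(groups)
    if groups.size != n:
        raise ValueError("groups must have one label per record")
    uniq = np.unique(groups)
    order = rng.permutation(uniq.size)
    label_fold = {uniq[gi]: rank % k for rank, gi in enumerate(order)}
    return np.array([label_fold[g] for g in groups], dtype=int)


def _subset(dataset: FunctionalDataset, mask: np.ndarray) -> FunctionalDataset:
    return FunctionalDataset(
        bases=dataset.bases,
        coords=dataset.coords[:, mask],
        response=dataset.response[mask],
        centered=False,
        tag=dataset.tag,
    )


def _val_mse_gmd(train: FunctionalDataset, val: FunctionalDataset,
                 grid_en: np.ndarray, alpha: float, lambda_der_en: float,
                 config: GMDConfig) -> np.ndarray:
    # the GMD objective carries no 1/n: scale the per-sample (E_n) grid and
    # curvature weight by the fold's sample count so every fold applies the
    # same per-sample penalty
    tr = center_dataset(train)
    grid = grid_en * tr.n
    lambda_der = lambda_der_en * tr.n
    ws = GMDWorkspace(tr, lambda_der)
    path = gmd_fit_path(tr, grid, alpha, lambda_der, config=config, workspace=ws)
    struct = tr.structure
    gb_all = np.empty((struct.M, len(path.fits)))
    for c, f in enumerate(path.fits):
        for j, sl in enumerate(struct.slices()):
            gb_all[sl, c] = tr.bases[j].gram @ f.beta.values[sl]
    centered = val.coords - tr.x_means[:, None]
    preds = tr.y_mean + centered.T @ gb_all     # (n_val, n_lambda)
    err = preds - val.response[:, None]
    return np.mean(err ** 2, axis=0)


def _val_mse_admm(train: FunctionalDataset, val: FunctionalDataset,
                  grid: np.ndarray, alpha: float, lambda_der_en: float,
                  config: ADMMConfig) -> np.ndarray:
    tr, klt, tr_c = _prepare(train)
    lambda_der = lambda_der_en * tr.n  # per-sample -> raw solver scale
    d2c = d2gram_orthonormal(klt, tr.bases) if lambda_der_en > 0 else None
    factor = ADMMFactor(tr_c, d2c, lambda_der, config.rho)
    struct = tr.structure
    warm = None
    out = np.empty(grid.size)
    gb = np.empty(struct.M)
    for c, lam in enumerate(grid):
        res = admm_fit(tr_c, lam, alpha, lambda_der, d2gram=d2c, config=config,
                       factor=factor, warm_start=warm)
        warm = (res.gamma.values.copy(), res.u.copy())
        beta_b = from_orthonormal(res.gamma, klt)
        for j, sl in enumerate(struct.slices()):
            gb[sl] = tr.bases[j].gram @ beta_b.values[sl]
        centered = val.coords - tr.x_means[:, None]
        preds = tr.y_mean + centered.T @ gb
        out[c] = np.mean((preds - val.response) ** 2)
    return out


def cross_validate(dataset: FunctionalDataset, solver: str = "gmd",
                   alpha_net=(0.0,), lambda_der_net=(0.0,), k: int = 5,
                   seed: int = 0, n_lambda: int = 100,
                   lambda_min_ratio: float = 1e-3, config=None,
                   groups=None) -> CVResult:
    """k-fold CV over the (alpha, lambda_der, lambda) net; refit at the argmin.

    The lambda grid for each (alpha, lambda_der) is built once from the full
    data; folds are solved along it with warm starts.  Surface keys report
    lambda on the E_n scale for both solvers.
    """
    if k < 2:
        raise ValueError("cross-validation needs k >= 2")
    alpha_net = list(alpha_net)
    lambda_der_net = list(lambda_der_net)
    if not alpha_net or not lambda_der_net:
        raise ValueError("alpha and lambda_der nets must be nonempty")
    n = dataset.n
    if n < k:
        raise ValueError("more folds than subjects")
    folds = _fold_assignment(n, k, seed, groups=groups)
    for f in range(k):
        if np.sum(folds == f) < 1:
            raise ValueError(f"fold {f} is empty")
    ds_full = center_dataset(dataset)

    surface: dict = {}
    best_key, best_mean = None, np.inf
    for alpha in alpha_net:
        for lder in lambda_der_net:
            # lder is per-sample; raw solver-scale weight is n * lder
            if solver == "gmd":
                if alpha >= 1.0:
                    ws = GMDWorkspace(ds_full, lder * n)
                    top = max(np.linalg.norm(c) for c in ws.c_blocks)
                    grid = np.geomspace(top, lambda_min_ratio * top, n_lambda)
                else:
                    grid = build_lambda_grid_gmd(
                        ds_full, alpha, lder * n, n_points=n_lambda,
                        min_ratio=lambda_min_ratio)
                lam_en = grid / n  # report on the E_n scale
            else:
                grid = build_lambda_grid_admm(ds_full, n_points=n_lambda,
                                              lambda_der=lder * n)
                lam_en = grid
            fold_mse = np.empty((k, grid.size))
            for f in range(k):
                mask_val = folds == f
                train = _subset(dataset, ~mask_val)
                val = _subset(dataset, mask_val)
                if train.n < 2:
                    raise ValueError(f"fold {f} leaves fewer than 2 training subjects")
                if solver == "gmd":
                    fold_mse[f] = _val_mse_gmd(train, val, lam_en, alpha, lder,
                                               config or GMDConfig())
                else:
                    fold_mse[f] = _val_mse_admm(train, val, grid, alpha, lder,
                                                config or ADMMConfig())
            means = fold_mse.mean(axis=0)
            sds = fold_mse.std(axis=0, ddof=1) if k > 1 else np.zeros(grid.size)
            for c in range(grid.size):
                key = (float(alpha), float(lder), float(lam_en[c]))
                surface[key] = (float(means[c]), float(sds[c]))
                if means[c] < best_mean:
                    best_mean, best_key = float(means[c]), key
    alpha_b, lder_b, lam_b = best_key
    final = fit(dataset, solver=solver, lambda_=lam_b, alpha=alpha_b,
                lambda_der=lder_b, config=config)
    return CVResult(error_surface=surface, best=best_key, k=k, seed=seed,
                    best_fit=final, solver=solver)


def select_num_basis(curves, response, m_candidates, kind: str = "bspline",
                     domain=(0.0, 1.0), order: int = 4, times=None,
                     solver: str = "gmd", k: int = 5, seed: int = 0,
                     **cv_kwargs):
    """Optional outer CV loop over the number of basis functions.

    Re-projects the raw curves for every candidate ``m``, runs
    :func:`cross_validate` on each, and returns ``(best_m, cv_by_m)`` where
    ``cv_by_m`` maps each candidate to its CVResult.  Off by default in every
    pipeline; intended for sensitivity checks on the basis dimension.
    """
    from .basis import build_basis as _build, dataset_from_curves
    if not m_candidates:
        raise ValueError("m_candidates must be nonempty")
    cv_by_m = {}
    best_m, best_err = None, np.inf
    for m in m_candidates:
        basis = _build(kind, int(m), domain, order=order)
        p = len(curves[0]) if times is None else np.asarray(curves).shape[1]
        ds = dataset_from_curves(curves, response, [basis] * p, times=times)
        cv = cross_validate(ds, solver=solver, k=k, seed=seed, **cv_kwargs)
        cv_by_m[int(m)] = cv
        if cv.best_mse() < best_err:
            best_err, best_m = cv.best_mse(), int(m)
    return best_m, cv_by_m
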