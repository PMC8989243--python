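"""Synthetic-data generator and scenario runner for the Monte-Carlo study.

Each replicate draws ``p = 19`` functional predictors per subject as running
cumulative sums of i.i.d. standard normals over a 500-point grid on [0, 1]
(a discretized Brownian motion), generates the scalar response

    Y = <X^1, beta^1> + <X^2, beta^2> + <X^3, beta^3> + sigma * eps ,

with the inner products computed by a 500-point Riemann sum and true
coefficients ``beta^1(t) = sin(3 pi t / 2)``, ``beta^2(t) = sin(5 pi t / 2)``,
``beta^3(t) = t^2`` (an alternative ``t^2``-argument reading of the sine
coefficients is switchable via ``beta_arg="squared"``), then drops 400 grid
points so the 100 retained observation times are equally spaced.  Predictors
4..19 never enter the response: the population active set is {1, 2, 3}.

The scenario runner projects the observed curves onto ``m = 21`` cubic
B-splines, splits subjects 80/20 into train and test, tunes the sparse
methods by 5-fold CV, and scores test RMSE plus the counts of correctly
selected active and correctly eliminated inactive predictors, the quantities
tabulated in the study.  Baselines: functional OLS (minimum-norm least
squares on all predictors), ridge (pure quadratic group penalty, CV-tuned
lambda), and the oracle (OLS restricted to the truly active predictors).

All randomness flows from the single scenario seed through named substreams
(curves, noise, split, folds), so reruns are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import FunctionalDataset, build_basis, center_dataset
from .gmd import GMDConfig
from .model import cross_validate, predict_coords

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "fine_grid",
    "true_coefficients",
    "generate_predictors",
    "generate_response",
    "downsample",
    "baseline_fits",
    "run_scenario",
]

ACTIVE_SET = (0, 1, 2)          # population active predictors (0-based)
ALL_METHODS = ("ols", "ridge", "mfg_lasso", "mfg_en", "oracle")


@dataclass
class ScenarioSpec:
    """One simulation scenario: the data-generating conditions plus tuning nets."""

    n: int = 500
    sigma: float = 0.01
    reps: int = 20
    seed: int = 0
    p: int = 19
    n_fine: int = 500
    n_obs: int = 100
    m: int = 21
    train_fraction: float = 0.8
    beta_arg: str = "half"            # sin(k pi t/2) vs sin(k pi t^2) reading
    k_folds: int = 5
    n_lambda: int = 40
    lambda_min_ratio: float = 1e-3
    en_alpha_net: tuple = (0.25, 0.75)
    # lambda_der net = these ratios times the data-driven scale tr(H_loss)/tr(P)
    lambda_der_ratios: tuple = (0.0, 1e-2)

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_fine % self.n_obs:
            raise ValueError("n_obs must divide n_fine for equally spaced retention")


@dataclass
class ScenarioResult:
    """Per-method aggregated metrics plus the per-replicate records behind them."""

    spec: ScenarioSpec
    rmse: dict = field(default_factory=dict)        # method -> (mean, sd)
    selection: dict = field(default_factory=dict)   # method -> (active %, inactive %)
    per_rep_rmse: dict = field(default_factory=dict)
    per_rep_active_sets: dict = field(default_factory=dict)

    def table_rows(self) -> list[dict]:
        rows = []
        for method in self.rmse:
            act, inact = self.selection[method]
            mean, sd = self.rmse[method]
            rows.append({
                "n": self.spec.n, "sigma": self.spec.sigma, "method": method,
                "active_pct": act, "inactive_pct": inact,
                "rmse_mean": mean, "rmse_sd": sd,
            })
        return rows


# ---------------------------------------------------------------------------
# data generation
# ---------------------------------------------------------------------------

def fine_grid(n_fine: int = 500) -> np.ndarray:
    """Generation grid t*_i = i / n_fine, i = 1..n_fine."""
    return np.arange(1, n_fine + 1) / n_fine


def true_coefficients(t: np.ndarray, beta_arg: str = "half") -> np.ndarray:
    """The three active coefficient functions, stacked (3, len(t))."""
    t = np.asarray(t, dtype=float)
    if beta_arg == "half":
        b1, b2 = np.sin(3 * np.pi * t / 2), np.sin(5 * np.pi * t / 2)
    elif beta_arg == "squared":
        b1, b2 = np.sin(3 * np.pi * t ** 2), np.sin(5 * np.pi * t ** 2)
    else:
        raise ValueError("beta_arg must be 'half' or 'squared'")
    return np.vstack([b1, b2, t ** 2])


def generate_predictors(n: int, p: int, n_fine: int, rng: np.random.Generator) -> np.ndarray:
    """Brownian-motion-style curves: cumulative sums of N(0,1) increments, (n, p, n_fine)."""
    return rng.standard_normal((n, p, n_fine)).cumsum(axis=2)


def generate_response(curves_fine: np.ndarray, sigma: float,
                      rng: np.random.Generator, beta_arg: str = "half") -> np.ndarray:
    """Riemann-sum inner products with the true coefficients plus Gaussian noise."""
    n_fine = curves_fine.shape[2]
    betas = true_coefficients(fine_grid(n_fine), beta_arg)
    signal = np.einsum("ijk,jk->i", curves_fine[:, :3, :], betas) / n_fine
    return signal + sigma * rng.standard_normal(curves_fine.shape[0])


def downsample(curves_fine: np.ndarray, n_obs: int) -> tuple[np.ndarray, np.ndarray]:
    """Retain every (n_fine/n_obs)-th grid point; returns (curves_obs, times_obs)."""
    n_fine = curves_fine.shape[-1]
    if n_fine % n_obs:
        raise ValueError(f"cannot retain {n_obs} equally spaced of {n_fine} points")
    step = n_fine // n_obs
    idx = np.arange(step - 1, n_fine, step)
    return curves_fine[..., idx], fine_grid(n_fine)[idx]


# ---------------------------------------------------------------------------
# baselines in transformed coordinates
# ---------------------------------------------------------------------------

class _TildeData:
    """Train/test design in per-block G^{1/2} coordinates (penalty = Euclidean)."""

    def __init__(self, train: FunctionalDataset, test_coords: np.ndarray,
                 y_test: np.ndarray):
        tr = center_dataset(train)
        self.struct = tr.structure
        self.y = tr.response
        self.y_mean = tr.y_mean
        sqrts = {}
        self.z_train = np.empty_like(tr.coords)
        self.z_test = np.empty((self.struct.M, test_coords.shape[1]))
        test_centered = test_coords - tr.x_means[:, None]
        for j, sl in enumerate(self.struct.slices()):
            basis = tr.bases[j]
            key = id(basis)
            if key not in sqrts:
                w, V = np.linalg.eigh(basis.gram)
                sqrts[key] = (V * np.sqrt(np.maximum(w, 1e-12 * w[-1]))) @ V.T
            sq = sqrts[key]
            self.z_train[sl] = sq @ tr.coords[sl]
            self.z_test[sl] = sq @ test_centered[sl]
        self.y_test = y_test

    def rows(self, blocks) -> np.ndarray:
        return np.concatenate([np.arange(self.struct.block_slice(j).start,
                                         self.struct.block_slice(j).stop)
                               for j in blocks])

    def ols_rmse(self, blocks) -> float:
        rows = self.rows(blocks)
        D = self.z_train[rows].T
        coef, *_ = np.linalg.lstsq(D, self.y, rcond=None)
        pred = self.y_mean + self.z_test[rows].T @ coef
        return float(np.sqrt(np.mean((pred - self.y_test) ** 2)))

    def ridge_rmse(self, k: int, fold_seed: int, n_lambda: int = 50) -> float:
        """Quadratic-penalty-only fit with lambda chosen by k-fold CV."""
        n = self.y.size
        rng = np.random.default_rng(fold_seed)
        idx = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        folds[idx] = np.arange(n) % k
        K_full = self.z_train.T @ self.z_train
        top = float(np.linalg.eigvalsh(K_full)[-1])
        grid = np.geomspace(top, 1e-6 * top, n_lambda)
        cv_mse = np.zeros(n_lambda)
        for f in range(k):
            tr_mask = folds != f
            Ztr = self.z_train[:, tr_mask]
            ytr = self.y[tr_mask]
            mu_x = Ztr.mean(axis=1)
            mu_y = ytr.mean()
            Ztr = Ztr - mu_x[:, None]
            ytr = ytr - mu_y
            Zval = self.z_train[:, ~tr_mask] - mu_x[:, None]
            yval = self.y[~tr_mask]
            w, Q = np.linalg.eigh(Ztr.T @ Ztr)
            qy = Q.T @ ytr
            for c, lam in enumerate(grid):
                coef_dual = Q @ (qy / (w + 2.0 * lam))
                pred = mu_y + Zval.T @ (Ztr @ coef_dual)
                cv_mse[c] += np.mean((pred - yval) ** 2)
        best = grid[int(np.argmin(cv_mse))]
        w, Q = np.linalg.eigh(K_full)
        coef_dual = Q @ ((Q.T @ self.y) / (w + 2.0 * best))
        pred = self.y_mean + self.z_test.T @ (self.z_train @ coef_dual)
        return float(np.sqrt(np.mean((pred - self.y_test) ** 2)))


def baseline_fits(train: FunctionalDataset, test_coords: np.ndarray,
                  y_test: np.ndarray, methods=("ols", "ridge", "oracle"),
                  k: int = 5, fold_seed: int = 0) -> dict:
    """OLS / ridge / oracle test RMSEs and their (fixed) active sets."""
    td = _TildeData(train, test_coords, y_test)
    p = td.struct.p
    out = {}
    if "ols" in methods:
        out["ols"] = {"rmse": td.ols_rmse(range(p)), "active_set": list(range(p))}
    if "ridge" in methods:
        out["ridge"] = {"rmse": td.ridge_rmse(k, fold_seed),
                        "active_set": list(range(p))}
    if "oracle" in methods:
        out["oracle"] = {"rmse": td.ols_rmse(ACTIVE_SET),
                         "active_set": list(ACTIVE_SET)}
    return out


# ---------------------------------------------------------------------------
# scenario runner
# ---------------------------------------------------------------------------

def _lambda_der_net(train: FunctionalDataset, ratios) -> list[float]:
    """Data-driven curvature-weight net: ratios of tr(loss Hessian)/tr(penalty)."""
    ratios = [float(r) for r in ratios]
    if all(r == 0 for r in ratios):
        return [0.0]
    tr = center_dataset(train)
    tr_h = tr_p = 0.0
    pen_trace = {}
    for j, sl in enumerate(tr.structure.slices()):
        basis = tr.bases[j]
        Zj = tr.coords[sl]
        # tr(Z~_j Z~_j^T) = tr(G_j X_j X_j^T) and tr(P_j) = tr(G_j^{-1} B_j'')
        tr_h += float(np.sum(basis.gram * (Zj @ Zj.T)))
        key = id(basis)
        if key not in pen_trace:
            pen_trace[key] = float(np.trace(np.linalg.solve(basis.gram, basis.d2gram)))
        tr_p += pen_trace[key]
    # per-sample scale: tr_h grows with n, the penalty trace does not
    scale = tr_h / (max(tr_p, 1e-300) * tr.n)
    return [r * scale for r in ratios]


def run_scenario(spec: ScenarioSpec, methods=ALL_METHODS,
                 gmd_config: GMDConfig | None = None) -> ScenarioResult:
    """Run the full Monte-Carlo loop for one (n, sigma) scenario."""
    methods = tuple(methods)
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    basis = build_basis("bspline", spec.m, (0.0, 1.0), order=4)
    bases = [basis] * spec.p
    inactive = [j for j in range(spec.p) if j not in ACTIVE_SET]
    gmd_config = gmd_config or GMDConfig(tol=3e-5, max_sweeps=300)

    rmse_lists = {m: [] for m in methods}
    active_lists = {m: [] for m in methods}
    rep_streams = np.random.SeedSequence(spec.seed).spawn(spec.reps)
    for rep, stream in enumerate(rep_streams):
        s_curves, s_noise, s_split, s_folds = stream.spawn(4)
        rng_curves = np.random.default_rng(s_curves)
        rng_noise = np.random.default_rng(s_noise)
        curves = generate_predictors(spec.n, spec.p, spec.n_fine, rng_curves)
        y = generate_response(curves, spec.sigma, rng_noise, spec.beta_arg)
        obs, times = downsample(curves, spec.n_obs)

        # project every curve onto the shared B-spline basis (shared grid)
        design = basis.evaluate(times)
        pinv = np.linalg.pinv(design)
        coords = np.empty((spec.p * spec.m, spec.n))
        for j in range(spec.p):
            coords[j * spec.m:(j + 1) * spec.m] = pinv @ obs[:, j, :].T

        perm = np.random.default_rng(s_split).permutation(spec.n)
        n_train = int(round(spec.train_fraction * spec.n))
        tr_idx, te_idx = perm[:n_train], perm[n_train:]
        train = FunctionalDataset(bases=bases, coords=coords[:, tr_idx],
                                  response=y[tr_idx])
        test_coords, y_test = coords[:, te_idx], y[te_idx]

        fold_seed = int(s_folds.generate_state(1)[0] % (2 ** 31))
        base_methods = [m for m in methods if m in ("ols", "ridge", "oracle")]
        if base_methods:
            base = baseline_fits(train, test_coords, y_test, base_methods,
                                 k=spec.k_folds, fold_seed=fold_seed)
            for m in base_methods:
                rmse_lists[m].append(base[m]["rmse"])
                active_lists[m].append(base[m]["active_set"])

        sparse_methods = [m for m in methods if m in ("mfg_lasso", "mfg_en")]
        if sparse_methods:
            lder_net = _lambda_der_net(train, spec.lambda_der_ratios)
            for m in sparse_methods:
                alpha_net = (0.0,) if m == "mfg_lasso" else spec.en_alpha_net
                cv = cross_validate(
                    train, solver="gmd", alpha_net=alpha_net,
                    lambda_der_net=lder_net, k=spec.k_folds, seed=fold_seed,
                    n_lambda=spec.n_lambda,
                    lambda_min_ratio=spec.lambda_min_ratio, config=gmd_config)
                fit_ = cv.best_fit
                pred = predict_coords(fit_, test_coords)
                rmse_lists[m].append(float(np.sqrt(np.mean((pred - y_test) ** 2))))
                active_lists[m].append(list(fit_.active_set))

    result = ScenarioResult(spec=spec)
    for m in methods:
        arr = np.asarray(rmse_lists[m])
        result.rmse[m] = (float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0)
        act_hits = sum(len(set(a) & set(ACTIVE_SET)) for a in active_lists[m])
        inact_hits = sum(len(set(inactive) - set(a)) for a in active_lists[m])
        result.selection[m] = (
            100.0 * act_hits / (len(ACTIVE_SET) * spec.reps),
            100.0 * inact_hits / (len(inactive) * spec.reps),
        )
        result.per_rep_rmse[m] = rmse_lists[m]
        result.per_rep_active_sets[m] = active_lists[m]
    return result
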