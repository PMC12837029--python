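"""Multivariate calibration engines.

Two model families share the ``predict`` interface:

* :class:`PLSModel` — NIPALS partial least squares (PLS2) with deflation,
  latent-variable count chosen by leave-one-out cross-validation.
* :class:`ANNModel` — a single-hidden-layer feed-forward network trained by
  Levenberg-Marquardt with a held-out validation split and early stopping.

Both models store their preprocessing state so they map raw spectra to
concentrations; fitted models serialize to JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLSModel",
    "ANNModel",
    "TrainingConfig",
    "fit_pls",
    "select_lv_loocv",
    "fit_ann",
    "predict",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# PLS (NIPALS, PLS2)

@dataclass
class PLSModel:
    n_lv: int
    x_mean: np.ndarray       # (p,)
    y_mean: np.ndarray       # (q,)
    weights: np.ndarray      # W, (p, a)
    x_loadings: np.ndarray   # P, (p, a)
    y_loadings: np.ndarray   # Q, (q, a)
    scores: np.ndarray       # T, (n, a) training X-scores
    coef: np.ndarray         # B, (p, q): (x - x_mean) @ B + y_mean
    rmsecv_curve: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
        if x_new.shape[1] != self.x_mean.size:
            raise ValueError(
                f"expected {self.x_mean.size} wavelengths, got {x_new.shape[1]}"
            )
        return (x_new - self.x_mean) @ self.coef + self.y_mean

    def transform(self, x_new: np.ndarray) -> np.ndarray:
        """Latent scores of new spectra (for leverage / applicability domain)."""
        x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
        xc = x_new - self.x_mean
        # R = W (P'W)^-1 maps X to scores directly
        r = self.weights @ np.linalg.inv(self.x_loadings.T @ self.weights)
        return xc @ r


def fit_pls(x: np.ndarray, y: np.ndarray, n_lv: int) -> PLSModel:
    """NIPALS PLS2 with per-component deflation.

    ``x`` and ``y`` are raw (uncentered) matrices; column means are removed
    internally and stored so prediction applies the same centering.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if x.shape[0] != y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n, p = x.shape
    q = y.shape[1]
    max_rank = min(n - 1, p)
    if not 1 <= n_lv <= max_rank:
        raise ValueError(f"n_lv must be in [1, {max_rank}]")

    x_mean = x.mean(axis=0)
    y_mean = y.mean(axis=0)
    xd = x - x_mean
    yd = y - y_mean

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((q, n_lv))
    T = np.zeros((n, n_lv))
    for a in range(n_lv):
        u = yd[:, int(np.argmax(yd.var(axis=0)))]
        if np.linalg.norm(u) < 1e-14:
            raise np.linalg.LinAlgError(
                f"rank deficiency: Y fully deflated before component {a + 1}"
            )
        t = None
        for _ in range(1000):
            w = xd.T @ u
            wn = np.linalg.norm(w)
            if wn < 1e-14:
                raise np.linalg.LinAlgError(
                    f"rank deficiency: X fully deflated before component {a + 1}"
                )
            w /= wn
            t = xd @ w
            tt = t @ t
            if tt < 1e-28:
                raise np.linalg.LinAlgError(
                    f"rank deficiency at component {a + 1}"
                )
            qv = yd.T @ t / tt
            u_new = yd @ qv / (qv @ qv) if qv @ qv > 0 else u
            if np.linalg.norm(u_new - u) <= 1e-12 * np.linalg.norm(u_new):
                u = u_new
                break
            u = u_new
        p_vec = xd.T @ t / (t @ t)
        xd = xd - np.outer(t, p_vec)
        yd = yd - np.outer(t, qv)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_vec, qv, t

    coef = W @ np.linalg.solve(P.T @ W, Q.T)
    return PLSModel(
        n_lv=n_lv, x_mean=x_mean, y_mean=y_mean,
        weights=W, x_loadings=P, y_loadings=Q, scores=T, coef=coef,
    )


def _coef_path(model: PLSModel) -> list[np.ndarray]:
    """Regression coefficients using the first k components, k = 1..n_lv."""
    out = []
    for k in range(1, model.n_lv + 1):
        W, P, Q = model.weights[:, :k], model.x_loadings[:, :k], model.y_loadings[:, :k]
        out.append(W @ np.linalg.solve(P.T @ W, Q.T))
    return out


def effective_rank(x: np.ndarray, rtol: float = 1e-9) -> int:
    """Numerical rank of the column-centered matrix."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    s = np.linalg.svd(x - x.mean(axis=0), compute_uv=False)
    if s.size == 0 or s[0] == 0:
        return 0
    return int(np.sum(s > rtol * s[0]))


def select_lv_loocv(
    x: np.ndarray,
    y: np.ndarray,
    max_lv: int,
    rule: str = "one_se",
    clip_rank: bool = True,
) -> tuple[int, np.ndarray]:
    """Leave-one-out RMSECV curve over 1..max_lv latent variables.

    ``rule='one_se'`` picks the smallest LV count whose RMSECV is within one
    standard error of the curve minimum; ``rule='min'`` picks the argmin.
    With ``clip_rank`` (default) max_lv is silently capped at the effective
    numerical rank of X, so noiseless low-rank data does not error.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = x.shape[0]
    max_rank = min(n - 2, x.shape[1])  # LOO leaves n-1 rows
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    if max_lv > max_rank:
        raise ValueError(f"max_lv {max_lv} exceeds the LOO rank bound {max_rank}")
    if clip_rank:
        max_lv = max(1, min(max_lv, effective_rank(x)))

    sq_err = np.zeros((n, max_lv))  # per-sample mean squared error across responses
    for i in range(n):
        keep = np.arange(n) != i
        try:
            m = fit_pls(x[keep], y[keep], max_lv)
        except np.linalg.LinAlgError:
            if not clip_rank:
                raise
            # Y deflated to zero early (e.g. exact low-rank response):
            # retry with progressively fewer components and pad the curve.
            k_ok = max_lv - 1
            while k_ok >= 1:
                try:
                    m = fit_pls(x[keep], y[keep], k_ok)
                    break
                except np.linalg.LinAlgError:
                    k_ok -= 1
            else:
                raise
        xc = x[i] - m.x_mean
        path = _coef_path(m)
        for k in range(max_lv):
            b = path[min(k, len(path) - 1)]
            pred = xc @ b + m.y_mean
            sq_err[i, k] = np.mean((pred - y[i]) ** 2)

    rmsecv = np.sqrt(sq_err.mean(axis=0))
    k_min = int(np.argmin(rmsecv))
    if rule == "min":
        best = k_min + 1
    elif rule == "one_se":
        # delta-method SE of the RMSECV at the curve minimum
        se_mse = sq_err[:, k_min].std(ddof=1) / np.sqrt(n)
        se_rmse = se_mse / (2 * rmsecv[k_min]) if rmsecv[k_min] > 0 else 0.0
        within = np.nonzero(rmsecv <= rmsecv[k_min] + se_rmse)[0]
        best = int(within[0]) + 1
    else:
        raise ValueError("rule must be 'one_se' or 'min'")
    return best, rmsecv


# ---------------------------------------------------------------------------
# ANN (single hidden layer, Levenberg-Marquardt)

@dataclass
class TrainingConfig:
    hidden: int = 6
    max_epochs: int = 400
    mu_init: float = 1e-3
    mu_raise: float = 10.0
    mu_lower: float = 10.0
    patience: int = 6
    val_fraction: float = 0.1
    seed: int | None = None
    hidden_transfer: str = "purelin"   # or "tansig"
    input_scores: int | None = None    # feed top-k PCA scores instead of raw spectra
    init_scale: float = 0.1
    goal_mse: float = 0.0              # stop once training MSE <= goal

    def __post_init__(self):
        if self.hidden < 1 or self.max_epochs < 1 or self.patience < 1:
            raise ValueError("hidden, max_epochs and patience must be positive")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.hidden_transfer not in ("purelin", "tansig"):
            raise ValueError("hidden_transfer must be 'purelin' or 'tansig'")


@dataclass
class ANNModel:
    w1: np.ndarray           # (h, d)
    b1: np.ndarray           # (h,)
    w2: np.ndarray           # (q, h)
    b2: np.ndarray           # (q,)
    hidden_transfer: str
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    pca_mean: np.ndarray | None = None        # raw-input mean when compressing
    pca_components: np.ndarray | None = None  # (p, k) projection
    training_record: dict = field(default_factory=dict)

    def _compress(self, x: np.ndarray) -> np.ndarray:
        if self.pca_components is None:
            return x
        return (x - self.pca_mean) @ self.pca_components

    def _forward_scaled(self, xs: np.ndarray) -> np.ndarray:
        a = xs @ self.w1.T + self.b1
        g = np.tanh(a) if self.hidden_transfer == "tansig" else a
        return g @ self.w2.T + self.b2

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
        xs = (self._compress(x_new) - self.x_mean) / self.x_scale
        return self._forward_scaled(xs) * self.y_scale + self.y_mean


def _pack(w1, b1, w2, b2):
    return np.concatenate([w1.ravel(), b1, w2.ravel(), b2])


def _unpack(theta, d, h, q):
    i = 0
    w1 = theta[i:i + h * d].reshape(h, d); i += h * d
    b1 = theta[i:i + h]; i += h
    w2 = theta[i:i + q * h].reshape(q, h); i += q * h
    b2 = theta[i:i + q]
    return w1, b1, w2, b2


def _forward_and_jacobian(theta, xs, transfer, d, h, q):
    """Residual Jacobian of the scaled network, shape (n*q, n_params)."""
    n = xs.shape[0]
    w1, b1, w2, b2 = _unpack(theta, d, h, q)
    a = xs @ w1.T + b1                       # (n, h)
    if transfer == "tansig":
        g = np.tanh(a)
        gp = 1.0 - g * g
    else:
        g = a
        gp = np.ones_like(a)
    yhat = g @ w2.T + b2                     # (n, q)

    n_par = theta.size
    jac = np.zeros((n, q, n_par))
    # d yhat_o / d w2[o, j] = g_j ; d / d b2_o = 1
    off_w2 = h * d + h
    for o in range(q):
        jac[:, o, off_w2 + o * h: off_w2 + (o + 1) * h] = g
        jac[:, o, off_w2 + q * h + o] = 1.0
    # d yhat_o / d w1[j, k] = w2[o, j] * gp_j * x_k ; d / d b1_j = w2[o, j] * gp_j
    for o in range(q):
        s = w2[o] * gp                       # (n, h)
        jac[:, o, : h * d] = (s[:, :, None] * xs[:, None, :]).reshape(n, h * d)
        jac[:, o, h * d: h * d + h] = s
    return yhat, jac.reshape(n * q, n_par)


def fit_ann(x: np.ndarray, y: np.ndarray, config: TrainingConfig | None = None) -> ANNModel:
    """Train a 1-hidden-layer network by Levenberg-Marquardt with early stopping.

    Inputs are centered and scaled to unit SD per feature (optionally after
    PCA compression); outputs likewise.  The damping factor µ is raised on
    rejected steps and lowered on accepted ones; training stops at the epoch
    limit, on validation-MSE patience, or when µ escalation fails.
    """
    if config is None:
        config = TrainingConfig()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = x.shape[0]
    if n < 2 * config.hidden:
        warnings.warn(
            f"only {n} samples for {config.hidden} hidden neurons; "
            "recommend n >= 2*hidden", stacklevel=2)
    rng = np.random.default_rng(config.seed)

    pca_mean = pca_comp = None
    xin = x
    if config.input_scores is not None:
        k = min(config.input_scores, n - 1, x.shape[1])
        pca_mean = x.mean(axis=0)
        _, _, vt = np.linalg.svd(x - pca_mean, full_matrices=False)
        pca_comp = vt[:k].T
        xin = (x - pca_mean) @ pca_comp

    x_mean = xin.mean(axis=0)
    x_scale = xin.std(axis=0)
    x_scale[x_scale < 1e-12] = 1.0
    y_mean = y.mean(axis=0)
    y_scale = y.std(axis=0)
    y_scale[y_scale < 1e-12] = 1.0
    xs = (xin - x_mean) / x_scale
    ys = (y - y_mean) / y_scale

    d, h, q = xs.shape[1], config.hidden, ys.shape[1]
    # held-out validation split for early stopping
    n_val = max(1, int(round(config.val_fraction * n)))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    xs_tr, ys_tr = xs[tr_idx], ys[tr_idx]
    xs_val, ys_val = xs[val_idx], ys[val_idx]

    theta = rng.uniform(-config.init_scale, config.init_scale, size=h * d + h + q * h + q)
    mu = config.mu_init
    best_val = np.inf
    best_theta = theta.copy()
    stall = 0
    record = {"train_mse": [], "val_mse": [], "mu": [], "stop_reason": "max_epochs",
              "stop_epoch": config.max_epochs, "config": vars(config).copy()}

    def _mse(th, xs_, ys_):
        w1, b1, w2, b2 = _unpack(th, d, h, q)
        a = xs_ @ w1.T + b1
        g = np.tanh(a) if config.hidden_transfer == "tansig" else a
        return float(np.mean((g @ w2.T + b2 - ys_) ** 2))

    eye = np.eye(theta.size)
    for epoch in range(config.max_epochs):
        yhat, jac = _forward_and_jacobian(theta, xs_tr, config.hidden_transfer, d, h, q)
        err = (yhat - ys_tr).ravel()
        sse = err @ err
        if not np.isfinite(sse):
            raise FloatingPointError("non-finite training loss")
        jtj = jac.T @ jac
        jte = jac.T @ err
        accepted = False
        for _ in range(40):
            try:
                delta = np.linalg.solve(jtj + mu * eye, jte)
            except np.linalg.LinAlgError:
                mu *= config.mu_raise
                continue
            cand = theta - delta
            sse_new = _mse(cand, xs_tr, ys_tr) * err.size
            if np.isfinite(sse_new) and sse_new < sse:
                theta = cand
                mu = max(mu / config.mu_lower, 1e-20)
                accepted = True
                break
            mu *= config.mu_raise
            if mu > 1e12:
                break
        if not accepted:
            record["stop_reason"] = "mu_escalation"
            record["stop_epoch"] = epoch
            break

        tr_mse = _mse(theta, xs_tr, ys_tr)
        val_mse = _mse(theta, xs_val, ys_val)
        record["train_mse"].append(tr_mse)
        record["val_mse"].append(val_mse)
        record["mu"].append(mu)
        if val_mse < best_val - 1e-15:
            best_val = val_mse
            best_theta = theta.copy()
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                record["stop_reason"] = "early_stopping"
                record["stop_epoch"] = epoch + 1
                break
        if tr_mse <= config.goal_mse:
            best_val = val_mse
            best_theta = theta.copy()
            record["stop_reason"] = "goal_reached"
            record["stop_epoch"] = epoch + 1
            break

    theta = best_theta if record["stop_reason"] == "early_stopping" else theta
    w1, b1, w2, b2 = _unpack(theta, d, h, q)
    return ANNModel(
        w1=w1, b1=b1, w2=w2, b2=b2, hidden_transfer=config.hidden_transfer,
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, y_scale=y_scale,
        pca_mean=pca_mean, pca_components=pca_comp, training_record=record,
    )


def predict(model: PLSModel | ANNModel, x_new: np.ndarray) -> np.ndarray:
    """Apply a fitted model's stored preprocessing and map; model is not mutated."""
    return model.predict(x_new)


# ---------------------------------------------------------------------------
# JSON persistence

def _tolist(v):
    return v.tolist() if isinstance(v, np.ndarray) else v


def save_model(model: PLSModel | ANNModel, path: str) -> None:
    if isinstance(model, PLSModel):
        payload = {"kind": "pls"}
        for k, v in vars(model).items():
            payload[k] = _tolist(v)
    elif isinstance(model, ANNModel):
        payload = {"kind": "ann"}
        for k, v in vars(model).items():
            payload[k] = _tolist(v)
    else:
        raise TypeError(f"cannot serialize {type(model)}")
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)


def load_model(path: str) -> PLSModel | ANNModel:
    with open(path) as fh:
        payload = json.load(fh)
    kind = payload.pop("kind")
    def arr(v):
        return None if v is None else np.asarray(v, dtype=float)
    if kind == "pls":
        return PLSModel(
            n_lv=payload["n_lv"], x_mean=arr(payload["x_mean"]),
            y_mean=arr(payload["y_mean"]), weights=arr(payload["weights"]),
            x_loadings=arr(payload["x_loadings"]), y_loadings=arr(payload["y_loadings"]),
            scores=arr(payload["scores"]), coef=arr(payload["coef"]),
            rmsecv_curve=arr(payload.get("rmsecv_curve")),
            metadata=payload.get("metadata", {}),
        )
    if kind == "ann":
        return ANNModel(
            w1=arr(payload["w1"]), b1=arr(payload["b1"]),
            w2=arr(payload["w2"]), b2=arr(payload["b2"]),
            hidden_transfer=payload["hidden_transfer"],
            x_mean=arr(payload["x_mean"]), x_scale=arr(payload["x_scale"]),
            y_mean=arr(payload["y_mean"]), y_scale=arr(payload["y_scale"]),
            pca_mean=arr(payload.get("pca_mean")),
            pca_components=arr(payload.get("pca_components")),
            training_record=payload.get("training_record", {}),
        )
    raise ValueError(f"unknown model kind {kind!r}")
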