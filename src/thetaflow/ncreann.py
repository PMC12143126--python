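"""Directed effective connectivity via a nonlinear MVAR neural network.

A single-hidden-layer tanh network is fitted as a one-step-ahead
predictor of K z-scored ROI time series from their last ``p`` lags (a
nonlinear multivariate autoregression). Its fitted function

``f(z) = W_out tanh(W_in z + b_h) + b_o``

is split exactly into a constant, a linear map, and a nonlinear residual
by a first-order Taylor expansion of the hidden activation around the
operating point ``z = 0`` (the z-scored data mean):

``f(z) = f(0) + A z + nl(z)``,  ``A[i,m] = sum_h W_out[i,h] sech^2(b_h) W_in[h,m]``.

Directed *linear* connectivity from channel j to channel i is the
time-averaged magnitude of j's first-order contribution ``A`` makes to
predicting i; directed *nonlinear* connectivity is the time-averaged
deviation of the network's instantaneous Jacobian from ``A`` on j's lag
coordinates. Absolute magnitudes are a property of this edge statistic;
only the comparative structure across edges and directions is
interpreted downstream.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .exceptions import ConfigurationError, NumericalError

__all__ = [
    "NMVARModel",
    "embed_lags",
    "embed_trials",
    "train_nmvar",
    "predict",
    "taylor_decompose",
    "linear_connectivity",
    "nonlinear_connectivity",
    "evaluate_model",
    "model_to_json",
    "model_from_json",
]


@dataclass
class NMVARModel:
    """Fitted nonlinear MVAR network with its z-scoring scaler and metrics."""

    order: int
    n_hidden: int
    W_in: np.ndarray              # hidden x (K * order)
    b_h: np.ndarray               # hidden
    W_out: np.ndarray             # K x hidden
    b_o: np.ndarray               # K
    scaler_mean: np.ndarray       # K
    scaler_sd: np.ndarray         # K
    metrics: dict = field(default_factory=dict)
    node_names: tuple = ()

    def __post_init__(self):
        for name in ("W_in", "b_h", "W_out", "b_o", "scaler_mean",
                     "scaler_sd"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if not np.all(np.isfinite(arr)):
                raise NumericalError(f"{name} contains non-finite values")
        if np.any(self.scaler_sd <= 0):
            raise ConfigurationError("scaler SDs must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.b_o)

    def zscore(self, series: np.ndarray) -> np.ndarray:
        series = np.asarray(series, dtype=float)
        return (series - self.scaler_mean[:, None]) / self.scaler_sd[:, None]


def embed_lags(series: np.ndarray, p: int):
    """Lag-embed a K x T series.

    Row ``r`` of the design matrix holds, channel-major,
    ``x_j(t-1), ..., x_j(t-p)`` for ``t = p + r``; the target row is
    ``x(t)``. Shapes: design ``(T-p, K*p)``, target ``(T-p, K)``.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ConfigurationError("series must be K x T")
    k, t_len = series.shape
    if p < 1 or t_len <= p:
        raise ConfigurationError(f"cannot embed T={t_len} samples at p={p}")
    n = t_len - p
    design = np.empty((n, k * p))
    for j in range(k):
        for lag in range(1, p + 1):
            design[:, j * p + (lag - 1)] = series[j, p - lag:t_len - lag]
    target = series[:, p:].T.copy()
    return design, target


def embed_trials(trials, p: int):
    """Embed a list of trials, never straddling trial boundaries."""
    designs, targets = zip(*(embed_lags(tr, p) for tr in trials))
    return np.concatenate(designs), np.concatenate(targets)


def _unpack(theta: np.ndarray, k: int, p: int, h: int):
    m = k * p
    i = 0
    W_in = theta[i:i + h * m].reshape(h, m); i += h * m
    b_h = theta[i:i + h]; i += h
    W_out = theta[i:i + k * h].reshape(k, h); i += k * h
    b_o = theta[i:i + k]
    return W_in, b_h, W_out, b_o


def _loss_grad(theta, Z, Y, k, p, h, l2):
    W_in, b_h, W_out, b_o = _unpack(theta, k, p, h)
    n = Z.shape[0]
    U = Z @ W_in.T + b_h
    Hid = np.tanh(U)
    E = Hid @ W_out.T + b_o - Y
    scale = 2.0 / (n * k)
    loss = np.mean(E ** 2) + l2 * np.dot(theta, theta)
    dW_out = scale * E.T @ Hid
    db_o = scale * E.sum(axis=0)
    dU = (E @ W_out) * (1.0 - Hid ** 2)
    dW_in = scale * dU.T @ Z
    db_h = scale * dU.sum(axis=0)
    grad = np.concatenate([dW_in.ravel(), db_h, dW_out.ravel(), db_o])
    grad += 2.0 * l2 * theta
    return loss, grad


def train_nmvar(series, p: int = 3, n_hidden: int = 10,
                max_iter: int = 600, train_frac: float = 0.8,
                seed: int = 0, l2: float = 3e-3,
                r2_floor: float = 0.2, node_names=()) -> NMVARModel:
    """Fit the nonlinear MVAR network.

    ``series`` is a K x T array or a list of K x T_i trials; trials are
    demeaned individually and embedding rows never straddle a trial
    boundary. Channels are z-scored with statistics of the *training*
    portion only; the train/test split is contiguous in time (the first
    ``train_frac`` of embedded rows train the model) to respect temporal
    dependence. Optimization is full-batch L-BFGS with an analytic
    gradient and a seeded Gaussian initialization, so identical data and
    seed reproduce identical weights.

    The fitted model carries train/test MSE and per-channel R² (z-scored
    scale). A test mean R² below ``r2_floor`` sets
    ``metrics["quality_ok"] = False`` — the model is flagged, not
    silently discarded.
    """
    if isinstance(series, np.ndarray):
        trials = [np.asarray(series, dtype=float)]
    else:
        trials = [np.asarray(tr, dtype=float) for tr in series]
        trials = [tr - tr.mean(axis=1, keepdims=True) for tr in trials]
    k = trials[0].shape[0]
    if any(tr.shape[0] != k for tr in trials):
        raise ConfigurationError("all trials must share the channel count")
    total_t = sum(tr.shape[1] for tr in trials)
    if total_t <= p + 10 * k * p:
        raise ConfigurationError(
            f"{total_t} samples too few for K={k}, p={p} "
            f"(need > {p + 10 * k * p})"
        )
    if not 0 < train_frac < 1:
        raise ConfigurationError("train_frac must lie in (0, 1)")

    concat = np.concatenate(trials, axis=1)
    n_train_raw = int(train_frac * concat.shape[1])
    mean = concat[:, :n_train_raw].mean(axis=1)
    sd = concat[:, :n_train_raw].std(axis=1, ddof=0)
    degenerate = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    if np.any(degenerate):
        ch = int(np.argmax(degenerate))
        raise ConfigurationError(
            f"channel {ch} has zero variance in the training split"
        )
    ztrials = [(tr - mean[:, None]) / sd[:, None] for tr in trials]
    Z, Y = embed_trials(ztrials, p)
    n_rows = Z.shape[0]
    n_train = int(train_frac * n_rows)
    Ztr, Ytr = Z[:n_train], Y[:n_train]
    Zte, Yte = Z[n_train:], Y[n_train:]

    rng = np.random.default_rng(seed)
    m = k * p
    theta0 = np.concatenate([
        rng.normal(0.0, 1.0 / np.sqrt(m), size=n_hidden * m),
        np.zeros(n_hidden),
        rng.normal(0.0, 1.0 / np.sqrt(n_hidden), size=k * n_hidden),
        np.zeros(k),
    ])
    res = minimize(_loss_grad, theta0, args=(Ztr, Ytr, k, p, n_hidden, l2),
                   jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": 1e-12,
                            "gtol": 1e-10})
    if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
        raise NumericalError(
            f"training diverged (loss={res.fun!r}); consider a smaller "
            "network or stronger regularization"
        )
    W_in, b_h, W_out, b_o = _unpack(res.x, k, p, n_hidden)
    model = NMVARModel(p, n_hidden, W_in, b_h, W_out, b_o, mean, sd,
                       node_names=tuple(node_names))

    def _split_metrics(Zs, Ys):
        if len(Zs) == 0:
            return {"mse": np.nan, "r2": np.full(k, np.nan)}
        pred = predict(model, Zs)
        err = pred - Ys
        mse = float(np.mean(err ** 2))
        sst = np.sum((Ys - Ys.mean(axis=0)) ** 2, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = 1.0 - np.sum(err ** 2, axis=0) / sst
        r2 = np.where(sst > 0, r2, np.nan)
        return {"mse": mse, "r2": r2}

    tr_m, te_m = _split_metrics(Ztr, Ytr), _split_metrics(Zte, Yte)
    model.metrics = {
        "train_mse": tr_m["mse"], "train_r2": tr_m["r2"],
        "test_mse": te_m["mse"], "test_r2": te_m["r2"],
        "n_train": int(n_train), "n_test": int(n_rows - n_train),
        "n_iter": int(res.nit), "seed": int(seed),
        "quality_ok": bool(np.nanmean(te_m["r2"]) >= r2_floor)
        if np.any(np.isfinite(te_m["r2"])) else False,
    }
    return model


def predict(model: NMVARModel, design: np.ndarray) -> np.ndarray:
    """Network output for embedded (z-scored) design rows."""
    U = design @ model.W_in.T + model.b_h
    return np.tanh(U) @ model.W_out.T + model.b_o


def _sech2(x: np.ndarray) -> np.ndarray:
    return 1.0 - np.tanh(x) ** 2


def taylor_decompose(model: NMVARModel) -> dict:
    """Exact split of the network into constant + linear + nonlinear parts.

    Returns ``{"A": (K, K*p) linear map, "f0": (K,) constant,
    "nonlinear": callable}`` with ``nonlinear(Z)`` the residual
    ``f(Z) - Z A^T - f0``; the identity ``f = f0 + A z + nl(z)`` holds at
    every point to machine precision because the residual is defined as
    exactly that difference.
    """
    s2 = _sech2(model.b_h)
    A = model.W_out @ (s2[:, None] * model.W_in)
    f0 = model.W_out @ np.tanh(model.b_h) + model.b_o

    def nonlinear(design: np.ndarray) -> np.ndarray:
        return predict(model, design) - design @ A.T - f0

    return {"A": A, "f0": f0, "nonlinear": nonlinear}


def _embedded_z(model: NMVARModel, series) -> np.ndarray:
    if isinstance(series, np.ndarray):
        trials = [np.asarray(series, dtype=float)]
    else:
        trials = [np.asarray(tr, dtype=float) for tr in series]
        trials = [tr - tr.mean(axis=1, keepdims=True) for tr in trials]
    z = [model.zscore(tr) for tr in trials]
    design, _ = embed_trials(z, model.order)
    return design


def linear_connectivity(model: NMVARModel, series) -> np.ndarray:
    """Directed linear connectivity L[i, j] (j -> i, diagonal NaN).

    ``L[i, j]`` is the time-averaged magnitude of channel j's first-order
    (Taylor-linear) contribution to the prediction of channel i:
    ``mean_t | sum_k A[i, (j,k)] z_j(t-k) |``.
    """
    A = taylor_decompose(model)["A"]
    Z = _embedded_z(model, series)
    k, p = model.n_channels, model.order
    L = np.empty((k, k))
    for j in range(k):
        cols = slice(j * p, (j + 1) * p)
        contrib = Z[:, cols] @ A[:, cols].T          # time x targets
        L[:, j] = np.mean(np.abs(contrib), axis=0)
    np.fill_diagonal(L, np.nan)
    return L


def nonlinear_connectivity(model: NMVARModel, series) -> np.ndarray:
    """Directed nonlinear connectivity NL[i, j] (j -> i, diagonal NaN).

    The network's instantaneous sensitivity of output i to input
    coordinate m at point z is the Jacobian
    ``J[i, m](z) = sum_h W_out[i,h] sech^2(u_h(z)) W_in[h,m]``; at the
    expansion point this equals the Taylor-linear map ``A``. ``NL[i, j]``
    averages ``|J - A|`` over observed time points and over channel j's
    lag coordinates — zero for an exactly linear fit, positive wherever
    the fitted response to j curves.
    """
    A = taylor_decompose(model)["A"]
    Z = _embedded_z(model, series)
    k, p, h = model.n_channels, model.order, model.n_hidden
    U = Z @ model.W_in.T + model.b_h
    S = _sech2(U) - _sech2(model.b_h)                # time x hidden
    # deviation tensor: time x targets x inputs, contracted over hidden
    D = np.einsum("ih,th,hm->tim", model.W_out, S, model.W_in,
                  optimize=True)
    NL = np.empty((k, k))
    for j in range(k):
        cols = slice(j * p, (j + 1) * p)
        NL[:, j] = np.mean(np.abs(D[:, :, cols]), axis=(0, 2))
    np.fill_diagonal(NL, np.nan)
    return NL


def evaluate_model(model: NMVARModel, series) -> dict:
    """Held-out MSE and R² per channel, on the z-scored scale.

    R² is ``1 - SSE/SST`` with SST about the held-out mean; a
    zero-variance channel has no defined R² and is reported as NaN.
    """
    if isinstance(series, np.ndarray):
        trials = [np.asarray(series, dtype=float)]
    else:
        trials = [np.asarray(tr, dtype=float) for tr in series]
        trials = [tr - tr.mean(axis=1, keepdims=True) for tr in trials]
    z = [model.zscore(tr) for tr in trials]
    Z, Y = embed_trials(z, model.order)
    pred = predict(model, Z)
    err = pred - Y
    mse = np.mean(err ** 2, axis=0)
    sst = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - np.sum(err ** 2, axis=0) / sst
    r2 = np.where(sst > 0, r2, np.nan)
    return {"mse": mse, "r2": r2, "mse_mean": float(mse.mean()),
            "r2_mean": float(np.nanmean(r2))}


def model_to_json(model: NMVARModel) -> str:
    payload = {
        "order": model.order, "n_hidden": model.n_hidden,
        "W_in": model.W_in.tolist(), "b_h": model.b_h.tolist(),
        "W_out": model.W_out.tolist(), "b_o": model.b_o.tolist(),
        "scaler_mean": model.scaler_mean.tolist(),
        "scaler_sd": model.scaler_sd.tolist(),
        "node_names": list(model.node_names),
        "metrics": {key: (val.tolist() if isinstance(val, np.ndarray)
                          else val)
                    for key, val in model.metrics.items()},
    }
    return json.dumps(payload)


def model_from_json(text: str) -> NMVARModel:
    d = json.loads(text)
    model = NMVARModel(
        d["order"], d["n_hidden"], np.asarray(d["W_in"]),
        np.asarray(d["b_h"]), np.asarray(d["W_out"]), np.asarray(d["b_o"]),
        np.asarray(d["scaler_mean"]), np.asarray(d["scaler_sd"]),
        node_names=tuple(d["node_names"]))
    model.metrics = {
        key: (np.asarray(val) if isinstance(val, list) else val)
        for key, val in d["metrics"].items()
    }
    return model
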