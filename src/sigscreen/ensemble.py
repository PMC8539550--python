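"""Acceptance-gated ensemble of single-hidden-layer networks.

The solubility model is an ensemble of small multilayer perceptrons
(6 descriptor inputs -> one hidden layer -> log10 x), grown by training
candidate networks of varied architecture and keeping only those that pass
three formal acceptance gates:

* accuracy     -- RMSD of back-computed log10 x over the full dataset
                  below 0.035 log units;
* precision    -- at most 3 records with |standardized residual| > 3;
* reliability  -- at least 99 percent of predictions inside the formal
                  [0, 1] range of the min-max-scaled output (equivalently,
                  inside the training min/max of log10 x).

Accepted members are kept sorted by rising RMSD; the ensemble prediction is
their unweighted mean, with the member spread reported as an uncertainty.
A convergence trace (cumulative means over the k most accurate members)
shows how quickly the averaged prediction stabilizes, and a
permutation-based sensitivity analysis ranks descriptor importance.

The trainer is a from-scratch re-implementation of the automated-network
protocol: inputs and output min-max scaled to [0, 1], a random 70:15:15
train/validation/test split, sum-of-squares error minimized by full-batch
Adam with early stopping on the validation split, hidden activations tanh
or logistic, output activations linear, exponential or logistic.  All
randomness flows from explicit integer seeds, so identical seeds give
identical weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import DESCRIPTOR_COLUMNS, SyntheticDataset
from .descriptors import DescriptorVector

__all__ = [
    "NetworkConfig",
    "GateThresholds",
    "TrainedNetwork",
    "Verdict",
    "Ensemble",
    "EnsembleError",
    "train_candidate",
    "accept_network",
    "build_ensemble",
    "predict",
    "convergence_trace",
    "sensitivity_analysis",
    "ensemble_to_json",
    "ensemble_from_json",
]

HIDDEN_ACTIVATIONS = ("tanh", "logistic")
OUTPUT_ACTIVATIONS = ("linear", "exponential", "logistic")

# architecture sampling weights follow the composition reported for the
# reference ensemble (~91/9 tanh:logistic hidden, ~62/33/5 output mix)
_HIDDEN_WEIGHTS = (0.91, 0.09)
_OUTPUT_WEIGHTS = (0.62, 0.33, 0.05)


class EnsembleError(RuntimeError):
    """Ensemble construction failed; carries the acceptance log."""

    def __init__(self, message: str, acceptance_log: list[dict] | None = None):
        super().__init__(message)
        self.acceptance_log = acceptance_log or []


@dataclass(frozen=True)
class NetworkConfig:
    """Hyper-parameters of one candidate network."""

    hidden_units: int = 8
    hidden_activation: str = "tanh"
    output_activation: str = "linear"
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    learning_rate: float = 0.02
    max_epochs: int = 3000
    patience: int = 200
    restarts: int = 5

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.hidden_activation not in HIDDEN_ACTIVATIONS:
            raise ValueError(f"hidden_activation must be one of {HIDDEN_ACTIVATIONS}")
        if self.output_activation not in OUTPUT_ACTIVATIONS:
            raise ValueError(f"output_activation must be one of {OUTPUT_ACTIVATIONS}")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")


@dataclass(frozen=True)
class GateThresholds:
    """Acceptance thresholds for ensemble membership."""

    rmsd: float = 0.035          # log10 units
    max_outliers: int = 3        # records with |standardized residual| > 3
    reliability: float = 0.99    # fraction of scaled predictions inside [0, 1]

    def __post_init__(self) -> None:
        if self.rmsd <= 0 or not 0 < self.reliability <= 1 or self.max_outliers < 0:
            raise ValueError("invalid gate thresholds")


@dataclass
class TrainedNetwork:
    """One fitted single-hidden-layer perceptron with its scalers."""

    config: NetworkConfig
    W1: np.ndarray          # (6, hidden)
    b1: np.ndarray          # (hidden,)
    w2: np.ndarray          # (hidden,)
    b2: float
    x_min: np.ndarray
    x_range: np.ndarray
    y_min: float
    y_range: float
    rmsd: float
    accepted: bool | None = None
    reasons: tuple[str, ...] = ()

    def _scale_x(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_min) / self.x_range

    def predict_scaled(self, X: np.ndarray) -> np.ndarray:
        """Raw network output in the [0, 1]-scaled target space."""
        Xs = self._scale_x(np.atleast_2d(np.asarray(X, dtype=float)))
        h = _act(Xs @ self.W1 + self.b1, self.config.hidden_activation)
        return _out(h @ self.w2 + self.b2, self.config.output_activation)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted log10 mole-fraction solubility."""
        return self.y_min + self.y_range * self.predict_scaled(X)


@dataclass(frozen=True)
class Verdict:
    """Per-gate acceptance decision for one candidate."""

    accepted: bool
    accuracy: bool
    precision: bool
    reliability: bool
    rmsd: float
    n_residual_outliers: int
    inside_range_fraction: float
    n_out_of_domain: int | None = None  # leverage-based count, logged only

    @property
    def reasons(self) -> tuple[str, ...]:
        out = []
        if not self.accuracy:
            out.append("accuracy")
        if not self.precision:
            out.append("precision")
        if not self.reliability:
            out.append("reliability")
        return tuple(out)


@dataclass
class Ensemble:
    """Accepted networks sorted by rising RMSD plus the full acceptance log."""

    networks: list[TrainedNetwork]
    acceptance_log: list[dict] = field(default_factory=list)
    target_size: int = 40

    def __post_init__(self) -> None:
        self.networks = sorted(self.networks, key=lambda n: n.rmsd)

    def __len__(self) -> int:
        return len(self.networks)


# -- network internals -------------------------------------------------------


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return np.tanh(z)
    return 1.0 / (1.0 + np.exp(-z))  # logistic


def _act_grad(a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return 1.0 - a * a
    return a * (1.0 - a)


def _out(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "linear":
        return z
    if kind == "exponential":
        return np.exp(np.clip(z, -50.0, 50.0))
    return 1.0 / (1.0 + np.exp(-z))


def _out_grad(y: np.ndarray, kind: str) -> np.ndarray:
    if kind == "linear":
        return np.ones_like(y)
    if kind == "exponential":
        return y
    return y * (1.0 - y)


def _as_xy(dataset) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Accept a SyntheticDataset, an (X, y) pair, or a DataFrame with 'log10_x'."""
    if isinstance(dataset, SyntheticDataset):
        return dataset.X.to_numpy(dtype=float), np.asarray(dataset.y, float), list(dataset.X.columns)
    if isinstance(dataset, tuple) and len(dataset) == 2:
        X, y = dataset
        cols = list(X.columns) if isinstance(X, pd.DataFrame) else list(DESCRIPTOR_COLUMNS)
        return np.asarray(X, dtype=float), np.asarray(y, dtype=float), cols
    raise TypeError("dataset must be a SyntheticDataset or an (X, y) pair")


def train_candidate(dataset, config: NetworkConfig) -> TrainedNetwork:
    """Fit one candidate network; deterministic given the config seed."""
    X, y, _ = _as_xy(dataset)
    n, p = X.shape
    if n < 30:
        raise ValueError("at least 30 records are required for training")

    x_min = X.min(axis=0)
    x_range = X.max(axis=0) - x_min
    degenerate = np.where(x_range == 0)[0]
    if degenerate.size:
        raise ValueError(f"degenerate descriptor column(s) with zero range: {degenerate.tolist()}")
    y_min = float(y.min())
    y_range = float(y.max() - y_min)
    if y_range == 0:
        raise ValueError("target column has zero range; cannot scale output")

    Xs = (X - x_min) / x_range
    ys = (y - y_min) / y_range

    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_train = int(round(config.split[0] * n))
    n_val = int(round(config.split[1] * n))
    idx_train = perm[:n_train]
    idx_val = perm[n_train : n_train + n_val]

    best = None
    best_val = np.inf
    for _ in range(max(1, config.restarts)):
        params = _fit_once(
            Xs[idx_train], ys[idx_train], Xs[idx_val], ys[idx_val], config, rng
        )
        if params[-1] < best_val:
            best_val = params[-1]
            best = params
    W1, b1, w2, b2, _ = best

    net = TrainedNetwork(
        config=config,
        W1=W1, b1=b1, w2=w2, b2=b2,
        x_min=x_min, x_range=x_range, y_min=y_min, y_range=y_range,
        rmsd=0.0,
    )
    pred = net.predict(X)
    net.rmsd = float(np.sqrt(np.mean((pred - y) ** 2)))
    return net


def _fit_once(Xtr, ytr, Xva, yva, config: NetworkConfig, rng: np.random.Generator):
    """One Adam run with early stopping; returns weights and best val SOS."""
    p = Xtr.shape[1]
    h = config.hidden_units
    W1 = rng.normal(0.0, np.sqrt(2.0 / (p + h)), size=(p, h))
    b1 = np.zeros(h)
    w2 = rng.normal(0.0, np.sqrt(2.0 / (h + 1)), size=h)
    ybar = float(np.clip(ytr.mean(), 1e-3, 1 - 1e-3))
    if config.output_activation == "linear":
        b2 = ybar
    elif config.output_activation == "exponential":
        b2 = float(np.log(ybar))
    else:
        b2 = float(np.log(ybar / (1 - ybar)))

    theta = [W1, b1, w2, np.array([b2])]
    m = [np.zeros_like(t) for t in theta]
    v = [np.zeros_like(t) for t in theta]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate

    def val_sos(th):
        a = _act(Xva @ th[0] + th[1], config.hidden_activation)
        yhat = _out(a @ th[2] + th[3][0], config.output_activation)
        return 0.5 * float(np.sum((yhat - yva) ** 2)) if len(yva) else 0.0

    best_theta = [t.copy() for t in theta]
    best_val = val_sos(theta)
    wait = 0
    t_step = 0
    for _ in range(config.max_epochs):
        a = _act(Xtr @ theta[0] + theta[1], config.hidden_activation)
        z2 = a @ theta[2] + theta[3][0]
        yhat = _out(z2, config.output_activation)
        err = (yhat - ytr) * _out_grad(yhat, config.output_activation)
        g_w2 = a.T @ err
        g_b2 = np.array([err.sum()])
        back = np.outer(err, theta[2]) * _act_grad(a, config.hidden_activation)
        g_W1 = Xtr.T @ back
        g_b1 = back.sum(axis=0)
        grads = [g_W1, g_b1, g_w2, g_b2]
        t_step += 1
        for i in range(4):
            m[i] = beta1 * m[i] + (1 - beta1) * grads[i]
            v[i] = beta2 * v[i] + (1 - beta2) * grads[i] ** 2
            mhat = m[i] / (1 - beta1**t_step)
            vhat = v[i] / (1 - beta2**t_step)
            theta[i] = theta[i] - lr * mhat / (np.sqrt(vhat) + eps)
        cur = val_sos(theta)
        if cur < best_val - 1e-12:
            best_val = cur
            best_theta = [t.copy() for t in theta]
            wait = 0
        else:
            wait += 1
            if wait >= config.patience:
                break
    W1, b1, w2, b2a = best_theta
    return W1, b1, w2, float(b2a[0]), best_val


# -- acceptance gating -------------------------------------------------------


def accept_network(
    net: TrainedNetwork,
    dataset,
    ad=None,
    gates: GateThresholds = GateThresholds(),
) -> Verdict:
    """Evaluate the three formal gates on the full dataset.

    When an applicability-domain model ``ad`` is supplied, the count of
    records with leverage above its critical value is logged on the verdict
    (it is informational; domain exclusion acts at screening time).
    """
    X, y, _ = _as_xy(dataset)
    pred = net.predict(X)
    resid = pred - y
    rmsd = float(np.sqrt(np.mean(resid**2)))

    sd = float(resid.std())
    std_resid = resid / sd if sd > 0 else np.zeros_like(resid)
    n_outliers = int(np.sum(np.abs(std_resid) > 3.0))

    scaled = net.predict_scaled(X)
    inside = float(np.mean((scaled >= -1e-9) & (scaled <= 1.0 + 1e-9)))

    n_ood = None
    if ad is not None:
        from .domain import leverages  # local import avoids a cycle

        n_ood = int(np.sum(leverages(ad, X) > ad.h_star))

    g1 = rmsd < gates.rmsd
    g2 = n_outliers <= gates.max_outliers
    g3 = inside >= gates.reliability
    return Verdict(
        accepted=g1 and g2 and g3,
        accuracy=g1,
        precision=g2,
        reliability=g3,
        rmsd=rmsd,
        n_residual_outliers=n_outliers,
        inside_range_fraction=inside,
        n_out_of_domain=n_ood,
    )


def build_ensemble(
    dataset,
    ad=None,
    target_size: int = 40,
    max_candidates: int = 400,
    seed: int = 0,
    gates: GateThresholds = GateThresholds(),
    hidden_range: tuple[int, int] = (3, 11),
) -> Ensemble:
    """Accumulate accepted networks until ``target_size`` or exhaustion.

    Candidate architectures are sampled per candidate: hidden-unit count
    uniform in ``hidden_range``, activations drawn with the weights of the
    reference ensemble composition.  Raises :class:`EnsembleError` (with
    the acceptance log attached) if fewer than 5 candidates are accepted
    after ``max_candidates`` attempts.
    """
    rng = np.random.default_rng(seed)
    members: list[TrainedNetwork] = []
    log: list[dict] = []
    for i in range(max_candidates):
        config = NetworkConfig(
            hidden_units=int(rng.integers(hidden_range[0], hidden_range[1] + 1)),
            hidden_activation=str(rng.choice(HIDDEN_ACTIVATIONS, p=_HIDDEN_WEIGHTS)),
            output_activation=str(rng.choice(OUTPUT_ACTIVATIONS, p=_OUTPUT_WEIGHTS)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        try:
            net = train_candidate(dataset, config)
        except ValueError as exc:
            raise EnsembleError(f"candidate {i} failed to train: {exc}", log) from exc
        verdict = accept_network(net, dataset, ad=ad, gates=gates)
        net.accepted = verdict.accepted
        net.reasons = verdict.reasons
        log.append(
            {
                "candidate": i,
                "hidden_units": config.hidden_units,
                "hidden_activation": config.hidden_activation,
                "output_activation": config.output_activation,
                "seed": config.seed,
                "rmsd": verdict.rmsd,
                "accepted": verdict.accepted,
                "reasons": list(verdict.reasons),
                "n_residual_outliers": verdict.n_residual_outliers,
                "inside_range_fraction": verdict.inside_range_fraction,
                "n_out_of_domain": verdict.n_out_of_domain,
            }
        )
        if verdict.accepted:
            members.append(net)
            if len(members) >= target_size:
                break
    if len(members) < min(5, target_size):
        raise EnsembleError(
            f"only {len(members)} networks accepted after {len(log)} candidates "
            f"(need at least {min(5, target_size)})",
            log,
        )
    return Ensemble(networks=members, acceptance_log=log, target_size=target_size)


# -- prediction and diagnostics ----------------------------------------------


def _as_feature_matrix(descriptors) -> np.ndarray:
    if isinstance(descriptors, DescriptorVector):
        return descriptors.as_array()[None, :]
    if isinstance(descriptors, pd.DataFrame):
        return descriptors.to_numpy(dtype=float)
    arr = np.asarray(descriptors, dtype=float)
    return np.atleast_2d(arr)


def predict(ensemble: Ensemble, descriptors) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Unweighted member mean and spread of predicted log10 x.

    ``descriptors`` may be a DescriptorVector, a length-6 vector, or a
    matrix/DataFrame of rows; scalars are returned for a single input.
    """
    if len(ensemble) == 0:
        raise EnsembleError("cannot predict with an empty ensemble")
    X = _as_feature_matrix(descriptors)
    preds = np.stack([net.predict(X) for net in ensemble.networks])  # (m, n)
    mean = preds.mean(axis=0)
    sd = preds.std(axis=0)
    if mean.size == 1:
        return float(mean[0]), float(sd[0])
    return mean, sd


def convergence_trace(ensemble: Ensemble, descriptors) -> np.ndarray:
    """Cumulative means over the k most accurate members, k = 1..size.

    Members enter in rising-RMSD order, so the trace starts at the most
    accurate single network and ends at the full-ensemble mean.
    """
    if len(ensemble) == 0:
        raise EnsembleError("cannot trace an empty ensemble")
    X = _as_feature_matrix(descriptors)
    preds = np.stack([net.predict(X) for net in ensemble.networks])
    trace = np.cumsum(preds, axis=0) / np.arange(1, len(ensemble) + 1)[:, None]
    return trace[:, 0] if X.shape[0] == 1 else trace


def sensitivity_analysis(
    ensemble: Ensemble, dataset, repeats: int = 10, seed: int = 0
) -> pd.Series:
    """Permutation importance of each descriptor.

    Importance of descriptor j is the mean (over ``repeats`` shuffles) of
    the ratio of the ensemble RMSD with column j permuted to the baseline
    ensemble RMSD.  Values near 1 mean the column is uninformative.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if len(ensemble) == 0:
        raise EnsembleError("cannot analyze an empty ensemble")
    X, y, cols = _as_xy(dataset)
    rng = np.random.default_rng(seed)
    base_pred, _ = predict(ensemble, X)
    base_rmsd = float(np.sqrt(np.mean((base_pred - y) ** 2)))
    ratios = {}
    for j, col in enumerate(cols):
        acc = 0.0
        for _ in range(repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            pred, _ = predict(ensemble, Xp)
            acc += float(np.sqrt(np.mean((pred - y) ** 2)))
        ratios[col] = (acc / repeats) / base_rmsd if base_rmsd > 0 else np.inf
    return pd.Series(ratios, name="importance")


# -- serialization ------------------------------------------------------------


def ensemble_to_json(ensemble: Ensemble) -> str:
    """Serialize weights, scalers, configs and the acceptance log."""
    payload = {
        "target_size": ensemble.target_size,
        "acceptance_log": ensemble.acceptance_log,
        "networks": [
            {
                "config": asdict(net.config),
                "W1": net.W1.tolist(),
                "b1": net.b1.tolist(),
                "w2": net.w2.tolist(),
                "b2": net.b2,
                "x_min": net.x_min.tolist(),
                "x_range": net.x_range.tolist(),
                "y_min": net.y_min,
                "y_range": net.y_range,
                "rmsd": net.rmsd,
                "accepted": net.accepted,
                "reasons": list(net.reasons),
            }
            for net in ensemble.networks
        ],
    }
    return json.dumps(payload, sort_keys=True, indent=1)


def ensemble_from_json(text: str) -> Ensemble:
    payload = json.loads(text)
    nets = []
    for d in payload["networks"]:
        cfg = d["config"]
        cfg["split"] = tuple(cfg["split"])
        nets.append(
            TrainedNetwork(
                config=NetworkConfig(**cfg),
                W1=np.asarray(d["W1"], float),
                b1=np.asarray(d["b1"], float),
                w2=np.asarray(d["w2"], float),
                b2=float(d["b2"]),
                x_min=np.asarray(d["x_min"], float),
                x_range=np.asarray(d["x_range"], float),
                y_min=float(d["y_min"]),
                y_range=float(d["y_range"]),
                rmsd=float(d["rmsd"]),
                accepted=d.get("accepted"),
                reasons=tuple(d.get("reasons", ())),
            )
        )
    return Ensemble(
        networks=nets,
        acceptance_log=payload.get("acceptance_log", []),
        target_size=payload.get("target_size", 40),
    )
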