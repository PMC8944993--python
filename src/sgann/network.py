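"""Shallow feed-forward network and its Levenberg-Marquardt trainer.

The model is a single-hidden-layer perceptron with 14 inputs, ``h`` hidden
units and one output:

    y = logsig( Wo . tansig(Wi x + b1) + b2 )

with tansig(z) = 2/(1+exp(-2z)) - 1 (hyperbolic-tangent sigmoid, range
(-1, 1)) and logsig(z) = 1/(1+exp(-z)) (logistic sigmoid, range (0, 1)).
Inputs are expected on the [0.1, 0.9] scale produced by
:mod:`sgann.preprocessing`; the output lives in (0, 1) where 0.5 encodes an
SGA outcome and 1.0 an AGA outcome.

Training minimises the RMSE between network output and the codified target
by damped Gauss-Newton (Levenberg-Marquardt): each epoch builds the analytic
Jacobian of the residuals with respect to all 14h + 2h + 1 parameters,
solves the damped normal equations, and adapts the damping factor mu --
decrease on an accepted (error-reducing) step, increase and retry otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.special

N_INPUTS = 14

TANSIG = "tansig"
PURELIN = "purelin"


def tansig(z: np.ndarray) -> np.ndarray:
    """Hyperbolic-tangent sigmoid, range (-1, 1)."""
    return np.tanh(z)


def logsig(z: np.ndarray) -> np.ndarray:
    """Logistic sigmoid, range (0, 1)."""
    return scipy.special.expit(z)


@dataclass
class NetworkParams:
    """Weights and biases of the 14-h-1 network.

    Attributes
    ----------
    Wi : (h, n_inputs) input-to-hidden weights
    b1 : (h,) hidden biases
    Wo : (h,) hidden-to-output weights
    b2 : float, output bias
    hidden_activation : "tansig" (default) or "purelin"
    """

    Wi: np.ndarray
    b1: np.ndarray
    Wo: np.ndarray
    b2: float
    hidden_activation: str = TANSIG

    def __post_init__(self) -> None:
        self.Wi = np.atleast_2d(np.asarray(self.Wi, dtype=float))
        self.b1 = np.asarray(self.b1, dtype=float).ravel()
        self.Wo = np.asarray(self.Wo, dtype=float).ravel()
        self.b2 = float(self.b2)
        h, _ = self.Wi.shape
        if h < 1:
            raise ValueError("hidden layer must have at least one unit")
        if self.b1.shape != (h,) or self.Wo.shape != (h,):
            raise ValueError("inconsistent parameter shapes")
        if self.hidden_activation not in (TANSIG, PURELIN):
            raise ValueError(f"unknown hidden activation {self.hidden_activation!r}")
        for arr in (self.Wi, self.b1, self.Wo):
            if not np.all(np.isfinite(arr)):
                raise ValueError("network parameters must be finite")
        if not math.isfinite(self.b2):
            raise ValueError("network parameters must be finite")

    @property
    def h(self) -> int:
        return self.Wi.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.Wi.shape[1]

    @property
    def n_params(self) -> int:
        return self.h * self.n_inputs + 2 * self.h + 1

    # -- flat-vector view used by the optimizer ---------------------------
    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.Wi.ravel(), self.b1, self.Wo, [self.b2]])

    @classmethod
    def from_vector(cls, theta: np.ndarray, h: int, n_inputs: int = N_INPUTS,
                    hidden_activation: str = TANSIG) -> "NetworkParams":
        theta = np.asarray(theta, dtype=float)
        k = h * n_inputs
        return cls(
            Wi=theta[:k].reshape(h, n_inputs),
            b1=theta[k:k + h],
            Wo=theta[k + h:k + 2 * h],
            b2=theta[k + 2 * h],
            hidden_activation=hidden_activation,
        )

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.Wi.copy(), self.b1.copy(), self.Wo.copy(),
                             self.b2, self.hidden_activation)


def _as_batch(x: np.ndarray, n_inputs: int) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != n_inputs:
        raise ValueError(f"expected {n_inputs} input features, got {X.shape[1]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("inputs must be finite")
    return X, single


def forward(x: np.ndarray, params: NetworkParams) -> np.ndarray | float:
    """Network output(s) in (0, 1) for input vector(s) ``x``.

    Accepts a single feature vector or an (n, 14) batch; vectorized.
    """
    X, single = _as_batch(x, params.n_inputs)
    z1 = X @ params.Wi.T + params.b1
    a1 = tansig(z1) if params.hidden_activation == TANSIG else z1
    z2 = a1 @ params.Wo + params.b2
    y = logsig(z2)
    return float(y[0]) if single else y


def hidden_activations(x: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Hidden-layer activations (n, h); exposed for diagnostics."""
    X, _ = _as_batch(x, params.n_inputs)
    z1 = X @ params.Wi.T + params.b1
    return tansig(z1) if params.hidden_activation == TANSIG else z1


def rmse(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Root-mean-square error between two equal-length vectors."""
    predicted = np.asarray(predicted, dtype=float).ravel()
    actual = np.asarray(actual, dtype=float).ravel()
    if predicted.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have equal length")
    return float(np.sqrt(np.mean((predicted - actual) ** 2)))


def jacobian(params: NetworkParams, X: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the residuals r = y(x) - t w.r.t. all parameters.

    Returns an (n, 14h + 2h + 1) matrix; column order matches
    :meth:`NetworkParams.to_vector` (Wi rows, b1, Wo, b2).  The residual does
    not depend on t through the parameters, so dr/dtheta = dy/dtheta.
    """
    X, _ = _as_batch(X, params.n_inputs)
    n = X.shape[0]
    h = params.h
    z1 = X @ params.Wi.T + params.b1                      # (n, h)
    if params.hidden_activation == TANSIG:
        a1 = tansig(z1)
        da1 = 1.0 - a1 ** 2                               # tansig'
    else:
        a1 = z1
        da1 = np.ones_like(z1)
    y = logsig(a1 @ params.Wo + params.b2)                # (n,)
    dy = y * (1.0 - y)                                    # logsig'

    # output-layer derivatives
    d_b2 = dy                                             # (n,)
    d_Wo = dy[:, None] * a1                               # (n, h)
    # hidden-layer derivatives
    delta = dy[:, None] * params.Wo * da1                 # (n, h)
    d_Wi = delta[:, :, None] * X[:, None, :]              # (n, h, 14)
    d_b1 = delta                                          # (n, h)

    J = np.empty((n, params.n_params))
    k = h * params.n_inputs
    J[:, :k] = d_Wi.reshape(n, k)
    J[:, k:k + h] = d_b1
    J[:, k + h:k + 2 * h] = d_Wo
    J[:, k + 2 * h] = d_b2
    return J


@dataclass
class TrainingConfig:
    """Levenberg-Marquardt hyper-parameters.

    ``mu_init`` is the initial damping factor (the trainer's "learning
    rate"); mu is multiplied by ``mu_dec`` after an accepted step and by
    ``mu_inc`` after a rejected one.  Training stops when the RMSE goal is
    reached, the epoch cap is hit, or mu exceeds ``max_mu`` (no improving
    step can be found).  Optional early stopping monitors validation RMSE.
    """

    max_epochs: int = 1000
    mu_init: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 0.1
    goal: float = 1e-12
    seed: int = 0
    max_mu: float = 1e10
    init_scheme: str = "uniform"      # "uniform" on [-0.5, 0.5] or "nguyen-widrow"
    early_stopping: bool = False
    patience: int = 20

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.mu_init <= 0:
            raise ValueError("mu_init must be > 0")
        if self.mu_inc <= 1:
            raise ValueError("mu_inc must be > 1")
        if not 0 < self.mu_dec < 1:
            raise ValueError("mu_dec must be in (0, 1)")
        if self.goal < 0:
            raise ValueError("goal must be >= 0")


@dataclass
class TrainingHistory:
    """Per-epoch training trace: RMSE on train (and validation, if given)
    after each accepted step, plus the reason training stopped."""

    train_rmse: list = field(default_factory=list)
    val_rmse: list = field(default_factory=list)
    stop_reason: str = ""
    n_epochs: int = 0


def init_params(h: int, seed: int, n_inputs: int = N_INPUTS,
                scheme: str = "uniform",
                hidden_activation: str = TANSIG) -> NetworkParams:
    """Seeded weight initialization.

    "uniform" draws every weight and bias from U[-0.5, 0.5].
    "nguyen-widrow" additionally rescales input-to-hidden rows so the hidden
    units partition the input range, which can speed convergence.
    """
    rng = np.random.default_rng(seed)
    Wi = rng.uniform(-0.5, 0.5, size=(h, n_inputs))
    b1 = rng.uniform(-0.5, 0.5, size=h)
    Wo = rng.uniform(-0.5, 0.5, size=h)
    b2 = rng.uniform(-0.5, 0.5)
    if scheme == "nguyen-widrow":
        beta = 0.7 * h ** (1.0 / n_inputs)
        norms = np.linalg.norm(Wi, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        Wi = beta * Wi / norms
        b1 = rng.uniform(-beta, beta, size=h)
    elif scheme != "uniform":
        raise ValueError(f"unknown init scheme {scheme!r}")
    return NetworkParams(Wi, b1, Wo, b2, hidden_activation)


def _lm_step(J: np.ndarray, r: np.ndarray, mu: float) -> np.ndarray:
    """Solve (J'J + mu I) delta = -J'r through a damped least-squares
    formulation: lstsq on the stacked system [J; sqrt(mu) I] delta = [-r; 0].
    Numerically stable near convergence where J'J is ill-conditioned.
    """
    p = J.shape[1]
    A = np.vstack([J, math.sqrt(mu) * np.eye(p)])
    b = np.concatenate([-r, np.zeros(p)])
    delta, *_ = scipy.linalg.lstsq(A, b, lapack_driver="gelsd")
    return delta


def train_lm(X_train: np.ndarray, t_train: np.ndarray, h: int,
             config: TrainingConfig | None = None,
             X_val: np.ndarray | None = None,
             t_val: np.ndarray | None = None,
             init: NetworkParams | None = None,
             hidden_activation: str = TANSIG,
             ) -> tuple[NetworkParams, TrainingHistory]:
    """Train a 14-h-1 network by Levenberg-Marquardt.

    Parameters
    ----------
    X_train : (n, 14) normalized inputs; t_train : (n,) codified targets.
    h : hidden-layer size.
    config : :class:`TrainingConfig`; defaults are the published
        super-parameters (1000 epochs, initial damping 1e-3, RMSE goal 1e-12).
    X_val, t_val : optional held-out partition monitored per epoch.
    init : optional explicit starting point (overrides seeded init).

    Returns the trained parameters and a :class:`TrainingHistory`.  The
    training RMSE sequence is non-increasing across accepted steps by
    construction; a rejected step never mutates the parameters.
    """
    if h < 1:
        raise ValueError("hidden layer size must be >= 1")
    config = config or TrainingConfig()
    X_train = np.asarray(X_train, dtype=float)
    t_train = np.asarray(t_train, dtype=float).ravel()
    if X_train.size == 0:
        raise ValueError("training set must be nonempty")

    params = (init.copy() if init is not None else
              init_params(h, config.seed, X_train.shape[1], config.init_scheme,
                          hidden_activation))
    theta = params.to_vector()
    mu = config.mu_init
    history = TrainingHistory()

    def _make(vec: np.ndarray) -> NetworkParams:
        return NetworkParams.from_vector(vec, h, X_train.shape[1], hidden_activation)

    def _rmse_of(vec: np.ndarray) -> float:
        return rmse(forward(X_train, _make(vec)), t_train)

    err = _rmse_of(theta)
    best_val = math.inf
    best_theta = theta.copy()
    stale = 0
    stop = "max_epochs"

    for epoch in range(config.max_epochs):
        if err <= config.goal:
            stop = "goal"
            break
        p = _make(theta)
        r = forward(X_train, p) - t_train
        J = jacobian(p, X_train)
        # inner damping loop: retry with larger mu until the step helps
        accepted = False
        while mu <= config.max_mu:
            delta = _lm_step(J, r, mu)
            cand = theta + delta
            cand_err = _rmse_of(cand)
            if cand_err < err:
                theta, err = cand, cand_err
                mu = max(mu * config.mu_dec, 1e-20)
                accepted = True
                break
            mu *= config.mu_inc
        if not accepted:
            stop = "mu_overflow"
            break
        history.train_rmse.append(err)
        history.n_epochs = epoch + 1
        if X_val is not None and len(np.atleast_1d(t_val)) > 0:
            v = rmse(forward(X_val, _make(theta)), np.asarray(t_val))
            history.val_rmse.append(v)
            if v < best_val - 1e-12:
                best_val, best_theta, stale = v, theta.copy(), 0
            else:
                stale += 1
                if config.early_stopping and stale >= config.patience:
                    stop = "validation"
                    break
    else:
        stop = "max_epochs" if err > config.goal else "goal"

    if config.early_stopping and X_val is not None and best_val < math.inf:
        theta = best_theta
    history.stop_reason = stop
    return _make(theta), history


def train_with_restarts(X_train, t_train, h, restarts, seeds,
                        config: TrainingConfig | None = None,
                        X_val=None, t_val=None,
                        hidden_activation: str = TANSIG):
    """Run ``restarts`` seeded initializations and keep the best model.

    ``seeds`` is a sequence of at least ``restarts`` integers.  Selection is
    by validation RMSE when a validation set is given, else by training
    RMSE; ties break toward the lower seed index.  Returns
    (params, history, selection_rmse).
    """
    base = config or TrainingConfig()
    best = None
    for i in range(restarts):
        cfg = TrainingConfig(**{**vars(base), "seed": int(seeds[i])})
        params, hist = train_lm(X_train, t_train, h, cfg, X_val, t_val,
                                hidden_activation=hidden_activation)
        if X_val is not None and len(np.atleast_1d(t_val)) > 0:
            score = rmse(forward(X_val, params), np.asarray(t_val))
        else:
            score = hist.train_rmse[-1] if hist.train_rmse else math.inf
        if best is None or score < best[2]:
            best = (params, hist, score)
    return best


def architecture_search(X_train, t_train, X_val, t_val,
                        max_hidden: int, restarts: int,
                        config: TrainingConfig | None = None,
                        seed: int = 0):
    """Grow the hidden layer from one unit up to ``max_hidden``, training
    ``restarts`` seeded initializations per size, and return the model with
    the best validation RMSE.

    Ties break toward the smaller hidden-layer size, then the lower restart
    seed.  Returns (params, history, val_rmse, h_selected).
    """
    if max_hidden < 1:
        raise ValueError("max_hidden must be >= 1")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(max_hidden * restarts)]
    best = None
    for idx, h in enumerate(range(1, max_hidden + 1)):
        chunk = seeds[idx * restarts:(idx + 1) * restarts]
        params, hist, score = train_with_restarts(
            X_train, t_train, h, restarts, chunk, config, X_val, t_val)
        if best is None or score < best[2] - 1e-15:
            best = (params, hist, score, h)
    return best
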