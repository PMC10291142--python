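"""Sample-wise metabolic flux estimation from bulk transcriptomics.

Each reaction module m gets its own small fully connected network
``flux_m(sample) = f_m(expression of the module's genes)`` — a learned
stand-in for the module's lumped Michaelis–Menten kinetics.  All module
networks are trained *jointly* by gradient descent on one loss over the
whole cohort:

    L =   sum_j sum_{k in intermediates} (influx_kj - outflux_kj)^2     (flux imbalance)
        + sum_j sum_m (flux_mj - |flux_mj|)^2                           (negative flux)
        + lambda * sum_j (sum_m flux_mj - TA_j)^2                       (scale anchor)

where TA_j — a per-sample surrogate for total metabolic activity — pins
the overall flux scale and excludes the trivial all-zero solution.  There
is no direct expression->flux supervision: the balance constraint across
many samples is what identifies the predictors.

The networks, backpropagation and the Adam optimizer are implemented here
directly on numpy arrays; the models are small (two tanh hidden layers,
default 8 and 4 units, scalar linear output) and train full-batch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import ExpressionMatrix, as_expression
from .errors import DimensionError, InputError, ParameterError, TrainingError
from .network import FactorGraph, incidence_matrix

logger = logging.getLogger(__name__)


class LossTerms(NamedTuple):
    total: float
    balance: float
    nonneg: float
    scale: float


@dataclass
class TrainingConfig:
    """Bag of training hyperparameters mirroring :class:`FluxEstimator` arguments."""

    lambda_scale: float = 1.0
    hidden_sizes: tuple[int, ...] = (8, 4)
    epochs: int = 100
    learning_rate: float = 0.008
    seed: int = 42
    ta_mode: str = "metabolic_total"
    convergence_tol: float = 1e-4
    patience: int = 10

    def __post_init__(self):
        if self.lambda_scale < 0:
            raise ParameterError("lambda_scale must be non-negative")
        if self.epochs < 0:
            raise ParameterError("epochs must be non-negative")
        if self.learning_rate <= 0 or self.convergence_tol <= 0 or self.patience <= 0:
            raise ParameterError("learning_rate, convergence_tol and patience must be positive")
        if any(h <= 0 for h in self.hidden_sizes):
            raise ParameterError("hidden_sizes must be positive")


def total_activity(expression, graph: FactorGraph, mode: str = "metabolic_total") -> pd.Series:
    """Per-sample total-activity surrogate TA_j.

    ``metabolic_total``: sum of expression over the union of the graph's
    genes (genes absent from the data contribute 0).  ``constant:c``: the
    constant c for every sample.
    """
    expr = as_expression(expression)
    if mode == "metabolic_total":
        genes = [g for g in graph.genes() if g in expr.values.index]
        ta = expr.values.loc[genes].sum(axis=0) if genes else pd.Series(
            0.0, index=expr.values.columns
        )
        ta = ta.astype(float)
        if (ta == 0).all():
            warnings.warn("total activity is zero for all samples", stacklevel=2)
        return ta.rename("TA")
    if mode.startswith("constant:"):
        try:
            c = float(mode.split(":", 1)[1])
        except ValueError as exc:
            raise ParameterError(f"cannot parse constant ta_mode {mode!r}") from exc
        if c < 0:
            raise ParameterError("constant TA must be non-negative")
        return pd.Series(c, index=expr.values.columns, name="TA")
    raise ParameterError(f"unknown ta_mode {mode!r}")


def compute_loss(flux, graph: FactorGraph, ta, lambda_scale: float = 1.0) -> LossTerms:
    """Evaluate the three loss terms on a sample x module flux matrix.

    Pure function of its inputs: returns (total, balance, nonneg, scale)
    as raw sums over samples, exactly as optimized during training.
    """
    flux = pd.DataFrame(flux)
    if list(flux.columns) != graph.module_ids:
        try:
            flux = flux[graph.module_ids]
        except KeyError as exc:
            raise DimensionError(f"flux columns do not match graph modules: {exc}") from exc
    F = flux.to_numpy(dtype=float)
    n = F.shape[0]
    ta_arr = np.asarray(ta, dtype=float).reshape(-1)
    if ta_arr.size == 1:
        ta_arr = np.full(n, ta_arr[0])
    elif ta_arr.size != n:
        raise DimensionError(f"TA has length {ta_arr.size}, flux has {n} samples")

    S = incidence_matrix(graph).to_numpy()
    residual = F @ S.T                       # sample x intermediate, influx - outflux
    balance = float(np.sum(residual**2))
    nonneg = float(np.sum((F - np.abs(F)) ** 2))
    scale = float(lambda_scale * np.sum((F.sum(axis=1) - ta_arr) ** 2))
    return LossTerms(balance + nonneg + scale, balance, nonneg, scale)


# ---------------------------------------------------------------------------
# numpy MLP machinery


def _init_module_params(rng: np.random.Generator, n_in: int, hidden: tuple[int, ...],
                        out_bias: float) -> dict[str, np.ndarray]:
    sizes = [n_in, *hidden, 1]
    params: dict[str, np.ndarray] = {}
    for layer, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
        params[f"W{layer}"] = rng.normal(0.0, 1.0 / np.sqrt(max(a, 1)), size=(a, b))
        params[f"b{layer}"] = np.zeros(b)
    params[f"b{len(sizes) - 2}"] = params[f"b{len(sizes) - 2}"] + out_bias
    return params


def _forward(params: dict[str, np.ndarray], X: np.ndarray, n_layers: int):
    acts = [X]
    h = X
    for layer in range(n_layers):
        z = h @ params[f"W{layer}"] + params[f"b{layer}"]
        h = z if layer == n_layers - 1 else np.tanh(z)
        acts.append(h)
    return h[:, 0], acts


def _backward(params: dict[str, np.ndarray], acts: list[np.ndarray], dout: np.ndarray,
              n_layers: int) -> dict[str, np.ndarray]:
    grads: dict[str, np.ndarray] = {}
    delta = dout[:, None]
    for layer in range(n_layers - 1, -1, -1):
        h_prev = acts[layer]
        grads[f"W{layer}"] = h_prev.T @ delta
        grads[f"b{layer}"] = delta.sum(axis=0)
        if layer > 0:
            delta = (delta @ params[f"W{layer}"].T) * (1.0 - acts[layer] ** 2)
    return grads


class _Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params_list, grads_list):
        self.t += 1
        for i, (params, grads) in enumerate(zip(params_list, grads_list)):
            for key, g in grads.items():
                mk = (i, key)
                m = self.m.get(mk, 0.0) * self.b1 + (1 - self.b1) * g
                v = self.v.get(mk, 0.0) * self.b2 + (1 - self.b2) * g**2
                self.m[mk], self.v[mk] = m, v
                m_hat = m / (1 - self.b1**self.t)
                v_hat = v / (1 - self.b2**self.t)
                params[key] = params[key] - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------


class FluxEstimator(BaseEstimator):
    """Joint neural flux predictor for a metabolic factor graph.

    scikit-learn-style estimator: construct with hyperparameters, ``fit``
    on an expression matrix (:class:`ExpressionMatrix` or a genes-as-rows
    DataFrame on the log(FPKM+1) scale), then ``predict`` sample-wise
    fluxes for new samples with the trained module networks.

    Parameters
    ----------
    graph : FactorGraph
        The metabolic network whose module fluxes are estimated.
    hidden_sizes : tuple of int
        Hidden-layer widths of each module's network (tanh activations,
        scalar linear output).
    lambda_scale : float
        Weight of the total-activity anchor term.
    ta_mode : str
        ``"metabolic_total"`` or ``"constant:<c>"``.
    epochs, learning_rate, convergence_tol, patience
        Full-batch Adam budget and early-stopping rule (stop when the
        relative change of the total loss stays below ``convergence_tol``
        for ``patience`` consecutive epochs).
    random_state : int
        Seeds weight initialization; runs are deterministic given it.
    clamp_nonnegative : bool
        If True, clip predicted fluxes at zero when reporting (training
        itself only discourages negativity through the loss).

    Attributes
    ----------
    flux_ : DataFrame, sample x module fluxes on the training cohort.
    loss_trace_ : DataFrame, per-epoch (total, balance, nonneg, scale).
    n_epochs_ : int, epochs actually run.
    converged_ : bool, whether early stopping triggered.
    negative_fraction_ : float, fraction of training flux entries < -1e-6.
    pinned_modules_ : list of modules with no observed genes (flux fixed at 0).
    """

    def __init__(self, graph=None, hidden_sizes=(8, 4), lambda_scale=1.0,
                 ta_mode="metabolic_total", epochs=100, learning_rate=0.008,
                 convergence_tol=1e-4, patience=10, random_state=42,
                 clamp_nonnegative=False):
        self.graph = graph
        self.hidden_sizes = hidden_sizes
        self.lambda_scale = lambda_scale
        self.ta_mode = ta_mode
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.convergence_tol = convergence_tol
        self.patience = patience
        self.random_state = random_state
        self.clamp_nonnegative = clamp_nonnegative

    # -- internal helpers ------------------------------------------------
    def _module_inputs(self, expr: ExpressionMatrix, warn_missing: bool = True):
        """Per-module (gene list, sample x gene matrix), zero-filling absent genes."""
        values = expr.values
        present = set(values.index)
        blocks = {}
        for mid in self.graph.module_ids:
            genes = list(self.graph.modules[mid].genes)
            missing = [g for g in genes if g not in present]
            if missing and warn_missing:
                logger.warning("module %s: genes %s absent from data, imputed as 0",
                               mid, missing)
            X = np.zeros((values.shape[1], len(genes)))
            for i, g in enumerate(genes):
                if g in present:
                    X[:, i] = values.loc[g].to_numpy(dtype=float)
            blocks[mid] = (genes, X)
        return blocks

    def _forward_all(self, blocks) -> np.ndarray:
        n = next(iter(blocks.values()))[1].shape[0]
        F = np.zeros((n, len(self.module_ids_)))
        for m, mid in enumerate(self.module_ids_):
            if mid in self.pinned_modules_:
                continue
            out, _ = _forward(self.params_[mid], blocks[mid][1], self.n_layers_)
            F[:, m] = out
        return F

    # -- sklearn API -----------------------------------------------------
    def fit(self, X, y=None):
        cfg = TrainingConfig(
            lambda_scale=self.lambda_scale, hidden_sizes=tuple(self.hidden_sizes),
            epochs=self.epochs, learning_rate=self.learning_rate,
            seed=self.random_state, ta_mode=self.ta_mode,
            convergence_tol=self.convergence_tol, patience=self.patience,
        )
        if self.graph is None:
            raise ParameterError("FluxEstimator requires a graph")
        expr = as_expression(X)

        graph_genes = set(self.graph.genes())
        if not graph_genes & set(expr.values.index):
            raise InputError("no overlap between expression genes and graph genes")

        self.module_ids_ = self.graph.module_ids
        blocks = self._module_inputs(expr)
        self.pinned_modules_ = [
            mid for mid in self.module_ids_
            if not any(g in expr.values.index for g in self.graph.modules[mid].genes)
        ]
        for mid in self.pinned_modules_:
            logger.warning("module %s has no observed genes; flux pinned to 0", mid)

        ta = total_activity(expr, self.graph, cfg.ta_mode).to_numpy(dtype=float)
        n = expr.n_samples
        S = incidence_matrix(self.graph).to_numpy()
        self.n_layers_ = len(cfg.hidden_sizes) + 1

        rng = np.random.default_rng(cfg.seed)
        active = [m for m in self.module_ids_ if m not in self.pinned_modules_]
        out_bias = float(ta.mean()) / max(len(active), 1)
        self.params_ = {
            mid: _init_module_params(rng, len(blocks[mid][0]), tuple(cfg.hidden_sizes), out_bias)
            for mid in active
        }

        opt = _Adam(cfg.learning_rate)
        trace = []
        F = self._forward_all(blocks)
        terms = self._loss_terms(F, S, ta, cfg.lambda_scale)
        trace.append(terms)
        below_tol = 0
        epochs_run = 0
        self.converged_ = False
        for epoch in range(1, cfg.epochs + 1):
            if not np.isfinite(terms.total):
                raise TrainingError(f"non-finite loss at epoch {epoch - 1}")
            G = self._loss_grad(F, S, ta, cfg.lambda_scale) / n
            params_list, grads_list = [], []
            for m, mid in enumerate(self.module_ids_):
                if mid in self.pinned_modules_:
                    continue
                _, acts = _forward(self.params_[mid], blocks[mid][1], self.n_layers_)
                grads = _backward(self.params_[mid], acts, G[:, m], self.n_layers_)
                params_list.append(self.params_[mid])
                grads_list.append(grads)
            opt.step(params_list, grads_list)
            F = self._forward_all(blocks)
            new_terms = self._loss_terms(F, S, ta, cfg.lambda_scale)
            rel = abs(new_terms.total - terms.total) / max(abs(terms.total), 1e-12)
            below_tol = below_tol + 1 if rel < cfg.convergence_tol else 0
            terms = new_terms
            trace.append(terms)
            epochs_run = epoch
            if below_tol >= cfg.patience:
                self.converged_ = True
                break
        if not np.isfinite(terms.total):
            raise TrainingError(f"non-finite loss at epoch {epochs_run}")

        self.n_epochs_ = epochs_run
        self.loss_trace_ = pd.DataFrame(trace, columns=LossTerms._fields)
        self.loss_trace_.index.name = "epoch"
        self.negative_fraction_ = float((F < -1e-6).mean())
        if self.clamp_nonnegative:
            F = np.maximum(F, 0.0)
        self.flux_ = pd.DataFrame(F, index=expr.samples, columns=self.module_ids_)
        self.ta_ = pd.Series(ta, index=expr.samples, name="TA")
        return self

    @staticmethod
    def _loss_terms(F, S, ta, lam) -> LossTerms:
        residual = F @ S.T
        balance = float(np.sum(residual**2))
        nonneg = float(np.sum((F - np.abs(F)) ** 2))
        scale = float(lam * np.sum((F.sum(axis=1) - ta) ** 2))
        return LossTerms(balance + nonneg + scale, balance, nonneg, scale)

    @staticmethod
    def _loss_grad(F, S, ta, lam) -> np.ndarray:
        grad = 2.0 * (F @ S.T) @ S
        D = F - np.abs(F)
        grad += 2.0 * D * (1.0 - np.sign(F))
        grad += 2.0 * lam * (F.sum(axis=1) - ta)[:, None]
        return grad

    def predict(self, X) -> pd.DataFrame:
        """Forward pass of the trained module networks; no retraining."""
        if not hasattr(self, "params_"):
            raise TrainingError("estimator is not fitted")
        expr = as_expression(X)
        blocks = self._module_inputs(expr, warn_missing=True)
        F = self._forward_all(blocks)
        if self.clamp_nonnegative:
            F = np.maximum(F, 0.0)
        return pd.DataFrame(F, index=expr.samples, columns=self.module_ids_)

    def fit_predict(self, X, y=None) -> pd.DataFrame:
        return self.fit(X).flux_


def metabolite_change(flux, graph: FactorGraph) -> pd.DataFrame:
    """Per-sample abundance-change surrogate: influx minus outflux.

    Returns a sample x intermediate table; positive values mean predicted
    accumulation, negative predicted depletion.  Linear in flux.
    """
    flux = pd.DataFrame(flux)
    S = incidence_matrix(graph)
    try:
        F = flux[list(S.columns)].to_numpy(dtype=float)
    except KeyError as exc:
        raise DimensionError(f"flux columns do not match graph modules: {exc}") from exc
    return pd.DataFrame(F @ S.to_numpy().T, index=flux.index, columns=S.index)


def train(graph: FactorGraph, expression, config: TrainingConfig | None = None):
    """Functional wrapper: returns (fitted FluxEstimator, flux matrix, loss trace)."""
    config = config or TrainingConfig()
    est = FluxEstimator(
        graph=graph, hidden_sizes=config.hidden_sizes, lambda_scale=config.lambda_scale,
        ta_mode=config.ta_mode, epochs=config.epochs, learning_rate=config.learning_rate,
        convergence_tol=config.convergence_tol, patience=config.patience,
        random_state=config.seed,
    ).fit(expression)
    return est, est.flux_, est.loss_trace_


def predict_flux(model: FluxEstimator, expression) -> pd.DataFrame:
    """Functional wrapper over :meth:`FluxEstimator.predict`."""
    return model.predict(expression)
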