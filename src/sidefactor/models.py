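"""Matrix-factorization models for drug/side-effect association prediction.

Three model families share the latent structure ``score(i, j) = d_i's_j +
b_i + b_j`` with drug factors D (m×k), side-effect factors S (n×k) and bias
terms:

``mf``
    Classic biased matrix factorization trained on squared error against the
    binary association matrix.  Zero entries are learned as true zeros and
    all pairs carry the same importance.

``logistic_mf``
    The implicit-feedback variant: predictions pass through a sigmoid and the
    loss is a per-pair *weighted* log loss.  Weights come from the report
    counts (see :mod:`sidefactor.matrices`), so heavily reported positives
    dominate while unreported pairs — which may simply be unobserved — are
    down-weighted by ``beta``.

``fgrmf``
    Squared-error factorization with an extra graph regularizer
    ``mu * sum_{i,i'} sim_{ii'} ||d_i - d_{i'}||^2`` pulling structurally
    similar drugs toward similar factors (fingerprint Tanimoto similarity by
    default).

All three are trained full-batch with Adam, early stopping on the mean
PR-AUC of a designated "severe" side-effect set on validation pairs, and a
learning-rate schedule that multiplies the rate by ``lr_decay`` whenever the
validation metric has dipped below its best for ``decay_patience``
consecutive epochs (a plateau scheduler).

The L2 penalty is accumulated *per pair*, as written in the loss
``sum_{(i,j)} [err_ij + lambda(||d_i||^2 + ||s_j||^2)]`` — a drug appearing
in many pairs is regularized proportionally harder.  A conventional
per-parameter variant is available via ``penalty="per_param"``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .matrices import AssociationMatrix, ParameterError, WeightMatrix
from . import evaluation

FAMILIES = ("mf", "logistic_mf", "fgrmf")

#: Default hyperparameter grids for the exhaustive search.
GRID_SEARCH_RANGES: dict[str, dict[str, list[float]]] = {
    "logistic_mf": {
        "lambda_l2": [1e-4, 5e-4, 1e-3, 5e-3, 1e-2],
        "alpha": [0, 1, 2, 5, 10, 15],
        "beta": [0.2, 0.4, 0.6, 0.8, 1.0],
    },
    "mf": {"lambda_l2": [1e-4, 5e-4, 1e-3, 5e-3, 1e-2]},
    "fgrmf": {
        "lambda_l2": [1e-5, 5e-5, 1e-4, 5e-4, 1e-3],
        "mu_graph": [1e-4, 5e-4, 1e-3, 5e-3, 1e-2],
    },
}


@dataclass
class FactorModel:
    """Latent factors and biases for one fitted (or random) model."""

    D: np.ndarray  # (m, k) drug factors, row i = d_i
    S: np.ndarray  # (n, k) side-effect factors, row j = s_j
    b_drug: np.ndarray  # (m,)
    b_se: np.ndarray  # (n,)
    family: str = "logistic_mf"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        self.D = np.asarray(self.D, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.b_drug = np.asarray(self.b_drug, dtype=float)
        self.b_se = np.asarray(self.b_se, dtype=float)
        m, k = self.D.shape
        n, k2 = self.S.shape
        if k != k2 or self.b_drug.shape != (m,) or self.b_se.shape != (n,):
            raise ValueError("inconsistent model dimensions")
        for arr in (self.D, self.S, self.b_drug, self.b_se):
            if not np.isfinite(arr).all():
                raise ValueError("model parameters must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.D.shape[0], self.S.shape[0]

    @property
    def k(self) -> int:
        return self.D.shape[1]

    def logits(self) -> np.ndarray:
        """Raw scores d_i's_j + b_i + b_j for every pair."""
        return self.D @ self.S.T + self.b_drug[:, None] + self.b_se[None, :]

    def score_matrix(self) -> np.ndarray:
        """Model predictions for every pair: sigmoid of the logits for the
        logistic family, the raw logits otherwise."""
        z = self.logits()
        return expit(z) if self.family == "logistic_mf" else z


def predict_linear(model: FactorModel, i: int, j: int) -> float:
    """Linear score d_i's_j + b_i + b_j (mf / fgrmf families)."""
    if model.family == "logistic_mf":
        raise ValueError("predict_linear is for the mf/fgrmf families")
    m, n = model.shape
    if not (0 <= i < m and 0 <= j < n):
        raise IndexError(f"pair ({i}, {j}) out of range for {m}x{n} model")
    return float(model.D[i] @ model.S[j] + model.b_drug[i] + model.b_se[j])


def predict_logistic(model: FactorModel, i: int, j: int) -> float:
    """Association probability sigmoid(d_i's_j + b_i + b_j)."""
    if model.family != "logistic_mf":
        raise ValueError("predict_logistic requires the logistic_mf family")
    m, n = model.shape
    if not (0 <= i < m and 0 <= j < n):
        raise IndexError(f"pair ({i}, {j}) out of range for {m}x{n} model")
    return float(expit(model.D[i] @ model.S[j] + model.b_drug[i] + model.b_se[j]))


# ---------------------------------------------------------------------------
# Losses and analytic gradients

_EPS = 1e-12


def pairs_to_mask(pairs, shape: tuple[int, int]) -> np.ndarray:
    """Convert a (P, 2) index array (or boolean mask) to a boolean mask."""
    if isinstance(pairs, np.ndarray) and pairs.dtype == bool:
        if pairs.shape != shape:
            raise ValueError("boolean pair mask has wrong shape")
        return pairs
    pairs = np.asarray(pairs, dtype=int)
    if pairs.size == 0:
        raise ValueError("empty pair set")
    mask = np.zeros(shape, dtype=bool)
    mask[pairs[:, 0], pairs[:, 1]] = True
    return mask


def _penalty_and_grads(model, mask, lambda_l2, penalty):
    if penalty == "per_pair":
        row = mask.sum(axis=1).astype(float)
        col = mask.sum(axis=0).astype(float)
        pen = lambda_l2 * (
            row @ (model.D**2).sum(axis=1) + col @ (model.S**2).sum(axis=1)
        )
        gD = 2.0 * lambda_l2 * row[:, None] * model.D
        gS = 2.0 * lambda_l2 * col[:, None] * model.S
    elif penalty == "per_param":
        pen = lambda_l2 * ((model.D**2).sum() + (model.S**2).sum())
        gD = 2.0 * lambda_l2 * model.D
        gS = 2.0 * lambda_l2 * model.S
    else:
        raise ValueError(f"unknown penalty mode {penalty!r}")
    return pen, gD, gS


def _squared_error_core(model, A_dense, mask):
    R = (A_dense - model.logits()) * mask
    loss = float((R**2).sum())
    gD = -2.0 * (R @ model.S)
    gS = -2.0 * (R.T @ model.D)
    gbd = -2.0 * R.sum(axis=1)
    gbs = -2.0 * R.sum(axis=0)
    return loss, gD, gS, gbd, gbs


def mf_loss_grad(
    model: FactorModel,
    A: AssociationMatrix | np.ndarray,
    pairs,
    lambda_l2: float,
    penalty: str = "per_pair",
):
    """Squared-error loss over a pair set, with analytic gradients."""
    A_dense = A.dense() if isinstance(A, AssociationMatrix) else np.asarray(A, float)
    mask = pairs_to_mask(pairs, A_dense.shape)
    if not mask.any():
        raise ValueError("empty pair set")
    loss, gD, gS, gbd, gbs = _squared_error_core(model, A_dense, mask)
    pen, pD, pS = _penalty_and_grads(model, mask, lambda_l2, penalty)
    return loss + pen, {"D": gD + pD, "S": gS + pS, "b_drug": gbd, "b_se": gbs}


def mf_loss(model, A, pairs, lambda_l2: float, penalty: str = "per_pair") -> float:
    return mf_loss_grad(model, A, pairs, lambda_l2, penalty)[0]


def lmf_loss_grad(
    model: FactorModel,
    A: AssociationMatrix | np.ndarray,
    W: WeightMatrix | np.ndarray,
    pairs,
    lambda_l2: float,
    penalty: str = "per_pair",
):
    """Weighted log loss over a pair set, with analytic gradients.

    Predictions are clipped to [eps, 1-eps] with eps=1e-12 before the log;
    the gradient uses the exact unclipped form w*(p - a), which matches the
    clipped loss everywhere the clip is inactive.
    """
    A_dense = A.dense() if isinstance(A, AssociationMatrix) else np.asarray(A, float)
    mask = pairs_to_mask(pairs, A_dense.shape)
    if not mask.any():
        raise ValueError("empty pair set")
    W_dense = W.dense() if isinstance(W, WeightMatrix) else np.asarray(W, float)
    if W_dense.shape != A_dense.shape:
        raise ValueError("weight matrix not aligned with association matrix")
    P = expit(model.logits())
    Pc = np.clip(P, _EPS, 1.0 - _EPS)
    ll = W_dense * (A_dense * np.log(Pc) + (1.0 - A_dense) * np.log(1.0 - Pc))
    loss = -float(ll[mask].sum())
    G = mask * W_dense * (P - A_dense)
    gD = G @ model.S
    gS = G.T @ model.D
    gbd = G.sum(axis=1)
    gbs = G.sum(axis=0)
    pen, pD, pS = _penalty_and_grads(model, mask, lambda_l2, penalty)
    return loss + pen, {"D": gD + pD, "S": gS + pS, "b_drug": gbd, "b_se": gbs}


def lmf_loss(model, A, W, pairs, lambda_l2: float, penalty: str = "per_pair") -> float:
    return lmf_loss_grad(model, A, W, pairs, lambda_l2, penalty)[0]


@dataclass
class SimilarityGraph:
    """Symmetric m×m drug–drug similarity in [0, 1] with unit diagonal."""

    sim: np.ndarray

    def __post_init__(self) -> None:
        self.sim = np.asarray(self.sim, dtype=float)
        m, m2 = self.sim.shape
        if m != m2:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(self.sim, self.sim.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.sim), 1.0):
            raise ValueError("similarity diagonal must be 1")
        if self.sim.min() < 0 or self.sim.max() > 1 + 1e-12:
            raise ValueError("similarities must lie in [0, 1]")

    def laplacian(self) -> np.ndarray:
        return np.diag(self.sim.sum(axis=1)) - self.sim


def fgrmf_loss_grad(
    model: FactorModel,
    A: AssociationMatrix | np.ndarray,
    graph: SimilarityGraph,
    pairs,
    lambda_l2: float,
    mu_graph: float,
    penalty: str = "per_pair",
):
    """Squared-error loss plus the drug-graph smoothness regularizer.

    The graph term is ``mu * sum_{i,i'} sim_{ii'} ||d_i - d_{i'}||^2`` over
    ordered pairs, equal to ``2 mu tr(D' L D)`` with L the graph Laplacian.
    """
    A_dense = A.dense() if isinstance(A, AssociationMatrix) else np.asarray(A, float)
    mask = pairs_to_mask(pairs, A_dense.shape)
    if not mask.any():
        raise ValueError("empty pair set")
    if graph.sim.shape[0] != model.shape[0]:
        raise ValueError("graph dimension does not match drug count")
    loss, gD, gS, gbd, gbs = _squared_error_core(model, A_dense, mask)
    pen, pD, pS = _penalty_and_grads(model, mask, lambda_l2, penalty)
    L = graph.laplacian()
    graph_term = 2.0 * mu_graph * float(np.trace(model.D.T @ L @ model.D))
    gD_graph = 4.0 * mu_graph * (L @ model.D)
    return loss + pen + graph_term, {
        "D": gD + pD + gD_graph,
        "S": gS + pS,
        "b_drug": gbd,
        "b_se": gbs,
    }


def fgrmf_loss(
    model, A, graph, pairs, lambda_l2: float, mu_graph: float,
    penalty: str = "per_pair",
) -> float:
    return fgrmf_loss_grad(model, A, graph, pairs, lambda_l2, mu_graph, penalty)[0]


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainConfig:
    """Optimization settings shared by all model families.

    Defaults follow the standard protocol for this method: k=100, initial
    learning rate 0.01 decayed by ×0.1 on a validation dip, Adam optimizer,
    early stopping on validation severe-set PR-AUC.
    """

    k: int = 100
    lambda_l2: float = 5e-3
    alpha: float = 10.0
    beta: float = 0.8
    mu_graph: float = 5e-4
    lr_init: float = 0.01
    lr_decay: float = 0.1
    patience: int = 5
    decay_patience: int = 5
    max_epochs: int = 200
    init_sd: float = 0.1
    penalty: str = "per_pair"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_init <= 0:
            raise ParameterError("lr_init must be positive")
        if not (0 < self.lr_decay < 1):
            raise ParameterError("lr_decay must lie in (0, 1)")
        if self.lambda_l2 < 0 or self.mu_graph < 0:
            raise ParameterError("regularization strengths must be >= 0")
        if self.k < 1:
            raise ParameterError("latent dimension k must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch training trace."""

    loss: list[float] = field(default_factory=list)
    val_metric: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1


class _Adam:
    def __init__(self, shapes: Mapping[str, tuple], b1=0.9, b2=0.999, eps=1e-8):
        self.b1, self.b2, self.eps = b1, b2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params: dict, grads: Mapping[str, np.ndarray], lr: float):
        self.t += 1
        for key, g in grads.items():
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1**self.t)
            vhat = self.v[key] / (1 - self.b2**self.t)
            params[key] = params[key] - lr * mhat / (np.sqrt(vhat) + self.eps)


def init_model(
    m: int, n: int, k: int, family: str, seed: int, init_sd: float = 0.1
) -> FactorModel:
    """Seeded small-random initialization: factors ~ N(0, init_sd^2), biases 0."""
    rng = np.random.default_rng(seed)
    return FactorModel(
        D=rng.normal(0.0, init_sd, (m, k)),
        S=rng.normal(0.0, init_sd, (n, k)),
        b_drug=np.zeros(m),
        b_se=np.zeros(n),
        family=family,
    )


def _training_state(A, W, split):
    """Build the dense training target, loss mask and weight matrix.

    Training sees the training-role positives as ones.  Held-out positives
    (validation and test roles) are masked out of the loss entirely.  Pairs
    deleted by the cold-start simulation stay in the loss as zeros with the
    'unreported' weight beta — the model is given no hint they ever existed.
    """
    m, n = A.shape
    A_train = np.zeros((m, n))
    if len(split.train_pairs):
        A_train[split.train_pairs[:, 0], split.train_pairs[:, 1]] = 1.0
    mask = np.ones((m, n), dtype=bool)
    for held in (split.val_pairs, split.test_pairs):
        if len(held):
            mask[held[:, 0], held[:, 1]] = False
    W_dense = None
    if W is not None:
        counts = np.asarray(W.counts.todense(), dtype=float)
        counts[~mask] = 0.0
        if len(split.deleted_pairs):
            counts[split.deleted_pairs[:, 0], split.deleted_pairs[:, 1]] = 0.0
        W_dense = W.weight_of_counts(counts)
    return A_train, mask, W_dense


def train(
    family: str,
    A: AssociationMatrix,
    split: "evaluation.SplitSpec",
    cfg: TrainConfig,
    severe: Sequence[int],
    W: WeightMatrix | None = None,
    graph: SimilarityGraph | None = None,
) -> tuple[FactorModel, TrainHistory]:
    """Fit one model family with Adam, plateau LR decay, and early
    stopping on the mean severe-set validation PR-AUC.

    Returns the best-epoch parameters together with the per-epoch history.
    Stops after ``patience + 1`` epochs without a new validation best (so
    ``patience=0`` trains exactly one epoch beyond the first
    non-improvement).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if family == "mf" and W is not None:
        raise ValueError("plain MF takes no weight matrix")
    if family == "logistic_mf" and W is None:
        raise ValueError("logistic_mf requires a WeightMatrix")
    if family == "fgrmf" and graph is None:
        raise ValueError("fgrmf requires a SimilarityGraph")

    m, n = A.shape
    A_train, mask, W_dense = _training_state(A, W, split)
    model = init_model(m, n, cfg.k, family, cfg.seed, cfg.init_sd)
    params = {"D": model.D, "S": model.S, "b_drug": model.b_drug, "b_se": model.b_se}
    opt = _Adam({k: v.shape for k, v in params.items()})
    history = TrainHistory()
    lr = cfg.lr_init
    best_metric = -np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    bad_epochs = 0

    for epoch in range(cfg.max_epochs):
        model = FactorModel(params["D"], params["S"], params["b_drug"],
                            params["b_se"], family)
        if family == "logistic_mf":
            loss, grads = lmf_loss_grad(
                model, A_train, W_dense, mask, cfg.lambda_l2, cfg.penalty
            )
        elif family == "mf":
            loss, grads = mf_loss_grad(model, A_train, mask, cfg.lambda_l2, cfg.penalty)
        else:
            loss, grads = fgrmf_loss_grad(
                model, A_train, graph, mask, cfg.lambda_l2, cfg.mu_graph, cfg.penalty
            )
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        opt.step(params, grads, lr)
        model = FactorModel(params["D"], params["S"], params["b_drug"],
                            params["b_se"], family)
        has_val = len(split.val_pairs) > 0
        metric = (
            evaluation.validation_metric(model.score_matrix(), split, severe)
            if has_val else float("nan")
        )
        history.loss.append(float(loss))
        history.val_metric.append(float(metric))
        history.lr.append(float(lr))
        if not has_val:
            # no validation signal: keep training to max_epochs, return final
            best_params = params
            history.best_epoch = epoch
            continue
        if metric > best_metric:
            best_metric = metric
            best_params = {k: v.copy() for k, v in params.items()}
            history.best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            # sustained dip: decay once per decay_patience bad epochs
            if bad_epochs % cfg.decay_patience == 0:
                lr *= cfg.lr_decay
            if bad_epochs > cfg.patience:
                break

    fitted = FactorModel(best_params["D"], best_params["S"],
                         best_params["b_drug"], best_params["b_se"], family)
    return fitted, history


def grid_search(
    family: str,
    grids: Mapping[str, Sequence[float]],
    A: AssociationMatrix,
    split: "evaluation.SplitSpec",
    cfg: TrainConfig,
    severe: Sequence[int],
    counts=None,
    graph: SimilarityGraph | None = None,
):
    """Exhaustive hyperparameter search maximizing the validation metric.

    ``grids`` maps TrainConfig field names (lambda_l2, alpha, beta,
    mu_graph) to candidate lists.  Ties are broken by first-in-grid order.
    Returns ``(best_setting, results)`` where results is a list of
    ``{**setting, "val_metric": value}`` rows in evaluation order.
    For the logistic family, ``counts`` (a ReportCountMatrix) supplies the
    report counts from which each candidate (alpha, beta) weighting is built.
    """
    if not grids:
        raise ValueError("empty hyperparameter grid")
    from .matrices import compute_weights

    names = list(grids.keys())
    results = []
    best = None
    best_metric = -np.inf
    for values in itertools.product(*(grids[name] for name in names)):
        setting = dict(zip(names, values))
        trial_cfg = TrainConfig(**{**asdict(cfg), **setting})
        W = None
        if family == "logistic_mf":
            if counts is None:
                raise ValueError("logistic_mf grid search needs the count matrix")
            W = compute_weights(
                counts, A.threshold, trial_cfg.alpha, max(trial_cfg.beta, 1e-12)
            )
        _, history = train(family, A, split, trial_cfg, severe, W=W, graph=graph)
        metric = max(history.val_metric) if history.val_metric else -np.inf
        results.append({**setting, "val_metric": float(metric)})
        if metric > best_metric:
            best_metric = metric
            best = setting
    return best, results


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(
    model: FactorModel,
    path: str | Path,
    cfg: TrainConfig | None = None,
    drug_labels: Sequence[str] | None = None,
    se_labels: Sequence[str] | None = None,
) -> None:
    """Serialize a model (and optionally its config and labels) to ``.npz``."""
    meta = {"family": model.family}
    if cfg is not None:
        meta["config"] = asdict(cfg)
    np.savez(
        path,
        D=model.D,
        S=model.S,
        b_drug=model.b_drug,
        b_se=model.b_se,
        meta=np.array(json.dumps(meta)),
        drug_labels=np.asarray(list(drug_labels) if drug_labels else [], dtype="U"),
        se_labels=np.asarray(list(se_labels) if se_labels else [], dtype="U"),
    )


def load_checkpoint(path: str | Path):
    """Load a checkpoint; returns (model, config-or-None, drug_labels, se_labels)."""
    with np.load(path) as z:
        meta = json.loads(str(z["meta"]))
        model = FactorModel(z["D"], z["S"], z["b_drug"], z["b_se"], meta["family"])
        cfg = TrainConfig(**meta["config"]) if "config" in meta else None
        drugs = [str(x) for x in z["drug_labels"]]
        ses = [str(x) for x in z["se_labels"]]
    return model, cfg, drugs, ses
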