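"""Attribute-to-feature mapping for cold-start drugs (Map-LMF).

A factorization model can only place a drug in latent space if it has
reporting history.  For a cold drug the mapping model predicts its latent
factor vector from chemical attributes instead:

    d_hat_i = M' desc_i

with M fitted by ridge regression from the training drugs' attributes onto
their converged latent factors.  Scoring then proceeds exactly as in the
logistic model, with the unknown drug bias filled in by the mean training
drug bias.  The hybrid scorer switches per drug between learned and mapped
factors depending on how many side effects are already known.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .chem import DescriptorMatrix
from .models import FactorModel


@dataclass
class MappingModel:
    """Linear attribute→factor map with the attribute kind it expects."""

    M: np.ndarray  # (p, k)
    attr_kind: str
    ridge: float = 0.0

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 2:
            raise ValueError("M must be a p×k matrix")
        if not np.isfinite(self.M).all():
            raise ValueError("mapping matrix must be finite")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")

    def map_factors(self, desc_values: np.ndarray) -> np.ndarray:
        """d_hat rows for each attribute row: desc @ M."""
        desc_values = np.atleast_2d(np.asarray(desc_values, dtype=float))
        return desc_values @ self.M


def fit_mapping(
    desc: DescriptorMatrix, D: np.ndarray, ridge: float = 1e-6
) -> MappingModel:
    """Ridge-regression fit of attributes onto latent factors.

    Minimizes ``||X M - D||^2 + ridge ||M||^2`` in closed form; with
    ridge=0 the minimum-norm least-squares solution is used.  ``desc`` and
    ``D`` must cover the same training drugs, row-aligned.
    """
    X = desc.values
    D = np.asarray(D, dtype=float)
    if X.shape[0] != D.shape[0]:
        raise ValueError(
            f"attribute rows ({X.shape[0]}) and factor rows ({D.shape[0]}) differ"
        )
    if ridge > 0:
        p = X.shape[1]
        M = np.linalg.solve(X.T @ X + ridge * np.eye(p), X.T @ D)
    else:
        M = np.linalg.lstsq(X, D, rcond=None)[0]
    return MappingModel(M=M, attr_kind=desc.kind, ridge=ridge)


def _check_kind(mapping: MappingModel, kind: str) -> None:
    if kind != mapping.attr_kind:
        raise ValueError(
            f"attribute kind {kind!r} does not match the fitted map "
            f"({mapping.attr_kind!r})"
        )


def bias_fill(model: FactorModel, training_drugs: Sequence[int] | None = None) -> float:
    """Drug-bias stand-in for cold drugs: mean training drug bias."""
    b = model.b_drug if training_drugs is None else model.b_drug[list(training_drugs)]
    return float(np.mean(b))


def map_and_predict(
    model: FactorModel,
    mapping: MappingModel,
    desc_i: np.ndarray,
    j: int,
    attr_kind: str | None = None,
    b_fill: float | None = None,
) -> float:
    """Probability for one (cold drug, side effect) pair from mapped factors."""
    if model.family != "logistic_mf":
        raise ValueError("mapped prediction requires a logistic_mf model")
    if attr_kind is not None:
        _check_kind(mapping, attr_kind)
    d_hat = mapping.map_factors(desc_i)[0]
    bb = bias_fill(model) if b_fill is None else b_fill
    return float(expit(d_hat @ model.S[j] + bb + model.b_se[j]))


def mapped_score_matrix(
    model: FactorModel,
    mapping: MappingModel,
    desc: DescriptorMatrix,
    training_drugs: Sequence[int] | None = None,
) -> np.ndarray:
    """Full m×n probability matrix scoring *every* drug through its mapped
    factors (the Map-LMF scorer).  The drug bias is the training mean."""
    if model.family != "logistic_mf":
        raise ValueError("mapped prediction requires a logistic_mf model")
    _check_kind(mapping, desc.kind)
    D_hat = mapping.map_factors(desc.values)
    bb = bias_fill(model, training_drugs)
    return expit(D_hat @ model.S.T + bb + model.b_se[None, :])


def hybrid_score(
    model: FactorModel,
    mapping: MappingModel,
    known_se_count: int,
    switch_threshold: int,
    j: int,
    i: int | None = None,
    desc_i: np.ndarray | None = None,
) -> float:
    """Use learned factors when the drug has enough known side effects,
    mapped factors otherwise.

    ``switch_threshold=0`` always uses the learned factors; a drug with
    zero known side effects always falls back to the mapped ones.
    """
    from .models import predict_logistic

    if known_se_count >= switch_threshold:
        if i is None:
            raise ValueError("learned-factor branch needs the drug index i")
        return predict_logistic(model, i, j)
    if desc_i is None:
        raise ValueError("mapped branch needs the drug attributes desc_i")
    return map_and_predict(model, mapping, desc_i, j)


def hybrid_score_matrix(
    model: FactorModel,
    mapping: MappingModel,
    desc: DescriptorMatrix,
    known_se_counts: np.ndarray,
    switch_threshold: int,
    training_drugs: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized hybrid scoring for all drugs.

    Returns the m×n score matrix and a boolean per-drug flag that is True
    where the mapped factors were used.
    """
    known_se_counts = np.asarray(known_se_counts, dtype=int)
    learned = model.score_matrix()
    mapped = mapped_score_matrix(model, mapping, desc, training_drugs)
    use_mapped = known_se_counts < switch_threshold
    scores = np.where(use_mapped[:, None], mapped, learned)
    return scores, use_mapped


def map_lmf_scores(
    counts,
    A,
    split,
    cfg,
    severe: Sequence[int],
    attrs: DescriptorMatrix,
    ridge: float = 1e-6,
) -> tuple[np.ndarray, FactorModel, MappingModel]:
    """The full Map-LMF pipeline: reference model, mapping, mapped scores.

    The reference logistic model is trained on the *training drugs only* —
    its side-effect factors and the fitted attribute map are therefore
    untouched by whatever cold-start deletion was applied to the test
    drugs.  Every drug is then scored through its mapped factors against
    the reference side-effect factors, with the mean training drug bias
    filled in.

    Returns the full m×n mapped score matrix, the reference model and the
    fitted mapping.
    """
    from .evaluation import SplitSpec
    from .matrices import compute_weights
    from .models import train

    sub = np.asarray(split.training_drugs, dtype=int)
    row_of = -np.ones(A.shape[0], dtype=int)
    row_of[sub] = np.arange(sub.size)

    def _reindex(pairs):
        pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
        keep = row_of[pairs[:, 0]] >= 0
        out = pairs[keep].copy()
        out[:, 0] = row_of[out[:, 0]]
        return out

    counts_sub = type(counts)(
        counts.counts[sub], tuple(counts.drug_labels[i] for i in sub),
        counts.se_labels,
    )
    A_sub = type(A)(
        A.assoc[sub], A.threshold, tuple(A.drug_labels[i] for i in sub),
        A.se_labels,
    )
    split_sub = SplitSpec(
        training_drugs=np.arange(sub.size),
        test_drugs=np.empty(0, dtype=int),
        train_pairs=_reindex(split.train_pairs),
        val_pairs=_reindex(split.val_pairs),
        test_pairs=np.empty((0, 2), dtype=int),
        seed=split.seed,
    )
    W_sub = compute_weights(counts_sub, A.threshold, cfg.alpha, cfg.beta)
    ref_model, _ = train("logistic_mf", A_sub, split_sub, cfg, severe, W=W_sub)

    desc_train = DescriptorMatrix(
        attrs.values[sub], attrs.attr_names, attrs.kind
    )
    mapped = fit_mapping(desc_train, ref_model.D, ridge=ridge)
    D_hat = mapped.map_factors(attrs.values)
    bb = float(np.mean(ref_model.b_drug))
    scores = expit(D_hat @ ref_model.S.T + bb + ref_model.b_se[None, :])
    return scores, ref_model, mapped


def save_mapping(mapping: MappingModel, path: str | Path) -> None:
    np.savez(path, M=mapping.M, attr_kind=np.array(mapping.attr_kind),
             ridge=np.array(mapping.ridge))


def load_mapping(path: str | Path) -> MappingModel:
    with np.load(path) as z:
        return MappingModel(M=z["M"], attr_kind=str(z["attr_kind"]),
                            ridge=float(z["ridge"]))
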