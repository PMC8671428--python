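"""Drug-level data splitting, cold-start deletion and PR-AUC evaluation.

The evaluation protocol is drug-level, not pair-level: drugs are first split
in half into *training drugs* and *test drugs*.  Within the training drugs,
20% of the known (positive) drug–side-effect pairs are held out for
validation; within the test drugs, 40% are held out for testing and the rest
stay in training.  In expectation this puts 70% of all positive pairs in the
training role, 10% in validation and 20% in test.  The point of the drug
split is that cold-start deletion can then remove a test drug's remaining
training pairs without touching the training drugs at all.

Evaluation is per side effect: for one side-effect column, the test drugs
are ranked by model score against the binary test-role labels and the area
under the precision–recall curve is computed.  The headline metric is the
mean PR-AUC over a designated set of severe side effects, aggregated over
repeated re-splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .matrices import AssociationMatrix, ParameterError


class EvaluationError(ValueError):
    """Raised when a metric is undefined for the given labels."""


# ---------------------------------------------------------------------------
# PR-AUC


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision–recall curve for one ranked list.

    Uses the step-wise (average-precision style) estimator: thresholds run
    over the *distinct* score values from high to low, tied scores collapse
    to a single curve point, and the area is sum_k (R_k - R_{k-1}) * P_k.
    Constant scores therefore give exactly the positive prevalence.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-D arrays")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos + n_neg != labels.size:
        raise ValueError("labels must be binary")
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("PR-AUC undefined without both classes")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order].astype(float)
    # boundaries of tie groups in the descending sort
    boundary = np.nonzero(np.diff(s))[0]
    ends = np.append(boundary, s.size - 1)
    tp = np.cumsum(y)[ends]
    pred_pos = ends + 1.0
    precision = tp / pred_pos
    recall = tp / n_pos
    prev_recall = np.concatenate(([0.0], recall[:-1]))
    return float(((recall - prev_recall) * precision).sum())


# ---------------------------------------------------------------------------
# Splitting


@dataclass
class SplitSpec:
    """Role assignment for drugs and positive pairs, plus deletions.

    ``train_pairs``/``val_pairs``/``test_pairs`` are (P, 2) integer arrays of
    (drug, side-effect) indices over the positive associations;
    ``deleted_pairs`` records cold-start deletions (removed from the
    training role and treated as unreported during training).
    """

    training_drugs: np.ndarray
    test_drugs: np.ndarray
    train_pairs: np.ndarray
    val_pairs: np.ndarray
    test_pairs: np.ndarray
    deleted_pairs: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=int)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.training_drugs = np.asarray(self.training_drugs, dtype=int)
        self.test_drugs = np.asarray(self.test_drugs, dtype=int)
        for name in ("train_pairs", "val_pairs", "test_pairs", "deleted_pairs"):
            arr = np.asarray(getattr(self, name), dtype=int).reshape(-1, 2)
            setattr(self, name, arr)
        if np.intersect1d(self.training_drugs, self.test_drugs).size:
            raise ValueError("training and test drug sets overlap")
        roles = [self.train_pairs, self.val_pairs, self.test_pairs, self.deleted_pairs]
        seen: set[tuple[int, int]] = set()
        for arr in roles:
            for ij in map(tuple, arr):
                if ij in seen:
                    raise ValueError(f"pair {ij} assigned to multiple roles")
                seen.add(ij)

    def n_drugs(self) -> int:
        return self.training_drugs.size + self.test_drugs.size


def _pair_mask(pairs: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    if len(pairs):
        mask[pairs[:, 0], pairs[:, 1]] = True
    return mask


def split_dataset(
    A: AssociationMatrix,
    seed: int,
    val_fraction: float = 0.2,
    test_fraction: float = 0.4,
) -> SplitSpec:
    """Drug-level split: half the drugs become test drugs; 20% of
    training-drug positives go to validation, 40% of test-drug positives to
    test, everything else to the training role.  Fully seeded.
    """
    rng = np.random.default_rng(seed)
    m, n = A.shape
    if m < 2:
        raise ValueError("need at least 2 drugs to split")
    perm = rng.permutation(m)
    n_train_drugs = m - m // 2
    training_drugs = np.sort(perm[:n_train_drugs])
    test_drugs = np.sort(perm[n_train_drugs:])

    coo = A.assoc.tocoo()
    pos = np.column_stack([coo.row, coo.col])[coo.data == 1]
    is_test_drug = np.zeros(m, dtype=bool)
    is_test_drug[test_drugs] = True

    train_list, val_list, test_list = [], [], []
    for drug_pool, holdout_frac, holdout_list in (
        (~is_test_drug, val_fraction, val_list),
        (is_test_drug, test_fraction, test_list),
    ):
        pool = pos[drug_pool[pos[:, 0]]]
        n_hold = int(round(holdout_frac * len(pool)))
        idx = rng.permutation(len(pool))
        holdout_list.append(pool[idx[:n_hold]])
        train_list.append(pool[idx[n_hold:]])

    return SplitSpec(
        training_drugs=training_drugs,
        test_drugs=test_drugs,
        train_pairs=np.concatenate(train_list) if train_list else np.empty((0, 2), int),
        val_pairs=val_list[0],
        test_pairs=test_list[0],
        seed=seed,
    )


def apply_cold_start(
    split: SplitSpec, test_delete_ratio: float, seed: int
) -> SplitSpec:
    """Delete a fraction of the test drugs' training-role pairs.

    Deletion simulates a drug with little reporting history: the chosen
    pairs leave the training role and are recorded in ``deleted_pairs``.
    Per-pair deletion probability is proportional to its drug's
    training-role positive count (drugs with rich histories lose more),
    sampled without replacement until ``round(ratio * eligible)`` pairs are
    removed.  Training-drug pairs are untouched.

    For a fixed ``seed`` the deletions are *nested* across ratios: one
    weighted deletion order is drawn and each ratio removes a prefix of
    it, so sweeping the ratio monotonically shrinks a test drug's
    surviving history rather than re-rolling it.
    """
    if not (0.0 <= test_delete_ratio <= 1.0):
        raise ParameterError("test_delete_ratio must lie in [0, 1]")
    if test_delete_ratio == 0.0:
        return split
    rng = np.random.default_rng(seed)
    is_test_drug = np.zeros(
        int(max(split.training_drugs.max(initial=-1),
                split.test_drugs.max(initial=-1))) + 1, dtype=bool
    )
    is_test_drug[split.test_drugs] = True
    eligible_mask = is_test_drug[split.train_pairs[:, 0]]
    eligible = split.train_pairs[eligible_mask]
    keep_rows = split.train_pairs[~eligible_mask]
    n_delete = int(round(test_delete_ratio * len(eligible)))
    if n_delete == 0:
        return split
    drug_counts = np.bincount(eligible[:, 0], minlength=is_test_drug.size)
    weights = drug_counts[eligible[:, 0]].astype(float)
    # weighted order without replacement (Efraimidis–Spirakis keys);
    # ratio-independent given the seed, so prefixes nest across ratios
    keys = np.log(rng.random(len(eligible))) / weights
    order = np.argsort(-keys, kind="stable")
    chosen = order[:n_delete]
    deleted = eligible[np.sort(chosen)]
    survivors = np.delete(eligible, chosen, axis=0)
    return SplitSpec(
        training_drugs=split.training_drugs,
        test_drugs=split.test_drugs,
        train_pairs=np.concatenate([keep_rows, survivors]),
        val_pairs=split.val_pairs,
        test_pairs=split.test_pairs,
        deleted_pairs=np.concatenate([split.deleted_pairs, deleted]),
        seed=split.seed,
    )


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class EvaluationResult:
    """Per-side-effect PR-AUCs plus the severe-set summary."""

    per_se_prauc: dict[int, float]
    mean_severe: float
    sd_severe: float = float("nan")
    n_repeats: int = 1
    flagged: tuple[int, ...] = ()  # severe side effects with degenerate labels


def _ranked_prauc_over_ses(
    scores: np.ndarray,
    pos_mask: np.ndarray,
    candidate_mask: np.ndarray,
    severe: Sequence[int],
) -> tuple[dict[int, float], list[int]]:
    per_se: dict[int, float] = {}
    flagged: list[int] = []
    for j in severe:
        cand = candidate_mask[:, j]
        if not cand.any():
            flagged.append(j)
            continue
        labels = pos_mask[cand, j].astype(int)
        if labels.min() == labels.max():
            flagged.append(j)
            continue
        per_se[j] = pr_auc(scores[cand, j], labels)
    return per_se, flagged


def validation_metric(
    scores: np.ndarray, split: SplitSpec, severe: Sequence[int]
) -> float:
    """Mean severe-set PR-AUC on validation pairs (early-stopping metric).

    Candidates are the training drugs with their training-role positives
    masked out; validation-role positives are the targets.
    """
    shape = scores.shape
    val_mask = _pair_mask(split.val_pairs, shape)
    train_mask = _pair_mask(split.train_pairs, shape)
    candidate = np.zeros(shape, dtype=bool)
    candidate[split.training_drugs, :] = True
    candidate &= ~train_mask
    per_se, _ = _ranked_prauc_over_ses(scores, val_mask, candidate, severe)
    if not per_se:
        return 0.0
    return float(np.mean(list(per_se.values())))


def evaluate(
    scores: np.ndarray,
    split: SplitSpec,
    severe: Sequence[int],
    exclude_known: bool = True,
) -> EvaluationResult:
    """Rank test drugs per severe side effect against test-role labels.

    ``scores`` is the full m×n score matrix from any scorer (fitted model,
    attribute-mapped model, oracle...).  With ``exclude_known`` (default),
    a test drug's training/validation-role positives — and any cold-start
    deleted pairs — are removed from the candidate set, the standard
    holdout convention for recommender evaluation.
    """
    if len(severe) == 0:
        raise EvaluationError("severe side-effect set is empty")
    if len(split.test_pairs) == 0:
        raise EvaluationError("split has no test pairs")
    shape = scores.shape
    test_mask = _pair_mask(split.test_pairs, shape)
    candidate = np.zeros(shape, dtype=bool)
    candidate[split.test_drugs, :] = True
    if exclude_known:
        for known in (split.train_pairs, split.val_pairs, split.deleted_pairs):
            candidate &= ~_pair_mask(known, shape)
    per_se, flagged = _ranked_prauc_over_ses(scores, test_mask, candidate, severe)
    mean = float(np.mean(list(per_se.values()))) if per_se else float("nan")
    return EvaluationResult(
        per_se_prauc=per_se, mean_severe=mean, flagged=tuple(flagged)
    )


def aggregate_repeats(results: Sequence[EvaluationResult]) -> EvaluationResult:
    """Combine per-repeat results: mean and sample SD of the severe means."""
    means = np.array([r.mean_severe for r in results], dtype=float)
    pooled: dict[int, list[float]] = {}
    for r in results:
        for j, v in r.per_se_prauc.items():
            pooled.setdefault(j, []).append(v)
    return EvaluationResult(
        per_se_prauc={j: float(np.mean(v)) for j, v in pooled.items()},
        mean_severe=float(means.mean()),
        sd_severe=float(means.std(ddof=1)) if len(means) > 1 else float("nan"),
        n_repeats=len(results),
    )


def future_validation(
    scores: np.ndarray,
    A_past: AssociationMatrix,
    A_future: AssociationMatrix,
    severe: Sequence[int],
) -> EvaluationResult:
    """External validation against labels from a later reporting cutoff.

    Candidates are the pairs *negative* at the past cutoff (fewer than t
    reports then); labels are the future association matrix restricted to
    those pairs.  Side effects with no future-emerging positives are flagged
    and excluded from the mean.
    """
    if A_past.drug_labels != A_future.drug_labels or (
        A_past.se_labels != A_future.se_labels
    ):
        raise ValueError("past and future matrices must share labels")
    past = A_past.dense().astype(bool)
    future = A_future.dense().astype(bool)
    candidate = ~past
    per_se, flagged = _ranked_prauc_over_ses(scores, future, candidate, severe)
    mean = float(np.mean(list(per_se.values()))) if per_se else float("nan")
    return EvaluationResult(
        per_se_prauc=per_se, mean_severe=mean, flagged=tuple(flagged)
    )


# ---------------------------------------------------------------------------
# Split manifests (text round trip for exact replay)


def save_split(split: SplitSpec, path: str | Path) -> None:
    """Write a split as a text manifest of (role, drug, side-effect) lines."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# seed {split.seed}\n")
        for i in split.training_drugs:
            fh.write(f"training_drug\t{i}\t-\n")
        for i in split.test_drugs:
            fh.write(f"test_drug\t{i}\t-\n")
        for role, pairs in (
            ("train", split.train_pairs),
            ("val", split.val_pairs),
            ("test", split.test_pairs),
            ("deleted", split.deleted_pairs),
        ):
            for i, j in pairs:
                fh.write(f"{role}\t{i}\t{j}\n")


def load_split(path: str | Path) -> SplitSpec:
    """Read a manifest written by :func:`save_split`."""
    seed = 0
    buckets: dict[str, list] = {
        "training_drug": [], "test_drug": [],
        "train": [], "val": [], "test": [], "deleted": [],
    }
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                seed = int(line.split()[-1])
                continue
            role, i, j = line.split("\t")
            if role.endswith("_drug"):
                buckets[role].append(int(i))
            else:
                buckets[role].append((int(i), int(j)))
    empty = np.empty((0, 2), dtype=int)

    def pairs(key):
        return np.array(buckets[key], dtype=int) if buckets[key] else empty

    return SplitSpec(
        training_drugs=np.array(buckets["training_drug"], dtype=int),
        test_drugs=np.array(buckets["test_drug"], dtype=int),
        train_pairs=pairs("train"),
        val_pairs=pairs("val"),
        test_pairs=pairs("test"),
        deleted_pairs=pairs("deleted"),
        seed=seed,
    )
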