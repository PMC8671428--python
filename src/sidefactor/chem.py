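"""Drug attribute vectors from chemical structure.

Two attribute families feed the cold-start mapping:

* circular (extended-connectivity) fingerprints, 2048 bits at radius 2 by
  default, reduced to 100 dimensions with kernel PCA fitted on the training
  drugs only;
* the standard RDKit physicochemical/topological descriptor panel,
  standardized to zero mean and unit variance over the training drugs.

Both are returned as a :class:`DescriptorMatrix` whose ``kind`` tag lets the
mapping model refuse attribute matrices it was not fitted on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Descriptors import CalcMolDescriptors
from sklearn.decomposition import KernelPCA

from .models import SimilarityGraph

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

ATTR_KINDS = ("fingerprint_reduced", "descriptor_panel", "synthetic")


@dataclass
class DescriptorMatrix:
    """Per-drug attribute vectors with attribute names and a kind tag."""

    values: np.ndarray  # (m, p)
    attr_names: tuple[str, ...]
    kind: str
    drug_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ATTR_KINDS:
            raise ValueError(f"unknown attribute kind {self.kind!r}")
        if not np.isfinite(self.values).all():
            raise ValueError("attribute values must be finite")
        self.attr_names = tuple(self.attr_names)
        if len(self.attr_names) != self.values.shape[1]:
            raise ValueError("attr_names do not match attribute dimension")
        self.drug_labels = tuple(self.drug_labels)
        if self.drug_labels and len(self.drug_labels) != self.values.shape[0]:
            raise ValueError("drug_labels do not match row count")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _parse_mols(structures: Sequence[str], labels: Sequence[str] | None):
    labels = list(labels) if labels is not None else [
        f"DRUG_{i}" for i in range(len(structures))
    ]
    mols, kept, failed = [], [], []
    for label, smi in zip(labels, structures):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            failed.append(label)
        else:
            mols.append(mol)
            kept.append(label)
    if failed:
        logger.warning("unparseable structures excluded: %s", failed)
    if not mols:
        raise ValueError("no parseable structures")
    return mols, kept, failed


def compute_fingerprints(
    structures: Sequence[str],
    radius: int = 2,
    n_bits: int = 2048,
    labels: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Morgan/circular fingerprints as a binary matrix.

    Returns ``(matrix, kept_labels, failed_labels)``; rows for unparseable
    structures are excluded and their labels reported.
    """
    mols, kept, failed = _parse_mols(structures, labels)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    X = np.zeros((len(mols), n_bits), dtype=np.int8)
    for row, mol in enumerate(mols):
        fp = gen.GetFingerprint(mol)
        X[row, list(fp.GetOnBits())] = 1
    return X, kept, failed


@dataclass
class KernelPCAReducer:
    """Kernel-PCA projection fitted on training drugs and reused for all.

    Storing the fitted projector with its training-drug labels enforces the
    no-refit rule: test drugs are always transformed through the projection
    learned from training drugs alone.
    """

    target_dim: int = 100
    kernel: str = "rbf"
    gamma: float | None = None
    degree: int = 3
    train_labels: tuple[str, ...] = ()
    _kpca: KernelPCA | None = field(default=None, repr=False)

    def fit(self, X_train: np.ndarray, train_labels: Sequence[str] = ()) -> "KernelPCAReducer":
        X_train = np.asarray(X_train, dtype=float)
        if self.target_dim > min(X_train.shape):
            raise ValueError(
                f"target_dim {self.target_dim} exceeds min(rows, cols) "
                f"= {min(X_train.shape)}"
            )
        self._kpca = KernelPCA(
            n_components=self.target_dim,
            kernel=self.kernel,
            gamma=self.gamma,
            degree=self.degree,
            random_state=0,
        )
        self._kpca.fit(X_train)
        self.train_labels = tuple(train_labels)
        return self

    def transform(
        self, X: np.ndarray, drug_labels: Sequence[str] = ()
    ) -> DescriptorMatrix:
        if self._kpca is None:
            raise RuntimeError("reducer is not fitted")
        Z = self._kpca.transform(np.asarray(X, dtype=float))
        names = tuple(f"kpc_{i}" for i in range(Z.shape[1]))
        return DescriptorMatrix(Z, names, "fingerprint_reduced", tuple(drug_labels))


def reduce_kernel_pca(
    X: np.ndarray,
    target_dim: int = 100,
    kernel: str = "rbf",
    gamma: float | None = None,
    train_index: Sequence[int] | None = None,
    drug_labels: Sequence[str] = (),
) -> tuple[DescriptorMatrix, KernelPCAReducer]:
    """Fit kernel PCA on the training rows and project all rows.

    ``train_index`` selects the rows the projection is fitted on (all rows
    when omitted).  Returns the reduced attribute matrix and the fitted
    reducer for later reuse on new drugs.
    """
    X = np.asarray(X, dtype=float)
    idx = np.arange(X.shape[0]) if train_index is None else np.asarray(train_index)
    labels = tuple(drug_labels) if drug_labels else ()
    reducer = KernelPCAReducer(target_dim=target_dim, kernel=kernel, gamma=gamma)
    reducer.fit(X[idx], tuple(np.asarray(labels)[idx]) if labels else ())
    return reducer.transform(X, labels), reducer


def compute_descriptor_panel(
    structures: Sequence[str],
    labels: Sequence[str] | None = None,
    train_index: Sequence[int] | None = None,
) -> DescriptorMatrix:
    """RDKit descriptor panel, standardized over the training drugs.

    Descriptors that are constant or non-finite on the training drugs are
    dropped (logged).  Requires at least two training drugs — a standard
    deviation cannot be estimated from one.
    """
    mols, kept, _failed = _parse_mols(structures, labels)
    rows = [CalcMolDescriptors(mol) for mol in mols]
    names = sorted(rows[0].keys())
    X = np.array([[float(r[name]) for name in names] for r in rows])
    idx = np.arange(X.shape[0]) if train_index is None else np.asarray(train_index)
    if idx.size < 2:
        raise ValueError("descriptor standardization needs >= 2 training drugs")
    mu = X[idx].mean(axis=0)
    sd = X[idx].std(axis=0, ddof=0)
    finite = np.isfinite(X[idx]).all(axis=0)
    keep = finite & (sd > 0)
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        logger.info("dropping constant/non-finite descriptors: %s", dropped)
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    return DescriptorMatrix(
        Z, tuple(n for n, k in zip(names, keep) if k), "descriptor_panel", tuple(kept)
    )


def tanimoto_similarity(fingerprints: np.ndarray) -> SimilarityGraph:
    """Pairwise Tanimoto similarity of binary fingerprint rows.

    Rows with no bits set get self-similarity 1 and zero similarity to all
    others.  Feeds the graph regularizer of the fgrmf family.
    """
    X = np.asarray(fingerprints, dtype=float)
    inter = X @ X.T
    card = X.sum(axis=1)
    union = card[:, None] + card[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    np.fill_diagonal(sim, 1.0)
    sim = 0.5 * (sim + sim.T)  # kill floating-point asymmetry
    return SimilarityGraph(sim)


# ---------------------------------------------------------------------------
# Serialization


def save_descriptors(desc: DescriptorMatrix, path: str | Path) -> None:
    """Tab-separated text: header row of attribute names, one row per drug."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug\tkind=" + desc.kind + "\t" + "\t".join(desc.attr_names) + "\n")
        labels = desc.drug_labels or tuple(
            f"DRUG_{i}" for i in range(desc.values.shape[0])
        )
        for label, row in zip(labels, desc.values):
            fh.write(
                label + "\t.\t"
                + "\t".join(repr(float(v)) for v in row) + "\n"
            )


def load_descriptors(path: str | Path) -> DescriptorMatrix:
    """Inverse of :func:`save_descriptors` (lossless via float repr)."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        kind = header[1].removeprefix("kind=")
        names = tuple(header[2:])
        labels, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[2:]])
    return DescriptorMatrix(np.array(rows), names, kind, tuple(labels))


def read_smiles_file(path: str | Path) -> tuple[list[str], list[str]]:
    """Read a two-column (label, SMILES) tab-separated file."""
    labels, smiles = [], []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            label, smi = line.split("\t")[:2]
            labels.append(label)
            smiles.append(smi)
    return labels, smiles
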