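"""Synthetic spontaneous-report worlds with the structure the models assume.

The generator draws a ground-truth logistic factor model, samples binary
drug/side-effect associations from it, and converts associations into
report counts the way a reporting system would produce them: a true
association accrues ``t - 1 + Poisson(report_intensity)`` reports (so it
typically clears the occurrence threshold ``t``), while a non-association
receives a low Poisson noise floor of spurious reports.  Drug attributes
are a linear mixing of the true drug factors plus Gaussian noise, giving
the attribute-to-feature mapping an exactly recoverable target when
``attr_noise_sd = 0``.

The default priors (factor sd 2.0 per coordinate, bias mean -5 per side)
put most true probabilities near 0 or 1 with roughly 10-15% positive
pairs: a drug either does or does not cause a side effect, and the latent
structure decides which — the regime the thresholded association model
assumes.  Real spontaneous-report matrices are sparser (~1%); that regime
is reachable through ``bias_mean``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json
import warnings

import numpy as np
import scipy.sparse as sp

from .chem import DescriptorMatrix, save_descriptors, load_descriptors
from .matrices import ReportCountMatrix, save_count_matrix, load_count_matrix
from .models import FactorModel


@dataclass
class GeneratorConfig:
    """All knobs of the generative process, with the seed."""

    m: int = 200
    n: int = 300
    k_true: int = 5
    n_severe: int = 30
    threshold: int = 3
    report_intensity: float = 5.0
    false_report_rate: float = 0.1
    attr_dim: int = 20
    attr_noise_sd: float = 0.0
    factor_sd: float = 2.0
    bias_mean: float = -5.0
    bias_sd: float = 0.5
    seed: int = 0


@dataclass
class SyntheticWorld:
    """Ground truth plus everything the pipeline consumes."""

    true_model: FactorModel
    counts: ReportCountMatrix
    attrs: DescriptorMatrix
    severe: np.ndarray  # indices of designated severe side effects
    gen_cfg: GeneratorConfig
    true_assoc: np.ndarray = field(default=None, repr=False)  # (m, n) binary

    @property
    def true_probabilities(self) -> np.ndarray:
        return self.true_model.score_matrix()


def generate_world(
    m: int = 200,
    n: int = 300,
    k_true: int = 5,
    n_severe: int = 30,
    report_intensity: float = 5.0,
    attr_noise_sd: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> SyntheticWorld:
    """Sample one synthetic world; deterministic under a fixed seed.

    Degenerate draws (no positive associations at all) are resampled with a
    warning up to 10 times before raising.
    """
    cfg = GeneratorConfig(
        m=m, n=n, k_true=k_true, n_severe=n_severe,
        report_intensity=report_intensity, attr_noise_sd=attr_noise_sd,
        seed=seed, **kwargs,
    )
    if min(cfg.m, cfg.n, cfg.k_true) < 1 or cfg.n_severe > cfg.n:
        raise ValueError("invalid world dimensions")
    for attempt in range(10):
        rng = np.random.default_rng((cfg.seed, attempt))
        world = _sample(cfg, rng)
        if world is not None:
            return world
        warnings.warn("degenerate synthetic world (no positives); resampling")
    raise RuntimeError("could not generate a non-degenerate world in 10 attempts")


def _sample(cfg: GeneratorConfig, rng: np.random.Generator):
    D = rng.normal(0.0, cfg.factor_sd, (cfg.m, cfg.k_true))
    S = rng.normal(0.0, cfg.factor_sd, (cfg.n, cfg.k_true))
    b_drug = rng.normal(cfg.bias_mean, cfg.bias_sd, cfg.m)
    b_se = rng.normal(cfg.bias_mean, cfg.bias_sd, cfg.n)
    model = FactorModel(D, S, b_drug, b_se, "logistic_mf")

    p = model.score_matrix()
    z = rng.random((cfg.m, cfg.n)) < p
    if not z.any():
        return None

    reports = cfg.threshold - 1 + rng.poisson(cfg.report_intensity, (cfg.m, cfg.n))
    noise = rng.poisson(cfg.false_report_rate, (cfg.m, cfg.n))
    counts = np.where(z, reports, noise).astype(np.int64)

    drug_labels = tuple(f"DRUG_{i:04d}" for i in range(cfg.m))
    se_labels = tuple(f"SE_{j:04d}" for j in range(cfg.n))
    count_matrix = ReportCountMatrix(sp.csr_matrix(counts), drug_labels, se_labels)

    G = rng.normal(0.0, 1.0, (cfg.k_true, cfg.attr_dim))
    attrs_vals = D @ G
    if cfg.attr_noise_sd > 0:
        attrs_vals = attrs_vals + rng.normal(0.0, cfg.attr_noise_sd, attrs_vals.shape)
    attrs = DescriptorMatrix(
        attrs_vals,
        tuple(f"attr_{a}" for a in range(cfg.attr_dim)),
        "synthetic",
        drug_labels,
    )

    prevalence = z.sum(axis=0)
    severe = np.sort(np.argsort(-prevalence, kind="stable")[: cfg.n_severe])
    return SyntheticWorld(
        true_model=model,
        counts=count_matrix,
        attrs=attrs,
        severe=severe,
        gen_cfg=cfg,
        true_assoc=z.astype(np.int8),
    )


# ---------------------------------------------------------------------------
# Fixture files


def world_to_fixtures(world: SyntheticWorld, directory: str | Path) -> None:
    """Write counts, labels, attributes and the severe list as text files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_count_matrix(world.counts, directory / "counts")
    save_descriptors(world.attrs, directory / "attributes.tsv")
    (directory / "severe.txt").write_text(
        "\n".join(str(j) for j in world.severe) + "\n", encoding="utf-8"
    )
    (directory / "generator.json").write_text(
        json.dumps(asdict(world.gen_cfg), indent=1) + "\n", encoding="utf-8"
    )


def load_fixtures(directory: str | Path):
    """Read fixture files back: (counts, attrs, severe indices, config)."""
    directory = Path(directory)
    counts = load_count_matrix(directory / "counts")
    attrs = load_descriptors(directory / "attributes.tsv")
    severe = np.array(
        [int(x) for x in
         (directory / "severe.txt").read_text(encoding="utf-8").split()],
        dtype=int,
    )
    cfg = GeneratorConfig(
        **json.loads((directory / "generator.json").read_text(encoding="utf-8"))
    )
    return counts, attrs, severe, cfg
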