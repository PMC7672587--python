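"""Synthetic imbalanced screening benchmarks with a planted linear model.

Emulates the statistical shape of a small-scale virtual-screening study:
a small active pool, a roughly ten-fold larger inactive training pool,
and a test library of the same actives' kin embedded in thousands of
presumed-inactive decoys.  Descriptors are standard-normal (optionally
equicorrelated); a planted unit-norm linear model over ``k_informative``
descriptors defines latent activity; actives are displaced by
``effect_size`` descriptor-sd units along the planted direction while
inactives sit at the baseline.  Decoys are baseline compounds displaced
by ``domain_shift`` along a random direction, modeling test libraries
that fall outside the training applicability domain — the mechanism
blamed when models with excellent training statistics fail on screens.

Continuous activity is pKi = 5.5 + latent + Gaussian noise, clipped to a
plausible 4-11 range, so actives land near pKi 8-9 and inactives near
5-6 at the default effect size.  This generator tests ranking algorithms,
not chemistry: descriptor marginals, scaffold structure and
property-matched decoys are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .data import ACTIVE, INACTIVE, DescriptorDataset, write_descriptor_table
from .eoa import EOAError, LinearModel, predict_scores, screen
from .metrics import ScreeningScores

PKI_BASE = 5.5
PKI_RANGE = (4.0, 11.0)


@dataclass
class BenchmarkConfig:
    """Composition and signal parameters of a generated benchmark.

    Set-size defaults mirror a typical screening-study design: 50 actives
    with 450 inactives in both training and validation, and a test pool of
    50 actives plus 5141 decoys.
    """

    n_descriptors: int = 30
    k_informative: int = 7
    n_active_train: int = 50
    n_inactive_train: int = 450
    n_active_valid: int = 50
    n_inactive_valid: int = 450
    n_active_test: int = 50
    n_decoys: int = 5141
    effect_size: float = 3.0  # active-vs-inactive mean separation, descriptor-sd units
    noise_sd: float = 0.3  # pKi noise
    domain_shift: float = 0.0  # decoy displacement from the training distribution
    correlation: float = 0.0  # equicorrelation among descriptors
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.k_informative <= self.n_descriptors):
            raise EOAError("need 1 <= k_informative <= n_descriptors")
        counts = (
            self.n_active_train, self.n_inactive_train, self.n_active_valid,
            self.n_inactive_valid, self.n_active_test, self.n_decoys,
        )
        if min(counts) < 0:
            raise EOAError("set sizes must be non-negative")
        if self.effect_size < 0 or self.noise_sd < 0 or self.domain_shift < 0:
            raise EOAError("effect_size, noise_sd and domain_shift must be >= 0")
        if not (0 <= self.correlation < 1):
            raise EOAError("correlation must lie in [0, 1)")


@dataclass
class SyntheticBenchmark:
    """A generated dataset plus its ground truth."""

    dataset: DescriptorDataset
    planted_model: LinearModel
    true_labels: np.ndarray
    config: BenchmarkConfig = field(repr=False, default=None)


def generate_benchmark(cfg: BenchmarkConfig) -> SyntheticBenchmark:
    """Draw a benchmark; deterministic under ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_descriptors

    # planted direction: k_informative random descriptors, unit-norm weights
    informative = np.sort(rng.choice(n, size=cfg.k_informative, replace=False))
    w = rng.uniform(0.5, 1.5, size=cfg.k_informative)
    w /= np.linalg.norm(w)
    planted = LinearModel(informative, w)
    w_full = np.zeros(n)
    w_full[informative] = w

    def baseline(count: int) -> np.ndarray:
        z = rng.standard_normal((count, n))
        if cfg.correlation > 0:
            shared = rng.standard_normal((count, 1))
            z = np.sqrt(1 - cfg.correlation) * z + np.sqrt(cfg.correlation) * shared
        return z

    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    sets: list[str] = []
    has_pki: list[bool] = []

    def add(count: int, active: bool, set_name: str, decoy: bool = False) -> None:
        x = baseline(count)
        if active:
            x = x + cfg.effect_size * w_full
        if decoy and cfg.domain_shift > 0:
            g = rng.standard_normal(n)
            g /= np.linalg.norm(g)
            x = x + cfg.domain_shift * g
        blocks.append(x)
        labels.append(np.full(count, ACTIVE if active else INACTIVE, dtype=int))
        sets.extend([set_name] * count)
        has_pki.extend([not decoy] * count)

    add(cfg.n_active_train, True, "train")
    add(cfg.n_inactive_train, False, "train")
    add(cfg.n_active_valid, True, "validation")
    add(cfg.n_inactive_valid, False, "validation")
    add(cfg.n_active_test, True, "test1")
    add(cfg.n_decoys, False, "test1", decoy=True)

    X = np.vstack(blocks)
    all_labels = np.concatenate(labels)
    m = X.shape[0]
    latent = X @ w_full
    pki = PKI_BASE + latent + rng.normal(0, cfg.noise_sd, size=m)
    pki = np.clip(pki, *PKI_RANGE)
    pki[~np.array(has_pki)] = np.nan  # decoys: presumed inactive, activity unknown

    ds = DescriptorDataset(
        compound_ids=[f"cmpd{i:06d}" for i in range(m)],
        X=X,
        descriptor_names=[f"D{j:03d}" for j in range(n)],
        activity=pki,
        labels=all_labels,
        set_labels=np.array(sets, dtype=object),
    )
    return SyntheticBenchmark(
        dataset=ds, planted_model=planted, true_labels=all_labels, config=cfg
    )


def evaluate_planted(bench: SyntheticBenchmark) -> dict[str, ScreeningScores]:
    """Screen every set with the planted model: the ceiling any learner is judged against."""
    out: dict[str, ScreeningScores] = {}
    for set_name in ("train", "validation", "test1", "test2"):
        mask = bench.dataset.set_mask(set_name)
        if not mask.any():
            continue
        sub = bench.dataset.subset_rows(mask)
        L = int(sub.binary_labels().sum())
        if L == 0:
            continue
        _, summary = screen(bench.planted_model, sub, L)
        out[set_name] = summary
    return out


def planted_scores(bench: SyntheticBenchmark) -> np.ndarray:
    """Planted-model score for every compound in the benchmark."""
    return predict_scores(bench.planted_model, bench.dataset)


def save_benchmark(
    bench: SyntheticBenchmark, table_path: str | Path, truth_path: str | Path | None = None
) -> None:
    """Write the descriptor table (loader-compatible CSV/TSV) and a ground-truth sidecar."""
    write_descriptor_table(bench.dataset, table_path)
    if truth_path is not None:
        ds = bench.dataset
        doc = {
            "planted_descriptors": [
                ds.descriptor_names[j] for j in bench.planted_model.descriptor_indices
            ],
            "planted_weights": [float(v) for v in bench.planted_model.weights],
            "labels": {
                cid: int(lab) for cid, lab in zip(ds.compound_ids, bench.true_labels)
            },
        }
        Path(truth_path).write_text(yaml.safe_dump(doc, sort_keys=False))
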