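"""Enrichment Optimization Algorithm: MC/SA search for linear screening models.

The model is a k-descriptor linear scoring equation A_j = Σ_i X_ji · C_i
used only to rank compounds.  The search maximizes P, the number of known
actives within the first L places of the ranked training list (L = number
of training actives), by Metropolis Monte Carlo over descriptor identities
and weights with a saw-tooth simulated-annealing schedule: the control
parameter RT is lowered stepwise from rt_max to rt_min and then reset,
repeatedly, until the step budget is exhausted or a model attaining P = L
is found.  RT has no physical meaning; its range only sets the acceptance
rate.

Because P takes at most L+1 values, many models tie at the best count.
All of them are archived, and ties are broken by a rank-compactness score
S_Z: actives ranked beyond L and inactives ranked within the top L are
penalized by their z-score-normalized ranks (normalized independently
within the active and inactive populations to offset class imbalance);
lower S_Z is better.

One seeded generator owns every stochastic choice in a fixed order
(initialization, then per step: move type, position, value, Metropolis
draw), so identical seed and inputs give bit-identical results.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import DescriptorDataset, NormalizationParams
from .metrics import (
    MetricError,
    ScreeningScores,
    actives_in_top_L,
    rank_order,
    screening_scores,
)

#: archive deduplication: same descriptor set, weights within this tolerance
WEIGHT_DEDUP_TOL = 1e-9


class EOAError(ValueError):
    """Raised for invalid search configuration or inputs."""


# ---------------------------------------------------------------------------
# model and configuration
# ---------------------------------------------------------------------------

@dataclass
class LinearModel:
    """A k-descriptor subset with k weights; scores are X[:, idx] @ weights."""

    descriptor_indices: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.descriptor_indices = np.asarray(self.descriptor_indices, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.descriptor_indices.ndim != 1 or self.descriptor_indices.size < 1:
            raise EOAError("model needs at least one descriptor")
        if self.weights.shape != self.descriptor_indices.shape:
            raise EOAError("weights and descriptor_indices must have equal length")
        if len(set(self.descriptor_indices.tolist())) != self.descriptor_indices.size:
            raise EOAError("descriptor indices must be distinct")
        if not np.all(np.isfinite(self.weights)):
            raise EOAError("weights must be finite")

    @property
    def k(self) -> int:
        return self.descriptor_indices.size

    def canonical_key(self) -> tuple:
        """Order-independent key for archive deduplication."""
        order = np.argsort(self.descriptor_indices)
        return (
            tuple(self.descriptor_indices[order].tolist()),
            tuple(np.round(self.weights[order] / WEIGHT_DEDUP_TOL).astype(np.int64).tolist()),
        )


@dataclass
class AnnealConfig:
    """Saw-tooth schedule and move-proposal parameters of the MC/SA search.

    Defaults follow the standard protocol: RT lowered linearly from 0.3
    (alternative preset 0.6) to 0.01 in 0.01 decrements, 300 MC steps per
    RT level, one million steps in total.
    """

    rt_max: float = 0.3
    rt_min: float = 0.01
    rt_step: float = 0.01
    steps_per_interval: int = 300
    total_steps: int = 1_000_000
    delta_j_max: float = 0.5
    p_swap: float = 0.25
    weight_init_range: float = 1.0
    perturb_all_weights: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.rt_min <= self.rt_max):
            raise EOAError("need 0 < rt_min <= rt_max")
        if self.rt_step <= 0:
            raise EOAError("rt_step must be positive")
        if self.steps_per_interval < 1 or self.total_steps < 1:
            raise EOAError("step counts must be positive")
        if not (0 <= self.p_swap <= 1):
            raise EOAError("p_swap must lie in [0, 1]")
        if self.delta_j_max <= 0 or self.weight_init_range <= 0:
            raise EOAError("delta_j_max and weight_init_range must be positive")


@dataclass
class SolutionArchive:
    """All distinct models attaining the running best objective value."""

    p_best: int = -1
    solutions: list[LinearModel] = field(default_factory=list)
    tie_scores: list[float] = field(default_factory=list)
    _keys: set = field(default_factory=set, repr=False)

    def offer(self, model: LinearModel, p: int) -> None:
        """Record ``model`` with objective ``p``; resets on improvement."""
        if p > self.p_best:
            self.p_best = p
            self.solutions = []
            self._keys = set()
        if p == self.p_best:
            key = model.canonical_key()
            if key not in self._keys:
                self._keys.add(key)
                self.solutions.append(
                    LinearModel(
                        model.descriptor_indices.copy(), model.weights.copy()
                    )
                )


@dataclass
class EOAResult:
    """Outcome of one MC/SA run."""

    archive: SolutionArchive
    best_model: LinearModel
    trajectory: pd.DataFrame  # columns: step, rt, p_current, p_best, acceptance_rate
    terminated_early: bool
    L: int


# ---------------------------------------------------------------------------
# search primitives
# ---------------------------------------------------------------------------

def predict_scores(model: LinearModel, ds: DescriptorDataset) -> np.ndarray:
    """Per-compound predicted activity A_j = Σ_i X_ji · C_i."""
    if model.descriptor_indices.max() >= ds.n_descriptors:
        raise EOAError("model descriptor index out of range for dataset")
    return ds.X[:, model.descriptor_indices] @ model.weights


def objective_count(scores: np.ndarray, labels: np.ndarray, L: int) -> int:
    """The objective P: actives within the first L places of the ranked list."""
    return actives_in_top_L(scores, labels, L)


def propose_move(
    model: LinearModel,
    rng: np.random.Generator,
    cfg: AnnealConfig,
    n_descriptors: int,
) -> LinearModel:
    """One elementary move; k never changes.

    With probability ``p_swap`` (and if spare descriptors exist) a uniformly
    chosen position is given a uniformly drawn replacement descriptor not
    already in the model, with a fresh weight drawn from the initialization
    range.  Otherwise one weight (or, with ``perturb_all_weights``, every
    weight) is shifted by ±ΔJ with ΔJ ~ Uniform(0, delta_j_max) and an
    equiprobable sign.
    """
    idx = model.descriptor_indices.copy()
    w = model.weights.copy()
    k = idx.size
    swap_possible = n_descriptors > k
    if rng.random() < cfg.p_swap and swap_possible:
        pos = int(rng.integers(k))
        in_model = np.zeros(n_descriptors, dtype=bool)
        in_model[idx] = True
        candidates = np.flatnonzero(~in_model)
        idx[pos] = int(candidates[rng.integers(candidates.size)])
        w[pos] = rng.uniform(-cfg.weight_init_range, cfg.weight_init_range)
    else:
        positions = range(k) if cfg.perturb_all_weights else [int(rng.integers(k))]
        for pos in positions:
            delta = rng.uniform(0, cfg.delta_j_max)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            w[pos] += sign * delta
    return LinearModel(idx, w)


def metropolis_accept(p1: float, p2: float, rt: float, r: float) -> bool:
    """Accept when improving; otherwise when r < exp(-(p1 - p2)/rt)."""
    if rt <= 0:
        raise EOAError("rt must be positive")
    if p2 > p1:
        return True
    return r < math.exp(-(p1 - p2) / rt)


def anneal_schedule(cfg: AnnealConfig) -> list[tuple[float, int]]:
    """Expand the saw-tooth schedule into (rt, n_steps) intervals.

    One cycle walks RT from rt_max down to rt_min in rt_step decrements
    (endpoints included), steps_per_interval MC steps per level; cycles
    repeat until the cumulative count reaches total_steps, truncating the
    final interval.
    """
    n_levels = int(round((cfg.rt_max - cfg.rt_min) / cfg.rt_step)) + 1
    levels = [round(cfg.rt_max - i * cfg.rt_step, 12) for i in range(n_levels)]
    if levels[-1] <= 0:
        raise EOAError("schedule reaches non-positive rt; adjust rt_min/rt_step")
    out: list[tuple[float, int]] = []
    remaining = cfg.total_steps
    while remaining > 0:
        for rt in levels:
            n = min(cfg.steps_per_interval, remaining)
            out.append((rt, n))
            remaining -= n
            if remaining == 0:
                break
    return out


def tie_break_score(
    model: LinearModel,
    ds: DescriptorDataset,
    labels: np.ndarray,
    L: int,
) -> float:
    """Rank-compactness score S_Z; lower is better.

    Rank all compounds (1 = best).  Z-score the active ranks within the
    active population and the inactive ranks within the inactive population
    (sample sd), then S_active = Σ normalized ranks of actives placed
    beyond L, S_inactive = Σ normalized ranks of inactives placed within
    the top L, and S_Z = S_active − S_inactive.  A perfect ranking has both
    sums empty and scores exactly 0.  Misplaced inactives near the top have
    strongly negative normalized ranks, so subtracting S_inactive penalizes
    them.
    """
    labels = np.asarray(labels, dtype=int)
    scores = predict_scores(model, ds)
    order = rank_order(scores)
    ranks = np.empty(scores.size, dtype=float)
    ranks[order] = np.arange(1, scores.size + 1)
    active_ranks = ranks[labels == 1]
    inactive_ranks = ranks[labels == 0]
    if active_ranks.size < 2 or inactive_ranks.size < 2:
        raise MetricError("tie-break score needs at least 2 actives and 2 inactives")
    za = (active_ranks - active_ranks.mean()) / active_ranks.std(ddof=1)
    zi = (inactive_ranks - inactive_ranks.mean()) / inactive_ranks.std(ddof=1)
    s_active = float(za[active_ranks > L].sum())
    s_inactive = float(zi[inactive_ranks <= L].sum())
    return s_active - s_inactive


# ---------------------------------------------------------------------------
# the full search
# ---------------------------------------------------------------------------

def run_eoa(
    ds: DescriptorDataset,
    k: int,
    cfg: AnnealConfig,
    labels: np.ndarray | None = None,
) -> EOAResult:
    """Search descriptor identities and weights maximizing the top-L count.

    ``ds`` is the (already normalized) training subset; ``labels`` defaults
    to the dataset's binary labels.  L is the number of actives.  The
    search stops at ``cfg.total_steps`` or as soon as a model attaining
    P = L is found; every distinct model tying the running best count is
    archived, and the returned best model minimizes the S_Z tie-break.
    """
    labels = ds.binary_labels() if labels is None else np.asarray(labels, dtype=int)
    if labels.size != ds.n_compounds:
        raise EOAError("labels length does not match dataset")
    L = int(labels.sum())
    if L == 0:
        raise EOAError("no active compounds in the training set")
    if k > ds.n_descriptors:
        raise EOAError(f"k={k} exceeds the {ds.n_descriptors} available descriptors")
    n_inactive = labels.size - L
    if n_inactive > 10 * L:
        warnings.warn(
            f"active:inactive ratio 1:{n_inactive / L:.1f} exceeds the recommended "
            "1:10 imbalance limit",
            stacklevel=2,
        )

    rng = np.random.default_rng(cfg.seed)
    idx = rng.choice(ds.n_descriptors, size=k, replace=False)
    w = rng.uniform(-cfg.weight_init_range, cfg.weight_init_range, size=k)
    current = LinearModel(idx, w)
    p_current = objective_count(predict_scores(current, ds), labels, L)

    archive = SolutionArchive()
    archive.offer(current, p_current)
    trajectory_rows: list[tuple[int, float, int, int, float]] = []
    step = 0
    done = archive.p_best == L

    for rt, n_steps in anneal_schedule(cfg):
        if done:
            break
        accepted = 0
        steps_run = 0
        for _ in range(n_steps):
            step += 1
            steps_run += 1
            candidate = propose_move(current, rng, cfg, ds.n_descriptors)
            p_new = objective_count(predict_scores(candidate, ds), labels, L)
            if p_new > p_current:
                accept = True
            else:
                accept = metropolis_accept(p_current, p_new, rt, rng.random())
            if accept:
                current, p_current = candidate, p_new
                accepted += 1
                archive.offer(current, p_current)
                if archive.p_best == L:
                    done = True
                    break
        trajectory_rows.append(
            (step, rt, p_current, archive.p_best, accepted / max(steps_run, 1))
        )

    # tie-break among archived solutions
    tie_scores = [tie_break_score(m, ds, labels, L) for m in archive.solutions]
    archive.tie_scores = tie_scores
    best_model = archive.solutions[int(np.argmin(tie_scores))]

    trajectory = pd.DataFrame(
        trajectory_rows,
        columns=["step", "rt", "p_current", "p_best", "acceptance_rate"],
    )
    return EOAResult(
        archive=archive,
        best_model=best_model,
        trajectory=trajectory,
        terminated_early=done,
        L=L,
    )


def screen(
    model: LinearModel,
    ds: DescriptorDataset,
    L: int,
) -> tuple[pd.DataFrame, ScreeningScores | None]:
    """Rank a compound set by predicted activity and evaluate the top-L cut.

    Returns the ranked list (rank, compound_id, score, label when known)
    and, when every compound carries a binary label, the single-cut
    screening scores; otherwise the scores entry is ``None``.
    """
    scores = predict_scores(model, ds)
    order = rank_order(scores)
    have_labels = ds.labels is not None and not np.any(ds.labels == -1)
    ranked = pd.DataFrame(
        {
            "rank": np.arange(1, ds.n_compounds + 1),
            "compound_id": [ds.compound_ids[i] for i in order],
            "score": scores[order],
        }
    )
    summary = None
    if have_labels:
        ranked["label"] = ds.labels[order]
        if int(ds.labels.sum()) > 0:  # metrics need at least one active
            summary = screening_scores(scores, ds.labels, L)
    return ranked, summary


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(
    path: str | Path,
    model: LinearModel,
    descriptor_names: list[str],
    norm_params: NormalizationParams | None = None,
    meta: dict | None = None,
) -> None:
    """Write a scoring equation (and its provenance) as structured text."""
    doc: dict = {
        "descriptors": [descriptor_names[j] for j in model.descriptor_indices],
        "weights": [float(v) for v in model.weights],
        "k": int(model.k),
    }
    if norm_params is not None:
        doc["normalization"] = {
            name: {"mean": float(m), "sd": float(s)}
            for name, m, s in zip(
                norm_params.descriptor_names, norm_params.mean, norm_params.sd
            )
        }
    if meta:
        doc["meta"] = meta
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_model(
    path: str | Path, descriptor_names: list[str]
) -> tuple[LinearModel, NormalizationParams | None, dict]:
    """Load a saved scoring equation, resolving names against ``descriptor_names``."""
    doc = yaml.safe_load(Path(path).read_text())
    name_to_idx = {n: j for j, n in enumerate(descriptor_names)}
    missing = [n for n in doc["descriptors"] if n not in name_to_idx]
    if missing:
        raise EOAError(f"table lacks model descriptors: {', '.join(missing)}")
    model = LinearModel(
        np.array([name_to_idx[n] for n in doc["descriptors"]]),
        np.array(doc["weights"], dtype=float),
    )
    norm = None
    if "normalization" in doc:
        names = list(doc["normalization"])
        norm = NormalizationParams(
            descriptor_names=names,
            mean=np.array([doc["normalization"][n]["mean"] for n in names]),
            sd=np.array([doc["normalization"][n]["sd"] for n in names]),
        )
    return model, norm, doc.get("meta", {})
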