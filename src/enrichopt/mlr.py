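"""Baseline: descriptor-subset search minimizing the OLS regression sd.

The conventional way to derive a linear QSAR equation is multiple linear
regression coupled with stochastic feature selection, choosing the
descriptor subset that minimizes the residual standard deviation of the
fit to continuous activity.  This module reuses the same MC/SA engine as
the enrichment search, but moves change descriptor identities only (the
coefficients always come from an exact least-squares fit, never from
sampling) and the Metropolis energy is the change in residual sd scaled
by ``sd_scale`` so that acceptance rates land in the same regime as the
integer-valued enrichment objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DescriptorDataset
from .eoa import AnnealConfig, EOAError, anneal_schedule, metropolis_accept
from .metrics import r_squared


@dataclass
class MLRModel:
    """OLS fit on a descriptor subset: y ≈ intercept + X[:, idx] @ coefs."""

    descriptor_indices: np.ndarray
    coefficients: np.ndarray  # length k+1; [0] is the intercept
    residual_sd: float
    r2_train: float

    @property
    def k(self) -> int:
        return self.descriptor_indices.size

    def predict(self, ds: DescriptorDataset) -> np.ndarray:
        return self.coefficients[0] + ds.X[:, self.descriptor_indices] @ self.coefficients[1:]


def ols_fit(ds: DescriptorDataset, subset: np.ndarray) -> MLRModel:
    """Exact least-squares fit of continuous activity on a descriptor subset.

    residual_sd = sqrt(RSS / (n - k - 1)); a rank-deficient design raises,
    naming the descriptors involved.
    """
    subset = np.asarray(subset, dtype=int)
    if ds.activity is None or np.any(np.isnan(ds.activity)):
        raise EOAError("OLS baseline needs continuous activity for every compound")
    y = ds.activity
    k = subset.size
    n = ds.n_compounds
    if n < k + 2:
        raise EOAError(f"need at least k+2={k + 2} compounds, have {n}")
    design = np.column_stack([np.ones(n), ds.X[:, subset]])
    coefs, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < k + 1:
        names = ", ".join(ds.descriptor_names[j] for j in subset)
        raise EOAError(f"rank-deficient design (collinear descriptors among: {names})")
    fitted = design @ coefs
    rss = float(np.sum((fitted - y) ** 2))
    return MLRModel(
        descriptor_indices=subset,
        coefficients=coefs,
        residual_sd=float(np.sqrt(rss / (n - k - 1))),
        r2_train=r_squared(y, fitted),
    )


def run_mlr_sd_search(
    ds: DescriptorDataset,
    k: int,
    cfg: AnnealConfig,
    sd_scale: float | None = None,
) -> tuple[MLRModel, pd.DataFrame]:
    """MC/SA over descriptor subsets minimizing the OLS residual sd.

    Each move swaps one subset member for a descriptor outside the subset;
    the proposal is accepted when the refit sd improves, otherwise by the
    Metropolis criterion with ΔE = (sd_new − sd_old) / sd_scale.
    ``sd_scale`` defaults to one tenth of the training-activity sd.
    Returns the lowest-sd model visited and the per-interval trajectory.
    Rank-deficient proposals are rejected outright.
    """
    if k > ds.n_descriptors:
        raise EOAError(f"k={k} exceeds the {ds.n_descriptors} available descriptors")
    if ds.activity is None or np.any(np.isnan(ds.activity)):
        raise EOAError("sd search needs continuous activity for every compound")
    if sd_scale is None:
        sd_scale = float(np.std(ds.activity, ddof=1)) / 10.0
    if sd_scale <= 0:
        raise EOAError("sd_scale must be positive")

    rng = np.random.default_rng(cfg.seed)
    n_desc = ds.n_descriptors
    subset = np.sort(rng.choice(n_desc, size=k, replace=False))
    current = ols_fit(ds, subset)
    best = current

    rows: list[tuple[int, float, float, float, float]] = []
    step = 0
    if n_desc == k:  # single possible subset: nothing to search
        rows.append((0, cfg.rt_max, current.residual_sd, best.residual_sd, 0.0))
        return best, pd.DataFrame(
            rows, columns=["step", "rt", "sd_current", "sd_best", "acceptance_rate"]
        )

    for rt, n_steps in anneal_schedule(cfg):
        accepted = 0
        for _ in range(n_steps):
            step += 1
            pos = int(rng.integers(k))
            in_subset = np.zeros(n_desc, dtype=bool)
            in_subset[current.descriptor_indices] = True
            candidates = np.flatnonzero(~in_subset)
            new_subset = current.descriptor_indices.copy()
            new_subset[pos] = int(candidates[rng.integers(candidates.size)])
            try:
                proposal = ols_fit(ds, new_subset)
            except EOAError:
                continue  # collinear proposal: reject, keep current
            if proposal.residual_sd < current.residual_sd:
                accept = True
            else:
                # minimization: lower sd plays the role of higher P
                accept = metropolis_accept(
                    -current.residual_sd / sd_scale,
                    -proposal.residual_sd / sd_scale,
                    rt,
                    rng.random(),
                )
            if accept:
                current = proposal
                accepted += 1
                if current.residual_sd < best.residual_sd:
                    best = current
        rows.append(
            (step, rt, current.residual_sd, best.residual_sd, accepted / n_steps)
        )

    trajectory = pd.DataFrame(
        rows, columns=["step", "rt", "sd_current", "sd_best", "acceptance_rate"]
    )
    return best, trajectory
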