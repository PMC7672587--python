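"""Model-evaluation metrics for regression QSAR and ranked virtual screens.

Regression quality is measured by R² on the training fit and by the three
external-validation coefficients Q²F1, Q²F2, Q²F3, which differ in the
reference mean and normalization of the predictive residual sum of squares
(PRESS).  Screening quality is measured at a single early-recognition cut:
with L actives in a library of size M, count the actives among the first L
places of the score-ranked list and convert the count to an enrichment
factor relative to random ranking.  A ranked screen binarized at the same
cut yields a confusion matrix and the Matthews correlation coefficient.

Ranking tie rule used everywhere: stable descending sort, equal scores
ordered by ascending input index — deterministic and seed-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats


class MetricError(ValueError):
    """Raised for metric preconditions that cannot be evaluated."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as printed screening tables do.

    Python's built-in banker's rounding turns 1286.25 into 1286.2; reported
    enrichment tables print 1286.3.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# regression metrics
# ---------------------------------------------------------------------------

@dataclass
class RegressionScores:
    """R² and external Q² coefficients; NaN marks an undefined metric."""

    r2: float = float("nan")
    qf1: float = float("nan")
    qf2: float = float("nan")
    qf3: float = float("nan")


def r_squared(y_obs: np.ndarray, y_fit: np.ndarray) -> float:
    """Coefficient of determination, 1 - RSS/SS."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_fit = np.asarray(y_fit, dtype=float)
    if y_obs.shape != y_fit.shape or y_obs.size < 2:
        raise MetricError("y_obs and y_fit must be equal-length vectors, length >= 2")
    ss = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if ss == 0:
        raise MetricError("y_obs is constant; R2 undefined (zero total sum of squares)")
    rss = float(np.sum((y_fit - y_obs) ** 2))
    return 1.0 - rss / ss


def q_external(
    y_obs_ext: np.ndarray,
    y_pred_ext: np.ndarray,
    y_train: np.ndarray,
) -> RegressionScores:
    """External-validation Q²F1 / Q²F2 / Q²F3.

    With PRESS = Σ(y_pred − y)² over the external set,

    - Q²F1 normalizes PRESS by the external deviations about the training
      mean,
    - Q²F2 by the external deviations about the external mean,
    - Q²F3 compares per-compound PRESS with the per-compound training
      variance about the training mean.

    A zero denominator leaves that coefficient NaN; the others are still
    returned.
    """
    y_obs_ext = np.asarray(y_obs_ext, dtype=float)
    y_pred_ext = np.asarray(y_pred_ext, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if y_obs_ext.shape != y_pred_ext.shape or y_obs_ext.size < 2:
        raise MetricError("external vectors must be equal length >= 2")
    if y_train.size < 2:
        raise MetricError("training vector must have length >= 2")
    n_ext, n_tr = y_obs_ext.size, y_train.size
    press = float(np.sum((y_pred_ext - y_obs_ext) ** 2))
    mean_tr = y_train.mean()
    ss_ext_tr = float(np.sum((y_obs_ext - mean_tr) ** 2))
    ss_ext = float(np.sum((y_obs_ext - y_obs_ext.mean()) ** 2))
    ss_tr = float(np.sum((y_train - mean_tr) ** 2))
    out = RegressionScores()
    if ss_ext_tr > 0:
        out.qf1 = 1.0 - press / ss_ext_tr
    if ss_ext > 0:
        out.qf2 = 1.0 - press / ss_ext
    if ss_tr > 0:
        out.qf3 = 1.0 - (press / n_ext) / (ss_tr / n_tr)
    return out


# ---------------------------------------------------------------------------
# ranking and screening metrics
# ---------------------------------------------------------------------------

def rank_order(scores: np.ndarray) -> np.ndarray:
    """Indices sorted by descending score; ties by ascending input index."""
    scores = np.asarray(scores, dtype=float)
    return np.argsort(-scores, kind="stable")


def actives_in_top_L(scores: np.ndarray, labels: np.ndarray, L: int) -> int:
    """Count actives among the first L places of the score-ranked list."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if L < 1 or L > scores.size:
        raise MetricError(f"L={L} outside [1, {scores.size}]")
    if labels.shape != scores.shape:
        raise MetricError("scores and labels must have the same length")
    order = rank_order(scores)
    return int(labels[order[:L]].sum())


def enrichment_at_L(
    actives_in_top: int, L: int, n_active_lib: int, lib_size: int
) -> float:
    """Enrichment factor at the top-L cut.

    (fraction of top-L places held by actives) / (fraction of the library
    that is active) = (actives_in_top / L) / (n_active_lib / lib_size).
    """
    if n_active_lib < 1:
        raise MetricError("library contains no actives; enrichment undefined")
    if lib_size < L:
        raise MetricError("library smaller than the ranking cut L")
    if not (0 <= actives_in_top <= min(L, n_active_lib)):
        raise MetricError("actives_in_top outside [0, min(L, n_active_lib)]")
    return (actives_in_top / L) / (n_active_lib / lib_size)


def max_enrichment(n_active_lib: int, lib_size: int) -> float:
    """Maximal attainable enrichment: all top-L places active at L = n_active_lib."""
    if not (1 <= n_active_lib <= lib_size):
        raise MetricError("need 1 <= n_active_lib <= lib_size")
    return lib_size / n_active_lib


@dataclass
class ConfusionCounts:
    """Binary confusion counts at a classification cut."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise MetricError("confusion counts must be non-negative")


def confusion_at_top_L(
    scores: np.ndarray, labels: np.ndarray, L: int
) -> ConfusionCounts:
    """Binarize a ranking at the top-L cut: top L predicted active."""
    labels = np.asarray(labels, dtype=int)
    tp = actives_in_top_L(scores, labels, L)
    n_active = int(labels.sum())
    n = labels.size
    return ConfusionCounts(tp=tp, fp=L - tp, fn=n_active - tp, tn=n - L - (n_active - tp))


def confusion_at_threshold(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> ConfusionCounts:
    """Confusion counts with ``score >= threshold`` predicted active."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    act = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & act)),
        fp=int(np.sum(pred & ~act)),
        fn=int(np.sum(~pred & act)),
        tn=int(np.sum(~pred & ~act)),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    tp, tn, fp, fn = float(c.tp), float(c.tn), float(c.fp), float(c.fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def pearson_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Squared Pearson correlation plus OLS slope/intercept of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise MetricError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0:
        raise MetricError("x is constant; correlation undefined")
    res = stats.linregress(x, y)
    return float(res.rvalue**2), float(res.slope), float(res.intercept)


# ---------------------------------------------------------------------------
# per-(model, set) report
# ---------------------------------------------------------------------------

@dataclass
class ScreeningScores:
    """Single-cut screening summary for one model on one compound set."""

    L: int
    actives_in_top_L: int
    enrichment: float
    max_enrichment: float
    mcc: float
    confusion: ConfusionCounts


def screening_scores(scores: np.ndarray, labels: np.ndarray, L: int) -> ScreeningScores:
    """Evaluate a ranked screen at the top-L cut (L = #library actives by default use)."""
    labels = np.asarray(labels, dtype=int)
    n_active = int(labels.sum())
    if n_active < 1:
        raise MetricError("no actives in the evaluated set")
    conf = confusion_at_top_L(scores, labels, L)
    return ScreeningScores(
        L=L,
        actives_in_top_L=conf.tp,
        enrichment=enrichment_at_L(conf.tp, L, n_active, labels.size),
        max_enrichment=max_enrichment(n_active, labels.size),
        mcc=mcc(conf),
        confusion=conf,
    )


REPORT_COLUMNS = [
    "model_id", "set", "L", "actives_in_top_L", "enrichment", "max_enrichment",
    "r2", "qf1", "qf2", "qf3", "tp", "tn", "fp", "fn", "mcc",
]


def report_row(
    model_id: str,
    set_name: str,
    screen: ScreeningScores | None = None,
    regression: RegressionScores | None = None,
) -> dict:
    """One MetricReport row (see REPORT_COLUMNS); display rounding applied.

    Enrichment is rounded to one decimal, MCC and the regression
    coefficients to two, matching conventional reporting precision; callers
    needing full precision use the score objects directly.
    """
    row = dict.fromkeys(REPORT_COLUMNS, "")
    row["model_id"], row["set"] = model_id, set_name
    if screen is not None:
        row.update(
            L=screen.L,
            actives_in_top_L=screen.actives_in_top_L,
            enrichment=round_half_up(screen.enrichment, 1),
            max_enrichment=round_half_up(screen.max_enrichment, 1),
            tp=screen.confusion.tp,
            tn=screen.confusion.tn,
            fp=screen.confusion.fp,
            fn=screen.confusion.fn,
            mcc=round_half_up(screen.mcc, 2),
        )
    if regression is not None:
        for key in ("r2", "qf1", "qf2", "qf3"):
            val = getattr(regression, key)
            if not np.isnan(val):
                row[key] = round_half_up(val, 2)
    return row
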