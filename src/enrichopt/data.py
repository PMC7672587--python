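"""Descriptor-table container, preprocessing and delimited-text I/O.

A :class:`DescriptorDataset` holds an M x N matrix of molecular descriptor
values together with per-compound activity annotations (continuous pKi
values and/or binary active/inactive labels) and a set-membership tag
(train / validation / test1 / test2).  Preprocessing follows standard QSAR
practice: drop constant, nearly-constant and pairwise-correlated
descriptors, then z-score the survivors.  Filter statistics and the
z-scoring parameters are computed on the training subset only and frozen,
so external compounds can be screened without information leakage.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

SET_LABELS = ("train", "validation", "test1", "test2")

#: label codes used in DescriptorDataset.labels
INACTIVE, ACTIVE, UNLABELED = 0, 1, -1


class DataError(ValueError):
    """Raised for malformed descriptor tables or invalid preprocessing input."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DescriptorDataset:
    """Compounds x descriptors matrix with activity annotations.

    Parameters
    ----------
    compound_ids
        Unique compound identifiers, length M.
    X
        Descriptor matrix, shape (M, N), float64, no missing values.
    descriptor_names
        Unique descriptor names, length N.
    activity
        Continuous activity (pKi) per compound; NaN where unknown. ``None``
        when no compound has a continuous value.
    labels
        Binary label per compound: 1 active, 0 inactive, -1 unknown.
        ``None`` when no compound is labeled.
    set_labels
        Per-compound set tag from ``SET_LABELS``, or ``""`` when unassigned.
    """

    compound_ids: list[str]
    X: np.ndarray
    descriptor_names: list[str]
    activity: np.ndarray | None = None
    labels: np.ndarray | None = None
    set_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise DataError("descriptor matrix must be 2-D")
        m, n = self.X.shape
        if m < 2 or n < 1:
            raise DataError(f"need at least 2 compounds and 1 descriptor, got {m}x{n}")
        if len(self.compound_ids) != m:
            raise DataError("compound_ids length does not match matrix rows")
        if len(self.descriptor_names) != n:
            raise DataError("descriptor_names length does not match matrix columns")
        dup = _first_duplicate(self.compound_ids)
        if dup is not None:
            raise DataError(f"duplicate compound id {dup!r}")
        dup = _first_duplicate(self.descriptor_names)
        if dup is not None:
            raise DataError(f"duplicate descriptor name {dup!r}")
        if not np.all(np.isfinite(self.X)):
            i, j = np.argwhere(~np.isfinite(self.X))[0]
            raise DataError(
                f"non-finite descriptor value for compound {self.compound_ids[i]!r}, "
                f"descriptor {self.descriptor_names[j]!r}"
            )
        if self.activity is not None:
            self.activity = np.asarray(self.activity, dtype=float)
            if self.activity.shape != (m,):
                raise DataError("activity length does not match compound count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (m,):
                raise DataError("labels length does not match compound count")
            bad = set(np.unique(self.labels)) - {ACTIVE, INACTIVE, UNLABELED}
            if bad:
                raise DataError(f"invalid label codes {sorted(bad)}")
        if self.set_labels is None:
            self.set_labels = np.array([""] * m, dtype=object)
        else:
            self.set_labels = np.asarray(self.set_labels, dtype=object)
            if self.set_labels.shape != (m,):
                raise DataError("set_labels length does not match compound count")
            bad = set(np.unique(self.set_labels)) - set(SET_LABELS) - {""}
            if bad:
                raise DataError(f"unknown set labels {sorted(bad)}; expected {SET_LABELS}")
        # every compound needs a continuous activity or a binary label
        has_act = (
            ~np.isnan(self.activity) if self.activity is not None else np.zeros(m, bool)
        )
        has_lab = (
            self.labels != UNLABELED if self.labels is not None else np.zeros(m, bool)
        )
        missing = ~(has_act | has_lab)
        if missing.any():
            cid = self.compound_ids[int(np.argmax(missing))]
            raise DataError(f"compound {cid!r} has neither activity nor label")

    # -- basic views --------------------------------------------------------

    @property
    def n_compounds(self) -> int:
        return self.X.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.X.shape[1]

    def set_mask(self, set_label: str) -> np.ndarray:
        return np.asarray(self.set_labels == set_label)

    def subset_rows(self, mask: np.ndarray) -> "DescriptorDataset":
        mask = np.asarray(mask, dtype=bool)
        return DescriptorDataset(
            compound_ids=[c for c, keep in zip(self.compound_ids, mask) if keep],
            X=self.X[mask],
            descriptor_names=list(self.descriptor_names),
            activity=self.activity[mask] if self.activity is not None else None,
            labels=self.labels[mask] if self.labels is not None else None,
            set_labels=self.set_labels[mask],
        )

    def subset(self, set_label: str) -> "DescriptorDataset":
        """Rows belonging to one set (train / validation / test1 / test2)."""
        return self.subset_rows(self.set_mask(set_label))

    def select_descriptors(self, keep: np.ndarray) -> "DescriptorDataset":
        keep = np.asarray(keep)
        return replace(
            self,
            X=self.X[:, keep],
            descriptor_names=[self.descriptor_names[j] for j in keep],
        )

    def binary_labels(self) -> np.ndarray:
        """0/1 label vector; compounds without a binary label raise."""
        if self.labels is None or np.any(self.labels == UNLABELED):
            raise DataError("dataset has unlabeled compounds; binary labels required")
        return self.labels.astype(int)


@dataclass
class PruneReport:
    """Which descriptors the preprocessing filter removed, and why."""

    removed_constant: list[str] = field(default_factory=list)
    removed_near_constant: list[str] = field(default_factory=list)
    removed_correlated: list[tuple[str, str, float]] = field(default_factory=list)
    n_remaining: int = 0

    @property
    def n_removed(self) -> int:
        return (
            len(self.removed_constant)
            + len(self.removed_near_constant)
            + len(self.removed_correlated)
        )

    def to_text(self) -> str:
        lines = [f"n_remaining: {self.n_remaining}"]
        lines.append("removed_constant: " + ", ".join(self.removed_constant))
        lines.append("removed_near_constant: " + ", ".join(self.removed_near_constant))
        for kept, dropped, r2 in self.removed_correlated:
            lines.append(f"removed_correlated: {dropped} (r2={r2:.4f} with {kept})")
        return "\n".join(lines) + "\n"


@dataclass
class NormalizationParams:
    """Frozen per-descriptor mean/sd used for z-scoring (training statistics)."""

    descriptor_names: list[str]
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.descriptor_names) == self.mean.size == self.sd.size):
            raise DataError("normalization parameter lengths disagree")
        if np.any(self.sd <= 0):
            name = self.descriptor_names[int(np.argmax(self.sd <= 0))]
            raise DataError(f"non-positive standard deviation for descriptor {name!r}")

    def to_text(self) -> str:
        lines = ["descriptor\tmean\tsd"]
        for name, m, s in zip(self.descriptor_names, self.mean, self.sd):
            lines.append(f"{name}\t{float(m)!r}\t{float(s)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "NormalizationParams":
        rows = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
        return cls(
            descriptor_names=[r[0] for r in rows],
            mean=np.array([float(r[1]) for r in rows]),
            sd=np.array([float(r[2]) for r in rows]),
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_descriptor_table(
    path: str | Path | io.TextIOBase,
    activity_column: str | None = None,
    label_column: str | None = None,
    set_column: str | None = None,
    active_token: str = "active",
    inactive_token: str = "inactive",
) -> DescriptorDataset:
    """Read a delimited descriptor table into a validated dataset.

    The file must have a header row and one row per compound, the compound
    id in the first column.  The delimiter is inferred from the extension
    (``.tsv``/``.tab`` -> tab, otherwise comma).  All columns other than the
    id and the named annotation columns are treated as numeric descriptors;
    a non-numeric or empty descriptor cell fails the load, naming the
    offending row and column.
    """
    sep = "\t" if str(getattr(path, "name", path)).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise DataError("table needs an id column and at least one descriptor")
    id_col = df.columns[0]
    compound_ids = [str(v) for v in df[id_col]]
    annot = {c for c in (activity_column, label_column, set_column) if c}
    for c in annot:
        if c not in df.columns:
            raise DataError(f"column {c!r} not found in table")
    desc_cols = [c for c in df.columns[1:] if c not in annot]
    if not desc_cols:
        raise DataError("no descriptor columns left after annotation columns")

    def parse_column(col: str, empty_is_nan: bool) -> np.ndarray:
        # correctly-rounded strtod (exact round-trip); pandas' fast parser is lossy
        raw = df[col].to_numpy(dtype=object)
        if empty_is_nan:
            raw = np.where(raw == "", "nan", raw)
        try:
            return raw.astype(np.float64)
        except ValueError:
            for i, cell in enumerate(raw):
                try:
                    float(cell)
                except ValueError:
                    raise DataError(
                        f"non-numeric value {df[col].iloc[i]!r} for compound "
                        f"{compound_ids[i]!r} (row {i + 2}), column {col!r}"
                    ) from None
            raise

    X = np.empty((len(df), len(desc_cols)), dtype=float)
    for j, col in enumerate(desc_cols):
        X[:, j] = parse_column(col, empty_is_nan=False)

    activity = parse_column(activity_column, empty_is_nan=True) if activity_column else None

    labels = None
    if label_column:
        tokmap = {active_token: ACTIVE, inactive_token: INACTIVE, "": UNLABELED}
        labels = np.empty(len(df), dtype=int)
        for i, tok in enumerate(df[label_column]):
            if tok not in tokmap:
                raise DataError(
                    f"unrecognized label {tok!r} for compound {compound_ids[i]!r}; "
                    f"expected {active_token!r} or {inactive_token!r}"
                )
            labels[i] = tokmap[tok]

    set_labels = None
    if set_column:
        set_labels = df[set_column].to_numpy(dtype=object)

    return DescriptorDataset(
        compound_ids=compound_ids,
        X=X,
        descriptor_names=desc_cols,
        activity=activity,
        labels=labels,
        set_labels=set_labels,
    )


def write_descriptor_table(
    ds: DescriptorDataset,
    path: str | Path,
    activity_column: str = "pKi",
    label_column: str = "label",
    set_column: str = "set",
    active_token: str = "active",
    inactive_token: str = "inactive",
    float_format: str = "%.17g",
) -> None:
    """Write a dataset back to delimited text (round-trips with the loader).

    The default 17 significant digits round-trip IEEE doubles exactly.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.DataFrame(ds.X, columns=ds.descriptor_names)
    df.insert(0, "compound_id", ds.compound_ids)
    if ds.activity is not None:
        df[activity_column] = ds.activity
    if ds.labels is not None:
        tok = {ACTIVE: active_token, INACTIVE: inactive_token, UNLABELED: ""}
        df[label_column] = [tok[int(v)] for v in ds.labels]
    if ds.set_labels is not None:
        df[set_column] = ds.set_labels
    df.to_csv(path, sep=sep, index=False, float_format=float_format)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def prune_descriptors(
    ds: DescriptorDataset,
    near_constant_fraction: float = 0.70,
    r2_threshold: float = 0.70,
) -> tuple[DescriptorDataset, PruneReport]:
    """Drop constant, nearly-constant and pairwise-correlated descriptors.

    Filter statistics are computed on the training subset when set labels
    are assigned (falling back to all rows otherwise) and the resulting
    column selection is applied to every set.  Rules, applied in order:

    1. constant: a single distinct value;
    2. nearly constant: the most frequent value occupies at least
       ``near_constant_fraction`` of the compounds (exact value equality);
    3. correlated: for every remaining pair with squared Pearson correlation
       strictly above ``r2_threshold``, the later column in input order is
       dropped.
    """
    if not (0 < near_constant_fraction <= 1) or not (0 < r2_threshold <= 1):
        raise DataError("thresholds must lie in (0, 1]")
    train_mask = ds.set_mask("train")
    ref = ds.X[train_mask] if train_mask.any() else ds.X
    m = ref.shape[0]
    report = PruneReport()
    keep: list[int] = []
    for j, name in enumerate(ds.descriptor_names):
        col = ref[:, j]
        _, counts = np.unique(col, return_counts=True)
        if counts.size == 1:
            report.removed_constant.append(name)
        elif counts.max() / m >= near_constant_fraction:
            report.removed_near_constant.append(name)
        else:
            keep.append(j)

    if keep:
        r = np.atleast_2d(np.corrcoef(ref[:, keep], rowvar=False))
        r2 = r**2
        kept_pos: list[int] = []  # positions within `keep` that survive
        for pos, j in enumerate(keep):
            clash = next((kp for kp in kept_pos if r2[kp, pos] > r2_threshold), None)
            if clash is None:
                kept_pos.append(pos)
            else:
                report.removed_correlated.append(
                    (
                        ds.descriptor_names[keep[clash]],
                        ds.descriptor_names[j],
                        float(r2[clash, pos]),
                    )
                )
        keep = [keep[p] for p in kept_pos]

    if not keep:
        raise DataError(
            "all descriptors removed by pruning; relax near_constant_fraction "
            "or r2_threshold"
        )
    report.n_remaining = len(keep)
    return ds.select_descriptors(np.array(keep)), report


def zscore_normalize(
    ds: DescriptorDataset,
    params: NormalizationParams | None = None,
) -> tuple[DescriptorDataset, NormalizationParams]:
    """Z-score descriptors; statistics from the training subset, frozen.

    When ``params`` is given (screening new compounds) it is applied as-is
    after checking descriptor names match.  Sample (n-1) standard deviation
    is used throughout.
    """
    if params is None:
        train_mask = ds.set_mask("train")
        ref = ds.X[train_mask] if train_mask.any() else ds.X
        mean = ref.mean(axis=0)
        sd = ref.std(axis=0, ddof=1)
        if np.any(sd == 0):
            name = ds.descriptor_names[int(np.argmax(sd == 0))]
            raise DataError(
                f"descriptor {name!r} is constant on the training subset; "
                "prune before normalizing"
            )
        params = NormalizationParams(list(ds.descriptor_names), mean, sd)
    else:
        if list(params.descriptor_names) != list(ds.descriptor_names):
            raise DataError("normalization parameters were fit on different descriptors")
    out = replace(ds, X=(ds.X - params.mean) / params.sd)
    return out, params


def _first_duplicate(items: list[str]) -> str | None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None
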