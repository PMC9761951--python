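"""Multi-view omics matrices, survival tables, and the preprocessing recipe.

Conventions: a view is stored features x samples (one row per molecular
feature, one column per patient).  Preprocessing follows the standard
multi-omics survival recipe: drop any sample with more than 20% missing
entries in any view, drop features with more than 20% missing entries,
impute the rest by k-nearest-neighbour donor means, then z-score each
feature across all samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

logger = logging.getLogger(__name__)

#: cell contents treated as missing when parsing matrices
MISSING_MARKERS = ("", "NA", "NaN", "nan", "na")


@dataclass
class ViewMatrix:
    """One data type: a d_v x N numeric matrix with feature/sample labels."""

    view_name: str
    values: np.ndarray  # features x samples, NaN marks missing
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"view {self.view_name!r}: values shape {self.values.shape} does not "
                f"match {len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.values.size == 0:
            raise ValueError(f"view {self.view_name!r} is empty")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class SurvivalTable:
    """Right-censored survival outcomes: time in months, event=1 means death observed."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ValueError("duplicate sample ids in survival table")
        if not (self.time > 0).all():
            raise ValueError("survival times must be strictly positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0 (censored) or 1 (death)")

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass
class OmicsDataset:
    """V >= 2 aligned views plus survival outcomes for the same N samples."""

    views: list[ViewMatrix]
    survival: SurvivalTable

    def __post_init__(self) -> None:
        if len(self.views) < 2:
            raise ValueError("need at least two views")
        ids = self.survival.sample_ids
        for v in self.views:
            if v.sample_ids != ids:
                raise ValueError(
                    f"view {v.view_name!r} samples are not aligned with the survival table"
                )

    @property
    def n_views(self) -> int:
        return len(self.views)

    @property
    def n_samples(self) -> int:
        return len(self.survival)


# ---------------------------------------------------------------------------
# parsing


def _parse_cell(cell: str) -> float:
    s = str(cell).strip()
    if s in MISSING_MARKERS:
        return np.nan
    try:
        return float(s)
    except ValueError:
        return np.nan


def load_view(path: str | Path, view_name: str | None = None,
              orientation: str = "features_x_samples", sep: str | None = None) -> ViewMatrix:
    """Read a delimited matrix (header row, first column = ids) as a ViewMatrix.

    ``orientation`` says what the rows of the *file* are; the returned
    matrix is always canonical features x samples.  Non-numeric cells
    become missing values.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty matrix")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate row ids {dup}")
    dup = df.columns[df.columns.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate column ids {dup}")
    values = df.map(_parse_cell).to_numpy(dtype=float)
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if orientation == "samples_x_features":
        values, rows, cols = values.T, cols, rows
    elif orientation != "features_x_samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    return ViewMatrix(view_name or path.stem, values, rows, cols)


def load_survival(path: str | Path, sep: str | None = None) -> SurvivalTable:
    """Read a survival table with columns sample_id, time, event."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: survival table needs columns {sorted(required)}")
    return SurvivalTable(
        [str(s) for s in df["sample_id"]],
        df["time"].to_numpy(float),
        df["event"].to_numpy(int),
    )


def align(views: list[ViewMatrix], survival: SurvivalTable) -> OmicsDataset:
    """Intersect sample ids across views and survival; order follows the survival table."""
    keep = [s for s in survival.sample_ids
            if all(s in set(v.sample_ids) for v in views)]
    dropped = len(survival) - len(keep)
    if dropped:
        logger.info("align: dropped %d samples without data in every view", dropped)
    if not keep:
        raise ValueError("no samples shared by all views and the survival table")
    surv_idx = {s: i for i, s in enumerate(survival.sample_ids)}
    order = [surv_idx[s] for s in keep]
    aligned_surv = SurvivalTable(keep, survival.time[order], survival.event[order])
    aligned_views = []
    for v in views:
        vidx = {s: i for i, s in enumerate(v.sample_ids)}
        cols = [vidx[s] for s in keep]
        aligned_views.append(replace(v, values=v.values[:, cols], sample_ids=list(keep)))
    return OmicsDataset(aligned_views, aligned_surv)


# ---------------------------------------------------------------------------
# preprocessing


@dataclass
class PreprocessReport:
    n_samples_in: int = 0
    n_samples_out: int = 0
    samples_dropped: list[str] = field(default_factory=list)
    features_dropped: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_samples_in": self.n_samples_in,
            "n_samples_out": self.n_samples_out,
            "samples_dropped": self.samples_dropped,
            "features_dropped": self.features_dropped,
        }


def filter_missingness(dataset: OmicsDataset, sample_thresh: float = 0.2,
                       feature_thresh: float = 0.2,
                       report: PreprocessReport | None = None) -> OmicsDataset:
    """Drop samples with > ``sample_thresh`` missing in ANY view, then sparse features.

    The sample rule is applied per view: a patient exceeding the threshold
    in a single data type is removed from every view and from the survival
    table, keeping the alignment invariant.
    """
    if not (0 <= sample_thresh <= 1 and 0 <= feature_thresh <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    bad = np.zeros(dataset.n_samples, dtype=bool)
    for v in dataset.views:
        frac = np.isnan(v.values).mean(axis=0)
        bad |= frac > sample_thresh
    keep = ~bad
    if not keep.any():
        raise ValueError("missingness filter removed all samples")
    ids = [s for s, k in zip(dataset.survival.sample_ids, keep) if k]
    if report is not None:
        report.n_samples_in = dataset.n_samples
        report.n_samples_out = len(ids)
        report.samples_dropped = [s for s, k in zip(dataset.survival.sample_ids, keep) if not k]
    surv = SurvivalTable(ids, dataset.survival.time[keep], dataset.survival.event[keep])
    views = []
    for v in dataset.views:
        vals = v.values[:, keep]
        feat_keep = np.isnan(vals).mean(axis=1) <= feature_thresh
        if report is not None:
            report.features_dropped[v.view_name] = int((~feat_keep).sum())
        views.append(ViewMatrix(
            v.view_name, vals[feat_keep],
            [f for f, k in zip(v.feature_ids, feat_keep) if k], ids,
        ))
    return OmicsDataset(views, surv)


def impute_knn(view: ViewMatrix, k: int = 10) -> ViewMatrix:
    """Fill missing entries with the mean of the k nearest samples' values.

    Nearness is Euclidean distance over mutually observed features
    (nan-Euclidean); donors are the k closest samples observing the
    feature in question.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    observed_per_sample = (~np.isnan(view.values)).sum(axis=0)
    if (observed_per_sample == 0).any():
        empty = [s for s, n in zip(view.sample_ids, observed_per_sample) if n == 0]
        raise ValueError(f"view {view.view_name!r}: samples with no observed features: {empty}")
    if not np.isnan(view.values).any():
        return view
    # samples are the imputation units, so impute on the N x d_v transpose
    imputer = KNNImputer(n_neighbors=min(k, view.n_samples - 1))
    filled = imputer.fit_transform(view.values.T).T
    return replace(view, values=filled)


def zscore(view: ViewMatrix) -> ViewMatrix:
    """Standardize each feature to mean 0, population sd 1 across samples.

    Constant features cannot be scaled; they are set to all-zero with a
    warning so downstream distances ignore them.
    """
    if np.isnan(view.values).any():
        raise ValueError("zscore requires an imputed (complete) matrix")
    mean = view.values.mean(axis=1, keepdims=True)
    sd = view.values.std(axis=1, ddof=0, keepdims=True)
    const = sd.ravel() == 0
    if const.any():
        warnings.warn(
            f"view {view.view_name!r}: {int(const.sum())} constant feature(s) set to zero",
            stacklevel=2,
        )
    sd[sd == 0] = 1.0
    out = (view.values - mean) / sd
    out[const, :] = 0.0
    return replace(view, values=out)


def preprocess(dataset: OmicsDataset, sample_thresh: float = 0.2,
               feature_thresh: float = 0.2, impute_k: int = 10) -> tuple[OmicsDataset, PreprocessReport]:
    """Full recipe: missingness filters -> KNN imputation -> per-feature z-score."""
    report = PreprocessReport()
    ds = filter_missingness(dataset, sample_thresh, feature_thresh, report)
    views = [zscore(impute_knn(v, impute_k)) for v in ds.views]
    return OmicsDataset(views, ds.survival), report


def save_view(view: ViewMatrix, path: str | Path) -> None:
    pd.DataFrame(view.values, index=view.feature_ids, columns=view.sample_ids).to_csv(
        path, sep="\t")


def save_survival(surv: SurvivalTable, path: str | Path) -> None:
    pd.DataFrame({"sample_id": surv.sample_ids, "time": surv.time, "event": surv.event}
                 ).to_csv(path, sep="\t", index=False)
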