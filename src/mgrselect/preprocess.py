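"""Step-1 preprocessing: cleaning, preliminary filtering, and discretization.

The measures operate on discrete codes, so continuous biomarker tables must
be cleaned (binary label mapping, missing-data removal), optionally reduced
(intensity clamps, ratio/range exclusion, t-test or fold-change filters,
log10 transform), and discretized.  Discretization uses exact 1-D two-means:
each slice (a variable across samples, or a sample across variables) is
split into a low/high cluster by enumerating every sorted threshold and
minimizing within-cluster squared error — the global optimum of 1-D 2-means,
with no initialization sensitivity.  The lower-mean cluster always gets
code 0, so codes are stable across runs.

Because the right recipe is data-dependent, :func:`verify_preprocessing`
probes a candidate recipe: discretize, sample ~100 variables, run the subset
search plus classifier on them under cross-validation, and ask whether the
accuracy clears the majority-class baseline by a margin.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .measures import DiscreteMatrix

__all__ = [
    "PreprocessConfig",
    "CleanResult",
    "clean_matrix",
    "clamp_and_filter",
    "log10_transform",
    "two_means_split",
    "discretize_two_means",
    "preliminary_filter",
    "run_preprocess",
    "golub_config",
    "bcw_config",
    "VerificationReport",
    "verify_preprocessing",
]

log = logging.getLogger(__name__)

# label codings recognized without an explicit positive_label
_KNOWN_POSITIVE = {"M", "ALL", "1", "malignant", "case", "yes", "true"}


@dataclass
class PreprocessConfig:
    """Recipe parameters; unset clamps/thresholds skip the corresponding step."""

    floor_value: float | None = None
    ceiling_value: float | None = None
    ratio_threshold: float | None = None
    range_threshold: float | None = None
    log_base10: bool = False
    discretize_axis: str = "per-variable"
    prelim_filter: str = "none"
    prelim_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.discretize_axis not in ("per-variable", "per-sample"):
            raise ValueError("discretize_axis must be per-variable or per-sample")
        if self.prelim_filter not in ("none", "t-test", "fold-change"):
            raise ValueError("prelim_filter must be none, t-test or fold-change")
        for name in ("ratio_threshold", "range_threshold", "prelim_threshold"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PreprocessConfig":
        return cls(**json.loads(text))


def golub_config() -> PreprocessConfig:
    """Expression-array recipe: clamp 100/16000, ratio<=5 or range<=500 filter,
    log10, per-sample two-means."""
    return PreprocessConfig(floor_value=100, ceiling_value=16000,
                            ratio_threshold=5, range_threshold=500,
                            log_base10=True, discretize_axis="per-sample")


def bcw_config() -> PreprocessConfig:
    """Low-dimensional recipe: per-variable two-means only."""
    return PreprocessConfig(discretize_axis="per-variable")


@dataclass
class CleanResult:
    values: np.ndarray
    variable_names: tuple
    labels: np.ndarray
    dropped_rows: int = 0
    dropped_cols: int = 0


def clean_matrix(table: pd.DataFrame, label_col: str,
                 positive_label=None) -> CleanResult:
    """Extract a numeric samples-by-variables matrix and a 0/1 label vector.

    The label column must carry exactly two statuses; the positive (case)
    status is ``positive_label`` when given, a conventional disease code
    (M, ALL, 1, ...) when recognizable, otherwise the lexically larger one.
    Entirely-missing rows/columns are dropped, then any rows with remaining
    missing entries, all logged.
    """
    if label_col not in table.columns:
        raise ValueError(f"label column {label_col!r} not found")
    raw_labels = table[label_col]
    uniq = sorted(raw_labels.dropna().astype(str).unique())
    if len(uniq) != 2:
        raise ValueError(f"label column must have exactly 2 statuses, got {uniq}")
    if positive_label is not None:
        pos = str(positive_label)
        if pos not in uniq:
            raise ValueError(f"positive label {pos!r} not among {uniq}")
    else:
        known = [u for u in uniq if u in _KNOWN_POSITIVE]
        pos = known[0] if known else uniq[1]
    data = table.drop(columns=[label_col])
    numeric = data.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & data.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"unparseable numeric cell at row {data.index[r]}, "
            f"column {data.columns[c]!r}")
    n0, p0 = numeric.shape
    numeric = numeric.dropna(axis=1, how="all").dropna(axis=0, how="all")
    keep_rows = numeric.notna().all(axis=1)
    dropped_rows = n0 - int(keep_rows.sum())
    dropped_cols = p0 - numeric.shape[1]
    if dropped_rows or dropped_cols:
        log.info("dropped %d rows and %d columns with missing data",
                 dropped_rows, dropped_cols)
    numeric = numeric.loc[keep_rows]
    labels = (raw_labels.loc[numeric.index].astype(str) == pos).to_numpy(int)
    return CleanResult(values=numeric.to_numpy(float),
                       variable_names=tuple(numeric.columns.astype(str)),
                       labels=labels,
                       dropped_rows=dropped_rows, dropped_cols=dropped_cols)


def clamp_and_filter(values: np.ndarray, names, config: PreprocessConfig):
    """Clip intensities into [floor, ceiling], then drop near-constant variables.

    A variable is removed when its post-clamp ``max/min`` falls at or below
    the ratio threshold OR ``max - min`` at or below the range threshold.
    Applied before any log transform.
    """
    values = np.asarray(values, dtype=float)
    if config.floor_value is not None or config.ceiling_value is not None:
        values = np.clip(values, config.floor_value, config.ceiling_value)
    vmax = values.max(axis=0)
    vmin = values.min(axis=0)
    keep = np.ones(values.shape[1], dtype=bool)
    if config.ratio_threshold is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(vmin > 0, vmax / vmin, np.inf)
        keep &= ratio > config.ratio_threshold
    if config.range_threshold is not None:
        keep &= (vmax - vmin) > config.range_threshold
    if not keep.any():
        raise ValueError("clamp/filter removed every variable")
    log.info("clamp/filter: %d -> %d variables", len(keep), int(keep.sum()))
    return values[:, keep], tuple(n for n, k in zip(names, keep) if k)


def log10_transform(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if (values <= 0).any():
        raise ValueError("log10 transform requires strictly positive values")
    return np.log10(values)


def two_means_split(x: np.ndarray):
    """Exact 1-D two-means of one slice: codes in {0,1}, lower mean -> 0.

    Enumerates every threshold between distinct sorted values and minimizes
    total within-cluster squared error; SSE ties resolve to the lower
    threshold.  A constant slice returns all zeros and ``constant=True``.
    """
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(xs)
    if xs[0] == xs[-1]:
        return np.zeros(n, dtype=np.int8), True
    csum = np.cumsum(xs)
    csq = np.cumsum(xs ** 2)
    best_t, best_sse = None, np.inf
    for t in range(1, n):  # left cluster = xs[:t]
        if xs[t - 1] == xs[t]:
            continue  # identical values cannot straddle a centroid boundary
        left = csq[t - 1] - csum[t - 1] ** 2 / t
        right = (csq[-1] - csq[t - 1]) - (csum[-1] - csum[t - 1]) ** 2 / (n - t)
        sse = left + right
        if sse < best_sse:  # strict < keeps the lowest threshold on ties
            best_t, best_sse = t, sse
    threshold = xs[best_t - 1]
    return (x > threshold).astype(np.int8), False


def discretize_two_means(values: np.ndarray, axis: str = "per-variable",
                         seed: int = 0) -> np.ndarray:
    """Two-means discretize every slice of the matrix into binary codes.

    ``axis="per-variable"`` splits each column across samples;
    ``axis="per-sample"`` splits each row across variables.  The ``seed`` is
    accepted for interface symmetry; the exact solver leaves nothing random.
    """
    values = np.asarray(values, dtype=float)
    if axis not in ("per-variable", "per-sample"):
        raise ValueError("axis must be per-variable or per-sample")
    work = values if axis == "per-variable" else values.T
    codes = np.empty(work.shape, dtype=np.int8)
    n_constant = 0
    for j in range(work.shape[1]):
        codes[:, j], const = two_means_split(work[:, j])
        n_constant += const
    if n_constant:
        log.warning("%d constant slices discretized to all-0 codes", n_constant)
    return codes if axis == "per-variable" else codes.T


def preliminary_filter(values: np.ndarray, labels, method: str,
                       threshold: float):
    """Keep variables that pass a univariate screen; order preserved.

    ``t-test`` keeps Welch two-sample p < threshold; ``fold-change`` keeps
    variables whose between-group mean ratio (larger over smaller) meets the
    threshold.  ``none`` is the identity.
    Returns a boolean keep mask.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    if method == "none":
        return np.ones(values.shape[1], dtype=bool)
    g1 = values[labels == 1]
    g0 = values[labels == 0]
    if method == "t-test":
        pvals = stats.ttest_ind(g1, g0, axis=0, equal_var=False).pvalue
        return np.asarray(pvals) < threshold
    if method == "fold-change":
        m1 = g1.mean(axis=0)
        m0 = g0.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            hi = np.maximum(np.abs(m1), np.abs(m0))
            lo = np.minimum(np.abs(m1), np.abs(m0))
            fc = np.where(lo > 0, hi / lo, np.inf)
        return fc >= threshold
    raise ValueError(f"unknown preliminary filter {method!r}")


def run_preprocess(table: pd.DataFrame, label_col: str,
                   config: PreprocessConfig,
                   positive_label=None) -> DiscreteMatrix:
    """Full recipe: clean -> clamp/filter -> preliminary filter -> log10 ->
    two-means discretize.  Returns the discrete matrix ready for scoring."""
    clean = clean_matrix(table, label_col, positive_label=positive_label)
    values, names = clean.values, clean.variable_names
    if (config.floor_value is not None or config.ceiling_value is not None
            or config.ratio_threshold is not None
            or config.range_threshold is not None):
        values, names = clamp_and_filter(values, names, config)
    if config.prelim_filter != "none":
        keep = preliminary_filter(values, clean.labels, config.prelim_filter,
                                  config.prelim_threshold)
        log.info("preliminary %s filter: %d -> %d variables",
                 config.prelim_filter, len(keep), int(keep.sum()))
        values = values[:, keep]
        names = tuple(n for n, k in zip(names, keep) if k)
    if config.log_base10:
        values = log10_transform(values)
    codes = discretize_two_means(values, config.discretize_axis, config.seed)
    return DiscreteMatrix(codes, names, clean.labels)


@dataclass
class VerificationReport:
    accuracy: float
    baseline: float
    margin: float
    n_probe_used: int
    reasonable: bool
    warning: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def verify_preprocessing(table: pd.DataFrame, label_col: str,
                         candidate_config: PreprocessConfig,
                         n_probe: int = 100, seed: int = 0,
                         folds: int = 5, margin: float = 0.05,
                         bda_k: int = 4, bda_B: int = 200,
                         measure: str = "mgr",
                         positive_label=None) -> VerificationReport:
    """Pre-experiment: does the candidate recipe preserve enough signal?

    Applies the recipe, samples ``n_probe`` variables, runs the subset
    search + boosted classifier on them under ``folds``-fold CV, and calls
    the recipe *reasonable* iff CV accuracy beats the majority-class
    baseline by ``margin``.
    """
    from .pipeline import PipelineConfig, make_fit_predict

    matrix = run_preprocess(table, label_col, candidate_config,
                            positive_label=positive_label)
    rng = np.random.default_rng(seed)
    warning = None
    if matrix.p < n_probe:
        warning = (f"only {matrix.p} variables available; probing all "
                   f"instead of {n_probe}")
        log.warning(warning)
        probe_idx = np.arange(matrix.p)
    else:
        probe_idx = np.sort(rng.choice(matrix.p, n_probe, replace=False))
    probe = matrix.select(cols=probe_idx)
    config = PipelineConfig(measure=measure, screening_enabled=False,
                            k=min(bda_k, probe.p), B=bda_B, z=1,
                            folds=folds, seed=seed)
    from .classify import evaluate_cv
    result = evaluate_cv(probe.values, probe.labels,
                         make_fit_predict(tuple(probe.variable_names), config),
                         folds=folds, seed=seed)
    baseline = max(probe.pi1, 1.0 - probe.pi1)
    accuracy = result.accuracy
    return VerificationReport(
        accuracy=accuracy, baseline=baseline, margin=margin,
        n_probe_used=int(len(probe_idx)),
        reasonable=bool(accuracy > baseline + margin),
        warning=warning,
    )
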