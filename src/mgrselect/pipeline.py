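"""End-to-end orchestration of the five-step pipeline.

Preprocess -> (optional) triple screen -> backward-dropping search ->
overlap filter -> forward adding -> boosted ridge classifier, evaluated by
stratified cross-validation with the selection stages re-run inside every
training fold.  All stages draw their seeds deterministically from one root
seed, keyed by stage name, so inserting a stage never shifts another
stage's random stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict

import numpy as np

from .measures import DiscreteMatrix
from .screening import screen
from .bda import BDAConfig, run_bda, filter_overlaps, forward_add
from .classify import boost_combine, evaluate_cv

__all__ = ["PipelineConfig", "stage_seed", "select_interactions",
           "make_fit_predict", "run_pipeline"]

log = logging.getLogger(__name__)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed and stage name."""
    digest = hashlib.blake2s(f"{root_seed}:{stage}".encode(),
                             digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2 ** 31)


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the end-to-end run."""

    measure: str = "mgr"
    screening_enabled: bool | None = None   # None = auto (p > screening_threshold)
    screening_threshold: int = 100
    stride: int = 1000
    epsilon_frac: float = 0.01
    k: int = 4
    B: int = 2000
    z: int = 2
    forward_tol: float = 1e-9
    folds: int = 5
    ridge_cv_folds: int = 5
    seed: int = 17

    def to_dict(self) -> dict:
        return asdict(self)


def select_interactions(matrix: DiscreteMatrix, config: PipelineConfig,
                        seed: int | None = None):
    """Screen (when enabled) then search, filter and rebuild interactions.

    Returns ``(interactions, diagnostics)`` where interactions are tuples of
    variable indices into ``matrix`` and diagnostics records the count at
    each reduction stage.
    """
    seed = config.seed if seed is None else seed
    diag = {"p_input": matrix.p}
    enabled = config.screening_enabled
    if enabled is None:
        enabled = matrix.p > config.screening_threshold
    if enabled and matrix.p >= 3:
        report = screen(matrix, config.measure, config.stride,
                        config.epsilon_frac)
        cols = report.retained_variables
        work = matrix.select(cols=cols)
        diag["screened_variables"] = len(cols)
    else:
        cols = list(range(matrix.p))
        work = matrix
        diag["screened_variables"] = None
    k = min(config.k, work.p)
    z = min(config.z, k)
    bda_cfg = BDAConfig(k=k, B=config.B, z=z, measure=config.measure,
                        seed=stage_seed(seed, "bda"))
    returned = run_bda(work, bda_cfg)
    diag["return_sets"] = len(returned)
    kept = filter_overlaps(returned)
    diag["after_overlap_filter"] = len(kept)
    final = forward_add(work, kept, config.measure, tol=config.forward_tol)
    diag["final_interactions"] = len(final)
    # map back to the original variable indexing
    interactions = [tuple(sorted(cols[v] for v in rs.variables)) for rs in final]
    interactions.sort()
    log.info("selection: p=%d -> screen=%s -> %d return sets -> %d disjoint "
             "-> %d final", diag["p_input"], diag["screened_variables"],
             diag["return_sets"], diag["after_overlap_filter"],
             diag["final_interactions"])
    return interactions, diag


def make_fit_predict(variable_names, config: PipelineConfig):
    """Build the train-fold pipeline callable used inside cross-validation.

    The returned callable re-runs interaction selection on each training
    fold's samples and fits the boosted ensemble there, storing the fold's
    selected interactions on the returned model (``model.interactions``).
    """
    names = tuple(variable_names)

    def fit(train_values, train_labels):
        matrix = DiscreteMatrix(train_values, names, train_labels)
        interactions, diag = select_interactions(matrix, config)
        ensemble = boost_combine(matrix.values, matrix.labels, interactions,
                                 seed=stage_seed(config.seed, "boost"),
                                 cv_folds=config.ridge_cv_folds)
        ensemble.interactions = interactions
        ensemble.selection_diag = diag
        return ensemble

    return fit


def run_pipeline(matrix: DiscreteMatrix, config: PipelineConfig) -> dict:
    """Cross-validated end-to-end run; returns a JSON-serializable report."""
    fit = make_fit_predict(matrix.variable_names, config)
    fold_interactions = []
    fold_diags = []

    def fit_and_record(train_values, train_labels):
        model = fit(train_values, train_labels)
        fold_interactions.append(
            [[matrix.variable_names[v] for v in itx]
             for itx in model.interactions])
        fold_diags.append(model.selection_diag)
        return model

    result = evaluate_cv(matrix.values, matrix.labels, fit_and_record,
                         folds=config.folds,
                         seed=stage_seed(config.seed, "cv"))
    report = {
        "config": config.to_dict(),
        "n": matrix.n,
        "p": matrix.p,
        "pi1": matrix.pi1,
        "metrics": result.to_dict(),
        "interactions_per_fold": fold_interactions,
        "selection_per_fold": fold_diags,
    }
    return report


def report_to_json(report: dict) -> str:
    """Canonical serialization (sorted keys) so identical runs are
    byte-identical."""
    return json.dumps(report, sort_keys=True, indent=2)
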