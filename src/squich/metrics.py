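"""Scoring estimates against ground truth.

Detection recall, false positives, dropout, mean squared error on log10
abundances, and Pearson/Spearman correlations.  All metrics are
permutation-invariant in species order.  Undefined quantities (recall with
no positives, correlation with zero variance) are reported as None rather
than raising.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Iterable

import numpy as np
from scipy import stats

from .estimators import AbundanceEstimate
from .populations import SpeciesPopulation

__all__ = ["MetricReport", "detection_metrics", "log_mse", "correlations", "score"]


@dataclass
class MetricReport:
    recall: float | None = None
    fp_count: int | None = None
    dropout_count: int | None = None
    dropout_rate: float | None = None
    dropout_molecules: int | None = None
    log_mse: float | None = None
    pearson: float | None = None
    spearman: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _detected_vector(est) -> np.ndarray:
    if isinstance(est, AbundanceEstimate):
        return np.asarray(est.detected, dtype=bool)
    return np.asarray(est) >= 1


def detection_metrics(
    est,
    truth: SpeciesPopulation,
    positives: Iterable[int] | None = None,
    called: Iterable[int] | None = None,
) -> MetricReport:
    """Recall over ``positives``, false positives of a call set, and dropout.

    ``est`` is an :class:`AbundanceEstimate` (detection flags) or a raw count
    vector (detected iff count >= 1).  ``called`` is an explicit call set
    (e.g. an enrichment call); false positives are calls outside
    ``positives``.  Dropout counts species with truth > 0 and no detection;
    the molecule-weighted counterpart is also reported.
    """
    detected = _detected_vector(est)
    n = truth.abundances
    if detected.size != n.size:
        raise ValueError("estimate and truth sizes differ")

    report = MetricReport()
    pos = None if positives is None else np.asarray(list(positives), dtype=np.int64)
    if pos is not None and pos.size:
        if called is not None:
            called_arr = np.asarray(list(called), dtype=np.int64)
            hit = np.isin(pos, called_arr)
            report.fp_count = int(np.setdiff1d(called_arr, pos).size)
        else:
            hit = detected[pos]
        report.recall = float(np.mean(hit))
    elif called is not None:
        report.fp_count = int(np.asarray(list(called)).size)

    expressed = n > 0
    drop = expressed & ~detected
    report.dropout_count = int(drop.sum())
    report.dropout_rate = float(drop.sum() / expressed.sum()) if expressed.any() else None
    report.dropout_molecules = int(n[drop].sum())
    return report


def log_mse(est, truth) -> float:
    """Mean squared error of log10 abundances over expressed species.

    Both estimate and truth are floored at 1 molecule so undetected species
    contribute a finite penalty instead of an infinity; base 10 matches the
    decade structure of the protocols scored with it.
    """
    point = est.point if isinstance(est, AbundanceEstimate) else np.asarray(est, dtype=float)
    n = truth.abundances if isinstance(truth, SpeciesPopulation) else np.asarray(truth)
    mask = n > 0
    err = np.log10(np.maximum(point[mask], 1.0)) - np.log10(np.maximum(n[mask], 1.0))
    return float(np.mean(err**2))


def correlations(est, truth) -> tuple[float | None, float | None]:
    """(Pearson, Spearman) between estimates and truth over all species."""
    point = est.point if isinstance(est, AbundanceEstimate) else np.asarray(est, dtype=float)
    n = truth.abundances if isinstance(truth, SpeciesPopulation) else np.asarray(truth)
    if point.size < 2 or np.std(point) == 0 or np.std(n.astype(float)) == 0:
        return None, None
    pearson = float(stats.pearsonr(point, n).statistic)
    spearman = float(stats.spearmanr(point, n).statistic)
    return pearson, spearman


def score(
    est,
    truth: SpeciesPopulation,
    positives=None,
    called=None,
) -> MetricReport:
    """Full report: detection metrics plus log MSE and correlations."""
    report = detection_metrics(est, truth, positives=positives, called=called)
    report.log_mse = log_mse(est, truth)
    report.pearson, report.spearman = correlations(est, truth)
    return report
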