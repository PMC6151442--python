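"""Good2bad feature ranking by Monte Carlo subset modelling.

The screen draws many random (sample, feature) subsets, fits a joint-action
sub-model on each subset's training samples, and scores it by prediction
RMSE on the held-out samples. Sub-models in the low-error tail (SEM, small-
error models) tend to contain activity-relevant features; the high-error
tail (BEM, big-error models) tends to lack them. Each feature's importance
is the ratio of its selection frequencies in the two tails,

    Good2bad(i) = (F_SEM(i) + α) / (F_BEM(i) + α),

with a small pseudocount α guarding the zero-frequency case. Features are
ranked by descending score and the top 1-3 nominated as latent bioactives.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import FeatureTable, _fit_arrays, _resolve_labels, model_error
from .joint import CassetteAssignment, _olmstead_effect

__all__ = [
    "MCSConfig",
    "SubModelRecord",
    "Good2badResult",
    "draw_subsets",
    "run_mcs",
    "tail_split",
    "good2bad_scores",
    "select_features",
]


@dataclass(frozen=True)
class MCSConfig:
    """Monte Carlo sampling settings for the Good2bad screen.

    Defaults follow the screening protocol: 1000 iterations, feature
    fraction 0.05, sample fraction 0.7 (training share), 5% error tails.
    ``n_starts`` is the reduced multi-start count used for each sub-model
    fit.
    """

    iterations: int = 1000
    feature_frac: float = 0.05
    sample_frac: float = 0.70
    tail_frac: float = 0.05
    seed: int = 0
    n_starts: int = 8

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        for name in ("feature_frac", "sample_frac", "tail_frac"):
            frac = getattr(self, name)
            if not 0 < frac <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {frac}")
        if self.tail_frac > 0.5:
            raise ValueError("tail_frac must be <= 0.5")


def _subset_size(frac: float, total: int) -> int:
    return min(total, max(1, math.ceil(frac * total)))


def draw_subsets(
    n_samples: int, n_features: int, config: MCSConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded uniform draws of (sample indices, feature indices) pairs.

    Each of the ``iterations`` pairs is drawn without replacement in both
    directions; subset sizes are the ceilings of fraction × total, never
    below 1. Returned index arrays are sorted.
    """
    if n_samples < 1 or n_features < 1:
        raise ValueError("need at least one sample and one feature")
    n_s = _subset_size(config.sample_frac, n_samples)
    n_f = _subset_size(config.feature_frac, n_features)
    rng = np.random.default_rng(config.seed)
    return [
        (
            np.sort(rng.choice(n_samples, size=n_s, replace=False)),
            np.sort(rng.choice(n_features, size=n_f, replace=False)),
        )
        for _ in range(config.iterations)
    ]


@dataclass(frozen=True)
class SubModelRecord:
    """One Monte Carlo sub-model: its subset, prediction error, and fit."""

    feature_ids: tuple
    sample_ids: tuple
    test_error: float
    potencies: np.ndarray = field(repr=False, default=None)
    powers: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.test_error < 0:
            raise ValueError("error must be nonnegative")


def run_mcs(
    table: FeatureTable,
    activity: pd.Series,
    cassettes: CassetteAssignment | None,
    config: MCSConfig,
    model: str = "olmstead",
) -> list[SubModelRecord]:
    """Fit one joint-action sub-model per Monte Carlo subset.

    The drawn sample subset is the training set; the remaining samples form
    the test set whose RMSE is recorded for the tail analysis. Cassette
    labels are inherited from the full assignment and relabelled
    contiguously after subsetting (cassettes emptied by the draw drop out).
    The table should already be min-max normalized. Fully deterministic for
    a given config seed.
    """
    y = activity.reindex(table.abundance.index).to_numpy(dtype=float)
    if np.any(np.isnan(y)):
        raise ValueError("activity missing for some samples")
    conc = table.values()
    feature_ids = np.asarray(table.feature_ids, dtype=object)
    sample_ids = np.asarray(table.sample_ids, dtype=object)
    subsets = draw_subsets(table.n_samples, table.n_features, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    records: list[SubModelRecord] = []
    all_idx = np.arange(table.n_samples)
    for train_idx, feat_idx in subsets:
        test_idx = np.setdiff1d(all_idx, train_idx, assume_unique=True)
        labels = _resolve_labels(model, feature_ids[feat_idx], cassettes)
        sub_conc = conc[np.ix_(train_idx, feat_idx)]
        pot, pw, _, _ = _fit_arrays(
            sub_conc,
            y[train_idx],
            labels,
            rng,
            n_starts=config.n_starts,
            n_refine=2,
            maxfev=80 * (len(feat_idx) + int(labels.max())),
        )
        if len(test_idx):
            pred = _olmstead_effect(conc[np.ix_(test_idx, feat_idx)], pot, pw, labels)
            err = model_error(pred, y[test_idx])
        else:
            pred = _olmstead_effect(sub_conc, pot, pw, labels)
            err = model_error(pred, y[train_idx])
        records.append(
            SubModelRecord(
                feature_ids=tuple(feature_ids[feat_idx]),
                sample_ids=tuple(sample_ids[train_idx]),
                test_error=err,
                potencies=pot,
                powers=pw,
            )
        )
    return records


def tail_split(errors, tail_frac: float) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the small-error (SEM) and big-error (BEM) tails.

    The lowest ``ceil(tail_frac * N)`` errors form the SEM, the highest the
    BEM; the two tails are disjoint. Ties resolve by stable index order (a
    warning is emitted when all errors coincide).
    """
    errors = np.asarray(errors, dtype=float)
    n = len(errors)
    n_tail = math.ceil(tail_frac * n)
    if n < 2.0 / tail_frac or 2 * n_tail > n:
        raise ValueError(
            f"too few models ({n}) for tail fraction {tail_frac}: "
            f"need at least {math.ceil(2.0 / tail_frac)}"
        )
    if np.ptp(errors) == 0:
        warnings.warn("all sub-model errors identical; tails split by index order",
                      stacklevel=2)
    order = np.argsort(errors, kind="stable")
    return order[:n_tail], order[-n_tail:]


@dataclass(frozen=True)
class Good2badResult:
    """Per-feature SEM/BEM selection frequencies and Good2bad scores.

    ``table`` has one row per feature with columns ``f_sem``, ``f_bem``,
    ``score``; thresholds are the error values at the tail cutoffs.
    """

    table: pd.DataFrame
    sem_threshold: float
    bem_threshold: float
    n_models: int
    n_tail: int
    pseudocount: float


def good2bad_scores(
    records: list[SubModelRecord],
    feature_ids,
    tail_frac: float = 0.05,
    pseudocount: float | None = None,
) -> Good2badResult:
    """Good2bad score per feature from the sub-model error tails.

    ``F_SEM(i)`` / ``F_BEM(i)`` are the fractions of tail models whose
    subset contains feature ``i``; the score is their pseudocounted ratio
    ``(F_SEM + α) / (F_BEM + α)`` with α defaulting to 1 / (tail size).
    """
    if not records:
        raise ValueError("no sub-model records")
    errors = np.array([r.test_error for r in records])
    sem_idx, bem_idx = tail_split(errors, tail_frac)
    n_tail = len(sem_idx)
    alpha = 1.0 / n_tail if pseudocount is None else float(pseudocount)

    feature_ids = list(feature_ids)
    pos = {fid: i for i, fid in enumerate(feature_ids)}
    counts = np.zeros((2, len(feature_ids)))
    for row, idx_set in enumerate((sem_idx, bem_idx)):
        for i in idx_set:
            for fid in records[i].feature_ids:
                counts[row, pos[fid]] += 1
    f_sem, f_bem = counts / n_tail
    score = (f_sem + alpha) / (f_bem + alpha)
    table = pd.DataFrame(
        {"f_sem": f_sem, "f_bem": f_bem, "score": score}, index=feature_ids
    )
    return Good2badResult(
        table=table,
        sem_threshold=float(errors[sem_idx].max()),
        bem_threshold=float(errors[bem_idx].min()),
        n_models=len(records),
        n_tail=n_tail,
        pseudocount=alpha,
    )


def select_features(result: Good2badResult, k: int) -> list:
    """Top-``k`` feature ids by descending Good2bad score.

    Ties break by higher SEM frequency, then by feature id.
    """
    if not 1 <= k <= len(result.table):
        raise ValueError(f"k must lie in [1, {len(result.table)}]")
    ranked = result.table.sort_values(
        by=["score", "f_sem"], ascending=[False, False], kind="stable"
    )
    # stable sort keeps feature-id (input) order among full ties
    return list(ranked.index[:k])
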