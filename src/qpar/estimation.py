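"""Fitting joint-action models to fingerprint/activity data.

Given a samples × features abundance table (min-max normalized feature
"concentrations") and one inhibition-rate fraction per sample, the fitter
estimates per-feature potencies and per-cassette powers of a CA, RA or
Olmstead predictor by seeded multi-start bounded search (vectorised random
starts followed by derivative-free Nelder-Mead refinement). Model adequacy
is reported as RMSE and R²; a standard PLS regression serves as the linear
baseline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.cross_decomposition import PLSRegression

from .joint import CassetteAssignment, JointModelParams, _olmstead_effect

__all__ = [
    "FeatureTable",
    "FitResult",
    "PLSResult",
    "minmax_normalize",
    "model_error",
    "r_squared",
    "fit_joint_model",
    "pls_baseline",
    "POTENCY_BOUNDS",
    "POWER_BOUNDS",
]

# Search box for model parameters: potencies in normalized-abundance units,
# powers spanning the slope range seen for single flavonoid standards
# (~0.2-1.7) with generous margin.
POTENCY_BOUNDS: tuple[float, float] = (1e-3, 1e3)
POWER_BOUNDS: tuple[float, float] = (0.1, 10.0)


@dataclass(frozen=True)
class FeatureTable:
    """Samples × features abundance matrix with per-feature retention times.

    ``abundance`` is a pandas DataFrame (rows = sample ids, columns =
    feature ids) of nonnegative reals; ``retention_times`` is a Series of
    minutes indexed like the columns. ``constant_features`` records columns
    flagged as constant during normalization.
    """

    abundance: pd.DataFrame
    retention_times: pd.Series
    constant_features: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ab = self.abundance
        if ab.index.has_duplicates or ab.columns.has_duplicates:
            raise ValueError("sample and feature ids must be unique")
        values = ab.to_numpy(dtype=float)
        if np.any(~np.isfinite(values)) or np.any(values < 0):
            raise ValueError("abundances must be finite and nonnegative")
        rt = self.retention_times.reindex(ab.columns)
        if rt.isna().any() or not np.all(np.isfinite(rt.to_numpy(dtype=float))):
            raise ValueError("every feature needs a finite retention time")
        object.__setattr__(self, "retention_times", rt.astype(float))

    @property
    def sample_ids(self) -> tuple:
        return tuple(self.abundance.index)

    @property
    def feature_ids(self) -> tuple:
        return tuple(self.abundance.columns)

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_features(self) -> int:
        return self.abundance.shape[1]

    def values(self) -> np.ndarray:
        return self.abundance.to_numpy(dtype=float)


def minmax_normalize(table: FeatureTable) -> FeatureTable:
    """Map every feature column onto [0, 1] by min-max scaling.

    Constant columns are mapped to all zeros and flagged in
    ``constant_features``. Idempotent: normalizing twice equals once.
    """
    values = table.values()
    lo = values.min(axis=0)
    span = values.max(axis=0) - lo
    constant = span == 0
    safe_span = np.where(constant, 1.0, span)
    normed = (values - lo) / safe_span
    normed[:, constant] = 0.0
    return FeatureTable(
        abundance=pd.DataFrame(
            normed, index=table.abundance.index, columns=table.abundance.columns
        ),
        retention_times=table.retention_times,
        constant_features=tuple(np.asarray(table.feature_ids)[constant]),
    )


def model_error(predicted, observed) -> float:
    """Root mean squared error between prediction and observation."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size == 0:
        raise ValueError("predicted and observed must have equal nonzero length")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


def r_squared(observed, predicted) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size < 2:
        raise ValueError("need >=2 paired observations")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values have zero variance")
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class FitResult:
    """Outcome of one joint-action model fit."""

    params: JointModelParams
    train_rmse: float
    test_rmse: float
    converged: bool
    seed: int
    train_ids: tuple = ()
    test_ids: tuple = ()

    def predict(self, table: FeatureTable) -> np.ndarray:
        conc = table.abundance.loc[:, list(self.params.feature_ids)].to_numpy(float)
        return _olmstead_effect(
            conc, self.params.potencies, self.params.powers, self._labels
        )

    @property
    def _labels(self) -> np.ndarray:
        return self.__dict__["labels"]


def _batch_loss(
    conc: np.ndarray,
    y: np.ndarray,
    log_pot: np.ndarray,
    log_pow: np.ndarray,
    labels: np.ndarray,
    m: int,
) -> np.ndarray:
    """Vectorised RMSE for a batch of candidate parameter vectors."""
    group = np.equal.outer(np.arange(1, m + 1), labels).astype(float)  # m × f
    tu = conc[None, :, :] / (10.0 ** log_pot)[:, None, :]  # k × n × f
    s = np.einsum("knf,mf->knm", tu, group)
    powers = (10.0 ** log_pow)[:, None, :]
    # branch-free sigmoid: s^p finite or inf both yield the right limit
    with np.errstate(over="ignore"):
        e = 1.0 - 1.0 / (1.0 + s**powers)
    pred = 1.0 - np.prod(1.0 - e, axis=-1)
    return np.sqrt(np.mean((pred - y[None, :]) ** 2, axis=-1))


def _fit_arrays(
    conc: np.ndarray,
    y: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator,
    n_starts: int = 32,
    n_refine: int = 2,
    maxfev: int | None = None,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Core multi-start fit on arrays; returns (potencies, powers, rmse, ok).

    Starts are log-uniform for potencies and uniform for powers within the
    module bounds; the best starts are refined with bounded Nelder-Mead in
    log10 space. Deterministic for a given generator state.
    """
    n, f = conc.shape
    m = int(labels.max())
    lp_lo, lp_hi = math.log10(POTENCY_BOUNDS[0]), math.log10(POTENCY_BOUNDS[1])
    pw_lo, pw_hi = POWER_BOUNDS

    log_pot = rng.uniform(lp_lo, lp_hi, size=(n_starts, f))
    log_pow = np.log10(rng.uniform(pw_lo, pw_hi, size=(n_starts, m)))
    losses = _batch_loss(conc, y, log_pot, log_pow, labels, m)
    order = np.argsort(losses, kind="stable")

    bounds = [(lp_lo, lp_hi)] * f + [(math.log10(pw_lo), math.log10(pw_hi))] * m

    # Lean single-candidate objective for the local refinements: the batch
    # einsum path has too much overhead for the thousands of tiny fits the
    # Monte Carlo screen performs.
    group_t = np.equal.outer(labels, np.arange(1, m + 1)).astype(float)  # f × m

    def loss(theta: np.ndarray) -> float:
        s = (conc / 10.0 ** theta[:f]) @ group_t
        e = 1.0 - 1.0 / (1.0 + s ** (10.0 ** theta[f:]))
        pred = 1.0 - np.prod(1.0 - e, axis=1)
        d = pred - y
        return math.sqrt((d @ d) / len(d))

    dim = f + m
    options = {"xatol": 1e-7, "fatol": 1e-12, "maxfev": maxfev or 400 * dim}
    candidates: list[tuple[float, np.ndarray, bool]] = []
    with np.errstate(over="ignore"):
        for idx in order[: max(1, n_refine)]:
            theta0 = np.concatenate([log_pot[idx], log_pow[idx]])
            res = minimize(
                loss, theta0, method="Nelder-Mead", bounds=bounds, options=options
            )
            candidates.append((float(res.fun), res.x, bool(res.success)))

    best = min(
        candidates,
        key=lambda c: (c[0], tuple(c[1][f:]), tuple(c[1][:f])),
    )
    return 10.0 ** best[1][:f], 10.0 ** best[1][f:], best[0], best[2]


def _resolve_labels(
    model: str, feature_ids, cassettes: CassetteAssignment | None
) -> np.ndarray:
    model = model.lower()
    if model == "ca":
        return np.ones(len(feature_ids), dtype=int)
    if model == "ra":
        return np.arange(1, len(feature_ids) + 1)
    if model == "olmstead":
        if cassettes is None:
            raise ValueError("olmstead model requires a cassette assignment")
        labels = cassettes.for_features(feature_ids)
        # relabel contiguously in case the subset leaves gaps
        _, labels = np.unique(labels, return_inverse=True)
        return labels + 1
    raise ValueError(f"unknown model {model!r}; expected ca, ra or olmstead")


def fit_joint_model(
    table: FeatureTable,
    activity: pd.Series,
    cassettes: CassetteAssignment | None = None,
    model: str = "olmstead",
    split: float = 0.7,
    seed: int = 0,
    n_starts: int = 32,
    train_idx: np.ndarray | None = None,
    test_idx: np.ndarray | None = None,
    n_refine: int = 2,
    maxfev: int | None = None,
) -> FitResult:
    """Fit a joint-action model to (abundance table, activity vector).

    Samples are split at random into a training fraction ``split`` (used to
    minimise RMSE) and a held-out test set whose RMSE is reported as the
    prediction error; pass ``train_idx``/``test_idx`` to control the split
    explicitly (as the Monte Carlo screen does). Identical inputs and seed
    reproduce the fit bit-for-bit.
    """
    if table.n_samples < 4:
        raise ValueError("need at least 4 samples to fit and hold out")
    y_all = activity.reindex(table.abundance.index)
    if y_all.isna().any():
        raise ValueError("activity missing for some samples")
    y_arr = y_all.to_numpy(dtype=float)
    if np.ptp(y_arr) == 0:
        raise ValueError("unfittable: activity is constant across samples")

    rng = np.random.default_rng(seed)
    n = table.n_samples
    if train_idx is None:
        if not 0 < split <= 1:
            raise ValueError("split must lie in (0, 1]")
        n_train = min(n, max(2, math.ceil(split * n)))
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
        test_idx = np.sort(perm[n_train:])
    else:
        train_idx = np.asarray(train_idx, dtype=int)
        test_idx = np.asarray(test_idx if test_idx is not None else [], dtype=int)

    labels = _resolve_labels(model, table.feature_ids, cassettes)
    conc = table.values()
    pot, pw, train_rmse, ok = _fit_arrays(
        conc[train_idx], y_arr[train_idx], labels, rng,
        n_starts=n_starts, n_refine=n_refine, maxfev=maxfev,
    )
    if len(test_idx):
        pred_test = _olmstead_effect(conc[test_idx], pot, pw, labels)
        test_rmse = model_error(pred_test, y_arr[test_idx])
    else:
        test_rmse = train_rmse

    params = JointModelParams(
        feature_ids=table.feature_ids, potencies=pot, powers=pw
    )
    result = FitResult(
        params=params,
        train_rmse=train_rmse,
        test_rmse=test_rmse,
        converged=ok,
        seed=seed,
        train_ids=tuple(np.asarray(table.sample_ids)[train_idx]),
        test_ids=tuple(np.asarray(table.sample_ids)[test_idx]),
    )
    result.__dict__["labels"] = labels
    return result


@dataclass(frozen=True)
class PLSResult:
    """PLS baseline: fitted predictions, adequacy R² and coefficients."""

    predictions: pd.Series
    r2: float
    coefficients: pd.Series
    n_components: int


def pls_baseline(
    table: FeatureTable,
    activity: pd.Series,
    n_components: int = 2,
    seed: int = 0,
) -> PLSResult:
    """Standard PLS regression of activity on the abundance table.

    The linear comparator for model adequacy: fits on all samples and
    reports in-sample predictions and R². Deterministic given inputs
    (``seed`` is recorded for provenance only).
    """
    n, f = table.abundance.shape
    if n_components >= min(n, f) + 1:
        raise ValueError(
            f"n_components={n_components} too large for {n} samples × {f} features"
        )
    y = activity.reindex(table.abundance.index).to_numpy(dtype=float)
    if np.any(np.isnan(y)):
        raise ValueError("activity missing for some samples")
    x = table.values()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns yield harmless warnings
        pls = PLSRegression(n_components=n_components, scale=True)
        pls.fit(x, y)
        pred = pls.predict(x).ravel()
    return PLSResult(
        predictions=pd.Series(pred, index=table.abundance.index),
        r2=r_squared(y, pred),
        coefficients=pd.Series(pls.coef_.ravel(), index=table.abundance.columns),
        n_components=n_components,
    )
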