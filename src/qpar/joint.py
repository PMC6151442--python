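"""Joint-action models for mixture effect prediction.

Three predictors map per-component concentrations (or normalized feature
abundances) to a mixture effect fraction:

* **Concentration addition (CA)** — components share a mode of action; their
  toxic units ``c_i / EC50_i`` sum, and the mixture responds as a single
  Hill curve in the summed toxic unit ``S``:  ``E = S^p / (1 + S^p)``.
* **Response addition (RA)** — components act independently; survival
  fractions multiply:  ``E = 1 - Π(1 - E_i)``.
* **Olmstead model** — the hybrid: CA inside each *cassette* (a group of
  components with a shared mode of action) and RA across cassettes. With a
  single cassette it reduces exactly to CA; with singleton cassettes it
  reduces exactly to RA.

All three return effects in ``[0, 1)`` and are nondecreasing in every
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hill import HillParams, hill_effect

__all__ = [
    "CassetteAssignment",
    "JointModelParams",
    "ca_predict",
    "ra_predict",
    "olmstead_predict",
]


@dataclass(frozen=True)
class CassetteAssignment:
    """Partition of features into cassettes, labelled contiguously 1..m.

    ``labels`` maps feature id to its cassette label. Every feature carries
    exactly one label and the label set is exactly {1, ..., m}.
    """

    labels: pd.Series

    def __post_init__(self) -> None:
        if self.labels.empty:
            raise ValueError("cassette assignment must cover at least one feature")
        if self.labels.index.has_duplicates:
            raise ValueError("duplicate feature ids in cassette assignment")
        values = np.asarray(self.labels, dtype=int)
        uniq = np.unique(values)
        if uniq[0] != 1 or not np.array_equal(uniq, np.arange(1, len(uniq) + 1)):
            raise ValueError(
                f"cassette labels must be contiguous 1..m, got {uniq.tolist()}"
            )
        object.__setattr__(self, "labels", self.labels.astype(int))

    @property
    def m(self) -> int:
        """Number of cassettes."""
        return int(self.labels.max())

    @property
    def feature_ids(self) -> tuple:
        return tuple(self.labels.index)

    def for_features(self, feature_ids) -> np.ndarray:
        """Label array for the given features, in their order."""
        missing = [f for f in feature_ids if f not in self.labels.index]
        if missing:
            raise KeyError(f"features without cassette label: {missing}")
        return self.labels.loc[list(feature_ids)].to_numpy()

    @classmethod
    def single(cls, feature_ids) -> "CassetteAssignment":
        """All features in one cassette (the CA limit)."""
        return cls(pd.Series(1, index=list(feature_ids)))

    @classmethod
    def singletons(cls, feature_ids) -> "CassetteAssignment":
        """One cassette per feature (the RA limit)."""
        ids = list(feature_ids)
        return cls(pd.Series(range(1, len(ids) + 1), index=ids))


@dataclass(frozen=True)
class JointModelParams:
    """Per-feature potencies and per-cassette powers of a joint-action model.

    ``potencies[i]`` is the half-maximal concentration of feature
    ``feature_ids[i]`` (in the same units as the inputs fed to the
    predictor); ``powers[g]`` is the shared Hill exponent of cassette
    ``g + 1``.
    """

    feature_ids: tuple
    potencies: np.ndarray
    powers: np.ndarray

    def __post_init__(self) -> None:
        pot = np.asarray(self.potencies, dtype=float)
        pw = np.asarray(self.powers, dtype=float)
        if pot.shape != (len(self.feature_ids),):
            raise ValueError("one potency per feature required")
        if np.any(pot <= 0) or not np.all(np.isfinite(pot)):
            raise ValueError("potencies must be positive and finite")
        if pw.ndim != 1 or np.any(pw <= 0) or not np.all(np.isfinite(pw)):
            raise ValueError("powers must be positive and finite")
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        object.__setattr__(self, "potencies", pot)
        object.__setattr__(self, "powers", pw)


def _sigmoid_in_s(s: np.ndarray, power) -> np.ndarray:
    """S^p / (1 + S^p), stable for S = 0 and very large S."""
    with np.errstate(over="ignore", invalid="ignore"):
        sp = s**power
        out = np.where(np.isinf(sp), 1.0, sp / (1.0 + sp))
    return np.where(s == 0, 0.0, out)


def ca_predict(conc, ec50s, p: float):
    """Concentration-addition mixture effect.

    ``conc`` and ``ec50s`` are equal-length vectors (or ``conc`` may be a
    2-D samples × features array); ``p`` is the common Hill exponent. With
    toxic-unit sum ``S = Σ c_i / EC50_i`` the effect is ``S^p / (1 + S^p)``.
    """
    conc = np.asarray(conc, dtype=float)
    ec50s = np.asarray(ec50s, dtype=float)
    if conc.shape[-1] != ec50s.shape[-1]:
        raise ValueError("conc and ec50s must have matching length")
    if np.any(conc < 0):
        raise ValueError("concentrations must be nonnegative")
    if np.any(ec50s <= 0):
        raise ValueError("ec50s must be positive")
    if not p > 0:
        raise ValueError("exponent p must be positive")
    s = (conc / ec50s).sum(axis=-1)
    out = _sigmoid_in_s(np.asarray(s, dtype=float), p)
    return float(out) if out.ndim == 0 else out


def ra_predict(effects):
    """Response-addition combination: ``1 - Π(1 - E_i)`` over the last axis."""
    effects = np.asarray(effects, dtype=float)
    if np.any((effects < 0) | (effects > 1)):
        raise ValueError("effects must lie in [0, 1]")
    out = 1.0 - np.prod(1.0 - effects, axis=-1)
    return float(out) if out.ndim == 0 else out


def _olmstead_effect(
    conc: np.ndarray, potencies: np.ndarray, powers: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """Vectorised Olmstead effect for samples × features ``conc``.

    ``labels`` are contiguous cassette labels 1..m aligned to columns.
    """
    group = np.equal.outer(np.arange(1, powers.shape[-1] + 1), labels).astype(float)
    s = (conc / potencies) @ group.T  # samples × cassettes
    e = _sigmoid_in_s(s, powers)
    return 1.0 - np.prod(1.0 - e, axis=-1)


def olmstead_predict(conc, params: JointModelParams, cassettes: CassetteAssignment):
    """Olmstead (CA-within-cassette, RA-across-cassette) mixture effect.

    Per cassette ``g``: ``S_g = Σ_{i∈g} c_i / EC50_i`` and
    ``E_g = S_g^{P_g} / (1 + S_g^{P_g})``; the mixture effect is
    ``1 - Π_g (1 - E_g)``. ``conc`` is a vector over ``params.feature_ids``
    or a samples × features array.
    """
    conc = np.asarray(conc, dtype=float)
    one_sample = conc.ndim == 1
    conc = np.atleast_2d(conc)
    if conc.shape[1] != len(params.feature_ids):
        raise ValueError("conc width must match params.feature_ids")
    if np.any(conc < 0):
        raise ValueError("concentrations must be nonnegative")
    labels = cassettes.for_features(params.feature_ids)
    m = int(labels.max())
    present = np.unique(labels)
    if len(present) != m:
        raise ValueError("empty cassette: labels must cover 1..m for these features")
    if len(params.powers) != m:
        raise ValueError(f"need one power per cassette ({m}), got {len(params.powers)}")
    out = _olmstead_effect(conc, params.potencies, params.powers, labels)
    return float(out[0]) if one_sample else out


def hill_effects(conc, params_list: list[HillParams]) -> np.ndarray:
    """Per-chemical Hill effects for a concentration vector (helper for RA)."""
    conc = np.asarray(conc, dtype=float)
    return np.array([hill_effect(c, prm) for c, prm in zip(conc, params_list)])
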