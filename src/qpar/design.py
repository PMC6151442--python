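"""Mixture-experiment construction utilities.

Builds the standard-mixture and paired-sample experiments used to generate
composition variance for pattern-activity modelling:

* an 8 × 6 level layout for six standards — six uniform-design rows
  (U7(7^6)-derived) plus two equivalent-effect rows (all EC50, all EC5);
* resolution of a level row into concentration ratios via each standard's
  EC table (ratio_j = EC_{x_j}(standard j) / Σ_k EC_{x_k}(standard k)),
  scaled to a fixed total concentration (default 500 μg/mL);
* two-fold serial dilution series;
* all-pairs 1:1 blending of base extracts (n base samples → n(n-1)/2
  pairs, each profile the arithmetic mean of its two parents); and
* the inhibition-rate transform I = (A_t - A_b) / (A_c - A_b) from raw
  assay absorbances, with an explicit complement for viability readouts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import FeatureTable
from .hill import EC_LEVELS, ECTable

__all__ = [
    "MixtureDesign",
    "PairwiseDesign",
    "uniform_design_levels",
    "mixture_ratios",
    "resolve_design",
    "dilution_series",
    "pairwise_design",
    "blend_profiles",
    "inhibition_rate",
    "complement_rate",
]

# Canonical 8 × 6 effect-level layout: rows 1-6 from the U7(7^6) uniform
# design, row 7 all EC50 (equivalent-effect), row 8 all EC5.
_LEVEL_LAYOUT: tuple[tuple[float, ...], ...] = (
    (0.05, 0.10, 0.20, 0.30, 0.40, 0.50),
    (0.10, 0.30, 0.50, 0.05, 0.20, 0.40),
    (0.20, 0.50, 0.10, 0.40, 0.05, 0.30),
    (0.30, 0.05, 0.40, 0.10, 0.50, 0.20),
    (0.40, 0.20, 0.05, 0.50, 0.30, 0.10),
    (0.50, 0.40, 0.30, 0.20, 0.10, 0.05),
    (0.50, 0.50, 0.50, 0.50, 0.50, 0.50),
    (0.05, 0.05, 0.05, 0.05, 0.05, 0.05),
)


def uniform_design_levels() -> pd.DataFrame:
    """The 8 × 6 effect-level matrix (mixtures × standards).

    Entries are effect fractions from the six canonical EC levels; rows are
    indexed 1-8, columns 1-6 (standard number).
    """
    return pd.DataFrame(
        _LEVEL_LAYOUT,
        index=pd.RangeIndex(1, 9, name="mixture"),
        columns=pd.RangeIndex(1, 7, name="standard"),
        dtype=float,
    )


@dataclass(frozen=True)
class MixtureDesign:
    """One resolved mixture: levels, ratios and total concentration."""

    mixture_id: int
    levels: tuple[float, ...]
    ratios: np.ndarray
    total_concentration: float = 500.0

    def __post_init__(self) -> None:
        ratios = np.asarray(self.ratios, dtype=float)
        if np.any(ratios < 0) or abs(ratios.sum() - 1.0) > 1e-12:
            raise ValueError("ratios must be nonnegative and sum to 1")
        if any(x not in EC_LEVELS for x in self.levels):
            raise ValueError(f"levels must come from {EC_LEVELS}")
        object.__setattr__(self, "ratios", ratios)

    def concentrations(self) -> np.ndarray:
        """Per-standard concentrations at the design total (μg/mL)."""
        return self.ratios * self.total_concentration


def mixture_ratios(levels, ec_tables: list[ECTable] | tuple[ECTable, ...]) -> np.ndarray:
    """Concentration ratios for one design row.

    ``ratio_j = EC_{x_j}(standard j) / Σ_k EC_{x_k}(standard k)`` where
    ``x_j`` is standard j's assigned effect level; the ratios sum to 1.
    """
    levels = list(levels)
    if len(levels) != len(ec_tables):
        raise ValueError("one level per standard required")
    ecs = np.array([tbl.ec(x) for tbl, x in zip(ec_tables, levels)])
    return ecs / ecs.sum()


def resolve_design(
    ec_tables: list[ECTable] | tuple[ECTable, ...],
    total_concentration: float = 500.0,
) -> list[MixtureDesign]:
    """Resolve every row of the level layout against the EC tables."""
    layout = uniform_design_levels()
    if len(ec_tables) != layout.shape[1]:
        raise ValueError(f"expected {layout.shape[1]} EC tables")
    return [
        MixtureDesign(
            mixture_id=int(mid),
            levels=tuple(row),
            ratios=mixture_ratios(row, ec_tables),
            total_concentration=total_concentration,
        )
        for mid, row in layout.iterrows()
    ]


def dilution_series(c0: float, factor: float = 2.0, n: int = 7) -> np.ndarray:
    """Geometric dilution series ``c0, c0/factor, ...`` of length ``n``."""
    if c0 <= 0:
        raise ValueError("starting concentration must be positive")
    if factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    if n < 1:
        raise ValueError("need at least one concentration")
    return c0 / factor ** np.arange(n)


@dataclass(frozen=True)
class PairwiseDesign:
    """All unordered 1:1 pairs of base samples, in lexicographic order."""

    base_ids: tuple
    pairs: tuple[tuple, ...]
    blend_weights: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        n = len(self.base_ids)
        if len(self.pairs) != n * (n - 1) // 2:
            raise ValueError("pair count must be n(n-1)/2")
        if any(a == b for a, b in self.pairs):
            raise ValueError("self-pairs are not allowed")
        if len(set(map(frozenset, self.pairs))) != len(self.pairs):
            raise ValueError("duplicate pairs are not allowed")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def pairwise_design(sample_ids) -> PairwiseDesign:
    """All unordered pairs of the given base samples (n(n-1)/2 blends)."""
    ids = list(sample_ids)
    if len(ids) < 2:
        raise ValueError("need at least two base samples")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    return PairwiseDesign(
        base_ids=tuple(ids),
        pairs=tuple(itertools.combinations(ids, 2)),
    )


def blend_profiles(table: FeatureTable, design: PairwiseDesign) -> FeatureTable:
    """Fingerprints of the 1:1 blends.

    Because block solutions share one concentration, a 1:1 volumetric blend
    has the arithmetic mean profile of its parents. Blend sample ids are
    ``"{a}+{b}"``.
    """
    missing = [s for s in design.base_ids if s not in table.abundance.index]
    if missing:
        raise KeyError(f"base samples missing from table: {missing}")
    w1, w2 = design.blend_weights
    rows = {
        f"{a}+{b}": w1 * table.abundance.loc[a] + w2 * table.abundance.loc[b]
        for a, b in design.pairs
    }
    blended = pd.DataFrame(rows).T
    blended.index.name = table.abundance.index.name
    return FeatureTable(abundance=blended, retention_times=table.retention_times)


def inhibition_rate(a_test, a_background, a_control, clip: bool = False):
    """Inhibition rate ``I = (A_t - A_b) / (A_c - A_b)`` from absorbances.

    Computed exactly as defined; with ``clip=True`` values outside [0, 1]
    are clipped with a warning (the I/O-boundary convention), never
    silently.
    """
    a_test = np.asarray(a_test, dtype=float)
    denom = a_control - a_background
    if np.any(np.asarray(denom) == 0):
        raise ZeroDivisionError("control and background absorbances coincide")
    rate = (a_test - a_background) / denom
    if clip:
        out_of_range = (np.asarray(rate) < 0) | (np.asarray(rate) > 1)
        if np.any(out_of_range):
            warnings.warn(
                f"{int(np.sum(out_of_range))} inhibition rate(s) clipped to [0, 1]",
                stacklevel=2,
            )
        rate = np.clip(rate, 0.0, 1.0)
    return float(rate) if np.ndim(rate) == 0 else rate


def complement_rate(rate):
    """Complement transform ``1 - I`` (viability from inhibition or back)."""
    out = 1.0 - np.asarray(rate, dtype=float)
    return float(out) if out.ndim == 0 else out
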