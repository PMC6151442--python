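"""Synthetic fixture data with the statistical structure the screen assumes.

No measured fingerprints or activities are publicly deposited for this kind
of study, so every stage of the pipeline is exercised on generated data
whose structure mirrors the real experiment: a handful of base herbal
extracts blended into all pairwise 1:1 mixtures, per-feature UV spectra
with cassette (mode-of-action) group structure, and activities produced by
a ground-truth Olmstead model over a few planted active features plus
Gaussian noise. The generator returns its full ground truth so recovery can
be asserted exactly.

Default scales are calibrated to the reported experiment: 12 base samples
→ 66 blends, 73 features in 3 cassettes, log-normal abundances whose
blended coefficients of variation fall in the 0.1-1.3 band, and activity
summary statistics near max/min/mean/sd ≈ 0.74/0.09/0.33/0.14.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cassettes import SpectrumSet
from .design import blend_profiles, dilution_series, pairwise_design, resolve_design
from .estimation import FeatureTable
from .hill import ECTable
from .joint import CassetteAssignment, JointModelParams, olmstead_predict
from .standards import STANDARD_EC_TABLES

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_dataset",
    "generate_spectra",
    "standard_mixture_dataset",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings of the synthetic fingerprint/activity generator.

    ``potency_scale`` is the EC50 (in raw abundance units, median feature
    abundance ≈ 1.4 after blending) shared by the planted active features
    up to a fixed ×0.8/×1/×1.25 spread; ``active_power`` is the Hill slope
    of their cassette. ``sigma_log`` is the log-normal dispersion of base
    abundances and ``noise_sd`` the Gaussian activity noise (clipped to
    [0, 1]).

    Active features share a log-normal common factor with loading
    ``active_corr_weight``: congeneric constituents of one biosynthetic
    pathway rise and fall together across source plants, so their
    log-abundances correlate (≈ weight² between any two actives).
    Inactive features are mutually independent.
    """

    n_base: int = 12
    n_features: int = 73
    n_cassettes: int = 3
    n_active: int = 3
    active_cassette: int = 1
    potency_scale: float = 4.2
    active_power: float = 3.0
    sigma_log: float = 0.4
    active_corr_weight: float = 0.9
    noise_sd: float = 0.05
    spectrum_noise: float = 0.01
    wavelengths: tuple = tuple(range(200, 401, 2))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_base < 2 or self.n_features < 1:
            raise ValueError("need >=2 base samples and >=1 feature")
        if not 1 <= self.n_cassettes <= self.n_features:
            raise ValueError("n_cassettes must lie in [1, n_features]")
        if not 1 <= self.active_cassette <= self.n_cassettes:
            raise ValueError("active_cassette out of range")
        if self.n_active < 0:
            raise ValueError("n_active must be >= 0")
        if self.sigma_log <= 0 or self.noise_sd < 0 or self.spectrum_noise < 0:
            raise ValueError("dispersion must be > 0 and noise sds >= 0")
        if not 0 <= self.active_corr_weight <= 1:
            raise ValueError("active_corr_weight must lie in [0, 1]")

    @property
    def feature_ids(self) -> tuple:
        return tuple(f"F{i + 1:03d}" for i in range(self.n_features))

    def cassette_assignment(self) -> CassetteAssignment:
        """Contiguous near-equal split of features into cassettes."""
        labels = 1 + (
            np.arange(self.n_features) * self.n_cassettes // self.n_features
        )
        return CassetteAssignment(pd.Series(labels, index=list(self.feature_ids)))

    def active_feature_ids(self) -> tuple:
        labels = self.cassette_assignment().labels
        in_cassette = [f for f in self.feature_ids if labels[f] == self.active_cassette]
        if self.n_active > len(in_cassette):
            raise ValueError("more actives requested than features in the cassette")
        return tuple(in_cassette[: self.n_active])


@dataclass(frozen=True)
class SyntheticTruth:
    """A generated dataset together with its complete ground truth."""

    config: GeneratorConfig
    base_table: FeatureTable
    table: FeatureTable
    spectra: SpectrumSet
    cassettes: CassetteAssignment
    active_features: tuple
    params: JointModelParams | None
    activity_true: pd.Series
    activity: pd.Series
    n_clipped: int = 0


_POTENCY_SPREAD = (0.8, 1.0, 1.25)


def _true_params(config: GeneratorConfig) -> JointModelParams | None:
    actives = config.active_feature_ids()
    if not actives:
        return None
    potencies = np.array(
        [
            config.potency_scale * _POTENCY_SPREAD[i % len(_POTENCY_SPREAD)]
            for i in range(len(actives))
        ]
    )
    return JointModelParams(
        feature_ids=actives,
        potencies=potencies,
        powers=np.array([config.active_power]),
    )


def generate_dataset(config: GeneratorConfig | None = None) -> SyntheticTruth:
    """Generate base fingerprints, 1:1 blends, spectra and activities.

    Base abundances are drawn log-normal per feature (median 1, dispersion
    ``sigma_log``), blended over all pairs, and scored by the ground-truth
    Olmstead model restricted to the active features; Gaussian noise is
    added and the result clipped to [0, 1] (the clip count is recorded).
    Bit-identical for a given config.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))

    base_ids = [f"S{i + 1:02d}" for i in range(config.n_base)]
    z = rng.normal(size=(config.n_base, config.n_features))
    actives_mask = np.isin(list(config.feature_ids), config.active_feature_ids())
    if actives_mask.any() and config.active_corr_weight > 0:
        w = config.active_corr_weight
        z_common = rng.normal(size=(config.n_base, 1))
        z[:, actives_mask] = w * z_common + math.sqrt(1 - w**2) * z[:, actives_mask]
    abundance = pd.DataFrame(
        np.exp(config.sigma_log * z),
        index=base_ids,
        columns=list(config.feature_ids),
    )
    rts = pd.Series(
        np.linspace(0.5, 9.5, config.n_features), index=list(config.feature_ids)
    )
    base_table = FeatureTable(abundance=abundance, retention_times=rts)
    table = blend_profiles(base_table, pairwise_design(base_ids))

    cassettes = config.cassette_assignment()
    actives = config.active_feature_ids()
    params = _true_params(config)
    if params is None:
        activity_true = pd.Series(0.0, index=table.abundance.index)
    else:
        active_cassettes = CassetteAssignment.single(actives)
        conc = table.abundance.loc[:, list(actives)].to_numpy(float)
        activity_true = pd.Series(
            olmstead_predict(conc, params, active_cassettes),
            index=table.abundance.index,
        )

    noisy = activity_true + rng.normal(0.0, config.noise_sd, size=len(activity_true))
    clipped = noisy.clip(0.0, 1.0)
    n_clipped = int(((noisy < 0) | (noisy > 1)).sum())

    return SyntheticTruth(
        config=config,
        base_table=base_table,
        table=table,
        spectra=generate_spectra(config),
        cassettes=cassettes,
        active_features=actives,
        params=params,
        activity_true=activity_true,
        activity=clipped,
        n_clipped=n_clipped,
    )


# Well-separated absorption-band archetypes (center nm, width nm, amplitude)
# for the first few cassettes; further cassettes are spread procedurally.
_ARCHETYPE_BANDS: tuple[tuple[tuple[float, float, float], ...], ...] = (
    ((225.0, 12.0, 1.0), (270.0, 18.0, 0.85)),
    ((212.0, 9.0, 1.0), (320.0, 24.0, 0.9)),
    ((245.0, 14.0, 0.7), (368.0, 20.0, 1.0)),
    ((206.0, 8.0, 1.0), (292.0, 14.0, 0.6), (350.0, 16.0, 0.5)),
)


def _archetype(cassette: int, wavelengths: np.ndarray) -> np.ndarray:
    if cassette - 1 < len(_ARCHETYPE_BANDS):
        bands = _ARCHETYPE_BANDS[cassette - 1]
    else:
        center = 210.0 + 175.0 * ((cassette * 0.381966) % 1.0)
        bands = ((center, 12.0, 1.0), (min(395.0, center + 60.0), 18.0, 0.7))
    spectrum = np.zeros_like(wavelengths, dtype=float)
    for center, width, amp in bands:
        spectrum += amp * np.exp(-0.5 * ((wavelengths - center) / width) ** 2)
    return spectrum


def generate_spectra(config: GeneratorConfig | None = None) -> SpectrumSet:
    """Per-feature UV spectra with cassette archetype structure.

    Each cassette has a fixed archetype built from Gaussian absorption
    bands; a feature's spectrum is its cassette archetype with
    feature-specific band-amplitude jitter plus measurement noise, both
    scaled by ``spectrum_noise`` (zero noise reproduces the archetypes
    exactly, so within-cassette correlation is exactly 1).
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    wavelengths = np.asarray(config.wavelengths, dtype=float)
    labels = config.cassette_assignment().labels
    archetypes = {
        g: _archetype(g, wavelengths) for g in range(1, config.n_cassettes + 1)
    }
    rows = []
    for fid in config.feature_ids:
        arch = archetypes[int(labels[fid])]
        shape_jitter = 1.0 + rng.normal(0.0, 3.0 * config.spectrum_noise)
        warped = arch ** shape_jitter if shape_jitter > 0 else arch
        noise = rng.normal(0.0, config.spectrum_noise * arch.max(), size=arch.shape)
        rows.append(np.clip(warped + noise, 0.0, None))
    absorbance = pd.DataFrame(
        rows, index=list(config.feature_ids), columns=wavelengths
    )
    return SpectrumSet(absorbance=absorbance)


def standard_mixture_dataset(
    powers: np.ndarray | list[float],
    cassette_labels: list[int] | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    ec_tables: tuple[ECTable, ...] = STANDARD_EC_TABLES,
    total_concentration: float = 500.0,
    n_dilutions: int = 7,
) -> tuple[FeatureTable, pd.Series, JointModelParams, CassetteAssignment]:
    """Designed standard-mixture dataset for model-adequacy comparisons.

    Resolves the 8-mixture level layout against the standards' EC tables,
    expands each mixture into a two-fold dilution series (8 × n_dilutions
    concentration points), and generates activities from an Olmstead truth
    whose potencies are the standards' EC50s and whose cassette powers are
    given (steep powers make the dose-response strongly sigmoidal). Returns
    the concentration table (μg/mL), noisy activities, the generating
    parameters and the cassette assignment.
    """
    names = [t.name for t in ec_tables]
    if cassette_labels is None:
        cassette_labels = [1] * len(names)
    cassettes = CassetteAssignment(pd.Series(cassette_labels, index=names))
    params = JointModelParams(
        feature_ids=tuple(names),
        potencies=np.array([t.ec(0.50) for t in ec_tables]),
        powers=np.asarray(powers, dtype=float),
    )

    rows, ids = [], []
    for mix in resolve_design(ec_tables, total_concentration):
        for j, c_total in enumerate(dilution_series(total_concentration, 2.0, n_dilutions)):
            rows.append(mix.ratios * c_total)
            ids.append(f"M{mix.mixture_id}D{j + 1}")
    conc = pd.DataFrame(rows, index=ids, columns=names)
    rts = pd.Series(np.linspace(1.0, 8.0, len(names)), index=names)
    table = FeatureTable(abundance=conc, retention_times=rts)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    truth = olmstead_predict(conc.to_numpy(float), params, cassettes)
    activity = pd.Series(truth, index=ids) + rng.normal(0.0, noise_sd, size=len(ids))
    return table, activity.clip(0.0, 1.0), params, cassettes
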