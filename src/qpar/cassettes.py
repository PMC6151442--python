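"""Cassette assignment from UV-DAD spectra.

Chemicals with similar chromophores absorb similarly in the UV, and similar
structure is taken as a proxy for a shared mode of action. Features are
therefore grouped into cassettes for the Olmstead model by clustering their
UV absorbance spectra (200-400 nm): Pearson correlation for the diagnostic
heat-map, k-means on area-normalized spectra for the assignment, and a
silhouette-based recommendation of the cassette number with PCA score-plot
coordinates emitted for visual confirmation or override.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .joint import CassetteAssignment

__all__ = [
    "SpectrumSet",
    "KDiagnostics",
    "spectrum_correlation",
    "cluster_cassettes",
    "choose_k",
]


@dataclass(frozen=True)
class SpectrumSet:
    """Per-feature UV absorbance over a common wavelength grid.

    ``absorbance`` has one row per feature and one column per wavelength
    (nm); wavelengths must increase strictly.
    """

    absorbance: pd.DataFrame

    def __post_init__(self) -> None:
        wl = self.wavelengths
        if len(wl) and np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.absorbance.index.has_duplicates:
            raise ValueError("duplicate feature ids in spectrum set")
        if not np.all(np.isfinite(self.absorbance.to_numpy(dtype=float))):
            raise ValueError("absorbances must be finite")

    @property
    def feature_ids(self) -> tuple:
        return tuple(self.absorbance.index)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.absorbance.columns.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.absorbance.shape[0]


def spectrum_correlation(spectra: SpectrumSet) -> pd.DataFrame:
    """Pairwise Pearson correlation of feature spectra.

    Returns a symmetric matrix with unit diagonal. Constant spectra have no
    defined correlation; their off-diagonal entries are NaN and a warning
    names them.
    """
    if spectra.n_features < 2 or spectra.absorbance.shape[1] < 3:
        raise ValueError("need >=2 features and >=3 wavelengths")
    values = spectra.absorbance.to_numpy(dtype=float)
    constant = values.std(axis=1) == 0
    if constant.any():
        flagged = list(np.asarray(spectra.feature_ids)[constant])
        warnings.warn(
            f"constant spectra have undefined correlations: {flagged}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=spectra.feature_ids, columns=spectra.feature_ids)


def _area_normalize(values: np.ndarray) -> np.ndarray:
    """Scale each spectrum to unit area so shape, not intensity, drives clustering."""
    area = values.sum(axis=1, keepdims=True)
    safe = np.where(area == 0, 1.0, area)
    return values / safe


def cluster_cassettes(spectra: SpectrumSet, k: int, seed: int = 0) -> CassetteAssignment:
    """k-means clustering of area-normalized spectra into ``k`` cassettes.

    Runs 20 seeded restarts and keeps the best inertia; labels are
    relabelled 1..k in order of first appearance so the assignment is
    deterministic for a given seed and invariant content-wise under feature
    reordering.
    """
    if not 1 <= k <= spectra.n_features:
        raise ValueError(f"k={k} outside [1, {spectra.n_features}]")
    if k == 1:
        return CassetteAssignment.single(spectra.feature_ids)
    values = _area_normalize(spectra.absorbance.to_numpy(dtype=float))
    km = KMeans(n_clusters=k, n_init=20, random_state=seed)
    raw = km.fit_predict(values)
    # canonical labels: 1..k by order of first appearance
    order = {lab: i + 1 for i, lab in enumerate(pd.unique(raw))}
    labels = pd.Series([order[lab] for lab in raw], index=list(spectra.feature_ids))
    return CassetteAssignment(labels)


@dataclass(frozen=True)
class KDiagnostics:
    """Outcome of the cassette-number scan.

    ``recommended_k`` maximises the mean silhouette over the scanned range;
    ``pca_scores`` holds the 2-component score-plot coordinates for the
    visual check, preserving the option of a human override.
    """

    recommended_k: int
    silhouettes: dict[int, float]
    pca_scores: pd.DataFrame
    note: str = ""


# Mean silhouette below this is treated as "no real cluster structure".
_FLAT_SILHOUETTE = 0.25


def choose_k(spectra: SpectrumSet, k_range, seed: int = 0) -> KDiagnostics:
    """Recommend a cassette number by silhouette score over ``k_range``.

    Each candidate ``k`` (>=2) is clustered as in :func:`cluster_cassettes`
    and scored by mean silhouette on the area-normalized spectra; k=1 in
    the range is recorded with silhouette 0 (undefined). A flat/low profile
    is flagged with a "consider k=1" note.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    if ks[0] < 1 or ks[-1] > spectra.n_features:
        raise ValueError(f"k range must lie within [1, {spectra.n_features}]")
    values = _area_normalize(spectra.absorbance.to_numpy(dtype=float))
    pca = PCA(n_components=2, random_state=seed)
    scores = pca.fit_transform(values)
    pca_scores = pd.DataFrame(
        scores, index=list(spectra.feature_ids), columns=["PC1", "PC2"]
    )

    silhouettes: dict[int, float] = {}
    for k in ks:
        if k < 2 or k >= spectra.n_features:
            silhouettes[k] = 0.0
            continue
        labels = cluster_cassettes(spectra, k, seed=seed).labels.to_numpy()
        silhouettes[k] = float(silhouette_score(values, labels))

    scorable = [k for k in ks if silhouettes[k] != 0.0]
    if not scorable:
        return KDiagnostics(ks[0], silhouettes, pca_scores, note="single candidate")
    best = max(scorable, key=lambda k: (silhouettes[k], -k))
    note = ""
    if silhouettes[best] < _FLAT_SILHOUETTE:
        note = "silhouette profile flat/low; consider k=1"
    return KDiagnostics(best, silhouettes, pca_scores, note=note)
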