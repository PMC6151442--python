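"""Delimited-text I/O, run configuration and the screening pipeline.

All artifacts are UTF-8 comma-delimited text with a single header row;
feature tables carry retention times in a reserved second header row
(sample id ``_rt``). Files written by the pipeline start with ``#`` comment
lines recording the package version, the seed and a hash of the run
configuration; readers skip such lines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cassettes import SpectrumSet, choose_k, cluster_cassettes
from .estimation import FeatureTable, minmax_normalize, pls_baseline
from .good2bad import Good2badResult, MCSConfig, good2bad_scores, run_mcs, select_features
from .hill import EC_LEVELS, ECTable
from .joint import CassetteAssignment

__all__ = [
    "RunConfig",
    "ScreenReport",
    "read_feature_table",
    "write_feature_table",
    "read_activity",
    "write_activity",
    "read_spectra",
    "write_spectra",
    "read_cassettes",
    "write_cassettes",
    "read_ec_tables",
    "write_ec_tables",
    "write_ranking",
    "run_screen",
]

logger = logging.getLogger("qpar")

_RT_ROW = "_rt"


def _meta_lines(meta: dict | None) -> str:
    lines = [f"# qpar {__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}={value}")
    return "\n".join(lines) + "\n"


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=0)


def write_feature_table(table: FeatureTable, path, meta: dict | None = None) -> None:
    """Write a feature table with the ``_rt`` retention-time header row."""
    path = Path(path)
    frame = pd.concat(
        [table.retention_times.rename(_RT_ROW).to_frame().T, table.abundance]
    )
    frame.index.name = "sample_id"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_lines(meta))
        frame.to_csv(fh)


def read_feature_table(path) -> FeatureTable:
    """Read and validate a feature table written by :func:`write_feature_table`."""
    path = Path(path)
    try:
        frame = _read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed delimited file ({exc})") from exc
    if _RT_ROW not in frame.index:
        raise ValueError(f"{path}: missing '{_RT_ROW}' retention-time row")
    rts = frame.loc[_RT_ROW].astype(float)
    abundance = frame.drop(index=_RT_ROW).astype(float)
    negative = np.argwhere(abundance.to_numpy() < 0)
    if len(negative):
        r, c = negative[0]
        raise ValueError(
            f"{path}: negative abundance at sample {abundance.index[r]!r}, "
            f"feature {abundance.columns[c]!r}"
        )
    if abundance.index.has_duplicates:
        dups = abundance.index[abundance.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dups}")
    table = FeatureTable(abundance=abundance, retention_times=rts)
    logger.info("read %d samples × %d features from %s",
                table.n_samples, table.n_features, path)
    return table


def write_activity(activity: pd.Series, path, meta: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_lines(meta))
        activity.rename("inhibition_rate").rename_axis("sample_id").to_csv(fh)


def read_activity(path) -> pd.Series:
    """Read a two-column (sample id, inhibition rate) activity file."""
    frame = _read_csv(path)
    series = frame.iloc[:, 0].astype(float)
    if ((series < 0) | (series > 1)).any():
        bad = series[(series < 0) | (series > 1)].index.tolist()
        raise ValueError(f"{path}: inhibition rates outside [0, 1] for {bad}")
    return series


def write_spectra(spectra: SpectrumSet, path, meta: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_lines(meta))
        spectra.absorbance.rename_axis("feature_id").to_csv(fh)


def read_spectra(path) -> SpectrumSet:
    frame = _read_csv(path)
    frame.columns = frame.columns.astype(float)
    return SpectrumSet(absorbance=frame.astype(float))


def write_cassettes(cassettes: CassetteAssignment, path, meta: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_lines(meta))
        cassettes.labels.rename("cassette").rename_axis("feature_id").to_csv(fh)


def read_cassettes(path) -> CassetteAssignment:
    frame = _read_csv(path)
    return CassetteAssignment(frame.iloc[:, 0].astype(int))


def write_ec_tables(tables: list[ECTable] | tuple[ECTable, ...], path,
                    meta: dict | None = None) -> None:
    """Write EC tables in the standard layout (standard, name, EC5..EC50)."""
    rows = []
    for i, tbl in enumerate(tables, start=1):
        rows.append(
            {"standard": i, "name": tbl.name,
             **{f"EC{int(x * 100)}": tbl.values[x] for x in EC_LEVELS}}
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_lines(meta))
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_ec_tables(path) -> list[ECTable]:
    frame = pd.read_csv(path, comment="#")
    tables = []
    for _, row in frame.iterrows():
        values = {x: float(row[f"EC{int(x * 100)}"]) for x in EC_LEVELS}
        tables.append(ECTable(name=str(row["name"]), values=values))
    return tables


def write_ranking(result: Good2badResult, table: FeatureTable, path,
                  meta: dict | None = None) -> None:
    """Write the ranked Good2bad table (id, RT, frequencies, score, rank)."""
    out = result.table.copy()
    out.insert(0, "rt", table.retention_times.reindex(out.index))
    out = out.sort_values(by=["score", "f_sem"], ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_lines(meta))
        out.rename_axis("feature_id").to_csv(fh)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one screening run.

    Cassette mode is one of ``auto`` (silhouette-chosen k from spectra),
    ``fixed`` (cluster spectra at ``cassette_k``) or ``file`` (read the
    assignment from ``cassette_file``).
    """

    feature_table: str
    activity_file: str
    spectra_file: str | None = None
    cassette_file: str | None = None
    cassette_mode: str = "auto"
    cassette_k: int = 3
    model: str = "olmstead"
    mcs: MCSConfig = field(default_factory=MCSConfig)
    top_k: int = 3
    seed: int = 0
    out_dir: str = "qpar_out"

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        mcs_raw = raw.pop("mcs", {})
        cfg = cls(**raw, mcs=MCSConfig(**mcs_raw))
        for key in ("feature_table", "activity_file", "spectra_file", "cassette_file"):
            value = getattr(cfg, key)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{key}: {value} does not exist")
        return cfg


@dataclass(frozen=True)
class ScreenReport:
    """Bundle returned by :func:`run_screen`."""

    ranking: Good2badResult | None
    selected: list
    cassettes: CassetteAssignment | None
    summary: dict
    out_dir: Path


def _resolve_cassettes(config: RunConfig, table: FeatureTable) -> CassetteAssignment:
    if config.cassette_mode == "file":
        if not config.cassette_file:
            raise ValueError("cassette_mode=file requires cassette_file")
        return read_cassettes(config.cassette_file)
    if not config.spectra_file:
        raise ValueError(f"cassette_mode={config.cassette_mode} requires spectra_file")
    spectra = read_spectra(config.spectra_file)
    if config.cassette_mode == "fixed":
        k = config.cassette_k
    elif config.cassette_mode == "auto":
        upper = min(6, spectra.n_features - 1)
        diag = choose_k(spectra, range(2, max(3, upper + 1)), seed=config.seed)
        k = diag.recommended_k
        logger.info("auto cassette number: k=%d (silhouettes %s)", k, diag.silhouettes)
    else:
        raise ValueError(f"unknown cassette_mode {config.cassette_mode!r}")
    return cluster_cassettes(spectra, k, seed=config.seed)


def run_screen(config: RunConfig) -> ScreenReport:
    """Execute normalize → cassette assignment → MCS Good2bad → ranking.

    Writes the ranked feature table and a machine-readable JSON summary
    into ``config.out_dir``; byte-identical outputs for identical
    config and seed. With ``model="pls"`` a PLS-coefficient ranking is
    emitted instead of the Monte Carlo screen.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config": config.config_hash()}

    current_stage = "init"

    def stage(name):
        nonlocal current_stage
        current_stage = name
        logger.info("stage: %s", name)

    try:
        stage("read inputs")
        table = read_feature_table(config.feature_table)
        activity = read_activity(config.activity_file).reindex(table.abundance.index)
        if activity.isna().any():
            raise ValueError("activity missing for some samples")

        stage("min-max normalization")
        normed = minmax_normalize(table)
        if normed.constant_features:
            logger.warning("constant features: %s", list(normed.constant_features))

        summary: dict = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "model": config.model,
            "n_samples": table.n_samples,
            "n_features": table.n_features,
            "constant_features": list(normed.constant_features),
        }

        if config.model == "pls":
            stage("pls ranking")
            pls = pls_baseline(normed, activity, seed=config.seed)
            coef = pls.coefficients.abs().sort_values(ascending=False, kind="stable")
            ranked = coef.rename("abs_coefficient").to_frame()
            ranked.insert(0, "rt", table.retention_times.reindex(ranked.index))
            ranked["rank"] = np.arange(1, len(ranked) + 1)
            with open(out_dir / "ranked_features.csv", "w", encoding="utf-8") as fh:
                fh.write(_meta_lines(meta))
                ranked.rename_axis("feature_id").to_csv(fh)
            selected = list(coef.index[: config.top_k])
            summary.update({"r2": pls.r2, "selected": selected})
            result, cassettes = None, None
        else:
            stage("cassette assignment")
            cassettes = None
            if config.model == "olmstead":
                cassettes = _resolve_cassettes(config, table)
                write_cassettes(cassettes, out_dir / "cassettes.csv", meta)
                summary["n_cassettes"] = cassettes.m
            stage("monte carlo screen")
            mcs = dataclasses.replace(config.mcs, seed=config.seed)
            records = run_mcs(normed, activity, cassettes, mcs, model=config.model)
            stage("good2bad scoring")
            result = good2bad_scores(records, table.feature_ids, mcs.tail_frac)
            selected = select_features(result, config.top_k)
            write_ranking(result, table, out_dir / "ranked_features.csv", meta)
            summary.update(
                {
                    "selected": selected,
                    "n_models": result.n_models,
                    "n_tail": result.n_tail,
                    "sem_threshold": result.sem_threshold,
                    "bem_threshold": result.bem_threshold,
                    "mcs": dataclasses.asdict(mcs),
                }
            )
    except Exception as exc:
        raise RuntimeError(
            f"screening failed at stage {current_stage!r}: {exc}"
        ) from exc

    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return ScreenReport(
        ranking=result, selected=selected, cassettes=cassettes,
        summary=summary, out_dir=out_dir,
    )
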