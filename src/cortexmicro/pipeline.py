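"""End-to-end orchestration: score -> extract/ingest -> stats -> mlm -> pls.

The stages are library functions; this module wires them together behind a
single :class:`PipelineConfig`, handles the shared table formats, and writes
a run manifest (config snapshot, seed, package version, input checksums)
sufficient to re-run the deterministic stages bit-identically.

Randomness discipline: one seed per run; each stochastic stage draws from
its own fixed substream of that seed, so toggling one stage never perturbs
another's random numbers.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, atlas, bpls, cohort_stats, mlm, psychosex, synthdata

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "ingest_roi_table",
    "brain_long_format",
    "table1_report",
    "run_all",
    "reproduce_from_deposit",
]

GROUP_ORDER = ("cis_boy", "gd_afab", "cis_girl")
_STAGE_NAMES = ("cohort", "brain", "stats", "mlm", "pls")


@dataclass
class PipelineConfig:
    out_dir: str = "results"
    seed: int = 0
    participants_csv: str | None = None  # None -> simulate
    brain_csv: str | None = None         # None -> simulate
    gm_threshold: float = 0.40
    n_perm: int = 1000
    n_boot: int = 1000
    stability_threshold: float = 3.0
    permutation_scheme: str = "whole_sample"
    group_sizes: tuple = (14, 15, 17)
    run_stats: bool = True
    run_mlm: bool = True
    run_pls: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "group_sizes" in raw:
            raw["group_sizes"] = tuple(raw["group_sizes"])
        return cls(**raw)

    def validate(self) -> None:
        for key in ("participants_csv", "brain_csv"):
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"config {key}={path!r} does not resolve")

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class RunManifest:
    config: dict
    config_hash: str
    seed: int
    package_version: str
    started: str
    finished: str = ""
    input_checksums: dict = field(default_factory=dict)
    stage_status: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def ingest_roi_table(path_or_df, group_order=GROUP_ORDER) -> dict:
    """Validate and canonicalize a wide participant x ROI table.

    Expects ``id``, ``group``, the three behavior columns (``strength``,
    ``degree``, ``age_months``) and the 152 brain columns named as in
    :func:`cortexmicro.atlas.column_names` (any column order).  Rows are
    sorted group-major in ``group_order``.  Returns a dict with ``X_raw``
    (n x 152), ``Y`` (n x 3), ``group_sizes``, ``ids``, ``columns``.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    brain_cols = atlas.column_names()
    required = ["id", "group", *bpls.BEHAVIOR_COLUMNS, *brain_cols]
    missing = [c for c in required if c not in df.columns]
    dupes = df.columns[df.columns.duplicated()].tolist()
    if missing or dupes:
        raise ValueError(
            f"bad ROI table: missing columns {missing[:8]}"
            + (f"... ({len(missing)} total)" if len(missing) > 8 else "")
            + (f"; duplicated columns {dupes}" if dupes else "")
        )
    if df["id"].duplicated().any():
        raise ValueError("duplicated participant ids")
    unknown_groups = set(df["group"]) - set(group_order)
    if unknown_groups:
        raise ValueError(f"unknown groups {sorted(unknown_groups)}")
    df = df.copy()
    df["__order"] = df["group"].map({g: i for i, g in enumerate(group_order)})
    df = df.sort_values(["__order", "id"], kind="stable")
    group_sizes = tuple(int((df["group"] == g).sum()) for g in group_order)
    missing_beh = df[list(bpls.BEHAVIOR_COLUMNS)].isna().any(axis=1)
    if missing_beh.any():
        import logging

        logging.getLogger(__name__).warning(
            "excluding %d participants with missing behavior values",
            int(missing_beh.sum()),
        )
        df = df[~missing_beh]
        group_sizes = tuple(int((df["group"] == g).sum()) for g in group_order)
    return {
        "X_raw": df[brain_cols].to_numpy(dtype=float),
        "Y": df[list(bpls.BEHAVIOR_COLUMNS)].to_numpy(dtype=float),
        "group_sizes": group_sizes,
        "ids": df["id"].tolist(),
        "columns": brain_cols,
        "frame": df.drop(columns="__order"),
    }


def brain_long_format(wide: pd.DataFrame) -> pd.DataFrame:
    """Wide 152-column ROI table -> long (id, roi_id, t1, md) for the MLM."""
    n = atlas.N_ROIS
    cols = atlas.column_names()
    t1 = wide[cols[:n]].to_numpy(dtype=float)
    md = wide[cols[n:]].to_numpy(dtype=float)
    n_sub = len(wide)
    return pd.DataFrame({
        "id": np.repeat(wide["id"].to_numpy(), n),
        "roi_id": np.tile(np.arange(1, n + 1), n_sub),
        "t1": t1.ravel(),
        "md": md.ravel(),
    })


def table1_report(participants: pd.DataFrame) -> dict:
    """Group descriptives + omnibus/robust tests for the four key variables."""
    out = {}
    for var in ("age_months", "gidyq_mean", "strength", "degree"):
        groups = [
            participants.loc[participants["group"] == g, var].dropna().to_numpy(float)
            for g in GROUP_ORDER
        ]
        report = cohort_stats.anova_report(groups, labels=list(GROUP_ORDER),
                                           variable=var)
        out[var] = {
            "descriptives": cohort_stats.describe_groups(
                participants, var, group_order=list(GROUP_ORDER)
            ).round(3).to_dict(orient="records"),
            **report.to_dict(),
        }
    return out


def run_all(config: PipelineConfig) -> dict:
    """Execute the configured stages and write outputs + manifest.

    Synthetic inputs are generated for any stage whose input path is not
    configured.  A stage failure aborts the run with the failing stage named;
    outputs of completed stages are retained on disk.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=asdict(config), config_hash=config.config_hash, seed=config.seed,
        package_version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    stage_seeds = {
        name: np.random.SeedSequence(config.seed).spawn(len(_STAGE_NAMES))[i]
        for i, name in enumerate(_STAGE_NAMES)
    }
    results: dict = {}
    current = "cohort"
    try:
        if config.participants_csv:
            manifest.input_checksums["participants_csv"] = _checksum(
                config.participants_csv
            )
            records = psychosex.load_participants(config.participants_csv)
            participants = psychosex.participants_frame(records)
        else:
            spec = synthdata.CohortSpec(group_sizes=tuple(config.group_sizes))
            participants, _items = synthdata.generate_cohort(
                spec, seed=stage_seeds["cohort"]
            )
        participants.to_csv(out_dir / "participants.csv", index=False)
        results["participants"] = participants
        manifest.stage_status["cohort"] = "ok"

        current = "brain"
        if config.brain_csv:
            manifest.input_checksums["brain_csv"] = _checksum(config.brain_csv)
            ingested = ingest_roi_table(config.brain_csv)
        else:
            wide = synthdata.generate_brain(participants,
                                            seed=stage_seeds["brain"])
            wide = wide.merge(
                participants[["id", *bpls.BEHAVIOR_COLUMNS]], on="id"
            )
            ingested = ingest_roi_table(wide)
        results["brain"] = ingested
        manifest.stage_status["brain"] = "ok"

        if config.run_stats:
            current = "stats"
            stats_report = table1_report(participants)
            _dump_json(out_dir / "cohort_stats.json", stats_report,
                       config, "stats")
            results["stats"] = stats_report
            manifest.stage_status["stats"] = "ok"

        if config.run_mlm:
            current = "mlm"
            long = brain_long_format(ingested["frame"])
            fit = mlm.fit_random_intercept(mlm.standardize(long))
            _dump_json(out_dir / "mlm_fit.json", fit.to_dict(), config, "mlm")
            results["mlm"] = fit
            manifest.stage_status["mlm"] = "ok"

        if config.run_pls:
            current = "pls"
            pls_seed = int(stage_seeds["pls"].generate_state(1)[0] % (2**31))
            res = bpls.run_bpls(
                ingested["X_raw"], ingested["Y"], ingested["group_sizes"],
                n_perm=config.n_perm, n_boot=config.n_boot, seed=pls_seed,
                column_names=ingested["columns"], group_labels=GROUP_ORDER,
                permutation_scheme=config.permutation_scheme,
                stability_threshold=config.stability_threshold,
            )
            _dump_json(out_dir / "pls_result.json", res.to_dict(), config, "pls")
            bpls.stable_roi_table(res).to_csv(out_dir / "stable_rois.csv",
                                              index=False)
            bpls.correlation_table(res).to_csv(
                out_dir / "behavior_correlations.csv", index=False
            )
            results["pls"] = res
            manifest.stage_status["pls"] = "ok"
    except Exception as err:
        manifest.stage_status[current] = f"failed: {err}"
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.write(out_dir / "manifest.json")
        raise RuntimeError(f"pipeline stage {current!r} failed: {err}") from err
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out_dir / "manifest.json")
    results["manifest"] = manifest
    return results


def _dump_json(path, payload: dict, config: PipelineConfig, stage: str) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"stage": stage, "seed": config.seed,
             "config_hash": config.config_hash, "result": payload},
            fh, indent=2, default=str,
        )


def reproduce_from_deposit(data_dir, n_perm: int = 1000, seed: int = 1) -> dict:
    """Re-run the key analyses on the study's deposited ROI/behavior tables.

    Expects ``data_dir`` to contain a wide CSV ``roi_behavior.csv`` laid out
    as for :func:`ingest_roi_table` plus a ``gidyq_mean`` column (assemble it
    from the Borealis deposit, doi:10.5683/SP3/QVPE0F).  Returns the
    standardized T1->MD estimate, the LV1 cross-block covariance percentage,
    and the Welch statistic for the GIDYQ-AA group comparison.
    """
    path = Path(data_dir) / "roi_behavior.csv"
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found: download the deposited tables "
            "(doi:10.5683/SP3/QVPE0F) and assemble them into roi_behavior.csv"
        )
    df = pd.read_csv(path)
    ingested = ingest_roi_table(df)
    frame = ingested["frame"]
    fit = mlm.fit_random_intercept(
        mlm.standardize(brain_long_format(frame))
    )
    res = bpls.run_bpls(
        ingested["X_raw"], ingested["Y"], ingested["group_sizes"],
        n_perm=n_perm, n_boot=100, seed=seed,
        column_names=ingested["columns"], group_labels=GROUP_ORDER,
    )
    groups = [
        frame.loc[frame["group"] == g, "gidyq_mean"].to_numpy(float)
        for g in GROUP_ORDER
    ]
    welch_f, *_ = cohort_stats.welch_anova(groups)
    return {
        "mlm_estimate": fit.slope_std,
        "lv1_covariance_pct": float(res.covariance_pct[0]),
        "gidyq_welch_f": welch_f,
    }
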