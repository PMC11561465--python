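"""Formats, configuration, and the end-to-end pipeline driver.

Canonical CSV schemas (UTF-8, comma-separated, ``.`` decimal, header row
mandatory, coordinates always in micrometres):

* cell table — ``specimen_id, cell_id, x_um, y_um, z_um, ki67, dcx, sox9,
  brdu, reporter, kc_id``
* KC table — ``kc_id, n_tap, n_prnb, size, prnb_fraction, kc_type,
  pmnb_assoc, age_days, labeled, n_labeled, reporter, x_um, y_um, z_um``

`run_pipeline` chains synthetic generation → KC detection/classification →
spatial statistics → turnover closed forms → clone snapshot sampling into one
reproducible run: every output is regenerable from (config, seed), and a
provenance manifest records parameters, seeds, per-stage status, warnings,
and output file hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clone_model, kc_analysis, spatial_stats, synthetic_data, turnover_model
from .regions import region_from_dict

SCHEMA_VERSION = "1.0"

log = logging.getLogger("kcdyn")

CELL_REQUIRED = ["specimen_id", "cell_id", "x_um", "y_um", "z_um", "ki67", "dcx"]
CELL_BOOL = ["ki67", "dcx", "brdu"]
CELL_OPTIONAL_DEFAULTS = {"sox9": "neg", "brdu": False, "reporter": "none", "kc_id": pd.NA}


def read_cell_table(path) -> pd.DataFrame:
    """Read and validate a cell-table CSV.

    Required columns are checked by name; marker columns must be boolean-like
    (bool, 0/1, or true/false strings) — a non-boolean value fails with the
    offending row index. Unknown columns are preserved untouched.
    """
    df = pd.read_csv(path)
    for col in CELL_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"cell table {path} is missing required column {col!r}")
    for col, default in CELL_OPTIONAL_DEFAULTS.items():
        if col not in df.columns:
            df[col] = default
    xyz = df[["x_um", "y_um", "z_um"]]
    if not np.all(np.isfinite(xyz.to_numpy(float))):
        bad = int(np.flatnonzero(~np.isfinite(xyz.to_numpy(float)).all(axis=1))[0])
        raise ValueError(f"non-finite coordinates at row {bad}")
    truthy = {"true": True, "false": False, "1": True, "0": False,
              "1.0": True, "0.0": False, "t": True, "f": False}
    for col in CELL_BOOL:
        vals = df[col]
        parsed = vals.astype(str).str.strip().str.lower().map(truthy)
        if parsed.isna().any():
            bad = int(parsed.index[parsed.isna()][0])
            raise ValueError(
                f"non-boolean value {vals.loc[bad]!r} in column {col!r} at row {bad}"
            )
        df[col] = parsed.astype(bool)
    log.info("read %d cell records from %s", len(df), path)
    return df


def write_cell_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_kc_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("kc_id", "n_tap", "n_prnb", "x_um", "y_um", "z_um"):
        if col not in df.columns:
            raise ValueError(f"KC table {path} is missing required column {col!r}")
    return df


@dataclass
class RunConfig:
    """Full configuration of one pipeline run (serializable to YAML)."""

    seed: int = 0
    out_dir: str = "kcdyn_run"
    region: dict = field(default_factory=lambda: {"kind": "box", "lo": [0, 0, 0], "hi": [2000, 2000, 2000]})
    n_kc: int = 288
    contact_radius: float = kc_analysis.DEFAULT_CONTACT_RADIUS
    run_spatial: bool = True
    run_turnover: bool = True
    run_clone: bool = True
    n_sim_envelope: int = 199
    n_perm_moran: int = 199
    turnover_rate: float = 0.094
    label_prob: float = 0.361
    n_clone_snapshots: int = 2000
    schema_version: str = SCHEMA_VERSION

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic → detection → analysis chain.

    Deterministic under a fixed (config, seed): CSV outputs are
    byte-identical across repeats. Each stage runs independently; a failing
    stage is recorded in the manifest with its name and cause and does not
    corrupt the outputs of the others.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "schema_version": config.schema_version,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
        "warnings": [],
        "outputs": {},
    }
    results: dict = {"manifest": manifest}
    region = region_from_dict(config.region)

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
            manifest["stages"][name] = {"status": "ok", "seconds": round(time.perf_counter() - t0, 3)}
        except Exception as exc:  # pragma: no cover - exercised via broken configs
            log.exception("stage %s failed", name)
            manifest["stages"][name] = {
                "status": "failed", "error": f"{type(exc).__name__}: {exc}",
                "seconds": round(time.perf_counter() - t0, 3),
            }

    specimen_box: dict = {}

    def _simulate():
        cfg = synthetic_data.SpecimenConfig(
            n_kc=config.n_kc,
            region=region,
            renewal=turnover_model.RenewalParams(rate=config.turnover_rate, label_prob=config.label_prob),
            contact_radius=config.contact_radius,
            seed=config.seed,
        )
        spec = synthetic_data.gen_specimen(cfg)
        specimen_box["spec"] = spec
        manifest["warnings"].extend(spec.metadata.get("warnings", []))
        write_cell_table(spec.cells, out / "cells.csv")
        spec.kcs.drop(columns=["members"], errors="ignore").to_csv(out / "kcs.csv", index=False)

    def _detect():
        spec = specimen_box["spec"]
        assignment, kcs, small = kc_analysis.detect_kcs(spec.cells, config.contact_radius)
        results["kcs"] = kcs
        results["small_groups"] = small
        kcs.drop(columns=["members"], errors="ignore").to_csv(out / "kcs_detected.csv", index=False)
        small.drop(columns=["members"], errors="ignore").to_csv(out / "small_groups.csv", index=False)

    def _spatial():
        spec = specimen_box["spec"]
        env = spatial_stats.csr_envelope(
            spec.pattern, n_sim=config.n_sim_envelope, seed=config.seed + 1
        )
        kcs = results.get("kcs", spec.kcs)
        moran = spatial_stats.morans_i(
            spatial_stats.PointPattern3D(spec.pattern.points, region, marks=kcs["size"].to_numpy(float)),
            n_perm=config.n_perm_moran, seed=config.seed + 2,
        )
        results["envelope"] = env
        results["moran"] = moran
        pd.DataFrame(
            {"r_um": env.r, "g_obs": env.g_obs, "g_null_mean": env.g_null_mean,
             "env_low": env.lower, "env_high": env.upper}
        ).to_csv(out / "gfunction.csv", index=False)
        pd.DataFrame(
            [{"statistic": "morans_i_size", "value": moran.i, "p_value": moran.p_value,
              "n_points": moran.n_points, "weights": moran.weight_scheme,
              "envelope_p": env.p_value, "n_sim": env.n_sim}]
        ).to_csv(out / "spatial_summary.csv", index=False)

    def _turnover():
        params = turnover_model.RenewalParams(
            rate=config.turnover_rate, label_prob=config.label_prob, pool_size=config.n_kc
        )
        tau = params.tau
        rows = [
            {"quantity": "lifetime_days", "value": tau},
            {"quantity": "unlabeled_fraction_4d_chase",
             "value": turnover_model.expected_unlabeled_fraction(4.0, params)},
            {"quantity": "li_plateau", "value": turnover_model.expected_li(5 * tau, params)},
        ]
        results["turnover"] = pd.DataFrame(rows)
        results["turnover"].to_csv(out / "turnover_summary.csv", index=False)

    def _clone():
        snap, report = clone_model.sample_kc_snapshot(
            clone_model.CloneParams(), config.n_clone_snapshots,
            horizon=1.0 / config.turnover_rate, seed=config.seed + 3,
        )
        results["clone_snapshot"] = snap
        results["clone_report"] = report
        snap.to_csv(out / "clone_snapshot.csv", index=False)

    stage("simulate", _simulate)
    stage("detect", _detect)
    if config.run_spatial:
        stage("spatial", _spatial)
    else:
        manifest["stages"]["spatial"] = {"status": "skipped"}
    if config.run_turnover:
        stage("turnover", _turnover)
    else:
        manifest["stages"]["turnover"] = {"status": "skipped"}
    if config.run_clone:
        stage("clone", _clone)
    else:
        manifest["stages"]["clone"] = {"status": "skipped"}

    for f in sorted(out.glob("*.csv")):
        manifest["outputs"][f.name] = _hash_file(f)
    config.to_yaml(out / "config.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return results
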