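"""End-to-end experiment orchestration: configuration, logging, manifests.

``run_state_comparison`` executes the full protocol on a fixture cell:
F-I calibration, in vivo-like simulations at the configured input set,
rate-matched in vitro counterparts, and the charge / cross-correlation
analyses, writing tidy CSV tables plus a machine-readable run manifest.
Outputs are byte-for-byte reproducible from (config, master seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import compare_states, fi_line
from .bombardment import InputParameterSet, ei_metric, total_input
from .fixtures import make_reference_cell
from .metrics import IVLThresholds, consistency

log = logging.getLogger("ivlsim")

__all__ = ["ExperimentConfig", "ConfigError", "validate_config",
           "run_state_comparison", "CONFIG_TEMPLATE"]


class ConfigError(ValueError):
    """Raised with the full list of configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class ExperimentConfig:
    cell_id: int = 1
    ivl_params: tuple = ()  # (N_E, N_I, f_E, f_I); () -> fixture default
    n_seeds: int = 10
    master_seed: int = 0
    duration: float = 10000.0  # ms
    dt: float = 0.025  # ms
    window_start: float = 1000.0  # ms discarded before analysis
    thresholds: dict = field(default_factory=dict)
    check_consistency: bool = False
    save_traces: bool = False
    outdir: str = "results/state_comparison"

    def resolved_thresholds(self) -> IVLThresholds:
        return IVLThresholds(**self.thresholds)

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


_REQUIRED = ("cell_id",)
_KNOWN = set(ExperimentConfig.__dataclass_fields__)


def validate_config(config: dict | ExperimentConfig) -> ExperimentConfig:
    """Normalize a raw mapping into an :class:`ExperimentConfig`.

    Missing metric thresholds are filled with the printed defaults; errors
    are accumulated and reported together, naming the offending fields.
    """
    if isinstance(config, ExperimentConfig):
        config = config.to_dict()
    errors = []
    for key in _REQUIRED:
        if key not in config:
            errors.append(f"missing required field '{key}'")
    unknown = set(config) - _KNOWN
    if unknown:
        errors.append(f"unknown field(s): {sorted(unknown)}")
    cfg_kwargs = {k: v for k, v in config.items() if k in _KNOWN}
    if cfg_kwargs.get("cell_id") not in (1, 2, None):
        errors.append("cell_id must be 1 or 2")
    if cfg_kwargs.get("duration", 1.0) <= 0:
        errors.append("duration must be > 0")
    if cfg_kwargs.get("dt", 0.025) <= 0:
        errors.append("dt must be > 0")
    if cfg_kwargs.get("n_seeds", 1) < 1:
        errors.append("n_seeds must be >= 1")
    ivl = cfg_kwargs.get("ivl_params", ())
    if ivl and len(ivl) != 4:
        errors.append("ivl_params must be (N_E, N_I, f_E, f_I)")
    thr = cfg_kwargs.get("thresholds", {})
    bad_thr = set(thr) - set(IVLThresholds.__dataclass_fields__)
    if bad_thr:
        errors.append(f"unknown threshold field(s): {sorted(bad_thr)}")
    if errors:
        raise ConfigError(errors)
    cfg = ExperimentConfig(**cfg_kwargs)
    cfg.ivl_params = tuple(ivl)
    return cfg


def run_state_comparison(config: dict | ExperimentConfig) -> dict:
    """Execute the comparison protocol and persist its outputs.

    Writes ``fi_line.csv``, ``per_seed.csv``, ``charge.csv``, ``xcorr.csv``
    and ``run_manifest.json`` (resolved config, content hash, seeds,
    versions, per-stage status) under ``config.outdir``; returns the
    manifest.  Stage failures are recorded in the manifest and partial
    outputs preserved.
    """
    cfg = validate_config(config)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.to_dict(), "config_hash": cfg.content_hash(),
                      "version": __version__, "stages": {}}

    def _finish():
        (outdir / "run_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
        return manifest

    cell = make_reference_cell(cfg.cell_id)
    params = (InputParameterSet(*cfg.ivl_params) if cfg.ivl_params
              else cell.ivl_params)
    manifest["ivl_params"] = params.astuple()
    manifest["ei_metric"] = ei_metric(params)
    manifest["total_input"] = total_input(params)

    log.info("stage fi_line: cell %d", cfg.cell_id)
    try:
        line = fi_line(cell, duration=cfg.duration,
                       window_start=cfg.window_start)
        manifest["stages"]["fi_line"] = {
            "status": "ok", "m_hz_per_pa": line.m, "b_hz": line.b,
            "points": line.points}
        pd.DataFrame([{"m": line.m, "b": line.b,
                       "i1": line.points[0][0], "f1": line.points[0][1],
                       "i2": line.points[1][0], "f2": line.points[1][1]}
                      ]).to_csv(outdir / "fi_line.csv", index=False,
                                float_format="%.12g")
    except Exception as exc:  # noqa: BLE001 - recorded, not swallowed silently
        manifest["stages"]["fi_line"] = {"status": "failed", "error": str(exc)}
        return _finish()

    if cfg.check_consistency:
        log.info("stage consistency: %s", params)
        verdict = consistency(cell, params, n_seeds=cfg.n_seeds,
                              master_seed=cfg.master_seed,
                              duration=cfg.duration)
        manifest["stages"]["consistency"] = {
            "status": "ok", "scores": list(verdict.scores),
            "consistent": verdict.consistent}

    log.info("stage compare_states: %d seeds", cfg.n_seeds)
    try:
        charge, xcorr, per_seed = compare_states(
            cell, params, n_seeds=cfg.n_seeds, master_seed=cfg.master_seed,
            duration=cfg.duration, window_start=cfg.window_start, line=line)
        for name, df in (("charge", charge), ("xcorr", xcorr),
                         ("per_seed", per_seed)):
            df.to_csv(outdir / f"{name}.csv", index=False,
                      float_format="%.12g")
        manifest["stages"]["compare_states"] = {
            "status": "ok",
            "n_paired": int((~per_seed.skipped).sum()) if len(per_seed) else 0,
            "n_skipped": int(per_seed.skipped.sum()) if len(per_seed) else 0,
            "sites": sorted(charge.site.unique().tolist()) if len(charge) else [],
        }
    except Exception as exc:  # noqa: BLE001
        manifest["stages"]["compare_states"] = {"status": "failed",
                                                "error": str(exc)}
    return _finish()


CONFIG_TEMPLATE = """\
# ivlsim state-comparison experiment configuration
cell_id: 1            # fixture cell (1 or 2)
ivl_params: []        # [N_E, N_I, f_E, f_I]; empty -> packaged fixture set
n_seeds: 10           # re-randomizations of the bombardment
master_seed: 0        # all per-seed streams derive from this
duration: 10000.0     # ms per simulation
dt: 0.025             # ms integration step
window_start: 1000.0  # ms discarded before analysis (last 9 s analyzed)
thresholds: {}        # IVL metric overrides, e.g. {v_sd: 2.2, isi_cv: 0.8}
check_consistency: false  # also run the ten-seed consistency rule
save_traces: false    # persist full TraceSets (HDF5) per seed
outdir: results/state_comparison
"""


def load_config_file(path) -> ExperimentConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return validate_config(data)
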