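"""End-to-end pipeline: phantom -> solve -> TI map -> sweep -> report.

One YAML/dict configuration drives every stage; all validation happens
before any compute starts, and the run writes a JSON manifest listing
each output file with its SHA-256 content hash, so identical configs
give identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError, TidoseError
from .nifti_io import write_phantom, write_volume
from .phantom import (PhantomConfig, build_phantom, electrode_positions,
                      make_roi_set)
from .report import build_reports, report_to_json
from .sweep import run_sweep
from .ti import ti_envelope_map
from .solver import normalize_current, solve_channel
from .waveform import WaveformProtocol

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    electrodes: list = field(default_factory=lambda: ["F3", "F4", "TP7", "TP8"])
    currents_mA: tuple = (2.0, 2.0)
    percentile: float = 98.0
    solver_tol: float = 1e-6
    waveform: WaveformProtocol = field(default_factory=WaveformProtocol)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {"phantom", "electrodes", "currents_mA", "percentile",
                 "solver_tol", "waveform", "seed", "log_level"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        if "phantom" in raw:
            kwargs["phantom"] = PhantomConfig(**raw["phantom"])
        if "waveform" in raw:
            kwargs["waveform"] = WaveformProtocol(**raw["waveform"])
        for key in ("electrodes", "percentile", "solver_tol", "seed",
                    "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        if "currents_mA" in raw:
            kwargs["currents_mA"] = tuple(raw["currents_mA"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        self.phantom.validate()
        self.waveform.validate()
        if len(self.electrodes) < 4:
            raise ConfigurationError("pipeline needs at least 4 electrodes")
        if any(c <= 0 for c in self.currents_mA):
            raise ConfigurationError("channel currents must be positive")
        if not (0 < self.percentile < 100):
            raise ConfigurationError("percentile must lie in (0, 100)")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk).

    Validation runs before any compute, so a bad config produces no
    partial outputs.  On a stage failure the manifest is still written
    with a failure record and the error re-raised by the caller's
    discretion (status field says which stage failed).
    """
    config.validate()
    # resolve electrode labels before any compute (unknown label -> error now)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"status": "ok", "files": {}, "failure": None}

    def record(name: str, path: Path):
        manifest["files"][name] = {"path": str(path), "sha256": _sha256(path)}

    try:
        phantom = build_phantom(config.phantom)
        electrodes = electrode_positions(config.electrodes, phantom)
        for name, p in write_phantom(phantom, out).items():
            record(name, Path(p))

        rois = make_roi_set(phantom)
        aff = phantom.affine()
        for name in rois.names():
            p = out / f"roi_{name}.nii"
            write_volume(rois[name], aff, p, dtype=np.uint8)
            record(f"roi_{name}", p)

        # default montage: first channel pairs electrode 0-2, second 1-3
        from .solver import ChannelPair
        e = electrodes
        pair1 = ChannelPair(anode=e[0], cathode=e[2],
                            carrier_frequency_Hz=config.waveform.f1_Hz,
                            current_mA=config.currents_mA[0])
        pair2 = ChannelPair(anode=e[1], cathode=e[3],
                            carrier_frequency_Hz=config.waveform.f1_Hz
                            + config.waveform.delta_f_Hz,
                            current_mA=config.currents_mA[1])
        fields = []
        for pair in (pair1, pair2):
            pot, fld, injected = solve_channel(phantom, pair,
                                               tol=config.solver_tol)
            _, fld = normalize_current(pot, fld, injected, 1.0)
            p = out / f"field_{pair.label}.nii"
            write_volume(fld.E, phantom.affine(), p)
            record(f"field_{pair.label}", p)
            fields.append(fld)

        ti_map = ti_envelope_map(fields[0], fields[1], *config.currents_mA)
        p = out / "ti_map.nii"
        write_volume(ti_map.values, aff, p)
        record("ti_map", p)

        sweep = run_sweep(phantom, rois, electrodes,
                          currents_mA=config.currents_mA,
                          p=config.percentile, tol=config.solver_tol)
        p = out / "sweep.csv"
        sweep.table.to_csv(p, index=False, float_format="%.9g")
        record("sweep", p)
        p = out / "sweep_provenance.json"
        with open(p, "w") as fh:
            json.dump(sweep.provenance, fh, indent=2, sort_keys=True)
            fh.write("\n")
        record("sweep_provenance", p)

        roi_masks = {name: rois[name] for name in rois.names()}
        reports = build_reports(ti_map.values, roi_masks,
                                metadata={"currents_mA": list(config.currents_mA)})
        p = out / "report.json"
        report_to_json(reports, p)
        record("report", p)
    except TidoseError as exc:
        manifest["status"] = "failed"
        manifest["failure"] = str(exc)

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
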