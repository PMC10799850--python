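"""Config-driven end-to-end pipeline: prep -> track -> invert -> metrics.

The stage order is fixed — high-pass filter, mask, global registration,
displacement tracking, traction inversion — and a manifest (config hash,
package version, stage timings, objective trace) is written next to the
outputs so any run can be reproduced bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .elastic import ElasticSubstrate
from .io import (
    read_mask,
    read_volume,
    write_displacement_field,
    write_traction_field,
    write_volume,
)
from .model import TractionModel
from .prep import CellMask, HighPassKernelSpec, apply_mask, global_register, highpass_filter
from .solver import FISTAConfig
from .tracking import TrackingConfig, estimate_displacement_field

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated configuration of a full RI-TFM run."""

    ref_path: str
    mov_path: str
    out_dir: str
    young_modulus: float
    poisson_ratio: float = 0.5
    voxel_pitch: tuple[float, float, float] | None = None
    mask_path: str | None = None
    highpass_wxy: float = 0.5
    highpass_wz: float = 1.0
    tracking: TrackingConfig = dc_field(default_factory=TrackingConfig)
    fista: FISTAConfig = dc_field(default_factory=FISTAConfig)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # delegate numeric validation to the component dataclasses
        ElasticSubstrate(self.young_modulus, self.poisson_ratio)
        HighPassKernelSpec(self.highpass_wxy, self.highpass_wz)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        tracking = TrackingConfig(**raw.pop("tracking", {}))
        fista = FISTAConfig(**raw.pop("fista", {}))
        return cls(tracking=tracking, fista=fista, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_STAGES = ("highpass", "mask", "register", "track", "solve", "metrics")


def run_pipeline(config: PipelineConfig, dry_run: bool = False) -> dict:
    """Execute the full chain; returns the manifest dictionary.

    ``dry_run`` prints the stage plan and returns without computing.
    """
    if dry_run:
        plan = {"stages": list(_STAGES), "config_hash": config.config_hash()}
        print(json.dumps(plan, indent=2))
        return plan

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "seed": config.seed,
        "timings_s": {},
        "outputs": {},
    }

    def _stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                manifest["timings_s"][name] = round(time.perf_counter() - self.t0, 4)
                return False

        return _T()

    try:
        ref = read_volume(config.ref_path, pitch=config.voxel_pitch)
        mov = read_volume(config.mov_path, pitch=config.voxel_pitch)
        spec = HighPassKernelSpec(
            config.highpass_wxy, config.highpass_wz, voxel_pitch=ref.pitch
        )
        with _stage("highpass"):
            ref = highpass_filter(ref, spec)
            mov = highpass_filter(mov, spec)
        mask = None
        with _stage("mask"):
            if config.mask_path:
                mask = CellMask(read_mask(config.mask_path))
                ref = apply_mask(ref, mask, fill="background")
                mov = apply_mask(mov, mask, fill="background")
        with _stage("register"):
            drift, mov = global_register(ref, mov)
            manifest["global_drift_vox"] = [float(d) for d in drift]
        with _stage("track"):
            field = estimate_displacement_field(ref, mov, config.tracking, mask)
            p = write_displacement_field(field, out / "displacement.txt")
            manifest["outputs"]["displacement"] = str(p)
        with _stage("solve"):
            model = TractionModel(
                field,
                ElasticSubstrate(config.young_modulus, config.poisson_ratio),
                fista=config.fista,
            )
            results = model.fit()
            p = write_traction_field(results.traction, out / "traction.txt")
            manifest["outputs"]["traction"] = str(p)
            manifest["objective_trace"] = [
                float(v) for v in results.report.objective[:: max(1, len(results.report.objective) // 50)]
            ]
        with _stage("metrics"):
            stats = results.stats()
            manifest["traction_stats"] = {
                k: v for k, v in stats.items() if not k.endswith("hist")
            }
            (out / "summary.txt").write_text(results.summary() + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage: {exc}") from exc

    digest = hashlib.sha256()
    for key in sorted(manifest["outputs"]):
        digest.update(Path(manifest["outputs"][key]).read_bytes())
    manifest["output_hash"] = digest.hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
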