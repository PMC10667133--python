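"""Orchestration: simulate -> slabs -> detect -> analyze -> report.

A :class:`PipelineConfig` enables stages and carries every module's
parameters plus a single master seed.  ``run_pipeline`` validates the
configuration up front (enabled stages must have their inputs), executes
the enabled stages in order, writes a JSON provenance sidecar (seed,
config hash, package version) next to every artifact, and returns a
manifest listing each output file with its SHA-256.  Re-running the same
config reproduces byte-identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as ihrf_io
from .cohort import CohortSpec, simulate_cohort
from .detection import DetectionParams, quantify_eye
from .phantom import VolumeSpec, generate_surfaces, render_volume, sample_interior_foci
from .phantom import DrusenSpec, FocusSpec
from .slabs import make_slab_stack
from .stats import ProgressionModel, build_report

__all__ = ["PipelineConfig", "run_pipeline", "make_fixtures"]

log = logging.getLogger("ihrf")

STAGE_ORDER = ("simulate", "slabs", "detect", "analyze", "report")


@dataclass
class PipelineConfig:
    outdir: str = "ihrf_out"
    seed: int = 0
    stages: tuple = STAGE_ORDER
    volume: dict = field(default_factory=dict)  # VolumeSpec overrides
    phantom: dict = field(default_factory=dict)  # e.g. {"n_foci": 6}
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    detection: dict = field(default_factory=dict)  # DetectionParams overrides
    volume_path: Optional[str] = None  # external inputs when simulate is off
    surfaces_path: Optional[str] = None
    cohort_path: Optional[str] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGE_ORDER]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}")
        self.stages = tuple(s for s in STAGE_ORDER if s in self.stages)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)

    @classmethod
    def demo(cls, outdir, seed: Optional[int] = None) -> "PipelineConfig":
        """The bundled demonstration configuration (small, runs in seconds)."""
        payload = json.loads(
            resources.files("ihrf.data").joinpath("demo_config.json").read_text()
        )
        payload["outdir"] = str(outdir)
        if seed is not None:
            payload["seed"] = seed
        return cls(**payload)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def validate(self) -> None:
        """Fail fast: every enabled stage must be able to find its inputs."""
        have_sim = "simulate" in self.stages
        out = Path(self.outdir)

        def _input_ok(override, produced_name):
            if override is not None:
                return Path(override).exists()
            return have_sim or (out / produced_name).exists()

        problems = []
        for stage, needs in (
            ("slabs", [("volume", self.volume_path, "volume.tiff"),
                       ("surfaces", self.surfaces_path, "surfaces.csv")]),
            ("detect", [("volume", self.volume_path, "volume.tiff"),
                        ("surfaces", self.surfaces_path, "surfaces.csv")]),
            ("analyze", [("cohort table", self.cohort_path, "cohort.csv")]),
        ):
            if stage in self.stages:
                for what, override, produced in needs:
                    if not _input_ok(override, produced):
                        problems.append(f"stage '{stage}' needs a {what} input "
                                        f"({override or produced} not found)")
        if "report" in self.stages and "analyze" not in self.stages:
            problems.append("stage 'report' requires stage 'analyze'")
        if problems:
            raise FileNotFoundError("; ".join(problems))


def _sidecar_payload(config: PipelineConfig) -> dict:
    return {"seed": config.seed, "config_hash": config.config_hash()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages in order; return the artifact manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list = []
    prov = _sidecar_payload(config)

    def _emit(path):
        artifacts.append(Path(path))
        ihrf_io.write_sidecar(path, prov)
        artifacts.append(Path(str(path) + ".json"))

    volume = surfaces = None

    if "simulate" in config.stages:
        log.info("simulate: rendering phantom and cohort (seed=%d)", config.seed)
        spec = VolumeSpec(**{"seed": config.seed, **config.volume})
        drusen = [DrusenSpec(**d) for d in config.phantom.get("drusen", [])]
        vessels = [tuple(v) for v in config.phantom.get("vessels", [])]
        surfaces = generate_surfaces(spec, drusen)
        rng = np.random.default_rng(spec.seed)
        n_foci = int(config.phantom.get("n_foci", 6))
        foci = sample_interior_foci(rng, spec, surfaces, n_foci)
        volume, truth = render_volume(spec, surfaces, foci, vessels, rng=rng)
        ihrf_io.write_volume(out / "volume.tiff", volume)
        _emit(out / "volume.tiff")
        ihrf_io.write_surfaces(out / "surfaces.csv", surfaces)
        _emit(out / "surfaces.csv")
        truth.frame.to_csv(out / "truth.csv", index=False)
        _emit(out / "truth.csv")
        cohort = simulate_cohort(CohortSpec(**{"seed": config.seed, **config.cohort}))
        cohort.to_csv(out / "cohort.csv", index=False)
        _emit(out / "cohort.csv")

    if volume is None and ("slabs" in config.stages or "detect" in config.stages):
        volume = ihrf_io.read_volume(config.volume_path or out / "volume.tiff")
        surfaces = ihrf_io.read_surfaces(config.surfaces_path or out / "surfaces.csv")

    if "slabs" in config.stages:
        log.info("slabs: extracting five en-face images")
        stack = make_slab_stack(volume, surfaces)
        ihrf_io.write_slab_stack(out / "slabstack.tiff", stack)
        _emit(out / "slabstack.tiff")

    if "detect" in config.stages:
        log.info("detect: threshold, binarize, particle analysis")
        params = DetectionParams(**config.detection)
        table = quantify_eye(volume, surfaces, params)
        ihrf_io.write_ihrf_table(
            out / "ihrf_components.csv", table, counts_path=out / "slab_counts.csv"
        )
        _emit(out / "ihrf_components.csv")
        _emit(out / "slab_counts.csv")
        ihrf_io.write_sidecar(out / "detection_params", {**prov, **table.provenance()})
        artifacts.append(out / "detection_params.json")

    results = None
    if "analyze" in config.stages:
        log.info("analyze: fitting progression models")
        cohort_path = config.cohort_path or out / "cohort.csv"
        results = ProgressionModel.from_csv(cohort_path).fit()

    if "report" in config.stages:
        log.info("report: writing tables and summary")
        report_dir = out / "report"
        build_report(results, report_dir)
        for p in sorted(report_dir.iterdir()):
            artifacts.append(p)

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "files": {
            str(p.relative_to(out)): ihrf_io.file_sha256(p) for p in artifacts if p.exists()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# test fixtures


def make_fixtures(outdir, seed: int = 0) -> Path:
    """Write the standard demonstration/test fixtures.

    * ``fig_three_lesions/`` — noise-free phantom with 3 separated foci in
      slab 2 only (truth counts 0,3,0,0,0);
    * ``straddle/`` — one focus centered exactly on the slab 1/2 boundary
      (truth: counted once in each slab, total 2 for 1 physical lesion);
    * ``confounder/`` — a vessel plus a drusen whose apex the analysis
      surfaces miss (``surfaces_analysis.csv`` lacks the drusen bump);
    * ``cohort.csv`` — a 200-eye simulated cohort.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    noise_free = VolumeSpec(speckle_shape=0.0, seed=seed)

    def _write_phantom(name, spec, surfaces, foci, vessels=(), analysis_surfaces=None):
        d = out / name
        d.mkdir(exist_ok=True)
        volume, truth = render_volume(spec, surfaces, foci, vessels)
        ihrf_io.write_volume(d / "volume.tiff", volume)
        ihrf_io.write_surfaces(d / "surfaces.csv", surfaces)
        if analysis_surfaces is not None:
            ihrf_io.write_surfaces(d / "surfaces_analysis.csv", analysis_surfaces)
        truth.frame.to_csv(d / "truth.csv", index=False)
        return truth

    surfaces = generate_surfaces(noise_free)
    fig_foci = [
        FocusSpec(x=30, y=8, frac_depth=0.70, radius_px=2.0),
        FocusSpec(x=64, y=16, frac_depth=0.68, radius_px=2.0),
        FocusSpec(x=98, y=24, frac_depth=0.72, radius_px=2.0),
    ]
    _write_phantom("fig_three_lesions", noise_free, surfaces, fig_foci)

    _write_phantom(
        "straddle",
        noise_free,
        surfaces,
        [FocusSpec(x=64, y=16, frac_depth=0.80, radius_px=2.0)],
    )

    drusen = [DrusenSpec(x=90, y=20, radius_px=10.0, height_px=8.0)]
    true_surfaces = generate_surfaces(noise_free, drusen)
    missed = generate_surfaces(noise_free)  # segmentation misses the drusen
    _write_phantom(
        "confounder",
        noise_free,
        true_surfaces,
        [],
        vessels=[(30, 10)],
        analysis_surfaces=missed,
    )

    cohort = simulate_cohort(CohortSpec(n_eyes=200, seed=seed))
    cohort.to_csv(out / "cohort.csv", index=False)
    return out
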