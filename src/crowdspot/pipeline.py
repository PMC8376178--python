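"""End-to-end orchestration of the annotation pipeline.

Stages mirror the annotation workflow: simulate (or load) an image,
preprocess, first-pass detect, subdivide into annotatable crops, collect
(simulated) crowd annotations per crop, QC them into consensus points,
reassemble to the parent frame, tune a detector on the consensus and
evaluate against ground truth.  Every run is reproducible from its
manifest: all seeds, thresholds and artifact paths are recorded and the
fully-resolved configuration is written next to the outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .annoqc import QCOptions, run_qc
from .errors import ConfigError
from .evalmetrics import match_points
from .imageprep import Guidelines, log_detect, preprocess_stack, recursive_subdivide, reassemble, to_display_coords
from .io import write_crop_manifest, write_json, write_png, write_tiff
from .records import SpotRecord, spot_coords, spots_to_frame
from .spotimage import SynthConfig, simulate_image
from .tuning import extract_spot_params, detect_with_params
from .workersim import WorkerModel, simulate_crowd

logger = logging.getLogger(__name__)


def _from_mapping(cls, data: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class PipelineConfig:
    """Fully-resolved configuration of one pipeline run."""

    width: int = 256
    height: int = 256
    seed: int = 0
    out_dir: str = "pipeline_out"
    display_width: int = 512
    n_workers: int = 25
    highpass_sigma: float = 4.5
    correctness_threshold: float = 4.0
    dedup_radius: float = 4.0
    simulation: SynthConfig = field(default_factory=SynthConfig)
    worker_model: WorkerModel = field(default_factory=WorkerModel)
    guidelines: Guidelines = field(default_factory=Guidelines)
    qc: QCOptions = field(default_factory=QCOptions)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sub = {
            "simulation": SynthConfig,
            "worker_model": WorkerModel,
            "guidelines": Guidelines,
            "qc": QCOptions,
        }
        kwargs = {}
        for key, klass in sub.items():
            if key in data:
                kwargs[key] = _from_mapping(klass, data.pop(key), key)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs.update(data)
        cfg = cls(**kwargs)
        # one global seed propagates to every stochastic stage
        cfg.simulation.seed = cfg.seed
        cfg.worker_model.seed = cfg.seed + 1
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig, write_artifacts: bool = True) -> dict:
    """Execute all stages and return the run manifest.

    With ``write_artifacts`` the analysis image (TIFF), display crops
    (PNG), crop manifest, annotation/consensus CSVs, evaluation JSON and
    the resolved config all land in ``config.out_dir``.
    """
    out = Path(config.out_dir)
    if write_artifacts:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    # 1. synthetic image with ground truth
    image, truth = simulate_image(config.simulation, config.width, config.height)
    manifest["stages"]["simulate"] = {"n_spots": len(truth)}
    if write_artifacts:
        write_tiff(out / "image.tif", image)
        spots_to_frame(truth).to_csv(out / "truth.csv", index=False)

    # 2. preprocess + first-pass detection (guides the subdivision)
    filtered = preprocess_stack(image, config.highpass_sigma)
    first_pass = log_detect(filtered, 1.0, 4.0, 7, threshold=float(filtered.max()) * 0.05)
    manifest["stages"]["first_pass_detect"] = {"n_detections": len(first_pass)}

    # 3. subdivision into annotatable crops
    crops = recursive_subdivide(
        image, first_pass, config.guidelines, config.display_width
    )
    manifest["stages"]["subdivide"] = {
        "n_crops": len(crops),
        "n_saturated": sum(1 for c, _ in crops if c.flag == "saturated"),
    }
    if write_artifacts:
        write_crop_manifest(out / "crops.csv", [c for c, _ in crops])
        for spec, pixels in crops:
            write_png(out / f"{spec.crop_id}.png", pixels, scale=spec.scale)

    # 4. simulated crowd per crop (displayed coordinates), then QC
    truth_pts = spot_coords(truth)
    per_crop_consensus: dict[str, np.ndarray] = {}
    n_annotations = 0
    for spec, _pixels in crops:
        inside = [
            s
            for s in truth
            if spec.contains_parent_point(s.x, s.y)
        ]
        if not inside:
            continue
        disp = to_display_coords(spec, inside)
        disp_truth = [
            SpotRecord(x=float(px), y=float(py), sigma=s.sigma * spec.scale, amplitude=s.amplitude, snr=s.snr)
            for (px, py), s in zip(disp, inside)
        ]
        annos = simulate_crowd(
            disp_truth,
            int(round(spec.width * spec.scale)),
            int(round(spec.height * spec.scale)),
            config.worker_model,
            config.n_workers,
            image_id=spec.crop_id,
        )
        n_annotations += len(annos)
        if write_artifacts:
            annos.to_csv(out / f"annotations_{spec.crop_id}.csv")
        consensus, report = run_qc(annos, config.qc)
        per_crop_consensus[spec.crop_id] = np.array([[p.x, p.y] for p in consensus]).reshape(-1, 2)
        manifest["stages"].setdefault("qc", {})[spec.crop_id] = report.stages
    manifest["stages"]["annotate"] = {"n_annotations": n_annotations}

    # 5. reassemble consensus into the parent frame
    merged = reassemble(per_crop_consensus, [c for c, _ in crops], config.dedup_radius)
    manifest["stages"]["reassemble"] = {"n_consensus": len(merged)}
    if write_artifacts:
        import pandas as pd

        pd.DataFrame(merged, columns=["x", "y"]).to_csv(out / "consensus.csv", index=False)

    # 6. tune a detector on the consensus, evaluate against truth
    evaluation: dict = {}
    if len(merged) >= 3:
        params = extract_spot_params(image, merged, correctness_threshold=config.correctness_threshold)
        detections = detect_with_params(image, params)
        det_res = match_points(spot_coords(detections), truth_pts, config.correctness_threshold)
        evaluation["detector"] = det_res.to_dict()
        evaluation["params"] = dataclasses.asdict(params)
    cons_res = match_points(merged, truth_pts, config.correctness_threshold)
    evaluation["consensus"] = cons_res.to_dict()
    manifest["stages"]["evaluate"] = evaluation

    if write_artifacts:
        write_json(out / "evaluation.json", evaluation)
        write_json(out / "manifest.json", manifest)
        (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    return manifest
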