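"""End-to-end runs: validated run configuration, stage execution with a
reproducibility manifest, and canonical fixture generation."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from . import morphometry as morph
from . import preprocess, proteomics
from .phantom import PhantomSpec, generate_phantom, render_sem_view
from .presets import FIXTURE_NODULE_COUNTS, mandibular_spec, registration_spec
from .register import InPlaneAffine, Schedule, SlicePose, register_slice

logger = logging.getLogger("lymphomorph")

KNOWN_STAGES = ("phantom", "preprocess", "register", "morphometry", "proteomics")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline configuration: an ordered stage list with per-stage
    parameter blocks, a global seed, and an output directory."""

    stages: list = field(default_factory=list)
    seed: int = 0
    out_dir: str = "runs/out"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        for key in ("stages", "seed", "out_dir"):
            if key not in raw:
                raise ConfigError(f"missing required config block {key!r}")
        stages = raw["stages"]
        if not isinstance(stages, list) or not stages:
            raise ConfigError("'stages' must be a non-empty list")
        for st in stages:
            if not isinstance(st, dict) or "stage" not in st:
                raise ConfigError("each stage needs a 'stage' name")
            if st["stage"] not in KNOWN_STAGES:
                raise ConfigError(f"unknown stage {st['stage']!r}")
        return cls(stages=stages, seed=int(raw["seed"]),
                   out_dir=str(raw["out_dir"]),
                   log_level=str(raw.get("log_level", "INFO")))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _run_phantom(params: dict, seed: int, out: Path) -> list[Path]:
    spec = PhantomSpec(**{**params, "seed": params.get("seed", seed)})
    vol, labels = generate_phantom(spec)
    lio.save_volume(vol, out / "phantom_intensity.tif")
    lio.save_volume(labels, out / "phantom_labels.tif")
    return [out / "phantom_intensity.tif", out / "phantom_labels.tif"]


def _run_preprocess(params: dict, seed: int, out: Path) -> list[Path]:
    vol = lio.load_volume(params["input"])
    lo = params.get("clip_lo", float(vol.data.min()))
    hi = params.get("clip_hi", float(vol.data.max()))
    conditioned = preprocess.clip_normalize(vol, lo, hi)
    lio.save_volume(conditioned, out / "preprocessed.tif")
    return [out / "preprocessed.tif"]


def _run_register(params: dict, seed: int, out: Path) -> list[Path]:
    import tifffile

    vol = lio.load_volume(params["volume"])
    img = np.asarray(tifffile.imread(params["image"]))
    sched = Schedule(**params.get("schedule", {}))
    init = (SlicePose(**params.get("init_pose", {})),
            InPlaneAffine(**params.get("init_affine", {})))
    res = register_slice(vol, img, init=init, sched=sched)
    payload = {
        "pose": vars(res.pose), "affine": vars(res.affine),
        "mi_bits": res.mi_bits, "converged": res.converged,
        "trace": [list(t) for t in res.trace],
    }
    with open(out / "registration.yaml", "w") as fh:
        yaml.safe_dump(payload, fh)
    return [out / "registration.yaml"]


def _run_morphometry(params: dict, seed: int, out: Path) -> list[Path]:
    labels = lio.load_volume(params["labels"])
    crit = morph.NoduleCriteria(**params.get("criteria", {}))
    objects = morph.connected_components(labels, params.get("class", "nodule"),
                                         crit.min_voxels)
    accepted = morph.classify_nodules(objects, labels, crit)
    lio.objects_table(accepted, crit.shrinkage_s).to_csv(
        out / "objects.csv", index=False)
    stats = morph.capillary_stats(labels)
    lio.compartments_table(stats).to_csv(out / "compartments.csv", index=False)
    summary = {
        "candidates": len(objects),
        "accepted_nodules": len(accepted),
        "volume_fraction_pct": {
            name: s.volume_fraction_pct for name, s in stats.items()},
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return [out / "objects.csv", out / "compartments.csv", out / "summary.json"]


def _run_proteomics(params: dict, seed: int, out: Path) -> list[Path]:
    mat = pd.read_csv(params["matrix"], index_col=0)
    design = pd.read_csv(params["design"], index_col=0)
    contrast = params.get("contrast", "mand_vs_sub_mean")
    rows = proteomics.adaptive_test(mat, design, contrast)
    rows.to_csv(out / "differential.csv")
    proteomics.volcano_table(rows.dropna(subset=["p"])).to_csv(
        out / "volcano.csv")
    written = [out / "differential.csv", out / "volcano.csv"]
    if "sets" in params:
        sets = proteomics.read_gmt(params["sets"])
        scores, z = proteomics.ssgsea_scores(mat, sets)
        scores.to_csv(out / "ssgsea_scores.csv")
        z.to_csv(out / "ssgsea_z.csv")
        written += [out / "ssgsea_scores.csv", out / "ssgsea_z.csv"]
    return written


_STAGE_RUNNERS = {
    "phantom": _run_phantom,
    "preprocess": _run_preprocess,
    "register": _run_register,
    "morphometry": _run_morphometry,
    "proteomics": _run_proteomics,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order, writing a manifest with
    parameters, seeds, timings and output checksums."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}
    for i, block in enumerate(config.stages):
        name = block["stage"]
        params = {k: v for k, v in block.items() if k != "stage"}
        stage_out = out_root / f"{i:02d}_{name}"
        stage_out.mkdir(parents=True, exist_ok=True)
        t0 = time.perf_counter()
        logger.info("stage %s starting", name)
        try:
            outputs = _STAGE_RUNNERS[name](params, config.seed, stage_out)
        except Exception as exc:
            manifest["failed_stage"] = name
            manifest["error"] = str(exc)
            with open(out_root / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, default=str)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        logger.info("stage %s finished in %.1f s", name, dt)
        manifest["stages"].append({
            "stage": name,
            "params": params,
            "seconds": round(dt, 3),
            "outputs": {str(p.relative_to(out_root)): _sha256(p)
                        for p in outputs},
        })
    with open(out_root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def make_fixtures(out_dir, seed: int = 42) -> dict:
    """Write the canonical test fixtures: young/old mandibular phantom pairs,
    a registration phantom with an SEM-style tile set, and a toy abundance
    matrix with design, truth table and gene sets. Returns a checksum
    manifest (also written as fixtures.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for age in ("young", "old"):
        for rep in range(len(FIXTURE_NODULE_COUNTS[age])):
            spec = mandibular_spec(age, rep, base_seed=seed)
            vol, labels = generate_phantom(spec)
            base = out / f"{age}_{rep}"
            base.mkdir(exist_ok=True)
            lio.save_volume(labels, base / "labels.tif")
            written.append(base / "labels.tif")

    spec = registration_spec(seed=seed + 100)
    vol, _ = generate_phantom(spec)
    lio.save_volume(vol, out / "registration_volume.tif")
    written.append(out / "registration_volume.tif")
    tiles = render_sem_view(
        vol, SlicePose(rx=4.0, tz=5.0), InPlaneAffine(k=0.05),
        {"out_shape": (120, 120), "tile_shape": (70, 70),
         "overlap_fraction": 0.15, "jitter_px": 2, "vignette_strength": 0.2,
         "noise_sd": 0.01, "seed": seed},
    )
    lio.save_tileset(tiles, out / "sem_tiles")
    written += sorted((out / "sem_tiles").glob("*.tif"))

    mat, design, truth = proteomics.simulate_abundances(
        200, 10,
        effects={"site": {"P00000": 1.79, "P00001": 0.8},
                 "age_both": {"P00002": 1.0}},
        seed=seed,
    )
    mat.to_csv(out / "abundances.csv")
    design.to_csv(out / "design.csv")
    truth.to_csv(out / "truth.csv")
    proteomics.write_gmt(
        {"b_cell_panel": [f"P{i:05d}" for i in range(0, 10)],
         "stromal_panel": [f"P{i:05d}" for i in range(100, 120)]},
        out / "sets.gmt")
    written += [out / "abundances.csv", out / "design.csv", out / "truth.csv",
                out / "sets.gmt"]

    manifest = {str(p.relative_to(out)): _sha256(p) for p in written}
    with open(out / "fixtures.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
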