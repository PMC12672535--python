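"""On-disk formats: multi-page TIFF stacks with YAML sidecars for volumes,
per-tile TIFFs with a CSV offset table for SEM mosaics, CSV tables for
morphometry output."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .volumes import CLASS_MAP, LabelVolume, TileSet, Volume3D

__all__ = [
    "save_volume",
    "load_volume",
    "save_tileset",
    "load_tileset",
    "objects_table",
    "compartments_table",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def save_volume(vol, path) -> None:
    """Write a Volume3D or LabelVolume as a multi-page TIFF plus a YAML
    sidecar carrying voxel size (and the class map for labels)."""
    path = Path(path)
    meta: dict = {"voxel_um": float(vol.voxel_um)}
    if isinstance(vol, LabelVolume):
        tifffile.imwrite(path, vol.labels)
        meta["kind"] = "labels"
        meta["class_map"] = {int(k): v for k, v in vol.class_map.items()}
    else:
        tifffile.imwrite(path, vol.data.astype(np.float32))
        meta["kind"] = "intensity"
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(meta, fh)


def load_volume(path):
    path = Path(path)
    data = tifffile.imread(path)
    with open(_sidecar(path)) as fh:
        meta = yaml.safe_load(fh)
    if meta.get("kind") == "labels":
        cmap = {int(k): v for k, v in meta.get("class_map", CLASS_MAP).items()}
        return LabelVolume(np.asarray(data), float(meta["voxel_um"]), cmap)
    return Volume3D(np.asarray(data), float(meta["voxel_um"]))


def save_tileset(tiles: TileSet, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (tile, off) in enumerate(zip(tiles.tiles, tiles.nominal_offsets)):
        name = f"tile_{i:03d}.tif"
        tifffile.imwrite(out / name, tile.astype(np.float32))
        rows.append({"tile": name, "row": off[0], "col": off[1]})
    pd.DataFrame(rows).to_csv(out / "offsets.csv", index=False)
    with open(out / "tileset.yaml", "w") as fh:
        yaml.safe_dump({
            "overlap_fraction": float(tiles.overlap_fraction),
            "pixel_um": float(tiles.pixel_um),
            "vignette_model": tiles.vignette_model,
        }, fh)


def load_tileset(in_dir) -> TileSet:
    src = Path(in_dir)
    table = pd.read_csv(src / "offsets.csv")
    with open(src / "tileset.yaml") as fh:
        meta = yaml.safe_load(fh)
    tiles = [np.asarray(tifffile.imread(src / row.tile))
             for row in table.itertuples()]
    offsets = [(int(r), int(c)) for r, c in zip(table["row"], table["col"])]
    return TileSet(tiles=tiles, nominal_offsets=offsets,
                   overlap_fraction=float(meta["overlap_fraction"]),
                   pixel_um=float(meta["pixel_um"]),
                   vignette_model=meta.get("vignette_model"))


def objects_table(objects, shrinkage_s: float = 0.30) -> pd.DataFrame:
    """Per-object morphometry table with shrinkage-corrected Feret."""
    rows = []
    for o in objects:
        rows.append({
            "object_id": o.object_id,
            "class": o.class_name,
            "voxel_count": o.voxel_count,
            "volume_um3": o.volume_um3,
            "feret_um": o.feret_um,
            "feret_corrected_um": o.feret_um / (1.0 - shrinkage_s),
            "sphericity": o.sphericity,
            "centroid_z_um": o.centroid_um[0],
            "centroid_y_um": o.centroid_um[1],
            "centroid_x_um": o.centroid_um[2],
        })
    return pd.DataFrame(rows)


def compartments_table(stats: dict) -> pd.DataFrame:
    rows = [{
        "compartment": s.compartment,
        "total_voxels": s.total_voxels,
        "capillary_voxels": s.capillary_voxels,
        "capillary_density": s.capillary_density,
        "volume_fraction_pct": s.volume_fraction_pct,
    } for s in stats.values()]
    return pd.DataFrame(rows)
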