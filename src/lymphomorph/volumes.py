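"""Core image containers: 3D intensity volumes, integer label volumes, SEM tile sets.

Axis order is (z, y, x) throughout, matching the on-disk layout of a
multi-page TIFF stack (one page per z slice). Physical scale is carried as a
single isotropic voxel pitch in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Segmentation classes used for lymph-node volumes. 0 is background (resin /
#: air outside the specimen); "adjacent_tissue" stands for whatever non-nodal
#: tissue borders the node (salivary gland, muscle, ...).
CLASS_MAP: dict[int, str] = {
    0: "background",
    1: "parenchyma",
    2: "medullary_sinus",
    3: "dcu",
    4: "follicle",
    5: "subcapsular_sinus",
    6: "nodule",
    7: "fat_pad",
    8: "outer_vasculature",
    9: "venule",
    10: "capillary",
    11: "adjacent_tissue",
}

NAME_TO_LABEL: dict[str, int] = {v: k for k, v in CLASS_MAP.items()}


@dataclass
class Volume3D:
    """Isotropic 3D grayscale volume with voxel size in µm."""

    data: np.ndarray
    voxel_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D expects 3D data, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume3D data must be finite")
        if self.voxel_um <= 0:
            raise ValueError("voxel_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class LabelVolume:
    """Integer label partition of a volume; every voxel carries exactly one class."""

    labels: np.ndarray
    voxel_um: float
    class_map: dict[int, str] = field(default_factory=lambda: dict(CLASS_MAP))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelVolume expects 3D labels")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.voxel_um <= 0:
            raise ValueError("voxel_um must be positive")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.class_map)
        if missing:
            raise ValueError(f"class_map does not cover labels {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def mask(self, class_name: str) -> np.ndarray:
        """Boolean mask of one named class."""
        inv = {v: k for k, v in self.class_map.items()}
        if class_name not in inv:
            raise KeyError(f"unknown class {class_name!r}")
        return self.labels == inv[class_name]

    def ln_mask(self) -> np.ndarray:
        """Whole-node mask: every class except background and adjacent tissue."""
        inv = {v: k for k, v in self.class_map.items()}
        excluded = {inv.get("background", 0), inv.get("adjacent_tissue", -1)}
        out = np.ones(self.labels.shape, dtype=bool)
        for lab in excluded:
            out &= self.labels != lab
        return out


@dataclass
class TileSet:
    """A mosaic of overlapping 2D micrograph tiles with nominal grid offsets.

    ``nominal_offsets`` are (row, col) pixel coordinates of each tile's upper
    left corner in the panorama frame. ``meta`` carries generator ground truth
    (pose/affine) when the tiles were rendered from a phantom.
    """

    tiles: list[np.ndarray]
    nominal_offsets: list[tuple[int, int]]
    overlap_fraction: float
    pixel_um: float
    vignette_model: dict | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.tiles) < 1:
            raise ValueError("TileSet needs at least one tile")
        if len(self.tiles) != len(self.nominal_offsets):
            raise ValueError("one offset per tile required")
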