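"""Packaged phantom configurations.

Each preset encodes one study condition as a reproducible PhantomSpec. Sizes
follow the printed morphometry where available and are otherwise derived by
self-consistency:

* ``mandibular``: the node size is fixed so that the printed old-age nodule
  census (mean 59.5 nodules of the 90 ± 27 µm embedded-scale law) occupies
  the printed 4.7% of the node volume — semi-axes 427 x 470 x 534 µm. Young
  and old phantoms share this geometry and differ only in nodule count
  (fixture pairs 28/29 and 59/60). These phantoms carry no capillary class so
  class volume fractions are exactly the object fractions.
* ``vasculature``: a 256-cubed mandibular-type phantom whose per-compartment
  capillary fractions encode the printed density ratios (follicle/DCU = 2.2,
  nodule/DCU = 2.18) over a reference DCU density of 0.10.
* ``popliteal_young``: mild lipomatosis — 15 adipocytes of 40-90 µm corrected
  Feret (28-63 µm embedded), node size set so their expected volume share is
  the printed 0.26%; semi-axes 384 x 423 x 480 µm, 3.6 µm voxels so the small
  adipocytes stay well resolved.

The fixture voxel pitch is 7.2 µm (4x the native 1.8 µm) so a whole ~1 mm
node fits in a few-megavoxel grid; single-object experiments keep the native
pitch.
"""

from __future__ import annotations

from .phantom import PhantomSpec

__all__ = [
    "FIXTURE_NODULE_COUNTS",
    "DCU_REFERENCE_DENSITY",
    "CAPILLARY_RATIO_CONFIG",
    "mandibular_spec",
    "vasculature_spec",
    "popliteal_young_spec",
    "registration_spec",
]

#: committed fixture table: per-phantom nodule counts whose means are the
#: printed 28.5 (young) and 59.5 (old)
FIXTURE_NODULE_COUNTS: dict[str, tuple[int, int]] = {
    "young": (28, 29),
    "old": (59, 60),
}

DCU_REFERENCE_DENSITY = 0.10
#: per-compartment capillary volume fractions encoding the printed ratios
CAPILLARY_RATIO_CONFIG: dict[str, float] = {
    "dcu": DCU_REFERENCE_DENSITY,
    "follicle": 2.2 * DCU_REFERENCE_DENSITY,
    "nodule": 2.18 * DCU_REFERENCE_DENSITY,
    "parenchyma": 0.05,
}

_MANDIBULAR_RADII_UM = (427.0, 470.0, 534.0)  # (z, y, x) semi-axes


def mandibular_spec(age: str, replicate: int = 0, seed: int | None = None,
                    base_seed: int = 42) -> PhantomSpec:
    """Mandibular-type phantom for the nodule census (young or old)."""
    if age not in FIXTURE_NODULE_COUNTS:
        raise ValueError("age must be 'young' or 'old'")
    counts = FIXTURE_NODULE_COUNTS[age]
    if not 0 <= replicate < len(counts):
        raise ValueError("replicate must be 0 or 1")
    if seed is None:
        seed = base_seed + {"young": 0, "old": 2}[age] + replicate
    return PhantomSpec(
        shape_voxels=(196, 212, 240),
        voxel_um=4.8,
        ln_radii_um=_MANDIBULAR_RADII_UM,
        follicle_count=10,
        follicle_diam_um=(160.0, 30.0),
        nodule_count=counts[replicate],
        adipocyte_count=0,
        capillary_fraction={},
        noise_sd=0.05,
        seed=seed,
    )


def vasculature_spec(seed: int = 42) -> PhantomSpec:
    """256-cubed phantom carrying the printed capillary-density ratios."""
    return PhantomSpec(
        shape_voxels=(256, 256, 256),
        voxel_um=7.2,
        ln_radii_um=(670.0, 740.0, 840.0),
        follicle_count=12,
        follicle_diam_um=(170.0, 25.0),
        nodule_count=30,
        adipocyte_count=0,
        capillary_fraction=dict(CAPILLARY_RATIO_CONFIG),
        noise_sd=0.05,
        seed=seed,
    )


def popliteal_young_spec(seed: int = 42) -> PhantomSpec:
    """Young popliteal-type phantom with mild lipomatosis (15 adipocytes)."""
    return PhantomSpec(
        shape_voxels=(228, 252, 276),
        voxel_um=3.6,
        ln_radii_um=(384.0, 423.0, 480.0),
        follicle_count=8,
        follicle_diam_um=(160.0, 30.0),
        nodule_count=0,
        adipocyte_count=15,
        adipocyte_diam_um=(28.0, 63.0),
        capillary_fraction={},
        noise_sd=0.05,
        seed=seed,
    )


def registration_spec(seed: int = 7) -> PhantomSpec:
    """Structured 128-cubed phantom used as registration ground truth."""
    return PhantomSpec(
        shape_voxels=(128, 128, 128),
        voxel_um=7.2,
        ln_radii_um=(400.0, 430.0, 450.0),
        follicle_count=8,
        follicle_diam_um=(150.0, 25.0),
        nodule_count=10,
        adipocyte_count=0,
        capillary_fraction={},
        noise_sd=0.03,
        seed=seed,
    )
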