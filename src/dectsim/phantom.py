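"""Synthetic phantoms: calibration cylinders and a parametric pelvis.

The pelvis phantom is a fully synthetic stand-in for a licensed voxel
anatomy: an elliptical soft-tissue body, a cortical-bone pelvic ring, two
femoral heads, and a low-contrast bladder-like soft-tissue inset used as the
CNR signal region.  The optional hip prosthesis replaces one femoral head
with a metal head, a PMMA lining, and a metal acetabular shell (titanium or
surgical stainless steel).  All geometry is fixed in module constants so the
implant variants share identical anatomy outside the implant region, which
is what makes paired CNR/RMSE comparisons meaningful.

Conventions: square raster, label 0 is the air background, pixel centers at
(i + 0.5) * pixel_size from the grid corner, row index increasing with +y.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .materials import Material, get_material

__all__ = [
    "PhantomImage",
    "GroundTruthVMI",
    "water_cylinder",
    "pelvis_phantom",
    "ground_truth_vmi",
    "write_phantom",
    "read_phantom",
    "PELVIS_GEOMETRY",
]

#: Pelvis geometry (cm, isocenter-centered). Fixed so experiments reproduce.
PELVIS_GEOMETRY = {
    "body": (17.0, 11.5),  # ellipse semi-axes
    "ring_center": (0.0, -1.0),
    "ring_outer": (12.0, 8.0),
    "ring_inner": (10.4, 6.4),
    "femur_centers": ((-9.5, -3.0), (9.5, -3.0)),
    "femur_radius": 2.2,
    "inset_center": (0.0, 2.5),
    "inset_axes": (3.5, 2.5),
    "inset_density": 1.04,  # g/cm^3; ~+40 HU soft-tissue target
    "implant_head_radius": 1.4,
    "implant_lining_radius": 1.8,  # PMMA between head and shell
    "implant_shell_radius": 2.2,
    "roi_radius": 1.3,
    "roi_signal_center": (0.0, 2.5),
    "roi_background_center": (-5.5, 2.5),
}

LABELS = {"air": 0, "tissue": 1, "bone": 2, "inset": 3, "pmma": 4, "metal": 5}


def _air() -> Material:
    # vacuum-like background: water curve at negligible density -> -1000 HU
    return get_material("water").with_density(1e-9, name="air")


@dataclass(frozen=True)
class PhantomImage:
    """2-D material-label raster with per-label materials and named ROIs."""

    labels: np.ndarray  # int16 (n, n)
    pixel_size_mm: float
    materials: tuple  # Material per label index
    rois: dict  # name -> boolean mask
    name: str = "phantom"

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int16)
        object.__setattr__(self, "labels", lab)
        if lab.ndim != 2 or lab.shape[0] != lab.shape[1]:
            raise ParameterError("label raster must be square")
        if lab.max() >= len(self.materials) or lab.min() < 0:
            raise ParameterError("labels reference undefined materials")

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    @property
    def extent_cm(self) -> float:
        return self.n * self.pixel_size_mm / 10.0

    @property
    def density_map(self) -> np.ndarray:
        """Mass density (g/cm^3) per pixel."""
        rho = np.array([m.density for m in self.materials])
        return rho[self.labels]

    @property
    def body_mask(self) -> np.ndarray:
        return self.labels != LABELS["air"]

    def grid_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center world coordinates (x, y) in cm, isocenter at 0."""
        d = self.pixel_size_mm / 10.0
        half = self.n * d / 2.0
        c = (np.arange(self.n) + 0.5) * d - half
        return np.meshgrid(c, c)  # x varies along columns, y along rows

    def mu_map(self, energy_kev: float) -> np.ndarray:
        """Ground-truth linear attenuation (cm^-1) at one energy."""
        mus = np.array([m.mu(energy_kev) for m in self.materials])
        return mus[self.labels]


@dataclass(frozen=True)
class GroundTruthVMI:
    """Noise-free monoenergetic ground truth for RMSE evaluation."""

    energy_kev: float
    mu_map: np.ndarray  # cm^-1
    hu_map: np.ndarray


def _disk(x, y, cx, cy, r):
    return (x - cx) ** 2 + (y - cy) ** 2 <= r**2


def _ellipse(x, y, cx, cy, ax, ay):
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0


def water_cylinder(
    diameter_cm: float = 40.0, n: int = 512, pixel_mm: float = 1.0
) -> PhantomImage:
    """Circular water cylinder in air, centered in the field of view."""
    fov = n * pixel_mm / 10.0
    if diameter_cm > fov:
        raise ParameterError(f"diameter {diameter_cm} cm exceeds {fov} cm FOV")
    labels = np.zeros((n, n), dtype=np.int16)
    d = pixel_mm / 10.0
    c = (np.arange(n) + 0.5) * d - fov / 2.0
    x, y = np.meshgrid(c, c)
    labels[_disk(x, y, 0.0, 0.0, diameter_cm / 2.0)] = 1
    return PhantomImage(
        labels=labels,
        pixel_size_mm=pixel_mm,
        materials=(_air(), get_material("water")),
        rois={},
        name=f"water_{diameter_cm:g}cm",
    )


def pelvis_phantom(
    implant: str = "none",
    n: int = 512,
    pixel_mm: float = 1.0,
    seed: int = 0,
) -> PhantomImage:
    """Parametric pelvis with an optional hip prosthesis.

    ``implant`` is ``"none"``, ``"titanium"``, or ``"steel"``.  Generation is
    deterministic given the geometry constants (the seed is accepted for API
    stability but the anatomy is fixed, which keeps all variants paired).
    """
    if implant not in ("none", "titanium", "steel"):
        raise ParameterError(f"unknown implant {implant!r}")
    g = PELVIS_GEOMETRY
    labels = np.zeros((n, n), dtype=np.int16)
    d = pixel_mm / 10.0
    half = n * d / 2.0
    c = (np.arange(n) + 0.5) * d - half
    x, y = np.meshgrid(c, c)

    labels[_ellipse(x, y, 0, 0, *g["body"])] = LABELS["tissue"]
    ring = _ellipse(x, y, *g["ring_center"], *g["ring_outer"]) & ~_ellipse(
        x, y, *g["ring_center"], *g["ring_inner"]
    )
    labels[ring] = LABELS["bone"]
    for cx, cy in g["femur_centers"]:
        labels[_disk(x, y, cx, cy, g["femur_radius"])] = LABELS["bone"]
    labels[_ellipse(x, y, *g["inset_center"], *g["inset_axes"])] = LABELS["inset"]

    if implant != "none":
        cx, cy = g["femur_centers"][1]
        rr = np.hypot(x - cx, y - cy)
        # acetabular shell only on the half facing the body center
        ux, uy = -1.0, 0.3
        norm = np.hypot(ux, uy)
        medial = ((x - cx) * ux + (y - cy) * uy) / norm >= 0.0
        shell = (rr > g["implant_lining_radius"]) & (
            rr <= g["implant_shell_radius"]
        ) & medial
        lining = (rr > g["implant_head_radius"]) & (rr <= g["implant_lining_radius"])
        head = rr <= g["implant_head_radius"]
        labels[shell] = LABELS["metal"]
        labels[lining] = LABELS["pmma"]
        labels[head] = LABELS["metal"]

    tissue = get_material("tissue")
    metal = get_material("titanium" if implant != "steel" else "steel")
    materials = (
        _air(),
        tissue,
        get_material("bone"),
        tissue.with_density(g["inset_density"], name="soft_inset"),
        get_material("pmma"),
        metal,
    )
    rois = {
        "signal": _disk(x, y, *g["roi_signal_center"], g["roi_radius"]),
        "background": _disk(x, y, *g["roi_background_center"], g["roi_radius"]),
    }
    return PhantomImage(
        labels=labels,
        pixel_size_mm=pixel_mm,
        materials=materials,
        rois=rois,
        name=f"pelvis_{implant}",
    )


def ground_truth_vmi(phantom: PhantomImage, energy_kev: float) -> GroundTruthVMI:
    """Noise-free mu and HU maps of the phantom at one energy."""
    mu = phantom.mu_map(energy_kev)
    mu_w = float(get_material("water").mu(energy_kev))
    hu = 1000.0 * (mu - mu_w) / mu_w
    return GroundTruthVMI(energy_kev=float(energy_kev), mu_map=mu, hu_map=hu)


def write_phantom(phantom: PhantomImage, path) -> None:
    """Flat binary label raster plus a JSON sidecar."""
    path = Path(path)
    phantom.labels.astype("<i2").tofile(path)
    sidecar = {
        "n": phantom.n,
        "dtype": "<i2",
        "pixel_size_mm": phantom.pixel_size_mm,
        "name": phantom.name,
        "materials": [
            {"name": m.name, "density": m.density} for m in phantom.materials
        ],
        "rois": {
            k: np.flatnonzero(v.ravel()).tolist() for k, v in phantom.rois.items()
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_phantom(path) -> PhantomImage:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    n = meta["n"]
    labels = np.fromfile(path, dtype=meta["dtype"]).reshape(n, n)
    mats = []
    for m in meta["materials"]:
        if m["name"] == "air":
            mats.append(_air())
        elif m["name"] == "soft_inset":
            mats.append(
                get_material("tissue").with_density(m["density"], name="soft_inset")
            )
        else:
            mats.append(get_material(m["name"], density=m["density"]))
    rois = {}
    for k, idx in meta["rois"].items():
        mask = np.zeros(n * n, dtype=bool)
        mask[np.asarray(idx, dtype=int)] = True
        rois[k] = mask.reshape(n, n)
    return PhantomImage(
        labels=labels,
        pixel_size_mm=meta["pixel_size_mm"],
        materials=tuple(mats),
        rois=rois,
        name=meta.get("name", "phantom"),
    )
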