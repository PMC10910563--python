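"""Virtual monoenergetic images and image-quality metrics.

A VMI at energy E0 is the linear combination of the two basis density
images with the known mass attenuation coefficients:

    mu(E0) = rho_1 [mu(E0)/rho]_1 + rho_2 [mu(E0)/rho]_2

CNR uses the two phantom ROIs (signal vs background) with population
statistics over ROI pixels:

    CNR = |mean(ROI1) - mean(ROI2)| / sqrt(var(ROI1) + var(ROI2))

RMSE is the root mean square HU difference to the monoenergetic ground
truth inside a body mask (default: body outline eroded by 3 pixels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .materials import Material, get_material
from .phantom import GroundTruthVMI, PhantomImage
from .recon import ReconImage

__all__ = [
    "VmiImage",
    "synthesize_vmi",
    "cnr",
    "rmse",
    "cnr_vs_energy",
    "rmse_vs_energy",
    "body_mask",
    "DEFAULT_VMI_ENERGIES",
]

#: Default VMI energy grid (keV), covering soft-tissue through metal optima.
DEFAULT_VMI_ENERGIES = np.arange(40.0, 351.0, 1.0)


@dataclass(frozen=True)
class VmiImage:
    """Virtual monoenergetic image: mu and HU maps at one energy."""

    energy_kev: float
    mu_map: np.ndarray
    hu_map: np.ndarray
    meta: dict = field(default_factory=dict)


def synthesize_vmi(
    basis_tissue: ReconImage | np.ndarray,
    basis_bone: ReconImage | np.ndarray,
    energy_kev: float,
    tissue: Material | None = None,
    bone: Material | None = None,
    water: Material | None = None,
) -> VmiImage:
    """Combine basis density images into a VMI at ``energy_kev``."""
    tissue = tissue or get_material("tissue")
    bone = bone or get_material("bone")
    water = water or get_material("water")
    rho_t = basis_tissue.values if isinstance(basis_tissue, ReconImage) else np.asarray(basis_tissue)
    rho_b = basis_bone.values if isinstance(basis_bone, ReconImage) else np.asarray(basis_bone)
    if rho_t.shape != rho_b.shape:
        raise ParameterError("basis images must share shape")
    mu = rho_t * float(tissue.mu_rho(energy_kev)) + rho_b * float(bone.mu_rho(energy_kev))
    mu_w = float(water.mu(energy_kev))
    hu = 1000.0 * (mu - mu_w) / mu_w
    return VmiImage(energy_kev=float(energy_kev), mu_map=mu, hu_map=hu)


def cnr(values: np.ndarray, roi_signal: np.ndarray, roi_background: np.ndarray) -> float:
    """Contrast-to-noise ratio between two disjoint ROIs.

    Population variance over ROI pixels; a zero pooled variance returns
    ``inf`` (degenerate noiseless case) rather than raising.
    """
    s = np.asarray(values)[np.asarray(roi_signal, dtype=bool)]
    b = np.asarray(values)[np.asarray(roi_background, dtype=bool)]
    if s.size == 0 or b.size == 0:
        raise ParameterError("ROIs must be non-empty")
    if np.logical_and(roi_signal, roi_background).any():
        raise ParameterError("ROIs must be disjoint")
    contrast = abs(float(s.mean()) - float(b.mean()))
    pooled = float(np.var(s) + np.var(b))
    if pooled == 0.0:
        return float("inf") if contrast > 0 else 0.0
    return contrast / np.sqrt(pooled)


def contrast_noise(values, roi_signal, roi_background) -> tuple[float, float]:
    """The CNR numerator and denominator separately."""
    s = np.asarray(values)[np.asarray(roi_signal, dtype=bool)]
    b = np.asarray(values)[np.asarray(roi_background, dtype=bool)]
    return abs(float(s.mean() - b.mean())), float(np.sqrt(np.var(s) + np.var(b)))


def body_mask(phantom: PhantomImage, erode_px: int = 3) -> np.ndarray:
    """Body outline minus an eroded rim, for RMSE evaluation."""
    return ndimage.binary_erosion(phantom.body_mask, iterations=erode_px)


def rmse(vmi_hu: np.ndarray, truth_hu: np.ndarray, mask: np.ndarray) -> float:
    """Root mean square HU difference over ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ParameterError("empty RMSE mask")
    d = np.asarray(vmi_hu)[mask] - np.asarray(truth_hu)[mask]
    return float(np.sqrt(np.mean(d**2)))


def cnr_vs_energy(
    basis_tissue,
    basis_bone,
    roi_signal,
    roi_background,
    energies=None,
    **mats,
) -> dict:
    """CNR(E0) over an energy grid, with the peak coordinates."""
    energies = DEFAULT_VMI_ENERGIES if energies is None else np.asarray(energies, float)
    out = np.empty(energies.size)
    contrast = np.empty(energies.size)
    noise = np.empty(energies.size)
    for i, e0 in enumerate(energies):
        v = synthesize_vmi(basis_tissue, basis_bone, e0, **mats)
        out[i] = cnr(v.hu_map, roi_signal, roi_background)
        contrast[i], noise[i] = contrast_noise(v.hu_map, roi_signal, roi_background)
    k = int(np.argmax(out))
    return {
        "energies": energies,
        "cnr": out,
        "contrast": contrast,
        "noise": noise,
        "peak_energy_kev": float(energies[k]),
        "peak_cnr": float(out[k]),
    }


def rmse_vs_energy(
    basis_tissue,
    basis_bone,
    phantom: PhantomImage,
    energies=None,
    erode_px: int = 3,
    **mats,
) -> dict:
    """RMSE(E0) against the monoenergetic ground truth, with the minimum."""
    from .phantom import ground_truth_vmi

    energies = DEFAULT_VMI_ENERGIES if energies is None else np.asarray(energies, float)
    mask = body_mask(phantom, erode_px=erode_px)
    out = np.empty(energies.size)
    for i, e0 in enumerate(energies):
        v = synthesize_vmi(basis_tissue, basis_bone, e0, **mats)
        truth = ground_truth_vmi(phantom, e0)
        out[i] = rmse(v.hu_map, truth.hu_map, mask)
    k = int(np.argmin(out))
    return {
        "energies": energies,
        "rmse_hu": out,
        "min_energy_kev": float(energies[k]),
        "min_rmse_hu": float(out[k]),
    }
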