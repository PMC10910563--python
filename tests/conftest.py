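"""Shared fixtures: materials, detector, small-scale simulation products."""

from __future__ import annotations

import numpy as np
import pytest

import dectsim as ds
from dectsim.decompose import SpectralForwardModel, decompose_sinogram
from dectsim.detector import Detector
from dectsim.pipeline import spectrum_by_label
from dectsim.projector import FanBeamGeometry, material_length_sinogram, project_polychromatic
from dectsim.recon import ffbp
from dectsim.spectra import Spectrum, scale_to_dose


@pytest.fixture(scope="session")
def water():
    return ds.get_material("water")


@pytest.fixture(scope="session")
def tissue():
    return ds.get_material("tissue")


@pytest.fixture(scope="session")
def bone():
    return ds.get_material("bone")


@pytest.fixture(scope="session")
def detector():
    return Detector.default_xenon()


@pytest.fixture(scope="session")
def ideal_detector():
    """eta = 1 everywhere, energy-integrating: keeps oracles analytic."""
    return Detector(
        eta_energies=np.array([1.0, 1e4]), eta_values=np.array([1.0, 1.0])
    )


@pytest.fixture(scope="session")
def counting_detector():
    """eta = 1, D(E) = 1: makes the detected signal exactly Poisson."""
    return Detector(
        response_kind="counting",
        eta_energies=np.array([1.0, 1e4]),
        eta_values=np.array([1.0, 1.0]),
    )


def mono_spectrum(energy_kev: float, photons: float, label: str = "") -> Spectrum:
    """Single-line spectrum (second bin empty) for closed-form oracles."""
    return Spectrum(
        np.array([energy_kev, energy_kev + 1.0]),
        np.array([photons, 0.0]),
        label=label or f"mono{energy_kev:g}",
        dose_uGy=1.0,
    )


@pytest.fixture(scope="session")
def standard_spectra():
    return ds.standard_spectra()


@pytest.fixture(scope="session")
def noiseless_de_pipeline(detector):
    """Small noiseless dual-energy CT run shared by recon/VMI/acceptance tests.

    Returns phantom, geometry, per-material path lengths, raw sinogram pair,
    decomposition, and the reconstructed basis images.
    """
    phantom = ds.pelvis_phantom("none", n=160, pixel_mm=3.2)
    geometry = FanBeamGeometry(n_views=240, n_channels=160)
    lengths = material_length_sinogram(geometry, phantom)
    low = scale_to_dose(spectrum_by_label("80kV"), 1000.0 / geometry.n_views)
    high = scale_to_dose(spectrum_by_label("detunedMV"), 9000.0 / geometry.n_views)
    s_lo = project_polychromatic(
        phantom, low, detector, geometry, material_lengths=lengths
    )
    s_hi = project_polychromatic(
        phantom, high, detector, geometry, material_lengths=lengths
    )
    model = SpectralForwardModel((low, high), detector)
    result = decompose_sinogram(s_lo, s_hi, model)
    bt, bb = result.basis_sinograms(s_lo)
    return {
        "phantom": phantom,
        "geometry": geometry,
        "lengths": lengths,
        "spectra": (low, high),
        "sinograms": (s_lo, s_hi),
        "model": model,
        "decomposition": result,
        "basis_images": (ffbp(bt, n_pixels=phantom.n), ffbp(bb, n_pixels=phantom.n)),
    }


@pytest.fixture(scope="session")
def model2_de_metrics():
    """Seeded, scaled-down noisy CT study (no-implant + steel, both DE pairs)."""
    from dectsim.pipeline import ExperimentConfig, run_model2

    cfg = ExperimentConfig(seed=1, scale="test")
    out = run_model2(cfg, variants=("none", "steel"), include_se=False)
    return out["metrics"]
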