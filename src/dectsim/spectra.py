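"""X-ray spectra: synthetic generators, dose normalization, dose allocation.

A :class:`Spectrum` is a discrete photon fluence (photons per energy bin, per
cm^2 at the isocenter) on a strictly increasing keV grid.  All energy
integrals in the package are plain bin sums on the spectrum's own grid, with
attenuation curves interpolated log-log onto that grid — deterministic and
adequate for the smooth integrands involved.

Synthetic generators
--------------------
``generate_kv_spectrum``
    Kramers-law bremsstrahlung shaped by aluminum filtration (Beer-Lambert on
    the packaged Al table); characteristic lines omitted.  1 keV bins from
    1 keV to the tube voltage.
``generate_mv_spectrum``
    Thin-target bremsstrahlung (Schiff-like 1/E falloff to the endpoint)
    hardened by water-equivalent flattening filtration.  10 keV bins from
    10 keV to the endpoint.  ``mode="treatment"`` defaults to a 6 MV beam,
    ``mode="detuned"`` to a 2.5 MV imaging beam.

Dose normalization
------------------
Dose is scored at depth ``d`` in water under charged-particle equilibrium:

    Dose(d) = sum_E I(E) exp(-mu_w(E) d) [muen(E)/rho]_w E  (converted to uGy)

so each spectrum can be rescaled to deliver a target dose (default 1 uGy) to
the center of a 40 cm water cylinder, making spectra dose-comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import (
    DegenerateInputError,
    ParameterError,
    TableFormatError,
)
from .materials import Material, get_material

__all__ = [
    "Spectrum",
    "SpectralPair",
    "generate_kv_spectrum",
    "generate_mv_spectrum",
    "dose_at_depth",
    "scale_to_dose",
    "allocate",
    "read_spectrum",
    "write_spectrum",
]

#: uGy per (photon/cm^2 * keV * cm^2/g): keV->J times g->kg times Gy->uGy.
DOSE_FACTOR_UGY = 1.602176634e-16 * 1e3 * 1e6

#: Reference water depth (cm): center of a 40 cm diameter cylinder.
REFERENCE_DEPTH_CM = 20.0


@dataclass(frozen=True)
class Spectrum:
    """Photon fluence per energy bin on a keV grid."""

    energies: np.ndarray
    fluence: np.ndarray
    label: str = ""
    dose_uGy: float | None = None  # set by scale_to_dose / allocate

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        f = np.asarray(self.fluence, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "fluence", f)
        if e.ndim != 1 or e.size < 2:
            raise ParameterError("spectrum needs at least 2 energy bins")
        if np.any(np.diff(e) <= 0):
            raise ParameterError("spectrum energy grid must be strictly increasing")
        if f.shape != e.shape or np.any(f < 0) or not np.all(np.isfinite(f)):
            raise ParameterError("fluence must be finite and non-negative")

    @property
    def total_fluence(self) -> float:
        return float(self.fluence.sum())

    @property
    def mean_energy(self) -> float:
        """Fluence-weighted mean photon energy, keV."""
        tot = self.total_fluence
        if tot == 0:
            raise DegenerateInputError("zero-fluence spectrum has no mean energy")
        return float((self.energies * self.fluence).sum() / tot)

    def scaled(self, factor: float, label: str | None = None) -> "Spectrum":
        if factor < 0:
            raise ParameterError("scale factor must be >= 0")
        dose = None if self.dose_uGy is None else self.dose_uGy * factor
        return replace(
            self,
            fluence=self.fluence * factor,
            label=label if label is not None else self.label,
            dose_uGy=dose,
        )


def generate_kv_spectrum(
    kvp: float, filtration_mm_al: float = 2.5, label: str | None = None
) -> Spectrum:
    """Kramers bremsstrahlung at tube voltage ``kvp`` with Al filtration.

    Fluence is strictly zero at and above the endpoint energy (= kvp in keV).
    """
    if not 40.0 <= kvp <= 150.0:
        raise ParameterError(f"kvp={kvp} outside supported range [40, 150]")
    if filtration_mm_al < 0:
        raise ParameterError("filtration must be >= 0")
    e = np.arange(1.0, kvp + 0.5, 1.0)
    raw = np.clip(kvp - e, 0.0, None) / e
    al = get_material("aluminum")
    t_cm = filtration_mm_al / 10.0
    fl = raw * np.exp(-al.mu_rho(e) * al.density * t_cm)
    return Spectrum(e, fl, label=label or f"{int(round(kvp))}kV")


def generate_mv_spectrum(
    endpoint_mev: float | None = None,
    mode: str = "treatment",
    flattening_cm_water: float = 12.0,
    label: str | None = None,
) -> Spectrum:
    """Thin-target MV bremsstrahlung hardened by water-equivalent filtration.

    ``mode="treatment"`` defaults to a 6 MV endpoint; ``mode="detuned"`` to a
    2.5 MV endpoint (and requires the endpoint to stay below 3 MV).
    """
    if mode not in ("treatment", "detuned"):
        raise ParameterError(f"unknown MV mode {mode!r}")
    if endpoint_mev is None:
        endpoint_mev = 6.0 if mode == "treatment" else 2.5
    if not 1.0 <= endpoint_mev <= 10.0:
        raise ParameterError(f"endpoint={endpoint_mev} MeV outside [1, 10]")
    if mode == "detuned" and endpoint_mev >= 3.0:
        raise ParameterError("detuned beam endpoint must be below 3 MeV")
    e0 = endpoint_mev * 1000.0
    e = np.arange(10.0, e0 + 5.0, 10.0)
    raw = np.clip(e0 - e, 0.0, None) / e
    water = get_material("water")
    fl = raw * np.exp(-water.mu_rho(e) * water.density * flattening_cm_water)
    if label is None:
        label = "6MV" if mode == "treatment" else "detunedMV"
    return Spectrum(e, fl, label=label)


def dose_at_depth(
    spectrum: Spectrum,
    water: Material | None = None,
    depth_cm: float = REFERENCE_DEPTH_CM,
) -> float:
    """Water dose (uGy) at ``depth_cm`` under charged-particle equilibrium."""
    if depth_cm < 0:
        raise ParameterError("depth must be >= 0")
    water = water or get_material("water")
    if water.muen_over_rho is None:
        raise TableFormatError("water material must carry muen/rho")
    e = spectrum.energies
    atten = np.exp(-water.mu_rho(e) * water.density * depth_cm)
    return float(
        DOSE_FACTOR_UGY * np.sum(spectrum.fluence * atten * water.muen_rho(e) * e)
    )


def scale_to_dose(
    spectrum: Spectrum,
    target_uGy: float = 1.0,
    depth_cm: float = REFERENCE_DEPTH_CM,
    water: Material | None = None,
) -> Spectrum:
    """Rescale fluence so the spectrum delivers ``target_uGy`` at depth.

    Spectral shape is unchanged (a single multiplicative factor).
    """
    if target_uGy <= 0:
        raise ParameterError("target dose must be > 0")
    current = dose_at_depth(spectrum, water=water, depth_cm=depth_cm)
    if current <= 0:
        raise DegenerateInputError("cannot dose-normalize a zero-dose spectrum")
    out = spectrum.scaled(target_uGy / current)
    return replace(out, dose_uGy=target_uGy)


@dataclass(frozen=True)
class SpectralPair:
    """A dual-energy pair with a dose split.

    Both member spectra must be pre-normalized to ``total_dose_uGy``;
    :func:`allocate` then rescales the high-energy spectrum by ``r`` and the
    low-energy spectrum by ``1 - r``.
    """

    low: Spectrum
    high: Spectrum
    r: float = 0.5
    total_dose_uGy: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.r < 1.0:
            raise ParameterError(f"dose allocation r={self.r} outside (0, 1)")
        if self.total_dose_uGy <= 0:
            raise ParameterError("total dose must be > 0")

    @property
    def label(self) -> str:
        return f"{self.high.label}-{self.low.label}"


def allocate(pair: SpectralPair) -> tuple[Spectrum, Spectrum]:
    """Split the pair's total dose: returns ``(low*(1-r), high*r)``."""
    for s in (pair.low, pair.high):
        if s.dose_uGy is None or not np.isclose(
            s.dose_uGy, pair.total_dose_uGy, rtol=1e-9
        ):
            raise ParameterError(
                "pair members must be pre-normalized to total_dose_uGy "
                "(use scale_to_dose)"
            )
    return pair.low.scaled(1.0 - pair.r), pair.high.scaled(pair.r)


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write the delimited-text spectrum dialect (energy_kev, photons_per_bin)."""
    lines = ["energy_kev,photons_per_bin"]
    lines += [
        f"{e:.6g},{f:.10g}" for e, f in zip(spectrum.energies, spectrum.fluence)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum(path, label: str | None = None) -> Spectrum:
    """Read the spectrum dialect written by :func:`write_spectrum`."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    sep = "," if "," in lines[0] else None
    header = [c.strip().lower() for c in lines[0].split(sep)]
    if "energy_kev" not in header or "photons_per_bin" not in header:
        raise TableFormatError(
            f"{path}: spectrum file needs columns energy_kev, photons_per_bin"
        )
    ie, if_ = header.index("energy_kev"), header.index("photons_per_bin")
    e, f = [], []
    for i, ln in enumerate(lines[1:], start=2):
        cells = ln.split(sep)
        try:
            e.append(float(cells[ie]))
            f.append(float(cells[if_]))
        except (ValueError, IndexError) as exc:
            raise TableFormatError(f"{path}: bad row {i}: {ln!r}") from exc
    return Spectrum(np.asarray(e), np.asarray(f), label=label or path.stem)
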