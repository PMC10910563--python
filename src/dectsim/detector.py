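"""Detector model: detective efficiency eta(E) and response D(E).

The default detector emulates a high-DQE pressurized-xenon gas detector of
the kind used for fan-beam MV CT: an energy-integrating response D(E) = E and
a thick-absorber detective efficiency

    eta(E) = 1 - exp(-(mu/rho)_Xe(E) * x_eff)

with the effective mass thickness ``x_eff`` (g/cm^2) calibrated once so that
eta(1 MeV) = 0.20, the quoted efficiency of such detectors in the MeV range.
A counting response D(E) = 1 is available for analytic oracles (it makes the
signal exactly Poisson).  A user-supplied eta table (columns ``energy_kev``,
``eta``) may replace the absorber model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EnergyRangeError, ParameterError, TableFormatError
from .materials import Material, get_material
from .spectra import Spectrum

__all__ = ["Detector", "detected_mean"]

_EMIN_KEV, _EMAX_KEV = 1.0, 10000.0


def _calibrated_xenon_thickness(target_eta: float = 0.20, at_kev: float = 1000.0) -> float:
    xe = get_material("xenon")
    return float(-np.log(1.0 - target_eta) / xe.mu_rho(at_kev))


@dataclass(frozen=True)
class Detector:
    """Energy-integrating (or counting) detector with efficiency eta(E).

    Exactly one of the absorber model (default) or a tabulated eta curve is
    active: if ``eta_energies``/``eta_values`` are given they are interpolated
    log-linearly, otherwise the calibrated xenon absorber form is used.
    """

    response_kind: str = "energy_integrating"  # or "counting"
    mass_thickness: float | None = None  # g/cm^2 of absorber; None = calibrated
    absorber: Material | None = None  # None = packaged xenon
    eta_energies: np.ndarray | None = None
    eta_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.response_kind not in ("energy_integrating", "counting"):
            raise ParameterError(f"unknown response kind {self.response_kind!r}")
        if (self.eta_energies is None) != (self.eta_values is None):
            raise ParameterError("eta table needs both energies and values")
        if self.eta_values is not None:
            ev = np.asarray(self.eta_values, dtype=float)
            ee = np.asarray(self.eta_energies, dtype=float)
            object.__setattr__(self, "eta_values", ev)
            object.__setattr__(self, "eta_energies", ee)
            if np.any(ev < 0) or np.any(ev > 1):
                raise ParameterError("tabulated eta must lie in [0, 1]")
            if np.any(np.diff(ee) <= 0):
                raise ParameterError("eta energy grid must be strictly increasing")

    @classmethod
    def default_xenon(cls, response_kind: str = "energy_integrating") -> "Detector":
        """The calibrated xenon EID with eta(1 MeV) = 0.20."""
        return cls(
            response_kind=response_kind,
            mass_thickness=_calibrated_xenon_thickness(),
        )

    @classmethod
    def from_eta_table(cls, path, response_kind: str = "energy_integrating") -> "Detector":
        """Load a user-supplied eta table (columns energy_kev, eta)."""
        lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
        sep = "," if "," in lines[0] else None
        header = [c.strip().lower() for c in lines[0].split(sep)]
        if "energy_kev" not in header or "eta" not in header:
            raise TableFormatError(f"{path}: eta table needs columns energy_kev, eta")
        ie, iv = header.index("energy_kev"), header.index("eta")
        rows = [ln.split(sep) for ln in lines[1:]]
        e = np.array([float(r[ie]) for r in rows])
        v = np.array([float(r[iv]) for r in rows])
        return cls(response_kind=response_kind, eta_energies=e, eta_values=v)

    def efficiency(self, energies) -> np.ndarray:
        """Detective efficiency eta at ``energies`` (keV), values in [0, 1]."""
        e = np.asarray(energies, dtype=float)
        if np.any(e < _EMIN_KEV) or np.any(e > _EMAX_KEV):
            raise EnergyRangeError(
                f"detector model covers [{_EMIN_KEV}, {_EMAX_KEV}] keV"
            )
        if self.eta_values is not None:
            return np.interp(np.log(e), np.log(self.eta_energies), self.eta_values)
        absorber = self.absorber or get_material("xenon")
        x = (
            self.mass_thickness
            if self.mass_thickness is not None
            else _calibrated_xenon_thickness()
        )
        return 1.0 - np.exp(-absorber.mu_rho(e) * x)

    def response(self, energies) -> np.ndarray:
        """D(E): photon weight in the integrated signal (E or 1)."""
        e = np.asarray(energies, dtype=float)
        if self.response_kind == "energy_integrating":
            return e
        return np.ones_like(e)


def detected_mean(
    spectrum: Spectrum, transmission, detector: Detector
) -> float:
    """Mean detected signal: lambda = sum_E D(E) I(E) T(E) eta(E)."""
    t = np.asarray(transmission, dtype=float)
    if t.shape != spectrum.energies.shape:
        raise ParameterError("transmission must match the spectrum grid")
    if np.any(t < 0):
        raise ParameterError("transmission must be non-negative")
    e = spectrum.energies
    return float(
        np.sum(detector.response(e) * spectrum.fluence * t * detector.efficiency(e))
    )
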