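"""Material property tables: mass attenuation and energy-absorption curves.

A :class:`Material` bundles a density with tabulated mass attenuation
``mu/rho`` (and optionally mass energy-absorption ``muen/rho``) curves on a
strictly increasing energy grid spanning 1 keV to 10 MeV.  Queries inside the
grid are interpolated log-log, the standard choice for photon cross sections,
which are near power laws between tabulation knots.

Packaged tables (water, ICRU soft tissue, ICRU cortical bone, PMMA, titanium,
stainless steel, aluminum, xenon) are transcribed from the standard NIST/XCOM
reference compilations on the NIST energy grid.  Default densities follow
standard references: ICRU tissue 1.00 g/cm3, ICRU cortical bone 1.85 g/cm3,
PMMA 1.19, commercially pure titanium 4.51, surgical stainless steel 8.00,
aluminum 2.699.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import EnergyRangeError, TableFormatError

__all__ = [
    "Material",
    "load_attenuation_table",
    "get_material",
    "DEFAULT_DENSITIES",
]

#: Default mass densities (g/cm^3) for the packaged tables.
DEFAULT_DENSITIES = {
    "water": 1.00,
    "tissue": 1.00,
    "bone": 1.85,
    "pmma": 1.19,
    "titanium": 4.51,
    "steel": 8.00,
    "aluminum": 2.699,
    "xenon": 0.011,  # pressurized gas; only the mass thickness matters
}


def _loglog_interp(e: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    return np.exp(np.interp(np.log(e), np.log(xp), np.log(fp)))


@dataclass(frozen=True)
class Material:
    """A named substance with energy-resolved photon interaction coefficients.

    Parameters
    ----------
    name : str
    density : float
        Mass density in g/cm^3 (> 0).
    energies : ndarray
        Strictly increasing energy grid, keV.
    mu_over_rho : ndarray
        Mass attenuation coefficient at each grid energy, cm^2/g (> 0).
    muen_over_rho : ndarray, optional
        Mass energy-absorption coefficient, cm^2/g; required for dose
        computations (water).
    """

    name: str
    density: float
    energies: np.ndarray
    mu_over_rho: np.ndarray
    muen_over_rho: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        m = np.asarray(self.mu_over_rho, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "mu_over_rho", m)
        if self.muen_over_rho is not None:
            object.__setattr__(
                self, "muen_over_rho", np.asarray(self.muen_over_rho, dtype=float)
            )
        if self.density <= 0:
            raise TableFormatError(f"{self.name}: density must be > 0")
        if e.ndim != 1 or e.size < 2:
            raise TableFormatError(f"{self.name}: need at least 2 energy knots")
        if np.any(np.diff(e) <= 0):
            raise TableFormatError(f"{self.name}: energy grid not strictly increasing")
        if m.shape != e.shape or np.any(m <= 0):
            raise TableFormatError(f"{self.name}: mu/rho must be positive, same shape")
        if self.muen_over_rho is not None and (
            self.muen_over_rho.shape != e.shape or np.any(self.muen_over_rho <= 0)
        ):
            raise TableFormatError(f"{self.name}: muen/rho must be positive, same shape")

    def _check_range(self, energy_kev: np.ndarray) -> None:
        if np.any(energy_kev < self.energies[0]) or np.any(
            energy_kev > self.energies[-1]
        ):
            raise EnergyRangeError(
                f"{self.name}: query outside tabulated range "
                f"[{self.energies[0]}, {self.energies[-1]}] keV"
            )

    def mu_rho(self, energy_kev) -> np.ndarray:
        """Mass attenuation coefficient (cm^2/g) at ``energy_kev`` (log-log)."""
        e = np.asarray(energy_kev, dtype=float)
        self._check_range(e)
        return _loglog_interp(e, self.energies, self.mu_over_rho)

    def mu(self, energy_kev) -> np.ndarray:
        """Linear attenuation coefficient (cm^-1) at ``energy_kev``."""
        return self.density * self.mu_rho(energy_kev)

    def muen_rho(self, energy_kev) -> np.ndarray:
        """Mass energy-absorption coefficient (cm^2/g) at ``energy_kev``."""
        if self.muen_over_rho is None:
            raise TableFormatError(f"{self.name}: no muen/rho table available")
        e = np.asarray(energy_kev, dtype=float)
        self._check_range(e)
        return _loglog_interp(e, self.energies, self.muen_over_rho)

    def with_density(self, density: float, name: str | None = None) -> "Material":
        """Same curves, different density (e.g. a denser soft-tissue inset)."""
        return Material(
            name=name or self.name,
            density=density,
            energies=self.energies,
            mu_over_rho=self.mu_over_rho,
            muen_over_rho=self.muen_over_rho,
        )


def _parse_table(text: str, source: str) -> tuple[list[str], np.ndarray]:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise TableFormatError(f"{source}: empty table")
    sep = "," if "," in lines[0] else None
    header = [c.strip().lower() for c in lines[0].split(sep)]
    rows = []
    for i, ln in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in ln.split(sep)]
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise TableFormatError(f"{source}: row {i} is not numeric: {ln!r}") from exc
        if len(cells) != len(header):
            raise TableFormatError(f"{source}: row {i} has {len(cells)} columns")
    return header, np.asarray(rows, dtype=float)


def load_attenuation_table(
    path, density: float, name: str | None = None
) -> Material:
    """Load a delimited-text attenuation table into a :class:`Material`.

    The file must have a header line with columns ``energy_kev`` and
    ``mu_over_rho`` (optionally ``muen_over_rho``); comma or whitespace
    delimited.  Errors name the offending row.
    """
    path = Path(path)
    header, data = _parse_table(path.read_text(), str(path))
    for col in ("energy_kev", "mu_over_rho"):
        if col not in header:
            raise TableFormatError(f"{path}: missing required column {col!r}")
    e = data[:, header.index("energy_kev")]
    m = data[:, header.index("mu_over_rho")]
    bad = np.nonzero(np.diff(e) <= 0)[0]
    if bad.size:
        raise TableFormatError(
            f"{path}: energies not strictly increasing at row {bad[0] + 3}"
        )
    neg = np.nonzero(m <= 0)[0]
    if neg.size:
        raise TableFormatError(f"{path}: non-positive mu/rho at row {neg[0] + 2}")
    muen = None
    if "muen_over_rho" in header:
        muen = data[:, header.index("muen_over_rho")]
        neg = np.nonzero(muen <= 0)[0]
        if neg.size:
            raise TableFormatError(f"{path}: non-positive muen/rho at row {neg[0] + 2}")
    return Material(
        name=name or path.stem,
        density=density,
        energies=e,
        mu_over_rho=m,
        muen_over_rho=muen,
    )


@functools.lru_cache(maxsize=None)
def get_material(name: str, density: float | None = None) -> Material:
    """Return a packaged material table by name.

    Known names: water, tissue, bone, pmma, titanium, steel, aluminum, xenon.
    ``density`` overrides the packaged default.
    """
    key = name.lower()
    if key not in DEFAULT_DENSITIES:
        raise TableFormatError(
            f"unknown packaged material {name!r}; known: {sorted(DEFAULT_DENSITIES)}"
        )
    ref = resources.files("dectsim.data").joinpath(f"{key}.csv")
    with resources.as_file(ref) as p:
        return load_attenuation_table(
            p, density if density is not None else DEFAULT_DENSITIES[key], name=key
        )
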