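"""Estimation-theoretic SNR for a single dual-energy line integral.

A two-material object (ICRU tissue + bone) is traversed by one ray, measured
with two dose-allocated spectra on an energy-integrating detector.  The
energy-weighted compound-Poisson signal is approximated as Gaussian with
matching first two moments:

    lambda_i = sum_E D(E) I_i(E) T(E) eta(E)
    sigma2_i = sum_E D(E)^2 I_i(E) T(E) eta(E)

The Fisher information for the basis mass thicknesses A = (A_tissue, A_bone)
(g/cm^2) then has the two-term Gaussian form

    F_jk = sum_i (1/sigma2_i) dlambda_i/dA_j dlambda_i/dA_k
         + 1/2 sum_i (1/sigma2_i^2) dsigma2_i/dA_j dsigma2_i/dA_k

with analytic derivatives d(lambda,sigma2)/dA_j = -sum_E [.] (mu/rho)_j(E).
The Cramer-Rao bound on the variance of any unbiased estimator of A_j is the
j-th diagonal of F^{-1}, and SNR_j = A_j / sqrt(CRLB_j).

Because both moments and their derivatives are linear in fluence, sweeping
the dose allocation r only rescales per-spectrum terms; the first Fisher term
scales with r while the second is scale-invariant, so a full 99-point sweep
costs two moment evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detector import Detector
from .errors import DegenerateInputError, ParameterError
from .materials import Material, get_material
from .spectra import SpectralPair, Spectrum, allocate

__all__ = [
    "LineObject",
    "FisherResult",
    "AllocationCurve",
    "transmission",
    "signal_moments",
    "fisher_matrix",
    "sweep_allocation",
    "thickness_sweep",
    "DEFAULT_R_GRID",
]

#: Dose-allocation sweep grid: 1% to 99% in 1% increments (99 points).
DEFAULT_R_GRID = np.round(np.arange(0.01, 0.995, 0.01), 2)

#: Condition number above which the 2x2 Fisher matrix is treated as singular.
SINGULAR_CONDITION = 1e12


@dataclass(frozen=True)
class LineObject:
    """Mass thicknesses A_j = rho_j * t_j (g/cm^2) of the two basis materials."""

    a_tissue: float
    a_bone: float

    def __post_init__(self) -> None:
        if self.a_tissue < 0 or self.a_bone < 0:
            raise ParameterError("mass thicknesses must be >= 0")

    @classmethod
    def from_thickness(
        cls,
        t_bone_cm: float,
        t_tissue_cm: float = 40.0,
        rho_tissue: float = 1.00,
        rho_bone: float = 1.85,
    ) -> "LineObject":
        """Default object: 40 cm tissue at 1.00 g/cm^3 plus bone at 1.85."""
        return cls(a_tissue=rho_tissue * t_tissue_cm, a_bone=rho_bone * t_bone_cm)

    @property
    def a(self) -> np.ndarray:
        return np.array([self.a_tissue, self.a_bone])


@dataclass(frozen=True)
class FisherResult:
    """Fisher matrix, CRLB variances, and basis SNRs for one spectral pair."""

    fisher: np.ndarray  # 2x2, (g/cm^2)^-2
    crlb: np.ndarray  # 2-vector of variance bounds, (g/cm^2)^2
    snr: np.ndarray  # 2-vector, dimensionless
    means: np.ndarray  # lambda per spectrum
    variances: np.ndarray  # sigma^2 per spectrum
    singular: bool = False


@dataclass(frozen=True)
class AllocationCurve:
    """SNR vs dose allocation r, with grid-argmax peaks per basis material."""

    r_grid: np.ndarray
    snr_tissue: np.ndarray
    snr_bone: np.ndarray
    peak_tissue: tuple[float, float]  # (r_max, snr_max)
    peak_bone: tuple[float, float]


def transmission(
    obj: LineObject,
    tissue: Material,
    bone: Material,
    energies,
) -> np.ndarray:
    """Beer-Lambert transmission through the two-material object."""
    e = np.asarray(energies, dtype=float)
    return np.exp(-(tissue.mu_rho(e) * obj.a_tissue + bone.mu_rho(e) * obj.a_bone))


def _spectrum_terms(
    spectrum: Spectrum,
    obj: LineObject,
    tissue: Material,
    bone: Material,
    detector: Detector,
):
    """Moments and their analytic A-derivatives for one spectrum."""
    if spectrum.total_fluence <= 0:
        raise DegenerateInputError(f"spectrum {spectrum.label!r} has zero fluence")
    e = spectrum.energies
    d = detector.response(e)
    w = d * spectrum.fluence * detector.efficiency(e) * transmission(
        obj, tissue, bone, e
    )
    mu = np.stack([tissue.mu_rho(e), bone.mu_rho(e)])  # (2, nE)
    lam = float(w.sum())
    sig2 = float((d * w).sum())
    dlam = -(mu @ w)  # (2,)
    dsig2 = -(mu @ (d * w))
    return lam, sig2, dlam, dsig2


def signal_moments(
    spectra,
    obj: LineObject,
    tissue: Material,
    bone: Material,
    detector: Detector,
) -> tuple[np.ndarray, np.ndarray]:
    """(lambda_i, sigma2_i) for each allocated spectrum."""
    out = [_spectrum_terms(s, obj, tissue, bone, detector)[:2] for s in spectra]
    lam, sig2 = zip(*out)
    return np.array(lam), np.array(sig2)


def _fisher_from_terms(terms) -> np.ndarray:
    f = np.zeros((2, 2))
    for lam, sig2, dlam, dsig2 in terms:
        f += np.outer(dlam, dlam) / sig2
        f += 0.5 * np.outer(dsig2, dsig2) / sig2**2
    return f


def _invert_fisher(f: np.ndarray) -> tuple[np.ndarray, bool]:
    det = f[0, 0] * f[1, 1] - f[0, 1] * f[1, 0]
    # closed-form 2x2 inverse with an explicit conditioning guard
    norm = np.linalg.norm(f, 2)
    if det <= 0 or norm == 0 or np.linalg.cond(f) > SINGULAR_CONDITION:
        return np.full((2, 2), np.inf), True
    inv = np.array([[f[1, 1], -f[0, 1]], [-f[1, 0], f[0, 0]]]) / det
    return inv, False


def fisher_matrix(
    allocated,
    obj: LineObject,
    tissue: Material | None = None,
    bone: Material | None = None,
    detector: Detector | None = None,
) -> FisherResult:
    """Fisher/CRLB/SNR for a pair of already dose-allocated spectra.

    A singular Fisher matrix (condition number above ``SINGULAR_CONDITION``)
    is reported as unbounded variance with SNR 0 and ``singular=True`` rather
    than raised, so allocation sweeps never abort.
    """
    tissue = tissue or get_material("tissue")
    bone = bone or get_material("bone")
    detector = detector or Detector.default_xenon()
    terms = [_spectrum_terms(s, obj, tissue, bone, detector) for s in allocated]
    f = _fisher_from_terms(terms)
    inv, singular = _invert_fisher(f)
    crlb = np.diag(inv).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(np.isfinite(crlb) & (crlb > 0), obj.a / np.sqrt(crlb), 0.0)
    lam = np.array([t[0] for t in terms])
    sig2 = np.array([t[1] for t in terms])
    return FisherResult(
        fisher=f, crlb=crlb, snr=snr, means=lam, variances=sig2, singular=singular
    )


def sweep_allocation(
    pair: SpectralPair,
    obj: LineObject,
    tissue: Material | None = None,
    bone: Material | None = None,
    detector: Detector | None = None,
    r_grid: np.ndarray | None = None,
) -> AllocationCurve:
    """SNR per basis material over the dose-allocation grid (deterministic).

    Peaks are the grid argmax exactly as swept; ties break toward smaller r.
    """
    tissue = tissue or get_material("tissue")
    bone = bone or get_material("bone")
    detector = detector or Detector.default_xenon()
    r_grid = DEFAULT_R_GRID if r_grid is None else np.asarray(r_grid, dtype=float)
    if np.any(r_grid <= 0) or np.any(r_grid >= 1):
        raise ParameterError("r grid must lie strictly inside (0, 1)")
    # terms for each member at the full total dose; allocation just rescales
    low_full, high_full = allocate(
        SpectralPair(pair.low, pair.high, r=0.5, total_dose_uGy=pair.total_dose_uGy)
    )
    t_low = _spectrum_terms(low_full.scaled(2.0), obj, tissue, bone, detector)
    t_high = _spectrum_terms(high_full.scaled(2.0), obj, tissue, bone, detector)

    snr = np.zeros((r_grid.size, 2))
    for k, r in enumerate(r_grid):
        terms = []
        for t, c in ((t_low, 1.0 - r), (t_high, r)):
            lam, sig2, dlam, dsig2 = t
            terms.append((lam * c, sig2 * c, dlam * c, dsig2 * c))
        f = _fisher_from_terms(terms)
        inv, singular = _invert_fisher(f)
        if singular:
            continue
        crlb = np.diag(inv)
        snr[k] = np.where(crlb > 0, obj.a / np.sqrt(crlb), 0.0)
    it, ib = int(np.argmax(snr[:, 0])), int(np.argmax(snr[:, 1]))
    return AllocationCurve(
        r_grid=r_grid,
        snr_tissue=snr[:, 0],
        snr_bone=snr[:, 1],
        peak_tissue=(float(r_grid[it]), float(snr[it, 0])),
        peak_bone=(float(r_grid[ib]), float(snr[ib, 1])),
    )


def thickness_sweep(
    pair: SpectralPair,
    t_bone_grid=None,
    detector: Detector | None = None,
    t_tissue_cm: float = 40.0,
    tissue: Material | None = None,
    bone: Material | None = None,
    r_grid: np.ndarray | None = None,
) -> dict:
    """Peak SNR (and its r) per basis material over a bone-thickness grid."""
    t_bone_grid = (
        np.arange(1.0, 10.5, 1.0) if t_bone_grid is None else np.asarray(t_bone_grid)
    )
    if np.any(t_bone_grid <= 0):
        raise ParameterError("bone thicknesses must be > 0")
    out = {
        "t_bone_cm": t_bone_grid,
        "peak_snr_tissue": np.zeros(t_bone_grid.size),
        "peak_snr_bone": np.zeros(t_bone_grid.size),
        "r_max_tissue": np.zeros(t_bone_grid.size),
        "r_max_bone": np.zeros(t_bone_grid.size),
    }
    for i, tb in enumerate(t_bone_grid):
        obj = LineObject.from_thickness(t_bone_cm=float(tb), t_tissue_cm=t_tissue_cm)
        curve = sweep_allocation(
            pair, obj, tissue=tissue, bone=bone, detector=detector, r_grid=r_grid
        )
        out["r_max_tissue"][i], out["peak_snr_tissue"][i] = curve.peak_tissue
        out["r_max_bone"][i], out["peak_snr_bone"][i] = curve.peak_bone
    return out
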