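"""Forward model of a cell-covered ECIS electrode.

The model of Lo, Ferrier and Giaever treats the confluent monolayer as a
disc-shaped cell of radius r_c hovering a small distance above the
electrode.  Current that leaves the electrode under a cell either squeezes
radially through the thin cell-substrate channel and out through the
junctions (paracellular path, resistance ``rb``) or crosses the two cell
membranes in series (transcellular path, capacitance ``cm``).  Solving the
radial cable equation gives the specific (per-area) impedance of the
cell-covered electrode in terms of the *measured* cell-free electrode
impedance Z_n and the three constants (alpha, rb, cm)::

    1/Z_c = (1/Z_n) * [ Z_n/(Z_n + Z_m)
                        + (Z_m/(Z_n + Z_m))
                          / ( (γ/2)·I₀(γ)/I₁(γ) + rb·(1/Z_n + 1/Z_m) ) ]

    γ   = alpha · sqrt(1/Z_n + 1/Z_m)        (principal square root)
    Z_m = 1/(jπf·cm)                         (two membranes in series)

where I₀, I₁ are modified Bessel functions of the first kind.  All
impedances in this module are *specific* impedances in Ω·cm² unless a
function says otherwise; ``to_specific``/``from_specific`` convert between
whole-electrode ohms and the per-area scale using the electrode geometry.

Sign convention: time dependence e^{+jωt}, so capacitive impedances have a
negative imaginary part.  The membrane capacitance ``cm`` is the
capacitance of ONE membrane; the two membranes in series give
Z_m = 2/(j·2πf·cm) = 1/(jπf·cm).  This convention is recorded in
:data:`CONVENTIONS` so fitted values remain comparable across tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .errors import InvalidArgumentError

__all__ = [
    "CONVENTIONS",
    "MonolayerParams",
    "ComplexSpectrum",
    "ElectrodeGeometry",
    "membrane_impedance",
    "bessel_ratio",
    "cell_covered_impedance",
    "series_rc_equivalent",
    "to_specific",
    "from_specific",
]

#: Modelling conventions carried into every output's metadata.
CONVENTIONS = {
    "time_convention": "e^{+j omega t}; capacitive Im(Z) < 0",
    "membrane_capacitance": "cm is one membrane; Z_m = 1/(j*pi*f*cm) (two in series)",
    "gamma_branch": "principal square root, Re(gamma) > 0",
    "specific_impedance": "Z_specific = Z_measured_ohm * electrode area (cm^2)",
}


@dataclass(frozen=True)
class MonolayerParams:
    """The three microscopic constants of the cell-covered electrode model.

    Attributes
    ----------
    alpha : float
        Cell-substrate constriction parameter, Ω^0.5·cm.  Microscopically
        alpha = r_c·sqrt(rho/h) for cell radius r_c, medium resistivity rho
        and cell-substrate separation h.
    rb : float
        Barrier resistance, Ω·cm².  Specific resistance of the cell-cell
        junctions to paracellular ion flow; the direct readout of
        junctional permeability.
    cm : float
        Capacitance of one cell membrane per unit area, µF/cm².
    """

    alpha: float
    rb: float
    cm: float

    def __post_init__(self) -> None:
        vals = (self.alpha, self.rb, self.cm)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidArgumentError(f"non-finite monolayer parameters: {vals}")
        if self.alpha < 0 or self.rb < 0:
            raise InvalidArgumentError("alpha and rb must be >= 0")
        if self.cm <= 0:
            raise InvalidArgumentError("cm must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.rb, self.cm], dtype=float)

    @classmethod
    def from_array(cls, a) -> "MonolayerParams":
        return cls(alpha=float(a[0]), rb=float(a[1]), cm=float(a[2]))

    def scaled(self, alpha_factor: float = 1.0, rb_factor: float = 1.0,
               cm_factor: float = 1.0) -> "MonolayerParams":
        return MonolayerParams(self.alpha * alpha_factor, self.rb * rb_factor,
                               self.cm * cm_factor)


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Working-electrode geometry used to convert Ω to Ω·cm².

    The default is an 8W10E-style array: 10 circular electrodes of 250 µm
    diameter per well, total active area 10·π·(0.0125 cm)² ≈ 4.91e-3 cm².
    The array vendor does not publish the exact value, so it is
    configurable.
    """

    area_cm2: float = 10 * np.pi * 0.0125**2
    label: str = "8W10E"

    def __post_init__(self) -> None:
        if not (self.area_cm2 > 0 and np.isfinite(self.area_cm2)):
            raise InvalidArgumentError("electrode area must be positive and finite")


@dataclass
class ComplexSpectrum:
    """One electrode's frequency scan: complex impedance in whole-electrode Ω."""

    electrode_id: str
    role: str  # "cell_covered" or "reference"
    phase_label: str  # e.g. "pre", "post"
    frequencies_hz: np.ndarray
    z_real_ohm: np.ndarray
    z_imag_ohm: np.ndarray

    ROLES = ("cell_covered", "reference")

    def __post_init__(self) -> None:
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.z_real_ohm = np.asarray(self.z_real_ohm, dtype=float)
        self.z_imag_ohm = np.asarray(self.z_imag_ohm, dtype=float)
        if self.role not in self.ROLES:
            raise InvalidArgumentError(f"role must be one of {self.ROLES}, got {self.role!r}")
        n = len(self.frequencies_hz)
        if n < 3:
            raise InvalidArgumentError("a spectrum needs at least 3 frequencies")
        if len(self.z_real_ohm) != n or len(self.z_imag_ohm) != n:
            raise InvalidArgumentError("frequency and impedance sequences must be aligned")
        if not np.all(self.frequencies_hz > 0):
            raise InvalidArgumentError("frequencies must be positive")
        if not np.all(np.diff(self.frequencies_hz) > 0):
            raise InvalidArgumentError("frequencies must be strictly increasing")

    @property
    def z_ohm(self) -> np.ndarray:
        return self.z_real_ohm + 1j * self.z_imag_ohm

    def __len__(self) -> int:
        return len(self.frequencies_hz)

    def subset(self, mask: np.ndarray) -> "ComplexSpectrum":
        return ComplexSpectrum(
            electrode_id=self.electrode_id,
            role=self.role,
            phase_label=self.phase_label,
            frequencies_hz=self.frequencies_hz[mask],
            z_real_ohm=self.z_real_ohm[mask],
            z_imag_ohm=self.z_imag_ohm[mask],
        )


def membrane_impedance(frequency_hz, cm: float):
    """Specific impedance of the two cell membranes in series, Ω·cm².

    Z_m(f) = 1/(j·π·f·C_m) with ``cm`` the single-membrane capacitance in
    µF/cm² (converted to F/cm² internally).  Purely imaginary with
    negative imaginary part under the e^{+jωt} convention.
    """
    f = np.asarray(frequency_hz, dtype=float)
    if np.any(f <= 0) or not np.all(np.isfinite(f)):
        raise InvalidArgumentError("frequency must be positive and finite")
    if not (cm > 0 and np.isfinite(cm)):
        raise InvalidArgumentError("cm must be positive and finite")
    cm_f = cm * 1e-6  # µF/cm² -> F/cm²
    z = 1.0 / (1j * np.pi * f * cm_f)
    return z if z.shape else complex(z)


def bessel_ratio(z):
    """I₀(z)/I₁(z) for complex z with Re(z) ≥ 0, z ≠ 0, evaluated stably.

    Uses the exponentially scaled modified Bessel functions, whose scaling
    factors cancel in the ratio; this stays accurate from |z| ~ 1e-12 up to
    arbitrarily large arguments (where the ratio tends to 1).
    """
    z = np.asarray(z, dtype=complex)
    if np.any(z == 0):
        raise InvalidArgumentError(
            "bessel_ratio is singular at z = 0; use the small-argument limit "
            "(z/2)*I0/I1 -> 1 instead")
    if np.any(z.real < 0):
        raise InvalidArgumentError("bessel_ratio requires Re(z) >= 0")
    r = special.ive(0, z) / special.ive(1, z)
    return r if r.shape else complex(r)


def cell_covered_impedance(frequency_hz, zn, params: MonolayerParams):
    """Specific impedance Z_c (Ω·cm²) of a cell-covered electrode.

    Parameters
    ----------
    frequency_hz : float or array
        Measurement frequency, Hz.
    zn : complex or array
        Specific impedance of the *naked* (cell-free) electrode at the same
        frequencies, Ω·cm².  Used as measured; the model makes no
        assumption about its internal structure.
    params : MonolayerParams
        (alpha, rb, cm).

    With alpha = 0 the constriction term (γ/2)·I₀(γ)/I₁(γ) is replaced by
    its analytic small-argument limit 1, so alpha = rb = 0 returns zn
    exactly and the function is continuous in all parameters.
    """
    f = np.asarray(frequency_hz, dtype=float)
    zn = np.asarray(zn, dtype=complex)
    if np.any(zn == 0):
        raise InvalidArgumentError("naked-electrode impedance must be nonzero")
    zm = np.asarray(membrane_impedance(f, params.cm), dtype=complex)
    s = 1.0 / zn + 1.0 / zm  # admittance sum, Re > 0 in all physical cases
    if params.alpha == 0.0:
        constriction = np.ones_like(s)
    else:
        gamma = params.alpha * np.sqrt(s)
        constriction = (gamma / 2.0) * bessel_ratio(gamma)
    denom = constriction + params.rb * s
    inv_zc = (1.0 / zn) * (zn / (zn + zm) + (zm / (zn + zm)) / denom)
    zc = 1.0 / inv_zc
    return zc if zc.shape else complex(zc)


def series_rc_equivalent(z: complex, frequency_hz: float):
    """Interpret a complex impedance as one resistor and capacitor in series.

    Returns ``(r_series, c_series)`` with r in Ω and c in F.  The
    capacitance is only meaningful for capacitive impedances (Im(z) < 0);
    otherwise c is reported as NaN and the resistance is still returned.
    This is the legacy macroscopic ECIS readout.
    """
    if not (frequency_hz > 0):
        raise InvalidArgumentError("frequency must be positive")
    z = complex(z)
    r = z.real
    if z.imag < 0:
        c = -1.0 / (2.0 * np.pi * frequency_hz * z.imag)
    else:
        c = float("nan")
    return r, c


def to_specific(z_ohm, geometry: ElectrodeGeometry):
    """Whole-electrode Ω → specific Ω·cm² (multiply by active area)."""
    return np.asarray(z_ohm) * geometry.area_cm2


def from_specific(z_specific, geometry: ElectrodeGeometry):
    """Specific Ω·cm² → whole-electrode Ω (divide by active area)."""
    return np.asarray(z_specific) / geometry.area_cm2
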