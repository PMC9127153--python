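"""Pulsatile wall shear stress and flow-regime classification in a rigid tube.

The centerline velocity waveform of one cardiac cycle is decomposed into
Fourier harmonics; each oscillatory harmonic is mapped to its wall shear
contribution through the analytical oscillatory-flow velocity profile
(complex-argument Bessel functions), and the steady component through the
parabolic (Poiseuille) profile.  Shear stress is reported in dyn/cm^2
(1 Pa = 10 dyn/cm^2); everything internal is SI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import jv

__all__ = [
    "VelocityWaveform",
    "VesselGeometry",
    "BloodProperties",
    "HarmonicSpectrum",
    "ShearResult",
    "FlowRegime",
    "FlowClassification",
    "viscosity_from_hematocrit",
    "fourier_decompose",
    "womersley_number",
    "harmonic_wall_shear",
    "ess_waveform",
    "mean_velocity_estimate",
    "reynolds_number",
    "reynolds_from_waveform",
    "classify_flow",
]

PA_TO_DYN_CM2 = 10.0

#: default dynamic viscosity of whole blood when no hematocrit is available (Pa s)
DEFAULT_VISCOSITY = 3.5e-3
#: plasma dynamic viscosity used by the hematocrit -> viscosity relation (Pa s)
PLASMA_VISCOSITY = 1.2e-3
#: default whole-blood density (kg/m^3)
DEFAULT_DENSITY = 1060.0

_MIN_SAMPLES = 32
_JITTER_TOL = 1e-9


def viscosity_from_hematocrit(hematocrit: float | None) -> float:
    """Whole-blood dynamic viscosity (Pa s) from hematocrit fraction.

    Uses a quadratic suspension relation on top of plasma viscosity,
    ``mu = mu_p * (1 + 2.5 h + 7.35 h^2)``.  ``None`` returns the
    documented whole-blood default of 3.5e-3 Pa s.
    """
    if hematocrit is None:
        return DEFAULT_VISCOSITY
    h = float(hematocrit)
    if not 0.0 <= h <= 0.65:
        raise ValueError(f"hematocrit {h!r} outside the supported range [0, 0.65]")
    return PLASMA_VISCOSITY * (1.0 + 2.5 * h + 7.35 * h * h)


@dataclass(frozen=True)
class VelocityWaveform:
    """One cardiac cycle of uniformly sampled centerline velocity.

    Samples cover exactly one period on the half-open grid
    ``t_k = k * T / M`` for ``k = 0 .. M-1``.
    """

    t: np.ndarray
    v: np.ndarray
    period: float

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("t and v must be 1-D arrays of equal length")
        if t.size < _MIN_SAMPLES:
            raise ValueError(f"need at least {_MIN_SAMPLES} samples per cycle, got {t.size}")
        if not self.period > 0:
            raise ValueError("period must be positive")
        dt = np.diff(t)
        dt0 = self.period / t.size
        if np.any(np.abs(dt - dt0) > _JITTER_TOL * dt0):
            raise ValueError("samples are not uniform on the [0, T) grid")
        if abs(t[0]) > _JITTER_TOL * self.period:
            raise ValueError("first sample must sit at t = 0")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def omega(self) -> float:
        """Fundamental angular frequency 2*pi/T (rad/s)."""
        return 2.0 * np.pi / self.period

    @classmethod
    def from_samples(cls, v: np.ndarray, period: float) -> "VelocityWaveform":
        v = np.asarray(v, dtype=float)
        t = np.arange(v.size) * (period / v.size)
        return cls(t=t, v=v, period=float(period))

    def scaled(self, factor: float) -> "VelocityWaveform":
        return VelocityWaveform(t=self.t, v=self.v * factor, period=self.period)


@dataclass(frozen=True)
class VesselGeometry:
    """Lumen geometry of a straight rigid vessel segment."""

    diameter: float

    def __post_init__(self):
        if not self.diameter > 0:
            raise ValueError("diameter must be positive")
        if not 2e-3 <= self.diameter <= 12e-3:
            warnings.warn(
                f"diameter {self.diameter * 1e3:.2f} mm is outside the 2-12 mm "
                "physiological carotid range",
                stacklevel=2,
            )

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class BloodProperties:
    """Density and dynamic viscosity of blood.

    When a hematocrit is supplied the viscosity is derived from it; supplying
    both a hematocrit and an inconsistent explicit viscosity is an error.
    """

    density: float = DEFAULT_DENSITY
    viscosity: float | None = None
    hematocrit: float | None = None

    def __post_init__(self):
        if self.hematocrit is not None:
            mu = viscosity_from_hematocrit(self.hematocrit)
            if self.viscosity is not None and not np.isclose(
                self.viscosity, mu, rtol=1e-9, atol=0.0
            ):
                raise ValueError(
                    "explicit viscosity contradicts the hematocrit-derived value"
                )
            object.__setattr__(self, "viscosity", mu)
        elif self.viscosity is None:
            object.__setattr__(self, "viscosity", DEFAULT_VISCOSITY)
        if not 1000.0 <= self.density <= 1125.0:
            raise ValueError(f"density {self.density} outside [1000, 1125] kg/m^3")
        if not 1e-3 <= self.viscosity <= 1e-2:
            raise ValueError(f"viscosity {self.viscosity} outside [1e-3, 1e-2] Pa s")


@dataclass(frozen=True)
class HarmonicSpectrum:
    """Complex Fourier description of a velocity cycle.

    ``v(t) ~= c0 + sum_n Re(2 * c_n * exp(i n omega t))`` where ``c0`` is the
    (real) cycle mean and ``coefficients[n-1]`` holds ``c_n`` for n >= 1.
    """

    omega: float
    c0: float
    coefficients: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, dtype=complex)
        )
        if self.coefficients.size < 1:
            raise ValueError("a spectrum needs at least one oscillatory harmonic")

    @property
    def n_harmonics(self) -> int:
        return self.coefficients.size

    def reconstruct(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.c0)
        for n, cn in enumerate(self.coefficients, start=1):
            out = out + np.real(2.0 * cn * np.exp(1j * n * self.omega * t))
        return out


def fourier_decompose(waveform: VelocityWaveform, n_harmonics: int) -> HarmonicSpectrum:
    """Discrete Fourier coefficients of the sampled cycle.

    ``c_n = (1/M) sum_k v_k exp(-i n omega t_k)``; ``c0`` equals the sample
    mean.  ``n_harmonics`` may not exceed ``floor(M/2) - 1``.
    """
    m = waveform.n_samples
    if not 1 <= n_harmonics <= m // 2 - 1:
        raise ValueError(
            f"n_harmonics must be in [1, {m // 2 - 1}] for {m} samples, got {n_harmonics}"
        )
    coeffs = np.fft.fft(waveform.v) / m
    return HarmonicSpectrum(
        omega=waveform.omega,
        c0=float(coeffs[0].real),
        coefficients=coeffs[1 : n_harmonics + 1],
    )


def womersley_number(radius: float, omega: float, density: float, viscosity: float) -> float:
    """alpha = R * sqrt(omega * rho / mu); zero frequency gives alpha = 0."""
    if radius <= 0 or density <= 0 or viscosity <= 0 or omega < 0:
        raise ValueError("radius, density, viscosity must be > 0 and omega >= 0")
    return radius * np.sqrt(omega * density / viscosity)


def harmonic_wall_shear(
    c_n: complex, alpha_n: float, radius: float, viscosity: float
) -> complex:
    """Wall shear stress phasor (Pa) for one oscillatory velocity harmonic.

    The oscillatory profile with centerline amplitude ``c_n`` is
    ``u(r) = A (1 - J0(L r / R) / J0(L))`` with ``L = i^{3/2} alpha_n`` and
    ``A = c_n J0(L) / (J0(L) - 1)``; the shear exerted on the wall is
    ``tau_n = -mu du/dr|_{r=R} = -mu c_n L J1(L) / (R (J0(L) - 1))``.

    The sign convention matches the steady Poiseuille term (forward flow
    exerts positive shear), and for ``alpha_n -> 0`` the result collapses to
    the quasi-steady ``2 mu c_n / R``.
    """
    if alpha_n <= 0:
        raise ValueError("alpha_n must be positive for an oscillatory harmonic")
    if radius <= 0 or viscosity <= 0:
        raise ValueError("radius and viscosity must be positive")
    lam = (1j) ** 1.5 * alpha_n
    denom = jv(0, lam) - 1.0
    if abs(denom) < 1e-14:
        raise ArithmeticError(
            f"degenerate Bessel denominator |J0(L) - 1| = {abs(denom):.3e}"
        )
    return -viscosity * c_n * lam * jv(1, lam) / (radius * denom)


@dataclass(frozen=True)
class ShearResult:
    """Wall shear stress over one cycle, in dyn/cm^2."""

    tau: np.ndarray  # time series on the waveform grid
    mean_ess: float  # cycle-time average
    peak_ess: float  # cycle maximum
    alphas: np.ndarray = field(repr=False)  # per-harmonic Womersley numbers

    @property
    def n_harmonics(self) -> int:
        return self.alphas.size


def ess_waveform(
    waveform: VelocityWaveform,
    geometry: VesselGeometry,
    blood: BloodProperties,
    n_harmonics: int = 8,
) -> ShearResult:
    """Endothelial shear stress time series from a centerline velocity cycle.

    The steady component uses the Poiseuille relation ``tau_0 = 2 mu c0 / R``
    (centerline velocity); oscillatory harmonics use the analytical
    oscillatory-flow transfer of :func:`harmonic_wall_shear`.  Output is
    converted to dyn/cm^2.
    """
    spectrum = fourier_decompose(waveform, n_harmonics)
    r = geometry.radius
    mu = blood.viscosity
    tau = np.full(waveform.n_samples, 2.0 * mu * spectrum.c0 / r)
    alphas = np.empty(n_harmonics)
    for n in range(1, n_harmonics + 1):
        alphas[n - 1] = womersley_number(r, n * spectrum.omega, blood.density, mu)
        tau_n = harmonic_wall_shear(spectrum.coefficients[n - 1], alphas[n - 1], r, mu)
        tau = tau + np.real(2.0 * tau_n * np.exp(1j * n * spectrum.omega * waveform.t))
    tau = tau * PA_TO_DYN_CM2
    return ShearResult(
        tau=tau,
        mean_ess=float(tau.mean()),
        peak_ess=float(tau.max()),
        alphas=alphas,
    )


def mean_velocity_estimate(waveform: VelocityWaveform) -> float:
    """Cycle-averaged spatial-mean velocity estimate from centerline samples.

    Assumes a near-parabolic profile, so the cross-sectional mean is half the
    centerline speed: ``V = mean(|v|) / 2``.
    """
    return float(np.mean(np.abs(waveform.v)) / 2.0)


def reynolds_number(v_mean: float, diameter: float, density: float, viscosity: float) -> float:
    """Re = rho * V * D / mu for the cycle-averaged spatial-mean velocity."""
    if diameter <= 0 or density <= 0 or viscosity <= 0:
        raise ValueError("diameter, density and viscosity must be positive")
    if v_mean < 0:
        raise ValueError("v_mean must be non-negative")
    return density * v_mean * diameter / viscosity


def reynolds_from_waveform(
    waveform: VelocityWaveform, geometry: VesselGeometry, blood: BloodProperties
) -> float:
    return reynolds_number(
        mean_velocity_estimate(waveform), geometry.diameter, blood.density, blood.viscosity
    )


class FlowRegime:
    UNDISTURBED_LAMINAR = "undisturbed_laminar"
    DISTURBED = "disturbed"
    INDETERMINATE = "indeterminate"
    TURBULENT = "turbulent"

    ORDER = (UNDISTURBED_LAMINAR, DISTURBED, INDETERMINATE, TURBULENT)


@dataclass(frozen=True)
class FlowClassification:
    reynolds: float
    regime: str


def classify_flow(reynolds: float) -> FlowClassification:
    """Flow regime from the Reynolds number.

    Thresholds: Re < 200 undisturbed laminar, 200 <= Re <= 1800 disturbed,
    Re > 2000 turbulent.  The 1800-2000 band is not covered by those ranges
    and is labelled ``indeterminate`` rather than silently merged.
    """
    if reynolds < 0:
        raise ValueError("Reynolds number must be non-negative")
    if reynolds < 200.0:
        regime = FlowRegime.UNDISTURBED_LAMINAR
    elif reynolds <= 1800.0:
        regime = FlowRegime.DISTURBED
    elif reynolds <= 2000.0:
        regime = FlowRegime.INDETERMINATE
    else:
        regime = FlowRegime.TURBULENT
    return FlowClassification(reynolds=float(reynolds), regime=regime)
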