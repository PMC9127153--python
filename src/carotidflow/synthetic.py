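"""Seeded generator of participant-structured synthetic carotid velocity data.

Each synthetic record is a carotid-like centerline velocity cycle scaled so
that the downstream shear pipeline reproduces a drawn per-record target ESS;
targets are drawn around per-condition calibration means with a participant
random intercept controlling the between/within variance split (ICC).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import truncnorm

from .hemodynamics import (
    BloodProperties,
    VelocityWaveform,
    VesselGeometry,
    ess_waveform,
)

__all__ = [
    "StudyDesign",
    "ConditionTarget",
    "ConditionCalibration",
    "SyntheticRecord",
    "canonical_waveform",
    "calibrate_scale",
    "generate_study",
    "default_calibration",
    "DEFAULT_HEART_RATES",
]

EXERCISE_MODALITIES = (
    "Treadmill",
    "Cycle-ergometer",
    "Arm-ergometer",
    "Squat",
    "Bench",
    "Biceps",
)
INTENSITIES = ("low", "moderate", "high")
BASELINES = ("Baseline", "Baseline2")
REST = "rest"

# Fixed 8-harmonic recipe for the unit-mean carotid-like cycle: sharp systolic
# peak near 0.16 T, dicrotic bump near 0.5 T, strictly positive throughout.
_PULSE_AMPLITUDES = (
    0.634061, 0.485798, 0.458208, 0.232941,
    0.116362, 0.059326, 0.022549, 0.007631,
)
_PULSE_PHASES = (
    -1.268511, -1.807121, -2.977856, 2.133403,
    1.309080, 0.273984, -0.780128, -1.754541,
)

#: heart rate schedule (bpm) per intensity level
DEFAULT_HEART_RATES = {REST: 65.0, "low": 100.0, "moderate": 140.0, "high": 175.0}

# Condition-level ESS calibration targets, dyn/cm^2 (mean, SD).
DEFAULT_ESS_TARGETS = {
    ("Baseline", REST): (23.8, 4.8),
    ("Baseline2", REST): (26.5, 3.3),
    ("Arm-ergometer", "low"): (39.4, 10.7),
    ("Arm-ergometer", "moderate"): (47.8, 12.1),
    ("Arm-ergometer", "high"): (57.8, 20.7),
    ("Cycle-ergometer", "low"): (48.0, 10.8),
    ("Cycle-ergometer", "moderate"): (62.6, 19.4),
    ("Cycle-ergometer", "high"): (77.5, 20.3),
    ("Treadmill", "low"): (47.5, 13.1),
    ("Treadmill", "moderate"): (67.3, 17.9),
    ("Treadmill", "high"): (84.7, 9.7),
    ("Bench", "low"): (34.8, 13.0),
    ("Bench", "moderate"): (42.1, 12.0),
    ("Bench", "high"): (45.6, 13.7),
    ("Biceps", "low"): (37.3, 13.3),
    ("Biceps", "moderate"): (41.3, 12.8),
    ("Biceps", "high"): (50.7, 14.7),
    ("Squat", "low"): (44.1, 14.4),
    ("Squat", "moderate"): (48.8, 16.4),
    ("Squat", "high"): (56.8, 13.57),
}

# Geometry/blood defaults.  The exercise-condition lumen diameter and the low
# hematocrit are calibration knobs chosen so that, jointly with the ESS
# targets above, every exercise condition lands above the Re = 2000
# turbulence threshold while both baselines stay below it.
_BASELINE_DIAMETER = (6.3e-3, 0.3e-3)
_EXERCISE_DIAMETER = (7.6e-3, 0.25e-3)
_HEMATOCRIT = (0.32, 0.02)


@dataclass(frozen=True)
class StudyDesign:
    """Complete crossing of exercise modality x intensity plus two baselines."""

    n_participants: int = 14
    modalities: tuple[str, ...] = EXERCISE_MODALITIES
    intensities: tuple[str, ...] = INTENSITIES
    baselines: tuple[str, ...] = BASELINES

    def conditions(self) -> list[tuple[str, str]]:
        """Condition list in the fixed generation order."""
        out = [(b, REST) for b in self.baselines]
        out.extend((m, i) for m in self.modalities for i in self.intensities)
        return out

    def sexes(self) -> list[str]:
        half = self.n_participants // 2
        return ["M"] * half + ["F"] * (self.n_participants - half)


@dataclass(frozen=True)
class ConditionTarget:
    """Calibration targets for one (modality, intensity) cell."""

    ess_mean: float
    ess_sd: float
    heart_rate: float
    diameter_mean: float
    diameter_sd: float
    hematocrit_mean: float
    hematocrit_sd: float

    def __post_init__(self):
        if self.ess_mean <= 0:
            raise ValueError("ESS target mean must be positive")
        if not 0 <= self.ess_sd < self.ess_mean:
            raise ValueError("ESS target SD must satisfy 0 <= SD < mean")


@dataclass(frozen=True)
class ConditionCalibration:
    """Per-condition calibration table keyed by (modality, intensity)."""

    targets: dict[tuple[str, str], ConditionTarget] = field(default_factory=dict)

    def __getitem__(self, key: tuple[str, str]) -> ConditionTarget:
        return self.targets[key]

    def with_ess(self, key: tuple[str, str], mean: float, sd: float) -> "ConditionCalibration":
        new = dict(self.targets)
        new[key] = replace(new[key], ess_mean=mean, ess_sd=sd)
        return ConditionCalibration(new)

    def with_uniform_ess(self, mean: float, sd: float) -> "ConditionCalibration":
        """All conditions set to the same ESS mean/SD (null calibration)."""
        return ConditionCalibration(
            {k: replace(t, ess_mean=mean, ess_sd=sd) for k, t in self.targets.items()}
        )


def default_calibration(
    ess_targets: dict[tuple[str, str], tuple[float, float]] | None = None,
    heart_rates: dict[str, float] | None = None,
) -> ConditionCalibration:
    ess_targets = dict(DEFAULT_ESS_TARGETS if ess_targets is None else ess_targets)
    hr = dict(DEFAULT_HEART_RATES)
    if heart_rates:
        hr.update(heart_rates)
    targets = {}
    for (modality, intensity), (mean, sd) in ess_targets.items():
        d_mean, d_sd = _BASELINE_DIAMETER if intensity == REST else _EXERCISE_DIAMETER
        targets[(modality, intensity)] = ConditionTarget(
            ess_mean=mean,
            ess_sd=sd,
            heart_rate=hr[intensity],
            diameter_mean=d_mean,
            diameter_sd=d_sd,
            hematocrit_mean=_HEMATOCRIT[0],
            hematocrit_sd=_HEMATOCRIT[1],
        )
    return ConditionCalibration(targets)


@dataclass(frozen=True)
class SyntheticRecord:
    participant_id: str
    sex: str
    modality: str
    intensity: str
    waveform: VelocityWaveform | None
    diameter: float
    hematocrit: float
    true_ess: float  # dyn/cm^2, by construction the pipeline's mean ESS


def canonical_waveform(heart_rate: float, samples: int = 128) -> VelocityWaveform:
    """Deterministic unit-scale carotid-like velocity cycle.

    The shape is a fixed 8-harmonic recipe with cycle mean 1 m/s, a systolic
    peak and a dicrotic bump, and no retrograde flow.
    """
    if not 30.0 <= heart_rate <= 220.0:
        raise ValueError(f"heart rate {heart_rate} bpm outside [30, 220]")
    if samples < 64:
        raise ValueError(f"need at least 64 samples, got {samples}")
    period = 60.0 / heart_rate
    s = np.arange(samples) / samples
    v = np.ones(samples)
    for n, (amp, phase) in enumerate(zip(_PULSE_AMPLITUDES, _PULSE_PHASES), start=1):
        v += amp * np.cos(2.0 * np.pi * n * s + phase)
    return VelocityWaveform.from_samples(v, period)


def calibrate_scale(
    target_ess: float,
    base: VelocityWaveform,
    geometry: VesselGeometry,
    blood: BloodProperties,
    n_harmonics: int = 8,
) -> float:
    """Velocity scale factor mapping ``base`` onto a target mean ESS.

    Exact by linearity of the shear pipeline in the velocity amplitude.
    """
    if target_ess <= 0:
        raise ValueError("target ESS must be positive")
    base_ess = ess_waveform(base, geometry, blood, n_harmonics).mean_ess
    if base_ess <= 0:
        raise ValueError("base waveform has non-positive mean ESS")
    return target_ess / base_ess


def _draw_truncnorm(rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
    """Standard normal truncated at +/- 3 SD."""
    return truncnorm.rvs(-3.0, 3.0, size=size, random_state=rng)


def generate_study(
    design: StudyDesign | None = None,
    calibration: ConditionCalibration | None = None,
    icc: float = 0.5,
    seed: int = 0,
    samples: int = 128,
    n_harmonics: int = 8,
    build_waveforms: bool = True,
) -> list[SyntheticRecord]:
    """Generate one synthetic repeated-measures study.

    Per condition, a participant's ESS target is
    ``mean + sd * (sqrt(icc) * z_i + sqrt(1 - icc) * e_ic)`` with ``z_i`` a
    participant-level standard-normal intercept shared across conditions and
    ``e_ic`` an independent residual; both are truncated at +/- 3 SD and the
    combined deviation is clipped to the same band so targets stay positive.
    All randomness derives from a single seed via per-participant substreams.

    ``build_waveforms=False`` skips the waveform construction (records carry
    ``waveform=None``) without touching the random stream; useful for
    statistics-only Monte-Carlo runs on the generating-truth ESS.
    """
    if design is None:
        design = StudyDesign()
    if calibration is None:
        calibration = default_calibration()
    if not 0.0 <= icc < 1.0:
        raise ValueError("icc must lie in [0, 1)")

    conditions = design.conditions()
    sexes = design.sexes()
    streams = np.random.SeedSequence(seed).spawn(design.n_participants)
    width = len(str(design.n_participants))
    records: list[SyntheticRecord] = []
    n_cond = len(conditions)
    for idx in range(design.n_participants):
        rng = np.random.default_rng(streams[idx])
        pid = f"P{idx + 1:0{width}d}"
        z_i = float(_draw_truncnorm(rng))
        e_draws = np.atleast_1d(_draw_truncnorm(rng, n_cond))
        d_draws = np.atleast_1d(_draw_truncnorm(rng, n_cond))
        h_draws = np.atleast_1d(_draw_truncnorm(rng, n_cond))
        for c, (modality, intensity) in enumerate(conditions):
            target = calibration[(modality, intensity)]
            u = np.sqrt(icc) * z_i + np.sqrt(1.0 - icc) * e_draws[c]
            u = float(np.clip(u, -3.0, 3.0))
            # +/-3 SD truncation alone cannot keep every target positive when
            # 3 SD exceeds the condition mean; floor at 5% of the mean.
            ess_target = max(
                target.ess_mean + target.ess_sd * u, 0.05 * target.ess_mean
            )
            diameter = target.diameter_mean + target.diameter_sd * d_draws[c]
            hematocrit = target.hematocrit_mean + target.hematocrit_sd * h_draws[c]
            waveform = None
            if build_waveforms:
                geometry = VesselGeometry(diameter)
                blood = BloodProperties(hematocrit=hematocrit)
                base = canonical_waveform(target.heart_rate, samples)
                scale = calibrate_scale(ess_target, base, geometry, blood, n_harmonics)
                waveform = base.scaled(scale)
            records.append(
                SyntheticRecord(
                    participant_id=pid,
                    sex=sexes[idx],
                    modality=modality,
                    intensity=intensity,
                    waveform=waveform,
                    diameter=diameter,
                    hematocrit=hematocrit,
                    true_ess=ess_target,
                )
            )
    return records
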