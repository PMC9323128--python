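"""Parametric simulator of HRM pressure fields and pressure-topography images.

The clinical images this package classifies come from a 36-sensor solid-state
catheter; no patient data ship with the package, so this module generates
labeled stand-ins.  The generative model is deliberately minimal — a traveling
Gaussian pressure ridge over a 36 x 600 grid (60 s at 10 Hz) plus a lower
esophageal sphincter (LES) band that either relaxes after the swallow or does
not — because the only requirement is that each of the seven swallow
appearances is realized with a verifiable ground-truth label:

* NORMAL      — contiguous ridge traveling proximal -> distal, normal vigor;
* PANESOPHAGEAL — simultaneous pressurization of the whole esophageal body;
* PREMATURE   — ridge reaching the distal esophagus in under 4.5 s;
* WEAK        — faint ridge, distal contractile integral (DCI) < 450;
* FRAGMENTED  — ridge with a >= 5 cm break, vigor otherwise preserved;
* DCI_GT_8000 — hypercontractile ridge, DCI > 8000 mmHg·cm·s;
* FAILED      — esophageal body stays at baseline.

Ground-truth IRP and DCI labels are *measured from the simulated field* with
:func:`compute_irp` / :func:`compute_dci`, never asserted from the generator's
parameters, so label fidelity is checked at generation time.

Rendering maps pressure through a fixed monotone blue->green->yellow->red
palette whose every color is darker than gray level 128; only the swallow
onset marker is pure white, so binarizing at 128 isolates the marker column
exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import chicago_rules
from .preprocess import HRMImage
from .types import (
    Diagnosis,
    HIGH_IRP_DIAGNOSES,
    IRP_CUTOFF_MMHG,
    DCI_ISOBAR_MMHG,
    IRPClass,
    SwallowPattern,
)

__all__ = [
    "PressureField",
    "SimParams",
    "GroundTruth",
    "SwallowSample",
    "StudyBatch",
    "simulate_pressure_field",
    "compute_dci",
    "compute_irp",
    "render_hrm_image",
    "generate_swallow",
    "generate_study",
    "save_study",
    "MANIFEST_COLUMNS",
]

# --- catheter geometry ------------------------------------------------------
# sensor 0 is the most proximal (upper esophageal sphincter); sensor 35 the
# most distal (stomach side).  1 cm spacing.
N_SENSORS = 36
UES_SENSORS = (0, 1)
BODY_SENSORS = (2, 30)  # inclusive range of esophageal-body sensors
LES_SENSORS = (31, 35)  # inclusive range: LES / esophago-gastric junction
DISTAL_SENSORS = (17, 30)  # inclusive: distal segment integrated by the DCI


@dataclass(frozen=True)
class PressureField:
    """Simulated pressure matrix in mmHg, indexed [sensor, time sample]."""

    values: np.ndarray
    n_sensors: int = N_SENSORS
    duration_s: float = 60.0
    sample_rate_hz: float = 10.0
    swallow_onset_s: float = 30.0
    sensor_spacing_cm: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        expected = (self.n_sensors, round(self.duration_s * self.sample_rate_hz))
        if v.shape != expected:
            raise ValueError(f"values shape {v.shape} != {expected}")
        if not np.isfinite(v).all():
            raise ValueError("pressures must be finite")
        if (v < 0).any():
            raise ValueError("pressures must be >= 0 mmHg")
        if not 0 <= self.swallow_onset_s < self.duration_s:
            raise ValueError(
                f"swallow onset {self.swallow_onset_s} s outside [0, {self.duration_s})"
            )
        object.__setattr__(self, "values", v)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz


@dataclass(frozen=True)
class SimParams:
    """Knobs of the generative model.  All pressures in mmHg, times in s.

    ``wave_velocity_cm_per_s`` is redundant with ``distal_latency_s`` (the
    ridge travels the esophageal body at constant speed); when it is given it
    overrides the latency.
    """

    wave_amplitude_mmHg: float = 80.0
    wave_velocity_cm_per_s: float | None = None
    distal_latency_s: float = 7.0
    wave_width_s: float = 1.0
    break_length_cm: float = 5.0
    les_resting_mmHg: float = 40.0
    les_relaxed_mmHg: float = 8.0
    relaxation_duration_s: float = 12.0
    pressurization_mmHg: float = 35.0
    pressurization_duration_s: float = 8.0
    baseline_mmHg: float = 2.0
    ues_mmHg: float = 25.0
    noise_sd_mmHg: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distal_latency_s <= 0:
            raise ValueError("distal_latency_s must be > 0")
        for name in (
            "wave_amplitude_mmHg",
            "wave_width_s",
            "break_length_cm",
            "les_resting_mmHg",
            "les_relaxed_mmHg",
            "relaxation_duration_s",
            "pressurization_mmHg",
            "pressurization_duration_s",
            "baseline_mmHg",
            "ues_mmHg",
            "noise_sd_mmHg",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.wave_velocity_cm_per_s is not None and self.wave_velocity_cm_per_s <= 0:
            raise ValueError("wave_velocity_cm_per_s must be > 0 when given")

    @classmethod
    def defaults_for(cls, pattern: SwallowPattern, **overrides) -> "SimParams":
        """Default parameters that realize ``pattern``'s appearance.

        WEAK swallows use a faint ridge (DCI well under 450), DCI_GT_8000 a
        broad hypercontractile one (DCI well over 8000), PREMATURE a 3 s
        distal latency (under the 4.5 s bound), FAILED no ridge at all.
        """
        adjust: dict = {
            SwallowPattern.WEAK: {"wave_amplitude_mmHg": 35.0},
            SwallowPattern.DCI_GT_8000: {
                "wave_amplitude_mmHg": 220.0,
                "wave_width_s": 2.0,
            },
            SwallowPattern.PREMATURE: {"distal_latency_s": 3.0},
            SwallowPattern.FAILED: {"wave_amplitude_mmHg": 0.0},
        }.get(pattern, {})
        adjust.update(overrides)
        return cls(**adjust)

    def effective_distal_latency_s(self, body_length_cm: float) -> float:
        if self.wave_velocity_cm_per_s is not None:
            return body_length_cm / self.wave_velocity_cm_per_s
        return self.distal_latency_s

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimParams":
        return cls(**data)


@dataclass(frozen=True)
class GroundTruth:
    """Measured labels of one simulated swallow."""

    pattern: SwallowPattern
    irp_mmHg: float
    irp_class: IRPClass
    dci: float  # mmHg·cm·s

    def __post_init__(self) -> None:
        expected = IRPClass.HIGH if self.irp_mmHg > IRP_CUTOFF_MMHG else IRPClass.NORMAL
        if self.irp_class is not expected:
            raise ValueError(
                f"irp_class {self.irp_class} inconsistent with IRP "
                f"{self.irp_mmHg:.1f} mmHg (cutoff {IRP_CUTOFF_MMHG})"
            )


@dataclass(frozen=True)
class SwallowSample:
    image: HRMImage | None
    truth: GroundTruth
    field: PressureField


@dataclass(frozen=True)
class StudyBatch:
    """Ten simulated swallows whose ground-truth labels yield one diagnosis."""

    swallows: tuple[SwallowSample, ...]
    intended_diagnosis: Diagnosis

    @property
    def irp_classes(self) -> list[IRPClass]:
        return [s.truth.irp_class for s in self.swallows]

    @property
    def patterns(self) -> list[SwallowPattern]:
        return [s.truth.pattern for s in self.swallows]


def simulate_pressure_field(
    pattern: SwallowPattern,
    params: SimParams | None = None,
    *,
    n_sensors: int = N_SENSORS,
    duration_s: float = 60.0,
    sample_rate_hz: float = 10.0,
    swallow_onset_s: float = 30.0,
    sensor_spacing_cm: float = 1.0,
) -> PressureField:
    """Simulate one swallow's pressure field realizing ``pattern``.

    With ``params=None`` the pattern-appropriate defaults from
    :meth:`SimParams.defaults_for` are used; an explicit ``params`` is taken
    as-is (the caller is then responsible for the appearance).
    """
    if not isinstance(pattern, SwallowPattern):
        raise ValueError(f"unknown swallow pattern {pattern!r}")
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be positive")
    if params is None:
        params = SimParams.defaults_for(pattern)

    n_samples = round(duration_s * sample_rate_hz)
    t = np.arange(n_samples) / sample_rate_hz
    p = np.full((n_sensors, n_samples), params.baseline_mmHg)

    body_lo, body_hi = BODY_SENSORS
    n_body = body_hi - body_lo + 1
    body_length_cm = (n_body - 1) * sensor_spacing_cm

    if pattern is SwallowPattern.PANESOPHAGEAL:
        # simultaneous isobaric pressurization of the whole body
        band = (t >= swallow_onset_s) & (
            t < swallow_onset_s + params.pressurization_duration_s
        )
        p[body_lo : body_hi + 1, band] += params.pressurization_mmHg
    elif pattern is not SwallowPattern.FAILED and params.wave_amplitude_mmHg > 0:
        latency = params.effective_distal_latency_s(body_length_cm)
        amp = np.full(n_body, params.wave_amplitude_mmHg)
        if pattern is SwallowPattern.FRAGMENTED:
            n_gap = max(round(params.break_length_cm / sensor_spacing_cm), 1)
            gap_center = 16 - body_lo  # mid-body, proximal edge of distal segment
            g0 = max(gap_center - n_gap // 2, 0)
            amp[g0 : g0 + n_gap] = 0.0
        frac = np.arange(n_body) / (n_body - 1)
        arrival = swallow_onset_s + latency * frac
        p[body_lo : body_hi + 1, :] += amp[:, None] * np.exp(
            -((t[None, :] - arrival[:, None]) ** 2) / (2 * params.wave_width_s**2)
        )

    # upper esophageal sphincter: constant tone
    p[UES_SENSORS[0] : UES_SENSORS[1] + 1, :] = params.ues_mmHg

    # LES band: resting tone, deglutitive window at the relaxed (or not) level
    les_lo, les_hi = LES_SENSORS
    p[les_lo : les_hi + 1, :] = params.les_resting_mmHg
    relax = (t >= swallow_onset_s) & (
        t < swallow_onset_s + params.relaxation_duration_s
    )
    p[les_lo : les_hi + 1, relax] = params.les_relaxed_mmHg

    if params.noise_sd_mmHg > 0:
        rng = np.random.default_rng(params.seed)
        p = p + rng.normal(0.0, params.noise_sd_mmHg, size=p.shape)
    return PressureField(
        np.clip(p, 0.0, None),
        n_sensors=n_sensors,
        duration_s=duration_s,
        sample_rate_hz=sample_rate_hz,
        swallow_onset_s=swallow_onset_s,
        sensor_spacing_cm=sensor_spacing_cm,
    )


def compute_dci(
    field: PressureField,
    distal_from_sensor: int = DISTAL_SENSORS[0],
    distal_to_sensor: int = DISTAL_SENSORS[1],
) -> float:
    """Distal contractile integral, mmHg·cm·s.

    Integral over the distal segment and the post-onset window of the
    pressure in excess of the 20 mmHg isobar:
    ``sum(max(p - 20, 0)) * sensor_spacing_cm * dt``.
    """
    if distal_from_sensor > distal_to_sensor:
        raise ValueError("empty distal segment")
    if distal_from_sensor < 0 or distal_to_sensor >= field.n_sensors:
        raise ValueError("distal segment outside the sensor array")
    onset_idx = round(field.swallow_onset_s * field.sample_rate_hz)
    seg = field.values[distal_from_sensor : distal_to_sensor + 1, onset_idx:]
    excess = np.clip(seg - DCI_ISOBAR_MMHG, 0.0, None)
    dt = 1.0 / field.sample_rate_hz
    return float(excess.sum() * field.sensor_spacing_cm * dt)


def compute_irp(field: PressureField, window_s: float = 10.0) -> float:
    """Integrated relaxation pressure, mmHg.

    Mean of the lowest 4 s of the LES-band aggregate (mean over the LES
    sensors) within the ``window_s`` post-onset window; the low samples need
    not be contiguous.
    """
    if field.swallow_onset_s + window_s > field.duration_s:
        raise ValueError(
            f"IRP window of {window_s} s after onset {field.swallow_onset_s} s "
            f"extends past the {field.duration_s} s field"
        )
    les_lo, les_hi = LES_SENSORS
    signal = field.values[les_lo : les_hi + 1, :].mean(axis=0)
    onset_idx = round(field.swallow_onset_s * field.sample_rate_hz)
    n_window = round(window_s * field.sample_rate_hz)
    window = signal[onset_idx : onset_idx + n_window]
    n_low = min(round(4.0 * field.sample_rate_hz), len(window))
    lowest = np.sort(window)[:n_low]
    return float(lowest.mean())


# --- rendering --------------------------------------------------------------

#: Pressure->color stops, mmHg -> RGB.  Every color has grayscale mean < 128,
#: so only the pure-white onset marker survives binarization at 128.
DEFAULT_PALETTE: tuple[tuple[float, tuple[int, int, int]], ...] = (
    (0.0, (0, 0, 120)),
    (30.0, (0, 120, 120)),
    (60.0, (0, 140, 0)),
    (100.0, (170, 150, 0)),
    (150.0, (180, 0, 0)),
)


def render_hrm_image(
    field: PressureField,
    width_px: int = 600,
    height_px: int = 360,
    palette: Sequence[tuple[float, tuple[int, int, int]]] = DEFAULT_PALETTE,
    *,
    marker_thickness_px: int = 2,
) -> HRMImage:
    """Render a pressure field to an RGB pressure-topography image.

    Proximal sensors at the top, LES/stomach at the bottom, time left to
    right; a pure-white full-height column of ``marker_thickness_px`` marks
    the swallow onset.
    """
    if width_px < 1 or height_px < 1:
        raise ValueError("image dimensions must be positive")
    marker_x = round(field.swallow_onset_s / field.duration_s * width_px)
    if marker_x < 0 or marker_x + marker_thickness_px > width_px:
        raise ValueError(
            f"marker column [{marker_x}, {marker_x + marker_thickness_px}) "
            f"outside image of width {width_px}"
        )
    stops = np.array([s[0] for s in palette])
    colors = np.array([s[1] for s in palette], dtype=np.float64)
    flat = np.clip(field.values, stops[0], stops[-1]).ravel()
    rgb = np.stack(
        [np.interp(flat, stops, colors[:, c]) for c in range(3)], axis=-1
    ).reshape(field.values.shape + (3,))
    # nearest-neighbour upscale to the pixel grid
    rows = (np.arange(height_px) * field.n_sensors) // height_px
    cols = (np.arange(width_px) * field.n_samples) // width_px
    pixels = rgb[np.ix_(rows, cols)].round().astype(np.uint8)
    pixels[:, marker_x : marker_x + marker_thickness_px, :] = 255
    return HRMImage(pixels, seconds_per_pixel=field.duration_s / width_px)


# --- labeled swallow and study generation -----------------------------------


def generate_swallow(
    pattern: SwallowPattern,
    irp_class: IRPClass,
    seed: int,
    *,
    render: bool = True,
    width_px: int = 600,
    height_px: int = 360,
    params: SimParams | None = None,
) -> SwallowSample:
    """One labeled swallow with the requested pattern and IRP class.

    The IRP class is realized through the LES relaxation level (a normal
    swallow relaxes to single digits, a high-IRP one stays in the 30s); the
    stored labels are re-measured from the simulated field.
    """
    rng = np.random.default_rng(seed)
    base = params if params is not None else SimParams.defaults_for(pattern)
    if irp_class is IRPClass.HIGH:
        relaxed = rng.uniform(32.0, 45.0)
    else:
        relaxed = rng.uniform(4.0, 12.0)
    sim = replace(
        base,
        les_resting_mmHg=rng.uniform(35.0, 45.0),
        les_relaxed_mmHg=relaxed,
        seed=int(rng.integers(2**31)),
    )
    onset = float(rng.uniform(26.0, 34.0))
    field = simulate_pressure_field(pattern, sim, swallow_onset_s=onset)
    truth = GroundTruth(
        pattern=pattern,
        irp_mmHg=compute_irp(field),
        irp_class=irp_class,
        dci=compute_dci(field),
    )
    image = render_hrm_image(field, width_px, height_px) if render else None
    return SwallowSample(image=image, truth=truth, field=field)


def _compose_patterns(
    diagnosis: Diagnosis, n: int, rng: np.random.Generator
) -> list[SwallowPattern]:
    """Sample a per-swallow pattern list that the decision tree maps back to
    ``diagnosis`` (inverse construction against the literal rule order)."""
    P = SwallowPattern

    def fill(counts: dict[SwallowPattern, int], filler: SwallowPattern):
        used = sum(counts.values())
        if used > n:
            raise ValueError(
                f"cannot realize {diagnosis} with {n} swallows (needs {used})"
            )
        labels = [pat for pat, c in counts.items() for _ in range(c)]
        labels += [filler] * (n - used)
        return labels

    ri = rng.integers
    if diagnosis is Diagnosis.ACHALASIA_TYPE_I:
        return fill({}, P.FAILED)
    if diagnosis is Diagnosis.ACHALASIA_TYPE_II:
        return fill({P.PANESOPHAGEAL: int(ri(2, min(6, n) + 1))}, P.FAILED)
    if diagnosis is Diagnosis.ACHALASIA_TYPE_III:
        # exactly one panesophageal swallow escapes the type I rule while
        # staying under the type II threshold
        return fill(
            {P.PANESOPHAGEAL: 1, P.PREMATURE: int(ri(3, min(6, n - 1) + 1))}, P.FAILED
        )
    if diagnosis is Diagnosis.EGJ_OUTFLOW_OBSTRUCTION:
        return fill({P.PANESOPHAGEAL: 1, P.PREMATURE: int(ri(0, 3))}, P.NORMAL)
    if diagnosis is Diagnosis.DISTAL_ESOPHAGEAL_SPASM:
        return fill({P.PREMATURE: int(ri(3, min(6, n) + 1))}, P.NORMAL)
    if diagnosis is Diagnosis.HYPERCONTRACTILE_ESOPHAGUS:
        return fill({P.DCI_GT_8000: int(ri(2, min(5, n) + 1))}, P.NORMAL)
    if diagnosis is Diagnosis.INEFFECTIVE_ESOPHAGEAL_MOTILITY:
        return fill({P.WEAK: int(ri(5, min(8, n) + 1))}, P.NORMAL)
    if diagnosis is Diagnosis.FRAGMENTED_PERISTALSIS:
        return fill({P.FRAGMENTED: int(ri(5, min(8, n) + 1))}, P.NORMAL)
    if diagnosis is Diagnosis.NORMAL_MOTILITY:
        return fill({P.WEAK: int(ri(0, 3)), P.FRAGMENTED: int(ri(0, 3))}, P.NORMAL)
    raise ValueError(f"unsupported diagnosis {diagnosis!r}")


def generate_study(
    diagnosis: Diagnosis,
    n_swallows: int = 10,
    seed: int = 0,
    *,
    render: bool = True,
    width_px: int = 600,
    height_px: int = 360,
) -> StudyBatch:
    """A study batch whose ground-truth labels diagnose as ``diagnosis``.

    Deterministic for a fixed seed.  The constructed batch is verified by
    running the decision tree over its ground-truth labels before returning.
    """
    if not isinstance(diagnosis, Diagnosis):
        raise ValueError(f"unsupported diagnosis {diagnosis!r}")
    if n_swallows < 6:
        raise ValueError("a study needs at least 6 swallows for the rule thresholds")
    rng = np.random.default_rng(seed)
    patterns = _compose_patterns(diagnosis, n_swallows, rng)
    rng.shuffle(patterns)

    if diagnosis in HIGH_IRP_DIAGNOSES:
        n_high = int(rng.integers(n_swallows // 2 + 1, n_swallows + 1))
    else:
        n_high = int(rng.integers(0, n_swallows // 2 + 1))
    irp_classes = [IRPClass.HIGH] * n_high + [IRPClass.NORMAL] * (n_swallows - n_high)
    rng.shuffle(irp_classes)

    swallows = tuple(
        generate_swallow(
            pat,
            irp,
            int(rng.integers(2**31)),
            render=render,
            width_px=width_px,
            height_px=height_px,
        )
        for pat, irp in zip(patterns, irp_classes)
    )
    batch = StudyBatch(swallows=swallows, intended_diagnosis=diagnosis)
    verdict = chicago_rules.diagnose(
        chicago_rules.aggregate_irp(batch.irp_classes),
        chicago_rules.count_patterns(batch.patterns),
    )
    if verdict is not diagnosis:
        raise RuntimeError(
            f"inverse construction failed: built {verdict}, wanted {diagnosis}"
        )
    return batch


MANIFEST_COLUMNS = [
    "study_id",
    "swallow_index",
    "filename",
    "pattern",
    "irp_mmHg",
    "irp_class",
    "dci",
    "intended_diagnosis",
]


def save_study(batch: StudyBatch, out_dir, study_id: str) -> pd.DataFrame:
    """Write a study's PNGs and return its manifest rows."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sample in enumerate(batch.swallows):
        if sample.image is None:
            raise ValueError("study was generated with render=False")
        filename = f"{study_id}_swallow_{i:02d}.png"
        sample.image.save(out / filename)
        rows.append(
            {
                "study_id": study_id,
                "swallow_index": i,
                "filename": filename,
                "pattern": sample.truth.pattern.value,
                "irp_mmHg": round(sample.truth.irp_mmHg, 3),
                "irp_class": sample.truth.irp_class.value,
                "dci": round(sample.truth.dci, 3),
                "intended_diagnosis": batch.intended_diagnosis.value,
            }
        )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
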