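"""Synthetic labeled IMU streams for the eight activity classes.

Each dynamic activity is modelled as a sum of sinusoids — a class-specific
fundamental frequency plus decaying harmonics — with a per-channel amplitude
profile, a gravity offset on the accelerometer channels and white Gaussian
sensor noise. The static postures (still, lying) are a gravity offset plus
noise, distinguished by the orientation of the gravity axis. This is a
signal-level emulation of waist-worn smartphone data: class-distinct
periodicity, amplitude and noise, with no biomechanical realism.

The default presets are the package's fixed study conditions; everything
downstream (windowing, representations, network training, streaming) is
exercised against them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .labels import ActivityLabel, DYNAMIC_LABELS, N_CLASSES, STATIC_LABELS
from .sensor_io import ActivityStream, N_CHANNELS

GRAVITY = 9.81  # m/s²

#: Relative amplitudes of the fundamental and its harmonics (k = 1, 2, 3).
HARMONIC_PROFILE = (1.0, 0.5, 0.25)


@dataclass(frozen=True)
class SyntheticActivityModel:
    """Signal model for one activity class.

    Parameters
    ----------
    label
        The activity this model emulates.
    fundamental_hz
        Base frequency of the periodic motion; 0 for static postures.
    harmonic_amps
        Peak amplitude per channel (ax, ay, az, gx, gy, gz) in sensor units,
        scaling the shared harmonic profile.
    gravity_axis
        Unit 3-vector giving the orientation of gravity in the device frame;
        the accelerometer channels carry ``GRAVITY * gravity_axis`` as a
        static offset.
    noise_sd
        Standard deviation of the white Gaussian sensor noise, per channel.
    phase_jitter
        Half-width (radians) of the uniform random phase offset drawn once
        per channel per generated stream.
    """

    label: ActivityLabel
    fundamental_hz: float
    harmonic_amps: Tuple[float, ...]
    gravity_axis: Tuple[float, float, float] = (0.0, 0.0, 1.0)
    noise_sd: float = 0.3
    phase_jitter: float = 0.1

    def __post_init__(self) -> None:
        if self.fundamental_hz < 0:
            raise ValueError("fundamental_hz must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.harmonic_amps) != N_CHANNELS:
            raise ValueError(f"harmonic_amps must have {N_CHANNELS} entries")
        norm = float(np.linalg.norm(self.gravity_axis))
        if not np.isclose(norm, 1.0, atol=1e-9):
            raise ValueError(f"gravity_axis must have unit norm, got {norm}")

    @property
    def is_static(self) -> bool:
        return self.fundamental_hz == 0.0


@dataclass(frozen=True)
class GenerationConfig:
    """Shared generation settings.

    ``class_mix`` gives per-class proportions of the generated streams and
    must sum to 1; ``duration`` is seconds per stream.
    """

    rate: float = 50.0
    duration: float = 120.0
    seed: int = 0
    class_mix: Optional[Mapping[ActivityLabel, float]] = None

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.duration <= 0:
            raise ValueError("rate and duration must be positive")
        if self.class_mix is not None:
            total = sum(self.class_mix.values())
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError(f"class_mix proportions must sum to 1, got {total}")


def _preset(label, f, amps, axis=(0.0, 0.0, 1.0), noise=0.3):
    return SyntheticActivityModel(
        label=label, fundamental_hz=f, harmonic_amps=amps,
        gravity_axis=axis, noise_sd=noise,
    )


#: Default per-class signal models. Fundamentals and amplitude profiles are
#: distinct per class (jumping: large vertical acceleration; cycling:
#: gyroscope-dominant; still vs lying: orthogonal gravity axes) so classes
#: are separable yet overlap enough to exercise training.
DEFAULT_PRESETS: Dict[ActivityLabel, SyntheticActivityModel] = {
    ActivityLabel.WALKING: _preset(
        ActivityLabel.WALKING, 1.5, (1.0, 0.8, 2.0, 0.5, 0.5, 0.3)),
    ActivityLabel.JOGGING: _preset(
        ActivityLabel.JOGGING, 2.5, (2.0, 1.5, 4.0, 1.0, 1.0, 0.6), noise=0.5),
    ActivityLabel.JUMPING: _preset(
        ActivityLabel.JUMPING, 2.0, (1.0, 0.8, 6.0, 0.4, 0.4, 0.3), noise=0.5),
    ActivityLabel.UPSTAIRS: _preset(
        ActivityLabel.UPSTAIRS, 1.2, (1.2, 0.6, 1.8, 0.8, 0.4, 0.5)),
    ActivityLabel.DOWNSTAIRS: _preset(
        ActivityLabel.DOWNSTAIRS, 1.4, (1.5, 0.7, 2.2, 0.9, 0.5, 0.6)),
    ActivityLabel.STILL: _preset(
        ActivityLabel.STILL, 0.0, (0.0,) * 6, axis=(0.0, 0.0, 1.0), noise=0.05),
    ActivityLabel.LYING: _preset(
        ActivityLabel.LYING, 0.0, (0.0,) * 6, axis=(1.0, 0.0, 0.0), noise=0.05),
    ActivityLabel.CYCLING: _preset(
        ActivityLabel.CYCLING, 1.0, (0.5, 0.4, 0.6, 1.5, 1.2, 2.0), noise=0.2),
}

# fixed per-channel phase offsets so the six channels are not in lockstep
_CHANNEL_PHASES = np.arange(N_CHANNELS) * np.pi / 4


def generate_activity_stream(
    model: SyntheticActivityModel,
    config: GenerationConfig,
    subject_id: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
) -> ActivityStream:
    """Generate one labeled stream of ``round(duration * rate)`` samples.

    Deterministic given ``config.seed``: a fresh generator is seeded per call
    unless an explicit ``rng`` is passed (used by the dataset generator to
    draw many streams from one seeded source). Noise is drawn channel by
    channel in fixed order for reproducibility.
    """
    n = int(round(config.duration * config.rate))
    if n <= 0:
        raise ValueError("requested stream length is zero")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    t = np.arange(n) / config.rate
    data = np.zeros((n, N_CHANNELS))

    # gravity offset on the accelerometer channels
    data[:, :3] += GRAVITY * np.asarray(model.gravity_axis)

    if not model.is_static:
        phases = _CHANNEL_PHASES + rng.uniform(
            -model.phase_jitter, model.phase_jitter, size=N_CHANNELS)
        for ch in range(N_CHANNELS):
            amp = model.harmonic_amps[ch]
            if amp == 0.0:
                continue
            for k, rel in enumerate(HARMONIC_PROFILE, start=1):
                data[:, ch] += amp * rel * np.sin(
                    2 * np.pi * k * model.fundamental_hz * t + phases[ch])

    if model.noise_sd > 0:
        for ch in range(N_CHANNELS):  # fixed channel order
            data[:, ch] += rng.normal(0.0, model.noise_sd, size=n)

    return ActivityStream(
        data=data, t=t, rate=config.rate, label=model.label,
        subject_id=subject_id or f"synthetic-{model.label.name.lower()}",
    )


def _allocate_counts(total: int, weights: Sequence[float]) -> List[int]:
    """Largest-remainder allocation of `total` items to `weights`."""
    raw = np.asarray(weights, dtype=float) * total
    counts = np.floor(raw).astype(int)
    short = total - int(counts.sum())
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts.tolist()


def generate_labeled_dataset(
    models: Mapping[ActivityLabel, SyntheticActivityModel],
    config: GenerationConfig,
    n_streams: int = 8,
) -> List[ActivityStream]:
    """Generate ``n_streams`` labeled streams covering all eight classes.

    Stream counts per class follow ``config.class_mix`` (uniform by default)
    under largest-remainder rounding. Reproducible given ``config.seed``.
    """
    missing = [lab.name.lower() for lab in ActivityLabel if lab not in models]
    if missing:
        raise ValueError(f"missing class models: {missing}")
    if n_streams < 1:
        raise ValueError("n_streams must be >= 1")

    mix = config.class_mix or {lab: 1.0 / N_CLASSES for lab in ActivityLabel}
    labels = list(ActivityLabel)
    counts = _allocate_counts(n_streams, [mix.get(lab, 0.0) for lab in labels])

    rng = np.random.default_rng(config.seed)
    streams: List[ActivityStream] = []
    for lab, count in zip(labels, counts):
        for i in range(count):
            streams.append(generate_activity_stream(
                models[lab], config,
                subject_id=f"synthetic-{lab.name.lower()}-{i:03d}", rng=rng))
    return streams


def load_presets(path) -> Dict[ActivityLabel, SyntheticActivityModel]:
    """Load preset overrides from a key/value text file.

    Lines look like ``walking.fundamental_hz = 1.6`` or
    ``jogging.noise_sd = 0.4``; unknown fields raise. Unlisted classes keep
    their defaults.
    """
    presets = dict(DEFAULT_PRESETS)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                key, value = (part.strip() for part in line.split("=", 1))
                class_name, field_name = key.split(".", 1)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: expected 'class.field = value'")
            label = ActivityLabel.from_name(class_name)
            model = presets[label]
            if field_name in ("fundamental_hz", "noise_sd", "phase_jitter"):
                presets[label] = replace(model, **{field_name: float(value)})
            elif field_name in ("harmonic_amps", "gravity_axis"):
                vec = tuple(float(v) for v in value.split(","))
                presets[label] = replace(model, **{field_name: vec})
            else:
                raise ValueError(f"{path}:{lineno}: unknown field {field_name!r}")
    return presets
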