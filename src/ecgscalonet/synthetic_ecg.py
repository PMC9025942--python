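"""Synthetic three-class ECG generator.

Builds labeled single-channel recordings whose rhythm and morphology differ
by class, so the whole scalogram/classifier pipeline can be exercised without
any external database:

* **NSR** — regular sinus rhythm at a resting rate, normal P-QRS-T morphology;
* **ARR** — irregular rhythm (high RR variability) with occasional ectopic
  beats rendered as wide, large QRS complexes without a preceding P wave;
* **CHF** — regular but fast rhythm with attenuated/flattened T waves.

Each beat is a sum of Gaussian bumps for the P, Q, R, S and T deflections
placed at RR intervals drawn per class; sinusoidal baseline wander and white
noise are added on top. The phenotypes are deliberate caricatures chosen for
class-distinct time-frequency signatures, not clinical simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import CLASSES, ECGRecord

__all__ = ["ClassParams", "SynthesisConfig", "generate_record", "generate_dataset"]


@dataclass(frozen=True)
class ClassParams:
    """Per-class rhythm/morphology knobs.

    ``mean_heart_rate_bpm`` sets the average RR interval;
    ``rr_coefficient_of_variation`` the relative RR spread (rhythm
    irregularity); ``ectopic_beat_probability`` the chance that a beat is an
    ectopic wide-QRS beat; ``t_wave_amplitude_scale`` multiplies the T bump
    (mV scale, 1.0 = normal); ``baseline_wander_amplitude`` (mV) and
    ``noise_sd`` (mV) control the additive nuisances.
    """

    mean_heart_rate_bpm: float = 75.0
    rr_coefficient_of_variation: float = 0.03
    ectopic_beat_probability: float = 0.0
    t_wave_amplitude_scale: float = 1.0
    baseline_wander_amplitude: float = 0.05
    noise_sd: float = 0.03

    def __post_init__(self) -> None:
        if not 0.0 <= self.ectopic_beat_probability <= 1.0:
            raise ValueError("ectopic_beat_probability must be in [0, 1]")
        if self.mean_heart_rate_bpm <= 0:
            raise ValueError("mean_heart_rate_bpm must be positive")
        for name in ("rr_coefficient_of_variation", "baseline_wander_amplitude",
                     "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


#: Default class phenotypes. NSR: regular ~75 bpm. ARR: irregular with
#: ectopy. CHF: fast and regular with flattened T waves.
DEFAULT_CLASS_PARAMS: dict[str, ClassParams] = {
    "NSR": ClassParams(),
    "ARR": ClassParams(
        mean_heart_rate_bpm=85.0,
        rr_coefficient_of_variation=0.28,
        ectopic_beat_probability=0.25,
    ),
    "CHF": ClassParams(
        mean_heart_rate_bpm=115.0,
        rr_coefficient_of_variation=0.04,
        t_wave_amplitude_scale=0.25,
    ),
}


@dataclass(frozen=True)
class SynthesisConfig:
    sampling_rate_hz: float = 128.0
    duration_samples: int = 65_536
    class_params: dict[str, ClassParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS)
    )

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.duration_samples < 1:
            raise ValueError("duration_samples must be positive")


# (name, time offset from R in s, amplitude in mV, width in s)
_NORMAL_BEAT = (
    ("P", -0.20, 0.15, 0.040),
    ("Q", -0.045, -0.10, 0.012),
    ("R", 0.00, 1.00, 0.014),
    ("S", 0.045, -0.18, 0.014),
    ("T", 0.30, 0.30, 0.070),
)
# Ectopic (PVC-like) beat: no P wave, wide tall QRS, discordant T.
_ECTOPIC_BEAT = (
    ("R", 0.00, 1.30, 0.045),
    ("S", 0.09, -0.45, 0.045),
    ("T", 0.36, -0.35, 0.090),
)

#: Sum of absolute template amplitudes (worst-case stack-up), used by the
#: documented amplitude bound |signal| <= this + wander + 6 * noise_sd.
MAX_TEMPLATE_AMPLITUDE = max(
    sum(abs(a) for _, _, a, _ in _NORMAL_BEAT),
    sum(abs(a) for _, _, a, _ in _ECTOPIC_BEAT),
)


def _record_seed(global_seed: int, class_label: str, index: int) -> np.random.SeedSequence:
    """Stable per-record seed; inserting records never reshuffles others."""
    return np.random.SeedSequence(
        entropy=int(global_seed) & 0x7FFFFFFF,
        spawn_key=(CLASSES.index(class_label), int(index)),
    )


def generate_record(
    class_label: str,
    config: SynthesisConfig | None = None,
    seed: int = 0,
    *,
    record_index: int = 0,
) -> ECGRecord:
    """Generate one labeled synthetic recording, deterministically in
    ``(class_label, config, seed, record_index)``.

    The realised RR intervals (seconds) are recorded in
    ``record.meta["rr_intervals_s"]`` and the ectopy flags in
    ``record.meta["is_ectopic"]`` so rhythm statistics can be checked against
    the generator's own beat log.
    """
    if class_label not in CLASSES:
        raise ValueError(f"unknown class {class_label!r}; expected one of {CLASSES}")
    config = config or SynthesisConfig()
    params = config.class_params.get(class_label, DEFAULT_CLASS_PARAMS[class_label])
    fs = config.sampling_rate_hz
    n = config.duration_samples
    mean_rr = 60.0 / params.mean_heart_rate_bpm
    if n < mean_rr * fs:
        raise ValueError(
            f"duration_samples={n} is shorter than one beat at "
            f"{params.mean_heart_rate_bpm} bpm and {fs} Hz"
        )

    rng = np.random.default_rng(_record_seed(seed, class_label, record_index))
    duration_s = n / fs

    # Draw RR intervals until the record is covered.
    rr: list[float] = []
    ectopic: list[bool] = []
    t = 0.0
    while t < duration_s + 2.0 * mean_rr:
        iv = rng.normal(mean_rr, params.rr_coefficient_of_variation * mean_rr)
        iv = max(iv, 0.25 * mean_rr)
        is_ect = bool(rng.random() < params.ectopic_beat_probability)
        if is_ect:
            # premature beat followed by a compensatory pause
            iv *= 0.7
        rr.append(iv)
        ectopic.append(is_ect)
        t += iv

    beat_times = np.cumsum([0.0] + rr[:-1])
    signal = np.zeros(n)
    tgrid = np.arange(n) / fs
    for bt, is_ect in zip(beat_times, ectopic):
        template = _ECTOPIC_BEAT if is_ect else _NORMAL_BEAT
        for name, off, amp, width in template:
            if name == "T":
                amp = amp * params.t_wave_amplitude_scale
            centre = bt + off
            lo = max(0, int((centre - 5 * width) * fs))
            hi = min(n, int((centre + 5 * width) * fs) + 1)
            if hi <= lo:
                continue
            tt = tgrid[lo:hi] - centre
            signal[lo:hi] += amp * np.exp(-0.5 * (tt / width) ** 2)

    # Baseline wander: slow sinusoid with randomised frequency and phase.
    wander_f = rng.uniform(0.15, 0.35)
    signal += params.baseline_wander_amplitude * np.sin(
        2 * np.pi * wander_f * tgrid + rng.uniform(0, 2 * np.pi)
    )
    signal += rng.normal(0.0, params.noise_sd, size=n)

    return ECGRecord(
        record_id=f"syn-{class_label}-{record_index:03d}",
        samples=signal,
        sampling_rate_hz=fs,
        label=class_label,
        meta={
            "rr_intervals_s": np.asarray(rr),
            "is_ectopic": np.asarray(ectopic),
            "seed": seed,
        },
    )


def generate_dataset(
    n_per_class: int,
    config: SynthesisConfig | None = None,
    seed: int = 0,
) -> list[ECGRecord]:
    """Generate a class-balanced dataset of ``3 * n_per_class`` records.

    Records are ordered class-by-class (ARR block, CHF block, NSR block) and
    seeded per (class, index) so the same (n, config, seed) always reproduces
    the identical dataset, and growing ``n_per_class`` only appends records.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    config = config or SynthesisConfig()
    return [
        generate_record(cls, config, seed, record_index=i)
        for cls in CLASSES
        for i in range(n_per_class)
    ]
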