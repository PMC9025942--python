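"""Continuous wavelet transform scalograms and their rendering as RGB images.

Each 500-sample chunk is analysed with a complex (analytic) Morlet wavelet on
a logarithmic frequency grid of ``voices_per_octave`` scales per octave
spanning [f_min, Nyquist]; the coefficient magnitudes form the scalogram,
which is min-max scaled, colormapped and resized to a fixed RGB resolution
(227 x 227 x 3 by default) — the time-frequency "image" the classifier
consumes. The CWT doubles as the pipeline's denoising stage: broadband noise
spreads across scales while the rhythm and beat morphology concentrate along
ridges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .preprocess import ChunkSet

__all__ = [
    "CWTConfig",
    "Scalogram",
    "ScalogramImage",
    "ImageSet",
    "cwt_transform",
    "render_scalogram",
    "chunks_to_images",
]

#: Centre (angular) frequency of the analytic Morlet, omega0. The value 6 is
#: the standard "amor" wavelet; recognised identifiers map onto it.
_MORLET_OMEGA0 = {"amor": 6.0, "morlet": 6.0}


@dataclass(frozen=True)
class CWTConfig:
    """Scale-grid parameters for the transform.

    ``min_cycles`` sets the lowest analysed frequency: the slowest
    oscillation must complete that many cycles within one chunk, i.e.
    f_min = min_cycles * fs / chunk_length (~0.5 Hz for 500 samples at
    128 Hz with the default 2 cycles).
    """

    wavelet: str = "amor"
    voices_per_octave: int = 12
    min_cycles: float = 2.0
    sampling_rate_hz: float = 128.0

    def __post_init__(self) -> None:
        if self.voices_per_octave < 1:
            raise ValueError("voices_per_octave must be >= 1")
        if self.min_cycles <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("min_cycles and sampling_rate_hz must be positive")

    @property
    def omega0(self) -> float:
        try:
            return _MORLET_OMEGA0[self.wavelet]
        except KeyError:
            raise ValueError(
                f"unsupported wavelet {self.wavelet!r}; "
                f"supported identifiers: {sorted(_MORLET_OMEGA0)}"
            ) from None

    def frequency_grid(self, chunk_length: int) -> np.ndarray:
        """Ascending log-spaced analysis frequencies in Hz, capped at Nyquist."""
        nyquist = self.sampling_rate_hz / 2.0
        f_min = self.min_cycles * self.sampling_rate_hz / chunk_length
        if f_min >= nyquist:
            raise ValueError(
                f"chunk of {chunk_length} samples leaves no analysable band "
                f"between f_min={f_min:.3g} and Nyquist={nyquist:.3g} Hz"
            )
        n_octaves = np.log2(nyquist / f_min)
        k = np.arange(int(np.floor(n_octaves * self.voices_per_octave)) + 1)
        return f_min * 2.0 ** (k / self.voices_per_octave)


@dataclass
class Scalogram:
    """CWT coefficient magnitudes on a frequency-by-time grid.

    ``magnitudes`` is (n_scales, n_times), nonnegative, with row k at
    ``frequencies_hz[k]`` (ascending).
    """

    magnitudes: np.ndarray
    frequencies_hz: np.ndarray
    times_s: np.ndarray

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=np.float64)
        if self.magnitudes.ndim != 2:
            raise ValueError("magnitudes must be 2-D")
        if self.magnitudes.shape != (len(self.frequencies_hz), len(self.times_s)):
            raise ValueError("axis lengths do not match magnitude shape")
        if np.any(self.magnitudes < 0):
            raise ValueError("magnitudes must be nonnegative")


@dataclass
class ScalogramImage:
    """Rendered RGB scalogram with provenance back to its source chunk."""

    pixels: np.ndarray  # (H, W, 3) uint8
    record_id: str = ""
    chunk_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be HxWx3")


@dataclass
class ImageSet:
    """A stack of rendered scalogram images with labels and provenance."""

    images: np.ndarray  # (N, H, W, 3) uint8
    labels: list[str]
    record_ids: list[str] = field(default_factory=list)
    chunk_indices: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return int(self.images.shape[0])


def cwt_transform(chunk: np.ndarray, config: CWTConfig) -> Scalogram:
    """Analytic Morlet CWT of one chunk; magnitudes on the config's log grid.

    Evaluated in the frequency domain: W(s, b) = ifft( x_hat(w) *
    psi_hat(s*w) ) with psi_hat(w) = exp(-(w - omega0)^2 / 2) for w > 0 and
    exactly 0 for w <= 0 (L1 scale normalisation, so equal-amplitude
    sinusoids produce equal ridge magnitudes at every frequency, and the
    zero-mean wavelet gives an exactly zero response to constant input).
    The chunk is reflection-padded on both sides before the transform and the
    result cropped back, so cone-of-influence columns are filled rather than
    zero-leaking.
    """
    chunk = np.asarray(chunk, dtype=np.float64).ravel()
    if chunk.size == 0:
        raise ValueError("empty chunk")
    if chunk.size < 2:
        raise ValueError("chunk must have at least 2 samples")
    fs = config.sampling_rate_hz
    freqs = config.frequency_grid(chunk.size)
    omega0 = config.omega0
    scales = omega0 / (2.0 * np.pi * freqs)  # seconds; peak response at each freq

    pad = chunk.size
    padded = np.pad(chunk, pad, mode="reflect")
    n = padded.size
    omega = 2.0 * np.pi * np.fft.fftfreq(n, d=1.0 / fs)  # angular, signed
    xhat = np.fft.fft(padded)
    # (n_scales, n) filter bank; one-sided spectrum => analytic coefficients
    arg = scales[:, None] * omega[None, :]
    psi_hat = np.where(arg > 0, np.exp(-0.5 * (arg - omega0) ** 2), 0.0)
    coeffs = np.fft.ifft(xhat[None, :] * psi_hat, axis=1)[:, pad : pad + chunk.size]
    return Scalogram(
        magnitudes=np.abs(coeffs),
        frequencies_hz=freqs,
        times_s=np.arange(chunk.size) / fs,
    )


def render_scalogram(
    scalogram: Scalogram,
    colormap: str = "jet",
    out_size: tuple[int, int] = (227, 227),
) -> ScalogramImage:
    """Render magnitudes to a colormapped RGB image of ``out_size``.

    Magnitudes are min-max scaled per image (so rendering is invariant to
    positive rescaling), mapped through the colormap, and bilinearly resized.
    The frequency axis is oriented low-at-bottom. An all-equal magnitude
    matrix renders uniformly at the colormap's low end.
    """
    mags = scalogram.magnitudes
    if mags.size == 0:
        raise ValueError("empty scalogram")
    lo, hi = float(mags.min()), float(mags.max())
    norm = np.zeros_like(mags) if hi == lo else (mags - lo) / (hi - lo)
    # row 0 holds the lowest frequency; image row 0 is the top -> flip.
    norm = norm[::-1, :]
    cmap = colormaps[colormap]
    rgb = (cmap(norm)[..., :3] * 255.0).round().astype(np.uint8)
    im = Image.fromarray(rgb, mode="RGB").resize(
        (out_size[1], out_size[0]), resample=Image.BILINEAR
    )
    return ScalogramImage(pixels=np.asarray(im, dtype=np.uint8))


def chunks_to_images(
    chunk_sets: list[ChunkSet],
    cwt_config: CWTConfig | None = None,
    colormap: str = "jet",
    out_size: tuple[int, int] = (227, 227),
) -> ImageSet:
    """Render every chunk of every ChunkSet, in (record order, chunk order).

    Labels are inherited from the source recording. Errors are re-raised with
    (record_id, chunk_index) context.
    """
    if not chunk_sets:
        raise ValueError("no chunk sets given")
    images, labels, rids, cidx = [], [], [], []
    for cs in chunk_sets:
        cfg = cwt_config or CWTConfig(sampling_rate_hz=cs.sampling_rate_hz)
        for j in range(len(cs)):
            try:
                scal = cwt_transform(cs.chunks[j], cfg)
                img = render_scalogram(scal, colormap=colormap, out_size=out_size)
            except Exception as exc:
                raise RuntimeError(
                    f"scalogram failed for record {cs.record_id} chunk {j}: {exc}"
                ) from exc
            images.append(img.pixels)
            labels.append(cs.label)
            rids.append(cs.record_id)
            cidx.append(j)
    return ImageSet(
        images=np.stack(images), labels=labels,
        record_ids=rids, chunk_indices=cidx,
    )
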