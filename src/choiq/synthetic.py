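"""Synthetic low-contrast phantom ROI generation.

Emulates the square regions of interest used by the observer study: a 2D
Gaussian lesion (default FWHM 5 mm, 20 HU contrast) on a stationary Gaussian
noise background, in a 90 signal-absent / 40 signal-present design at pixel
spacings matching 320/370/420 mm reconstruction FOV on a 512 matrix.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np

SIGNAL_ABSENT = "signal_absent"
SIGNAL_PRESENT = "signal_present"

#: FWHM of a unit-variance Gaussian: 2*sqrt(2*ln 2).
FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Pixel spacing presets (mm/pixel): reconstruction FOV / assumed 512 matrix.
PHANTOM_PRESETS = {
    "small": 320.0 / 512.0,
    "medium": 370.0 / 512.0,
    "large": 420.0 / 512.0,
}

NOISE_MODELS = ("white", "correlated")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic labelled ROI dataset."""

    roi_size_px: int = 64
    pixel_spacing_mm: float = PHANTOM_PRESETS["medium"]
    n_signal_absent: int = 90
    n_signal_present: int = 40
    lesion_fwhm_mm: float = 5.0
    lesion_amplitude_hu: float = 20.0
    background_hu: float = 0.0
    noise_sd_hu: float = 10.0
    noise_model: str = "white"
    correlation_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roi_size_px < 8:
            raise ValueError(f"roi_size_px must be >= 8, got {self.roi_size_px}")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.n_signal_absent < 2:
            raise ValueError(
                "n_signal_absent must be >= 2 (covariance estimation needs >= 2 samples)"
            )
        if self.n_signal_present < 0:
            raise ValueError("n_signal_present must be non-negative")
        if self.lesion_fwhm_mm <= 0:
            raise ValueError("lesion_fwhm_mm must be positive")
        if self.lesion_fwhm_mm / self.pixel_spacing_mm < 2:
            raise ValueError(
                "lesion_fwhm_mm must span at least 2 pixels at the given spacing"
            )
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be non-negative")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(
                f"noise_model must be one of {NOISE_MODELS}, got {self.noise_model!r}"
            )

    @classmethod
    def for_preset(cls, preset: str, **overrides) -> "SyntheticConfig":
        """Configuration for a phantom size preset ('small'/'medium'/'large')."""
        try:
            spacing = PHANTOM_PRESETS[preset]
        except KeyError:
            raise ValueError(
                f"unknown preset {preset!r}; choose from {sorted(PHANTOM_PRESETS)}"
            ) from None
        return cls(pixel_spacing_mm=spacing, **overrides)


@dataclass(frozen=True)
class ROIImage:
    """One square region of interest in Hounsfield units."""

    pixels: np.ndarray
    pixel_spacing_mm: float
    label: str
    lesion_diameter_mm: Optional[float] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError(f"pixels must be a square 2D matrix, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels must be finite-valued")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.label not in (SIGNAL_ABSENT, SIGNAL_PRESENT):
            raise ValueError(f"unknown label {self.label!r}")
        if self.label == SIGNAL_ABSENT and self.lesion_diameter_mm is not None:
            raise ValueError("signal_absent ROIs carry no lesion_diameter_mm")
        object.__setattr__(self, "pixels", px)

    @property
    def size_px(self) -> int:
        return self.pixels.shape[0]


def _radial_distance_mm(roi_size_px: int, pixel_spacing_mm: float) -> np.ndarray:
    """Physical distance of every pixel from the ROI centre pixel floor(N/2)."""
    centre = roi_size_px // 2
    idx = np.arange(roi_size_px) - centre
    dy, dx = np.meshgrid(idx, idx, indexing="ij")
    return pixel_spacing_mm * np.hypot(dy, dx)


def make_gaussian_signal(
    roi_size_px: int,
    pixel_spacing_mm: float,
    fwhm_mm: float,
    amplitude_hu: float,
) -> np.ndarray:
    """Centred 2D Gaussian lesion field.

    Value at physical radius ``d`` from the ROI centre is
    ``amplitude_hu * exp(-d^2 / (2 sigma^2))`` with
    ``sigma = fwhm_mm / (2 sqrt(2 ln 2))``; the centre pixel holds the peak.
    """
    if roi_size_px < 1:
        raise ValueError("roi_size_px must be positive")
    if pixel_spacing_mm <= 0:
        raise ValueError("pixel_spacing_mm must be positive")
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sigma = fwhm_mm / FWHM_TO_SIGMA
    d = _radial_distance_mm(roi_size_px, pixel_spacing_mm)
    return amplitude_hu * np.exp(-(d**2) / (2.0 * sigma**2))


def _correlated_filter(roi_size_px: int, exponent: float) -> np.ndarray:
    """Radially symmetric spectral shaping filter |H| on the DFT grid.

    Magnitude ~ f^(exponent/2) with the DC bin exactly zero and a cosine
    roll-off above 60% of the Nyquist frequency (a crude stand-in for the
    band-limited texture of filtered back-projection). Normalised so that
    mean(|H|^2) over all bins equals 1, which preserves pixel variance of a
    unit white field in expectation.
    """
    f = np.fft.fftfreq(roi_size_px)
    fr = np.hypot(*np.meshgrid(f, f, indexing="ij"))
    with np.errstate(divide="ignore"):
        h = np.where(fr > 0, fr ** (exponent / 2.0), 0.0)
    f_apod = 0.6 * 0.5  # 60% of Nyquist (0.5 cycles/pixel)
    f_max = fr.max()
    if f_max > f_apod:
        t = np.clip((fr - f_apod) / (f_max - f_apod), 0.0, 1.0)
        h = h * np.cos(0.5 * np.pi * t)
    h[0, 0] = 0.0
    norm = math.sqrt(float(np.mean(h**2)))
    if norm == 0:
        raise ValueError("degenerate correlated-noise filter (all-zero response)")
    return h / norm


def make_noise_field(
    roi_size_px: int,
    noise_model: str,
    noise_sd_hu: float,
    correlation_exponent: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Zero-mean stationary Gaussian noise field in HU.

    ``white``: i.i.d. pixels with standard deviation ``noise_sd_hu``.
    ``correlated``: a white field shaped in the frequency domain by a radial
    filter proportional to f^(correlation_exponent/2) with zero DC response,
    scaled so the pixel SD equals ``noise_sd_hu`` in expectation.
    """
    if noise_model not in NOISE_MODELS:
        raise ValueError(
            f"noise_model must be one of {NOISE_MODELS}, got {noise_model!r}"
        )
    if noise_sd_hu < 0:
        raise ValueError("noise_sd_hu must be non-negative")
    if rng is None:
        rng = np.random.default_rng()
    if noise_sd_hu == 0:
        # consume the same stream so label layouts stay aligned across sd values
        rng.standard_normal((roi_size_px, roi_size_px))
        return np.zeros((roi_size_px, roi_size_px))
    white = rng.standard_normal((roi_size_px, roi_size_px))
    if noise_model == "white":
        return noise_sd_hu * white
    h = _correlated_filter(roi_size_px, correlation_exponent)
    shaped = np.fft.ifft2(np.fft.fft2(white) * h).real
    return noise_sd_hu * shaped


def generate_dataset(config: SyntheticConfig) -> List[ROIImage]:
    """Generate the labelled ROI stack: signal-absent first, then signal-present.

    Each signal-present ROI is ``background + noise + Gaussian signal``;
    signal-absent ROIs are ``background + noise``. Noise fields are drawn
    independently per image from a generator seeded with ``config.seed``, so
    identical configurations yield bit-identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    signal = make_gaussian_signal(
        config.roi_size_px,
        config.pixel_spacing_mm,
        config.lesion_fwhm_mm,
        config.lesion_amplitude_hu,
    )
    rois: List[ROIImage] = []
    for i in range(config.n_signal_absent):
        noise = make_noise_field(
            config.roi_size_px,
            config.noise_model,
            config.noise_sd_hu,
            config.correlation_exponent,
            rng,
        )
        rois.append(
            ROIImage(
                pixels=config.background_hu + noise,
                pixel_spacing_mm=config.pixel_spacing_mm,
                label=SIGNAL_ABSENT,
                source_id=f"synthetic-absent-{i:03d}",
            )
        )
    for i in range(config.n_signal_present):
        noise = make_noise_field(
            config.roi_size_px,
            config.noise_model,
            config.noise_sd_hu,
            config.correlation_exponent,
            rng,
        )
        rois.append(
            ROIImage(
                pixels=config.background_hu + noise + signal,
                pixel_spacing_mm=config.pixel_spacing_mm,
                label=SIGNAL_PRESENT,
                lesion_diameter_mm=config.lesion_fwhm_mm,
                source_id=f"synthetic-present-{i:03d}",
            )
        )
    return rois


# ---------------------------------------------------------------------------
# portable dataset container: one text array per ROI + CSV manifest
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.csv"
_MANIFEST_FIELDS = ["filename", "label", "pixel_spacing_mm", "lesion_diameter_mm", "source_id"]


def save_dataset(rois: Sequence[ROIImage], out_dir: str | Path) -> Path:
    """Write ROIs as plain-text arrays plus a CSV manifest; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / MANIFEST_NAME
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_MANIFEST_FIELDS)
        writer.writeheader()
        for i, roi in enumerate(rois):
            fname = f"roi_{i:04d}.txt"
            np.savetxt(out / fname, roi.pixels, fmt="%.17e")  # lossless float64 round trip
            writer.writerow(
                {
                    "filename": fname,
                    "label": roi.label,
                    "pixel_spacing_mm": repr(roi.pixel_spacing_mm),
                    "lesion_diameter_mm": ""
                    if roi.lesion_diameter_mm is None
                    else repr(roi.lesion_diameter_mm),
                    "source_id": roi.source_id,
                }
            )
    return manifest


def load_dataset(in_dir: str | Path) -> List[ROIImage]:
    """Read a dataset written by :func:`save_dataset`."""
    src = Path(in_dir)
    manifest = src / MANIFEST_NAME
    if not manifest.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} in {src}")
    rois: List[ROIImage] = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            pixels = np.loadtxt(src / row["filename"], ndmin=2)
            diam = row["lesion_diameter_mm"]
            rois.append(
                ROIImage(
                    pixels=pixels,
                    pixel_spacing_mm=float(row["pixel_spacing_mm"]),
                    label=row["label"],
                    lesion_diameter_mm=None if diam == "" else float(diam),
                    source_id=row["source_id"],
                )
            )
    return rois
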