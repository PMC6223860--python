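"""Channelised Hotelling observer with dense difference-of-Gaussian channels.

The observer reduces each ROI to a J-vector through a bank of radially
symmetric bandpass channels, estimates the signal-absent channel covariance,
and scores images with the covariance-whitened matched template applied to
the channelised theoretical signal. An analytic performance oracle for
Gaussian statistics is included for validation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import linalg, stats

from choiq.synthetic import (
    ROIImage,
    SIGNAL_ABSENT,
    SIGNAL_PRESENT,
    make_gaussian_signal,
)

#: condition-number threshold above which the covariance solve is refused
CONDITION_LIMIT = 1e12


class SingularCovarianceError(np.linalg.LinAlgError):
    """Channel covariance is numerically singular.

    Raised when cond(K + ridge*I) exceeds ``CONDITION_LIMIT``; add a ridge or
    supply more signal-absent images.
    """


@dataclass(frozen=True)
class ChannelParams:
    """Generating parameters of the DDoG channel bank.

    sigma_j = sigma0 * alpha**(j-1) is the width (cycles/pixel) of channel j
    (1-based); Q is the relative bandwidth of each difference of Gaussians.
    """

    sigma0: float = 0.005
    alpha: float = 1.4
    q: float = 1.67
    n_channels: int = 10

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if self.alpha <= 1:
            raise ValueError("alpha must be > 1")
        if self.q <= 1:
            raise ValueError("Q must be > 1")
        if self.n_channels < 1:
            raise ValueError("n_channels must be positive")

    def sigma(self, j: int) -> float:
        """Width of channel j (1-based): sigma0 * alpha**(j-1)."""
        if not 1 <= j <= self.n_channels:
            raise ValueError(f"channel index {j} out of range 1..{self.n_channels}")
        return self.sigma0 * self.alpha ** (j - 1)


def ddog_response(rho, j: int, params: ChannelParams):
    """Radial frequency response of channel j at spatial frequency rho.

    C_j(rho) = exp(-(rho/(Q sigma_j))^2 / 2) - exp(-(rho/sigma_j)^2 / 2);
    zero at rho = 0 and bandpass around sigma_j. Accepts scalar or array rho.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("rho must be non-negative")
    sigma_j = params.sigma(j)
    wide = np.exp(-0.5 * (rho / (params.q * sigma_j)) ** 2)
    narrow = np.exp(-0.5 * (rho / sigma_j) ** 2)
    out = wide - narrow
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ChannelBank:
    """Spatial and frequency representations of the channel bank on one grid.

    ``spatial_templates`` is the (N^2, J) matrix U whose columns are the real
    spatial channel templates centred on pixel floor(N/2);
    ``frequency_responses`` holds the (J, N, N) radial responses sampled on
    the DFT grid (numpy fftfreq layout) with the DC bin forced to zero.
    """

    params: ChannelParams
    roi_size_px: int
    spatial_templates: np.ndarray
    frequency_responses: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.params.n_channels


def build_channel_bank(roi_size_px: int, params: Optional[ChannelParams] = None) -> ChannelBank:
    """Sample the DDoG responses on the ROI's DFT grid and invert to space.

    Radial frequency of bin (a, b) is hypot(a/N, b/N) cycles/pixel with the
    fftfreq sign convention; the response is real, even and radially
    symmetric, so the inverse DFT is real. Templates are shifted so their
    centre lands on pixel (N//2, N//2), matching the lesion placement.
    """
    if roi_size_px < 8:
        raise ValueError("roi_size_px must be >= 8")
    if params is None:
        params = ChannelParams()
    n = roi_size_px
    f = np.fft.fftfreq(n)
    rho = np.hypot(*np.meshgrid(f, f, indexing="ij"))
    responses = np.empty((params.n_channels, n, n))
    templates = np.empty((n * n, params.n_channels))
    for j in range(1, params.n_channels + 1):
        resp = ddog_response(rho, j, params)
        resp[0, 0] = 0.0
        spatial = np.fft.ifft2(resp)
        # response is real & even on the DFT grid -> imaginary part is roundoff
        spatial = np.fft.fftshift(spatial.real)
        responses[j - 1] = resp
        templates[:, j - 1] = spatial.ravel()
    return ChannelBank(
        params=params,
        roi_size_px=n,
        spatial_templates=templates,
        frequency_responses=responses,
    )


@dataclass(frozen=True)
class ChannelisedSet:
    """n x J matrix of channelised image vectors for one class."""

    vectors: np.ndarray
    label: str
    lesion_size_tag: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2 or v.shape[0] < 1:
            raise ValueError("vectors must be a non-empty n x J matrix")
        object.__setattr__(self, "vectors", v)

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_channels(self) -> int:
        return self.vectors.shape[1]


def _as_pixel_matrix(images: Sequence[Union[ROIImage, np.ndarray]], n: int) -> np.ndarray:
    rows = []
    for i, img in enumerate(images):
        px = img.pixels if isinstance(img, ROIImage) else np.asarray(img, dtype=float)
        if px.shape != (n, n):
            raise ValueError(
                f"image {i} has shape {px.shape}, bank expects ({n}, {n})"
            )
        rows.append(px.ravel())
    return np.asarray(rows)


def channelize(
    images: Sequence[Union[ROIImage, np.ndarray]],
    bank: ChannelBank,
    label: str = "",
    lesion_size_tag: str = "",
) -> ChannelisedSet:
    """Project images onto the channel bank: row i of the result is U^T g_i."""
    if len(images) == 0:
        raise ValueError("no images to channelise")
    g = _as_pixel_matrix(images, bank.roi_size_px)
    return ChannelisedSet(
        vectors=g @ bank.spatial_templates,
        label=label,
        lesion_size_tag=lesion_size_tag,
    )


def estimate_covariance(absent: Union[ChannelisedSet, np.ndarray]) -> np.ndarray:
    """Sample covariance of channelised signal-absent vectors (ddof=1).

    Mean-subtracted with denominator (n - 1); symmetric by construction.
    """
    v = absent.vectors if isinstance(absent, ChannelisedSet) else np.asarray(absent, float)
    if v.ndim != 2 or v.shape[0] < 2:
        raise ValueError("covariance estimation needs at least 2 samples")
    centred = v - v.mean(axis=0)
    k = centred.T @ centred / (v.shape[0] - 1)
    return 0.5 * (k + k.T)


def theoretical_signal_channelised(
    bank: ChannelBank,
    fwhm_mm: float,
    pixel_spacing_mm: float,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Channelised theoretical lesion: a centred Gaussian of the given FWHM.

    Uses the same construction as the synthetic lesion model, so the template
    targets exactly the signal the generator injects. Amplitude defaults to 1
    (observer scores are invariant to template scale).
    """
    if fwhm_mm <= 0 or pixel_spacing_mm <= 0:
        raise ValueError("fwhm_mm and pixel_spacing_mm must be positive")
    if fwhm_mm / pixel_spacing_mm < 2:
        warnings.warn(
            "theoretical signal FWHM spans fewer than 2 pixels; aliasing risk",
            RuntimeWarning,
            stacklevel=2,
        )
    signal = make_gaussian_signal(bank.roi_size_px, pixel_spacing_mm, fwhm_mm, amplitude)
    return signal.ravel() @ bank.spatial_templates


def mean_signal_channelised(
    absent: ChannelisedSet, present: ChannelisedSet
) -> np.ndarray:
    """Empirical alternative to the theoretical signal: mean(present) - mean(absent)."""
    if absent.n_channels != present.n_channels:
        raise ValueError("channel dimensions differ between classes")
    return present.vectors.mean(axis=0) - absent.vectors.mean(axis=0)


def build_template(
    K: np.ndarray, v_theo: np.ndarray, ridge: float = 0.0
) -> np.ndarray:
    """Hotelling template: solve (K + ridge*I) w = v_theo.

    Uses a symmetric linear solve (no explicit inverse). Raises
    :class:`SingularCovarianceError` when the regularised covariance has a
    condition number above 1e12.
    """
    K = np.asarray(K, dtype=float)
    v_theo = np.asarray(v_theo, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    if not np.allclose(K, K.T, atol=1e-10 * max(1.0, float(np.abs(K).max()))):
        raise ValueError("K must be symmetric")
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    a = K + ridge * np.eye(K.shape[0])
    cond = np.linalg.cond(a)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise SingularCovarianceError(
            f"covariance condition number {cond:.3e} exceeds {CONDITION_LIMIT:.0e}; "
            "add a ridge or use more signal-absent images"
        )
    return linalg.solve(a, v_theo, assume_a="sym")


@dataclass(frozen=True)
class CHOModel:
    """Fitted observer: covariance K, channelised signal v_theo, template w."""

    bank: ChannelBank
    K: np.ndarray
    v_theo: np.ndarray
    w: np.ndarray
    ridge: float = 0.0
    condition_number: float = float("nan")

    def score(self, images: Sequence[Union[ROIImage, np.ndarray]]) -> np.ndarray:
        """Decision variable w^T v for each image."""
        vs = channelize(images, self.bank)
        return vs.vectors @ self.w


@dataclass(frozen=True)
class ScoreSet:
    """Decision variables for the two classes."""

    lambda_absent: np.ndarray
    lambda_present: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "lambda_absent", np.asarray(self.lambda_absent, float).ravel()
        )
        object.__setattr__(
            self, "lambda_present", np.asarray(self.lambda_present, float).ravel()
        )


def decision_variables(
    w: np.ndarray, absent: ChannelisedSet, present: ChannelisedSet
) -> ScoreSet:
    """lambda = w^T v per image, preserving input ordering within each class."""
    w = np.asarray(w, dtype=float).ravel()
    if absent.n_channels != w.size or present.n_channels != w.size:
        raise ValueError(
            f"template length {w.size} does not match channel dimensions "
            f"({absent.n_channels} absent, {present.n_channels} present)"
        )
    return ScoreSet(
        lambda_absent=absent.vectors @ w,
        lambda_present=present.vectors @ w,
    )


def fit_cho_model(
    absent_images: Sequence[Union[ROIImage, np.ndarray]],
    bank: ChannelBank,
    fwhm_mm: float,
    pixel_spacing_mm: float,
    amplitude: float = 1.0,
    ridge: float = 0.0,
) -> CHOModel:
    """Estimate K from signal-absent images and build the matched template."""
    absent = channelize(absent_images, bank, label=SIGNAL_ABSENT)
    K = estimate_covariance(absent)
    v_theo = theoretical_signal_channelised(bank, fwhm_mm, pixel_spacing_mm, amplitude)
    w = build_template(K, v_theo, ridge)
    cond = float(np.linalg.cond(K + ridge * np.eye(K.shape[0])))
    return CHOModel(
        bank=bank, K=K, v_theo=v_theo, w=w, ridge=ridge, condition_number=cond
    )


def score_dataset(
    rois: Sequence[ROIImage],
    params: Optional[ChannelParams] = None,
    fwhm_mm: float = 5.0,
    ridge: float = 0.0,
    signal_mode: str = "theoretical",
) -> ScoreSet:
    """Full observer pipeline on a labelled ROI stack.

    Splits ROIs by label, fits the covariance on the signal-absent class,
    builds the template from either the theoretical Gaussian signal
    (default) or the empirical mean-signal difference, and returns the
    decision variables for both classes. No internal noise is added at any
    point in the score path.
    """
    if signal_mode not in ("theoretical", "mean"):
        raise ValueError("signal_mode must be 'theoretical' or 'mean'")
    absent_imgs = [r for r in rois if r.label == SIGNAL_ABSENT]
    present_imgs = [r for r in rois if r.label == SIGNAL_PRESENT]
    if not absent_imgs or not present_imgs:
        raise ValueError("dataset must contain both signal-absent and signal-present ROIs")
    n = absent_imgs[0].size_px
    spacing = absent_imgs[0].pixel_spacing_mm
    bank = build_channel_bank(n, params)
    absent = channelize(absent_imgs, bank, label=SIGNAL_ABSENT)
    present = channelize(present_imgs, bank, label=SIGNAL_PRESENT)
    K = estimate_covariance(absent)
    if signal_mode == "theoretical":
        v_theo = theoretical_signal_channelised(bank, fwhm_mm, spacing)
    else:
        v_theo = mean_signal_channelised(absent, present)
    w = build_template(K, v_theo, ridge)
    return decision_variables(w, absent, present)


def white_noise_channel_covariance(bank: ChannelBank, noise_sd: float) -> np.ndarray:
    """Exact channel covariance under i.i.d. pixel noise: sd^2 * U^T U."""
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    u = bank.spatial_templates
    return noise_sd**2 * (u.T @ u)


def analytic_cho_auc(K_true: np.ndarray, v_signal: np.ndarray) -> float:
    """Closed-form AUC of the ideal channelised observer under Gaussian scores.

    SNR^2 = v^T K^{-1} v and AUC = Phi(SNR / sqrt(2)). Validation oracle for
    the empirical pipeline; requires a positive-definite true covariance.
    """
    K_true = np.asarray(K_true, dtype=float)
    v_signal = np.asarray(v_signal, dtype=float).ravel()
    try:
        c, low = linalg.cho_factor(K_true, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError("K_true must be positive definite") from exc
    snr2 = float(v_signal @ linalg.cho_solve((c, low), v_signal))
    return float(stats.norm.cdf(math.sqrt(max(snr2, 0.0)) / math.sqrt(2.0)))


# ---------------------------------------------------------------------------
# model persistence / score export
# ---------------------------------------------------------------------------

def save_model(model: CHOModel, path) -> None:
    """Serialise K, v_theo, w and channel parameters to one YAML bundle."""
    import yaml

    doc = {
        "channel_params": {
            "sigma0": model.bank.params.sigma0,
            "alpha": model.bank.params.alpha,
            "q": model.bank.params.q,
            "n_channels": model.bank.params.n_channels,
        },
        "roi_size_px": model.bank.roi_size_px,
        "ridge": model.ridge,
        "condition_number": model.condition_number,
        "K": model.K.tolist(),
        "v_theo": model.v_theo.tolist(),
        "w": model.w.tolist(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def save_scores(scores: ScoreSet, path) -> None:
    """Export decision variables as CSV with columns (label, score)."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "score"])
        for s in scores.lambda_absent:
            writer.writerow([SIGNAL_ABSENT, repr(float(s))])
        for s in scores.lambda_present:
            writer.writerow([SIGNAL_PRESENT, repr(float(s))])


def load_scores(path) -> ScoreSet:
    """Read a (label, score) CSV back into a ScoreSet."""
    import csv

    absent, present = [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            if row["label"] == SIGNAL_ABSENT:
                absent.append(float(row["score"]))
            elif row["label"] == SIGNAL_PRESENT:
                present.append(float(row["score"]))
            else:
                raise ValueError(f"unknown label {row['label']!r} in {path}")
    if not absent or not present:
        raise ValueError("scores file must contain both classes")
    return ScoreSet(lambda_absent=np.array(absent), lambda_present=np.array(present))
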