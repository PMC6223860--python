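"""End-to-end validation experiments for the observer pipeline.

Property-based checks used by the acceptance suite and report: estimator
cross-validation against a brute-force pair counter, null calibration of the
full pipeline, agreement with the analytic performance oracle, monotonicity
in lesion contrast, channel-algebra invariances, and recovery of a known
latent correlation by the aggregation statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from choiq.aggregate import correlation_matrix, simulate_cohort
from choiq.cho import (
    build_channel_bank,
    build_template,
    channelize,
    decision_variables,
    estimate_covariance,
    fit_cho_model,
    score_dataset,
    theoretical_signal_channelised,
    white_noise_channel_covariance,
)
from choiq.cho import ChannelisedSet, analytic_cho_auc
from choiq.roc import auc_mann_whitney, bootstrap_auc
from choiq.synthetic import SIGNAL_ABSENT, SIGNAL_PRESENT, SyntheticConfig, generate_dataset


def brute_force_auc(absent: Sequence[float], present: Sequence[float]) -> float:
    """Exhaustive double-loop pair counter (ties as 1/2); oracle for the AUC."""
    wins = 0.0
    for a in absent:
        for p in present:
            if p > a:
                wins += 1.0
            elif p == a:
                wins += 0.5
    return wins / (len(absent) * len(present))


def auc_estimator_max_error(n_sets: int = 1000, seed: int = 0) -> float:
    """Max |fast AUC - brute-force AUC| over random score sets up to 90/40.

    Half the sets use discretised scores so ties are exercised.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_sets):
        na = int(rng.integers(2, 91))
        np_ = int(rng.integers(2, 41))
        a = rng.normal(size=na)
        p = rng.normal(rng.uniform(0, 1), size=np_)
        if i % 2 == 0:
            a = np.round(a)  # force ties
            p = np.round(p)
        worst = max(worst, abs(auc_mann_whitney(a, p) - brute_force_auc(a, p)))
    return worst


def null_calibration(
    n_seeds: int = 100, seed: int = 0, n_boot: int = 500
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Full pipeline on zero-signal 90/40 datasets across seeds.

    Returns (mean of bootstrap AUC means, per-seed bootstrap means,
    per-seed point AUCs).
    """
    means = np.empty(n_seeds)
    points = np.empty(n_seeds)
    for k in range(n_seeds):
        cfg = SyntheticConfig(lesion_amplitude_hu=0.0, seed=seed + k)
        scores = score_dataset(generate_dataset(cfg))
        res = bootstrap_auc(
            scores.lambda_absent, scores.lambda_present, n_boot=n_boot, seed=seed + k
        )
        means[k] = res.auc_mean
        points[k] = res.auc_point
    return float(means.mean()), means, points


def amplitude_for_target_auc(
    target_auc: float,
    noise_sd: float,
    roi_size_px: int = 64,
    pixel_spacing_mm: float = 370.0 / 512.0,
    fwhm_mm: float = 5.0,
) -> float:
    """Lesion contrast (HU) at which the analytic observer AUC equals target.

    Under white pixel noise the channel covariance is sd^2 U^T U and the SNR
    is linear in amplitude, so the required contrast has a closed form.
    """
    bank = build_channel_bank(roi_size_px)
    k_true = white_noise_channel_covariance(bank, noise_sd)
    v_unit = theoretical_signal_channelised(bank, fwhm_mm, pixel_spacing_mm, 1.0)
    snr_per_hu = math.sqrt(float(v_unit @ np.linalg.solve(k_true, v_unit)))
    return math.sqrt(2.0) * float(stats.norm.ppf(target_auc)) / snr_per_hu


def analytic_agreement(
    target_auc: float = 0.85,
    noise_sd: float = 30.0,
    n_train: int = 2000,
    n_per_class: int = 2000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Empirical AUC of a fitted observer vs the analytic oracle.

    The template is fitted on an independent set of ``n_train`` signal-absent
    images, then applied to ``n_per_class`` fresh images per class whose
    contrast is chosen so the analytic AUC equals ``target_auc``. Returns
    (empirical AUC, analytic AUC).
    """
    spacing = 370.0 / 512.0
    amp = amplitude_for_target_auc(target_auc, noise_sd, pixel_spacing_mm=spacing)
    train_cfg = SyntheticConfig(
        seed=seed, n_signal_absent=n_train, n_signal_present=0,
        noise_sd_hu=noise_sd, lesion_amplitude_hu=amp, pixel_spacing_mm=spacing,
    )
    test_cfg = SyntheticConfig(
        seed=seed + 1, n_signal_absent=n_per_class, n_signal_present=n_per_class,
        noise_sd_hu=noise_sd, lesion_amplitude_hu=amp, pixel_spacing_mm=spacing,
    )
    bank = build_channel_bank(train_cfg.roi_size_px)
    model = fit_cho_model(generate_dataset(train_cfg), bank, 5.0, spacing)
    test = generate_dataset(test_cfg)
    lam_absent = model.score([r for r in test if r.label == SIGNAL_ABSENT])
    lam_present = model.score([r for r in test if r.label == SIGNAL_PRESENT])
    empirical = auc_mann_whitney(lam_absent, lam_present)
    k_true = white_noise_channel_covariance(bank, noise_sd)
    v_sig = theoretical_signal_channelised(bank, 5.0, spacing, amp)
    return float(empirical), float(analytic_cho_auc(k_true, v_sig))


def amplitude_sweep(
    amplitudes: Sequence[float] = (0.0, 5.0, 10.0, 20.0, 40.0),
    noise_sd: float = 60.0,
    n_per_class: int = 1000,
    seed: int = 0,
) -> List[float]:
    """Empirical pipeline AUC at each lesion contrast, fixed noise level."""
    aucs = []
    for i, amp in enumerate(amplitudes):
        cfg = SyntheticConfig(
            seed=seed + i, n_signal_absent=n_per_class, n_signal_present=n_per_class,
            noise_sd_hu=noise_sd, lesion_amplitude_hu=amp,
        )
        scores = score_dataset(generate_dataset(cfg))
        aucs.append(auc_mann_whitney(scores.lambda_absent, scores.lambda_present))
    return aucs


def channel_algebra_deviations(
    n_recombinations: int = 50, seed: int = 0
) -> Tuple[float, float]:
    """Invariance of decision variables under channel algebra.

    Returns (max relative deviation of any score over random invertible
    channel recombinations, max relative score change under a +100 HU
    offset applied to every pixel).
    """
    rng = np.random.default_rng(seed)
    cfg = SyntheticConfig(seed=seed)
    rois = generate_dataset(cfg)
    bank = build_channel_bank(cfg.roi_size_px)
    absent = channelize([r for r in rois if r.label == SIGNAL_ABSENT], bank)
    present = channelize([r for r in rois if r.label == SIGNAL_PRESENT], bank)
    k = estimate_covariance(absent)
    v_theo = theoretical_signal_channelised(bank, 5.0, cfg.pixel_spacing_mm)
    w = build_template(k, v_theo)
    base = decision_variables(w, absent, present)
    scale = max(np.abs(base.lambda_absent).max(), np.abs(base.lambda_present).max())

    worst_recomb = 0.0
    j = bank.n_channels
    for _ in range(n_recombinations):
        q, _ = np.linalg.qr(rng.standard_normal((j, j)))
        a = q @ np.diag(rng.uniform(0.5, 2.0, j))
        absent_t = ChannelisedSet(absent.vectors @ a, SIGNAL_ABSENT)
        present_t = ChannelisedSet(present.vectors @ a, SIGNAL_PRESENT)
        w_t = build_template(a.T @ k @ a, a.T @ v_theo)
        s = decision_variables(w_t, absent_t, present_t)
        dev = max(
            np.abs(s.lambda_absent - base.lambda_absent).max(),
            np.abs(s.lambda_present - base.lambda_present).max(),
        )
        worst_recomb = max(worst_recomb, dev / scale)

    shifted = [r.pixels + 100.0 for r in rois]
    absent_s = channelize(shifted[: absent.n], bank)
    present_s = channelize(shifted[absent.n:], bank)
    s = decision_variables(w, absent_s, present_s)
    offset_dev = max(
        np.abs(s.lambda_absent - base.lambda_absent).max(),
        np.abs(s.lambda_present - base.lambda_present).max(),
    ) / scale
    return float(worst_recomb), float(offset_dev)


def cohort_recovery(
    n_centres: int = 500, latent_r: float = 0.5, seed: int = 0
) -> Dict[Tuple[str, str], float]:
    """Recovered pairwise AUC correlations from a synthetic cohort."""
    records = simulate_cohort(n_centres, latent_r, seed=seed)
    mat = correlation_matrix(records)
    return {
        ("S", "M"): float(mat.loc["S", "M"]),
        ("S", "L"): float(mat.loc["S", "L"]),
        ("M", "L"): float(mat.loc["M", "L"]),
    }
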