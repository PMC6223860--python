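"""Study-level aggregation: dose/AUC distributions and cross-size correlations.

Summarises per-centre CTDIvol and AUC by phantom size (median, quartiles,
5th/95th percentiles, outliers outside that band), and computes Pearson
correlation matrices of AUC across phantom sizes, stratified by the type of
automatic tube current modulation, with qualitative strength labels on the
Evans scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

PHANTOM_SIZES = ("S", "M", "L")
ATCM_TYPES = ("noise_level", "reference_mAs", "unknown")

_EVANS_BINS = (0.20, 0.40, 0.60, 0.80)
_EVANS_LABELS = ("very weak", "weak", "moderate", "strong", "very strong")


class UndefinedCorrelationError(ValueError):
    """Correlation is undefined (constant input or too few complete pairs)."""


@dataclass(frozen=True)
class StudyRecord:
    """One centre/scanner/phantom-size observation."""

    centre_id: str
    scanner_model: str
    manufacturer: str
    atcm_type: str
    phantom_size: str
    ctdi_vol_mgy: float
    auc_mean: float
    auc_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.atcm_type not in ATCM_TYPES:
            raise ValueError(f"atcm_type must be one of {ATCM_TYPES}")
        if self.phantom_size not in PHANTOM_SIZES:
            raise ValueError(f"phantom_size must be one of {PHANTOM_SIZES}")
        if self.ctdi_vol_mgy <= 0:
            raise ValueError("ctdi_vol_mgy must be positive")
        if self.auc_sd < 0:
            raise ValueError("auc_sd must be non-negative")


@dataclass(frozen=True)
class DistributionSummary:
    """Quantile summary with outliers outside the 5th-95th percentile band."""

    n: int
    median: float
    q1: float
    q3: float
    p5: float
    p95: float
    outliers: Tuple[Tuple[str, float], ...]


def summarize_distribution(
    values: Sequence[float], ids: Optional[Sequence[str]] = None
) -> DistributionSummary:
    """Median, quartiles and 5th/95th percentiles of a sample.

    Quantiles use linear interpolation between order statistics. Outliers
    are the values strictly outside [p5, p95], reported with their ids.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("cannot summarise an empty sample")
    if ids is None:
        ids = [str(i) for i in range(v.size)]
    if len(ids) != v.size:
        raise ValueError("ids must match values in length")
    p5, q1, med, q3, p95 = np.quantile(v, [0.05, 0.25, 0.5, 0.75, 0.95])
    outliers = tuple(
        (str(i), float(x)) for i, x in zip(ids, v) if x < p5 or x > p95
    )
    return DistributionSummary(
        n=int(v.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        p5=float(p5),
        p95=float(p95),
        outliers=outliers,
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation is undefined for constant input")
    dx = x - x.mean()
    dy = y - y.mean()
    return float(dx @ dy / np.sqrt((dx @ dx) * (dy @ dy)))


def evans_label(r: float) -> str:
    """Qualitative strength of |r|: very weak / weak / moderate / strong / very strong.

    Intervals are half-open at the upper edge ([0, 0.20), [0.20, 0.40), ...)
    except the final closed interval [0.80, 1.0].
    """
    a = abs(r)
    if a > 1.0:
        raise ValueError("|r| must not exceed 1")
    for bound, label in zip(_EVANS_BINS, _EVANS_LABELS):
        if a < bound:
            return label
    return _EVANS_LABELS[-1]


def _records_frame(records: Sequence[StudyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "centre_id": [r.centre_id for r in records],
            "scanner_model": [r.scanner_model for r in records],
            "manufacturer": [r.manufacturer for r in records],
            "atcm_type": [r.atcm_type for r in records],
            "phantom_size": [r.phantom_size for r in records],
            "ctdi_vol_mgy": [r.ctdi_vol_mgy for r in records],
            "auc_mean": [r.auc_mean for r in records],
            "auc_sd": [r.auc_sd for r in records],
        }
    )


def correlation_matrix(
    records: Sequence[StudyRecord], atcm_type: Optional[str] = None
) -> pd.DataFrame:
    """3x3 symmetric matrix of Pearson r of AUC over phantom sizes {S, M, L}.

    Optionally restricted to one ATCM stratum. Each centre contributes at
    most one AUC per size; off-diagonal cells use pairwise-complete
    observations and are NaN when fewer than 3 complete pairs exist or the
    correlation is undefined (constant input).
    """
    if not records:
        raise ValueError("no records")
    df = _records_frame(records)
    if atcm_type is not None:
        df = df[df["atcm_type"] == atcm_type]
    dup = df.duplicated(subset=["centre_id", "phantom_size"])
    if dup.any():
        raise ValueError("each centre may contribute at most one AUC per phantom size")
    wide = df.pivot(index="centre_id", columns="phantom_size", values="auc_mean")
    out = pd.DataFrame(
        np.eye(3), index=list(PHANTOM_SIZES), columns=list(PHANTOM_SIZES)
    )
    for i, a in enumerate(PHANTOM_SIZES):
        for b in PHANTOM_SIZES[i + 1:]:
            if a in wide.columns and b in wide.columns:
                pair = wide[[a, b]].dropna()
                try:
                    r = pearson_r(pair[a].to_numpy(), pair[b].to_numpy())
                except (ValueError, UndefinedCorrelationError):
                    r = float("nan")
            else:
                r = float("nan")
            out.loc[a, b] = out.loc[b, a] = r
    return out


def build_report(records: Sequence[StudyRecord], out_dir=None) -> Dict[str, pd.DataFrame]:
    """Assemble the study report: per-size summaries + correlation matrices.

    Returns (and optionally writes as CSVs under ``out_dir``) deterministic
    tables: ``auc_summary`` and ``ctdi_summary`` with one row per phantom
    size, and one correlation matrix per ATCM stratum plus ``correlation_all``,
    each off-diagonal cell annotated with its Evans label in a companion
    ``*_labels`` table.
    """
    if not records:
        raise ValueError("no records")
    df = _records_frame(records)

    def size_table(column: str) -> pd.DataFrame:
        rows = []
        for size in PHANTOM_SIZES:
            sub = df[df["phantom_size"] == size]
            if sub.empty:
                rows.append(
                    {"phantom_size": size, "n": 0, "median": np.nan, "q1": np.nan,
                     "q3": np.nan, "p5": np.nan, "p95": np.nan, "n_outliers": 0}
                )
                continue
            s = summarize_distribution(sub[column].to_numpy(), sub["centre_id"].tolist())
            rows.append(
                {"phantom_size": size, "n": s.n, "median": s.median, "q1": s.q1,
                 "q3": s.q3, "p5": s.p5, "p95": s.p95, "n_outliers": len(s.outliers)}
            )
        return pd.DataFrame(rows)

    tables: Dict[str, pd.DataFrame] = {
        "auc_summary": size_table("auc_mean"),
        "ctdi_summary": size_table("ctdi_vol_mgy"),
    }
    strata = [("all", None)] + [
        (t, t) for t in ATCM_TYPES if (df["atcm_type"] == t).any()
    ]
    for name, stratum in strata:
        mat = correlation_matrix(records, atcm_type=stratum)
        tables[f"correlation_{name}"] = mat
        labels = mat.copy().astype(object)
        for a in PHANTOM_SIZES:
            for b in PHANTOM_SIZES:
                r = mat.loc[a, b]
                labels.loc[a, b] = "undefined" if np.isnan(r) else evans_label(r)
        tables[f"correlation_{name}_labels"] = labels

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            table.to_csv(out / f"{name}.csv", index=name.startswith("correlation"))
    return tables


def read_records(path) -> List[StudyRecord]:
    """Read study records from CSV (columns: centre_id, manufacturer,
    scanner_model, atcm_type, phantom_size, ctdi_vol_mgy, auc_mean, auc_sd)."""
    df = pd.read_csv(path, dtype={"centre_id": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(
            StudyRecord(
                centre_id=str(row.centre_id),
                scanner_model=str(getattr(row, "scanner_model", "")),
                manufacturer=str(getattr(row, "manufacturer", "")),
                atcm_type=str(row.atcm_type),
                phantom_size=str(row.phantom_size),
                ctdi_vol_mgy=float(row.ctdi_vol_mgy),
                auc_mean=float(row.auc_mean),
                auc_sd=float(getattr(row, "auc_sd", 0.0)),
            )
        )
    return records


def simulate_cohort(
    n_centres: int,
    latent_r: float,
    seed: Optional[int] = None,
    auc_centre_by_size: Tuple[float, float, float] = (0.96, 0.90, 0.83),
    auc_spread: float = 0.03,
    ctdi_median_by_size: Tuple[float, float, float] = (5.8, 10.5, 16.3),
) -> List[StudyRecord]:
    """Synthetic multicentre cohort with a known latent cross-size correlation.

    Per centre, a 3-variate normal with equicorrelation ``latent_r`` across
    phantom sizes is mapped affinely onto AUC values (so the pairwise Pearson
    correlation of the generated AUCs equals ``latent_r`` in expectation);
    CTDIvol is drawn lognormally around the given per-size medians. ATCM
    type alternates between the two real modes.
    """
    if not -0.5 < latent_r <= 1.0:
        raise ValueError("latent_r must be in (-0.5, 1] for a valid equicorrelation")
    rng = np.random.default_rng(seed)
    cov = np.full((3, 3), latent_r)
    np.fill_diagonal(cov, 1.0)
    z = rng.multivariate_normal(np.zeros(3), cov, size=n_centres)
    records: List[StudyRecord] = []
    for c in range(n_centres):
        atcm = ATCM_TYPES[c % 2]
        for k, size in enumerate(PHANTOM_SIZES):
            auc = auc_centre_by_size[k] + auc_spread * z[c, k]
            ctdi = ctdi_median_by_size[k] * float(np.exp(rng.normal(0.0, 0.35)))
            records.append(
                StudyRecord(
                    centre_id=f"centre-{c:03d}",
                    scanner_model="synthetic",
                    manufacturer="synthetic",
                    atcm_type=atcm,
                    phantom_size=size,
                    ctdi_vol_mgy=ctdi,
                    auc_mean=float(auc),
                    auc_sd=0.01,
                )
            )
    return records
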