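"""Turnover estimation from labeling curves.

The kinetic core of the heavy-water method: peptide-level QC filtering,
one-compartment exponential fitting of ``E(t) = E_as (1 - e^{-kt})``,
plateau-normalized aggregation of peptides into protein curves, the
precursor-product (initial-slope) route for proteins too slow to
approach plateau inside the labeling window, and the derived turnover
quantities (half-life, residence time, pool size, production rate).

Time base is days internally; half-lives are reported in hours
(protein-table convention) and cholesterol parameters in days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .constants import HOURS_PER_DAY, PLASMA_VOLUME_FRACTION
from .errors import (
    InvalidParameterError,
    MissingDataError,
)
from .synthetic import SubjectRecord

__all__ = [
    "LabelingCurve",
    "KineticFit",
    "QCConfig",
    "FluxResult",
    "PeptideRecord",
    "filter_peptides",
    "fit_exponential_rise",
    "aggregate_protein_curve",
    "fit_precursor_product",
    "select_method",
    "half_life",
    "residence_time",
    "cholesterol_flux",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class LabelingCurve:
    """Time-ordered net enrichment values for one analyte in one subject."""

    analyte: str
    subject: str
    time_d: np.ndarray
    enrichment: np.ndarray
    flags: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.time_d = np.asarray(self.time_d, dtype=float)
        self.enrichment = np.asarray(self.enrichment, dtype=float)
        if self.time_d.shape != self.enrichment.shape:
            raise InvalidParameterError("time and enrichment lengths differ")
        if np.any(self.time_d < 0):
            raise InvalidParameterError("times must be non-negative")
        order = np.argsort(self.time_d, kind="stable")
        self.time_d = self.time_d[order]
        self.enrichment = self.enrichment[order]
        if self.flags is not None:
            self.flags = np.asarray(self.flags)[order]

    def __len__(self) -> int:
        return self.time_d.size


@dataclass
class KineticFit:
    """Fitted turnover parameters for one analyte.

    ``k`` is in pools/day.  ``e_as`` is absent (NaN) for precursor-product
    fits, where the asymptote is imposed rather than estimated.  The exact
    identities ``half_life_h = 24 ln2 / k`` and ``residence_time_d = 1/k``
    hold whenever the fit succeeded.
    """

    analyte: str
    subject: str
    ok: bool
    k: float = float("nan")
    e_as: float = float("nan")
    r_squared: float = float("nan")
    ci_k: tuple[float, float] = (float("nan"), float("nan"))
    half_life_h: float = float("nan")
    residence_time_d: float = float("nan")
    method: str = "exponential"
    n_points_used: int = 0
    outliers_removed: int = 0
    excluded: bool = False
    reason: str | None = None
    n_peptides: int | None = None

    @classmethod
    def failure(cls, analyte: str, subject: str, reason: str, method: str = "exponential") -> "KineticFit":
        return cls(analyte=analyte, subject=subject, ok=False, reason=reason, method=method)


@dataclass
class QCConfig:
    """Peptide acceptance thresholds.

    Defaults follow the workflow's stated rules: identification score
    above 35, total intensity inside 1e6-1e7, at least four usable time
    points, exponential fit R^2 >= 0.95, uniqueness required.  The
    outlier threshold applies to studentized residuals in the single
    outlier-removal pass of the exponential fit.
    """

    min_id_score: float = 35.0
    intensity_window: tuple[float, float] = (1e6, 1e7)
    min_timepoints: int = 4
    min_r_squared: float = 0.95
    outlier_threshold: float = 2.5
    max_outlier_fraction: float = 0.2
    require_unique: bool = True

    def __post_init__(self) -> None:
        low, high = self.intensity_window
        if not 0 < low < high:
            raise InvalidParameterError("intensity window must satisfy 0 < low < high")
        if min(self.min_id_score, self.min_r_squared, self.outlier_threshold) <= 0:
            raise InvalidParameterError("QC thresholds must be positive")
        if self.min_timepoints < 1:
            raise InvalidParameterError("min_timepoints must be >= 1")


@dataclass
class PeptideRecord:
    """QC-relevant metadata of one peptide time course."""

    subject: str
    accession: str
    peptide: str
    id_score: float
    intensity: float
    n_timepoints: int
    unique: bool = True
    charge: int = 2


@dataclass
class FluxResult:
    """Pool size and production rate of HDL cholesterol for one subject.

    ``pr = pool_size * fcr`` exactly; plasma volume is 4.5% of body
    weight, so ``pool_size (mg/kg) = 0.45 * [HDL-C] (mg/dL)``.
    """

    subject: str
    pool_size_mg_kg: float
    fcr_per_day: float
    pr_mg_kg_day: float
    plasma_volume_l: float


# ---------------------------------------------------------------------------
# QC filtering


def filter_peptides(
    records: Iterable[PeptideRecord], qc: QCConfig | None = None
) -> tuple[list[PeptideRecord], pd.DataFrame]:
    """Apply the peptide acceptance rules; order-stable.

    Returns the retained records and a rejection log naming the first
    failed rule per rejected record, so that
    ``len(input) == len(retained) + len(log)`` always holds.
    """
    qc = qc or QCConfig()
    retained: list[PeptideRecord] = []
    log_rows: list[dict] = []
    low, high = qc.intensity_window
    for rec in records:
        reason = None
        if rec.id_score <= qc.min_id_score:
            reason = f"id_score {rec.id_score:g} <= {qc.min_id_score:g}"
        elif not low <= rec.intensity <= high:
            reason = f"intensity {rec.intensity:g} outside [{low:g}, {high:g}]"
        elif rec.n_timepoints < qc.min_timepoints:
            reason = f"only {rec.n_timepoints} timepoints (< {qc.min_timepoints})"
        elif qc.require_unique and not rec.unique:
            reason = "peptide not unique to one protein"
        if reason is None:
            retained.append(rec)
        else:
            log_rows.append(
                {
                    "subject": rec.subject,
                    "accession": rec.accession,
                    "peptide": rec.peptide,
                    "rule": reason.split()[0],
                    "reason": reason,
                }
            )
    log = pd.DataFrame(log_rows, columns=["subject", "accession", "peptide", "rule", "reason"])
    return retained, log


# ---------------------------------------------------------------------------
# exponential fit


def _rise(t: np.ndarray, k: float, e_as: float) -> np.ndarray:
    return e_as * (1.0 - np.exp(-k * t))


def _r_squared(y: np.ndarray, resid: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def _fit_once(
    t: np.ndarray, y: np.ndarray, e_as_max: float
) -> tuple[np.ndarray, np.ndarray] | None:
    """Bounded least squares with multistart; returns (params, cov) or None."""
    t_last = float(t.max())
    t_mid = float(np.median(t[t > 0]))
    starts = [
        (math.log(2.0) / t_last, None),
        (math.log(2.0) / t_mid, None),
        (math.log(2.0) / (0.1 * t_last), None),
    ]
    e0 = float(max(y.max(), 1e-6))
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for k0, _ in starts:
        try:
            popt, pcov = optimize.curve_fit(
                _rise,
                t,
                y,
                p0=[min(max(k0, 1.1e-4), 49.0), min(e0, e_as_max * 0.999)],
                bounds=([1e-4, 1e-9], [50.0, e_as_max]),
                maxfev=10000,
            )
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((y - _rise(t, *popt)) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)
    if best is None:
        return None
    return best[1], best[2]


def _studentized_residuals(t: np.ndarray, resid: np.ndarray, popt: np.ndarray) -> np.ndarray:
    """Internally studentized residuals using the fit's local Jacobian."""
    k, e_as = popt
    j = np.column_stack([e_as * t * np.exp(-k * t), 1.0 - np.exp(-k * t)])
    dof = max(len(t) - 2, 1)
    s2 = float(np.sum(resid**2)) / dof
    if s2 == 0:
        return np.zeros_like(resid)
    try:
        hat = j @ np.linalg.pinv(j.T @ j) @ j.T
        lev = np.clip(np.diag(hat), 0.0, 0.999)
    except np.linalg.LinAlgError:
        lev = np.zeros_like(resid)
    return resid / np.sqrt(s2 * (1.0 - lev))


def fit_exponential_rise(
    curve: LabelingCurve,
    qc: QCConfig | None = None,
    e_as_max: float = 1.0,
) -> KineticFit:
    """Fit the one-compartment rise-to-plateau model to one curve.

    Nonlinear least squares of ``E(t) = E_as (1 - e^{-kt})`` with bounds
    ``k in (1e-4, 50]/day`` and ``E_as in (0, e_as_max]``, multistart
    initialization, a single outlier-removal pass (|studentized residual|
    above the QC threshold, never more than the configured fraction of
    points) followed by a refit.  Fits whose final R^2 falls below the QC
    floor are returned with ``excluded=True``; unidentifiable or
    non-convergent curves yield a failure result, never an exception.
    """
    qc = qc or QCConfig()
    t, y = curve.time_d, curve.enrichment
    if len(curve) < qc.min_timepoints:
        return KineticFit.failure(curve.analyte, curve.subject, "too few points")
    if not np.any(t > 0):
        return KineticFit.failure(curve.analyte, curve.subject, "no post-dose points")
    if np.all(y <= 0) or float(y.max()) <= 0:
        return KineticFit.failure(curve.analyte, curve.subject, "no labeling signal (k unidentifiable)")

    fitted = _fit_once(t, y, e_as_max)
    if fitted is None:
        return KineticFit.failure(curve.analyte, curve.subject, "fit did not converge")
    popt, pcov = fitted
    resid = y - _rise(t, *popt)

    n_out = 0
    stud = _studentized_residuals(t, resid, popt)
    worst = np.argsort(-np.abs(stud))
    allowed = int(qc.max_outlier_fraction * len(t))
    drop = [i for i in worst[:allowed] if abs(stud[i]) > qc.outlier_threshold]
    if drop:
        keep = np.setdiff1d(np.arange(len(t)), drop)
        if keep.size >= qc.min_timepoints:
            refit = _fit_once(t[keep], y[keep], e_as_max)
            if refit is not None:
                popt, pcov = refit
                t, y = t[keep], y[keep]
                resid = y - _rise(t, *popt)
                n_out = len(drop)

    k, e_as = float(popt[0]), float(popt[1])
    r2 = _r_squared(y, resid)
    dof = max(len(t) - 2, 1)
    se_k = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    tq = stats.t.ppf(0.975, dof)
    fit = KineticFit(
        analyte=curve.analyte,
        subject=curve.subject,
        ok=True,
        k=k,
        e_as=e_as,
        r_squared=r2,
        ci_k=(k - tq * se_k, k + tq * se_k),
        half_life_h=half_life(k),
        residence_time_d=residence_time(k),
        method="exponential",
        n_points_used=len(t),
        outliers_removed=n_out,
    )
    if np.isfinite(r2) and r2 < qc.min_r_squared:
        fit.excluded = True
        fit.reason = f"R^2 {r2:.3f} < {qc.min_r_squared}"
    return fit


# ---------------------------------------------------------------------------
# peptide -> protein aggregation


def aggregate_protein_curve(
    peptide_fits: Sequence[KineticFit],
    peptide_curves: Sequence[LabelingCurve],
    qc: QCConfig | None = None,
) -> tuple[LabelingCurve | None, KineticFit]:
    """Aggregate accepted peptide curves of one protein/subject and refit.

    Each peptide's enrichment is divided by its own fitted plateau
    ``E_as`` (values below half the negative plateau are floored for
    stability), the normalized curves are averaged per time point, and
    the one-compartment model is refit on the aggregate, whose plateau is
    expected near 1.  With no accepted peptides the protein is marked
    unquantified.
    """
    qc = qc or QCConfig()
    pairs = [
        (f, c)
        for f, c in zip(peptide_fits, peptide_curves)
        if f.ok and not f.excluded
    ]
    if not pairs:
        analyte = peptide_fits[0].analyte if peptide_fits else "?"
        subject = peptide_fits[0].subject if peptide_fits else "?"
        return None, KineticFit.failure(analyte, subject, "no accepted peptides")

    accumulator: dict[float, list[float]] = {}
    for fit, curve in pairs:
        norm = np.maximum(curve.enrichment, -0.5 * fit.e_as) / fit.e_as
        for t, v in zip(curve.time_d, norm):
            accumulator.setdefault(float(t), []).append(float(v))
    times = np.array(sorted(accumulator))
    values = np.array([np.mean(accumulator[t]) for t in times])

    protein_curve = LabelingCurve(
        analyte=pairs[0][0].analyte,
        subject=pairs[0][0].subject,
        time_d=times,
        enrichment=values,
        normalized=True,
    )
    # protein-level fit: R^2 reported but not used for exclusion
    relaxed = replace(qc, min_r_squared=1e-12)
    fit = fit_exponential_rise(protein_curve, relaxed, e_as_max=2.0)
    fit.n_peptides = len(pairs)
    return protein_curve, fit


# ---------------------------------------------------------------------------
# precursor-product route


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    return float(stats.linregress(t, y).slope)


def fit_precursor_product(
    curve: LabelingCurve,
    n_exchangeable: float,
    mpe_water: float,
    baseline_a0: float = 1.0,
    max_label_fraction: float = 0.1,
    min_points: int = 5,
) -> KineticFit:
    """Initial-slope (precursor-product) turnover for slow proteins.

    ``FCR = slope / (A0 * N * MPE)``: the labeling slope from ordinary
    linear regression of raw enrichment on time (days) divided by the
    linearized asymptote imposed from the peptide's exchangeable-hydrogen
    count and the measured body-water enrichment.

    Because the rise curve is concave, a slope taken over points that are
    already appreciably labeled underestimates the rate; the regression
    is therefore restricted iteratively to the quasi-linear window where
    the estimated cumulative labeling ``k*t`` stays below
    ``max_label_fraction`` (at least ``min_points`` points are always
    kept).  For genuinely slow proteins every point satisfies the window
    and the estimate is the plain regression slope over the full curve.
    """
    if n_exchangeable <= 0 or mpe_water <= 0:
        raise InvalidParameterError("N and body-water MPE must be positive")
    if baseline_a0 <= 0:
        raise InvalidParameterError("baseline A0 must be positive")
    if len(curve) < 3:
        return KineticFit.failure(curve.analyte, curve.subject, "too few points", "precursor_product")

    denom = baseline_a0 * n_exchangeable * mpe_water
    t, y = curve.time_d, curve.enrichment
    keep = np.ones(t.size, dtype=bool)
    fcr = float("nan")
    for _ in range(4):
        slope = _ols_slope(t[keep], y[keep])
        if slope <= 0:
            return KineticFit.failure(
                curve.analyte, curve.subject, "non-positive labeling slope", "precursor_product"
            )
        fcr = slope / denom
        new_keep = fcr * t <= max_label_fraction
        if new_keep.sum() < min_points:
            order = np.argsort(t)
            new_keep = np.zeros_like(keep)
            new_keep[order[:min_points]] = True
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep

    reg = stats.linregress(t[keep], y[keep])
    se_fcr = float(reg.stderr) / denom if reg.stderr is not None else float("nan")
    dof = max(int(keep.sum()) - 2, 1)
    tq = stats.t.ppf(0.975, dof)
    return KineticFit(
        analyte=curve.analyte,
        subject=curve.subject,
        ok=True,
        k=fcr,
        e_as=float("nan"),
        r_squared=float(reg.rvalue) ** 2,
        ci_k=(fcr - tq * se_fcr, fcr + tq * se_fcr),
        half_life_h=half_life(fcr),
        residence_time_d=residence_time(fcr),
        method="precursor_product",
        n_points_used=int(keep.sum()),
    )


def select_method(
    curve: LabelingCurve,
    preliminary: KineticFit,
    study_duration_d: float = 7.0,
) -> str:
    """Choose the fitting route for a protein.

    The precursor-product route is selected when the preliminary
    exponential fit indicates a half-life longer than the labeling window
    (plateau unreachable) or an unidentifiable plateau (failed fit, or a
    k confidence interval spanning zero); otherwise the exponential fit
    stands.
    """
    if not preliminary.ok:
        return "precursor_product"
    if preliminary.half_life_h / HOURS_PER_DAY > study_duration_d:
        return "precursor_product"
    lo, hi = preliminary.ci_k
    if np.isfinite(lo) and lo <= 0:
        return "precursor_product"
    return "exponential"


# ---------------------------------------------------------------------------
# derived quantities


def half_life(k_per_day: float) -> float:
    """Half-life in hours from a rate constant in pools/day: 24 ln2 / k."""
    if k_per_day <= 0:
        raise InvalidParameterError("rate constant must be positive")
    return HOURS_PER_DAY * math.log(2.0) / k_per_day


def residence_time(k_per_day: float) -> float:
    """Mean residence time in days: 1/k."""
    if k_per_day <= 0:
        raise InvalidParameterError("rate constant must be positive")
    return 1.0 / k_per_day


def cholesterol_flux(subject: SubjectRecord, fit: KineticFit) -> FluxResult:
    """Pool size and production rate of HDL cholesterol for one subject.

    Plasma volume is 4.5% of body weight; the circulating pool is
    ``[HDL-C] (mg/dL) * plasma volume * 10`` mg, i.e. per kilogram
    ``0.45 * [HDL-C]`` mg/kg, and ``PR = pool * FCR`` (mg/kg/day).
    """
    if not fit.ok:
        raise MissingDataError("cannot derive flux from a failed kinetic fit")
    weight = subject.weight_kg
    hdlc = subject.hdl_cholesterol_mg_dl
    if not (weight and weight > 0) or math.isnan(weight):
        raise MissingDataError(f"subject {subject.id}: missing body weight")
    if hdlc is None or math.isnan(hdlc):
        raise MissingDataError(f"subject {subject.id}: missing HDL cholesterol")
    plasma_volume_l = PLASMA_VOLUME_FRACTION * weight
    pool_mg = hdlc * plasma_volume_l * 10.0  # mg/dL * L * 10 dL/L
    pool_size = pool_mg / weight
    return FluxResult(
        subject=subject.id,
        pool_size_mg_kg=pool_size,
        fcr_per_day=fit.k,
        pr_mg_kg_day=pool_size * fit.k,
        plasma_volume_l=plasma_volume_l,
    )
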