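"""Synthetic heavy-water labeling studies with known ground truth.

Everything downstream of the mass spectrometer is simulated here: a
cohort of control and type-2-diabetic subjects with Table-1-like
covariates, per-subject body-water deuterium enrichment under the
loading/maintenance dosing protocol, peptide isotopomer time courses,
HDL-cholesterol enrichment curves, and the acetone GC-MS calibration
series.  Every generator is seeded and returns plain pandas/numpy
objects, so the full pipeline can be exercised end-to-end against known
true kinetic parameters.

Model summary
-------------
* Body water is a single well-mixed pool with first-order turnover;
  doses are instantaneous boluses (five hourly loading doses, then one
  maintenance dose per day taken an hour before the daily blood draw).
* A peptide's spectrum at time t is the mixture
  ``(1-f(t)) * baseline + f(t) * labeled`` with newly-synthesized
  fraction ``f(t) = 1 - exp(-k t)``; the labeled MID is the baseline
  convolved with a generalized-binomial deuterium distribution over the
  peptide's N exchangeable hydrogens at the body-water plateau.
* Between-subject variation of true rate constants is lognormal
  (keeps k > 0); measurement noise is additive Gaussian on enrichment.
* Covariates come from a Gaussian copula over piecewise-linear marginal
  quantile maps pinned at each group's (min, median, max).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm as _norm

from . import isotopes
from .constants import HOURS_PER_DAY
from .errors import (
    DegenerateCalibrationError,
    InvalidParameterError,
)

__all__ = [
    "StudyDesign",
    "GroundTruth",
    "SubjectRecord",
    "simulate_body_water",
    "plateau_mpe",
    "simulate_cohort",
    "simulate_peptide_timecourse",
    "simulate_cholesterol_timecourse",
    "simulate_acetone_calibration",
    "generate_study",
    "write_study",
]

#: Blood sampling schedule of the one-week protocol, in hours.
DEFAULT_SAMPLE_TIMES_H = (0, 2, 4, 5, 6, 7, 8, 10, 24, 48, 96, 168)


# ---------------------------------------------------------------------------
# design and truth containers


@dataclass
class StudyDesign:
    """Dosing and sampling protocol of a labeling study."""

    n_control: int = 8
    n_t2d: int = 9
    sample_times_h: tuple[float, ...] = DEFAULT_SAMPLE_TIMES_H
    loading_dose_ml_per_kg: float = 4.0
    dose_fraction_2h2o: float = 0.70
    n_loading_doses: int = 5
    maintenance_fraction_per_day: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.sample_times_h)
        if len(times) < 2 or times[0] != 0.0:
            raise InvalidParameterError("sample_times_h must start at 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidParameterError("sample_times_h must be strictly increasing")
        self.sample_times_h = times
        for name in ("dose_fraction_2h2o", "maintenance_fraction_per_day"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise InvalidParameterError(f"{name} must lie in (0, 1]")
        if self.loading_dose_ml_per_kg < 0:
            raise InvalidParameterError("loading dose must be >= 0")
        if self.n_loading_doses < 1:
            raise InvalidParameterError("need at least one loading dose")

    @property
    def sample_times_d(self) -> np.ndarray:
        return np.asarray(self.sample_times_h, dtype=float) / HOURS_PER_DAY

    @property
    def duration_d(self) -> float:
        return self.sample_times_h[-1] / HOURS_PER_DAY


@dataclass
class ProteinTruth:
    """True kinetics of one HDL protein, per group."""

    accession: str
    name: str
    half_life_h: dict[str, float]
    half_life_sd_h: dict[str, float]
    peptides: list[str]
    hba1c_slope_per_h: float | None = None
    slow: bool = False

    def k_per_day(self, group: str) -> float:
        return math.log(2.0) * HOURS_PER_DAY / self.half_life_h[group]

    def k_cv(self, group: str) -> float:
        return self.half_life_sd_h[group] / self.half_life_h[group]


@dataclass
class GroundTruth:
    """Generating parameters of a synthetic study.

    The shipped defaults (``GroundTruth.default()``) encode the reference
    study conditions: group kinetic values, covariate marginals and the
    covariate/kinetics coupling structure.  ``between_subject_cv``
    overrides the per-protein, table-derived lognormal CV when set.
    """

    cholesterol: dict[str, Any]
    proteins: dict[str, ProteinTruth]
    subjects: dict[str, dict[str, Any]]
    correlations: dict[str, float] = field(default_factory=dict)
    peptide_plateau_range: tuple[float, float] = (0.02, 0.06)
    noise_sd_frac: float = 0.05
    between_subject_cv: float | None = None

    def __post_init__(self) -> None:
        for key, r in self.correlations.items():
            if abs(r) > 1.0:
                raise InvalidParameterError(
                    f"correlation {key}={r} is unsatisfiable (|r| > 1)"
                )
        lo, hi = self.peptide_plateau_range
        if not 0 < lo <= hi < 1:
            raise InvalidParameterError("peptide plateau range must be within (0,1)")
        if self.noise_sd_frac < 0:
            raise InvalidParameterError("noise SD must be >= 0")
        if self.between_subject_cv is not None and self.between_subject_cv < 0:
            raise InvalidParameterError("between-subject CV must be >= 0")
        for prot in self.proteins.values():
            for group, hl in prot.half_life_h.items():
                if hl <= 0:
                    raise InvalidParameterError(
                        f"{prot.accession}/{group}: half-life must be > 0"
                    )

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "GroundTruth":
        proteins = {
            acc: ProteinTruth(
                accession=acc,
                name=spec["name"],
                half_life_h=dict(spec["half_life_h"]),
                half_life_sd_h=dict(spec["half_life_sd_h"]),
                peptides=list(spec["peptides"]),
                hba1c_slope_per_h=spec.get("hba1c_slope_per_h"),
                slow=bool(spec.get("slow", False)),
            )
            for acc, spec in raw["proteins"].items()
        }
        return cls(
            cholesterol=dict(raw["cholesterol"]),
            proteins=proteins,
            subjects={g: dict(v) for g, v in raw["subjects"].items()},
            correlations=dict(raw.get("correlations", {})),
            peptide_plateau_range=tuple(raw.get("peptide_plateau_range", (0.02, 0.06))),
            noise_sd_frac=float(raw.get("noise_sd_frac", 0.05)),
            between_subject_cv=raw.get("between_subject_cv"),
        )

    @classmethod
    def from_yaml(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "GroundTruth":
        ref = importlib.resources.files("hdlflux.data") / "default_study.yaml"
        return cls.from_mapping(yaml.safe_load(ref.read_text()))


@dataclass
class SubjectRecord:
    """One participant: group label, anthropometrics, clinical chemistry."""

    id: str
    group: str
    weight_kg: float
    bmi_kg_m2: float = float("nan")
    hba1c_percent: float = float("nan")
    glucose_mg_dl: float = float("nan")
    insulin_miu_l: float = float("nan")
    adiponectin_ug_ml: float = float("nan")
    lcat_activity: float = float("nan")
    cetp_activity_pmol_ml_min: float = float("nan")
    hdl_cholesterol_mg_dl: float = float("nan")
    proinflammatory_index: float = float("nan")

    def __post_init__(self) -> None:
        if self.group not in ("control", "t2d"):
            raise InvalidParameterError(f"unknown group {self.group!r}")
        if not self.weight_kg > 0 and not math.isnan(self.weight_kg):
            raise InvalidParameterError("weight must be positive")

    @classmethod
    def from_series(cls, row: pd.Series) -> "SubjectRecord":
        fields = {f.name for f in dataclasses.fields(cls)}
        data = {k: row[k] for k in fields if k in row.index}
        data["id"] = str(row.get("subject_id", row.get("id")))
        return cls(**data)


# ---------------------------------------------------------------------------
# body water


def simulate_body_water(
    design: StudyDesign,
    weight_kg: float,
    tbw_fraction: float = 0.35,
    water_turnover_per_day: float = 0.10,
    times_h: Sequence[float] | None = None,
) -> pd.Series:
    """Body-water deuterium enrichment (MPE fraction) at the sample times.

    One well-mixed pool of size ``tbw_fraction * weight`` litres with
    first-order turnover.  Loading boluses fall at hours 0..n-1; a dose
    taken at time ``t_d`` contributes to samples strictly after ``t_d``,
    so the t=0 draw is a clean pre-dose baseline.  Maintenance doses
    (a fixed fraction of the loading volume per day) are taken one hour
    before each daily draw, mirroring the protocol's evening dose before
    the fasted morning sample.

    With maintenance exactly offsetting turnover the plateau equals
    ``loading_volume * dose_fraction / TBW`` — pure mass balance.
    """
    if weight_kg <= 0:
        raise InvalidParameterError("weight must be positive")
    if water_turnover_per_day < 0:
        raise InvalidParameterError("water turnover must be >= 0")
    if not 0.2 < tbw_fraction < 0.7:
        raise InvalidParameterError("total-body-water fraction must lie in (0.2, 0.7)")

    times = np.asarray(
        design.sample_times_h if times_h is None else times_h, dtype=float
    )
    tbw_ml = tbw_fraction * weight_kg * 1000.0
    loading_total_ml = (
        design.loading_dose_ml_per_kg * weight_kg * design.dose_fraction_2h2o
    )
    doses: list[tuple[float, float]] = [
        (float(h), loading_total_ml / design.n_loading_doses)
        for h in range(design.n_loading_doses)
    ]
    maintenance_ml = design.maintenance_fraction_per_day * loading_total_ml
    t_max = float(times.max())
    day = 1
    while 24.0 * day - 1.0 < t_max:
        doses.append((24.0 * day - 1.0, maintenance_ml))
        day += 1

    rate_per_h = water_turnover_per_day / HOURS_PER_DAY
    enrichment = np.zeros_like(times)
    for t_dose, amount in doses:
        active = times > t_dose
        enrichment[active] += (amount / tbw_ml) * np.exp(
            -rate_per_h * (times[active] - t_dose)
        )
    return pd.Series(enrichment, index=pd.Index(times, name="time_h"), name="mpe")


def plateau_mpe(body_water: pd.Series | float, min_time_h: float = 5.0) -> float:
    """Post-loading body-water enrichment: time-averaged MPE after the
    loading phase (scalar inputs pass through)."""
    if np.isscalar(body_water):
        return float(body_water)
    series = pd.Series(body_water)
    post = series[series.index.astype(float) >= min_time_h]
    if post.empty:
        raise InvalidParameterError("no samples after the loading phase")
    return float(post.mean())


# ---------------------------------------------------------------------------
# cohort


def _quantile_map(u: np.ndarray, lo: float, med: float, hi: float) -> np.ndarray:
    """Piecewise-linear quantile function through (0,lo), (0.5,med), (1,hi)."""
    u = np.asarray(u, dtype=float)
    lower = lo + 2.0 * u * (med - lo)
    upper = med + 2.0 * (u - 0.5) * (hi - med)
    return np.where(u < 0.5, lower, upper)


def _coupled_normal(rng, base: np.ndarray, r: float) -> np.ndarray:
    return r * base + math.sqrt(1.0 - r * r) * rng.standard_normal(base.size)


def _lognormal_factor(rng, cv: float, n: int) -> np.ndarray:
    """Mean-one multiplicative lognormal spread with coefficient of variation cv."""
    if cv <= 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def simulate_cohort(
    design: StudyDesign,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort and its per-subject true kinetic parameters.

    Returns ``(subjects, true_kinetics)``.  Covariates follow a Gaussian
    copula: latent standard normals with the configured structural
    couplings (HbA1c and insulin on glucose; LCAT inversely on glucose;
    CETP inversely on adiponectin within the T2D group), pushed through
    each group's piecewise-linear marginal quantile map so the group
    medians land on their configured targets.

    True rate constants: proteins with an HbA1c coupling follow one
    global line, ``k/h = k_control/h + slope * (HbA1c - control median)``
    — which reproduces both the regression slope and the group contrast —
    times a mean-one lognormal between-subject factor; all other analytes
    are lognormal around their group value.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    n_by_group = {"control": design.n_control, "t2d": design.n_t2d}
    for group, n in n_by_group.items():
        if n < 2:
            raise InvalidParameterError(f"need >= 2 subjects per group ({group})")

    corr = truth.correlations
    subj_rows: list[dict[str, Any]] = []
    kin_rows: list[dict[str, Any]] = []
    control_hba1c_median = truth.subjects["control"]["marginals"]["hba1c_percent"][0]

    counter = 1
    for group in ("control", "t2d"):
        n = n_by_group[group]
        marg = truth.subjects[group]["marginals"]

        z_glucose = rng.standard_normal(n)
        z_adiponectin = rng.standard_normal(n)
        z = {
            "glucose_mg_dl": z_glucose,
            "hba1c_percent": _coupled_normal(rng, z_glucose, corr.get("hba1c_glucose", 0.0)),
            "insulin_miu_l": _coupled_normal(rng, z_glucose, corr.get("insulin_glucose", 0.0)),
            "lcat_activity": _coupled_normal(rng, z_glucose, corr.get("lcat_glucose", 0.0)),
            "adiponectin_ug_ml": z_adiponectin,
            "cetp_activity_pmol_ml_min": _coupled_normal(
                rng,
                z_adiponectin,
                corr.get("cetp_adiponectin_t2d", 0.0) if group == "t2d" else 0.0,
            ),
        }
        values: dict[str, np.ndarray] = {}
        for var, (med, lo, hi) in marg.items():
            u = _norm.cdf(z[var]) if var in z else rng.uniform(size=n)
            values[var] = _quantile_map(u, lo, med, hi)

        ids = [f"S{counter + i:02d}" for i in range(n)]
        counter += n
        for i, sid in enumerate(ids):
            subj_rows.append(
                {"subject_id": sid, "group": group}
                | {var: float(values[var][i]) for var in marg}
            )

        # --- true kinetics
        chol = truth.cholesterol
        chol_k = chol["fcr_per_day"][group]
        chol_cv = (
            truth.between_subject_cv
            if truth.between_subject_cv is not None
            else chol["fcr_sd_per_day"][group] / chol_k
        )
        chol_ks = chol_k * _lognormal_factor(rng, chol_cv, n)
        for sid, k in zip(ids, chol_ks):
            kin_rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "analyte": "HDL-C",
                    "true_k_per_day": float(k),
                    "true_e_as": float(chol["e_as"]),
                }
            )

        for acc, prot in truth.proteins.items():
            cv = (
                truth.between_subject_cv
                if truth.between_subject_cv is not None
                else prot.k_cv(group)
            )
            if prot.hba1c_slope_per_h is not None:
                k_ctrl_h = math.log(2.0) / prot.half_life_h["control"]
                hba1c = values["hba1c_percent"]
                base = HOURS_PER_DAY * (
                    k_ctrl_h
                    + prot.hba1c_slope_per_h * (hba1c - control_hba1c_median)
                )
            else:
                base = np.full(n, prot.k_per_day(group))
            ks = np.maximum(base, 1e-4) * _lognormal_factor(rng, cv, n)
            for sid, k in zip(ids, ks):
                kin_rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "analyte": acc,
                        "true_k_per_day": float(k),
                        "true_e_as": float("nan"),
                    }
                )

    return pd.DataFrame(subj_rows), pd.DataFrame(kin_rows)


# ---------------------------------------------------------------------------
# peptide and cholesterol time courses


def _label_increment_distribution(
    n_exchangeable: float, p: float, n_peaks: int
) -> np.ndarray:
    """Distribution of deuterium count in a newly synthesized peptide.

    Generalized binomial over a real-valued number of sites N: term j is
    ``C(N,j) p^j (1-p)^(N-j)`` with the generalized binomial coefficient,
    so the unlabeled fraction is exactly ``(1-p)^N``.  Truncated to
    ``n_peaks`` terms and renormalized (the tail is O(p^n_peaks)).
    """
    coef = np.ones(n_peaks)
    for j in range(1, n_peaks):
        coef[j] = coef[j - 1] * (n_exchangeable - (j - 1)) / j
    js = np.arange(n_peaks)
    dist = np.clip(coef, 0.0, None) * p**js * (1.0 - p) ** (n_exchangeable - js)
    return dist / dist.sum()


def simulate_peptide_timecourse(
    sequence: str,
    body_water: pd.Series | float,
    true_k_per_day: float,
    design: StudyDesign,
    noise_sd: float = 0.05,
    rng: np.random.Generator | None = None,
    *,
    n_peaks: int = 6,
    n_replicates: int = 2,
    intensity_range: tuple[float, float] = (1e6, 1e7),
    id_score_range: tuple[float, float] = (40.0, 95.0),
    exchangeable_table: Mapping[str, float] | None = None,
    carbamidomethyl: bool = False,
) -> list[isotopes.IsotopomerSpectrum]:
    """Isotopomer spectra of one peptide over the sampling schedule.

    ``noise_sd`` is the Gaussian SD of enrichment noise as a fraction of
    the plateau M0 depletion; ``body_water`` may be the enrichment series
    (its post-loading plateau is used) or a scalar MPE fraction.  At t=0
    the noiseless spectrum is the peptide's natural-abundance MID; M0
    then decays toward ``A0 * (1-p)^N`` with one-compartment kinetics.
    Total intensities are drawn log-uniformly inside the QC window.
    """
    if true_k_per_day <= 0:
        raise InvalidParameterError("true rate constant must be positive")
    if noise_sd < 0:
        raise InvalidParameterError("noise SD must be >= 0")
    if rng is None:
        rng = np.random.default_rng(design.seed)

    baseline = isotopes.peptide_baseline_mid(sequence, n_peaks, carbamidomethyl)
    n_ex = isotopes.exchangeable_hydrogens(sequence, exchangeable_table)
    p = plateau_mpe(body_water)
    if p > 0:
        increment = _label_increment_distribution(n_ex, p, n_peaks)
        labeled = np.convolve(baseline, increment)
        tail = labeled[n_peaks:].sum()
        labeled = labeled[:n_peaks]
        labeled[-1] += tail  # keep unit mass without rescaling M0
    else:
        labeled = baseline.copy()
    e_max = baseline[0] - labeled[0]

    spectra: list[isotopes.IsotopomerSpectrum] = []
    for t_h, t_d in zip(design.sample_times_h, design.sample_times_d):
        f = 1.0 - math.exp(-true_k_per_day * t_d)
        clean = (1.0 - f) * baseline + f * labeled
        for rep in range(1, n_replicates + 1):
            spec = clean.copy()
            if noise_sd > 0 and e_max > 0:
                eps = rng.normal(0.0, noise_sd * e_max)
                spec[0] -= eps
                spec[1] += eps
                spec = np.clip(spec, 0.0, None)
                spec /= spec.sum()
            intensity = math.exp(
                rng.uniform(math.log(intensity_range[0]), math.log(intensity_range[1]))
            )
            score = rng.uniform(*id_score_range)
            spectra.append(
                isotopes.IsotopomerSpectrum(
                    time_h=float(t_h),
                    abundances=spec,
                    total_intensity=intensity,
                    id_score=score,
                    replicate=rep,
                )
            )
    return spectra


def simulate_cholesterol_timecourse(
    true_k_per_day: float,
    e_as: float,
    design: StudyDesign,
    noise_sd: float = 0.05,
    rng: np.random.Generator | None = None,
    n_replicates: int = 2,
) -> pd.DataFrame:
    """HDL-cholesterol net enrichment curve E(t) = E_as (1 - e^{-kt}) + noise.

    ``noise_sd`` is a fraction of the plateau E_as.  Columns:
    ``time_h, replicate, enrichment``.
    """
    if true_k_per_day < 0:
        raise InvalidParameterError("rate constant must be >= 0")
    if not 0 < e_as < 1:
        raise InvalidParameterError("plateau enrichment must lie in (0, 1)")
    if noise_sd < 0:
        raise InvalidParameterError("noise SD must be >= 0")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    rows = []
    for t_h, t_d in zip(design.sample_times_h, design.sample_times_d):
        clean = e_as * (1.0 - math.exp(-true_k_per_day * t_d))
        for rep in range(1, n_replicates + 1):
            value = clean + (rng.normal(0.0, noise_sd * e_as) if noise_sd else 0.0)
            rows.append(
                {"time_h": float(t_h), "replicate": rep, "enrichment": float(value)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# acetone calibration

#: Natural M1 fractional ratio and M2 fraction of acetone (C3H6O),
#: computed once from the isotope table.
_ACETONE_MID = isotopes.natural_isotope_distribution({"C": 3, "H": 6, "O": 1}, 4)
_ACETONE_R0 = float(_ACETONE_MID[1] / _ACETONE_MID[:3].sum())
_ACETONE_F2 = float(_ACETONE_MID[2] / _ACETONE_MID[:3].sum())


def simulate_acetone_calibration(
    levels_percent: Sequence[float] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0),
    response_slope: float = 0.0585,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    sample_levels_percent: Sequence[float] = (),
    base_intensity: float = 1e7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GC-MS SIM intensities (m/z 58/59/60) for standards and samples.

    The M1 fractional ratio is affine in the % 2H2O level with slope
    ``response_slope`` (six exchange-labile hydrogens give ~0.06 per
    percent) on top of acetone's natural ratio.  ``noise_sd`` is the
    relative SD applied to the ratio; injection volumes vary log-normally
    but cancel in the ratio.  Returns ``(calibration, samples)`` frames
    with columns ``level_percent, i58, i59, i60``.
    """
    levels = np.asarray(levels_percent, dtype=float)
    if np.any(levels < 0):
        raise InvalidParameterError("calibration levels must be non-negative")
    if np.unique(levels).size < 2:
        raise DegenerateCalibrationError("need >= 2 distinct calibration levels")
    if noise_sd < 0:
        raise InvalidParameterError("noise SD must be >= 0")
    if rng is None:
        rng = np.random.default_rng(0)

    def rows_for(level_values: np.ndarray) -> pd.DataFrame:
        rows = []
        for level in level_values:
            ratio = _ACETONE_R0 + response_slope * level
            if noise_sd > 0:
                ratio += rng.normal(0.0, noise_sd * ratio)
            total = base_intensity * math.exp(rng.normal(0.0, 0.05)) if noise_sd else base_intensity
            f2 = _ACETONE_F2
            rows.append(
                {
                    "level_percent": float(level),
                    "i58": total * (1.0 - ratio - f2),
                    "i59": total * ratio,
                    "i60": total * f2,
                }
            )
        return pd.DataFrame(rows)

    return rows_for(levels), rows_for(np.asarray(sample_levels_percent, dtype=float))


# ---------------------------------------------------------------------------
# full-study generation


def generate_study(
    design: StudyDesign,
    truth: GroundTruth | None = None,
    rng: np.random.Generator | None = None,
    tbw_fraction: float = 0.35,
    water_turnover_per_day: float = 0.10,
) -> dict[str, pd.DataFrame]:
    """One complete synthetic study: every table the pipeline ingests.

    Returns a dict with ``subjects``, ``true_kinetics``, ``body_water``,
    ``peptides`` (long isotopomer-intensity table), ``cholesterol`` and
    ``acetone`` (calibration + per-subject plasma rows).  Deterministic
    given ``design.seed``.
    """
    truth = truth or GroundTruth.default()
    if rng is None:
        rng = np.random.default_rng(design.seed)

    subjects, kinetics = simulate_cohort(design, truth, rng)
    noise = truth.noise_sd_frac

    bw_rows, pep_rows, chol_rows, sample_levels = [], [], [], []
    lo, hi = truth.peptide_plateau_range
    for _, subj in subjects.iterrows():
        sid = subj["subject_id"]
        bw = simulate_body_water(
            design, subj["weight_kg"], tbw_fraction, water_turnover_per_day
        )
        mpe = plateau_mpe(bw)
        sample_levels.append(mpe * 100.0)
        for t, v in bw.items():
            bw_rows.append({"subject_id": sid, "time_h": float(t), "mpe": float(v)})

        sub_kin = kinetics[kinetics["subject_id"] == sid].set_index("analyte")
        chol = simulate_cholesterol_timecourse(
            float(sub_kin.loc["HDL-C", "true_k_per_day"]),
            float(sub_kin.loc["HDL-C", "true_e_as"]),
            design,
            noise,
            rng,
        )
        chol.insert(0, "subject_id", sid)
        chol_rows.append(chol)

        for acc, prot in truth.proteins.items():
            k = float(sub_kin.loc[acc, "true_k_per_day"])
            for peptide in prot.peptides:
                # peptides of one protein share k; their raw plateaus
                # differ naturally through N and the baseline A0
                spectra = simulate_peptide_timecourse(
                    peptide, mpe, k, design, noise, rng
                )
                for spec in spectra:
                    intensities = spec.abundances * spec.total_intensity
                    pep_rows.append(
                        {
                            "subject_id": sid,
                            "accession": acc,
                            "protein": prot.name,
                            "peptide": peptide,
                            "charge": 2,
                            "time_h": spec.time_h,
                            "replicate": spec.replicate,
                            **{
                                f"i_m{i}": float(x)
                                for i, x in enumerate(intensities)
                            },
                            "total_intensity": spec.total_intensity,
                            "id_score": spec.id_score,
                        }
                    )

    calib, samples = simulate_acetone_calibration(
        noise_sd=min(noise, 0.01) if noise else 0.0,
        rng=rng,
        sample_levels_percent=sample_levels,
    )
    samples.insert(0, "subject_id", list(subjects["subject_id"]))

    return {
        "subjects": subjects,
        "true_kinetics": kinetics,
        "body_water": pd.DataFrame(bw_rows),
        "peptides": pd.DataFrame(pep_rows),
        "cholesterol": pd.concat(chol_rows, ignore_index=True),
        "acetone_calibration": calib,
        "acetone_samples": samples,
    }


def write_study(tables: Mapping[str, pd.DataFrame], outdir) -> None:
    """Write every study table as an uncompressed UTF-8 CSV."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, frame in tables.items():
        frame.to_csv(out / f"{name}.csv", index=False)
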