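"""Isotopomer spectra to deuterium enrichment.

This module holds the mass-isotopomer arithmetic of the heavy-water
labeling method:

* theoretical natural-abundance isotopomer distributions (MIDs) from a
  peptide's elemental composition, by iterated convolution of per-element
  isotope vectors;
* the exchangeable-hydrogen count ``N`` of a peptide;
* net deuterium labeling ``E(t)`` as depletion of the monoisotopic (M0)
  relative abundance against the pre-dose baseline;
* the plateau labeling implied by ``N`` deuterium sites at a given
  body-water enrichment; and
* body-water enrichment from the acetone-exchange GC-MS calibration
  (selected ion monitoring at m/z 58/59/60).

Enrichment convention
---------------------
Net labeling is defined as ``E(t) = A0(baseline) - A0(t)``: newly made
molecules carry deuterium, which moves intensity out of the monoisotopic
peak, so M0 depletion grows in proportion to the newly synthesized
fraction.  At isotopic steady state a peptide with ``N`` exchangeable
hydrogens at water enrichment ``p`` retains the fraction ``(1-p)^N`` of
its baseline M0 abundance, giving the plateau
``E_max = A0 * (1 - (1-p)^N)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pyteomics_mass
from scipy import stats as _scipy_stats

from .constants import (
    CARBAMIDOMETHYL,
    EXCHANGEABLE_H,
    ISOTOPE_ABUNDANCES,
    STANDARD_RESIDUES,
)
from .errors import (
    ConfigurationError,
    DegenerateCalibrationError,
    InvalidInputError,
    InvalidParameterError,
    InvalidSequenceError,
    MissingDataError,
)

__all__ = [
    "IsotopomerSpectrum",
    "BodyWaterCalibration",
    "elemental_composition",
    "natural_isotope_distribution",
    "exchangeable_hydrogens",
    "net_labeling",
    "plateau_labeling",
    "body_water_enrichment",
    "average_duplicates",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class IsotopomerSpectrum:
    """Relative isotopomer abundances of one peptide at one time point.

    ``abundances[i]`` is the relative abundance of the M_i peak.  Raw total
    intensity and the search-engine identification score ride along for QC.
    """

    time_h: float
    abundances: np.ndarray
    total_intensity: float = float("nan")
    id_score: float = float("nan")
    replicate: int = 1

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.ndim != 1 or self.abundances.size < 2:
            raise InvalidInputError("spectrum needs at least two isotopomer peaks")
        if np.any(self.abundances < -1e-12):
            raise InvalidInputError("isotopomer abundances must be non-negative")

    def normalized(self) -> "IsotopomerSpectrum":
        total = float(self.abundances.sum())
        if total <= 0:
            raise InvalidInputError("cannot normalize an all-zero spectrum")
        return IsotopomerSpectrum(
            self.time_h,
            self.abundances / total,
            self.total_intensity,
            self.id_score,
            self.replicate,
        )

    @property
    def a0(self) -> float:
        """Monoisotopic relative abundance after normalization."""
        return float(self.abundances[0] / self.abundances.sum())


@dataclass
class BodyWaterCalibration:
    """Acetone GC-MS calibration line and the sample enrichments read off it.

    The M1 fractional ratio ``R = I59/(I58+I59+I60)`` is affine in the
    calibration level (% 2H2O); ``sample_mpe`` holds molar-percent-excess
    values as *fractions* (0.0085 == 0.85%).
    """

    slope: float
    intercept: float
    r_squared: float
    sample_mpe: np.ndarray = field(default_factory=lambda: np.array([]))

    def mpe_from_ratio(self, ratio: float | np.ndarray) -> np.ndarray:
        """Invert the calibration line; result floored at zero, as a fraction."""
        level_percent = (np.asarray(ratio, dtype=float) - self.intercept) / self.slope
        return np.maximum(level_percent, 0.0) / 100.0


# ---------------------------------------------------------------------------
# composition and distributions


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise InvalidSequenceError("empty peptide sequence")
    bad = set(sequence) - STANDARD_RESIDUES
    if bad:
        raise InvalidSequenceError(
            f"non-standard residue(s) {sorted(bad)} in peptide {sequence!r}"
        )


def elemental_composition(
    sequence: str, carbamidomethyl: bool = False
) -> dict[str, int]:
    """Elemental composition (C,H,N,O,S counts) of an intact peptide.

    The composition is the residue sum minus one water per peptide bond,
    i.e. the neutral peptide including its terminal H and OH.  With
    ``carbamidomethyl=True`` every cysteine carries the +C2H3NO
    iodoacetamide adduct (the fixed modification of the workflow).
    """
    _validate_sequence(sequence)
    comp = _pyteomics_mass.Composition(sequence=sequence)
    out = {el: int(comp.get(el, 0)) for el in ("C", "H", "N", "O", "S")}
    if carbamidomethyl:
        n_cys = sequence.count("C")
        for el, n in CARBAMIDOMETHYL.items():
            out[el] = out.get(el, 0) + n * n_cys
    return {el: n for el, n in out.items() if n > 0}


def _vector_power(base: np.ndarray, n: int) -> np.ndarray:
    """n-fold self-convolution by binary exponentiation."""
    result = np.array([1.0])
    acc = base
    while n:
        if n & 1:
            result = np.convolve(result, acc)
        n >>= 1
        if n:
            acc = np.convolve(acc, acc)
    return result


def natural_isotope_distribution(
    composition: Mapping[str, int],
    n_peaks: int = 6,
    abundances: Mapping[str, Sequence[float]] | None = None,
) -> np.ndarray:
    """Natural-abundance MID of an elemental composition.

    Convolves per-element isotope vectors (each element's vector raised to
    its atom count).  Returns the first ``n_peaks`` relative abundances
    A_0..A_{n-1}; the truncated tail means they sum to <= 1.
    """
    if n_peaks < 2:
        raise InvalidParameterError("n_peaks must be >= 2")
    table = dict(ISOTOPE_ABUNDANCES if abundances is None else abundances)
    total_atoms = sum(int(n) for n in composition.values())
    if total_atoms <= 0:
        raise InvalidParameterError("empty elemental composition")
    dist = np.array([1.0])
    for element, count in composition.items():
        count = int(count)
        if count < 0:
            raise InvalidParameterError(f"negative atom count for {element}")
        if count == 0:
            continue
        if element not in table:
            raise ConfigurationError(f"no isotope abundances for element {element}")
        dist = np.convolve(dist, _vector_power(np.asarray(table[element], float), count))
    out = np.zeros(n_peaks)
    k = min(n_peaks, dist.size)
    out[:k] = dist[:k]
    return out


def peptide_baseline_mid(
    sequence: str, n_peaks: int = 6, carbamidomethyl: bool = False
) -> np.ndarray:
    """Normalized natural-abundance MID of a peptide (sums to 1 over n_peaks)."""
    mid = natural_isotope_distribution(
        elemental_composition(sequence, carbamidomethyl), n_peaks
    )
    return mid / mid.sum()


def exchangeable_hydrogens(
    sequence: str, table: Mapping[str, float] | None = None
) -> float:
    """Asymptotic deuterium number N of a peptide: sum of residue values.

    Additive over concatenation by construction.  A residue absent from a
    user-supplied table is a configuration error, not a sequence error.
    """
    _validate_sequence(sequence)
    tab = EXCHANGEABLE_H if table is None else table
    try:
        return float(sum(tab[aa] for aa in sequence))
    except KeyError as exc:
        raise ConfigurationError(
            f"residue {exc.args[0]!r} missing from exchangeable-hydrogen table"
        ) from None


# ---------------------------------------------------------------------------
# enrichment


def net_labeling(
    observed: IsotopomerSpectrum, baseline: IsotopomerSpectrum
) -> float:
    """Net deuterium labeling E(t) = A0(baseline) - A0(t).

    Both spectra are normalized internally, so arbitrary intensity scales
    are fine; they must cover the same number of isotopomer peaks.
    Negative values (measurement noise around t=0) are returned as-is —
    clipping for plateau normalization happens at aggregation time.
    """
    if observed.abundances.size != baseline.abundances.size:
        raise InvalidInputError(
            "observed and baseline spectra have different peak counts "
            f"({observed.abundances.size} vs {baseline.abundances.size})"
        )
    return baseline.a0 - observed.a0


def plateau_labeling(baseline_a0: float, n_exchangeable: float, mpe: float) -> float:
    """Asymptotic M0 depletion E_max = A0 * (1 - (1-p)^N).

    ``mpe`` is the body-water deuterium enrichment as a fraction.  For
    small ``mpe`` this linearizes to ``A0 * N * mpe`` — the form used by
    the precursor-product flux equation.
    """
    if n_exchangeable < 0:
        raise InvalidParameterError("N must be >= 0")
    if not 0 <= mpe <= 0.05:
        raise InvalidParameterError("body-water MPE must lie in [0, 0.05]")
    return float(baseline_a0 * (1.0 - (1.0 - mpe) ** n_exchangeable))


# ---------------------------------------------------------------------------
# body-water calibration


def _m1_ratio(frame: pd.DataFrame) -> np.ndarray:
    total = frame["i58"] + frame["i59"] + frame["i60"]
    return (frame["i59"] / total).to_numpy(dtype=float)


def body_water_enrichment(
    calibration: pd.DataFrame, samples: pd.DataFrame
) -> BodyWaterCalibration:
    """Fit the acetone calibration line and read sample MPEs off it.

    ``calibration`` needs columns ``level_percent, i58, i59, i60``;
    ``samples`` needs ``i58, i59, i60``.  The fit is ordinary least
    squares of the M1 fractional ratio on the % 2H2O level — the
    fractional ratio cancels injection-volume variation.  Sample MPE is
    ``(ratio - intercept)/slope``, floored at zero, returned as fraction.
    """
    levels = np.asarray(calibration["level_percent"], dtype=float)
    if np.unique(levels).size < 2:
        raise DegenerateCalibrationError(
            "calibration requires at least two distinct 2H2O levels"
        )
    ratios = _m1_ratio(calibration)
    fit = _scipy_stats.linregress(levels, ratios)
    result = BodyWaterCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
    )
    if len(samples):
        result.sample_mpe = result.mpe_from_ratio(_m1_ratio(samples))
    return result


def average_duplicates(
    values: Iterable[float], max_relative_difference: float = 0.02
) -> tuple[float, bool]:
    """Average duplicate injections with the 2%-agreement check.

    Returns ``(mean, flagged)``.  One replicate passes through unflagged;
    two replicates are flagged when their relative difference (absolute
    difference over absolute mean) exceeds ``max_relative_difference``.
    Flagged points are retained by callers — the flag is reported, never
    silently dropped.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise MissingDataError("no replicate values to average")
    if len(vals) > 2:
        raise InvalidInputError("at most two injection replicates expected")
    mean = float(np.mean(vals))
    if len(vals) == 1:
        return mean, False
    denom = abs(mean)
    if denom == 0.0:
        flagged = vals[0] != vals[1]
    else:
        flagged = abs(vals[0] - vals[1]) / denom > max_relative_difference
    return mean, flagged
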