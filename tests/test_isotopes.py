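"""Isotopomer math: compositions, distributions, enrichment, calibration."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdlflux import isotopes, synthetic
from hdlflux.constants import EXCHANGEABLE_H, ISOTOPE_ABUNDANCES
from hdlflux.errors import (
    ConfigurationError,
    DegenerateCalibrationError,
    InvalidInputError,
    InvalidParameterError,
    InvalidSequenceError,
    MissingDataError,
)


# ---------------------------------------------------------------------------
# elemental composition


@pytest.mark.parametrize(
    "sequence, cam, expected",
    [
        ("G", False, {"C": 2, "H": 5, "N": 1, "O": 2}),
        ("GG", False, {"C": 4, "H": 8, "N": 2, "O": 3}),
        # free cysteine C3H7NO2S plus the iodoacetamide adduct C2H3NO
        ("C", True, {"C": 5, "H": 10, "N": 2, "O": 3, "S": 1}),
    ],
)
def test_elemental_composition(sequence, cam, expected):
    assert isotopes.elemental_composition(sequence, carbamidomethyl=cam) == expected


def test_composition_monoisotopic_mass_crosscheck():
    """Composition agrees with published monoisotopic residue masses."""
    masses = {"C": 12.0, "H": 1.0078250319, "N": 14.0030740052, "O": 15.9949146221, "S": 31.97207069}
    comp = isotopes.elemental_composition("PEPTIDE")
    mass = sum(masses[el] * n for el, n in comp.items())
    assert mass == pytest.approx(799.35997, abs=1e-4)


def test_composition_rejects_unknown_residue():
    with pytest.raises(InvalidSequenceError):
        isotopes.elemental_composition("GAB")
    with pytest.raises(InvalidSequenceError):
        isotopes.elemental_composition("")


# ---------------------------------------------------------------------------
# natural isotope distribution vs exhaustive enumeration oracle


def _enumeration_mid(composition: dict[str, int], n_peaks: int) -> np.ndarray:
    """Independent oracle: exact multinomial enumeration per element,
    combined across elements with plain dictionaries (no convolution)."""

    def element_shifts(element: str, count: int) -> dict[int, float]:
        probs = ISOTOPE_ABUNDANCES[element]
        shifts: dict[int, float] = {}
        for combo in itertools.combinations_with_replacement(range(len(probs)), count):
            weight = math.factorial(count)
            for iso in range(len(probs)):
                k = combo.count(iso)
                weight = weight // math.factorial(k)
            prob = weight
            for iso in combo:
                prob *= probs[iso]
            shift = sum(combo)
            shifts[shift] = shifts.get(shift, 0.0) + prob
        return shifts

    total: dict[int, float] = {0: 1.0}
    for element, count in composition.items():
        if count == 0:
            continue
        nxt: dict[int, float] = {}
        for s1, p1 in total.items():
            for s2, p2 in element_shifts(element, count).items():
                nxt[s1 + s2] = nxt.get(s1 + s2, 0.0) + p1 * p2
        total = nxt
    return np.array([total.get(i, 0.0) for i in range(n_peaks)])


@pytest.mark.parametrize(
    "composition",
    [
        {"C": 1},
        {"H": 2},
        {"C": 4, "H": 8, "N": 2, "O": 3},  # diglycine
        {"C": 5, "H": 4, "N": 3, "O": 1, "S": 2},
        {"C": 10, "H": 5},
    ],
)
def test_mid_matches_enumeration_oracle(composition):
    """Convolution MID equals exhaustive enumeration for <=15 atoms."""
    expected = _enumeration_mid(composition, 6)
    got = isotopes.natural_isotope_distribution(composition, 6)
    assert np.allclose(got, expected, atol=1e-9)


def test_mid_single_elements():
    a = isotopes.natural_isotope_distribution({"C": 1}, 2)
    assert a == pytest.approx([0.9893, 0.0107])
    a = isotopes.natural_isotope_distribution({"H": 2}, 2)
    assert a[0] == pytest.approx(0.999885**2)
    assert a[1] == pytest.approx(2 * 0.999885 * 0.000115)


def test_mid_properties_and_errors():
    mid = isotopes.natural_isotope_distribution({"C": 30, "H": 50, "N": 8, "O": 12}, 6)
    assert np.all(mid >= 0) and mid.sum() <= 1.0 + 1e-12
    with pytest.raises(InvalidParameterError):
        isotopes.natural_isotope_distribution({}, 6)
    with pytest.raises(InvalidParameterError):
        isotopes.natural_isotope_distribution({"C": 2}, 1)


# ---------------------------------------------------------------------------
# exchangeable hydrogens


def test_exchangeable_hydrogens_examples():
    assert isotopes.exchangeable_hydrogens("AA", {"A": 4.0}) == pytest.approx(8.0)
    zeros = {aa: 0.0 for aa in EXCHANGEABLE_H}
    assert isotopes.exchangeable_hydrogens("GAVL", zeros) == 0.0
    # shipped table, independent hand sum
    expected = 2.06 + 4.00 + 0.56 + 0.60
    assert isotopes.exchangeable_hydrogens("GAVL") == pytest.approx(expected)


@settings(max_examples=50, deadline=None)
@given(
    s1=st.text(alphabet=sorted(EXCHANGEABLE_H), min_size=1, max_size=12),
    s2=st.text(alphabet=sorted(EXCHANGEABLE_H), min_size=1, max_size=12),
)
def test_exchangeable_hydrogens_additive(s1, s2):
    n12 = isotopes.exchangeable_hydrogens(s1 + s2)
    assert n12 == pytest.approx(
        isotopes.exchangeable_hydrogens(s1) + isotopes.exchangeable_hydrogens(s2)
    )


def test_exchangeable_hydrogens_missing_residue():
    with pytest.raises(ConfigurationError):
        isotopes.exchangeable_hydrogens("AG", {"A": 4.0})


# ---------------------------------------------------------------------------
# net labeling and plateau


def _spec(a0: float, n: int = 4, t: float = 0.0) -> isotopes.IsotopomerSpectrum:
    rest = (1.0 - a0) / (n - 1)
    return isotopes.IsotopomerSpectrum(t, [a0] + [rest] * (n - 1))


def test_net_labeling_subtraction():
    assert isotopes.net_labeling(_spec(0.57, t=24), _spec(0.60)) == pytest.approx(0.03)
    assert isotopes.net_labeling(_spec(0.60), _spec(0.60)) == pytest.approx(0.0)
    with pytest.raises(InvalidInputError):
        isotopes.net_labeling(_spec(0.5, n=5), _spec(0.5, n=4))


def test_net_labeling_plateau_identity():
    """A fully labeled synthetic spectrum reproduces the binomial plateau."""
    design = synthetic.StudyDesign(sample_times_h=(0.0, 24.0 * 100 / 0.2))
    seq, mpe = "VTDYGQDLK", 0.0085
    spectra = synthetic.simulate_peptide_timecourse(
        seq, mpe, 0.2, design, 0.0, np.random.default_rng(0), n_replicates=1
    )
    baseline, plateau = spectra[0], spectra[-1]
    n = isotopes.exchangeable_hydrogens(seq)
    expected = baseline.a0 * (1.0 - (1.0 - mpe) ** n)
    assert isotopes.net_labeling(plateau, baseline) == pytest.approx(expected, abs=1e-6)


def test_net_labeling_linear_in_new_fraction():
    """E is linear in the newly synthesized fraction (mixture property)."""
    design = synthetic.StudyDesign(sample_times_h=tuple(range(0, 2000, 100)))
    k = 0.1
    spectra = synthetic.simulate_peptide_timecourse(
        "SPELQAEAK", 0.0085, k, design, 0.0, np.random.default_rng(0), n_replicates=1
    )
    base = spectra[0]
    f_last = 1.0 - math.exp(-k * spectra[-1].time_h / 24.0)
    e_plateau = isotopes.net_labeling(spectra[-1], base) / f_last
    closed_form = isotopes.plateau_labeling(
        base.a0, isotopes.exchangeable_hydrogens("SPELQAEAK"), 0.0085
    )
    assert e_plateau == pytest.approx(closed_form, abs=1e-6)
    for spec in spectra[1:]:
        f = 1.0 - math.exp(-k * spec.time_h / 24.0)
        assert isotopes.net_labeling(spec, base) == pytest.approx(f * e_plateau, abs=1e-9)


@pytest.mark.parametrize(
    "a0, n, mpe, expected",
    [
        (0.6, 0.0, 0.0085, 0.0),
        (0.6, 10.0, 0.0, 0.0),
        (0.6, 10.0, 0.0085, 0.6 * (1 - 0.9915**10)),  # = 0.0491
    ],
)
def test_plateau_labeling(a0, n, mpe, expected):
    assert isotopes.plateau_labeling(a0, n, mpe) == pytest.approx(expected, abs=1e-9)


def test_plateau_labeling_bounds():
    with pytest.raises(InvalidParameterError):
        isotopes.plateau_labeling(0.6, -1.0, 0.0085)
    with pytest.raises(InvalidParameterError):
        isotopes.plateau_labeling(0.6, 10.0, 0.2)


# ---------------------------------------------------------------------------
# body-water calibration


def _calib_frame(levels, ratios, total=1e7):
    return pd.DataFrame(
        {
            "level_percent": levels,
            "i58": [total * (1 - r - 0.001) for r in ratios],
            "i59": [total * r for r in ratios],
            "i60": [total * 0.001 for r in ratios],
        }
    )


def test_body_water_affine_inversion():
    cal = _calib_frame([0.0, 5.0], [0.02, 0.07])
    samples = _calib_frame([0.0], [0.028])
    res = isotopes.body_water_enrichment(cal, samples)
    assert res.sample_mpe[0] == pytest.approx(0.008, abs=1e-12)  # 0.8%
    assert res.r_squared == pytest.approx(1.0)
    # ratio at the intercept reads back zero enrichment
    assert res.mpe_from_ratio(res.intercept)[()] == pytest.approx(0.0)


def test_body_water_round_trip_noiseless():
    cal, samples = synthetic.simulate_acetone_calibration(
        sample_levels_percent=[0.85, 2.5, 0.0]
    )
    res = isotopes.body_water_enrichment(cal, samples)
    assert np.allclose(res.sample_mpe, [0.0085, 0.025, 0.0], atol=1e-9)


def test_body_water_degenerate_calibration():
    cal = _calib_frame([2.0, 2.0], [0.03, 0.03])
    with pytest.raises(DegenerateCalibrationError):
        isotopes.body_water_enrichment(cal, cal.iloc[:0])


def test_body_water_unbiased_under_noise():
    """Mean recovery error stays below noise SD / sqrt(n) on simulations."""
    errors = []
    for seed in range(100):
        cal, samples = synthetic.simulate_acetone_calibration(
            noise_sd=0.01, rng=np.random.default_rng(seed), sample_levels_percent=[0.85]
        )
        res = isotopes.body_water_enrichment(cal, samples)
        errors.append(res.sample_mpe[0] * 100 - 0.85)
    assert abs(np.mean(errors)) < 0.01
    assert np.median(np.abs(errors)) < 0.03  # percentage points


# ---------------------------------------------------------------------------
# duplicate averaging


@pytest.mark.parametrize(
    "values, mean, flagged",
    [
        ((0.0300, 0.0302), 0.0301, False),
        ((0.030, 0.040), 0.035, True),  # 28.6% difference
        ((0.031,), 0.031, False),
    ],
)
def test_average_duplicates(values, mean, flagged):
    got_mean, got_flag = isotopes.average_duplicates(values)
    assert got_mean == pytest.approx(mean)
    assert got_flag is flagged


def test_average_duplicates_empty():
    with pytest.raises(MissingDataError):
        isotopes.average_duplicates([])
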