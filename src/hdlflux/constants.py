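"""Physical constants: natural isotope abundances and the exchangeable-
hydrogen table.

Isotope abundances follow the IUPAC 2021 representative values.  Each
element maps to a vector of relative abundances indexed by the nominal
mass shift (+0, +1, +2, ...) of its stable isotopes; peptides only need
C, H, N, O and S.

``EXCHANGEABLE_H`` is the residue-specific table of effective C-H
positions that equilibrate with body-water deuterium during protein
synthesis (values on the 0-4 scale widely used in heavy-water proteome
dynamics: Ala 4.0, Gly 2.06, Ser 2.61, ...).  The asymptotic deuterium
number N of a peptide is the sum over its residues.  Every operation that
consumes N accepts a user-supplied replacement table, so results can be
reproduced under alternative incorporation calibrations.
"""

from __future__ import annotations

# Relative isotopic abundances by nominal mass shift.
ISOTOPE_ABUNDANCES: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
}

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

# Effective exchangeable hydrogens per residue.
EXCHANGEABLE_H: dict[str, float] = {
    "A": 4.00,
    "R": 3.43,
    "N": 1.89,
    "D": 1.89,
    "C": 1.62,
    "E": 3.95,
    "Q": 3.95,
    "G": 2.06,
    "H": 2.88,
    "I": 1.00,
    "L": 0.60,
    "K": 0.54,
    "M": 1.12,
    "F": 0.32,
    "P": 2.59,
    "S": 2.61,
    "T": 0.20,
    "W": 0.08,
    "Y": 0.42,
    "V": 0.56,
}

#: Elemental formula of the carbamidomethyl adduct on cysteine
#: (iodoacetamide alkylation), added per modified residue.
CARBAMIDOMETHYL = {"C": 2, "H": 3, "N": 1, "O": 1}

#: Plasma volume as a fraction of body weight (L/kg).
PLASMA_VOLUME_FRACTION = 0.045

#: Hours per day; the package's internal kinetic time base is days.
HOURS_PER_DAY = 24.0
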