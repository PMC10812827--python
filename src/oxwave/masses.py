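"""Monoisotopic mass constants and peptide mass arithmetic.

All masses are monoisotopic and in Da. Residue masses come from pyteomics'
standard amino-acid table; modification deltas are computed from elemental
formulas so they agree with Unimod to the printed precision.
"""

from __future__ import annotations

import numpy as np
from pyteomics import mass as _pmass

#: residue (amino acid minus water) monoisotopic masses, one-letter codes
RESIDUE_MASS: dict[str, float] = dict(_pmass.std_aa_mass)

WATER = _pmass.calculate_mass(formula="H2O")

# modification deltas
OXIDATION = _pmass.calculate_mass(formula="O")          # +15.994915
DIOXIDATION = 2.0 * OXIDATION
TRIOXIDATION = 3.0 * OXIDATION
CARBAMIDOMETHYL = _pmass.calculate_mass(formula="C2H3NO")  # IAM tag, +57.021464
METHYLTHIO = _pmass.calculate_mass(formula="CH2S")         # MMTS tag, +45.987721
DEAMIDATION = _pmass.calculate_mass(formula="O") - _pmass.calculate_mass(formula="NH")

#: ΔM of a reversibly oxidized Cys when the search applies fixed
#: carbamidomethylation: the observed tag is methylthio instead.
METHYLTHIO_EXCHANGE = METHYLTHIO - CARBAMIDOMETHYL  # -11.033743

#: C13 - C12 spacing, the usual isotope-error artifact
ISOTOPE_SPACING = 1.00335484

#: TMT 10-plex reagent monoisotopic mass (N-terminus and Lys)
TMT10 = 229.162932

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def peptide_mass(peptide: str, *, tmt: bool = True, fixed_cys: float = CARBAMIDOMETHYL) -> float:
    """Monoisotopic mass of a tryptic peptide under the search's fixed
    modifications: TMT on the N-terminus and every Lys, and an alkylation
    tag on every Cys (carbamidomethyl by default, matching the open-search
    convention under which a methylthio Cys shows up as ΔM ≈ -11.0337).
    """
    m = WATER + sum(RESIDUE_MASS[aa] for aa in peptide)
    if tmt:
        m += TMT10 * (1 + peptide.count("K"))
    m += fixed_cys * peptide.count("C")
    return m


def peptide_masses(peptides, **kwargs) -> np.ndarray:
    """Vectorized :func:`peptide_mass` over an iterable of sequences."""
    return np.array([peptide_mass(p, **kwargs) for p in peptides], dtype=float)
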