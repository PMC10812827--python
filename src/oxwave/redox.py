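"""Differential-alkylation (dual-tag) redox readout for Cys peptides.

Free (reduced) Cys thiols are blocked with the first alkylator during
extraction (iodoacetamide → carbamidomethyl, +57.02146 Da); reversibly
oxidized Cys, once reduced on the filter, are tagged with the second
alkylator (MMTS → methylthio, +45.98772 Da). The mass tag localized on a
Cys therefore encodes the residue's original redox state.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from . import masses as M
from .io import DesignTable
from .quant import QuantResult

DEFAULT_TAG_MASSES = {
    "reduced": M.CARBAMIDOMETHYL,
    "reversibly_oxidized": M.METHYLTHIO,
}


class CysState(str, Enum):
    REDUCED = "reduced"
    REVERSIBLY_OXIDIZED = "reversibly_oxidized"
    INDETERMINATE = "indeterminate"


@dataclass
class RedoxCall:
    peptide: str
    cys_position: int
    state: CysState
    tag_mass: float


def classify_cys_state(peptide: str, tag_mass: float,
                       tag_masses: dict[str, float] | None = None,
                       tol: float = 0.010,
                       cys_position: int | None = None) -> RedoxCall:
    """Classify one Cys site from its observed alkylation tag mass.

    The state is reduced iff the tag matches the first alkylator within
    *tol*, reversibly oxidized iff it matches the second; no match (or a
    multi-Cys peptide without a per-site mass) is indeterminate.
    """
    if "C" not in peptide:
        raise ValueError(f"{peptide}: not a redox-informative peptide (no Cys)")
    tags = DEFAULT_TAG_MASSES if tag_masses is None else tag_masses
    if cys_position is None:
        positions = [i + 1 for i, aa in enumerate(peptide) if aa == "C"]
        if len(positions) > 1 and (tag_mass is None or np.isnan(tag_mass)):
            return RedoxCall(peptide, positions[0], CysState.INDETERMINATE, np.nan)
        cys_position = positions[0]
    if tag_mass is None or np.isnan(tag_mass):
        return RedoxCall(peptide, cys_position, CysState.INDETERMINATE, np.nan)
    if abs(tag_mass - tags["reduced"]) <= tol:
        state = CysState.REDUCED
    elif abs(tag_mass - tags["reversibly_oxidized"]) <= tol:
        state = CysState.REVERSIBLY_OXIDIZED
    else:
        state = CysState.INDETERMINATE
    return RedoxCall(peptide, cys_position, state, float(tag_mass))


def classify_cys_states(psms: pd.DataFrame,
                        tag_masses: dict[str, float] | None = None,
                        tol: float = 0.010,
                        tag_col: str = "cys_tag_mass") -> pd.DataFrame:
    """Vectorized classification of every Cys-containing PSM in a table."""
    tags = DEFAULT_TAG_MASSES if tag_masses is None else tag_masses
    has_cys = psms["peptide"].str.contains("C")
    sub = psms[has_cys]
    tag = sub[tag_col].to_numpy(dtype=float) if tag_col in sub.columns \
        else np.full(len(sub), np.nan)
    state = np.full(len(sub), CysState.INDETERMINATE.value, dtype=object)
    state[np.abs(tag - tags["reduced"]) <= tol] = CysState.REDUCED.value
    state[np.abs(tag - tags["reversibly_oxidized"]) <= tol] = \
        CysState.REVERSIBLY_OXIDIZED.value
    out = sub[["spectrum_id", "peptide", "protein"]].copy()
    out["cys_position"] = sub["peptide"].str.index("C") + 1
    out["tag_mass"] = tag
    out["state"] = state
    return out.reset_index(drop=True)


def reversible_oxidation_timecourse(quant: QuantResult, design: DesignTable,
                                    reversible_ptm: str = "Methylthio_exchange"):
    """Replicate-averaged Zp time course for reversibly oxidized Cys
    peptidoforms (the methylthio-tagged forms quantified in pass 2 against
    their protein values). Peptides whose parent protein lacks a
    quantification were already flagged and excluded by the quantifier.
    """
    from .waves import build_timecourse_matrix

    zp = quant.zp_long(modified=True)
    zp = zp[zp["pepform_id"].str.contains(f"|{reversible_ptm}|", regex=False)]
    if len(zp) == 0:
        return build_timecourse_matrix(pd.DataFrame(
            columns=["row_id", "sample_id", "z"]), design)
    table = zp.rename(columns={"pepform_id": "row_id", "Zp": "z"})
    return build_timecourse_matrix(table[["row_id", "sample_id", "z"]], design)
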