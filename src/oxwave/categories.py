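"""Coordinated protein-abundance changes per functional category (Zc).

The category statistic is the sum of member-protein Zq values divided by
the square root of the member count, which is standard normal when the
member Zq are independent standard normals; two-sided normal p-values are
corrected per sample with Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def compute_category_z(protein_zq: pd.DataFrame, categories: dict[str, set[str]],
                       min_size: int = 5, max_size: int = 500) -> pd.DataFrame:
    """Zc per (category, sample) from a protein x sample Zq matrix.

    Categories are restricted to their quantified members; categories with
    a quantified size outside [min_size, max_size] are skipped (logged).
    Zc = sum(Zq) / sqrt(n); p = 2 * (1 - Phi(|Zc|)).
    """
    quantified = set(protein_zq.index)
    rows = []
    skipped = 0
    for name in sorted(categories):
        members = sorted(categories[name] & quantified)
        if not members:
            skipped += 1
            continue
        if not min_size <= len(members) <= max_size:
            skipped += 1
            continue
        sub = protein_zq.loc[members]
        zc = sub.sum(axis=0) / np.sqrt(len(members))
        for sample, value in zc.items():
            rows.append((name, len(members), sample, float(value)))
    if skipped:
        warnings.warn(f"compute_category_z: {skipped} categories skipped "
                      "(no quantified members or size out of bounds)")
    out = pd.DataFrame(rows, columns=["category", "n_proteins", "sample_id", "Zc"])
    out["Zc"] = out["Zc"].astype(float)
    out["p"] = 2.0 * stats.norm.sf(np.abs(out["Zc"].to_numpy()))
    return out


def category_fdr(results: pd.DataFrame, alpha: float = 0.05,
                 per_sample: bool = True) -> pd.DataFrame:
    """Benjamini-Hochberg q-values; significant iff q < alpha.

    Correction is applied within each sample (time point) by default.
    """
    out = results.copy()
    if ((out["p"] < 0) | (out["p"] > 1)).any():
        raise ValueError("category_fdr: p-values must be in [0, 1]")
    out["q"] = np.nan
    groups = out.groupby("sample_id").groups.values() if per_sample else [out.index]
    for idx in groups:
        if len(idx):
            out.loc[idx, "q"] = multipletests(out.loc[idx, "p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < alpha
    return out
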