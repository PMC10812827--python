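"""Hierarchical standardized quantification (weighted spectrum → peptide →
protein → grand-mean integration).

Each level integrates child log2 ratios into a parent value by
inverse-variance weighting, where a child's total variance is the level
variance sigma2 plus the child's own integration variance from below. The
level variance is the fixed point at which the standardized deviations z
have unit variance. Protein values standardized against the per-sample
grand mean are Zq; peptide deviations from their protein are Zp. Modified
peptides are quantified in a second pass against the protein values and
variances determined from non-modified peptides only, which are frozen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import DesignTable

_TINY = 1e-12


# ---------------------------------------------------------------------------
# spectrum-level log2 ratios

def compute_log2_ratios(psms: pd.DataFrame, design: DesignTable,
                        extra_cols: tuple[str, ...] = ("pepform_id", "protein",
                                                       "is_modified")) -> pd.DataFrame:
    """One row per (spectrum, sample): x = log2(sample / reference intensity).

    Spectra with a non-positive reference intensity are excluded with a
    warning; non-positive sample intensities become missing values (no row).
    """
    frames = []
    n_excluded = 0
    for plex, sub in psms.groupby("plex_id", sort=True):
        ref_ch = design.reference_channel(plex)
        ref = sub[f"reporter_{ref_ch:02d}"].to_numpy(dtype=float)
        ok = ref > 0
        n_excluded += int((~ok).sum())
        sub, ref = sub[ok], ref[ok]
        chans = design.samples[design.samples["plex_id"] == plex]
        for ch, sid in zip(chans["channel_index"], chans["sample_id"]):
            intensity = sub[f"reporter_{ch:02d}"].to_numpy(dtype=float)
            present = intensity > 0
            frame = pd.DataFrame({
                "spectrum_id": sub["spectrum_id"].to_numpy()[present],
                "sample_id": sid,
                "x": np.log2(intensity[present] / ref[present]),
            })
            for col in extra_cols:
                frame[col] = sub[col].to_numpy()[present]
            frames.append(frame)
    if n_excluded:
        warnings.warn(f"compute_log2_ratios: {n_excluded} spectra excluded "
                      "(non-positive reference intensity)")
    if not frames:
        raise ValueError("compute_log2_ratios: no usable spectra")
    out = pd.concat(frames, ignore_index=True)
    if len(out) == 0:
        raise ValueError("compute_log2_ratios: no usable spectra")
    return out


# ---------------------------------------------------------------------------
# level integration and variance estimation

def integrate_level(x, w):
    """Integrate children (x, w) into one parent: parent x is the weighted
    mean and each child's standardized deviation is z = (x - parent) * sqrt(w).
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if len(x) == 0 or not (np.isfinite(x) & np.isfinite(w)).any():
        raise ValueError("integrate_level: need at least one finite child")
    keep = np.isfinite(x) & np.isfinite(w)
    parent = float(np.sum(w[keep] * x[keep]) / np.sum(w[keep]))
    z = np.where(keep, (x - parent) * np.sqrt(w), np.nan)
    return parent, z


def _grouped_mean(x, w, codes, n_groups):
    sw = np.bincount(codes, weights=w, minlength=n_groups)
    swx = np.bincount(codes, weights=w * x, minlength=n_groups)
    return swx / np.maximum(sw, _TINY), sw


def _winsorized_normal_var(winsor: tuple[float, float]) -> float:
    """Variance of a standard normal after clipping at its own percentile
    pair; the fixed-point target, so winsorization does not bias sigma2."""
    c = float(stats.norm.ppf(winsor[1] / 100.0))
    q = stats.norm.sf(c)
    return 1.0 - 2.0 * (c * stats.norm.pdf(c) + q) + 2.0 * c * c * q


def estimate_level_variance(x, inv_precision, parent_codes, n_parents,
                            winsor: tuple[float, float] = (1.0, 99.0),
                            max_sigma2: float = 1e3) -> float:
    """Level variance by the unit-variance-of-z fixed point.

    z uses the membership-corrected denominator sqrt(1/w - 1/W_parent)
    (exact unit variance for children inside their parent's weighted mean);
    only parents with >= 2 children inform the estimate, and the winsorized
    (1-99%) variance of z is matched to the winsorized variance of a
    standard normal. sigma2 is floored at 0.
    """
    x = np.asarray(x, dtype=float)
    inv_precision = np.broadcast_to(np.asarray(inv_precision, dtype=float), x.shape)
    codes = np.asarray(parent_codes)
    if len(x) < 20:
        warnings.warn("estimate_level_variance: fewer than 20 children; "
                      "estimate will be unstable")
    counts = np.bincount(codes, minlength=n_parents)
    multi = counts[codes] >= 2
    if multi.sum() < 2:
        warnings.warn("estimate_level_variance: no parents with >= 2 children; "
                      "sigma2 set to 0")
        return 0.0
    target = _winsorized_normal_var(winsor)

    def excess(s2):
        # variance floor keeps w finite at s2 = 0 with exact precisions;
        # zero-dispersion children then still give z = 0 (sigma2 -> 0)
        w = 1.0 / np.maximum(s2 + inv_precision, 1e-9)
        mu, sw = _grouped_mean(x, w, codes, n_parents)
        denom2 = 1.0 / w - 1.0 / sw[codes]
        ok = multi & (denom2 > 0)
        z = (x[ok] - mu[codes][ok]) / np.sqrt(denom2[ok])
        if len(z) == 0:
            return -target
        lo, hi = np.percentile(z, winsor)
        zc = np.clip(z, lo, hi)
        return float(np.mean(zc * zc)) - target

    if excess(0.0) <= 0.0:
        return 0.0
    hi = 0.25
    while excess(hi) > 0.0 and hi < max_sigma2:
        hi *= 4.0
    if excess(hi) > 0.0:
        warnings.warn("estimate_level_variance: fixed point did not converge; "
                      "returning bracket upper bound")
        return hi
    return float(optimize.brentq(excess, 0.0, hi, xtol=1e-9))


def _standardize(x, w, codes, mu, sw, *, member: bool) -> np.ndarray:
    """Standardized deviation from the parent. For children that are part of
    the parent's weighted mean the deviation variance is 1/w - 1/W; for
    children standardized against an independently determined (frozen)
    parent it is 1/w + 1/W."""
    sign = -1.0 if member else 1.0
    denom2 = 1.0 / w + sign / sw[codes]
    z = np.zeros(len(x))
    ok = denom2 > _TINY
    z[ok] = (x[ok] - mu[codes][ok]) / np.sqrt(denom2[ok])
    return z


# ---------------------------------------------------------------------------
# peptidoform labeling

def label_peptidoforms(psms: pd.DataFrame, peaks) -> pd.DataFrame:
    """Attach pepform_id / is_modified / is_quantifiable from peak annotations.

    A PSM on the annotated ΔM-0 peak is the unmodified form of its peptide
    (pepform ``peptide||0``); a PSM on another annotated, non-artifact,
    non-combination peak with a localized site is a modified peptidoform
    ``peptide|ptm|site``; everything else is not quantifiable.
    """
    ann = {p.peak_id: p.annotation for p in peaks}
    out = psms.copy()
    names, modified, quant = [], [], []
    sites = out["site_position"]
    for pid, pep, site in zip(out["peak_id"], out["peptide"], sites):
        a = ann.get(pid) if pd.notna(pid) else None
        if a is None or a.is_artifact or a.is_combination:
            names.append("")
            modified.append(False)
            quant.append(False)
        elif abs(a.delta_mass) < 1e-9:
            names.append(f"{pep}||0")
            modified.append(False)
            quant.append(True)
        elif pd.isna(site):
            names.append("")
            modified.append(True)
            quant.append(False)
        else:
            names.append(f"{pep}|{a.name}|{int(site)}")
            modified.append(True)
            quant.append(True)
    out["pepform_id"] = names
    out["is_modified"] = modified
    out["is_quantifiable"] = quant
    return out


# ---------------------------------------------------------------------------
# the two-pass model

@dataclass
class QuantResult:
    peptide_table: pd.DataFrame     # pepform_id, protein, sample_id, x, w, Zp, ...
    protein_table: pd.DataFrame     # protein, sample_id, x, w, Zq
    grand: pd.DataFrame             # sample_id, x
    variances: dict[str, float]
    no_anchor: list[str] = field(default_factory=list)

    def zq_matrix(self) -> pd.DataFrame:
        return self.protein_table.pivot(index="protein", columns="sample_id",
                                        values="Zq")

    def zp_long(self, modified: bool | None = None) -> pd.DataFrame:
        t = self.peptide_table
        if modified is not None:
            t = t[t["is_modified"] == modified]
        return t[["pepform_id", "protein", "sample_id", "Zp", "is_modified"]]


def _integrate_spectra(ratios: pd.DataFrame, sigma2_s: float):
    """spectrum → (pepform, sample): returns per-group x, n, inv_precision."""
    g = ratios.groupby(["pepform_id", "sample_id"], sort=True, observed=True)
    codes = g.ngroup().to_numpy()
    n_groups = codes.max() + 1 if len(codes) else 0
    x = ratios["x"].to_numpy(dtype=float)
    w = np.full(len(x), 1.0 / max(sigma2_s, _TINY))
    mu, sw = _grouped_mean(x, w, codes, n_groups)
    keys = g.size().reset_index()[["pepform_id", "sample_id"]]
    out = keys.copy()
    out["x"] = mu
    out["n_spectra"] = g.size().to_numpy()
    out["inv_precision"] = 1.0 / sw
    out["protein"] = g["protein"].first().to_numpy()
    return out, codes, n_groups


def run_wspp(psms: pd.DataFrame, design: DesignTable,
             winsor: tuple[float, float] = (1.0, 99.0)) -> QuantResult:
    """Two-pass hierarchical quantification.

    Pass 1 integrates spectrum → peptide → protein → grand mean on
    non-modified peptides only, estimating the spectrum, peptide and
    protein level variances. Pass 2 quantifies modified peptidoforms
    against the frozen pass-1 protein values and variances; protein Zq is
    never touched by pass 2. Expects PSMs labeled by
    :func:`label_peptidoforms` (or carrying equivalent ``pepform_id`` /
    ``is_modified`` columns), FDR-filtered, targets only.
    """
    usable = psms[psms["is_quantifiable"]] if "is_quantifiable" in psms.columns else psms
    ratios = compute_log2_ratios(usable, design)
    unmod = ratios[~ratios["is_modified"]]
    if len(unmod) == 0:
        raise ValueError("run_wspp: no non-modified peptides to anchor the model")

    # -- pass 1: spectrum level
    x_sp = unmod["x"].to_numpy(dtype=float)
    g_sp = unmod.groupby(["pepform_id", "sample_id"], sort=True, observed=True)
    codes_sp = g_sp.ngroup().to_numpy()
    sigma2_s = estimate_level_variance(x_sp, 0.0, codes_sp, codes_sp.max() + 1,
                                       winsor=winsor)
    pep, _, _ = _integrate_spectra(unmod, sigma2_s)

    # -- peptide level
    g_pep = pep.groupby(["protein", "sample_id"], sort=True, observed=True)
    codes_pep = g_pep.ngroup().to_numpy()
    n_prot_samples = codes_pep.max() + 1
    x_pep = pep["x"].to_numpy(dtype=float)
    inv_prec_pep = pep["inv_precision"].to_numpy(dtype=float)
    sigma2_p = estimate_level_variance(x_pep, inv_prec_pep, codes_pep,
                                       n_prot_samples, winsor=winsor)
    w_pep = 1.0 / (sigma2_p + inv_prec_pep)
    mu_prot, sw_prot = _grouped_mean(x_pep, w_pep, codes_pep, n_prot_samples)
    pep["w"] = w_pep
    pep["Zp"] = _standardize(x_pep, w_pep, codes_pep, mu_prot, sw_prot, member=True)
    pep["is_modified"] = False

    prot_keys = g_pep.size().reset_index()[["protein", "sample_id"]]
    prot = prot_keys.copy()
    prot["x"] = mu_prot
    prot["inv_precision"] = 1.0 / sw_prot

    # -- protein level vs per-sample grand mean
    g_q = prot.groupby("sample_id", sort=True, observed=True)
    codes_q = g_q.ngroup().to_numpy()
    n_samples = codes_q.max() + 1
    x_q = prot["x"].to_numpy(dtype=float)
    inv_prec_q = prot["inv_precision"].to_numpy(dtype=float)
    sigma2_q = estimate_level_variance(x_q, inv_prec_q, codes_q, n_samples,
                                       winsor=winsor)
    w_q = 1.0 / (sigma2_q + inv_prec_q)
    mu_grand, sw_grand = _grouped_mean(x_q, w_q, codes_q, n_samples)
    prot["w"] = w_q
    prot["Zq"] = _standardize(x_q, w_q, codes_q, mu_grand, sw_grand, member=True)
    grand = pd.DataFrame({"sample_id": g_q.size().index.to_numpy(), "x": mu_grand})

    # -- pass 2: modified peptidoforms against frozen protein values
    tables = [pep]
    no_anchor: list[str] = []
    mod = ratios[ratios["is_modified"]]
    if len(mod):
        pep_m, _, _ = _integrate_spectra(mod, sigma2_s)
        anchor = prot.set_index(["protein", "sample_id"])
        idx = pd.MultiIndex.from_frame(pep_m[["protein", "sample_id"]])
        have = idx.isin(anchor.index)
        no_anchor = sorted(pep_m.loc[~have, "pepform_id"].unique())
        if no_anchor:
            warnings.warn(f"run_wspp: {len(no_anchor)} modified peptidoforms have "
                          "no protein anchor (protein quantified from no "
                          "non-modified peptide); excluded")
        pep_m = pep_m[have]
        idx = idx[have]
        prot_x = anchor["x"].to_numpy()[anchor.index.get_indexer(idx)]
        prot_w = anchor["inv_precision"].to_numpy()[anchor.index.get_indexer(idx)]
        inv_prec_m = pep_m["inv_precision"].to_numpy(dtype=float)
        w_m = 1.0 / (sigma2_p + inv_prec_m)
        pep_m["w"] = w_m
        x_m = pep_m["x"].to_numpy(dtype=float)
        pep_m["Zp"] = (x_m - prot_x) / np.sqrt(1.0 / w_m + prot_w)
        pep_m["is_modified"] = True
        tables.append(pep_m)

    peptide_table = pd.concat(tables, ignore_index=True)
    protein_table = prot[["protein", "sample_id", "x", "w", "Zq"]].copy()
    return QuantResult(
        peptide_table=peptide_table,
        protein_table=protein_table,
        grand=grand,
        variances={"spectrum": sigma2_s, "peptide": sigma2_p, "protein": sigma2_q},
        no_anchor=no_anchor,
    )
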