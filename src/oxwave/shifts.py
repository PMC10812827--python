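"""Open-search ΔM post-processing.

The stages mirror the standard open-search workflow: recalibrate masses on
a high-quality PSM subset, model the ΔM distribution as a histogram, detect
peaks by frequency and slope, assign PSMs to peaks, compute target-decoy
FDR at three scopes (global, local 1-Da bins, per peak), annotate peaks
against a known-modification list, explain residual ΔM values by peptide
truncation, verify site positions, and curate the modified-peptide list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import C_TERM, N_TERM, DesignTable, ModAnnotation, reporter_columns
from .masses import RESIDUE_MASS


# ---------------------------------------------------------------------------
# recalibration

def recalibrate(psms: pd.DataFrame, min_score: float = 0.15, ppm_window: float = 20.0,
                min_subset: int = 30) -> pd.DataFrame:
    """Remove the systematic constant-ppm mass offset.

    The offset is the median signed ppm error of a quality subset (score >=
    *min_score*, |ppm residual against the nearest integer-ΔM hypothesis| <=
    *ppm_window*, targets only) and is divided out of every observed mass;
    ΔM is then recomputed. Idempotent to numerical tolerance.
    """
    if len(psms) == 0:
        raise ValueError("recalibrate: empty PSM table")
    out = psms.copy()
    dm = out["delta_mass"].to_numpy(dtype=float)
    obs = out["observed_mass"].to_numpy(dtype=float)
    resid_ppm = (dm - np.round(dm)) / obs * 1e6
    quality = ((out["score"].to_numpy(dtype=float) >= min_score)
               & (np.abs(resid_ppm) <= ppm_window)
               & ~out["is_decoy"].to_numpy(dtype=bool))
    if quality.sum() < min_subset:
        warnings.warn(
            f"recalibrate: only {int(quality.sum())} quality PSMs "
            f"(< {min_subset}); skipping correction")
        return out
    offset_ppm = float(np.median(resid_ppm[quality]))
    corrected = obs / (1.0 + offset_ppm * 1e-6)
    out["observed_mass"] = corrected
    out["delta_mass"] = corrected - out["theoretical_mass"].to_numpy(dtype=float)
    out.attrs["recalibration_offset_ppm"] = offset_ppm
    return out


# ---------------------------------------------------------------------------
# ΔM histogram and peak detection

@dataclass
class DeltaMassHistogram:
    edges: np.ndarray       # len n_bins + 1, uniform spacing, half-open bins
    counts: np.ndarray

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def build_deltam_histogram(psms: pd.DataFrame, bin_width: float = 0.001) -> DeltaMassHistogram:
    """Histogram of ΔM values in half-open [low, high) bins of *bin_width*."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if len(psms) == 0:
        raise ValueError("build_deltam_histogram: empty PSM table")
    dm = psms["delta_mass"].to_numpy(dtype=float)
    lo = np.floor(dm.min() / bin_width) * bin_width
    idx = np.floor((dm - lo) / bin_width).astype(np.int64)
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    edges = lo + bin_width * np.arange(n_bins + 1)
    return DeltaMassHistogram(edges=edges, counts=counts)


@dataclass
class DeltaMassPeak:
    peak_id: str
    apex_deltam: float
    low: float               # bin_range is the half-open interval [low, high)
    high: float
    psm_count: int = 0
    target_count: int = 0
    decoy_count: int = 0
    peak_fdr: float = float("nan")
    annotation: ModAnnotation | None = None

    def contains(self, deltam: float) -> bool:
        return self.low <= deltam < self.high


def default_min_count(counts: np.ndarray, factor: float = 5.0, floor: int = 10,
                      min_background_bins: int = 100) -> int:
    """Peak threshold: *factor* times the median occupied-bin count, floored
    so that sparse Poisson backgrounds (median occupied count of 1) cannot
    promote noise bins to peaks. With fewer than *min_background_bins*
    occupied bins there is no background to estimate — the occupied bins
    are the peaks themselves — and the floor is used directly."""
    occupied = counts[counts > 0]
    if len(occupied) < min_background_bins:
        return floor
    return int(max(floor, np.ceil(factor * np.median(occupied))))


def detect_peaks(hist: DeltaMassHistogram, min_count: int | None = None,
                 min_count_factor: float = 5.0, min_count_floor: int = 10,
                 smooth_bins: int = 5, merge_frac: float = 0.5
                 ) -> list[DeltaMassPeak]:
    """Find ΔM peaks by the frequency and slope of the bins.

    An apex is a local maximum (rise then fall; plateaus take the leftmost
    bin) of the histogram after a light moving-average smoothing over
    *smooth_bins* bins, which keeps Poisson bin-to-bin jitter from
    fragmenting one ΔM population into satellites. The extent grows
    outward from the apex while smoothed counts decrease monotonically,
    never crossing into another peak's claim (greedy, in descending apex
    order). Nearly touching neighbors whose separating valley stays above
    *merge_frac* of the smaller smoothed apex are merged — a shallow dip
    inside one population is not two populations. A candidate survives iff
    its extent's raw count in excess of the local background (the median
    occupied-bin count, taken as 0 when fewer than 100 bins are occupied)
    clears *min_count*; the extent is then trimmed to the raw-count
    support and the reported apex is the raw-count-weighted centroid.
    Bin ranges are half-open and disjoint.
    """
    c = hist.counts.astype(float)
    if len(c) == 0:
        raise ValueError("detect_peaks: empty histogram")
    if min_count is None:
        min_count = default_min_count(hist.counts, min_count_factor, min_count_floor)
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        s = np.convolve(c, kernel, mode="same")
    else:
        s = c
    pad = np.concatenate([[-1.0], s, [-1.0]])
    apexes = []
    i = 1
    while i <= len(s):
        if pad[i] > 0 and pad[i] > pad[i - 1]:
            j = i                       # plateau: apex is the leftmost bin
            while j + 1 <= len(s) + 1 and pad[j + 1] == pad[i]:
                j += 1
            if pad[j + 1] < pad[i]:
                apexes.append(i - 1)
            i = j + 1
        else:
            i += 1
    apexes.sort(key=lambda a: (-s[a], a))

    claimed = np.zeros(len(s), dtype=bool)
    candidates = []          # dicts: left, right, apex (bin indices)
    for a in apexes:
        if claimed[a]:
            continue
        left = a
        while left - 1 >= 0 and not claimed[left - 1] and 0 < s[left - 1] <= s[left]:
            left -= 1
        right = a
        while (right + 1 < len(s) and not claimed[right + 1]
               and 0 < s[right + 1] <= s[right]):
            right += 1
        claimed[left:right + 1] = True
        candidates.append({"left": left, "right": right, "apex": a})
    candidates.sort(key=lambda c: c["left"])

    # merge neighbors separated by a shallow valley
    merged = True
    while merged:
        merged = False
        out = []
        for c in candidates:
            if out:
                p = out[-1]
                gap = c["left"] - p["right"] - 1
                if gap <= 2:
                    valley = s[p["apex"]:c["apex"] + 1].min()
                    if valley > merge_frac * min(s[p["apex"]], s[c["apex"]]):
                        p["right"] = c["right"]
                        if s[c["apex"]] > s[p["apex"]]:
                            p["apex"] = c["apex"]
                        merged = True
                        continue
            out.append(dict(c))
        candidates = out

    occupied = hist.counts[hist.counts > 0]
    background = float(np.median(occupied)) if len(occupied) >= 100 else 0.0
    peaks = []
    for c in candidates:
        raw = hist.counts[c["left"]:c["right"] + 1]
        if raw.sum() - background * len(raw) < min_count:
            continue
        # trim to the raw-count support
        nz = np.flatnonzero(raw > 0)
        lo_bin = c["left"] + int(nz[0])
        hi_bin = c["left"] + int(nz[-1])
        span = slice(lo_bin, hi_bin + 1)
        apex_dm = float(np.average(hist.centers[span], weights=hist.counts[span]))
        peaks.append(DeltaMassPeak(
            peak_id=f"peak_{len(peaks):04d}",
            apex_deltam=apex_dm,
            low=float(hist.edges[lo_bin]),
            high=float(hist.edges[hi_bin + 1]),
            psm_count=int(hist.counts[span].sum()),
        ))
    peaks.sort(key=lambda p: p.low)
    for k, p in enumerate(peaks):
        p.peak_id = f"peak_{k:04d}"
    return peaks


def assign_psms_to_peaks(psms: pd.DataFrame, peaks: list[DeltaMassPeak]) -> pd.DataFrame:
    """Label each PSM with the peak whose [low, high) range contains its ΔM.

    Returns a copy with a ``peak_id`` column (NA = unassigned) and updates
    each peak's psm/target/decoy counts in place.
    """
    lows = np.array([p.low for p in peaks])
    highs = np.array([p.high for p in peaks])
    order = np.argsort(lows)
    if (lows[order][1:] < highs[order][:-1]).any():
        raise ValueError("assign_psms_to_peaks: peaks overlap")
    out = psms.copy()
    dm = out["delta_mass"].to_numpy(dtype=float)
    pos = np.searchsorted(lows[order], dm, side="right") - 1
    inside = (pos >= 0) & (dm < highs[order][np.clip(pos, 0, None)])
    ids = np.array([p.peak_id for p in peaks])[order]
    labels = pd.array([ids[p] if ok else pd.NA for p, ok in zip(pos, inside)],
                      dtype="string")
    out["peak_id"] = labels
    decoy = out["is_decoy"].to_numpy(dtype=bool)
    by_peak_total = out.groupby("peak_id", dropna=True).size()
    by_peak_decoy = out[decoy].groupby("peak_id", dropna=True).size()
    for p in peaks:
        p.psm_count = int(by_peak_total.get(p.peak_id, 0))
        p.decoy_count = int(by_peak_decoy.get(p.peak_id, 0))
        p.target_count = p.psm_count - p.decoy_count
    return out


def peaks_to_frame(peaks: list[DeltaMassPeak]) -> pd.DataFrame:
    return pd.DataFrame([{
        "peak_id": p.peak_id, "apex_deltam": p.apex_deltam, "low": p.low,
        "high": p.high, "psm_count": p.psm_count, "target_count": p.target_count,
        "decoy_count": p.decoy_count, "peak_fdr": p.peak_fdr,
        "annotation": p.annotation.name if p.annotation else "",
    } for p in peaks])


def peaks_from_frame(frame: pd.DataFrame, mod_list) -> list[DeltaMassPeak]:
    """Rebuild peak objects from a written peak table, reattaching
    annotations by name from the modification list."""
    by_name = {m.name: m for m in mod_list}
    frame = frame.copy()
    for col in ("apex_deltam", "low", "high", "peak_fdr"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    for col in ("psm_count", "target_count", "decoy_count"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce").fillna(0)
    peaks = []
    for row in frame.itertuples(index=False):
        peaks.append(DeltaMassPeak(
            peak_id=row.peak_id, apex_deltam=float(row.apex_deltam),
            low=float(row.low), high=float(row.high),
            psm_count=int(row.psm_count), target_count=int(row.target_count),
            decoy_count=int(row.decoy_count), peak_fdr=float(row.peak_fdr),
            annotation=by_name.get(str(row.annotation)) or None,
        ))
    return peaks


# ---------------------------------------------------------------------------
# target-decoy FDR at three scopes

def _td_qvalues(score: np.ndarray, is_decoy: np.ndarray) -> np.ndarray:
    """q-values from target-decoy counting: sort by descending score (ties:
    decoys first, the conservative order), FDR_k = decoys<=k / targets<=k,
    monotonized from the bottom, clipped to [0, 1]."""
    n = len(score)
    order = np.lexsort((~is_decoy, -score))
    d = np.cumsum(is_decoy[order])
    t = np.cumsum(~is_decoy[order])
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(t > 0, d / np.maximum(t, 1), np.inf)
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(n)
    out[order] = q
    return out


def compute_fdr(psms: pd.DataFrame) -> pd.DataFrame:
    """Per-PSM q-values at three scopes: global, local (half-open 1-Da ΔM
    bins [n - 0.5, n + 0.5)), and per assigned peak. PSMs not assigned to a
    peak get a missing ``q_peak``. A scope with zero targets gets q = 1."""
    out = psms.copy()
    score = out["score"].to_numpy(dtype=float)
    decoy = out["is_decoy"].to_numpy(dtype=bool)

    out["q_global"] = _td_qvalues(score, decoy)

    local_bin = np.floor(out["delta_mass"].to_numpy(dtype=float) + 0.5).astype(int)
    q_local = np.empty(len(out))
    for b in np.unique(local_bin):
        m = local_bin == b
        if (~decoy[m]).sum() == 0:
            warnings.warn(f"compute_fdr: no target PSMs in 1-Da bin {b}; q set to 1")
            q_local[m] = 1.0
        else:
            q_local[m] = _td_qvalues(score[m], decoy[m])
    out["q_local"] = q_local

    q_peak = np.full(len(out), np.nan)
    if "peak_id" in out.columns:
        labels = out["peak_id"]
        for pid in labels.dropna().unique():
            m = (labels == pid).fillna(False).to_numpy(dtype=bool)
            if (~decoy[m]).sum() == 0:
                warnings.warn(f"compute_fdr: no target PSMs in {pid}; q set to 1")
                q_peak[m] = 1.0
            else:
                q_peak[m] = _td_qvalues(score[m], decoy[m])
    out["q_peak"] = q_peak
    return out


def filter_fdr(psms: pd.DataFrame, threshold: float = 0.01,
               scope: str = "q_global") -> pd.DataFrame:
    """Identification filter: keep target PSMs with q below *threshold*."""
    keep = (psms[scope] <= threshold) & ~psms["is_decoy"]
    return psms[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# annotation, truncation, site position

def annotate_peaks(peaks: list[DeltaMassPeak], mod_list: list[ModAnnotation],
                   match_tol: float = 0.010) -> list[DeltaMassPeak]:
    """Attach to each peak the known mass shift closest to its apex, if any
    lies within *match_tol*; ties break by smaller |difference|, then name."""
    if not mod_list:
        raise ValueError("annotate_peaks: empty modification list")
    for p in peaks:
        best = min(mod_list,
                   key=lambda m: (abs(p.apex_deltam - m.delta_mass), m.name))
        if abs(p.apex_deltam - best.delta_mass) <= match_tol:
            p.annotation = best
        else:
            p.annotation = None
    return peaks


@dataclass
class TruncationExplanation:
    terminus: str            # "N" or "C"
    residues: str            # residues lost, in peptide order
    mass: float              # summed residue mass (equals -ΔM within tol)


def check_truncation(peptide: str, delta_mass: float, tol: float = 0.005,
                     max_depth: int = 3) -> TruncationExplanation | None:
    """Explain a negative ΔM as the loss of up to *max_depth* terminal
    residues from either end; prefers fewer residues, then the N-terminus."""
    if not peptide:
        raise ValueError("check_truncation: empty peptide")
    target = -delta_mass
    if target <= tol:
        return None
    candidates = []
    acc = 0.0
    for d in range(1, min(max_depth, len(peptide)) + 1):
        acc += RESIDUE_MASS[peptide[d - 1]]
        if abs(acc - target) <= tol:
            candidates.append((d, 0, TruncationExplanation("N", peptide[:d], acc)))
    acc = 0.0
    for d in range(1, min(max_depth, len(peptide)) + 1):
        acc += RESIDUE_MASS[peptide[-d]]
        if abs(acc - target) <= tol:
            candidates.append((d, 1, TruncationExplanation("C", peptide[-d:], acc)))
    if not candidates:
        return None
    return min(candidates, key=lambda c: (c[0], c[1]))[2]


def check_site_position(peptide: str, site_position, annotation: ModAnnotation
                        ) -> bool | None:
    """True iff the residue (or terminus marker) at the localized position is
    allowed by the annotation; None (indeterminate) when no site is given.
    Position 0 is the N-terminus, len(peptide) + 1 the C-terminus."""
    if site_position is None or (isinstance(site_position, float) and np.isnan(site_position)) \
            or site_position is pd.NA:
        return None
    pos = int(site_position)
    if pos == 0:
        return annotation.allows(N_TERM)
    if pos == len(peptide) + 1:
        return annotation.allows(C_TERM)
    if not 1 <= pos <= len(peptide):
        return False
    return annotation.allows(peptide[pos - 1])


# ---------------------------------------------------------------------------
# curation

@dataclass
class CuratedPeptide:
    peptide: str
    ptm: ModAnnotation
    site_position: int
    site_residue: str
    protein: str
    peak_id: str
    n_psms: int
    n_replicates_detected: int
    zp: dict = field(default_factory=dict)   # filled by the quantification stage


def _replicates_detected(sub: pd.DataFrame, design: DesignTable) -> int:
    """Max over groups of the number of distinct biological replicates
    (samples) in which the peptidoform was detected: a PSM covers every
    sample of its plex whose reporter intensity is positive."""
    rep_cols = reporter_columns(sub)
    samples = design.samples
    detected: set[str] = set()
    for plex, plex_sub in sub.groupby("plex_id"):
        chans = samples[samples["plex_id"] == plex]
        for ch, sid in zip(chans["channel_index"], chans["sample_id"]):
            col = f"reporter_{ch:02d}"
            if col in rep_cols and (plex_sub[col] > 0).any():
                detected.add(sid)
    if not detected:
        return 0
    groups = design.sample_to_group()
    return int(pd.Series(list(detected)).map(groups).value_counts().max())


def curate_modified_peptides(psms: pd.DataFrame, peaks: list[DeltaMassPeak],
                             design: DesignTable, min_replicates: int = 4
                             ) -> pd.DataFrame:
    """The curation filter for modified peptides.

    Keeps a (peptide, PTM, site) peptidoform iff its ΔM peak carries a known
    annotation that is neither an artifact nor a combination of
    modifications (and is not the unmodified peak), the localized site is an
    allowed residue for that annotation, and the form was detected in at
    least *min_replicates* biological replicates of at least one group.
    Expects FDR-filtered, peak-assigned target PSMs. Output is sorted by
    (peptide, ptm, site) and therefore invariant to input row order.
    """
    by_id = {p.peak_id: p for p in peaks}
    rows = []
    assigned = psms[psms["peak_id"].notna() & ~psms["is_decoy"]]
    for (pid, peptide, site), sub in assigned.groupby(
            ["peak_id", "peptide", "site_position"], dropna=True, sort=True):
        peak = by_id[pid]
        ann = peak.annotation
        if ann is None or ann.is_artifact or ann.is_combination:
            continue
        if abs(ann.delta_mass) < 1e-9:      # the unmodified peak
            continue
        if check_site_position(peptide, site, ann) is not True:
            continue
        n_rep = _replicates_detected(sub, design)
        if n_rep < min_replicates:
            continue
        site = int(site)
        residue = (N_TERM if site == 0
                   else C_TERM if site == len(peptide) + 1
                   else peptide[site - 1])
        rows.append({
            "peptide": peptide,
            "ptm_name": ann.name,
            "ptm_delta": ann.delta_mass,
            "site_position": site,
            "site_residue": residue,
            "protein": sub["protein"].iloc[0],
            "peak_id": pid,
            "n_psms": len(sub),
            "n_replicates_detected": n_rep,
            "is_reversible_tag": ann.name == "Methylthio_exchange",
        })
    out = pd.DataFrame(rows, columns=[
        "peptide", "ptm_name", "ptm_delta", "site_position", "site_residue",
        "protein", "peak_id", "n_psms", "n_replicates_detected",
        "is_reversible_tag"])
    return out.sort_values(["peptide", "ptm_name", "site_position"]).reset_index(drop=True)
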