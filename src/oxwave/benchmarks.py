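"""Ground-truth recovery studies.

Each function simulates experiments under the generator's study conditions,
runs the relevant pipeline stages from scratch, and measures how well the
known injected structure is recovered: FDR control, ΔM peak recovery,
recalibration residual, null calibration of the standardized variables,
effect and wave recovery, redox classification accuracy, and agreement of
the analytic small-n statistics with exhaustive enumeration. These back
both the statistical test suite and the reproduction script.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score

from . import masses as M, shifts
from .categories import category_fdr, compute_category_z
from .quant import label_peptidoforms, run_wspp
from .redox import CysState, classify_cys_states
from .simulate import (SimConfig, default_mod_list, generate_ground_truth,
                       make_design, simulate_psm_table)
from .waves import (build_timecourse_matrix, group_difference_tests, hca_pearson,
                    hypergeom_sf, ptm_enrichment)

OX_CLASS_KFND = "mono_ox_KFND"
OX_CLASS_CW = "ox_CW"


def _simulate(cfg: SimConfig):
    truth = generate_ground_truth(cfg)
    return simulate_psm_table(truth, cfg), make_design(cfg), truth


def _shifts_chain(psms, design, fdr=0.01):
    rec = shifts.recalibrate(psms)
    peaks = shifts.detect_peaks(shifts.build_deltam_histogram(rec))
    rec = shifts.assign_psms_to_peaks(rec, peaks)
    filt = shifts.filter_fdr(shifts.compute_fdr(rec), threshold=fdr)
    peaks = shifts.annotate_peaks(peaks, default_mod_list())
    curated = shifts.curate_modified_peptides(filt, peaks, design)
    return rec, filt, peaks, curated


def _quantify(filt, peaks, curated, design):
    lab = label_peptidoforms(filt, peaks)
    keys = set(curated["peptide"] + "|" + curated["ptm_name"] + "|"
               + curated["site_position"].astype(str))
    keep_mod = lab["is_modified"] & lab["pepform_id"].isin(keys)
    lab["is_quantifiable"] = (lab["is_quantifiable"] & ~lab["is_modified"]) | keep_mod
    return lab, run_wspp(lab, design)


# ---------------------------------------------------------------------------
# FDR control

def fdr_control_study(n_seeds: int = 20, base_seed: int = 1000,
                      threshold: float = 0.01) -> dict:
    """Aggregate empirical false-target fraction among PSMs passing the
    q-value threshold, over seeded simulations of >= 20,000 PSMs each."""
    cfg0 = SimConfig(n_proteins=220, peptides_per_protein=10)
    n_false = n_accepted = n_psms = 0
    for s in range(n_seeds):
        cfg = replace(cfg0, seed=base_seed + s)
        psms, _, _ = _simulate(cfg)
        n_psms += len(psms)
        rec = shifts.recalibrate(psms)
        filt = shifts.filter_fdr(shifts.compute_fdr(rec), threshold=threshold)
        n_accepted += len(filt)
        n_false += int((filt["truth_label"] != "correct").sum())
    return {"false_target_fraction": n_false / n_accepted,
            "n_accepted": n_accepted, "mean_psms_per_run": n_psms / n_seeds}


# ---------------------------------------------------------------------------
# ΔM peak recovery

def peak_recovery_study(n_seeds: int = 20, base_seed: int = 2000) -> dict:
    """Recovery of every injected ΔM population whose PSM support clears the
    detection threshold (apex within one bin width of truth), plus the false
    peak count on pure uniform ΔM noise."""
    recovered = expected = 0
    max_apex_err_bins = 0.0
    false_peaks = 0
    for s in range(n_seeds):
        cfg = SimConfig(n_proteins=150, peptides_per_protein=8, seed=base_seed + s)
        psms, _, truth = _simulate(cfg)
        hist = shifts.build_deltam_histogram(psms)
        min_count = shifts.default_min_count(hist.counts)
        peaks = shifts.detect_peaks(hist, min_count=min_count)
        apexes = np.array([p.apex_deltam for p in peaks])
        dm = psms["truth_delta_mass"].round(6)
        for injected in truth.injected_deltam_peaks:
            support = int((np.abs(dm - injected) < 1e-4).sum())
            if support < min_count:
                continue
            expected += 1
            err = np.min(np.abs(apexes - injected)) if len(apexes) else np.inf
            if err <= hist.bin_width:
                recovered += 1
                max_apex_err_bins = max(max_apex_err_bins, err / hist.bin_width)
        # pure uniform noise
        rng = np.random.default_rng(base_seed + 10_000 + s)
        noise = pd.DataFrame({"delta_mass": rng.uniform(-60, 60, 20_000)})
        false_peaks += len(shifts.detect_peaks(
            shifts.build_deltam_histogram(noise)))
    return {"recovery_rate": recovered / expected, "n_expected": expected,
            "max_apex_error_bins": max_apex_err_bins,
            "uniform_noise_false_peaks": false_peaks}


# ---------------------------------------------------------------------------
# recalibration

def recalibration_study(n_seeds: int = 5, base_seed: int = 3000,
                        offset_ppm: float = 8.0) -> dict:
    """Residual systematic ppm error (|median signed error| against
    generator truth) after removing an injected constant offset."""
    residuals = []
    for s in range(n_seeds):
        cfg = SimConfig(n_proteins=120, peptides_per_protein=8,
                        calib_offset_ppm=offset_ppm, seed=base_seed + s)
        psms, _, _ = _simulate(cfg)
        rec = shifts.recalibrate(psms)
        correct = rec["truth_label"] == "correct"
        ppm = ((rec["delta_mass"] - rec["truth_delta_mass"])
               / rec["observed_mass"] * 1e6)[correct]
        residuals.append(abs(float(np.median(ppm))))
    return {"max_abs_median_ppm": max(residuals),
            "injected_offset_ppm": offset_ppm, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# null calibration

def null_calibration_study(seed: int = 4000, n_categories: int = 1000) -> dict:
    """With every injected effect at zero: moments of Zq and Zp, and the
    fraction of random protein categories reaching p < 0.05."""
    cfg = SimConfig(n_proteins=500, peptides_per_protein=8, seed=seed,
                    site_error_rate=0.0).null()
    psms, design, _ = _simulate(cfg)
    _, filt, peaks, curated = _shifts_chain(psms, design)
    _, quant = _quantify(filt, peaks, curated, design)
    zq = quant.protein_table["Zq"].to_numpy()
    zp = quant.peptide_table["Zp"].to_numpy()
    rng = np.random.default_rng(seed + 1)
    zq_matrix = quant.zq_matrix().dropna()
    cats = {f"rand{i}": set(rng.choice(zq_matrix.index,
                                       size=int(rng.integers(10, 31)),
                                       replace=False))
            for i in range(n_categories)}
    one_sample = zq_matrix.iloc[:, [len(zq_matrix.columns) // 2]]
    zc = compute_category_z(one_sample, cats)
    return {"zq_mean": float(zq.mean()), "zq_var": float(zq.var()),
            "zp_mean": float(zp.mean()), "zp_var": float(zp.var()),
            "n_proteins": int(quant.zq_matrix().shape[0]),
            "n_zq": len(zq), "n_zp": len(zp),
            "category_fpr": float((zc["p"] < 0.05).mean()),
            "n_categories": len(zc)}


# ---------------------------------------------------------------------------
# effect recovery

def effect_recovery_study(n_seeds: int = 20, base_seed: int = 5000) -> dict:
    """Recovery of an injected protein log2 fold change of 1.0 (within
    3 SE) and the power to detect a +0.5 whole-category shift at BH
    q < 0.05 for a category of >= 20 proteins."""
    n_tp = 8
    fc_one = tuple(0.0 if i == 0 else 1.0 for i in range(n_tp))
    late = tuple(0.5 if i >= 4 else 0.0 for i in range(n_tp))
    recovered_fc = []
    recovery_ok = 0
    detected = 0
    for s in range(n_seeds):
        cfg = SimConfig(n_proteins=150, peptides_per_protein=8,
                        seed=base_seed + s,
                        category_effects={"immune": late, "fc_one": fc_one})
        psms, design, truth = _simulate(cfg)
        _, filt, peaks, curated = _shifts_chain(psms, design)
        _, quant = _quantify(filt, peaks, curated, design)
        prot = quant.protein_table
        affected = prot[prot["protein"].isin(truth.categories["fc_one"])
                        & ~prot["sample_id"].str.startswith("baseline")]
        means = affected.groupby("protein")["x"].mean()
        se = float(means.std(ddof=1) / np.sqrt(len(means)))
        recovered_fc.append(float(means.mean()))
        recovery_ok += abs(means.mean() - 1.0) < 3 * se
        zc = category_fdr(compute_category_z(quant.zq_matrix().dropna(),
                                             truth.categories))
        tp = design.sample_to_timepoint()
        zc["tp_index"] = zc["sample_id"].map(
            {s_: design.timepoint_order.index(t) for s_, t in tp.items()})
        hit = zc[(zc["category"] == "immune") & (zc["tp_index"] >= 4)
                 & zc["significant"] & (zc["Zc"] > 0)]
        detected += int(len(hit) > 0)
    return {"mean_recovered_log2fc": float(np.mean(recovered_fc)),
            "recovery_within_3se_rate": recovery_ok / n_seeds,
            "category_power": detected / n_seeds,
            "category_size": 25, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# wave recovery

def _ox_class(ptm_name: str, residue: str) -> str | None:
    if residue in "CW" and ptm_name in {"Oxidation", "Dioxidation", "Trioxidation"}:
        return OX_CLASS_CW
    if residue in "KFND" and ptm_name == "Oxidation":
        return OX_CLASS_KFND
    return None


def wave_recovery_study(n_seeds: int = 20, base_seed: int = 6000) -> dict:
    """End-to-end recovery of the two injected oxidation waves: Pearson-HCA
    at k = 2 vs generator labels (adjusted Rand index) and hypergeometric
    assignment of K/F/N/D mono-oxidation to the early cluster and C/W
    mono/di/tri-oxidation to the late cluster."""
    aris = []
    successes = 0
    enrich_successes = 0
    for s in range(n_seeds):
        cfg = SimConfig(n_proteins=150, peptides_per_protein=8, frac_modified=0.3,
                        seed=base_seed + s)
        psms, design, truth = _simulate(cfg)
        _, filt, peaks, curated = _shifts_chain(psms, design)
        lab, quant = _quantify(filt, peaks, curated, design)
        irr = curated[~curated["is_reversible_tag"]]
        keys = set(irr["peptide"] + "|" + irr["ptm_name"] + "|"
                   + irr["site_position"].astype(str))
        zp = quant.zp_long(modified=True)
        zp = zp[zp["pepform_id"].isin(keys)].rename(
            columns={"pepform_id": "row_id", "Zp": "z"})
        matrix = build_timecourse_matrix(zp[["row_id", "sample_id", "z"]], design)
        hca = hca_pearson(matrix.values, n_clusters=2)
        wave_of = truth.modified_peptide_truth.set_index("pepform_id")["wave_id"]
        rows = hca.labels.index
        truth_labels = rows.map(wave_of)
        ari = adjusted_rand_score(truth_labels, hca.labels.to_numpy())
        aris.append(ari)

        # cluster-level PTM class enrichment on curated PSMs
        sub = lab[lab["is_modified"] & lab["pepform_id"].isin(keys)].copy()
        sub["ptm_name"] = [p.split("|")[1] for p in sub["pepform_id"]]
        sub["residue"] = [pep[int(site) - 1]
                          for pep, site in zip(sub["peptide"],
                                               sub["site_position"])]
        sub["ox_class"] = [_ox_class(n, r)
                           for n, r in zip(sub["ptm_name"], sub["residue"])]
        sub = sub[sub["ox_class"].notna()]
        sub["cluster"] = sub["pepform_id"].map(hca.labels)
        sub = sub[sub["cluster"].notna()]
        # early cluster = the one whose mean series peaks earliest
        peak_idx = {c: int(np.argmax(matrix.values
                                     .loc[hca.labels[hca.labels == c].index]
                                     .mean(axis=0).to_numpy()))
                    for c in sorted(hca.labels.unique())}
        early = min(peak_idx, key=peak_idx.get)
        late = max(peak_idx, key=peak_idx.get)
        p_early = ptm_enrichment(sub[sub["cluster"] == early], sub,
                                 min_psms=50, keys=("ox_class",))
        p_late = ptm_enrichment(sub[sub["cluster"] == late], sub,
                                min_psms=50, keys=("ox_class",))
        def _p(tab, cls):
            row = tab[tab["ox_class"] == cls]
            return float(row["p"].iloc[0]) if len(row) else 1.0
        enrich_ok = (early != late
                     and _p(p_early, OX_CLASS_KFND) < 0.01
                     and _p(p_late, OX_CLASS_CW) < 0.01)
        enrich_successes += int(enrich_ok)
        successes += int(ari >= 0.9 and enrich_ok)
    return {"median_ari": float(np.median(aris)),
            "ari_ge_0.9_rate": float(np.mean(np.asarray(aris) >= 0.9)),
            "enrichment_rate": enrich_successes / n_seeds,
            "joint_success_rate": successes / n_seeds, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# redox classification

def redox_accuracy_study(seed: int = 7000, tol: float = 0.010) -> dict:
    """State-call accuracy on noise-free tags and under Gaussian tag-mass
    noise with sigma = tol/3."""
    out = {}
    for label, noise in (("noise_free", 0.0), ("noisy", tol / 3.0)):
        cfg = SimConfig(n_proteins=100, peptides_per_protein=8, seed=seed,
                        decoy_fraction=0.0, mass_noise_ppm=0.0,
                        site_error_rate=0.0, peptide_detect_prob=1.0,
                        tag_mass_noise=noise)
        psms, _, truth = _simulate(cfg)
        calls = classify_cys_states(psms, tol=tol)
        redox_forms = set(truth.modified_peptide_truth
                          .query("wave_id == 'redox'")["pepform_id"])
        merged = calls.merge(psms[["spectrum_id", "truth_pepform"]],
                             on="spectrum_id")
        expected = np.where(merged["truth_pepform"].isin(redox_forms),
                            CysState.REVERSIBLY_OXIDIZED.value,
                            CysState.REDUCED.value)
        out[f"accuracy_{label}"] = float((merged["state"] == expected).mean())
        out[f"n_calls_{label}"] = len(merged)
    return out


# ---------------------------------------------------------------------------
# exact-statistic oracle agreement

def hypergeometric_oracle_agreement(max_n: int = 12) -> dict:
    """Max |analytic - enumerated| tail probability over every
    (N <= max_n, K, n, k)."""
    worst = 0.0
    checked = 0
    for N in range(1, max_n + 1):
        items = list(range(N))
        for K in range(N + 1):
            marked = set(items[:K])
            for n in range(N + 1):
                overlaps = np.array([len(marked.intersection(d))
                                     for d in itertools.combinations(items, n)])
                for k in range(min(K, n) + 1):
                    exact = float(np.mean(overlaps >= k))
                    worst = max(worst, abs(hypergeom_sf(k, N, K, n) - exact))
                    checked += 1
    return {"max_abs_error": worst, "n_checked": checked}


def _enumerated_kw_p(groups) -> float:
    vals = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    h_obs, _ = group_difference_tests(groups, test="kruskal_wallis")
    assign0 = [gi for gi, sz in enumerate(sizes) for _ in range(sz)]
    ranks = rankdata(vals)
    n = len(vals)
    count = total = 0
    for perm in set(itertools.permutations(assign0)):
        h = 0.0
        for gi in range(len(sizes)):
            r = ranks[[i for i, a in enumerate(perm) if a == gi]]
            h += r.sum() ** 2 / len(r)
        h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
        total += 1
        count += h >= h_obs - 1e-12
    return count / total


def _enumerated_mw_p(a, b) -> float:
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    na = len(a)
    u_obs = float(np.sum(ranks[:na]) - na * (na + 1) / 2)
    n = len(pooled)
    us = []
    for comb in itertools.combinations(range(n), na):
        u = float(np.sum(ranks[list(comb)]) - na * (na + 1) / 2)
        us.append(u)
    us = np.asarray(us)
    mean_u = na * (len(b)) / 2.0
    # two-sided: values at least as extreme in |U - mean|
    return float(np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12))


def rank_test_oracle_agreement(seed: int = 8000) -> dict:
    """Max |p_implementation - p_enumeration| for Mann-Whitney and
    Kruskal-Wallis on tie-free samples with total n <= 8."""
    rng = np.random.default_rng(seed)
    worst_mw = worst_kw = 0.0
    for sizes in [(3, 3), (4, 4), (3, 5), (2, 6)]:
        for _ in range(10):
            vals = rng.normal(size=sum(sizes))
            a, b = vals[:sizes[0]], vals[sizes[0]:]
            _, p = group_difference_tests([a, b], test="mann_whitney")
            worst_mw = max(worst_mw, abs(p - _enumerated_mw_p(a, b)))
    for sizes in [(3, 3), (2, 3, 3), (2, 2, 2), (4, 4)]:
        for _ in range(5):
            vals = rng.normal(size=sum(sizes))
            groups = []
            start = 0
            for sz in sizes:
                groups.append(vals[start:start + sz])
                start += sz
            _, p = group_difference_tests(groups, test="kruskal_wallis")
            worst_kw = max(worst_kw, abs(p - _enumerated_kw_p(groups)))
    return {"mann_whitney_max_abs_error": worst_mw,
            "kruskal_wallis_max_abs_error": worst_kw}


def truncation_oracle_agreement(seed: int = 8100, n_cases: int = 300) -> dict:
    """Agreement of the truncation explainer with a brute-force subset-sum
    over contiguous terminal residue losses (peptides <= 8 residues)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_cases):
        pep = "".join(rng.choice(list(M.AMINO_ACIDS),
                                 size=int(rng.integers(2, 9))))
        if rng.random() < 0.5:   # half the cases are true truncations
            d = int(rng.integers(1, min(3, len(pep)) + 1))
            res = pep[:d] if rng.random() < 0.5 else pep[-d:]
            dm = -sum(M.RESIDUE_MASS[a] for a in res)
        else:
            dm = -float(rng.uniform(50, 500))
        expl = shifts.check_truncation(pep, dm, tol=0.01, max_depth=3)
        matches = []
        for d in range(1, min(3, len(pep)) + 1):
            for term, res in (("N", pep[:d]), ("C", pep[-d:])):
                s = sum(M.RESIDUE_MASS[a] for a in res)
                if abs(s - (-dm)) <= 0.01:
                    matches.append((d, term))
        if expl is None:
            agree += not matches
        else:
            best = min(matches, key=lambda m: (m[0], m[1] != "N"))
            agree += (len(expl.residues), expl.terminus) == best
    return {"agreement_rate": agree / n_cases, "n_cases": n_cases}


# ---------------------------------------------------------------------------
# two-pass freezing

def pass2_freezing_study(seed: int = 9000) -> dict:
    """Max |Zq difference| between a quantification run with modified
    peptides included (pass 2) and one without them."""
    cfg = SimConfig(n_proteins=100, peptides_per_protein=8, seed=seed)
    psms, design, _ = _simulate(cfg)
    _, filt, peaks, curated = _shifts_chain(psms, design)
    lab, with_mod = _quantify(filt, peaks, curated, design)
    unmod_only = lab.copy()
    unmod_only["is_quantifiable"] = (unmod_only["is_quantifiable"]
                                     & ~unmod_only["is_modified"])
    without_mod = run_wspp(unmod_only, design)
    a = with_mod.protein_table.set_index(["protein", "sample_id"])["Zq"]
    b = without_mod.protein_table.set_index(["protein", "sample_id"])["Zq"]
    diff = (a - b).abs()
    return {"max_abs_zq_diff": float(diff.max()),
            "bit_identical": bool((a.to_numpy() == b.loc[a.index].to_numpy()).all()),
            "n_proteins": int(a.index.get_level_values(0).nunique())}
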