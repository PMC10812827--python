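"""End-to-end orchestration: simulate (or load) → recalibrate → peaks →
FDR → annotate → curate → quant → redox → categories → waves →
enrichment → group tests, from a single YAML config, with a run manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, categories as cat, io, quant as q, redox as rx, shifts, waves as wv
from .simulate import SimConfig, default_mod_list, generate_ground_truth, \
    make_design, make_fasta, simulate_psm_table

DEFAULT_THRESHOLDS = {
    "min_score": 0.15,        # calibration-subset corrected-XCorr gate
    "ppm_window": 20.0,       # calibration-subset ppm tolerance
    "bin_width": 0.001,       # ΔM histogram bin, Da
    "min_count": None,        # peak threshold; None = max(10, 5 x median occupied bin)
    "fdr": 0.01,              # PSM identification q-value threshold
    "match_tol": 0.010,       # ΔM annotation tolerance, Da
    "min_replicates": 4,      # curation: biological replicates per group
    "category_alpha": 0.05,   # category BH q threshold
    "category_min_size": 5,
    "category_max_size": 500,
    "min_psms": 50,           # enrichment reporting threshold
    "n_clusters": 2,
    "zp_filter_rule": "max_gt",
    "zp_filter_threshold": 0.0,
    "redox_tol": 0.010,
    "linkage": "average",
}

TRUTH_COLUMNS = ["truth_label", "truth_pepform", "truth_wave",
                 "truth_delta_mass", "truth_ppm_error"]


class ConfigError(ValueError):
    pass


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    if ("simulation" in config) == ("inputs" in config):
        raise ConfigError("config needs exactly one of a 'simulation' block "
                          "or an 'inputs' block")
    cfg = dict(config)
    thresholds = dict(DEFAULT_THRESHOLDS)
    extra = set(cfg.get("thresholds", {})) - set(thresholds)
    if extra:
        raise ConfigError(f"unknown threshold keys: {sorted(extra)}")
    thresholds.update(cfg.get("thresholds", {}))
    cfg["thresholds"] = thresholds
    cfg.setdefault("seed", 0)
    return cfg


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, fanned out from the global
    seed via a SeedSequence keyed on the stage name."""
    key = [seed] + [ord(c) for c in stage]
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2 ** 31))


class _Manifest:
    def __init__(self, cfg: dict):
        self.data = {
            "software_version": __version__,
            "seed": cfg.get("seed"),
            "config": {k: v for k, v in cfg.items() if k != "thresholds"},
            "thresholds": cfg["thresholds"],
            "stages": [],
        }
        self._t0 = time.time()

    def stage(self, name: str, n_in: int, n_out: int, **info):
        self.data["stages"].append(
            {"stage": name, "n_in": int(n_in), "n_out": int(n_out),
             "elapsed_s": round(time.time() - self._t0, 3), **info})
        self._t0 = time.time()

    def write(self, path):
        self.data["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.data, fh, indent=2, default=str)


def _peaks_frame(peaks) -> pd.DataFrame:
    return pd.DataFrame([{
        "peak_id": p.peak_id, "apex_deltam": p.apex_deltam, "low": p.low,
        "high": p.high, "psm_count": p.psm_count, "target_count": p.target_count,
        "decoy_count": p.decoy_count, "peak_fdr": p.peak_fdr,
        "annotation": p.annotation.name if p.annotation else "",
        "annotation_delta": p.annotation.delta_mass if p.annotation else np.nan,
        "is_artifact": bool(p.annotation.is_artifact) if p.annotation else False,
        "is_combination": bool(p.annotation.is_combination) if p.annotation else False,
    } for p in peaks])


def run_pipeline(config, out_dir=None) -> Path:
    """Execute all stages in order; every output is a versioned TSV under
    *out_dir* plus a ``manifest.json``. Re-running with the same config and
    seed reproduces all stage tables bit-identically."""
    cfg = load_config(config)
    th = cfg["thresholds"]
    out = Path(out_dir or cfg.get("output_dir", "results/run"))
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(cfg)

    # -- stage 1: simulate or load
    if "simulation" in cfg:
        sim_kwargs = dict(cfg["simulation"])
        sim_kwargs.setdefault("seed", derive_seed(cfg["seed"], "simulate"))
        sim = SimConfig(**sim_kwargs)
        truth = generate_ground_truth(sim)
        psms = simulate_psm_table(truth, sim)
        design = make_design(sim)
        mods = default_mod_list()
        categories = truth.categories
        io.write_psm_table(psms.drop(columns=TRUTH_COLUMNS), out / "psm_table.tsv")
        io._write_table(psms[["spectrum_id"] + TRUTH_COLUMNS],
                        out / "psm_truth.tsv", "truth")
        io.write_design(design, out / "design.tsv")
        io.write_mod_list(mods, out / "mods.tsv")
        io.write_categories(categories, out / "categories.tsv")
        io.write_fasta(make_fasta(truth), out / "database.fasta")
        manifest.stage("simulate", 0, len(psms), sim_seed=sim.seed)
        psms = psms.drop(columns=TRUTH_COLUMNS)
    else:
        paths = cfg["inputs"]
        psms = io.read_psm_table(paths["psm_table"])
        design = io.read_design(paths["design"])
        mods = io.read_mod_list(paths["mods"])
        categories = io.read_categories(paths["categories"])
        manifest.stage("load_inputs", 0, len(psms))

    # -- stage 2: recalibrate
    psms = shifts.recalibrate(psms, min_score=th["min_score"],
                              ppm_window=th["ppm_window"])
    io.write_psm_table(psms, out / "psms_recalibrated.tsv")
    manifest.stage("recalibrate", len(psms), len(psms),
                   offset_ppm=psms.attrs.get("recalibration_offset_ppm"))

    # -- stage 3: ΔM histogram, peak detection, assignment
    hist = shifts.build_deltam_histogram(psms, bin_width=th["bin_width"])
    peaks = shifts.detect_peaks(hist, min_count=th["min_count"])
    psms = shifts.assign_psms_to_peaks(psms, peaks)
    manifest.stage("peaks", len(psms), len(peaks), n_bins=len(hist.counts))

    # -- stage 4: three-scope FDR and the identification filter
    psms = shifts.compute_fdr(psms)
    io._write_table(psms[["spectrum_id", "q_global", "q_local", "q_peak"]],
                    out / "psms_fdr.tsv", "fdr")
    filtered = shifts.filter_fdr(psms, threshold=th["fdr"])
    manifest.stage("fdr", len(psms), len(filtered), threshold=th["fdr"])

    # -- stage 5: annotate peaks
    peaks = shifts.annotate_peaks(peaks, mods, match_tol=th["match_tol"])
    io._write_table(_peaks_frame(peaks), out / "peaks_annotated.tsv", "peaks")
    manifest.stage("annotate", len(peaks),
                   sum(p.annotation is not None for p in peaks))

    # -- stage 6: curation filter
    curated = shifts.curate_modified_peptides(filtered, peaks, design,
                                              min_replicates=th["min_replicates"])
    io._write_table(curated, out / "curated_peptides.tsv", "curated")
    manifest.stage("curate", len(filtered), len(curated))

    # -- stage 7: two-pass quantification
    labeled = q.label_peptidoforms(filtered, peaks)
    curated_keys = set(curated["peptide"] + "|" + curated["ptm_name"] + "|"
                       + curated["site_position"].astype(str))
    keep_mod = labeled["is_modified"] & labeled["pepform_id"].isin(curated_keys)
    labeled["is_quantifiable"] = \
        (labeled["is_quantifiable"] & ~labeled["is_modified"]) | keep_mod
    quant = q.run_wspp(labeled, design)
    io._write_table(quant.protein_table, out / "proteins_zq.tsv", "zq")
    io._write_table(quant.peptide_table, out / "peptides_zp.tsv", "zp")
    io._write_table(pd.DataFrame(quant.variances.items(),
                                 columns=["level", "sigma2"]),
                    out / "variances.tsv", "variances")
    manifest.stage("quant", int(labeled["is_quantifiable"].sum()),
                   len(quant.protein_table), **quant.variances)

    # -- stage 8: redox classification and reversible-oxidation time course
    calls = rx.classify_cys_states(filtered, tol=th["redox_tol"])
    io._write_table(calls, out / "redox_calls.tsv", "redox")
    redox_tc = rx.reversible_oxidation_timecourse(quant, design)
    io._write_table(redox_tc.values.reset_index(), out / "redox_timecourse.tsv",
                    "redox-tc")
    manifest.stage("redox", len(calls), len(redox_tc.values))

    # -- stage 9: category Zc with BH control
    zq = quant.zq_matrix()
    zc = cat.compute_category_z(zq, categories, min_size=th["category_min_size"],
                                max_size=th["category_max_size"])
    zc = cat.category_fdr(zc, alpha=th["category_alpha"])
    io._write_table(zc, out / "categories_zc.tsv", "zc")
    manifest.stage("categories", len(zq), len(zc))

    # -- stage 10: wave clustering of curated irreversible PTMs
    irreversible = curated[~curated["is_reversible_tag"]]
    irr_keys = set(irreversible["peptide"] + "|" + irreversible["ptm_name"] + "|"
                   + irreversible["site_position"].astype(str))
    zp = quant.zp_long(modified=True)
    zp = zp[zp["pepform_id"].isin(irr_keys)].rename(
        columns={"pepform_id": "row_id", "Zp": "z"})
    matrix = wv.build_timecourse_matrix(zp[["row_id", "sample_id", "z"]], design)
    clusters = pd.DataFrame(columns=["row_id", "cluster"])
    means = []
    if len(matrix.values) >= 2:
        hca = wv.hca_pearson(matrix.values, linkage_rule=th["linkage"],
                             n_clusters=th["n_clusters"])
        rule = (th["zp_filter_rule"], th["zp_filter_threshold"])
        clusters = hca.labels.rename_axis("row_id").reset_index()
        for c in sorted(hca.labels.unique()):
            res = wv.extract_wave_cluster(matrix, hca.labels, c, filter_rule=rule)
            m = res["mean"].to_frame().T
            m.insert(0, "cluster", c)
            m.insert(1, "n_rows", res["n"])
            means.append(m)
    io._write_table(clusters, out / "wave_clusters.tsv", "clusters")
    io._write_table(pd.concat(means, ignore_index=True) if means
                    else pd.DataFrame(), out / "wave_means.tsv", "wave-means")
    manifest.stage("waves", len(matrix.values), len(clusters))

    # -- stage 11: PTM and oxidized-protein enrichment
    labeled_curated = labeled[labeled["is_modified"]
                              & labeled["pepform_id"].isin(irr_keys)].copy()
    site = labeled_curated["site_position"].astype(int)
    labeled_curated["site_residue"] = [
        p[s - 1] if 1 <= s <= len(p) else "-"
        for p, s in zip(labeled_curated["peptide"], site)]
    labeled_curated["ptm_name"] = [pf.split("|")[1]
                                   for pf in labeled_curated["pepform_id"]]
    enrich_frames = []
    if len(clusters):
        member = clusters.set_index("row_id")["cluster"]
        labeled_curated["cluster"] = labeled_curated["pepform_id"].map(member)
        for c in sorted(member.unique()):
            sub = labeled_curated[labeled_curated["cluster"] == c]
            e = wv.ptm_enrichment(sub, labeled_curated, min_psms=th["min_psms"])
            e.insert(0, "cluster", c)
            enrich_frames.append(e)
    enrichment = (pd.concat(enrich_frames, ignore_index=True)
                  if enrich_frames else pd.DataFrame())
    io._write_table(enrichment, out / "ptm_enrichment.tsv", "enrichment")

    ox_names = {"Oxidation", "Dioxidation", "Trioxidation"}
    per_prot = labeled.groupby("protein").agg(
        total_psms=("spectrum_id", "size"),
        oxidized_psms=("pepform_id",
                       lambda s: sum(p.split("|")[1] in ox_names
                                     for p in s if "|" in p)))
    ox_enrich = wv.oxidized_protein_enrichment(per_prot.reset_index())
    io._write_table(ox_enrich, out / "oxidized_protein_enrichment.tsv", "ox-enrich")
    manifest.stage("enrichment", len(labeled_curated), len(enrichment))

    # -- stage 12: group-difference tests across reperfusion times
    test_rows = []
    group_of = design.sample_to_group()
    populations = [("irreversible", zp.rename(columns={"z": "Zp"}))]
    if not redox_tc.values.empty:
        redox_zp = quant.zp_long(modified=True)
        redox_zp = redox_zp[redox_zp["pepform_id"].isin(redox_tc.values.index)]
        populations.append(("redox", redox_zp.rename(columns={"pepform_id": "row_id"})))
    for name, table in populations:
        if len(table) == 0:
            continue
        table = table.copy()
        table["group"] = table["sample_id"].map(group_of)
        groups = [g["Zp"].to_numpy() for _, g in table.groupby("group", sort=False)]
        if len(groups) >= 2:
            h, p = wv.group_difference_tests(groups, test="kruskal_wallis")
            test_rows.append((name, "kruskal_wallis", h, p))
    tests = pd.DataFrame(test_rows, columns=["population", "test", "statistic", "p"])
    io._write_table(tests, out / "group_tests.tsv", "tests")
    manifest.stage("group_tests", len(test_rows), len(test_rows))

    manifest.write(out / "manifest.json")
    return out
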