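"""Oxidation-wave analysis of the demo data: Pearson-distance hierarchical
clustering (k = 2) of the curated irreversible PTM time courses, wave
extraction with the Zp filter, PCA, hypergeometric PTM enrichment of each
cluster, a per-protein oxidized-PSM enrichment, and Kruskal-Wallis tests
across reperfusion times — then a comparison against the generator truth."""

import importlib
import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

sys.path.insert(0, str(Path(__file__).parent))
cfgmod = importlib.import_module("00_config")

from oxwave import io
from oxwave.waves import (build_timecourse_matrix, extract_wave_cluster,
                          group_difference_tests, hca_pearson, max_gt,
                          oxidized_protein_enrichment, pca_scores, ptm_enrichment)

warnings.filterwarnings("ignore")

OX_NAMES = {"Oxidation", "Dioxidation", "Trioxidation"}


def main():
    inputs, out = cfgmod.INPUTS, cfgmod.RESULTS
    design = io.read_design(inputs / "design.tsv")
    curated = io._read_table(out / "curated_peptides.tsv", "curated")
    zp = io._read_table(out / "peptides_zp.tsv", "zp")
    zp["Zp"] = zp["Zp"].astype(float)
    truth = io._read_table(inputs / "modified_truth.tsv", "modtruth")

    irr = curated[curated["is_reversible_tag"] == "False"]
    keys = set(irr["peptide"] + "|" + irr["ptm_name"] + "|" + irr["site_position"])
    rows = zp[(zp["is_modified"] == "True") & zp["pepform_id"].isin(keys)]
    matrix = build_timecourse_matrix(
        rows.rename(columns={"pepform_id": "row_id", "Zp": "z"})
        [["row_id", "sample_id", "z"]], design)
    print(f"time-course matrix: {matrix.values.shape[0]} curated irreversible "
          f"peptidoforms x {matrix.values.shape[1]} time points")

    hca = hca_pearson(matrix.values, n_clusters=2)
    wave_of = truth.set_index("pepform_id")["wave_id"]
    ari = adjusted_rand_score(hca.labels.index.map(wave_of),
                              hca.labels.to_numpy())
    print(f"HCA at k=2 vs injected wave labels: adjusted Rand index {ari:.3f}")

    peak_tp = {}
    for c in sorted(hca.labels.unique()):
        res = extract_wave_cluster(matrix, hca.labels, c, filter_rule=max_gt(0.0))
        peak_tp[c] = res["mean"].idxmax()
        series = "  ".join(f"{v:+.2f}" for v in res["mean"])
        print(f"  cluster {c}: {res['n']} peptidoforms, peak at '{peak_tp[c]}', "
              f"mean Zp series [{series}]")
    order = design.timepoint_order
    early = min(peak_tp, key=lambda c: order.index(peak_tp[c]))
    late = max(peak_tp, key=lambda c: order.index(peak_tp[c]))

    scores, _, explained = pca_scores(matrix.values)
    print(f"PCA: first two components explain "
          f"{explained[0]:.1f} + {explained[1]:.1f} of the variance")

    # per-(PTM, residue) enrichment of each cluster's PSM population
    psm = rows.copy()
    psm["ptm_name"] = [p.split("|")[1] for p in psm["pepform_id"]]
    psm["site_residue"] = [p.split("|")[0][int(p.split("|")[2]) - 1]
                           for p in psm["pepform_id"]]
    psm["cluster"] = psm["pepform_id"].map(hca.labels)
    frames = []
    for c, label in ((early, "early"), (late, "late")):
        e = ptm_enrichment(psm[psm["cluster"] == c], psm, min_psms=50)
        e.insert(0, "cluster", label)
        frames.append(e)
        top = e.head(3)
        hits = ", ".join(f"{r.ptm_name}@{r.site_residue} (p={r.p:.1e})"
                         for r in top.itertuples())
        print(f"  {label} cluster enrichment: {hits}")
    enrichment = pd.concat(frames, ignore_index=True)

    filtered = io.read_psm_table(out / "psms_filtered.tsv")
    lab_ptm = filtered["peak_id"].map(
        io._read_table(out / "peaks.tsv", "peaks")
        .set_index("peak_id")["annotation"])
    per_prot = (filtered.assign(ox=lab_ptm.isin(OX_NAMES))
                .groupby("protein")
                .agg(total_psms=("spectrum_id", "size"), oxidized_psms=("ox", "sum")))
    ox_enrich = oxidized_protein_enrichment(per_prot.reset_index())
    n_sig = int((ox_enrich["q"] < 0.05).sum())
    print(f"oxidized-protein enrichment: {n_sig} proteins at q < 0.05")

    tests = []
    group_of = design.sample_to_group()
    for c, label in ((early, "early"), (late, "late")):
        sub = rows[rows["pepform_id"].isin(hca.labels[hca.labels == c].index)]
        groups = [g["Zp"].to_numpy()
                  for _, g in sub.groupby(sub["sample_id"].map(group_of))]
        h, p = group_difference_tests(groups, test="kruskal_wallis")
        tests.append((label, h, p))
        print(f"  Kruskal-Wallis across time groups, {label} cluster: "
              f"H={h:.1f}, p={p:.2e}")

    io._write_table(hca.labels.rename("cluster").rename_axis("pepform_id")
                    .reset_index(), out / "wave_clusters.tsv", "clusters")
    io._write_table(enrichment, out / "ptm_enrichment.tsv", "enrichment")
    io._write_table(ox_enrich, out / "oxidized_protein_enrichment.tsv", "ox-enrich")
    io._write_table(pd.DataFrame(tests, columns=["cluster", "H", "p"]),
                    out / "group_tests.tsv", "tests")
    io._write_table(scores.reset_index(names="pepform_id"),
                    out / "pca_scores.tsv", "pca")
    print(f"tables written to {out}")


if __name__ == "__main__":
    main()
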