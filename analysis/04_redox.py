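"""Redox readout of the demo data: classify every Cys-containing PSM as
reduced (carbamidomethyl tag) or reversibly oxidized (methylthio tag) and
build the replicate-averaged Zp time course of the reversibly oxidized Cys
peptidoforms."""

import importlib
import sys
import warnings
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
cfgmod = importlib.import_module("00_config")

from oxwave import io
from oxwave.redox import classify_cys_states
from oxwave.waves import build_timecourse_matrix

warnings.filterwarnings("ignore")


def main():
    inputs, out = cfgmod.INPUTS, cfgmod.RESULTS
    filtered = io.read_psm_table(out / "psms_filtered.tsv")
    design = io.read_design(inputs / "design.tsv")
    zp = io._read_table(out / "peptides_zp.tsv", "zp")
    zp["Zp"] = zp["Zp"].astype(float)

    calls = classify_cys_states(filtered)
    counts = calls["state"].value_counts()
    print(f"classified {len(calls)} Cys-containing PSMs: {counts.to_dict()}")

    rev = zp[(zp["is_modified"] == "True")
             & zp["pepform_id"].str.contains("|Methylthio_exchange|", regex=False)]
    tc = build_timecourse_matrix(
        rev.rename(columns={"pepform_id": "row_id", "Zp": "z"})
        [["row_id", "sample_id", "z"]], design)
    mean = tc.values.mean(axis=0)
    print(f"reversible Cys oxidation time course ({len(tc.values)} peptidoforms):")
    print("  " + "  ".join(f"{tp}:{m:+.2f}" for tp, m in mean.items()))
    print(f"  wave peaks at '{mean.idxmax()}' "
          f"(mean Zp {mean.max():.2f} vs baseline {mean.iloc[0]:+.2f})")

    io._write_table(calls, out / "redox_calls.tsv", "redox")
    io._write_table(tc.values.reset_index(names="pepform_id"),
                    out / "redox_timecourse.tsv", "redox-tc")
    print(f"tables written to {out}")


if __name__ == "__main__":
    main()
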