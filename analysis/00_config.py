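"""Shared settings for the demo analysis: one simulated ischemia/reperfusion
experiment (baseline + 7 reperfusion times, n = 4 replicates, one TMT
10-plex per replicate) analyzed end to end by the numbered scripts."""

from pathlib import Path

from oxwave.simulate import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "demo"
INPUTS = RESULTS / "inputs"

DEMO = SimConfig(
    n_proteins=150,
    peptides_per_protein=8,
    frac_modified=0.3,
    calib_offset_ppm=8.0,     # systematic miscalibration for stage 2 to remove
    seed=20240120,
)
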