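"""Shared fixtures: small simulated experiments and pre-run pipeline stages."""

import warnings

import pytest

from oxwave import quant as q, shifts
from oxwave.simulate import (SimConfig, default_mod_list, generate_ground_truth,
                             make_design, simulate_psm_table)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_proteins=60, peptides_per_protein=6, seed=11)


@pytest.fixture(scope="session")
def noise_free_config():
    """No mass error, no localization error, full detection, no decoys."""
    return SimConfig(
        n_proteins=60, peptides_per_protein=6, seed=12,
        mass_noise_ppm=0.0, calib_offset_ppm=0.0, site_error_rate=0.0,
        peptide_detect_prob=1.0, decoy_fraction=0.0, tag_mass_noise=0.0,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    truth = generate_ground_truth(small_config)
    psms = simulate_psm_table(truth, small_config)
    return psms, make_design(small_config), truth


@pytest.fixture(scope="session")
def processed(small_experiment):
    """The shifts chain run once: recalibrated, peak-assigned, FDR-filtered,
    annotated, curated."""
    psms, design, truth = small_experiment
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rec = shifts.recalibrate(psms)
        peaks = shifts.detect_peaks(shifts.build_deltam_histogram(rec))
        rec = shifts.assign_psms_to_peaks(rec, peaks)
        filtered = shifts.filter_fdr(shifts.compute_fdr(rec))
        peaks = shifts.annotate_peaks(peaks, default_mod_list())
        curated = shifts.curate_modified_peptides(filtered, peaks, design)
    return {"psms": rec, "filtered": filtered, "peaks": peaks,
            "curated": curated, "design": design, "truth": truth}


def run_quant(processed):
    """Label peptidoforms (modified ones restricted to the curated list)
    and run the two-pass quantification."""
    filtered, peaks, curated = (processed["filtered"], processed["peaks"],
                                processed["curated"])
    lab = q.label_peptidoforms(filtered, peaks)
    keys = set(curated["peptide"] + "|" + curated["ptm_name"] + "|"
               + curated["site_position"].astype(str))
    keep_mod = lab["is_modified"] & lab["pepform_id"].isin(keys)
    lab["is_quantifiable"] = (lab["is_quantifiable"] & ~lab["is_modified"]) | keep_mod
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return lab, q.run_wspp(lab, processed["design"])


@pytest.fixture(scope="session")
def quantified(processed):
    return run_quant(processed)
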