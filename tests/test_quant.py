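"""Hierarchical quantification: ratio computation, level integration,
variance fixed point, null calibration, effect recovery, pass-2 freezing."""

import warnings

import numpy as np
import pandas as pd
import pytest

from conftest import run_quant
from oxwave.io import DesignTable
from oxwave.quant import (compute_log2_ratios, estimate_level_variance,
                          integrate_level, label_peptidoforms, run_wspp)
from oxwave.simulate import SimConfig, generate_ground_truth, make_design, \
    simulate_psm_table


def _mini_design():
    return DesignTable(pd.DataFrame({
        "plex_id": ["plex1"] * 3,
        "channel_index": [1, 2, 3],
        "sample_id": ["ref", "a", "b"],
        "group_label": ["reference", "g1", "g2"],
        "timepoint_label": ["", "t1", "t2"],
        "is_reference": [True, False, False],
    }))


class TestLog2Ratios:
    def _psms(self, r1, r2, r3):
        return pd.DataFrame({
            "spectrum_id": ["s0"], "peptide": ["ACK"], "plex_id": ["plex1"],
            "pepform_id": ["ACK||0"], "protein": ["P1"], "is_modified": [False],
            "reporter_01": [r1], "reporter_02": [r2], "reporter_03": [r3],
        })

    def test_equal_sample_reference_zero(self):
        out = compute_log2_ratios(self._psms(100.0, 100.0, 200.0), _mini_design())
        assert out.loc[out["sample_id"] == "a", "x"].iloc[0] == 0.0
        assert out.loc[out["sample_id"] == "b", "x"].iloc[0] == 1.0

    def test_zero_sample_is_missing(self):
        out = compute_log2_ratios(self._psms(100.0, 0.0, 200.0), _mini_design())
        assert set(out["sample_id"]) == {"b"}

    def test_zero_reference_excludes_spectrum(self):
        with pytest.warns(UserWarning, match="reference"):
            with pytest.raises(ValueError):
                compute_log2_ratios(self._psms(0.0, 100.0, 200.0), _mini_design())


class TestIntegrateLevel:
    def test_single_child(self):
        parent, z = integrate_level([1.7], [2.0])
        assert parent == 1.7 and z[0] == 0.0

    def test_weighted_mean(self):
        parent, _ = integrate_level([0.0, 4.0], [1.0, 3.0])
        assert parent == 3.0

    def test_symmetric_deviations(self):
        parent, z = integrate_level([1.0, 3.0], [1.0, 1.0])
        assert parent == 2.0
        assert np.allclose(z, [-1.0, 1.0])

    def test_conservation(self):
        rng = np.random.default_rng(0)
        x, w = rng.normal(size=50), rng.uniform(0.5, 2.0, 50)
        parent, _ = integrate_level(x, w)
        assert abs(np.sum(w * (x - parent))) < 1e-9


class TestEstimateLevelVariance:
    def test_known_truth_recovered(self):
        rng = np.random.default_rng(1)
        n_parents, per = 200, 25
        codes = np.repeat(np.arange(n_parents), per)
        true_sigma2 = 0.25
        inv_prec = np.full(n_parents * per, 0.05)
        x = (rng.normal(0, 1.0, n_parents)[codes]
             + rng.normal(0, np.sqrt(true_sigma2 + 0.05), n_parents * per))
        est = estimate_level_variance(x, inv_prec, codes, n_parents)
        assert 0.2 <= est <= 0.3

    def test_zero_dispersion_gives_zero(self):
        codes = np.repeat(np.arange(10), 5)
        x = np.ones(50) * 2.0
        assert estimate_level_variance(x, 0.0, codes, 10) == 0.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        codes = np.repeat(np.arange(50), 10)
        x = rng.normal(0, 0.5, 500)
        perm = rng.permutation(500)
        a = estimate_level_variance(x, 0.02, codes, 50)
        b = estimate_level_variance(x[perm], 0.02, codes[perm], 50)
        assert np.isclose(a, b, rtol=1e-6)


@pytest.fixture(scope="module")
def null_quant():
    """Medium-size null experiment (no effects) quantified end to end."""
    cfg = SimConfig(n_proteins=500, peptides_per_protein=8, seed=31,
                    decoy_fraction=0.0, frac_modified=0.15,
                    site_error_rate=0.0).null()
    truth = generate_ground_truth(cfg)
    psms = simulate_psm_table(truth, cfg)
    design = make_design(cfg)
    from oxwave import shifts
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rec = shifts.recalibrate(psms)
        peaks = shifts.detect_peaks(shifts.build_deltam_histogram(rec))
        rec = shifts.assign_psms_to_peaks(rec, peaks)
        filt = shifts.filter_fdr(shifts.compute_fdr(rec))
        from oxwave.simulate import default_mod_list
        peaks = shifts.annotate_peaks(peaks, default_mod_list())
        lab = label_peptidoforms(filt, peaks)
        result = run_wspp(lab, design)
    return result


class TestRunWspp:
    def test_null_zq_calibrated(self, null_quant):
        zq = null_quant.protein_table["Zq"]
        assert len(zq) > 500
        assert abs(zq.mean()) < 0.05
        assert 0.9 <= zq.var() <= 1.1

    def test_null_zp_calibrated(self, null_quant):
        zp = null_quant.peptide_table["Zp"]
        assert len(zp) > 500
        assert abs(zp.mean()) < 0.05
        assert 0.9 <= zp.var() <= 1.1

    def test_injected_fold_change_recovered(self):
        cfg = SimConfig(n_proteins=80, peptides_per_protein=8, seed=33,
                        decoy_fraction=0.0, frac_modified=0.0, frac_redox=0.0,
                        category_effects={"shifted": (0, 1, 1, 1, 1, 1, 1, 1)})
        truth = generate_ground_truth(cfg)
        psms = simulate_psm_table(truth, cfg)
        psms["pepform_id"] = psms["peptide"] + "||0"
        psms["is_modified"] = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_wspp(psms, make_design(cfg))
        shifted = truth.categories["shifted"]
        prot = res.protein_table
        affected = prot[prot["protein"].isin(shifted)
                        & ~prot["sample_id"].str.startswith("baseline")]
        means = affected.groupby("protein")["x"].mean()
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 1.0) < 3 * se

    def test_modified_zp_tracks_injected_effect(self, quantified, processed):
        _, res = quantified
        truth = processed["truth"]
        zp = res.peptide_table[res.peptide_table["is_modified"]]
        wave = truth.modified_peptide_truth.set_index("pepform_id")["wave_id"]
        zp = zp.copy()
        zp["wave"] = zp["pepform_id"].map(wave)
        design = processed["design"]
        tp = design.sample_to_timepoint()
        zp["tp"] = zp["sample_id"].map(tp)
        # wave1 peaks at the first reperfusion time: mean Zp there is large
        w1 = zp[(zp["wave"] == "wave1")]
        peak_tp = design.timepoint_order[1]
        assert w1.loc[w1["tp"] == peak_tp, "Zp"].mean() > 1.0
        assert abs(w1.loc[w1["tp"] == "baseline", "Zp"].mean()) < 0.5

    def test_pass2_freezes_protein_values(self, processed):
        """Adding modified peptides never changes any protein's Zq."""
        lab, res_with = run_quant(processed)
        unmod_only = lab.copy()
        unmod_only["is_quantifiable"] = (unmod_only["is_quantifiable"]
                                         & ~unmod_only["is_modified"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res_without = run_wspp(unmod_only, processed["design"])
        pd.testing.assert_frame_equal(res_with.protein_table,
                                      res_without.protein_table,
                                      check_exact=True)

    def test_no_anchor_flagged(self):
        design = _mini_design()
        psms = pd.DataFrame({
            "spectrum_id": ["s0", "s1"],
            "peptide": ["ACK", "AMK"],
            "plex_id": ["plex1"] * 2,
            "pepform_id": ["ACK||0", "AMK|Oxidation|2"],
            "protein": ["P1", "P2"],          # P2 has no unmodified peptide
            "is_modified": [False, True],
            "reporter_01": [100.0, 100.0],
            "reporter_02": [120.0, 150.0],
            "reporter_03": [90.0, 80.0],
        })
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_wspp(psms, design)
        assert res.no_anchor == ["AMK|Oxidation|2"]
        assert not (res.peptide_table["pepform_id"] == "AMK|Oxidation|2").any()
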