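"""ΔM post-processing: recalibration, peaks, FDR, annotation, curation."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from oxwave import masses as M, shifts
from oxwave.io import ANY_RESIDUE, ModAnnotation
from oxwave.shifts import (DeltaMassHistogram, assign_psms_to_peaks, annotate_peaks,
                           build_deltam_histogram, check_site_position,
                           check_truncation, compute_fdr, curate_modified_peptides,
                           detect_peaks, filter_fdr, recalibrate)
from oxwave.simulate import (SimConfig, default_mod_list, generate_ground_truth,
                             make_design, simulate_psm_table)


def _toy_psms(dm, score=None, decoy=None, mass=1500.0):
    dm = np.asarray(dm, dtype=float)
    n = len(dm)
    return pd.DataFrame({
        "spectrum_id": [f"s{i}" for i in range(n)],
        "peptide": ["ACDEFK"] * n,
        "charge": 2,
        "theoretical_mass": mass,
        "observed_mass": mass + dm,
        "delta_mass": dm,
        "score": np.ones(n) if score is None else np.asarray(score, dtype=float),
        "is_decoy": np.zeros(n, bool) if decoy is None else np.asarray(decoy, bool),
        "protein": "P1",
        "site_position": pd.array([1] * n, dtype="Int64"),
        "plex_id": "plex1",
    })


class TestRecalibrate:
    def test_zero_offset_is_identity(self):
        psms = _toy_psms(np.zeros(100))
        out = recalibrate(psms)
        assert np.allclose(out["observed_mass"], psms["observed_mass"])
        assert np.allclose(out["delta_mass"], 0.0, atol=1e-9)

    def test_injected_offset_removed(self):
        cfg = SimConfig(n_proteins=60, peptides_per_protein=6, seed=21,
                        calib_offset_ppm=8.0)
        psms = simulate_psm_table(generate_ground_truth(cfg), cfg)
        out = recalibrate(psms)
        correct = out["truth_label"] == "correct"
        resid_ppm = ((out["delta_mass"] - out["truth_delta_mass"])
                     / out["observed_mass"] * 1e6)[correct]
        assert abs(np.median(resid_ppm)) < 1.0

    def test_low_score_excluded_from_subset_but_corrected(self):
        dm = np.full(200, 0.012)       # ~8 ppm at 1500 Da
        score = np.full(200, 0.5)
        score[0] = 0.10                # below the 0.15 gate
        psms = _toy_psms(dm, score=score)
        out = recalibrate(psms, min_score=0.15)
        # the gated PSM is corrected like every other
        assert np.isclose(out.loc[0, "observed_mass"], out.loc[1, "observed_mass"])
        assert abs(out["delta_mass"]).max() < 1e-3

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        psms = _toy_psms(rng.normal(0.012, 0.003, 500))
        once = recalibrate(psms)
        twice = recalibrate(once)
        assert np.allclose(once["observed_mass"], twice["observed_mass"], rtol=1e-10)

    def test_small_subset_skips_with_warning(self):
        psms = _toy_psms(np.zeros(5))
        with pytest.warns(UserWarning, match="skipping"):
            out = recalibrate(psms)
        pd.testing.assert_frame_equal(out, psms)

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            recalibrate(_toy_psms([]))


class TestHistogram:
    def test_all_zero_one_occupied_bin(self):
        hist = build_deltam_histogram(_toy_psms(np.zeros(50)), bin_width=0.001)
        occupied = hist.counts[hist.counts > 0]
        assert len(occupied) == 1 and occupied[0] == 50
        b = np.flatnonzero(hist.counts)[0]
        assert hist.edges[b] <= 0.0 < hist.edges[b + 1]

    def test_two_populations_separated(self):
        dm = np.concatenate([np.full(30, 15.995), np.full(30, 31.990)])
        hist = build_deltam_histogram(_toy_psms(dm))
        occ = np.flatnonzero(hist.counts)
        assert len(occ) == 2 and occ[1] - occ[0] > 100

    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        dm = rng.uniform(-50, 50, 5000)
        hist = build_deltam_histogram(_toy_psms(dm))
        assert hist.counts.sum() == 5000

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_deltam_histogram(_toy_psms([1.0]), bin_width=0.0)
        with pytest.raises(ValueError):
            build_deltam_histogram(_toy_psms([]))


class TestDetectPeaks:
    def test_single_spike_is_one_peak(self):
        counts = np.zeros(101, dtype=int)
        counts[50] = 40
        hist = DeltaMassHistogram(edges=np.arange(102) * 0.001, counts=counts)
        peaks = detect_peaks(hist, min_count=10)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.low <= p.apex_deltam < p.high
        assert np.isclose(p.high - p.low, 0.001)
        assert p.psm_count == 40

    def test_gaussian_cluster_over_uniform_noise(self):
        rng = np.random.default_rng(7)
        dm = np.concatenate([rng.normal(15.9949, 0.002, 500),
                             rng.uniform(-50, 50, 2000)])
        hist = build_deltam_histogram(_toy_psms(dm))
        peaks = detect_peaks(hist)
        assert len(peaks) == 1
        assert abs(peaks[0].apex_deltam - 15.9949) <= hist.bin_width

    def test_uniform_noise_yields_no_peaks(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            hist = build_deltam_histogram(_toy_psms(rng.uniform(-50, 50, 10_000)))
            assert detect_peaks(hist) == []


class TestAssign:
    def _peaks(self):
        return [shifts.DeltaMassPeak("peak_0000", 0.0, -0.005, 0.005),
                shifts.DeltaMassPeak("peak_0001", 15.9949, 15.99, 16.0)]

    def test_inside_and_boundary(self):
        psms = _toy_psms([0.0, 0.005, 15.995, 40.0])
        out = assign_psms_to_peaks(psms, self._peaks())
        assert out["peak_id"].tolist()[0] == "peak_0000"
        assert pd.isna(out["peak_id"].iloc[1])      # half-open upper bound
        assert out["peak_id"].tolist()[2] == "peak_0001"
        assert pd.isna(out["peak_id"].iloc[3])

    def test_overlapping_peaks_rejected(self):
        peaks = [shifts.DeltaMassPeak("a", 0.0, -0.01, 0.01),
                 shifts.DeltaMassPeak("b", 0.005, 0.0, 0.02)]
        with pytest.raises(ValueError, match="overlap"):
            assign_psms_to_peaks(_toy_psms([0.0]), peaks)

    def test_counts_match_truth_in_noise_free_simulation(self, noise_free_config):
        truth = generate_ground_truth(noise_free_config)
        psms = simulate_psm_table(truth, noise_free_config)
        hist = build_deltam_histogram(psms)
        peaks = detect_peaks(hist)
        out = assign_psms_to_peaks(psms, peaks)
        for p in peaks:
            expected = (np.abs(psms["truth_delta_mass"]
                               - p.apex_deltam) < 5e-4).sum()
            assert p.psm_count == expected
        assert out["peak_id"].notna().all()


class TestFdr:
    def test_no_decoys_all_q_zero(self):
        out = compute_fdr(_toy_psms([0.0] * 10, score=np.arange(10)))
        assert (out["q_global"] == 0.0).all()

    def test_symmetric_null_q_near_one(self):
        rng = np.random.default_rng(0)
        n = 4000
        scores = rng.normal(0, 1, n)
        decoy = np.zeros(n, bool)
        decoy[: n // 2] = True          # same distribution for both halves
        out = compute_fdr(_toy_psms(np.zeros(n), score=scores, decoy=decoy))
        assert out["q_global"].max() > 0.9

    def test_q_monotone_in_score(self, small_experiment):
        psms, _, _ = small_experiment
        out = compute_fdr(psms)
        # tie order matches the implementation's conservative decoys-first rule
        s = out.sort_values(["score", "is_decoy"], ascending=[False, False])
        assert (np.diff(s["q_global"]) >= -1e-12).all()

    def test_local_scope_uses_one_dalton_bins(self):
        # two 1-Da neighborhoods with very different decoy loads
        dm = np.array([0.0] * 50 + [15.9949] * 50)
        decoy = np.array([False] * 50 + [True, False] * 25)
        score = np.concatenate([np.linspace(2, 3, 50), np.linspace(2, 3, 50)])
        out = compute_fdr(_toy_psms(dm, score=score, decoy=decoy))
        clean = out[out["delta_mass"] == 0.0]
        dirty = out[out["delta_mass"] != 0.0]
        assert clean["q_local"].max() == 0.0
        assert dirty["q_local"].max() > 0.5

    def test_zero_targets_warns_q_one(self):
        with pytest.warns(UserWarning, match="no target"):
            out = compute_fdr(_toy_psms([100.0] * 5 + [0.0] * 5,
                                        decoy=[True] * 5 + [False] * 5))
        assert (out.loc[out["delta_mass"] == 100.0, "q_local"] == 1.0).all()

    def test_empirical_fdr_control(self, small_experiment):
        psms, _, _ = small_experiment
        filt = filter_fdr(compute_fdr(psms), threshold=0.01)
        fdp = (filt["truth_label"] != "correct").mean()
        assert fdp <= 0.03          # single-seed sanity bound


class TestAnnotate:
    def test_examples(self):
        mods = default_mod_list()
        peaks = [shifts.DeltaMassPeak("a", 15.9949, 15.99, 16.0),
                 shifts.DeltaMassPeak("b", 0.0, -0.005, 0.005),
                 shifts.DeltaMassPeak("c", 47.9847, 47.98, 47.99),
                 shifts.DeltaMassPeak("d", 5.0, 4.99, 5.01)]
        annotate_peaks(peaks, mods, match_tol=0.010)
        assert peaks[0].annotation.name == "Oxidation"
        assert peaks[1].annotation.name == "Unmodified"
        assert peaks[2].annotation.name == "Trioxidation"
        assert peaks[3].annotation is None

    def test_tie_break_by_distance_then_name(self):
        mods = [ModAnnotation("B_far", 10.002, frozenset("C")),
                ModAnnotation("A_near", 10.001, frozenset("C")),
                ModAnnotation("Z_near", 9.999, frozenset("C"))]
        peak = shifts.DeltaMassPeak("a", 10.000, 9.99, 10.01)
        annotate_peaks([peak], mods, match_tol=0.01)
        assert peak.annotation.name == "A_near"   # ties at 1 mDa: name order


class TestTruncation:
    def test_n_terminal_single_residue(self):
        expl = check_truncation("ACDEFK", -M.RESIDUE_MASS["A"])
        assert expl.terminus == "N" and expl.residues == "A"

    def test_c_terminal_pair(self):
        dm = -(M.RESIDUE_MASS["F"] + M.RESIDUE_MASS["K"])
        expl = check_truncation("ACDEFK", dm)
        assert expl.terminus == "C" and expl.residues == "FK"

    def test_zero_delta_none(self):
        assert check_truncation("ACDEFK", 0.0) is None

    def test_brute_force_oracle(self):
        """Every explanation matches an exhaustive subset-sum over contiguous
        terminal residue losses, for peptides up to 8 residues."""
        rng = np.random.default_rng(4)
        aas = list(M.AMINO_ACIDS)
        for _ in range(200):
            pep = "".join(rng.choice(aas, size=rng.integers(2, 9)))
            dm = -float(rng.uniform(50, 500))
            expl = check_truncation(pep, dm, tol=0.01, max_depth=3)
            # oracle: all prefix/suffix losses up to depth 3
            matches = []
            for d in range(1, min(3, len(pep)) + 1):
                for term, res in (("N", pep[:d]), ("C", pep[-d:])):
                    s = sum(M.RESIDUE_MASS[a] for a in res)
                    if abs(s - (-dm)) <= 0.01:
                        matches.append((d, term))
            if expl is None:
                assert matches == []
            else:
                best = min(matches, key=lambda m: (m[0], m[1] != "N"))
                assert (len(expl.residues), expl.terminus) == best


class TestSitePosition:
    ox = ModAnnotation("Oxidation", 15.9949, frozenset("MWCKFND"))

    def test_allowed_residue(self):
        assert check_site_position("AMK", 2, self.ox) is True

    def test_disallowed_residue(self):
        assert check_site_position("AGK", 2, self.ox) is False

    def test_terminus_convention(self):
        nt = ModAnnotation("Acetyl-like", 42.0106, frozenset({"N-term"}))
        assert check_site_position("AGK", 0, nt) is True
        assert check_site_position("AGK", 4, nt) is False

    def test_missing_site_indeterminate(self):
        assert check_site_position("AMK", None, self.ox) is None
        assert check_site_position("AMK", pd.NA, self.ox) is None


class TestCurate:
    def test_noise_free_recovers_truth_exactly(self, noise_free_config):
        truth = generate_ground_truth(noise_free_config)
        psms = simulate_psm_table(truth, noise_free_config)
        design = make_design(noise_free_config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = recalibrate(psms)
            peaks = detect_peaks(build_deltam_histogram(rec))
            rec = assign_psms_to_peaks(rec, peaks)
            filt = filter_fdr(compute_fdr(rec))
            peaks = annotate_peaks(peaks, default_mod_list())
            curated = curate_modified_peptides(filt, peaks, design)
        got = set(curated["peptide"] + "|" + curated["ptm_name"] + "|"
                  + curated["site_position"].astype(str))
        expected = set(truth.modified_peptide_truth
                       .query("wave_id != 'artifact'")["pepform_id"])
        assert got == expected

    def test_artifacts_and_combinations_excluded(self, processed):
        curated = processed["curated"]
        truth = processed["truth"]
        artifact_forms = set(truth.modified_peptide_truth
                             .query("wave_id == 'artifact'")["pepform_id"])
        got = set(curated["peptide"] + "|" + curated["ptm_name"] + "|"
                  + curated["site_position"].astype(str))
        assert got & artifact_forms == set()

    def test_replicate_threshold(self, processed):
        assert (processed["curated"]["n_replicates_detected"] >= 4).all()
        # rerunning with an impossible threshold empties the list
        strict = curate_modified_peptides(processed["filtered"],
                                          processed["peaks"],
                                          processed["design"],
                                          min_replicates=5)
        assert strict.empty

    def test_row_order_invariance(self, processed):
        filt = processed["filtered"]
        shuffled = filt.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = curate_modified_peptides(filt, processed["peaks"], processed["design"])
        b = curate_modified_peptides(shuffled, processed["peaks"],
                                     processed["design"])
        pd.testing.assert_frame_equal(a, b)
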