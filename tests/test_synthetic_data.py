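import filecmp
import json

import numpy as np
import pandas as pd
import pytest

from skintrait_pop.genotype_io import read_vcf_panel
from skintrait_pop.panel_model import load_panel
from skintrait_pop.qc_filters import apply_qc
from skintrait_pop.synthetic_data import (PlantedCorrelation, SimulationConfig,
                                          SimulationError, make_fixture_suite,
                                          simulate_frequencies,
                                          simulate_genotypes,
                                          simulate_questionnaire)
from skintrait_pop.trait_scoring import grs_rac_scores


class TestFrequencies:
    def test_f_zero_copies_ancestral(self):
        freqs = simulate_frequencies(100, {"A": 0.0}, seed=1)
        np.testing.assert_array_equal(freqs["A"], freqs["ancestral"])

    def test_fixed_seed_is_bit_identical(self):
        f1 = simulate_frequencies(50, {"A": 0.1, "B": 0.2}, seed=42)
        f2 = simulate_frequencies(50, {"A": 0.1, "B": 0.2}, seed=42)
        pd.testing.assert_frame_equal(f1, f2)

    def test_balding_nichols_variance_matches_closed_form(self):
        """Var(p_pop | p) = F * p * (1-p), checked over 10,000 loci."""
        F = 0.05
        freqs = simulate_frequencies(10_000, {"A": F},
                                     ancestral_range=(0.3, 0.3001), seed=3)
        p = freqs["ancestral"].mean()
        expected = F * p * (1 - p)
        observed = freqs["A"].var()
        assert observed == pytest.approx(expected, rel=0.1)

    def test_invalid_f_rejected(self):
        with pytest.raises(SimulationError):
            simulate_frequencies(10, {"A": 1.0}, seed=1)


class TestGenotypes:
    def test_fixed_frequency_limits(self):
        freqs = pd.DataFrame({"ancestral": [0.0], "A": [0.0]})
        m, _ = simulate_genotypes(freqs, {"A": 50}, seed=1)
        assert (m.dosage == 0).all()

    def test_heterozygote_fraction_at_half(self):
        """p=0.5 under HWE: heterozygote fraction 0.5 within 3 SE at n=10,000."""
        freqs = pd.DataFrame({"ancestral": [0.5], "A": [0.5]})
        m, _ = simulate_genotypes(freqs, {"A": 10_000}, seed=2)
        het = (m.dosage == 1).mean()
        assert abs(het - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_vcf_round_trip_reproduces_matrix(self, tmp_path):
        """Reading the emitted VCF returns the generator's dosages exactly."""
        from skintrait_pop.synthetic_data import simulate_panel
        rng = np.random.default_rng(9)
        panels = simulate_panel(rng, n_traits=4, variants_per_trait=[3, 3, 2, 2])
        freqs = simulate_frequencies(10, {"A": 0.05, "B": 0.05}, rng=rng)
        vcf = tmp_path / "g.vcf"
        m, _ = simulate_genotypes(freqs, {"A": 20, "B": 20}, missing_rate=0.05,
                                  panels=panels, rng=rng, vcf_path=vcf,
                                  r2_range=(0.8, 1.0))
        r = read_vcf_panel(vcf, panels)
        assert r.sample_ids == m.sample_ids
        assert r.rsids == m.rsids
        np.testing.assert_array_equal(r.dosage, m.dosage)
        np.testing.assert_allclose(r.impute_r2, m.impute_r2)


class TestQuestionnaire:
    def scores_for(self, rng, n=96, trait="wrinkles"):
        ids = [f"VN_{i:04d}" for i in range(n)]
        return pd.DataFrame({"sample_id": ids, "trait": trait,
                             "score": rng.normal(5, 2, size=n),
                             "n_variants_used": 3}), ids

    def test_zero_rho_stays_in_null_band(self):
        rng = np.random.default_rng(10)
        scores, ids = self.scores_for(rng)
        meta, codebook = simulate_questionnaire(
            scores, [PlantedCorrelation("v", "wrinkles", 0.0)], ids, rng=rng)
        r = np.corrcoef(meta["v"].astype(float),
                        scores.set_index("sample_id").loc[ids, "score"])[0, 1]
        assert abs(r) < 3 / np.sqrt(96)

    def test_planted_rho_recovered_within_fisher_z_interval(self):
        rho = 0.45
        rng = np.random.default_rng(11)
        scores, ids = self.scores_for(rng)
        meta, _ = simulate_questionnaire(
            scores, [PlantedCorrelation("v", "wrinkles", rho)], ids, rng=rng)
        r = np.corrcoef(meta["v"].astype(float),
                        scores.set_index("sample_id").loc[ids, "score"])[0, 1]
        z, z0 = np.arctanh(r), np.arctanh(rho)
        assert abs(z - z0) < 3 / np.sqrt(96 - 3)

    def test_binary_thresholding_attenuates_but_keeps_sign(self):
        rng = np.random.default_rng(12)
        scores, ids = self.scores_for(rng)
        meta, codebook = simulate_questionnaire(
            scores, [PlantedCorrelation("flag", "wrinkles", 0.8, kind="binary",
                                        prevalence=0.5)], ids, rng=rng)
        coded = meta["flag"].map({"yes": 1, "no": 0}).astype(float)
        r = np.corrcoef(coded, scores.set_index("sample_id").loc[ids, "score"])[0, 1]
        assert 0.2 < r < 0.8  # positive but attenuated point-biserial
        assert codebook["flag"]["type"] == "binary"

    def test_duplicate_variable_names_rejected(self):
        rng = np.random.default_rng(13)
        scores, ids = self.scores_for(rng)
        with pytest.raises(SimulationError, match="duplicate"):
            simulate_questionnaire(scores,
                                   [PlantedCorrelation("v", "wrinkles", 0.1),
                                    PlantedCorrelation("v", "wrinkles", 0.2)],
                                   ids, rng=rng)


class TestFixtureSuite:
    def test_all_files_present_and_truth_parses(self, fixture_suite):
        config, paths = fixture_suite
        for p in paths.values():
            assert p.exists()
        truth = json.loads(paths["truth"].read_text())
        assert truth["n_traits"] == 25
        assert truth["n_variants"] == 85
        assert truth["seed"] == config.seed

    def test_same_seed_reproduces_identical_bytes(self, tmp_path):
        cfg = SimulationConfig(seed=21, n_traits=5, variants_per_trait=[2] * 5,
                               populations=SimulationConfig(seed=0).populations[:1],
                               planted=[PlantedCorrelation("v", "freckles", 0.3)],
                               survey_n=50)
        p1 = make_fixture_suite(cfg, tmp_path / "a")
        p2 = make_fixture_suite(cfg, tmp_path / "b")
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_refuses_non_empty_directory(self, tmp_path):
        out = tmp_path / "x"
        out.mkdir()
        (out / "stale.txt").write_text("old")
        with pytest.raises(SimulationError, match="not empty"):
            make_fixture_suite(SimulationConfig(seed=1, n_traits=2,
                                                variants_per_trait=[1, 1]), out)

    def test_generated_cohort_passes_default_qc(self, fixture_suite,
                                                fixture_matrix):
        """At the default low missingness every variant survives QC and only
        occasional samples fall below the 98% call-rate bar."""
        filtered, report = apply_qc(fixture_matrix)
        assert filtered.n_variants == fixture_matrix.n_variants
        assert filtered.n_samples >= 0.95 * fixture_matrix.n_samples

    def test_scores_respect_truth_bounds(self, fixture_suite, fixture_matrix,
                                         fixture_panels):
        _, paths = fixture_suite
        truth = json.loads(paths["truth"].read_text())
        scores = grs_rac_scores(fixture_matrix, fixture_panels)
        for trait, (lo, hi) in truth["score_bounds"].items():
            s = scores.loc[scores["trait"] == trait, "score"]
            assert s.between(lo, hi).all()

    def test_planted_correlation_recovered_from_files(self, fixture_suite,
                                                      fixture_matrix,
                                                      fixture_panels):
        """End-to-end: panel+VCF+metadata files reproduce the planted rho."""
        config, paths = fixture_suite
        meta = pd.read_csv(paths["metadata"], sep="\t")
        scores = grs_rac_scores(fixture_matrix, fixture_panels)
        wide = scores.pivot(index="sample_id", columns="trait", values="score")
        planted = config.planted[0]  # continuous: wrinkle_severity ~ wrinkles
        merged = meta.merge(wide[[planted.trait]], on="sample_id")
        r = np.corrcoef(merged[planted.variable], merged[planted.trait])[0, 1]
        z, z0 = np.arctanh(r), np.arctanh(planted.rho)
        assert abs(z - z0) < 3 / np.sqrt(len(merged) - 3)
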