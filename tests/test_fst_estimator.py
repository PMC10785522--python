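import numpy as np
import pandas as pd
import pytest

from skintrait_pop.fst_estimator import (FstComponents, FstError, LocusPopStats,
                                         locus_pop_stats, mean_of_ratios_fst,
                                         pairwise_fst, wc_components,
                                         weighted_fst)
from skintrait_pop.synthetic_data import simulate_frequencies, simulate_genotypes

from conftest import make_matrix
from oracles import wc_components_scalar


def stats_from(n, p, h, r=None):
    n = np.atleast_2d(np.asarray(n, dtype=float).reshape(len(n), -1))
    p = np.atleast_2d(np.asarray(p, dtype=float).reshape(len(p), -1))
    h = np.atleast_2d(np.asarray(h, dtype=float).reshape(len(h), -1))
    return LocusPopStats(populations=[f"P{i}" for i in range(n.shape[0])],
                         loci=[f"L{j}" for j in range(n.shape[1])], n=n, p=p, h=h)


class TestLocusPopStats:
    samples = pd.DataFrame({
        "sample_id": ["A0", "A1", "A2", "B0", "B1", "B2"],
        "population": ["P1"] * 3 + ["P2"] * 3,
        "cohort": "",
    })

    def test_counts_frequency_heterozygosity(self):
        m = make_matrix([[0], [1], [2], [0], [1], [2]],
                        sample_ids=list(self.samples["sample_id"]))
        s = locus_pop_stats(m, self.samples, ["P1", "P2"])
        assert s.n[0, 0] == 3 and s.p[0, 0] == 0.5 and s.h[0, 0] == pytest.approx(1 / 3)
        np.testing.assert_allclose(s.p[0], s.p[1])  # identical dosage vectors

    def test_all_missing_population_flagged(self):
        m = make_matrix([[np.nan], [np.nan], [np.nan], [0], [1], [2]],
                        sample_ids=list(self.samples["sample_id"]))
        s = locus_pop_stats(m, self.samples, ["P1", "P2"])
        assert s.n[0, 0] == 0 and np.isnan(s.p[0, 0])
        comp = wc_components(s)
        assert not comp.defined[0]

    def test_unknown_population_label(self):
        m = make_matrix([[0]] * 6, sample_ids=list(self.samples["sample_id"]))
        with pytest.raises(FstError, match="unknown population"):
            locus_pop_stats(m, self.samples, ["P1", "XX"])


class TestWcComponents:
    def test_fixed_difference_gives_theta_one(self):
        """Populations fixed for alternate alleles: a=0.5, b=c=0, theta=1."""
        s = stats_from([10, 10], [1.0, 0.0], [0.0, 0.0])
        comp = wc_components(s)
        assert comp.a[0] == pytest.approx(0.5, abs=1e-12)
        assert comp.b[0] == pytest.approx(0.0, abs=1e-12)
        assert comp.c[0] == 0.0
        assert comp.theta[0] == pytest.approx(1.0, abs=1e-12)

    def test_monomorphic_locus_undefined(self):
        s = stats_from([10, 10], [0.0, 0.0], [0.0, 0.0])
        comp = wc_components(s)
        assert comp.a[0] == 0 and comp.b[0] == 0 and comp.c[0] == 0
        assert np.isnan(comp.theta[0])

    @pytest.mark.parametrize("n,p,h", [
        ([10, 14], [0.35, 0.60], [0.30, 0.50]),
        ([8, 20], [0.10, 0.15], [0.125, 0.25]),
        ([30, 30, 40], [0.2, 0.5, 0.8], [0.3, 0.5, 0.3]),
    ])
    def test_matches_step_by_step_oracle(self, n, p, h):
        """Vectorized components equal an independent scalar evaluation."""
        comp = wc_components(stats_from(n, p, h))
        a, b, c = wc_components_scalar(n, p, h)
        assert comp.a[0] == pytest.approx(a, rel=1e-12)
        assert comp.b[0] == pytest.approx(b, rel=1e-12)
        assert comp.c[0] == pytest.approx(c, rel=1e-12)

    def test_label_exchange_invariance(self):
        s1 = stats_from([10, 14], [0.35, 0.60], [0.30, 0.50])
        s2 = stats_from([14, 10], [0.60, 0.35], [0.50, 0.30])
        assert wc_components(s1).theta[0] == pytest.approx(
            wc_components(s2).theta[0], rel=1e-12)

    def test_single_population_rejected(self):
        with pytest.raises(FstError, match="at least 2"):
            wc_components(stats_from([10], [0.5], [0.5]))

    def test_theta_bounded_by_one(self):
        rng = np.random.default_rng(0)
        n = rng.integers(5, 50, size=(2, 200)).astype(float)
        p = rng.uniform(0, 1, size=(2, 200))
        h = np.minimum(2 * p * (1 - p), 1.0) * rng.uniform(0, 1, size=(2, 200))
        comp = wc_components(LocusPopStats(["A", "B"], [str(i) for i in range(200)],
                                           n, p, h))
        t = comp.theta
        assert np.all(t[np.isfinite(t)] <= 1.0 + 1e-12)


class TestWeightedFst:
    def test_single_locus_reduces_to_theta(self):
        comp = wc_components(stats_from([10, 14], [0.35, 0.60], [0.30, 0.50]))
        assert weighted_fst(comp) == pytest.approx(comp.theta[0])

    def test_copies_of_fixed_difference_locus_give_exactly_one(self):
        comp = FstComponents(loci=list("abc"), a=np.array([0.5] * 3),
                             b=np.zeros(3), c=np.zeros(3))
        assert weighted_fst(comp) == 1.0

    def test_ratio_of_sums_not_mean_of_ratios(self):
        """Heterogeneous loci: sum(a)/sum(a+b+c) differs from mean theta."""
        comp = FstComponents(loci=["l1", "l2"], a=np.array([0.5, 0.1]),
                             b=np.array([0.0, 0.9]), c=np.zeros(2))
        assert weighted_fst(comp) == pytest.approx(0.6 / 1.5)  # 0.4
        assert mean_of_ratios_fst(comp) == pytest.approx(0.55)

    def test_mixture_with_undifferentiated_locus(self):
        comp = FstComponents(loci=["l1", "l2"], a=np.array([0.5, 0.0]),
                             b=np.array([0.0, 0.5]), c=np.zeros(2))
        assert weighted_fst(comp) == pytest.approx(0.5)

    def test_all_undefined_errors(self):
        comp = FstComponents(loci=["l1"], a=np.array([np.nan]),
                             b=np.array([np.nan]), c=np.array([np.nan]))
        with pytest.raises(FstError):
            weighted_fst(comp)


class TestPairwiseFst:
    def simulate_pair(self, F, seed, n_loci=1000, n=100):
        rng = np.random.default_rng(seed)
        freqs = simulate_frequencies(n_loci, {"A": F, "B": F},
                                     ancestral_range=(0.1, 0.9), rng=rng)
        matrix, samples = simulate_genotypes(freqs, {"A": n, "B": n}, rng=rng)
        return matrix, samples

    def test_three_populations_symmetric_matrix(self):
        rng = np.random.default_rng(2)
        freqs = simulate_frequencies(50, {"A": 0.1, "B": 0.1, "C": 0.1}, rng=rng)
        matrix, samples = simulate_genotypes(freqs, {"A": 30, "B": 30, "C": 30},
                                             rng=rng)
        res = pairwise_fst(matrix, samples)
        vals = res.values
        assert np.allclose(vals.to_numpy(), vals.to_numpy().T, equal_nan=True)
        offdiag = vals.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.isfinite(offdiag).all()

    def test_duplicated_population_near_zero(self):
        """The same samples under two labels show (near-)zero differentiation."""
        matrix, samples = self.simulate_pair(0.2, seed=3, n_loci=500, n=80)
        dup = samples.copy()
        dup["population"] = dup["population"].map({"A": "A", "B": "A2"})
        dup.loc[:len(dup) // 2, "population"] = "A"
        # split population A's samples into two labels at random
        rng = np.random.default_rng(4)
        a_idx = samples.index[samples["population"] == "A"]
        labels = np.where(rng.uniform(size=len(a_idx)) < 0.5, "A1", "A2")
        samples2 = samples.loc[a_idx].copy()
        samples2["population"] = labels
        sub = matrix.subset(sample_idx=np.array(
            [matrix.sample_ids.index(s) for s in samples2["sample_id"]]))
        res = pairwise_fst(sub, samples2)
        assert abs(res.values.loc["A1", "A2"]) < 0.01

    def test_balding_nichols_recovery_at_f005(self):
        """Single simulation at F=0.05 lands within +/-0.01 of the planted value."""
        matrix, samples = self.simulate_pair(0.05, seed=12345)
        res = pairwise_fst(matrix, samples)
        assert res.values.loc["A", "B"] == pytest.approx(0.05, abs=0.01)
        assert res.n_loci.loc["A", "B"] == 1000

    def test_small_population_pair_skipped(self, caplog):
        matrix, samples = self.simulate_pair(0.05, seed=5, n_loci=20, n=10)
        samples = pd.concat([samples, pd.DataFrame(
            [{"sample_id": "L0", "population": "LONE", "cohort": ""}])],
            ignore_index=True)
        with caplog.at_level("WARNING"):
            res = pairwise_fst(matrix, samples, ["A", "B", "LONE"])
        assert np.isnan(res.values.loc["A", "LONE"])
        assert np.isfinite(res.values.loc["A", "B"])
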