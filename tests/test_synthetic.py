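"""Generative model: closed-form marginals, couplings, determinism."""

import numpy as np
import pytest

from xescape.locus_model import Sex, filter_diploid, summarize_counts
from xescape.synthetic import (
    LocusSim,
    SimConfig,
    pair_category_probs,
    simulate_pair,
    simulate_qpcr,
    simulate_single_locus,
)


def _two_signal_fraction(scores, locus="L"):
    s = summarize_counts(list(scores), locus)
    return s.n2 / s.n_scored


class TestSingleLocus:
    def test_full_escape_perfect_detection_all_biallelic(self):
        cfg = SimConfig(
            loci=(LocusSim("L", 1.0, 1.0),), n_nuclei=50,
            control_detection=1.0, seed=0,
        )
        assert all(s.test_signals == 2 for s in simulate_single_locus(cfg))

    def test_male_one_signal_fraction_tracks_detection(self):
        cfg = SimConfig(
            loci=(LocusSim("L", 0.0, 0.98),), n_nuclei=10_000,
            sex=Sex.MALE, control_detection=1.0, seed=3,
        )
        scores = simulate_single_locus(cfg)
        frac = np.mean([s.test_signals == 1 for s in scores])
        se = np.sqrt(0.98 * 0.02 / 10_000)
        assert abs(frac - 0.98) < 3 * se
        assert all(s.test_signals <= 1 for s in scores)

    def test_female_two_signal_fraction_matches_e_d_squared(self):
        e, d, n = 0.2, 0.97, 10_000
        cfg = SimConfig(
            loci=(LocusSim("L", e, d),), n_nuclei=n,
            control_detection=1.0, seed=3,
        )
        frac = _two_signal_fraction(simulate_single_locus(cfg))
        p = e * d * d
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * se

    def test_large_n_two_signal_fraction_converges_to_e(self):
        # with perfect detection the 2X-active fraction estimates e directly
        e, n = 0.35, 100_000
        cfg = SimConfig(
            loci=(LocusSim("L", e, 1.0),), n_nuclei=n,
            control_detection=1.0, seed=5,
        )
        frac = _two_signal_fraction(simulate_single_locus(cfg))
        se = np.sqrt(e * (1 - e) / n)
        assert abs(frac - e) < 3 * se

    def test_config_validation(self):
        with pytest.raises(ValueError):
            LocusSim("L", 1.2, 1.0)
        with pytest.raises(ValueError):
            LocusSim("L", 0.5, 0.0)
        with pytest.raises(ValueError):
            SimConfig(loci=(LocusSim("L", 0.5, 1.0),), n_nuclei=0)
        with pytest.raises(ValueError):
            SimConfig(loci=(LocusSim("L", 0.5, 1.0),), n_nuclei=10, coordination=1.5)


class TestPairCoupling:
    @staticmethod
    def _escapes(scores):
        a = np.array([s.locus_a_signals == 2 for s in scores])
        b = np.array([s.locus_b_signals == 2 for s in scores])
        return a, b

    def _run(self, e_a, e_b, rho, n, seed=11):
        cfg = SimConfig(
            loci=(LocusSim("A", e_a, 1.0), LocusSim("B", e_b, 1.0)),
            n_nuclei=n, coordination=rho, seed=seed, control_detection=1.0,
        )
        return simulate_pair(cfg)

    def test_independent_coupling_product_rate(self):
        a, b = self._escapes(self._run(0.5, 0.5, 0.0, 20_000))
        p = 0.25
        se = np.sqrt(p * (1 - p) / 20_000)
        assert abs(np.mean(a & b) - p) < 3 * se

    def test_comonotone_coupling_equal_e_forces_identity(self):
        a, b = self._escapes(self._run(0.3, 0.3, 1.0, 5_000, seed=9))
        assert np.array_equal(a, b)

    def test_comonotone_coupling_unequal_e_gives_min_rate(self):
        a, b = self._escapes(self._run(0.2, 0.4, 1.0, 20_000))
        p = 0.2  # comonotone: joint escape at min(e_a, e_b)
        se = np.sqrt(p * (1 - p) / 20_000)
        assert abs(np.mean(a & b) - p) < 3 * se
        # the lower-probability event is nested in the higher one
        assert not np.any(a & ~b)

    @pytest.mark.parametrize("rho", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_marginal_escape_rates_invariant_to_coupling(self, rho):
        e_a, e_b, n = 0.3, 0.55, 40_000
        a, b = self._escapes(self._run(e_a, e_b, rho, n, seed=21))
        se_a = np.sqrt(e_a * (1 - e_a) / n)
        se_b = np.sqrt(e_b * (1 - e_b) / n)
        assert abs(np.mean(a) - e_a) < 3 * se_a
        assert abs(np.mean(b) - e_b) < 3 * se_b

    def test_requires_exactly_two_loci(self):
        cfg = SimConfig(loci=(LocusSim("A", 0.3, 1.0),), n_nuclei=10, seed=0)
        with pytest.raises(ValueError, match="exactly two"):
            simulate_pair(cfg)

    def test_category_probs_match_mixture_formula(self):
        a_only, b_only, both = pair_category_probs(0.2, 0.4, 0.5)
        p_both = 0.5 * 0.2 + 0.5 * 0.08
        union = 0.2 + 0.4 - p_both
        assert both == pytest.approx(p_both / union)
        assert a_only + b_only + both == pytest.approx(1.0)


class TestQpcrSimulator:
    def test_noiseless_ratios_exact(self):
        for e, expected in [(1.0, 2.0), (0.0, 1.0)]:
            df = simulate_qpcr([("G", e)], n_f=3, n_m=3, noise_sd=0.0, seed=0)
            expr = 2.0 ** (df["ct_reference"] - df["ct_test"])
            fem = expr[df["sex"] == "female"].mean()
            mal = expr[df["sex"] == "male"].mean()
            assert fem / mal == pytest.approx(expected, abs=1e-9)

    def test_noisy_ratio_recovers_one_plus_e(self):
        df = simulate_qpcr([("G", 0.5)], n_f=6, n_m=5, noise_sd=0.1, seed=5)
        expr = 2.0 ** (df["ct_reference"] - df["ct_test"])
        ratio = (
            expr[df["sex"] == "female"].mean() / expr[df["sex"] == "male"].mean()
        )
        assert abs(ratio - 1.5) < 0.15


class TestDeterminism:
    def test_same_seed_same_records(self):
        cfg = SimConfig(
            loci=(LocusSim("L", 0.3, 0.95),), n_nuclei=500, seed=42
        )
        assert simulate_single_locus(cfg) == simulate_single_locus(cfg)

    def test_same_seed_byte_identical_tables(self, tmp_path):
        from xescape.locus_model import write_nucleus_table

        cfg = SimConfig(
            loci=(LocusSim("L", 0.3, 0.95),), n_nuclei=200, seed=42
        )
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_nucleus_table(simulate_single_locus(cfg), p1)
        write_nucleus_table(simulate_single_locus(cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()
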