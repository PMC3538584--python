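"""Quartet geometry, four-point method, Fisher criterion, accuracy simulation."""

import numpy as np
import pytest

import phylosr as ps
from phylosr.errors import InvalidInputError
from phylosr.quartets import SPLITS, quartet_accuracy_multi
from phylosr.sr import SRFunction


class TestExactDistances:
    def test_type_b_instantiation(self):
        q = ps.QuartetModel("B", t_i=0.2, t_s=0.4, t_l=0.4, R=2.0)
        D = ps.exact_distances(q)
        assert D[0, 1] == pytest.approx(0.8)
        assert D[2, 3] == pytest.approx(0.8)
        assert D[0, 2] == pytest.approx(1.0)
        assert D[1, 3] == pytest.approx(1.0)

    def test_type_a_instantiation(self):
        q = ps.QuartetModel("A", t_i=0.2, t_s=0.4, t_l=0.4, R=2.0)
        D = ps.exact_distances(q)
        assert D[0, 1] == pytest.approx(0.8)
        assert D[2, 3] == pytest.approx(0.8)
        for i, j in [(0, 2), (0, 3), (1, 2), (1, 3)]:
            assert D[i, j] == pytest.approx(1.0)

    @pytest.mark.parametrize("qtype", ["A", "B"])
    def test_four_point_condition(self, qtype):
        """The two non-split sums are equal and exceed the split sum by
        exactly twice the internal edge."""
        q = ps.QuartetModel(qtype, t_i=0.15, t_s=0.3, t_l=0.9, R=5.0)
        D = ps.exact_distances(q)
        s12 = D[0, 1] + D[2, 3]
        s13 = D[0, 2] + D[1, 3]
        s14 = D[0, 3] + D[1, 2]
        assert s13 == pytest.approx(s14)
        assert s13 == pytest.approx(s12 + 2 * q.t_i)


class TestFourPointMethod:
    def test_true_split_on_additive_distances(self):
        for qtype in ["A", "B"]:
            q = ps.QuartetModel(qtype, 0.1, 0.3, 1.0, 5.0)
            assert ps.four_point_method(ps.exact_distances(q)) == "12|34"

    def test_jc_flips_type_b_when_deviation_exceeds_half_internal_edge(self):
        """Lemma-tightness: transform exact type-B distances by the concave
        JC curve; the wrong split (13|24) becomes minimal exactly when the
        deviation from additivity exceeds t_i / 2 (within grid resolution)."""
        t_s, t_l, R = 0.2, 1.0, 10.0
        flips = []
        devs = []
        t_grid = np.linspace(0.01, 0.40, 40)
        for t_i in t_grid:
            q = ps.QuartetModel("B", t_i, t_s, t_l, R)
            D = ps.exact_distances(q)
            DJ = ps.delta_jc_time(R, D)
            np.fill_diagonal(DJ, 0.0)
            split = ps.four_point_method(DJ)
            flips.append(split == "13|24")
            iv = (D[np.triu_indices(4, 1)].min(), D[np.triu_indices(4, 1)].max())
            devs.append(ps.deviation_from_additivity(ps.JC, R, iv).dev)
        flips = np.array(flips)
        crit = np.array(devs) > t_grid / 2
        # the flip indicator and the threshold indicator agree except possibly
        # at the single grid point straddling the boundary
        assert np.sum(flips != crit) <= 1
        assert flips.any() and not flips.all()

    def test_tie_break_is_uniform(self):
        D = np.full((4, 4), 1.0)
        np.fill_diagonal(D, 0.0)
        counts = {s: 0 for s in SPLITS}
        for seed in range(600):
            counts[ps.four_point_method(D, tie_seed=seed)] += 1
        for s in SPLITS:
            assert 130 < counts[s] < 270

    def test_non_finite_rejected(self):
        D = np.zeros((4, 4))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(InvalidInputError):
            ps.four_point_method(D)


class TestFisherCriterion:
    def test_k2p_separation_is_twice_internal_edge(self):
        q = ps.QuartetModel("B", 0.2, 0.4, 1.0, 5.0)
        fc = ps.fisher_criterion(q, ps.K2P, 1000)
        assert fc.sep == pytest.approx(2 * q.t_i, abs=1e-10)

    def test_fc_is_sep_over_noise(self, quartet_b):
        fc = ps.fisher_criterion(quartet_b, ps.JC, 1000)
        assert fc.fc == fc.sep / fc.noise

    def test_type_a_alt_splits_symmetric(self):
        q = ps.QuartetModel("A", 0.2, 0.3, 0.9, 5.0)
        a = ps.fisher_criterion(q, ps.JC, 1000, "13|24")
        b = ps.fisher_criterion(q, ps.JC, 1000, "14|23")
        assert a.fc == pytest.approx(b.fc, abs=1e-12)

    def test_invalid_alt_split(self, quartet_b):
        with pytest.raises(InvalidInputError):
            ps.fisher_criterion(quartet_b, ps.JC, 1000, "12|34")

    def test_crossing_is_sequence_length_invariant(self):
        """Both noises scale as 1/sqrt(k), so the FC *comparison* between two
        SR functions does not depend on k."""
        q = ps.QuartetModel("B", 0.2, 0.3, 1.0, 5.0)
        for k in [200, 1000, 20000]:
            _, _, fc_ratio = ps.sep_noise_ratios(q, ps.JC, ps.K2P, k)
            if k == 200:
                base = fc_ratio
            assert fc_ratio == pytest.approx(base, rel=1e-12)


class TestSepNoiseRatios:
    def test_identical_functions_give_unit_ratios(self, quartet_b):
        assert ps.sep_noise_ratios(quartet_b, ps.JC, ps.JC, 1000) == \
            pytest.approx((1.0, 1.0, 1.0))

    def test_ratio_of_ratios_identity(self, quartet_b):
        sep_r, noise_r, fc_r = ps.sep_noise_ratios(quartet_b, ps.JC, ps.K2P, 1000)
        assert fc_r == pytest.approx(sep_r / noise_r, rel=1e-14)

    def test_unbalanced_series_trends(self):
        """As the quartet grows unbalanced (t_l up at fixed t_s), both the
        SEP ratio (JC loses separation) and the NOISE ratio (JC gains on
        noise) decrease."""
        sep_rs, noise_rs = [], []
        for t_l in np.linspace(0.25, 1.0, 8):
            q = ps.QuartetModel("B", 0.2, 0.2, t_l, 5.0)
            sep_r, noise_r, _ = ps.sep_noise_ratios(q, ps.JC, ps.K2P, 1000)
            sep_rs.append(sep_r)
            noise_rs.append(noise_r)
        assert np.all(np.diff(sep_rs) < 0)
        assert np.all(np.diff(noise_rs) < 0)
        assert np.all(np.array(noise_rs) < 1)
        assert np.all(np.array(sep_rs) <= 1 + 1e-12)


class TestMarginEffects:
    def test_type_a_concavity_widens_the_margin(self):
        """On exact JC-transformed type-A distances, the four-point margin
        exceeds the margin of the best affine fit (a * 2 t_i)."""
        q = ps.QuartetModel("A", 0.2, 0.2, 1.0, 10.0)
        D = ps.exact_distances(q)
        DJ = ps.delta_jc_time(q.R, D)
        s12 = DJ[0, 1] + DJ[2, 3]
        competing = min(DJ[0, 2] + DJ[1, 3], DJ[0, 3] + DJ[1, 2])
        iv = (D[np.triu_indices(4, 1)].min(), D[np.triu_indices(4, 1)].max())
        fit = ps.deviation_from_additivity(ps.JC, q.R, iv).fit
        assert competing - s12 > fit.a * 2 * q.t_i

    def test_type_b_concavity_shrinks_the_margin_by_twice_the_max_gap(self):
        """On type-B quartets the interpolation interval is [d13, d24] and
        d12 = d34 sits inside it, so the JC margin loses exactly twice the
        chord gap at d12 -- approximately twice the maximal gap, since d12
        lies near the gap's peak."""
        from phylosr.additivity import linear_interpolation as interp_fit

        q = ps.QuartetModel("B", 0.3, 0.2, 1.0, 10.0)
        D = ps.exact_distances(q)
        DJ = ps.delta_jc_time(q.R, D)
        margin = (DJ[0, 2] + DJ[1, 3]) - (DJ[0, 1] + DJ[2, 3])
        iv = (D[0, 2], D[1, 3])  # [d13, d24]
        fit = interp_fit(ps.JC, q.R, iv)
        interp_margin = fit.a * 2 * q.t_i
        gap_at_d12 = ps.delta_jc_time(q.R, D[0, 1]) - fit(D[0, 1])
        # exact identity: endpoints of the sum lie on the chord
        assert interp_margin - margin == pytest.approx(2 * gap_at_d12, abs=1e-10)
        # and the gap at d12 is close to the maximal chord gap X = 2 A dev
        res = ps.deviation_from_additivity(ps.JC, q.R, iv)
        X = 2 * res.fit.a * res.dev
        assert gap_at_d12 == pytest.approx(X, rel=0.15)
        assert margin < interp_margin


class TestAccuracySimulation:
    def test_overwhelming_signal(self):
        q = ps.QuartetModel("B", 5.0, 0.05, 0.1, 2.0)
        acc = ps.quartet_accuracy_sim(q, ps.JC, 1000, 400, seed=1)
        assert acc > 0.99

    def test_determinism(self, quartet_b):
        a = ps.quartet_accuracy_sim(quartet_b, ps.JC, 500, 300, seed=5)
        b = ps.quartet_accuracy_sim(quartet_b, ps.JC, 500, 300, seed=5)
        assert a == b

    def test_affine_invariance(self, quartet_b):
        """The four-point decision compares sums, so an affine transform
        a*D + b of the SR function cannot change any replicate's outcome."""
        affine_jc = SRFunction(
            "affine-jc",
            lambda p: 2.5 * ps.delta_jc(p) + 0.7,
            lambda pa, pb: 2.5 * ps.JC.from_probs_array(pa, pb) + 0.7,
            additive_in_k2p=False,
        )
        res = quartet_accuracy_multi(quartet_b, [ps.JC, affine_jc], 500, 500, seed=77)
        assert res["jc"] == res["affine-jc"]

    def test_detail_fields(self, quartet_b):
        out = ps.quartet_accuracy_sim(quartet_b, ps.JC, 300, 200, seed=2,
                                      return_detail=True)
        assert 0 <= out["accuracy"] <= 1
        assert out["reps"] == 200
        assert out["tie_fraction"] >= 0


class TestModelValidation:
    def test_bad_type_and_times(self):
        with pytest.raises(InvalidInputError):
            ps.QuartetModel("C", 0.1, 0.2, 0.3, 2.0)
        with pytest.raises(InvalidInputError):
            ps.QuartetModel("A", 0.0, 0.2, 0.3, 2.0)
        with pytest.raises(InvalidInputError):
            ps.QuartetModel("A", 0.1, 0.5, 0.3, 2.0)
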