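"""Observer-side probabilities, RSW, consensus, and outcome enumeration."""

import itertools

import numpy as np
import pytest

from ratdecide import (
    ALPHA,
    BETA,
    ModelParams,
    SubtypeSpec,
    SubtypeThresholdTable,
    ThresholdTable,
    build_threshold_table,
    conditional_choice_probability,
    conditional_choice_probability_subtype,
    consensus_score,
    focal_response_probability,
    focal_response_probability_subtype,
    outcome_distribution,
    rsw,
    sequence_probability,
)
from ratdecide.model import all_histories


class TestRSW:
    def test_identical_preferences_give_full_weight(self):
        assert rsw(1.0, 0.7) == pytest.approx(1.0)
        assert rsw(1.0, 3.0) == pytest.approx(1.0)

    def test_uncorrelated_preferences_give_zero_weight(self):
        assert rsw(0.0, 1.3) == 0.0

    def test_high_noise_limit_approaches_rho(self):
        assert rsw(0.5, 100.0) == pytest.approx(0.5, abs=1e-3)

    def test_low_noise_limit_vanishes(self):
        assert abs(rsw(0.9, 1e-4)) < 1e-3

    def test_opposed_preferences_give_negative_weight(self):
        assert rsw(-0.8, 1.0) < 0.0

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(ValueError):
            rsw(1.0, 0.0)


class TestConsensusScore:
    @pytest.mark.parametrize("na,nb,expected", [(8, 0, 1.0), (4, 4, 0.0), (6, 2, 0.5)])
    def test_definitional_values(self, na, nb, expected):
        assert consensus_score(na, nb) == expected

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            consensus_score(0, 0)


class TestSequenceProbability:
    def test_first_choice_is_fair(self, params_strong, thresholds_strong):
        assert sequence_probability("A", params_strong, thresholds_strong) == pytest.approx(0.5)

    def test_independent_agents_factorize(self):
        p = ModelParams(3, 0.0, 1.0)
        tab = ThresholdTable(p)
        assert sequence_probability("AA", p, tab) == pytest.approx(0.25, abs=1e-6)

    def test_length_four_partition_sums_to_one(self, params_strong, thresholds_strong):
        total = sum(
            sequence_probability("".join(s), params_strong, thresholds_strong)
            for s in itertools.product("AB", repeat=4))
        assert total == pytest.approx(1.0, abs=1e-5)

    def test_empty_sequence_certain(self, params_strong, thresholds_strong):
        assert sequence_probability("", params_strong, thresholds_strong) == 1.0


class TestConditionalChoice:
    def test_no_history_is_fair(self, params_strong, thresholds_strong):
        assert conditional_choice_probability("", params_strong, thresholds_strong) == \
            pytest.approx(0.5)

    def test_positive_social_influence(self, params_strong, thresholds_strong):
        assert conditional_choice_probability("A", params_strong, thresholds_strong) > 0.5

    def test_mirror_symmetry(self, params_strong, thresholds_strong):
        for m in (1, 2, 3):
            for h in all_histories(m):
                mirrored = h.mirror()
                total = (conditional_choice_probability(h, params_strong, thresholds_strong)
                         + conditional_choice_probability(mirrored, params_strong, thresholds_strong))
                assert total == pytest.approx(1.0, abs=2e-6)


class TestFocalResponse:
    def test_zero_threshold_gives_half(self):
        p = ModelParams(4, 0.0, 1.0)
        tab = ThresholdTable(p)
        for h in ("", "A", "BBA"):
            assert focal_response_probability(h, p, tab) == pytest.approx(0.5)

    def test_mirror_symmetry_exact(self, params_strong, thresholds_strong):
        a = focal_response_probability("BBA", params_strong, thresholds_strong)
        b = focal_response_probability("AAB", params_strong, thresholds_strong)
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_lower_experimental_noise_sharpens_response(self):
        """A lab much quieter than the habitual environment amplifies the
        social response: probabilities move away from 0.5."""
        eps = 1.0
        natural = ModelParams(4, 0.9, eps, eta=eps)
        lab = ModelParams(4, 0.9, eps, eta=eps / 2)
        tab = ThresholdTable(natural)  # thresholds depend on eps only
        for h in ("A", "AA", "AAB"):
            p_nat = focal_response_probability(h, natural, tab)
            p_lab = focal_response_probability(h, lab, tab)
            assert abs(p_lab - 0.5) > abs(p_nat - 0.5)

    def test_recency_crossing_with_noise(self):
        """With strong alignment the BBA response crosses 0.5 from below as
        habitual noise increases (majority-following to recency-following)."""
        def p_bba(eps):
            p = ModelParams(4, 0.9, eps)
            return focal_response_probability("BBA", p, ThresholdTable(p))

        assert p_bba(0.2) < 0.5 < p_bba(2.0)


class TestOutcomeDistribution:
    def test_uncorrelated_group_is_binomial(self):
        p = ModelParams(8, 0.0, 1.0)
        dist = outcome_distribution(p, build_threshold_table(8, p))
        from scipy.stats import binom

        np.testing.assert_allclose(dist.probs, binom.pmf(np.arange(9), 8, 0.5), atol=1e-6)
        assert dist.expected_consensus() == pytest.approx(35.0 / 128.0, abs=1e-6)

    def test_chain_method_matches_joint_at_zero_correlation(self):
        p = ModelParams(6, 0.0, 1.0)
        tab = build_threshold_table(6, p)
        joint = outcome_distribution(p, tab, method="joint")
        chain = outcome_distribution(p, tab, method="chain")
        np.testing.assert_allclose(joint.probs, chain.probs, atol=1e-6)

    def test_alignment_raises_consensus(self):
        eps = 1.0
        scores = []
        for rho in (0.0, 0.5, 0.9):
            p = ModelParams(6, rho, eps)
            scores.append(outcome_distribution(p, build_threshold_table(6, p)).expected_consensus())
        assert scores[0] < scores[1] < scores[2]

    def test_enumeration_guard(self):
        with pytest.raises(ValueError, match="enumeration"):
            outcome_distribution(ModelParams(11, 0.0, 1.0))


class TestSubtypeObserver:
    def test_degenerate_spec_matches_homogeneous(self):
        p = ModelParams(4, 0.6, 1.0)
        spec = SubtypeSpec(gamma=0.4, rho_high=0.6, rho_low=0.6)
        table = SubtypeThresholdTable(spec, p)
        hom = ThresholdTable(p)
        for h in ("A", "AB"):
            got = conditional_choice_probability_subtype(h, ALPHA, spec, p, table)
            want = conditional_choice_probability(h, p, hom)
            assert got == pytest.approx(want, abs=1e-6)

    def test_majority_type_is_more_social(self, majority_minority_spec):
        """After three A's at low noise, a majority-type focal follows far
        more strongly than a minority-type focal."""
        p = ModelParams(5, 0.9, 0.5)
        table = SubtypeThresholdTable(majority_minority_spec, p)
        maj = focal_response_probability_subtype("AAA", ALPHA, majority_minority_spec, p, table)
        mino = focal_response_probability_subtype("AAA", BETA, majority_minority_spec, p, table)
        assert maj > mino > 0.5

    def test_unanimity_is_qualitatively_special(self):
        """Equal split of identical-within / independent-between types at low
        noise: a unanimous history produces a markedly stronger response
        than any non-unanimous one."""
        spec = SubtypeSpec(gamma=0.5, rho_high=1.0, rho_low=0.0)
        p = ModelParams(5, 0.9, 0.3)
        table = SubtypeThresholdTable(spec, p)
        unanimous = focal_response_probability_subtype("AAA", ALPHA, spec, p, table)
        broken = [focal_response_probability_subtype(h, ALPHA, spec, p, table)
                  for h in ("AAB", "ABA", "BAA")]
        # non-unanimous histories barely move the response off 0.5; a
        # unanimous one produces several times that social pull
        assert max(broken) - 0.5 < 0.02
        assert unanimous - 0.5 > 3 * (max(broken) - 0.5)

    def test_subtype_mirror_symmetry(self, majority_minority_spec):
        p = ModelParams(4, 0.9, 1.0)
        table = SubtypeThresholdTable(majority_minority_spec, p)
        a = conditional_choice_probability_subtype("AB", ALPHA, majority_minority_spec, p, table)
        b = conditional_choice_probability_subtype("BA", ALPHA, majority_minority_spec, p, table)
        assert a + b == pytest.approx(1.0, abs=2e-6)
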