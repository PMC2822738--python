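"""Network construction, receiving/providing agreement, and imputation."""

from __future__ import annotations

import numpy as np
import pytest

from practicenet.build import (
    Provenance,
    agreement,
    build_network,
    impute_receiving,
    to_networkx,
)
from practicenet.metrics import density
from practicenet.roster import Condition, Direction
from practicenet.simulate import GeneratorConfig, generate_practice

from _oracles import oracle_agreement
from conftest import full_response_dataset, make_network, random_adjacency


class TestBuildNetwork:
    def test_single_tick_gives_single_tie(self):
        ds = full_response_dataset(
            4, ticks={("m01", Condition.CHF, Direction.RECEIVE): {"m02"}}
        )
        net = build_network(ds, Condition.CHF, Direction.RECEIVE)
        assert net.tie_count == 1
        assert net.adjacency[net.index("m01"), net.index("m02")] == 1

    def test_noise_free_build_matches_generator_truth(self):
        config = GeneratorConfig(seed=7, report_flip=0.0, nonresponse_prob=0.0)
        ds, truth = generate_practice(config)
        for condition in Condition:
            net = build_network(ds, condition, Direction.RECEIVE)
            np.testing.assert_array_equal(net.adjacency, truth.true_networks[condition])

    def test_nonresponder_row_is_missing_until_imputation(self):
        missing = {("m02", c, d) for c in Condition for d in Direction}
        ds = full_response_dataset(4, missing=missing)
        net = build_network(ds, Condition.COPD, Direction.RECEIVE)
        i = net.index("m02")
        assert net.missing_rows[i]
        assert net.adjacency[i].sum() == 0
        assert (net.provenance[i, [j for j in range(4) if j != i]]
                == Provenance.MISSING).all()

    def test_external_ticks_copied_per_member(self):
        ds = full_response_dataset(
            3,
            external_ticks={
                ("m01", Condition.CHF, Direction.RECEIVE): {"ext_cardio", "ext_physio"}
            },
        )
        net = build_network(ds, Condition.CHF, Direction.RECEIVE)
        assert net.external_ties["m01"] == {"ext_cardio", "ext_physio"}
        assert net.external_tie_count == 2


class TestAgreement:
    def test_mirrored_reports_agree_fully(self):
        receiving = make_network([[0, 1, 0], [0, 0, 1], [0, 0, 0]])
        providing = make_network(
            np.array([[0, 1, 0], [0, 0, 1], [0, 0, 0]]).T,
            direction=Direction.PROVIDE,
        )
        result = agreement(receiving, providing)
        assert result.proportion == 1.0
        assert result.n_pairs == 6

    def test_total_contradiction_gives_zero(self):
        ones = 1 - np.eye(3, dtype=int)
        receiving = make_network(ones)
        providing = make_network(np.zeros((3, 3), int), direction=Direction.PROVIDE)
        assert agreement(receiving, providing).proportion == 0.0

    def test_hand_enumerated_five_member_case(self):
        # receiving ties {(1,2),(3,4)}; providing ties {(2,1),(2,5)} (1-based):
        # disagreements only at (3,4) (reported received, never provided) and
        # (5,2) (provided, never reported received) -> 18/20
        receive = np.zeros((5, 5), int)
        receive[0, 1] = receive[2, 3] = 1
        provide = np.zeros((5, 5), int)
        provide[1, 0] = provide[1, 4] = 1
        receiving = make_network(receive)
        providing = make_network(provide, direction=Direction.PROVIDE)
        result = agreement(receiving, providing)
        assert result.n_pairs == 20
        assert result.n_matches == 18
        assert result.proportion == pytest.approx(0.90)

    def test_matches_pairwise_oracle_on_random_networks(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 7))
            receive = random_adjacency(rng, n)
            provide = random_adjacency(rng, n)
            rec_missing = rng.random(n) < 0.3
            pro_missing = rng.random(n) < 0.3
            receiving = make_network(receive, missing_rows=rec_missing)
            providing = make_network(
                provide, missing_rows=pro_missing, direction=Direction.PROVIDE
            )
            expected, n_pairs = oracle_agreement(
                receiving.adjacency, providing.adjacency,
                list(receiving.missing_rows), list(providing.missing_rows),
            )
            result = agreement(receiving, providing)
            assert result.n_pairs == n_pairs
            if expected is None:
                assert not result.defined
            else:
                assert result.proportion == pytest.approx(expected)

    def test_all_missing_is_undefined_not_zero(self):
        receiving = make_network(np.zeros((3, 3), int), missing_rows=[True] * 3)
        providing = make_network(
            np.zeros((3, 3), int), missing_rows=[True] * 3,
            direction=Direction.PROVIDE,
        )
        result = agreement(receiving, providing)
        assert not result.defined
        assert result.proportion is None

    def test_reverse_perspective_gives_same_value(self, rng):
        """Evaluating 'providing confirmed by receiving' over the same
        evaluable pairs is the same simple-matching proportion."""
        for _ in range(20):
            n = int(rng.integers(2, 6))
            receiving = make_network(
                random_adjacency(rng, n), missing_rows=rng.random(n) < 0.3
            )
            providing = make_network(
                random_adjacency(rng, n), missing_rows=rng.random(n) < 0.3,
                direction=Direction.PROVIDE,
            )
            forward = agreement(receiving, providing)
            # swap roles: compare providing(j, i) against receiving(i, j)
            # over pairs evaluable from the providing side
            expected, n_pairs = oracle_agreement(
                providing.adjacency, receiving.adjacency,
                list(providing.missing_rows), list(receiving.missing_rows),
            )
            assert n_pairs == forward.n_pairs
            if forward.defined:
                assert forward.proportion == pytest.approx(expected)

    def test_agreement_refuses_imputed_networks(self):
        missing = {("m02", c, Direction.RECEIVE) for c in Condition}
        ds = full_response_dataset(3, missing=missing)
        receiving = build_network(ds, Condition.CHF, Direction.RECEIVE)
        providing = build_network(ds, Condition.CHF, Direction.PROVIDE)
        imputed = impute_receiving(receiving, providing)
        with pytest.raises(ValueError, match="pre-imputation"):
            agreement(imputed, providing)


class TestImputation:
    def test_missing_row_filled_from_provider_report(self):
        ds = full_response_dataset(
            3,
            ticks={("m02", Condition.CHF, Direction.PROVIDE): {"m01"}},
            missing={("m01", Condition.CHF, Direction.RECEIVE)},
        )
        receiving = build_network(ds, Condition.CHF, Direction.RECEIVE)
        providing = build_network(ds, Condition.CHF, Direction.PROVIDE)
        imputed = impute_receiving(receiving, providing)
        i, j = imputed.index("m01"), imputed.index("m02")
        assert imputed.adjacency[i, j] == 1
        assert imputed.provenance[i, j] == Provenance.IMPUTED
        assert not imputed.has_missing

    def test_double_silence_zero_filled(self):
        missing = {
            ("m01", Condition.CHF, Direction.RECEIVE),
            ("m02", Condition.CHF, Direction.PROVIDE),
        }
        ds = full_response_dataset(3, missing=missing)
        receiving = build_network(ds, Condition.CHF, Direction.RECEIVE)
        providing = build_network(ds, Condition.CHF, Direction.PROVIDE)
        imputed = impute_receiving(receiving, providing)
        i, j = imputed.index("m01"), imputed.index("m02")
        assert imputed.adjacency[i, j] == 0
        assert imputed.provenance[i, j] == Provenance.ZERO_FILLED

    def test_idempotent_and_reported_rows_untouched(self, rng):
        for seed in range(5):
            ds, _ = generate_practice(
                GeneratorConfig(seed=seed, nonresponse_prob=0.3)
            )
            receiving = build_network(ds, Condition.CHF, Direction.RECEIVE)
            providing = build_network(ds, Condition.CHF, Direction.PROVIDE)
            once = impute_receiving(receiving, providing)
            twice = impute_receiving(once, providing)
            np.testing.assert_array_equal(once.adjacency, twice.adjacency)
            np.testing.assert_array_equal(once.provenance, twice.provenance)
            reported = ~receiving.missing_rows
            np.testing.assert_array_equal(
                once.adjacency[reported], receiving.adjacency[reported]
            )

    def test_no_missing_rows_is_a_no_op(self):
        ds = full_response_dataset(
            4, ticks={("m01", Condition.CHF, Direction.RECEIVE): {"m03"}}
        )
        receiving = build_network(ds, Condition.CHF, Direction.RECEIVE)
        providing = build_network(ds, Condition.CHF, Direction.PROVIDE)
        imputed = impute_receiving(receiving, providing)
        np.testing.assert_array_equal(imputed.adjacency, receiving.adjacency)
        np.testing.assert_array_equal(imputed.provenance, receiving.provenance)

    def test_post_imputation_density_consistency(self):
        """tie_count / n(n-1) of the imputed network equals metrics.density."""
        ds, _ = generate_practice(GeneratorConfig(seed=3, nonresponse_prob=0.3))
        receiving = build_network(ds, Condition.DIABETES, Direction.RECEIVE)
        providing = build_network(ds, Condition.DIABETES, Direction.PROVIDE)
        net = impute_receiving(receiving, providing)
        assert density(net) == net.tie_count / (net.n * (net.n - 1))


class TestExports:
    def test_networkx_conversion_carries_attributes(self):
        ds = full_response_dataset(
            3,
            ticks={("m01", Condition.CHF, Direction.RECEIVE): {"m02"}},
            external_ticks={("m01", Condition.CHF, Direction.RECEIVE): {"ext_cardio"}},
        )
        net = build_network(ds, Condition.CHF, Direction.RECEIVE)
        g = to_networkx(net)
        assert g.nodes["m01"]["discipline"] == "P"
        assert g.nodes["ext_cardio"]["kind"] == "external"
        assert g.edges["m01", "m02"]["provenance"] == "reported"
        assert g.edges["m01", "m02"]["condition"] == "CHF"
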