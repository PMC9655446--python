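"""Open-set identification metrics: rates, DET/EER, counts, sweeps."""

import math

import numpy as np
import pytest

import herdface as hf
from herdface.exceptions import InvalidInputError
from herdface.metrics import (
    NONMATE,
    SearchOutcome,
    det_and_eer,
    identification_rates,
    is_false_positive,
    is_miss,
    landmark_error_rate,
    outcome_from_match,
    outcomes_from_frame,
    outcomes_to_frame,
    unique_id_counts,
)


def mate(probe_id, cands, rank_of_true=None):
    return SearchOutcome(
        probe_id=probe_id,
        is_mate=True,
        candidates=cands,
        rank_of_true=rank_of_true,
        top_score=cands[0][1] if cands else math.nan,
    )


def nonmate(cands):
    return SearchOutcome(
        probe_id=NONMATE,
        is_mate=False,
        candidates=cands,
        top_score=cands[0][1] if cands else math.nan,
    )


def random_battery(rng, n_mates=40, n_nonmates=15, spread=0.5):
    """Outcomes with mate scores ~U(spread,1) and non-mate ~U(0,1-spread)."""
    outs = []
    for i in range(n_mates):
        true_rank = int(rng.integers(1, 4))
        cands = []
        score = float(rng.uniform(spread, 1.0))
        for r in range(1, 6):
            ident = f"M{i}" if r == true_rank else f"G{int(rng.integers(50))}"
            cands.append((ident, score))
            score -= float(rng.uniform(0.01, 0.1))
        outs.append(mate(f"M{i}", cands, rank_of_true=true_rank))
    for _ in range(n_nonmates):
        score = float(rng.uniform(0.0, 1.0 - spread))
        cands = [(f"G{int(rng.integers(50))}", score - 0.05 * r) for r in range(5)]
        outs.append(nonmate(cands))
    return outs


class TestErrorClassification:
    def test_rank_one_confident_hit_is_not_a_miss(self):
        o = mate("A", [("A", 0.9), ("B", 0.5)], rank_of_true=1)
        assert not is_miss(o, R=1, T=0.68)

    def test_out_of_top_r_is_a_miss(self):
        o = mate("A", [("B", 0.9), ("A", 0.8)], rank_of_true=2)
        assert is_miss(o, R=1, T=0.0)
        assert not is_miss(o, R=2, T=0.0)

    def test_low_score_is_a_miss(self):
        o = mate("A", [("A", 0.5)], rank_of_true=1)
        assert is_miss(o, R=1, T=0.68)

    def test_score_equal_to_threshold_is_a_miss(self):
        o = mate("A", [("A", 0.68)], rank_of_true=1)
        assert is_miss(o, R=1, T=0.68)

    def test_wrong_kind_rejected(self):
        with pytest.raises(InvalidInputError):
            is_miss(nonmate([("G", 0.9)]), 1, 0.0)
        with pytest.raises(InvalidInputError):
            is_false_positive(mate("A", [("A", 0.9)], 1), 0.0)

    @pytest.mark.parametrize(
        "score,T,expected", [(0.2, 0.68, False), (0.8, 0.68, True), (0.01, 0.0, True)]
    )
    def test_false_positive_rule(self, score, T, expected):
        assert is_false_positive(nonmate([("G", score)]), T) is expected


class TestIdentificationRates:
    def test_fpir_direct_ratio(self, rng):
        outs = [nonmate([("G", 0.9)])] * 3 + [nonmate([("G", 0.1)])] * 10
        outs.append(mate("A", [("A", 0.9)], 1))
        r = identification_rates(outs, R=1, T=0.68)
        assert r.fpir == pytest.approx(3 / 13)

    def test_perfect_battery(self):
        outs = [mate(f"A{i}", [(f"A{i}", 0.95)], 1) for i in range(10)]
        r = identification_rates(outs, R=1, T=0.0)
        assert (r.fnir, r.tpir, r.cmc) == (0.0, 1.0, 1.0)
        assert math.isnan(r.fpir)  # no non-mate searches attempted

    def test_identities_hold_on_random_battery(self, rng):
        outs = random_battery(rng)
        for R in (1, 2, 5):
            for T in (0.0, 0.3, 0.68):
                r = identification_rates(outs, R, T)
                assert r.tpir + r.fnir == pytest.approx(1.0, abs=1e-15)
                r0 = identification_rates(outs, R, 0.0)
                assert r.cmc == pytest.approx(r0.tpir)

    def test_rates_match_brute_force_counts(self, rng):
        outs = random_battery(rng)
        mates = [o for o in outs if o.is_mate]
        nons = [o for o in outs if not o.is_mate]
        R, T = 2, 0.4
        r = identification_rates(outs, R, T)
        n_miss = sum(
            1
            for o in mates
            if o.rank_of_true is None
            or o.rank_of_true > R
            or not (max(s for i, s in o.candidates if i == o.probe_id) > T)
        )
        n_fp = sum(1 for o in nons if o.top_score > T)
        assert r.fnir == pytest.approx(n_miss / len(mates))
        assert r.fpir == pytest.approx(n_fp / len(nons))

    def test_cmc_non_decreasing_in_r(self, rng):
        outs = random_battery(rng)
        cmcs = [identification_rates(outs, R, 0.0).cmc for R in range(1, 6)]
        assert cmcs == sorted(cmcs)

    def test_empty_outcomes_rejected(self):
        with pytest.raises(InvalidInputError):
            identification_rates([], 1, 0.0)


class TestDetAndEer:
    def test_separable_scores_give_near_zero_eer(self):
        outs = [mate(f"A{i}", [(f"A{i}", 0.9)], 1) for i in range(20)]
        outs += [nonmate([("G", 0.1)]) for _ in range(20)]
        curves = det_and_eer(outs, np.linspace(0, 1, 101))
        assert curves.crossed
        assert curves.eer_rate == pytest.approx(0.0, abs=1e-9)
        assert 0.1 <= curves.eer_threshold <= 0.9  # inside the separating gap

    def test_identical_distributions_give_half_eer(self, rng):
        outs = []
        for i in range(5000):
            s = float(rng.uniform(0, 1))
            outs.append(mate(f"A{i}", [(f"A{i}", s)], 1))
            s = float(rng.uniform(0, 1))
            outs.append(nonmate([("G", s)]))
        curves = det_and_eer(outs, np.linspace(0, 1, 201))
        assert curves.eer_rate == pytest.approx(0.5, abs=0.03)

    def test_monotone_error_curves(self, rng):
        curves = det_and_eer(random_battery(rng), np.linspace(-1, 1, 101))
        assert np.all(np.diff(curves.fnir) >= 0)
        assert np.all(np.diff(curves.fpir) <= 0)

    def test_no_crossing_reports_closest_gap(self):
        outs = [mate("A", [("A", 0.9)], 1), nonmate([("G", 0.95)])]
        curves = det_and_eer(outs, np.linspace(0.0, 0.5, 11))
        assert not curves.crossed
        assert 0.0 <= curves.eer_threshold <= 0.5

    def test_needs_both_probe_kinds(self):
        with pytest.raises(InvalidInputError):
            det_and_eer([mate("A", [("A", 0.9)], 1)], np.linspace(0, 1, 11))


class TestUniqueIdCounts:
    def test_every_mate_hits(self):
        outs = [mate(f"A{i}", [(f"A{i}", 0.9)], 1) for i in range(7)]
        assert unique_id_counts(outs, 1, 0.0) == (7, 0)

    def test_no_nonmate_accepted(self):
        outs = [nonmate([("G", 0.1)]) for _ in range(5)]
        assert unique_id_counts(outs, 1, 0.68) == (0, 0)

    def test_counts_match_set_union_oracle(self, rng):
        outs = random_battery(rng, n_mates=25, n_nonmates=10, spread=0.2)
        R, T = 1, 0.3
        got = unique_id_counts(outs, R, T)
        want_tp = {o.probe_id for o in outs if o.is_mate and not is_miss(o, R, T)}
        want_fp = {
            o.candidates[0][0]
            for o in outs
            if not o.is_mate and is_false_positive(o, T)
        }
        assert got == (len(want_tp), len(want_fp))


class TestLandmarkErrorRate:
    @pytest.mark.parametrize(
        "mse,width,expected", [(9.2, 224, 1.35), (0, 224, 0.0), (224**2, 224, 100.0)]
    )
    def test_examples(self, mse, width, expected):
        assert landmark_error_rate(mse, width) == pytest.approx(expected)

    def test_negative_mse_rejected(self):
        with pytest.raises(InvalidInputError):
            landmark_error_rate(-1.0, 224)


class TestOutcomeRoundTrip:
    def test_csv_round_trip(self, rng):
        outs = random_battery(rng, n_mates=5, n_nonmates=3)
        back = outcomes_from_frame(outcomes_to_frame(outs))
        for a, b in zip(outs, back):
            assert (a.probe_id, a.is_mate, a.rank_of_true) == (
                b.probe_id,
                b.is_mate,
                b.rank_of_true,
            )
            assert a.top_score == pytest.approx(b.top_score)
            assert [i for i, _ in a.candidates] == [i for i, _ in b.candidates]

    def test_outcome_from_match_sets_rank(self, embedding_gallery, identities, rng):
        m = identities[0]
        cands = hf.rank(embedding_gallery, hf.sample_embedding(m, rng), 10)
        o = outcome_from_match(m.identity_id, True, cands)
        assert o.rank_of_true == 1
        assert o.top_score == cands[0].score


@pytest.fixture(scope="module")
def sweep_result():
    spec = hf.SynthSpec(n_mates=10, n_nonmates=3, dimension=64, sigma=0.23, seed=17)
    sweep = hf.SweepSpec(
        nim_values=(1, 5, 10, 15, 20, 25),
        r_values=(1, 5, 10),
        buffer_sizes=(10,),
        probes_per_identity=30,
    )
    return hf.run_sweep(spec, sweep, seed=17)


class TestRunSweep:
    def test_table_shape_mirrors_protocol(self, sweep_result):
        still = sweep_result["still"]
        assert list(still.index) == [1, 5, 10, 15, 20, 25]
        assert list(still.columns) == [1, 5, 10]
        # voting over more candidates than records per identity is undefined
        assert math.isnan(still.loc[1, 5]) and math.isnan(still.loc[5, 10])

    def test_cmc_improves_with_enrollment_size(self, sweep_result):
        col = sweep_result["still"][1]
        assert col.loc[25] > col.loc[1]

    def test_buffering_improves_closed_set_cmc(self, sweep_result):
        buffered = sweep_result["buffered"]
        for R in (1, 5, 10):
            assert buffered.loc[("cmc_pct", R), 10] >= buffered.loc[("cmc_pct", R), "pipeline"]
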