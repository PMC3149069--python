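import itertools
import math

import numpy as np
import pandas as pd
import pytest

import cnastats as cna


def _d_oracle(x1, n1, x2, n2):
    """Independent scalar evaluation of the standardized difference of
    stabilized proportions."""
    p1 = (x1 + 0.5) / (n1 if x1 < n1 else n1 + 1)
    p2 = (x2 + 0.5) / (n2 if x2 < n2 else n2 + 1)
    return (p1 - p2) / math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)


def _D_oracle(events_a, events_b):
    n1, n2 = len(events_a), len(events_b)
    total = 0.0
    for i in range(events_a.shape[1]):
        total += _d_oracle(
            int(events_a[:, i].sum()), n1, int(events_b[:, i].sum()), n2
        ) ** 2
    return total


def _toy_calls(array):
    array = np.asarray(array, dtype=np.int8)
    pm = cna.ProbeMap(pd.DataFrame(
        {"probe_id": [f"p{i}" for i in range(array.shape[1])],
         "chromosome": "1",
         "position": np.arange(1, array.shape[1] + 1) * 1000}
    ))
    ids = [f"s{i}" for i in range(array.shape[0])]
    return cna.CallMatrix(ids, array, pm)


class TestStandardizedDifference:
    def test_symmetry_zero(self):
        assert cna.standardized_difference(3, 10, 3, 10) == 0.0

    def test_antisymmetry(self):
        d1 = cna.standardized_difference(3, 10, 1, 12)
        d2 = cna.standardized_difference(1, 12, 3, 10)
        assert d1 == pytest.approx(-d2, abs=1e-14)

    def test_matches_hand_formula(self):
        assert cna.standardized_difference(3, 10, 1, 10) == pytest.approx(
            _d_oracle(3, 10, 1, 10), abs=1e-12
        )

    @pytest.mark.parametrize("x1,n1,x2,n2", [
        (0, 5, 0, 8), (5, 5, 0, 5), (10, 10, 10, 10), (0, 2, 2, 2),
    ])
    def test_finite_at_edges(self, x1, n1, x2, n2):
        d = cna.standardized_difference(x1, n1, x2, n2)
        assert math.isfinite(d)
        assert d == pytest.approx(_d_oracle(x1, n1, x2, n2), abs=1e-12)

    def test_zero_group_size_rejected(self):
        with pytest.raises(ValueError):
            cna.standardized_difference(0, 0, 1, 5)


class TestGlobalCnaTest:
    def test_identical_groups_give_zero_d(self):
        # same per-locus counts, equal sizes -> every d_i = 0
        block = np.array([[1, 0, 1], [0, 1, 0]], dtype=np.int8)
        calls = _toy_calls(np.vstack([block, block]))
        res = cna.global_cna_test(
            calls, ["s0", "s1"], ["s2", "s3"], "gain", method="exact"
        )
        assert res.D_observed == 0.0
        assert res.p_value == 1.0

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            array = (rng.random((6, 4)) < 0.4).astype(np.int8)
            calls = _toy_calls(array)
            ids = calls.sample_ids
            res = cna.global_cna_test(
                calls, ids[:3], ids[3:], "gain", method="exact"
            )
            events = array == 1
            D_obs = _D_oracle(events[:3], events[3:])
            assert res.D_observed == pytest.approx(D_obs, rel=1e-12)
            null = [
                _D_oracle(events[list(combo)],
                          events[[i for i in range(6) if i not in combo]])
                for combo in itertools.combinations(range(6), 3)
            ]
            p_exact = np.mean([d >= D_obs - 1e-12 for d in null])
            assert res.p_value == pytest.approx(p_exact)

    def test_permutation_p_in_valid_grid_and_deterministic(self, small_cohort):
        calls = small_cohort["calls"]
        design = small_cohort["design"]
        blood = design.select(tissue="blood")
        tumors = design.tumors
        r1 = cna.global_cna_test(calls, blood, tumors, "gain", B=99, seed=4)
        r2 = cna.global_cna_test(calls, blood, tumors, "gain", B=99, seed=4)
        assert r1.p_value == r2.p_value
        assert (r1.null_draws == r2.null_draws).all()
        k = round(r1.p_value * 100)
        assert 1 <= k <= 100 and r1.p_value == pytest.approx(k / 100)

    def test_overlapping_groups_rejected(self):
        calls = _toy_calls(np.zeros((4, 3)))
        with pytest.raises(ValueError, match="overlap"):
            cna.global_cna_test(
                calls, ["s0", "s1"], ["s1", "s2"], "gain", B=10, seed=0
            )

    def test_detects_planted_rate_difference(self):
        cfg = cna.SimulationConfig(
            seed=21, n_probes=1000, n_chromosomes=2, noise_sd=0.0,
            segment_length_mean=10,
            group_specs=(
                cna.GroupSpec("a", "blood", "none", 10, 2.0, 0.0),
                cna.GroupSpec("b", "tumor", "early", 10, 12.0, 0.0),
            ),
        )
        pm, genes = cna.simulate_probe_map_and_genes(cfg)
        cn, design = cna.simulate_cohort(cfg, pm, genes)
        calls = cna.call_cnas(cn)
        res = cna.global_cna_test(
            calls, design.select(tissue="blood"), design.tumors,
            "gain", B=500, seed=1,
        )
        assert res.p_value < 0.05


class TestMatchByPackYears:
    def _design(self, late_py, early_py):
        rows = []
        for i, py in enumerate(late_py):
            rows.append([f"L{i}", "tumor", "late", "ACA", py, f"pl{i}"])
        for i, py in enumerate(early_py):
            rows.append([f"E{i}", "tumor", "early", "ACA", py, f"pe{i}"])
        return cna.CohortDesign(
            pd.DataFrame(rows, columns=cna.CohortDesign.COLUMNS)
        )

    def test_closest_pack_years_chosen(self):
        pairs = cna.match_by_pack_years(self._design([40], [35, 60]), seed=0)
        assert pairs.pairs == [("L0", "E0")]

    def test_tie_break_deterministic_under_seed(self):
        design = self._design([40], [35, 45])
        p1 = cna.match_by_pack_years(design, seed=9)
        p2 = cna.match_by_pack_years(design, seed=9)
        assert p1.pairs == p2.pairs

    def test_missing_pack_years_excluded(self):
        design = self._design([40, None], [38, 41, None])
        pairs = cna.match_by_pack_years(design, seed=0)
        assert len(pairs.pairs) == 1
        assert pairs.pairs[0][0] == "L0"

    def test_pool_exhaustion_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            cna.match_by_pack_years(self._design([40, 50], [30]), seed=0)

    def test_greedy_total_at_least_optimal(self):
        """Greedy matching is documented as possibly suboptimal: its total
        |pack-year difference| is >= the brute-force optimal assignment."""
        rng = np.random.default_rng(12)
        for _ in range(10):
            late = rng.uniform(0, 80, size=4).round(1).tolist()
            early = rng.uniform(0, 80, size=7).round(1).tolist()
            design = self._design(late, early)
            pairs = cna.match_by_pack_years(design, seed=0)
            py = {f"L{i}": v for i, v in enumerate(late)}
            py.update({f"E{i}": v for i, v in enumerate(early)})
            greedy_total = sum(abs(py[a] - py[b]) for a, b in pairs.pairs)
            best = min(
                sum(abs(l - e) for l, e in zip(late, combo))
                for combo in itertools.permutations(early, len(late))
            )
            assert greedy_total >= best - 1e-9


class TestPairedGlobalTest:
    def test_identical_members_give_p_one(self):
        row = np.array([1, 0, 1, 0], dtype=np.int8)
        calls = _toy_calls(np.vstack([row, row, row, row]))
        pairs = cna.MatchedPairs([("s0", "s1"), ("s2", "s3")])
        res = cna.paired_global_test(calls, pairs, "gain", method="exact")
        assert res.D_observed == 0.0 and res.p_value == 1.0

    def test_exact_matches_swap_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        array = (rng.random((6, 5)) < 0.5).astype(np.int8)
        calls = _toy_calls(array)
        pairs = cna.MatchedPairs([("s0", "s3"), ("s1", "s4"), ("s2", "s5")])
        res = cna.paired_global_test(calls, pairs, "gain", method="exact")
        events = array == 1
        first, second = events[:3], events[3:]
        D_obs = _D_oracle(first, second)
        null = []
        for flips in itertools.product([0, 1], repeat=3):
            a = np.array([second[i] if f else first[i]
                          for i, f in enumerate(flips)])
            b = np.array([first[i] if f else second[i]
                          for i, f in enumerate(flips)])
            null.append(_D_oracle(a, b))
        p_exact = np.mean([d >= D_obs - 1e-12 for d in null])
        assert res.D_observed == pytest.approx(D_obs, rel=1e-12)
        assert res.p_value == pytest.approx(p_exact)

    def test_reused_sample_rejected(self):
        with pytest.raises(ValueError, match="more than one pair"):
            cna.MatchedPairs([("a", "b"), ("a", "c")])

    def test_power_on_planted_paired_effect(self):
        """Late-vs-early paired design with a 3x rate difference: the
        paired test should mostly reject across replicates."""
        ps = []
        for rep in range(10):
            cfg = cna.SimulationConfig(
                seed=300 + rep, n_probes=800, n_chromosomes=2, noise_sd=0.0,
                segment_length_mean=10,
                group_specs=(
                    cna.GroupSpec("late", "tumor", "late", 20, 9.0, 0.0),
                    cna.GroupSpec("early", "tumor", "early", 20, 3.0, 0.0),
                ),
            )
            pm, genes = cna.simulate_probe_map_and_genes(cfg)
            cn, design = cna.simulate_cohort(cfg, pm, genes)
            calls = cna.call_cnas(cn)
            late = design.select(stage="late")
            early = design.select(stage="early")
            pairs = cna.MatchedPairs(list(zip(late, early)))
            res = cna.paired_global_test(
                calls, pairs, "gain", B=200, seed=rep
            )
            ps.append(res.p_value)
        assert np.median(ps) < 0.05
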