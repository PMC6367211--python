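import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kruskal

from cofun_instab.scna import (
    ModalProfile,
    classify_deviations,
    compare_groups,
    count_aberrations,
    modal_profile,
)

from ._oracles import kruskal_h_brute
from .conftest import make_profiles


def make_modal(modal_states, bins_per_chrom=None, n_chrom=1):
    prof = make_profiles(
        np.asarray([modal_states, modal_states]),
        bins_per_chrom=bins_per_chrom,
        n_chrom=n_chrom,
    )
    return ModalProfile(
        prof.chroms, prof.starts, prof.ends, np.asarray(modal_states, dtype=np.int64)
    )


class TestModalProfile:
    def test_uniform_control(self):
        prof = make_profiles(np.full((4, 10), 2))
        modal = modal_profile(prof, "CTRL")
        assert (modal.modal_state == 2).all()

    def test_majority_wins(self):
        states = np.full((5, 10), 2)
        states[3:, 0] = 3  # bin 0: (2,2,2,3,3) -> mode 2
        modal = modal_profile(make_profiles(states), "CTRL")
        assert modal.modal_state[0] == 2

    def test_tie_broken_toward_genome_median(self):
        # bin 0 states (2,2,3,3), genome-wide control median 2 -> 2
        states = np.full((4, 10), 2)
        states[2:, 0] = 3
        modal = modal_profile(make_profiles(states), "CTRL")
        assert modal.modal_state[0] == 2

    def test_tie_rule_exhaustive_enumeration(self):
        # enumerate all 2-state ties around different genome medians and
        # check the rule: nearest to genome median, then lower state
        for a, b in itertools.combinations(range(5), 2):
            for background in (1, 2, 3):
                states = np.full((4, 12), background)
                states[:2, 0] = a
                states[2:, 0] = b
                med = float(np.median(states))
                expected = min(
                    np.unique(states[:, 0]),
                    key=lambda s: (abs(s - med), s),
                )
                modal = modal_profile(make_profiles(states), "CTRL")
                assert modal.modal_state[0] == expected, (a, b, background)

    def test_no_control_cells_error(self):
        prof = make_profiles(np.full((3, 10), 2), conditions=["DOX"] * 3)
        with pytest.raises(ValueError, match="no cells"):
            modal_profile(prof, "CTRL")

    def test_too_few_control_cells_error(self):
        prof = make_profiles(np.full((2, 10), 2))
        with pytest.raises(ValueError, match=">= 3 control cells"):
            modal_profile(prof, "CTRL")

    def test_idempotence(self):
        # replicating the modal profile as cells returns itself
        rng = np.random.default_rng(0)
        base = rng.integers(1, 4, size=20)
        prof = make_profiles(np.tile(base, (3, 1)), n_chrom=2)
        modal = modal_profile(prof, "CTRL")
        np.testing.assert_array_equal(modal.modal_state, base)
        prof2 = make_profiles(np.tile(modal.modal_state, (3, 1)), n_chrom=2)
        modal2 = modal_profile(prof2, "CTRL")
        np.testing.assert_array_equal(modal2.modal_state, modal.modal_state)


class TestClassifyDeviations:
    def test_identical_to_modal_no_events(self):
        modal = make_modal([2] * 20)
        assert classify_deviations(np.full(20, 2), modal) == []

    def test_single_bin_focal(self):
        modal = make_modal([2] * 20)
        cell = np.full(20, 2)
        cell[5] = 3
        events = classify_deviations(cell, modal)
        assert len(events) == 1
        assert events[0].kind == "focal"
        assert (events[0].start_bin, events[0].end_bin) == (5, 6)
        assert events[0].direction == 1

    def test_whole_chromosome(self):
        modal = make_modal([2] * 20)
        events = classify_deviations(np.full(20, 3), modal)
        assert [e.kind for e in events] == ["whole_chromosome"]

    def test_fraction_boundary_is_inclusive(self):
        # 18 of 20 bins deviating = fraction 0.9 -> whole-chromosome
        modal = make_modal([2] * 20)
        cell = np.full(20, 3)
        cell[:2] = 2
        events = classify_deviations(cell, modal, whole_chrom_fraction=0.9)
        assert [e.kind for e in events] == ["whole_chromosome"]
        # 17 of 20 -> focal
        cell[:3] = 2
        events = classify_deviations(cell, modal, whole_chrom_fraction=0.9)
        assert [e.kind for e in events] == ["focal"]

    def test_boundary_enumeration_against_rule(self):
        # for every run length on a 20-bin chromosome the classification
        # matches the stated >= fraction rule
        modal = make_modal([2] * 20)
        for run in range(1, 21):
            cell = np.full(20, 2)
            cell[:run] = 3
            events = classify_deviations(cell, modal, whole_chrom_fraction=0.9)
            expected = "whole_chromosome" if run >= 18 else "focal"
            assert [e.kind for e in events] == [expected], run

    def test_sign_change_splits_run(self):
        modal = make_modal([2] * 20)
        cell = np.full(20, 2)
        cell[4:8] = 3
        cell[8:12] = 1  # contiguous with the gain run but opposite sign
        events = classify_deviations(cell, modal)
        assert len(events) == 2
        assert [e.direction for e in events] == [1, -1]

    def test_magnitude_ignored(self):
        modal = make_modal([2] * 20)
        cell = np.full(20, 2)
        cell[3] = 4
        cell[4] = 3  # states 4 and 3 against modal 2: one gain run
        events = classify_deviations(cell, modal)
        assert len(events) == 1

    def test_runs_break_at_chromosome_boundaries(self):
        modal = make_modal([2] * 20, bins_per_chrom=10, n_chrom=2)
        cell = np.full(20, 3)  # both chromosomes fully trisomic
        events = classify_deviations(cell, modal)
        assert [e.kind for e in events] == ["whole_chromosome"] * 2
        assert {e.chrom for e in events} == {"chr1", "chr2"}


class TestCountAberrations:
    def test_control_cell_zero_counts(self):
        prof = make_profiles(np.full((3, 20), 2))
        modal = modal_profile(prof, "CTRL")
        counts = count_aberrations(prof, modal)
        assert (counts["n_focal"] == 0).all()
        assert (counts["n_whole_chromosome"] == 0).all()

    def test_additivity(self):
        # 2 disjoint focal runs on chr1 + trisomic chr2 -> (2, 1)
        states = np.full((4, 40), 2)
        states[3, 2:5] = 3
        states[3, 10:12] = 1
        states[3, 20:40] = 3
        prof = make_profiles(
            states, conditions=["CTRL"] * 3 + ["DOX"], bins_per_chrom=20, n_chrom=2
        )
        modal = modal_profile(prof, "CTRL")
        counts = count_aberrations(prof, modal).set_index("cell_id")
        assert counts.loc["cell3", "n_focal"] == 2
        assert counts.loc["cell3", "n_whole_chromosome"] == 1
        assert (counts.loc[["cell0", "cell1", "cell2"], ["n_focal", "n_whole_chromosome"]] == 0).all().all()

    def test_conservation_against_classify(self):
        rng = np.random.default_rng(1)
        states = rng.integers(1, 4, size=(6, 60))
        states[:3] = 2  # controls diploid
        prof = make_profiles(
            states, conditions=["CTRL"] * 3 + ["X"] * 3, bins_per_chrom=20, n_chrom=3
        )
        modal = modal_profile(prof, "CTRL")
        counts = count_aberrations(prof, modal)
        for i in range(6):
            events = classify_deviations(prof.states[i], modal)
            total = counts.iloc[i]["n_focal"] + counts.iloc[i]["n_whole_chromosome"]
            assert total == len(events)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_fraction_monotonicity(self, seed):
        # lowering the whole-chromosome fraction never decreases whole
        # counts nor increases focal counts
        rng = np.random.default_rng(seed)
        states = rng.integers(1, 4, size=(5, 40))
        states[:3] = 2
        prof = make_profiles(
            states, conditions=["CTRL"] * 3 + ["X"] * 2, bins_per_chrom=20, n_chrom=2
        )
        modal = modal_profile(prof, "CTRL")
        prev = None
        for frac in [1.0, 0.9, 0.7, 0.5, 0.3]:
            counts = count_aberrations(prof, modal, whole_chrom_fraction=frac)
            if prev is not None:
                assert (counts["n_whole_chromosome"] >= prev["n_whole_chromosome"]).all()
                assert (counts["n_focal"] <= prev["n_focal"]).all()
            prev = counts


class TestCompareGroups:
    def _counts(self, groups: dict[str, list[int]]) -> pd.DataFrame:
        rows = []
        for cond, vals in groups.items():
            for i, v in enumerate(vals):
                rows.append((f"{cond}_{i}", cond, v, 0))
        return pd.DataFrame(
            rows, columns=["cell_id", "condition", "n_focal", "n_whole_chromosome"]
        )

    def test_identical_groups_p_near_one(self):
        cmp = compare_groups(
            self._counts({"A": [1, 2, 3, 4], "B": [1, 2, 3, 4]})
        )
        assert cmp.kw_pvalue > 0.9
        assert (cmp.pairwise["p_adj"] >= cmp.pairwise["p_raw"] - 1e-15).all()

    def test_all_constant_p_is_one(self):
        cmp = compare_groups(self._counts({"A": [0, 0, 0, 0], "B": [0, 0, 0, 0]}))
        assert cmp.kw_pvalue == 1.0
        assert cmp.kw_statistic == 0.0

    def test_separated_groups_statistic_is_maximal(self):
        # (0,0,0,0) vs (5,5,5,5): H equals its maximum over all
        # assignments of these 8 values into two groups of 4
        values = [0, 0, 0, 0, 5, 5, 5, 5]
        best = 0.0
        for subset in itertools.combinations(range(8), 4):
            a = [values[i] for i in subset]
            b = [values[i] for i in range(8) if i not in subset]
            best = max(best, kruskal_h_brute([a, b]))
        cmp = compare_groups(self._counts({"A": [0, 0, 0, 0], "B": [5, 5, 5, 5]}))
        assert cmp.kw_statistic == pytest.approx(best, abs=1e-10)

    def test_matches_scipy_kruskal(self):
        rng = np.random.default_rng(2)
        groups = {c: list(rng.integers(0, 6, size=10)) for c in "ABC"}
        cmp = compare_groups(self._counts(groups))
        stat, p = kruskal(*groups.values())
        assert cmp.kw_statistic == pytest.approx(stat)
        assert cmp.kw_pvalue == pytest.approx(p)

    def test_oracle_h_statistic(self):
        rng = np.random.default_rng(5)
        groups = {c: list(rng.integers(0, 4, size=6)) for c in "AB"}
        cmp = compare_groups(self._counts(groups))
        assert cmp.kw_statistic == pytest.approx(
            kruskal_h_brute(list(groups.values())), abs=1e-10
        )

    def test_small_condition_excluded_with_warning(self):
        counts = self._counts({"A": [1, 2, 3, 4], "B": [2, 3, 4, 5], "C": [9]})
        with pytest.warns(UserWarning, match="excluded"):
            cmp = compare_groups(counts)
        assert cmp.excluded == ["C"]
        assert set(cmp.group_stats["condition"]) == {"A", "B"}

    def test_too_few_conditions_error(self):
        counts = self._counts({"A": [1, 2, 3], "B": [5]})
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match=">= 2 conditions"):
                compare_groups(counts)

    def test_medians_reproducible(self):
        groups = {"A": [0, 1, 2, 10], "B": [3, 3, 4, 8]}
        cmp = compare_groups(self._counts(groups))
        med = cmp.group_stats.set_index("condition")["median"]
        for cond, vals in groups.items():
            assert med[cond] == np.median(vals)

    def test_total_metric(self):
        counts = self._counts({"A": [1, 2, 3, 4], "B": [2, 3, 4, 5]})
        counts["n_whole_chromosome"] = 1
        cmp = compare_groups(counts, metric="total")
        assert cmp.metric == "total"
        med = cmp.group_stats.set_index("condition")["median"]
        assert med["A"] == np.median([2, 3, 4, 5])

    def test_unknown_metric_error(self):
        with pytest.raises(ValueError, match="metric"):
            compare_groups(self._counts({"A": [1, 2, 3], "B": [1, 2, 3]}), metric="x")

    def test_dunn_bonferroni_adjustment(self):
        rng = np.random.default_rng(9)
        groups = {c: list(rng.integers(0, 8, size=8)) for c in "ABCD"}
        cmp = compare_groups(self._counts(groups))
        n_pairs = 6
        for row in cmp.pairwise.itertuples():
            assert row.p_adj == pytest.approx(min(1.0, row.p_raw * n_pairs))
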