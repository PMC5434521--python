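"""Phase-comparison metrics against brute-force string oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from scaffoldphase import (
    HaplotypeSet,
    MarkerPanel,
    compare_phase,
    distance_to_nearest_switch,
    genome_proportion_by_length,
    segment_stats,
    switch_count,
)
from scaffoldphase.mendel import PhasableMask
from scaffoldphase.metrics import ComparisonRecord, PhaseComparison


def make_panel(pos):
    pos = np.asarray(pos)
    return MarkerPanel(
        chrom=np.array(["1"] * len(pos), dtype=object),
        pos=pos,
        ref=np.array(["A"] * len(pos), dtype=object),
        alt=np.array(["T"] * len(pos), dtype=object),
        is_scaffold=np.zeros(len(pos), bool),
    )


def cmp_from_string(s, pos=None):
    match = np.array([c == "M" for c in s])
    if pos is None:
        pos = (np.arange(len(s)) + 1) * 10
    rec = ComparisonRecord(0, "1", np.arange(len(s)), match)
    return PhaseComparison(records=[rec]), make_panel(pos)


class TestComparePhase:
    def _setup(self, tiny_population):
        _, (ped, panel, gtd, gts, truth) = tiny_population
        from scaffoldphase import find_phasable, mendel_phase_offspring

        mendel, _ = mendel_phase_offspring(gtd, ped)
        mask = find_phasable(gtd, ped)
        return panel, gtd, mendel, mask, truth

    def test_identical_phases_all_match(self, tiny_population):
        panel, gtd, mendel, mask, truth = self._setup(tiny_population)
        test = HaplotypeSet(mendel.alleles.copy(), origin_known=np.ones(mendel.n_individuals, bool))
        cmp = compare_phase(test, mendel, mask, panel)
        assert cmp.pooled_error() == 0.0
        assert cmp.mean_per_animal_error() == 0.0

    def test_swapped_phase_all_mismatch(self, tiny_population):
        panel, gtd, mendel, mask, truth = self._setup(tiny_population)
        test = HaplotypeSet(
            mendel.alleles[:, :, ::-1].copy(), origin_known=np.ones(mendel.n_individuals, bool)
        )
        cmp = compare_phase(test, mendel, mask, panel)
        assert cmp.pooled_error() == 1.0

    def test_unknown_origin_rejected(self, tiny_population):
        panel, gtd, mendel, mask, truth = self._setup(tiny_population)
        test = HaplotypeSet(mendel.alleles.copy())  # origin_known False
        with pytest.raises(ValueError, match="origin"):
            compare_phase(test, mendel, mask, panel)
        cmp = compare_phase(test, mendel, mask, panel, assume_origin=True)
        assert cmp.pooled_error() == 0.0

    def test_random_phase_near_half(self, tiny_population, rng):
        panel, gtd, mendel, mask, truth = self._setup(tiny_population)
        alleles = mendel.alleles.copy()
        het = gtd.values == 1
        coins = rng.integers(0, 2, size=alleles.shape[:2]).astype(np.int8)
        a0 = np.where(het, coins, alleles[:, :, 0])
        a1 = np.where(het, 1 - coins, alleles[:, :, 1])
        test = HaplotypeSet(
            np.stack([a0, a1], axis=2), origin_known=np.ones(mendel.n_individuals, bool)
        )
        cmp = compare_phase(test, mendel, mask, panel)
        n = int(mask.mask.sum())
        p = cmp.pooled_error()
        assert abs(p - 0.5) < 3 * np.sqrt(0.25 / n)


class TestSwitchCount:
    @pytest.mark.parametrize("s,expected", [("MMMM", 0), ("MMXMM", 2), ("MX", 1), ("M", 0)])
    def test_examples(self, s, expected):
        cmp, _ = cmp_from_string(s)
        assert switch_count(cmp)["n_switches"].iloc[0] == expected

    @given(st.text(alphabet="MX", min_size=1, max_size=40))
    def test_matches_adjacent_scan(self, s):
        cmp, _ = cmp_from_string(s)
        brute = sum(1 for a, b in zip(s, s[1:]) if a != b)
        assert switch_count(cmp)["n_switches"].iloc[0] == brute


class TestSegmentStats:
    def test_singleton_example(self):
        cmp, panel = cmp_from_string("MMXMM", pos=[10, 20, 30, 40, 50])
        table, summary = segment_stats(cmp, panel)
        assert len(table) == 3
        wrong = table[table.status == "wrong"].iloc[0]
        assert wrong.is_singleton and wrong.length_bp == 1 and wrong.first_pos == 30

    def test_drop_singletons_merges(self):
        cmp, panel = cmp_from_string("MMXMM", pos=[10, 20, 30, 40, 50])
        table, _ = segment_stats(cmp, panel, filters="drop_singletons")
        assert len(table) == 1
        seg = table.iloc[0]
        assert seg.status == "correct" and seg.first_pos == 10 and seg.last_pos == 50
        assert seg.n_phasable_snps == 4

    def test_drop_small_requires_both_conditions(self):
        # 3 phasable SNPs spanning 10 kb: few SNPs but long -> kept
        cmp, panel = cmp_from_string("MMMXXXMMM", pos=[1, 2, 3, 10, 5010, 10010, 10011, 10012, 10013])
        table, _ = segment_stats(cmp, panel, filters="drop_small")
        assert (table.status == "wrong").sum() == 1

    def test_alternation_and_switch_relation(self, rng):
        for _ in range(20):
            s = "".join(rng.choice(list("MX"), size=rng.integers(1, 30)))
            cmp, panel = cmp_from_string(s)
            table, _ = segment_stats(cmp, panel)
            sw = switch_count(cmp)["n_switches"].iloc[0]
            assert len(table) == sw + 1
            statuses = list(table.status)
            assert all(a != b for a, b in zip(statuses, statuses[1:]))

    @given(st.text(alphabet="MX", min_size=1, max_size=30))
    def test_matches_rle_oracle(self, s):
        cmp, panel = cmp_from_string(s)
        table, _ = segment_stats(cmp, panel)
        # brute-force run-length encoding
        runs = []
        start = 0
        for t in range(1, len(s) + 1):
            if t == len(s) or s[t] != s[start]:
                runs.append((s[start] == "M", start, t))
                start = t
        assert len(table) == len(runs)
        for (st_, a, b), (_, row) in zip(runs, table.iterrows()):
            assert (row.status == "correct") == st_
            assert row.n_phasable_snps == b - a
            expected_len = (b - 1 - a) * 10 + 1 if b - a > 1 else 1
            assert row.length_bp == expected_len


class TestDistanceToSwitch:
    def test_single_switch(self):
        pos = [10_000_000, 50_000_000, 90_000_000]
        cmp, panel = cmp_from_string("MMX", pos=pos)
        per, summary = distance_to_nearest_switch(cmp, panel)
        d = per[(0, "1")]
        # switch midpoint at 70 Mb
        assert d[0] == pytest.approx(60.0)
        assert d[2] == pytest.approx(20.0)

    def test_no_switch_uses_chromosome_ends(self):
        pos = [10_000_000, 40_000_000, 90_000_000]
        cmp, panel = cmp_from_string("MMM", pos=pos)
        per, _ = distance_to_nearest_switch(cmp, panel)
        d = per[(0, "1")]
        assert d[0] == 0.0
        assert d[1] == pytest.approx(30.0)
        assert d[2] == 0.0

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            m = int(rng.integers(2, 20))
            pos = np.sort(rng.choice(10_000_000, size=m, replace=False)) + 1
            s = "".join(rng.choice(list("MX"), size=m))
            cmp, panel = cmp_from_string(s, pos=pos)
            per, _ = distance_to_nearest_switch(cmp, panel)
            d = per[(0, "1")]
            match = np.array([c == "M" for c in s])
            sw = [(pos[t] + pos[t + 1]) / 2 for t in range(m - 1) if match[t] != match[t + 1]]
            for j in range(m):
                if sw:
                    want = min(abs(pos[j] - x) for x in sw) / 1e6
                else:
                    want = min(pos[j] - pos[0], pos[-1] - pos[j]) / 1e6
                assert d[j] == pytest.approx(want)


class TestGenomeProportion:
    def test_whole_genome_one_segment(self):
        cmp, panel = cmp_from_string("MM", pos=[1, 60_000_000])
        table, _ = segment_stats(cmp, panel)
        props = genome_proportion_by_length(table, classes=(1, 5, 50))
        correct = props[props.status == "correct"]
        assert np.allclose(correct.proportion, 1.0)

    def test_short_segments_excluded(self):
        cmp, panel = cmp_from_string("MMXX", pos=[1, 3_000_000, 3_000_010, 6_000_000])
        table, _ = segment_stats(cmp, panel)
        props = genome_proportion_by_length(table, classes=(5,))
        assert np.allclose(props.proportion, 0.0)

    def test_matches_direct_sum(self, rng):
        s = "".join(rng.choice(list("MX"), size=25))
        pos = np.sort(rng.choice(100_000_000, size=25, replace=False)) + 1
        cmp, panel = cmp_from_string(s, pos=pos)
        table, _ = segment_stats(cmp, panel)
        total = table.length_bp.sum()
        props = genome_proportion_by_length(table, classes=(1, 10))
        for _, row in props.iterrows():
            sel = table[(table.status == row.status) & (table.length_bp >= row.min_length_mb * 1e6)]
            assert row.proportion == pytest.approx(sel.length_bp.sum() / total)
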