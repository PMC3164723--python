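from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmi import LabeledExpressionMatrix, count_bct, gmi_statistics, level_profiles

from conftest import bct_oracle


class TestCountBct:
    def test_perfectly_separated_groups(self):
        assert count_bct([0.9, 0.8, 0.7, 0.2, 0.1], [1, 1, 1, 0, 0]) == 1

    @pytest.mark.parametrize("m", [1, 2, 3, 5])
    def test_perfectly_interleaved_groups(self, m):
        # ABAB...AB over 2m samples has 2m - 1 adjacent group changes
        values = np.arange(2 * m)[::-1].astype(float)
        flags = np.tile([True, False], m)
        assert count_bct(values, flags) == 2 * m - 1
        assert bct_oracle(values, flags) == 2 * m - 1

    def test_sandwiched_sample_adds_two(self):
        # two-class illustration: 5 + 5 samples where outliers from each
        # class interleave in the sorted order, giving 5 transitions in
        # total (each fully sandwiched sample contributes two)
        values = np.array([0.9, 0.8, 0.7, 0.5, 0.3, 0.6, 0.4, 0.2, 0.15, 0.1])
        flags = np.array([1] * 5 + [0] * 5, dtype=bool)
        assert count_bct(values, flags) == 5
        assert bct_oracle(values, flags) == 5

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="lower"):
            count_bct([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="upper"):
            count_bct([1.0, 2.0], [0, 0])

    @given(st.data())
    @settings(derandomize=True, max_examples=300)
    def test_matches_adjacency_scan_oracle(self, data):
        n = data.draw(st.integers(min_value=2, max_value=30))
        values = np.array(
            data.draw(
                st.lists(
                    st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=n,
                    max_size=n,
                )
            )
        )
        n_up = data.draw(st.integers(min_value=1, max_value=n - 1))
        flags = np.zeros(n, dtype=bool)
        flags[data.draw(st.permutations(range(n)))[:n_up]] = True
        bct = count_bct(values, flags)
        assert bct == bct_oracle(values, flags)
        assert 1 <= bct <= 2 * min(n_up, n - n_up)

    @given(st.data())
    @settings(derandomize=True, max_examples=100)
    def test_invariant_under_strictly_increasing_transform(self, data):
        n = data.draw(st.integers(min_value=3, max_value=15))
        values = np.array(
            data.draw(
                st.lists(
                    st.floats(min_value=0.1, max_value=5, allow_nan=False),
                    min_size=n,
                    max_size=n,
                    unique=True,
                )
            )
        )
        flags = np.zeros(n, dtype=bool)
        flags[: data.draw(st.integers(min_value=1, max_value=n - 1))] = True
        # nonlinear strictly increasing transform, exact at the data
        # points (rank-based interpolation avoids rounding-induced ties)
        transformed = np.interp(values, np.sort(values), (np.arange(n) + 1.0) ** 2)
        assert count_bct(values, flags) == count_bct(transformed, flags)

    def test_moving_one_sample_changes_bct_by_at_most_two(self, rng):
        # robustness: the count depends on the outlier's rank position,
        # not its magnitude, so one sample moves BCT by <= 2
        for _ in range(50):
            n = int(rng.integers(4, 20))
            values = rng.uniform(size=n)
            flags = np.zeros(n, dtype=bool)
            flags[rng.permutation(n)[: int(rng.integers(1, n))]] = True
            base = count_bct(values, flags)
            moved = values.copy()
            moved[int(rng.integers(n))] = rng.choice([-100.0, 100.0])
            assert abs(count_bct(moved, flags) - base) <= 2


class TestPessimisticTies:
    def brute_force_max(self, values, flags):
        """Max BCT over all orderings within blocks of tied values."""
        order = sorted(range(len(values)), key=lambda i: -values[i])
        best = 0
        blocks = {}
        for i in order:
            blocks.setdefault(values[i], []).append(flags[i])
        keys = sorted(blocks, reverse=True)

        def rec(i, seq):
            nonlocal best
            if i == len(keys):
                best = max(best, sum(a != b for a, b in zip(seq, seq[1:])))
                return
            for perm in set(permutations(blocks[keys[i]])):
                rec(i + 1, seq + list(perm))

        rec(0, [])
        return best

    @pytest.mark.parametrize(
        "values,flags",
        [
            ([1, 1, 1, 0, 0], [1, 0, 1, 0, 1]),
            ([2, 2, 2, 2, 1], [1, 1, 0, 0, 1]),
            ([1, 1, 1, 1, 1, 1], [1, 1, 1, 0, 0, 0]),
            ([3, 2, 2, 2, 1, 1], [0, 1, 1, 0, 1, 0]),
            ([5, 5, 4, 4, 3, 3], [1, 0, 0, 1, 1, 0]),
        ],
    )
    def test_matches_exhaustive_tie_arrangement(self, values, flags):
        got = count_bct(np.array(values, float), np.array(flags, bool), tie_rule="pessimistic")
        assert got == self.brute_force_max(list(values), list(flags))

    def test_no_ties_agrees_with_stable(self, rng):
        for _ in range(20):
            values = rng.permutation(12).astype(float)
            flags = np.zeros(12, dtype=bool)
            flags[rng.permutation(12)[:5]] = True
            assert count_bct(values, flags, "pessimistic") == count_bct(values, flags, "stable")


class TestLevelProfiles:
    def test_perfect_two_class_gene(self, two_class_perfect):
        (p,) = level_profiles(two_class_perfect, "g1")
        assert p.level == 1 and p.mu_sep == 1.0 and p.bct == 1
        assert p.n_s == 5 and p.ovl == pytest.approx(0.2)
        assert p.gmi == pytest.approx(5.0)  # GMI = mu_sep * N_S when BCT = 1
        assert p.upper_group == (1,) and p.lower_group == (2,)

    def test_exactly_k_minus_1_profiles(self, rng):
        for K in (2, 3, 5):
            labels = np.repeat(np.arange(1, K + 1), 4)
            data = LabeledExpressionMatrix(
                rng.uniform(size=(3, 4 * K)),
                ("a", "b", "c"),
                tuple(f"s{i}" for i in range(4 * K)),
                labels,
            )
            assert len(level_profiles(data, "b")) == K - 1

    def test_level2_gene_dominates_other_levels(self, rng):
        # five balanced classes with two clearly elevated classes: the
        # level-2 index must strictly dominate levels 1, 3 and 4
        means = {1: 0.2, 2: 0.15, 3: 0.85, 4: 0.75, 5: 0.1}
        labels = np.repeat(np.arange(1, 6), 10)
        row = np.clip(
            [rng.normal(means[k], 0.05) for k in labels], 0, 1
        )
        data = LabeledExpressionMatrix(
            np.array(row)[None, :],
            ("g",),
            tuple(f"s{i}" for i in range(50)),
            labels,
        )
        profiles = level_profiles(data, "g")
        gmis = [p.gmi for p in profiles]
        assert int(np.argmax(gmis)) + 1 == 2
        assert all(gmis[1] > g for i, g in enumerate(gmis) if i != 1)
        assert profiles[1].upper_group in ((3, 4), (4, 3))

    def test_class_mean_ties_broken_by_ascending_class_id(self):
        values = np.array([[0.5, 0.5, 0.1, 0.1]])
        data = LabeledExpressionMatrix(
            values, ("g",), ("s0", "s1", "s2", "s3"), np.array([1, 2, 3, 4])
        )
        profiles = level_profiles(data, "g")
        assert profiles[0].class_order == (1, 2, 3, 4)

    def test_gmi_invariant_under_positive_affine_raw_row(self, rng):
        from gmi.preprocess import minmax_rows

        labels = np.repeat([1, 2, 3], 6)
        raw = rng.normal(size=(1, 18))
        a = gmi_statistics(minmax_rows(raw), labels)["gmi"]
        b = gmi_statistics(minmax_rows(3.7 * raw + 11.0), labels)["gmi"]
        assert np.allclose(a, b)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="class 2"):
            gmi_statistics(np.ones((1, 4)), np.array([1, 1, 3, 3]))
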