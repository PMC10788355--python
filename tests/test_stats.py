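"""Statistical kernels against textbook / brute-force oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from dartsex.panel import MISSING, MarkerType
from dartsex.stats import (
    catt,
    conformity_chi2,
    het_percent,
    kruskal_wallis,
    nemenyi_posthoc,
    pic,
)

from conftest import make_panel


def brute_force_catt(table, weights):
    """N·r² computed on the expanded per-individual (group, score) pairs."""
    table = np.asarray(table, dtype=int)
    ys, xs = [], []
    for row, y in ((0, 1), (1, 0)):
        for j, w in enumerate(weights):
            xs += [w] * table[row, j]
            ys += [y] * table[row, j]
    xs, ys = np.array(xs, float), np.array(ys, float)
    r = np.corrcoef(xs, ys)[0, 1]
    return len(xs) * r**2


def brute_force_kw(groups):
    """Textbook tie-corrected H on pooled ranks."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = pooled.size
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - ((counts**3 - counts).sum()) / (n**3 - n)
    return h / tie


class TestCATT:
    def test_perfect_separation_equals_sample_size(self):
        chi2, p = catt([[0, 16, 0], [16, 0, 0]], weights=[0, 1, 2])
        assert chi2 == pytest.approx(32.0, abs=1e-12)
        assert p < 1e-7

    def test_partial_separation_fixture(self):
        chi2, _ = catt([[4, 12, 0], [16, 0, 0]], weights=[0, 1, 2])
        assert chi2 == pytest.approx(19.2, abs=1e-12)

    def test_identical_rows_have_no_trend(self):
        chi2, p = catt([[5, 5, 5], [5, 5, 5]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_degenerate_table_warns_not_raises(self):
        with pytest.warns(UserWarning):
            chi2, p = catt([[10, 0, 0], [12, 0, 0]])
        assert (chi2, p) == (0.0, 1.0)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            k = rng.choice([2, 3])
            t = rng.integers(0, 12, size=(2, k))
            if t.sum(axis=1).min() == 0 or np.count_nonzero(t.sum(axis=0)) < 2:
                continue
            w = np.arange(k, dtype=float)
            expect = brute_force_catt(t, w)
            if not np.isfinite(expect):
                continue
            got, _ = catt(t, w)
            assert got == pytest.approx(expect, abs=1e-9)

    def test_invariance_row_swap_with_score_reversal(self):
        t = np.array([[3, 7, 6], [8, 2, 1]])
        a, _ = catt(t, weights=[0, 1, 2])
        b, _ = catt(t[::-1], weights=[2, 1, 0])
        assert a == pytest.approx(b, abs=1e-12)

    def test_invariance_under_affine_rescoring(self):
        t = np.array([[3, 7, 6], [8, 2, 1]])
        a, _ = catt(t, weights=[0, 1, 2])
        b, _ = catt(t, weights=[10, 13, 16])  # 3w + 10
        assert a == pytest.approx(b, abs=1e-9)


class TestPearsonConformity:
    def test_observed_equals_expected(self):
        chi2, p = conformity_chi2([[5, 5], [5, 5]], [[5, 5], [5, 5]])
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        chi2, _ = conformity_chi2([[10, 0], [0, 10]], [[5, 5], [5, 5]])
        assert chi2 == pytest.approx(20.0, abs=1e-12)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            obs = rng.integers(0, 20, size=6).astype(float)
            exp = rng.uniform(1, 20, size=6)
            chi2, _ = conformity_chi2(obs, exp)
            assert chi2 == pytest.approx(((obs - exp) ** 2 / exp).sum(), abs=1e-9)

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValueError):
            conformity_chi2([1, 2], [0, 3])


class TestPIC:
    @pytest.mark.parametrize("p,expected", [(0.5, 0.5), (1.0, 0.0), (0.0, 0.0), (0.1, 0.18)])
    def test_known_values(self, p, expected):
        assert pic(p) == pytest.approx(expected, abs=1e-12)

    def test_maximized_at_half_over_grid(self):
        grid = np.linspace(0, 1, 201)
        vals = [pic(p) for p in grid]
        assert max(vals) == pic(0.5)
        assert np.argmax(vals) == 100

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pic(1.2)


class TestHetPercent:
    def _panel(self, column):
        calls = np.array(column, dtype=np.int8).reshape(-1, 1)
        return make_panel(MarkerType.SNP, calls)

    def test_all_het_and_none_het(self):
        panel = self._panel([1] * 5)
        assert het_percent(panel, "S00", panel.loci) == 100.0
        panel = self._panel([0, 2, 0, 2])
        assert het_percent(panel, "S00", panel.loci) == 0.0

    def test_partial_with_missing_excluded(self):
        panel = self._panel([1, 1, 1] + [0] * 9 + [MISSING] * 2)
        assert het_percent(panel, "S00", panel.loci) == pytest.approx(25.0)

    def test_no_calls_is_nan(self):
        panel = self._panel([MISSING, MISSING])
        assert np.isnan(het_percent(panel, "S00", panel.loci))


class TestKruskalWallis:
    def test_identical_groups_define_h0_p1(self):
        h, p = kruskal_wallis([np.ones(5), np.ones(4), np.ones(6)])
        assert (h, p) == (0.0, 1.0)

    def test_two_clean_groups_match_rank_formula(self):
        h, _ = kruskal_wallis([np.array([1, 2, 3]), np.array([4, 5, 6])])
        assert h == pytest.approx(brute_force_kw([[1, 2, 3], [4, 5, 6]]), abs=1e-12)

    def test_group_order_invariance(self):
        g = [np.array([1.0, 5, 2]), np.array([3.0, 3, 8]), np.array([9.0, 1])]
        assert kruskal_wallis(g) == pytest.approx(kruskal_wallis(g[::-1]))

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(500):
            k = rng.integers(2, 5)
            groups = [
                rng.integers(0, 8, size=rng.integers(2, 8)).astype(float)
                for _ in range(k)
            ]
            pooled = np.concatenate(groups)
            if np.all(pooled == pooled[0]):
                continue
            h, _ = kruskal_wallis(groups)
            assert h == pytest.approx(brute_force_kw(groups), abs=1e-9)


class TestNemenyi:
    def test_identical_groups_all_p1(self):
        m = nemenyi_posthoc([np.ones(4), np.ones(4), np.ones(4)])
        assert (m.to_numpy() == 1.0).all()

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(size=6) for _ in range(4)]
        m = nemenyi_posthoc(groups).to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)

    def test_widening_separation_never_increases_p(self):
        base = np.array([0.0, 1.0, 2.0, 3.0])
        third = np.array([1.0, 2.0, 3.0, 4.0])
        last_p = 1.1
        for shift in (0.0, 2.0, 5.0, 10.0):
            m = nemenyi_posthoc([base, base + shift, third])
            p = m.iloc[0, 1]
            assert p <= last_p + 1e-12
            last_p = p

    def test_needs_three_groups(self):
        with pytest.raises(ValueError):
            nemenyi_posthoc([np.ones(3), np.ones(3)])
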