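import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact

import ranktype as rt
from ranktype.data_io import DataError
from ranktype.reversal import ContingencyTable


def exact_fisher_two_sided(f11, f12, f21, f22) -> Fraction:
    """Exact-rational enumeration oracle: sum P(table) over all tables with
    the observed margins whose point probability <= P(observed)."""
    n1, n2 = f11 + f12, f21 + f22
    K = f11 + f21
    t = n1 + n2
    denom = math.comb(t, K)

    def pmf(k):
        return Fraction(math.comb(n1, k) * math.comb(n2, K - k), denom)

    p_obs = pmf(f11)
    total = Fraction(0)
    for k in range(max(0, K - n2), min(K, n1) + 1):
        p = pmf(k)
        if p <= p_obs:
            total += p
    return total


class TestEnumeratePairs:
    @pytest.mark.parametrize("n_genes,expected", [
        (710, 251_695), (880, 386_760), (346, 59_685), (345, 59_340), (2, 1),
    ])
    def test_pair_counts(self, n_genes, expected):
        genes = [f"g{i:04d}" for i in range(n_genes)]
        assert len(rt.enumerate_pairs(genes)) == expected

    def test_lexicographic_and_deterministic(self):
        pairs = rt.enumerate_pairs({"b", "a", "c"})
        assert pairs == [("a", "b"), ("a", "c"), ("b", "c")]

    def test_fewer_than_two_genes_errors(self):
        with pytest.raises(DataError):
            rt.enumerate_pairs({"a"})


class TestIndicatorAndRatio:
    @pytest.mark.parametrize("ti,tj,expected", [(5, 3, 1), (3, 5, 0), (2.5, 2.5, 0)])
    def test_indicator(self, ti, tj, expected):
        assert rt.ger_indicator(ti, tj) == expected

    @given(st.floats(1, 100), st.floats(1, 100))
    @settings(max_examples=50, deadline=None)
    def test_indicator_complement(self, a, b):
        s = rt.ger_indicator(a, b) + rt.ger_indicator(b, a)
        assert s == (0 if a == b else 1)

    @pytest.mark.parametrize("cells,expected", [
        ((10, 0, 0, 10), 1.0), ((5, 5, 5, 5), 0.5), ((90, 10, 5, 95), 0.925),
    ])
    def test_ratio_spot_values(self, cells, expected):
        assert rt.reversal_ratio(ContingencyTable(*cells)) == pytest.approx(expected)

    def test_empty_table_is_an_error(self):
        with pytest.raises(DataError):
            ContingencyTable(0, 0, 0, 0)

    @given(st.tuples(*[st.integers(0, 30)] * 4).filter(lambda c: sum(c) > 0))
    @settings(max_examples=100, deadline=None)
    def test_orientation_complement_sums_to_one(self, cells):
        f11, f12, f21, f22 = cells
        r = rt.reversal_ratio(ContingencyTable(f11, f12, f21, f22))
        # flipping the pair orientation swaps the indicator columns
        r_flip = rt.reversal_ratio(ContingencyTable(f12, f11, f22, f21))
        assert r + r_flip == pytest.approx(1.0, abs=0)


class TestFisher:
    @pytest.mark.parametrize("cells,expected", [
        ((1, 1, 1, 1), 1.0),
        ((3, 1, 1, 3), 34 / 70),
        ((10, 0, 0, 10), 2 / math.comb(20, 10)),
    ])
    def test_spot_values(self, cells, expected):
        assert rt.fisher_p(ContingencyTable(*cells)) == pytest.approx(expected, rel=1e-12)

    def test_matches_exact_enumeration_oracle(self):
        rng = np.random.default_rng(2024)
        tables = []
        while len(tables) < 300:
            c = rng.integers(0, 20, size=4)
            if 0 < c.sum() <= 40:
                tables.append(tuple(int(x) for x in c))
        ps = rt.fisher_p_many(*[np.array([t[i] for t in tables]) for i in range(4)])
        for p, cells in zip(ps, tables):
            oracle = float(exact_fisher_two_sided(*cells))
            assert abs(p - oracle) < 1e-12
            assert 0 < p <= 1

    def test_matches_scipy(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            c = rng.integers(0, 25, size=4)
            if c.sum() == 0:
                continue
            table = [[int(c[0]), int(c[1])], [int(c[2]), int(c[3])]]
            _, p_ref = fisher_exact(table, alternative="two-sided")
            assert rt.fisher_p(ContingencyTable(*map(int, c))) == pytest.approx(p_ref, rel=1e-9)


def _rank_matrix(values):
    X = rt.ExpressionMatrix(
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        values,
    )
    return rt.rank_transform(X)


class TestScreenGers:
    def test_perfect_planted_pair_retained_with_orientation(self):
        # 6 genes, 5 samples per subtype; gene g0 outranks g1 only in SHH.
        rng = np.random.default_rng(0)
        sub = rt.SubtypeSet()
        labels = {}
        cols = []
        for k, s in enumerate(sub):
            for j in range(5):
                labels[f"s{5 * k + j}"] = s
        base = rng.normal(size=(6, 20))
        base[0, :] = -10.0  # g0 lowest everywhere ...
        base[1, :] = 10.0   # ... g1 highest everywhere
        base[0, :5], base[1, :5] = 10.0, -10.0  # reversed in SHH samples
        R = _rank_matrix(base)
        thr = rt.ReversalThresholds.uniform(sub, 0.95)
        feats = rt.screen_gers(R, labels, "SHH", {"g0", "g1"}, thr, subtypes=sub)
        assert len(feats) == 1
        f = feats[0]
        assert (f.gene_hi, f.gene_lo) == ("g0", "g1")
        assert all(r == 1.0 for r in f.ratios.values())
        assert all(p < 0.05 for p in f.pvalues.values())

    def test_all_three_comparisons_required(self):
        # g0 > g1 in Group3 and also in WNT: fails the WNT comparison.
        rng = np.random.default_rng(1)
        sub = rt.SubtypeSet()
        labels = {f"s{5 * k + j}": s for k, s in enumerate(sub) for j in range(5)}
        base = rng.normal(size=(5, 20))
        base[0, :], base[1, :] = -10.0, 10.0
        g3 = [i for i, sid in enumerate(sorted(labels, key=lambda x: int(x[1:])))
              if labels[f"s{i}"] == "Group3"]
        wnt = [i for i in range(20) if labels[f"s{i}"] == "WNT"]
        for i in list(g3) + list(wnt):
            base[0, i], base[1, i] = 10.0, -10.0
        R = _rank_matrix(base)
        thr = rt.ReversalThresholds.default()
        feats = rt.screen_gers(R, labels, "Group3", {"g0", "g1"}, thr, subtypes=sub)
        assert feats == []

    def test_empty_signature_warns_and_returns_empty(self, caplog):
        rng = np.random.default_rng(2)
        sub = rt.SubtypeSet()
        labels = {f"s{5 * k + j}": s for k, s in enumerate(sub) for j in range(5)}
        R = _rank_matrix(rng.normal(size=(4, 20)))
        with caplog.at_level("WARNING", logger="ranktype"):
            out = rt.screen_gers(R, labels, "SHH", set(), rt.ReversalThresholds.default(),
                                 subtypes=sub)
        assert out == [] and "no pairs" in caplog.text

    def test_brute_force_recomputation_oracle(self, small_cohort):
        """Every retained feature's stats re-derive from raw counts; every
        discarded pair genuinely fails at least one comparison."""
        spec, X, truth = small_cohort
        R = rt.rank_transform(X)
        sub = rt.SubtypeSet()
        s = "Group3"
        results = [rt.diff_rank_genes(R, truth.labels, s, o) for o in sub.others(s)]
        sig = rt.subtype_signature_genes(results, s)
        thr = rt.ReversalThresholds.default()
        feats = rt.screen_gers(R, truth.labels, s, sig, thr, subtypes=sub)
        assert feats, "expected some screened pairs under planted structure"
        gene_row = {g: i for i, g in enumerate(R.gene_ids)}
        col_of = {t: [j for j, sid in enumerate(R.sample_ids) if truth.labels[sid] == t]
                  for t in sub}
        retained = set()
        for f in feats:
            retained.add(frozenset((f.gene_hi, f.gene_lo)))
            for o in sub.others(s):
                f11 = sum(1 for j in col_of[s]
                          if R.ranks[gene_row[f.gene_hi], j] > R.ranks[gene_row[f.gene_lo], j])
                f21 = sum(1 for j in col_of[o]
                          if R.ranks[gene_row[f.gene_hi], j] > R.ranks[gene_row[f.gene_lo], j])
                ct = ContingencyTable(f11, len(col_of[s]) - f11, f21, len(col_of[o]) - f21)
                ratio = rt.reversal_ratio(ct)
                assert ratio == pytest.approx(f.ratios[o])
                assert ratio >= thr.get(s, o)
                p = rt.fisher_p(ct)
                assert p == pytest.approx(f.pvalues[o], rel=1e-9)
                assert p < 0.05
        # spot-check discarded pairs against the brute-force rule
        rng = np.random.default_rng(3)
        pairs = rt.enumerate_pairs(sig)
        for a, b in [pairs[i] for i in rng.choice(len(pairs), size=40, replace=False)]:
            if frozenset((a, b)) in retained:
                continue
            for hi, lo in ((a, b), (b, a)):
                ok = True
                for o in sub.others(s):
                    f11 = sum(1 for j in col_of[s]
                              if R.ranks[gene_row[hi], j] > R.ranks[gene_row[lo], j])
                    f21 = sum(1 for j in col_of[o]
                              if R.ranks[gene_row[hi], j] > R.ranks[gene_row[lo], j])
                    ct = ContingencyTable(f11, len(col_of[s]) - f11, f21, len(col_of[o]) - f21)
                    if rt.reversal_ratio(ct) < thr.get(s, o) or rt.fisher_p(ct) >= 0.05:
                        ok = False
                        break
                assert not ok, f"pair ({hi},{lo}) passes brute force but was discarded"

    def test_invariant_to_per_sample_monotone_distortion(self, small_cohort):
        spec, X, truth = small_cohort
        sub = rt.SubtypeSet()
        thr = rt.ReversalThresholds.default()
        s = "WNT"
        R = rt.rank_transform(X)
        results = [rt.diff_rank_genes(R, truth.labels, s, o) for o in sub.others(s)]
        sig = rt.subtype_signature_genes(results, s)
        feats1 = rt.screen_gers(R, truth.labels, s, sig, thr, subtypes=sub)
        rng = np.random.default_rng(9)
        warped = X.values.copy()
        for j in range(X.n_samples):
            warped[:, j] = np.exp(0.3 * warped[:, j] / warped[:, j].std()) * rng.uniform(1, 5)
        Xw = rt.ExpressionMatrix(X.gene_ids, X.sample_ids, warped)
        feats2 = rt.screen_gers(rt.rank_transform(Xw), truth.labels, s, sig, thr, subtypes=sub)
        key = lambda fs: sorted((f.gene_hi, f.gene_lo) for f in fs)
        assert key(feats1) == key(feats2)

    def test_raising_thresholds_shrinks_retained_set(self, small_cohort):
        spec, X, truth = small_cohort
        sub = rt.SubtypeSet()
        R = rt.rank_transform(X)
        s = "Group4"
        results = [rt.diff_rank_genes(R, truth.labels, s, o) for o in sub.others(s)]
        sig = rt.subtype_signature_genes(results, s)
        previous = None
        for v in (0.8, 0.85, 0.9, 0.95, 1.0):
            feats = rt.screen_gers(R, truth.labels, s, sig,
                                   rt.ReversalThresholds.uniform(sub, v), subtypes=sub)
            current = {(f.gene_hi, f.gene_lo) for f in feats}
            if previous is not None:
                assert current <= previous
            previous = current
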