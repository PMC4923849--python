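import numpy as np
import pytest

from stresswgbs import (
    DMRCallParams,
    MethylationTable,
    MethylomeSimConfig,
    SmoothParams,
    ValidationError,
    call_dmrs,
    compute_tstat,
    estimate_fdr,
    simulate_methylome,
    smooth_all,
    smooth_sample,
)
from stresswgbs.dmr import TStatTrack, _balanced_relabelings
from stresswgbs.core import GenomeLayout


def _table(pos, meth, total, groups=("low", "low", "high", "high")):
    meth = np.asarray(meth)
    n, s = meth.shape
    return MethylationTable(
        chrom=np.array(["chr1"] * n, dtype=object),
        pos=np.array(pos),
        meth=meth,
        total=np.asarray(total),
        sample_ids=[f"s{i}" for i in range(s)],
        group_labels=list(groups),
    )


class TestSmoothing:
    def test_saturated_counts_smooth_to_one(self):
        t = _table([100, 200, 300, 400], np.full((4, 4), 9), np.full((4, 4), 9))
        prof = smooth_sample(t, "s0", SmoothParams(min_window_bp=200, min_window_cpgs=3))
        np.testing.assert_allclose(prof.values, 1.0, atol=1e-12)

    def test_constant_half_smooths_to_half(self):
        t = _table([100, 200, 300, 400], np.full((4, 4), 5), np.full((4, 4), 10))
        prof = smooth_sample(t, "s1", SmoothParams(min_window_bp=200, min_window_cpgs=3))
        np.testing.assert_allclose(prof.values, 0.5, atol=1e-12)

    def test_matches_independent_weighted_quadratic_fit(self):
        # 10 CpGs, linear trend, window forced to the whole chromosome by a
        # dominating min_window_bp -> constant half-width for every CpG
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(100, 2000), size=10, replace=False))
        total = rng.integers(5, 30, size=(10, 4))
        frac = 0.1 + 0.8 * (pos - pos[0]) / (pos[-1] - pos[0])
        meth = np.rint(frac[:, None] * total).astype(int)
        t = _table(pos, meth, total)
        half = 10_000.0
        prof = smooth_sample(t, "s2", SmoothParams(min_window_bp=int(2 * half),
                                                   min_window_cpgs=3))
        y = meth[:, 2] / total[:, 2]
        expected = []
        for i in range(10):
            x = (pos - pos[i]) / half
            w = total[:, 2] * (1 - np.abs(x) ** 3) ** 3
            coeffs = np.polyfit(x, y, 2, w=np.sqrt(w))
            expected.append(np.clip(np.polyval(coeffs, 0.0), 0, 1))
        np.testing.assert_allclose(prof.values, expected, atol=1e-10)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(1)
        pos = np.sort(rng.choice(np.arange(1, 5000), size=30, replace=False))
        total = rng.integers(3, 25, size=(30, 4))
        meth = rng.binomial(total, 0.4)
        params = SmoothParams(min_window_bp=600, min_window_cpgs=9)
        a = smooth_sample(_table(pos, meth, total), "s0", params).values
        b = smooth_sample(_table(pos + 10_000, meth, total), "s0", params).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_zero_coverage_chromosome_names_it(self):
        t = _table([100, 200, 300], np.zeros((3, 4), int), np.zeros((3, 4), int))
        with pytest.raises(ValidationError, match="chr1"):
            smooth_sample(t, "s0", SmoothParams(min_window_bp=100, min_window_cpgs=3))


class TestTStatistic:
    def test_identical_groups_give_zero(self):
        sm = np.tile(np.array([0.2, 0.5, 0.9])[:, None], (1, 4))
        t = _table([10, 20, 30], np.zeros((3, 4), int), np.ones((3, 4), int))
        track = compute_tstat(sm, t)
        np.testing.assert_array_equal(track.diff, 0.0)
        np.testing.assert_array_equal(track.t, 0.0)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(2)
        sm = rng.uniform(0, 1, size=(50, 6))
        t = _table([10 * i for i in range(1, 51)], np.zeros((50, 6), int),
                   np.ones((50, 6), int),
                   groups=["low", "low", "low", "high", "high", "high"])
        fwd = compute_tstat(sm, t)
        swapped = ["high" if g == "low" else "low" for g in t.group_labels]
        rev = compute_tstat(sm, t, group_labels=swapped)
        np.testing.assert_allclose(fwd.diff, -rev.diff, atol=1e-14)
        np.testing.assert_allclose(fwd.t, -rev.t, atol=1e-12)

    def test_matches_direct_pooled_formula(self):
        # single CpG, 5v5, hand-evaluable equal-variance two-sample denominator
        rng = np.random.default_rng(3)
        sm = rng.uniform(0.2, 0.8, size=(1, 10))
        t = _table([100], np.zeros((1, 10), int), np.ones((1, 10), int),
                   groups=["low"] * 5 + ["high"] * 5)
        track = compute_tstat(sm, t, floor_quantile=0.0)
        hi, lo = sm[0, 5:], sm[0, :5]
        d = hi.mean() - lo.mean()
        sp2 = (hi.var(ddof=1) + lo.var(ddof=1)) / 2
        se = np.sqrt(sp2 * (1 / 5 + 1 / 5))
        assert track.diff[0] == pytest.approx(d, abs=1e-12)
        assert track.t[0] == pytest.approx(d / se, rel=1e-12)

    def test_variance_floor_limits_small_denominators(self):
        rng = np.random.default_rng(4)
        sm = rng.uniform(0, 1, size=(200, 10))
        t = _table([10 * i for i in range(1, 201)], np.zeros((200, 10), int),
                   np.ones((200, 10), int), groups=["low"] * 5 + ["high"] * 5)
        track = compute_tstat(sm, t, floor_quantile=0.75)
        floor = np.quantile(track.se_raw, 0.75)
        assert np.all(track.se_floored >= floor - 1e-15)
        assert np.isfinite(track.t).all()

    def test_single_sample_group_rejected(self):
        sm = np.zeros((3, 3))
        t = _table([10, 20, 30], np.zeros((3, 3), int), np.ones((3, 3), int),
                   groups=["low", "high", "high"])
        with pytest.raises(ValidationError):
            compute_tstat(sm, t)


def _track(pos, tvals, diffs, chrom=None):
    n = len(pos)
    chrom = np.array(chrom if chrom is not None else ["chr1"] * n, dtype=object)
    tvals = np.asarray(tvals, float)
    diffs = np.asarray(diffs, float)
    return TStatTrack(chrom=chrom, pos=np.asarray(pos), mean_high=diffs,
                      mean_low=np.zeros(n), diff=diffs, se_raw=np.ones(n),
                      se_floored=np.ones(n), t=tvals)


def _oracle_scan(track, params):
    """Independent exhaustive run enumeration: test every (i, j) index pair
    for being a maximal valid run, then apply the size and difference
    filters."""
    n = len(track.pos)

    def member(i):
        return abs(track.t[i]) > params.t_cutoff

    def joined(i, j):
        return (track.chrom[i] == track.chrom[j]
                and track.pos[j] - track.pos[i] <= params.max_gap_bp
                and member(i) and member(j)
                and np.sign(track.t[i]) == np.sign(track.t[j]))

    out = []
    for i in range(n):
        for j in range(i, n):
            if not all(member(k) and np.sign(track.t[k]) == np.sign(track.t[i])
                       for k in range(i, j + 1)):
                continue
            if not all(joined(k, k + 1) for k in range(i, j)):
                continue
            left_ext = i > 0 and joined(i - 1, i)
            right_ext = j < n - 1 and joined(j, j + 1)
            if left_ext or right_ext:
                continue
            if j - i + 1 >= params.min_cpgs and \
                    abs(np.mean(track.diff[i:j + 1])) > params.min_diff:
                out.append((str(track.chrom[i]), int(track.pos[i] - 1),
                            int(track.pos[j]), j - i + 1))
    return out


class TestCallDMRs:
    def test_all_zero_statistics_give_empty_list(self):
        assert call_dmrs(_track([10, 20, 30], [0, 0, 0], [0, 0, 0])) == []

    def test_single_clean_run(self):
        pos = [100, 200, 300, 400, 500, 600, 700]
        t = [0, 6, 6, 6, 6, 6, 0]
        d = [0, .2, .2, .2, .2, .2, 0]
        (dmr,) = call_dmrs(_track(pos, t, d))
        assert (dmr.start, dmr.end) == (199, 600)
        assert dmr.n_cpgs == 5
        assert dmr.direction == "hyper"
        assert dmr.mean_diff == pytest.approx(0.2)
        assert dmr.area_stat == pytest.approx(30.0)

    def test_small_difference_run_rejected(self):
        # above-threshold statistic but mean difference of 5% fails the
        # >10% methylation-difference filter
        out = call_dmrs(_track([100, 200, 300], [6, 6, 6], [.05, .05, .05]))
        assert out == []

    def test_gap_breaks_run(self):
        pos = [100, 200, 600, 700, 800]
        out = call_dmrs(_track(pos, [6] * 5, [.2] * 5),
                        DMRCallParams(max_gap_bp=300))
        assert [(d.start, d.end, d.n_cpgs) for d in out] == [(599, 800, 3)]

    def test_sign_change_breaks_run(self):
        pos = [100, 200, 300, 400, 500, 600]
        out = call_dmrs(_track(pos, [6, 6, 6, -6, -6, -6],
                               [.2, .2, .2, -.2, -.2, -.2]))
        assert [(d.direction, d.n_cpgs) for d in out] == \
               [("hyper", 3), ("hypo", 3)]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 100
        pos = np.cumsum(rng.integers(50, 400, size=n))
        chrom = np.where(np.arange(n) < 60, "chr1", "chr2")
        tvals = rng.normal(0, 4, size=n)
        diffs = np.sign(tvals) * rng.uniform(0, 0.3, size=n)
        track = _track(pos, tvals, diffs, chrom=chrom)
        params = DMRCallParams()
        got = [(d.chrom, d.start, d.end, d.n_cpgs) for d in call_dmrs(track, params)]
        assert got == _oracle_scan(track, params)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(9)
        n = 200
        pos = np.cumsum(rng.integers(50, 250, size=n))
        tvals = rng.normal(0, 5, size=n)
        diffs = np.sign(tvals) * rng.uniform(0, 0.3, size=n)
        track = _track(pos, tvals, diffs)
        counts_t = [len(call_dmrs(track, DMRCallParams(t_cutoff=c)))
                    for c in (2.0, 3.0, 4.5, 6.0)]
        assert counts_t == sorted(counts_t, reverse=True)
        counts_d = [len(call_dmrs(track, DMRCallParams(t_cutoff=2.0, min_diff=m)))
                    for m in (0.05, 0.10, 0.20)]
        assert counts_d == sorted(counts_d, reverse=True)

    def test_label_swap_flips_direction_only(self, study_simulation):
        meth = study_simulation["meth"]
        sm = study_simulation["smoothed"]
        swapped = ["high" if g == "low" else "low" for g in meth.group_labels]
        fwd = study_simulation["dmrs"]
        rev = call_dmrs(compute_tstat(sm, meth, group_labels=swapped,
                                      floor_quantile=0.5))
        assert [(d.chrom, d.start, d.end) for d in fwd] == \
               [(d.chrom, d.start, d.end) for d in rev]
        flip = {"hyper": "hypo", "hypo": "hyper"}
        assert [flip[d.direction] for d in fwd] == [d.direction for d in rev]


class TestPermutationFDR:
    def test_balanced_relabeling_enumeration_5v5(self):
        labels = ["low"] * 5 + ["high"] * 5
        rng = np.random.default_rng(0)
        rel = _balanced_relabelings(labels, rng, n_perms=10_000)
        assert len(rel) == 125            # C(10,5)/2 - 1
        assert all(sum(1 for g in r if g == "high") == 5 for r in rel)
        assert labels not in rel
        mirror = ["high"] * 5 + ["low"] * 5
        assert mirror not in rel

    def test_observed_zero_gives_fdr_one(self):
        cfg = MethylomeSimConfig(genome=GenomeLayout(("chr1",), (20_000,)),
                                 dmr_effect=0.0, n_true_dmrs=0, seed=8)
        meth, _ = simulate_methylome(cfg)
        est = estimate_fdr(meth, SmoothParams(min_window_bp=600, min_window_cpgs=19),
                           n_perms=5, seed=0, floor_quantile=0.5)
        assert est.observed_count == 0
        assert est.fdr == 1.0

    def test_invalid_perm_count_rejected(self, study_simulation):
        with pytest.raises(ValidationError):
            estimate_fdr(study_simulation["meth"], n_perms=0)

    def test_deterministic_given_seed(self):
        cfg = MethylomeSimConfig(genome=GenomeLayout(("chr1",), (30_000,)),
                                 n_true_dmrs=5, seed=9)
        meth, _ = simulate_methylome(cfg)
        sp = SmoothParams(min_window_bp=600, min_window_cpgs=19)
        a = estimate_fdr(meth, sp, n_perms=10, seed=3, floor_quantile=0.5)
        b = estimate_fdr(meth, sp, n_perms=10, seed=3, floor_quantile=0.5)
        assert a.fdr == b.fdr and a.null_counts == b.null_counts
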