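"""Degradation-filter design and library curation."""

import numpy as np
import pytest

from cardioabs import beats, filters
from cardioabs.beats import AAMI, BeatVector
from cardioabs.filters import (
    AbsFilter,
    CurationConfig,
    FilterDesignConfig,
    build_library,
    convolution_matrix,
    dedup_similar,
    design_filter,
    exclude_subject,
    is_all_pass,
    select_distinct,
)


def bv(samples, mode="single", label=AAMI.V, subject="s", idx=0):
    return BeatVector(np.asarray(samples, dtype=float), mode, label, subject,
                      beat_index=idx)


def ridge_oracle(a, b, M, lam):
    """Explicit normal-equations ridge fit (independent of design_filter)."""
    A = np.zeros((len(a), M))
    c = M // 2
    for t in range(len(a)):
        for k in range(M):
            src = t - k + c
            if 0 <= src < len(a):
                A[t, k] = a[src]
    return np.linalg.solve(A.T @ A + lam * np.eye(M), A.T @ b)


class TestConvolutionMatrix:
    def test_m1_column_is_the_signal(self, rng):
        a = rng.normal(size=128)
        A = convolution_matrix(a, 1)
        assert np.array_equal(A[:, 0], a)

    def test_center_delta_reproduces_input(self, rng):
        a = rng.normal(size=128)
        for M in (3, 7, 16):
            h = np.zeros(M)
            h[M // 2] = 1.0
            assert np.allclose(convolution_matrix(a, M) @ h, a, atol=1e-14)

    def test_matches_direct_convolution_loop(self, rng):
        a = rng.normal(size=128)
        h = rng.normal(size=7)
        direct = np.zeros(128)
        for t in range(128):
            for k in range(7):
                src = t - k + 3
                if 0 <= src < 128:
                    direct[t] += h[k] * a[src]
        assert np.allclose(convolution_matrix(a, 7) @ h, direct, atol=1e-12)
        assert np.allclose(filters.apply_filter(a, h), direct, atol=1e-12)


class TestDesignFilter:
    def test_all_pass_limit(self, rng):
        a = bv(rng.normal(size=128), label=AAMI.N)
        b = bv(a.samples.copy())
        f = design_filter(a, b, FilterDesignConfig(M=1, lam=0.0))
        assert np.allclose(f.h, [1.0], atol=1e-10)
        assert f.fit_residual < 1e-10

    def test_pure_gain(self, rng):
        a = bv(rng.normal(size=128), label=AAMI.N)
        b = bv(2.0 * a.samples)
        f = design_filter(a, b, FilterDesignConfig(M=1, lam=0.0))
        assert np.allclose(f.h, [2.0], atol=1e-10)

    def test_matches_ridge_oracle(self, rng):
        a = bv(rng.normal(size=128), label=AAMI.N)
        b = bv(rng.normal(size=128))
        f = design_filter(a, b, FilterDesignConfig(M=16, lam=1e-3))
        h_oracle = ridge_oracle(a.samples, b.samples, 16, 1e-3)
        assert np.allclose(f.h, h_oracle, atol=1e-8)

    def test_unregularized_residual_not_larger_than_regularized(self, rng):
        a = bv(rng.normal(size=128), label=AAMI.N)
        b = bv(rng.normal(size=128))
        r0 = design_filter(a, b, FilterDesignConfig(M=24, lam=0.0)).fit_residual
        for lam in (1e-3, 1e-1, 1.0):
            r = design_filter(a, b, FilterDesignConfig(M=24, lam=lam)).fit_residual
            assert r0 <= r + 1e-12

    def test_residual_nonincreasing_in_nested_m(self, rng):
        for _ in range(20):
            a = bv(rng.normal(size=128), label=AAMI.N)
            b = bv(rng.normal(size=128))
            prev = np.inf
            for M in (1, 2, 4, 8, 16, 32, 64, 128):
                r = design_filter(a, b, FilterDesignConfig(M=M, lam=0.0)).fit_residual
                assert r <= prev + 1e-9
                prev = r

    def test_rejects_normal_target_and_mode_mismatch(self, rng):
        a = bv(rng.normal(size=128), label=AAMI.N)
        with pytest.raises(ValueError, match="abnormal"):
            design_filter(a, bv(a.samples, label=AAMI.N), FilterDesignConfig())
        with pytest.raises(ValueError, match="mode"):
            design_filter(a, bv(a.samples, mode="trio"),
                          FilterDesignConfig(mode="single"))


class TestAllPass:
    def test_identical_beat_is_all_pass(self, rng):
        a = bv(rng.normal(size=128), label=AAMI.N)
        assert is_all_pass(a, bv(a.samples.copy()), threshold=0.01)

    def test_antiphase_is_not(self, rng):
        a = bv(rng.normal(size=128), label=AAMI.N)
        assert not is_all_pass(a, bv(-a.samples), threshold=1.5)

    def test_timing_only_anomaly_single_vs_trio(self):
        # single representation: identical morphology -> all-pass;
        # trio representation: premature center -> clearly different
        bump = np.exp(-0.5 * ((np.arange(128) - 64) / 3.0) ** 2)
        anb_s = bv(bump, label=AAMI.N)
        s_single = bv(bump.copy(), label=AAMI.S)
        trio = np.zeros(128)
        for c in (21, 64, 107):
            trio += np.exp(-0.5 * ((np.arange(128) - c) / 3.0) ** 2)
        trio_prem = np.zeros(128)
        for c in (21, 50, 107):
            trio_prem += np.exp(-0.5 * ((np.arange(128) - c) / 3.0) ** 2)
        anb_t = bv(trio, mode="trio", label=AAMI.N)
        s_trio = bv(trio_prem, mode="trio", label=AAMI.S)
        assert is_all_pass(anb_s, s_single, threshold=0.15)
        assert not is_all_pass(anb_t, s_trio, threshold=0.15)

    def test_zero_norm_reference_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            is_all_pass(bv(np.zeros(128), label=AAMI.N), bv(np.ones(128)), 0.15)


def mkfilter(h, resid, subject="s", fid=None, cls=AAMI.V):
    return AbsFilter(h=np.asarray(h, dtype=float), source_subject=subject,
                     source_class=cls, mode="single", fit_residual=resid,
                     filter_id=fid or f"{subject}:{resid}")


class TestDedup:
    def test_identical_filters_collapse(self, rng):
        h = rng.normal(size=16)
        out = dedup_similar([mkfilter(h, 0.2, fid="a"), mkfilter(h, 0.1, fid="b")])
        assert len(out) == 1
        assert out[0].fit_residual == 0.1  # best-fitting survivor

    def test_uncorrelated_filters_survive(self, rng):
        fs = [mkfilter(rng.normal(size=64), 0.1 * i, fid=str(i))
              for i in range(6)]
        out = dedup_similar(fs, sim_threshold=0.95)
        assert len(out) == 6

    def test_noisy_clusters_match_bruteforce(self, rng):
        bases = [rng.normal(size=32) for _ in range(3)]
        fs = []
        for i in range(10):
            b = bases[i % 3]
            fs.append(mkfilter(b + 1e-4 * rng.normal(size=32),
                               resid=0.01 * i, fid=f"f{i}"))
        out = dedup_similar(fs, sim_threshold=0.95)
        # brute force: exhaustive pairwise clustering, keep min residual
        survivors = set()
        for cluster in range(3):
            members = [f for i, f in enumerate(fs) if i % 3 == cluster]
            best = min(members, key=lambda f: f.fit_residual)
            survivors.add(best.filter_id)
        assert {f.filter_id for f in out} == survivors

    def test_order_independence(self, rng):
        fs = [mkfilter(rng.normal(size=16), 0.01 * i, fid=f"f{i}")
              for i in range(8)]
        a = dedup_similar(fs)
        b = dedup_similar(list(reversed(fs)))
        assert [f.filter_id for f in a] == [f.filter_id for f in b]


class TestSelectDistinct:
    def test_constant_filter_selected_last(self):
        const = mkfilter(np.full(8, 3.0), 0.1, fid="const")
        lively = mkfilter(np.arange(8.0), 0.2, fid="lively")
        out = select_distinct([const, lively], k=1)
        assert out[0].filter_id == "lively"

    def test_k_at_least_n_returns_all_sorted(self, rng):
        fs = [mkfilter(rng.normal(size=8), 0.1, fid=str(i)) for i in range(4)]
        out = select_distinct(fs, k=10)
        vars_ = [f.coeff_variance for f in out]
        assert len(out) == 4 and vars_ == sorted(vars_, reverse=True)

    def test_order_matches_recomputed_variances(self, rng):
        fs = [mkfilter(rng.normal(size=12) * (i + 1), 0.1, fid=str(i))
              for i in range(5)]
        out = select_distinct(fs)
        expected = sorted(fs, key=lambda f: -float(np.var(f.h)))
        assert [f.filter_id for f in out] == [f.filter_id for f in expected]


class TestBuildLibrary:
    def test_cohort_without_abnormal_beats_gives_empty_library(self):
        from cardioabs import simulate
        recs = [simulate.gen_record(7, 60, {AAMI.N: 1.0})]
        lib = build_library(recs)
        assert len(lib) == 0

    def test_identical_v_beats_dedup_to_one_filter_per_mode(self):
        fs_hz = 360.0
        bump = np.exp(-0.5 * ((np.arange(-40, 41)) / 4.0) ** 2)
        wide = np.exp(-0.5 * ((np.arange(-40, 41)) / 14.0) ** 2)
        sig = np.zeros(360 * 40)
        rs, labels = [], []
        for i in range(30):
            r = 400 * (i + 1)
            lab = AAMI.V if i in (10, 15, 20) else AAMI.N
            sig[r - 40:r + 41] += wide if lab == AAMI.V else bump
            rs.append(r)
            labels.append(lab)
        rec = beats.EcgRecord(
            "one", sig, fs_hz,
            [beats.BeatAnnotation(r, l) for r, l in zip(rs, labels)],
        )
        lib = build_library([rec])
        singles = [f for f in lib.by_mode("single") if f.source_class == AAMI.V]
        assert len(singles) == 1

    def test_curation_counts_add_up(self, small_library):
        att = small_library.attrition
        assert att, "donor records must contribute"
        n_kept = len(small_library)
        removed = sum(c["dedup_removed"] for c in att.values())
        designed = sum(c["designed"] for c in att.values())
        assert designed - removed == n_kept

    def test_deterministic(self, train_records):
        a = build_library(train_records)
        b = build_library(train_records)
        assert len(a) == len(b)
        for fa, fb in zip(a.filters, b.filters):
            assert fa.filter_id == fb.filter_id
            assert np.array_equal(fa.h, fb.h)

    def test_closure_filter_reproduces_source_beat(self, train_records):
        """A library filter applied to its own ANB reproduces the source
        abnormal beat with RMSE equal to the stored fit residual."""
        rec = train_records[0]
        anb = beats.select_anb(rec, require_trio=True)
        lib = build_library([rec])
        checked = 0
        for f in lib.filters:
            sid, bidx, mode = f.filter_id.split(":")
            src = (beats.segment_single_beat(rec, int(bidx))
                   if mode == "single" else beats.segment_trio(rec, int(bidx)))
            a = anb.single if mode == "single" else anb.trio
            out = filters.apply_filter(a.samples, f.h)
            rmse = np.sqrt(np.mean((out - src.samples) ** 2))
            assert rmse == pytest.approx(f.fit_residual, abs=1e-10)
            checked += 1
        assert checked > 0


class TestExcludeSubject:
    def test_absent_subject_is_noop(self, small_library):
        out = exclude_subject(small_library, "nobody")
        assert len(out) == len(small_library)

    def test_sole_owner_leaves_empty_view(self, train_records):
        lib = build_library([train_records[0]])
        out = exclude_subject(lib, train_records[0].subject_id)
        assert len(out) == 0

    def test_matches_set_difference(self, small_library):
        sid = small_library.filters[0].source_subject
        out = exclude_subject(small_library, sid)
        expected = {f.filter_id for f in small_library.filters
                    if f.source_subject != sid}
        assert {f.filter_id for f in out.filters} == expected
        # original untouched
        assert any(f.source_subject == sid for f in small_library.filters)


class TestSerialization:
    def test_round_trip_is_bit_exact(self, small_library, tmp_path):
        filters.save_library(small_library, tmp_path / "lib")
        back = filters.load_library(tmp_path / "lib")
        assert len(back) == len(small_library)
        for fa, fb in zip(small_library.filters, back.filters):
            assert fa.filter_id == fb.filter_id
            assert np.array_equal(fa.h, fb.h)
            assert fa.fit_residual == fb.fit_residual
            assert fa.source_class == fb.source_class
        assert back.provenance == small_library.provenance
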