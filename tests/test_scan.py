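import numpy as np
import pandas as pd
import pytest
import scipy.linalg as sla

from gxeqtl import (DosageMatrix, FounderProbMatrix, SignificanceThresholds,
                    classify_significance, compute_kinship, effective_tests,
                    effective_tests_threshold, fit_gxemm,
                    permutation_statistics, scan_additive, scan_interaction,
                    sequential_permutation_p)
from gxeqtl.gxemm import VarianceComponents, build_covariance
from gxeqtl.scan import _GLSWorkspace, variant_columns


@pytest.fixture(scope="module")
def scan_data(request):
    from gxeqtl import SimulationConfig, assign_environments, simulate_mosaics

    cfg = SimulationConfig(n_mice=120, n_markers=30, n_chromosomes=2, seed=31)
    fp, dm, counts = simulate_mosaics(cfg)
    K_loco = {c: compute_kinship(fp, exclude_chrom=c)
              for c in ("chr1", "chr2")}
    Z = assign_environments(cfg, np.random.default_rng(32))
    return fp, dm, counts, K_loco, Z


def dense_llr(Y, X_null, X_alt, Lam):
    """From-scratch profile-likelihood maxima via explicit inverses."""
    Li = np.linalg.inv(Lam)
    sign, logdet = np.linalg.slogdet(Lam)
    out = []
    for W in (X_null, X_alt):
        alpha = np.linalg.solve(W.T @ Li @ W, W.T @ Li @ Y)
        r = Y - W @ alpha
        out.append(-0.5 * (len(Y) * np.log(2 * np.pi) + logdet + r @ Li @ r))
    return out[1] - out[0]


class TestScans:
    def test_additive_matches_dense_oracle(self, scan_data):
        fp, _, _, K_loco, Z = scan_data
        rng = np.random.default_rng(33)
        N = fp.n_mice
        sub = slice(0, 30)
        fp30 = FounderProbMatrix(fp.probs[sub], fp.marker_map, fp.mouse_ids[:30])
        Z30 = Z[sub]
        Y = rng.standard_normal(30)
        X = np.ones((30, 1))
        vc = VarianceComponents(np.zeros(1), 0.3, [0.2, 0.2], [1.0, 1.0])
        K30 = {c: compute_kinship(fp30, exclude_chrom=c) for c in ("chr1", "chr2")}
        res = scan_additive(Y, fp30, X, Z30, K_loco=K30,
                            vc_by_chrom={"chr1": vc, "chr2": vc})
        for r, v in zip(res[:5], range(5)):
            Kc = K30[r.chrom]
            Lam = build_covariance(vc, Kc, Z30)
            cols = variant_columns(fp30, v)
            ref = dense_llr(Y, X, np.hstack([X, cols]), Lam)
            assert r.llr == pytest.approx(max(ref, 0.0), abs=1e-6)
            assert r.lod == pytest.approx(r.llr / np.log(10))

    def test_interaction_matches_dense_oracle(self, scan_data):
        fp, _, _, K_loco, Z = scan_data
        rng = np.random.default_rng(34)
        sub = slice(0, 30)
        fp30 = FounderProbMatrix(fp.probs[sub], fp.marker_map, fp.mouse_ids[:30])
        Z30 = Z[sub]
        Y = rng.standard_normal(30)
        X = np.column_stack([np.ones(30), Z30[:, 1:]])
        vc = VarianceComponents(np.zeros(2), 0.3, [0.2, 0.2], [1.0, 1.0])
        K30 = {c: compute_kinship(fp30, exclude_chrom=c) for c in ("chr1", "chr2")}
        res = scan_interaction(Y, fp30, X, Z30, Z_diet=Z30, K_loco=K30,
                               vc_by_chrom={"chr1": vc, "chr2": vc})
        from gxeqtl.scan import interaction_columns
        for r, v in zip(res[:5], range(5)):
            Lam = build_covariance(vc, K30[r.chrom], Z30)
            cols = variant_columns(fp30, v)
            inter = interaction_columns(cols, Z30)
            ref = dense_llr(Y, np.hstack([X, cols]),
                            np.hstack([X, cols, inter]), Lam)
            assert r.llr == pytest.approx(max(ref, 0.0), abs=1e-6)

    def test_injected_qtl_peaks_near_causal_marker(self, scan_data):
        fp, dm, counts, K_loco, Z = scan_data
        rng = np.random.default_rng(35)
        causal = 10  # marker index on chr1
        dosage = dm.dosages[:, causal]
        X = np.ones((fp.n_mice, 1))
        hits = 0
        for rep in range(10):
            noise = rng.standard_normal(fp.n_mice)
            Y = 1.0 * dosage / max(dosage.std(), 1e-9) * noise.std() + noise
            res = scan_additive(Y, fp, X, Z, K_loco=K_loco, seed=rep)
            top = max((r for r in res if r.chrom == "chr1"),
                      key=lambda r: r.llr)
            idx = int(top.variant_id.replace("c1m", "")) - 1
            if abs(idx - causal) <= 3:
                hits += 1
        assert hits >= 8

    def test_opposite_sign_diet_effects_drive_interaction_not_additive(
            self, scan_data):
        fp, dm, _, K_loco, Z = scan_data
        rng = np.random.default_rng(36)
        causal = 5
        dosage = dm.dosages[:, causal] - dm.dosages[:, causal].mean()
        # +effect in env 1, -effect in env 2: zero marginal effect
        Y = dosage * (Z[:, 0] - Z[:, 1]) + 0.5 * rng.standard_normal(fp.n_mice)
        X = np.ones((fp.n_mice, 1))
        add = scan_additive(Y, fp, X, Z, K_loco=K_loco)
        inter = scan_interaction(Y, fp, X, Z, Z_diet=Z, K_loco=K_loco)
        a = next(r for r in add if r.variant_id == "c1m6")
        i = next(r for r in inter if r.variant_id == "c1m6")
        assert i.llr > 10 * max(a.llr, 1.0)

    def test_monomorphic_variant_flagged(self):
        probs = np.zeros((20, 2, 8))
        probs[:, :, 2] = 1.0  # every mouse pure 129 at both markers
        probs[:, 1, 2] = 0.0
        probs[:10, 1, 0] = 1.0
        probs[10:, 1, 1] = 1.0
        mm = pd.DataFrame({"marker_id": ["a", "b"], "chrom": ["chr1"] * 2,
                           "pos_bp": [100, 200]})
        fp = FounderProbMatrix(probs, mm)
        K = {"chr1": compute_kinship(fp)}  # no other chrom; reuse full
        Y = np.random.default_rng(0).standard_normal(20)
        vc = VarianceComponents(np.zeros(1), 0.1, [0.0], [1.0])
        res = scan_additive(Y, fp, np.ones((20, 1)), np.ones((20, 1)),
                            K_loco=K, vc_by_chrom={"chr1": vc})
        assert res[0].monomorphic and res[0].llr == 0.0
        assert not res[1].monomorphic


class TestSequentialPermutation:
    def test_fixed_m_arithmetic(self):
        stats = iter([0.5] * 99)
        p, C, M = sequential_permutation_p(1.0, stats, fixed_m=99)
        assert (p, C, M) == (0.01, 0, 99)

    def test_tie_counts_as_exceedance(self):
        p, C, M = sequential_permutation_p(1.0, iter([1.0] * 9 + [0.0]),
                                           fixed_m=10)
        assert C == 9

    def test_sequential_interval(self):
        # exactly 10 exceedances reached at M = 200
        stats = iter(([2.0] * 9 + [0.5] * 190 + [2.0]) + [0.0] * 10)
        p, C, M = sequential_permutation_p(1.0, stats, c_stop=10,
                                           m_max=10 ** 6, seed=0,
                                           method="interval")
        assert (C, M) == (10, 200)
        assert 10 / 200 <= p <= 11 / 201

    def test_deterministic_given_seed_and_monotone(self):
        rng_stats = np.random.default_rng(1).random(5000)
        ps = []
        for phi in (0.5, 0.9, 0.99):
            p1, *_ = sequential_permutation_p(phi, iter(rng_stats), seed=7,
                                              m_max=5000)
            p2, *_ = sequential_permutation_p(phi, iter(rng_stats), seed=7,
                                              m_max=5000)
            assert p1 == p2
            ps.append(p1)
        assert ps[0] > ps[1] > ps[2]

    def test_bad_m_max_rejected(self):
        with pytest.raises(ValueError):
            sequential_permutation_p(1.0, iter([]), m_max=0)

    def test_stream_statistics_match_direct_evaluation(self, scan_data):
        fp, _, _, K_loco, Z = scan_data
        rng = np.random.default_rng(38)
        Y = rng.standard_normal(fp.n_mice)
        X = np.ones((fp.n_mice, 1))
        vc = VarianceComponents(np.zeros(1), 0.2, [0.1, 0.1], [1.0, 1.0])
        Lam = build_covariance(vc, K_loco["chr1"], Z)
        ws = _GLSWorkspace(Lam)
        cols = variant_columns(fp, 0)
        X_alt = np.hstack([X, cols])
        gen = permutation_statistics(Y, X, X_alt, ws, np.random.default_rng(9),
                                     batch=4)
        stats = [next(gen) for _ in range(4)]
        # same permutations recomputed densely
        rng2 = np.random.default_rng(9)
        for s in stats:
            Yp = Y[rng2.permutation(len(Y))]
            ref = dense_llr(Yp, X, X_alt, Lam)
            assert s == pytest.approx(max(ref, 0.0), abs=1e-8)


class TestEffectiveTests:
    def _dosage(self, M):
        # affine-map columns into [0, 2]; correlation is unaffected
        lo, hi = M.min(), M.max()
        D = (M - lo) / (hi - lo) * 2
        mm = pd.DataFrame({"marker_id": [f"m{i}" for i in range(M.shape[1])],
                           "chrom": ["chr1"] * M.shape[1],
                           "pos_bp": range(M.shape[1])})
        return DosageMatrix(D, mm)

    def test_uncorrelated_markers(self):
        V = 40
        M = sla.helmert(V + 1).T  # columns exactly uncorrelated, zero mean
        meff = effective_tests(self._dosage(M), 0.995)
        assert meff == int(np.ceil(0.995 * V))

    def test_perfectly_correlated_markers(self):
        col = np.linspace(0, 2, 30)[:, None]
        D = np.repeat(col, 12, axis=1)
        assert effective_tests(self._dosage(D), 0.90) == 1
        assert effective_tests(self._dosage(D), 0.995) == 1

    def test_ten_ld_blocks_of_twenty(self):
        base = sla.helmert(11).T  # 10 exactly uncorrelated block prototypes
        M = np.repeat(base, 20, axis=1)
        # 10 equal eigenvalues of 20: nine of them reach 90% of the total
        assert effective_tests(self._dosage(M), 0.90) == 9

    def test_threshold_ordering(self, scan_data):
        fp = scan_data[0]
        th = effective_tests_threshold(fp, alpha=0.05)
        assert th.meff_995 >= th.meff_90
        assert th.stringent <= th.significant <= th.suggestive


class TestClassification:
    TH = SignificanceThresholds(alpha=0.05, meff_90=500, meff_995=4545,
                                suggestive=1e-3, significant=1e-4,
                                stringent=1.1e-5)

    @pytest.mark.parametrize("p,test,label", [
        (1.0e-5, "additive", "***"),
        (1.0e-5, "interaction", "***"),
        (5e-5, "additive", "**"),
        (5e-4, "interaction", "*"),
        (5e-4, "additive", ""),      # suggestive tier is interaction-only
        (5e-3, "interaction", ""),
    ])
    def test_tiers(self, p, test, label):
        assert classify_significance(p, test, self.TH) == label
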