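"""Multivariate delay vectors, the three extension schemes, and the
analytic bivariate-WGN model of the proposed scheme."""

import numpy as np
import pytest
from scipy.special import erf

import mvsampen as mv
from _oracles import brute_count_pairs, brute_mv_dvs, brute_mv_sample_entropy


class TestDelayVectors:
    def test_bivariate_m11_is_sample_pair(self, rng):
        data = rng.standard_normal((50, 2))
        dvs = mv.build_delay_vectors(data, M=(1, 1), tau=(1, 1))
        np.testing.assert_array_equal(dvs.vectors, data[:-1])

    def test_univariate_degeneracy(self, rng):
        x = rng.standard_normal(40)
        dvs = mv.build_delay_vectors(x[:, None], M=(3,), tau=(2,))
        expected = np.array([[x[i], x[i + 2], x[i + 4]] for i in range(40 - 6)])
        np.testing.assert_array_equal(dvs.vectors, expected)

    def test_index_range_and_vector_length(self, rng):
        data = rng.standard_normal((10, 2))
        dvs = mv.build_delay_vectors(data, M=(2, 1), tau=(1, 1))
        assert dvs.vectors.shape == (8, 3)  # i = 1..N - max(m_k tau_k) = 8

    def test_matches_brute_transcription(self, rng):
        data = rng.standard_normal((30, 3))
        M, tau = (2, 1, 2), (1, 2, 1)
        np.testing.assert_array_equal(
            mv.build_delay_vectors(data, M, tau).vectors, brute_mv_dvs(data, M, tau)
        )


class TestExtensions:
    def test_naive_subspaces_bivariate(self, rng):
        data = rng.standard_normal((20, 2))
        e1 = mv.extend_naive(data, M=(1, 1), tau=(1, 1), channel=0)
        e2 = mv.extend_naive(data, M=(1, 1), tau=(1, 1), channel=1)
        n = 19
        np.testing.assert_array_equal(
            e1.vectors, np.column_stack([data[:n, 0], data[1 : n + 1, 0], data[:n, 1]])
        )
        np.testing.assert_array_equal(
            e2.vectors, np.column_stack([data[:n, 0], data[:n, 1], data[1 : n + 1, 1]])
        )
        assert set(e1.subspace) == {0} and set(e2.subspace) == {1}

    def test_proposed_extends_every_channel(self, rng):
        data = rng.standard_normal((20, 2))
        ext = mv.extend_proposed(data, M=(1, 1), tau=(1, 1))
        n = 19
        np.testing.assert_array_equal(
            ext.vectors,
            np.column_stack(
                [data[:n, 0], data[1 : n + 1, 0], data[:n, 1], data[1 : n + 1, 1]]
            ),
        )

    def test_extended_vector_length_is_sum_m_plus_p(self, rng):
        data = rng.standard_normal((40, 3))
        M, tau = (2, 1, 3), (1, 1, 1)
        ext = mv.extend_proposed(data, M, tau)
        assert ext.vectors.shape[1] == sum(M) + 3

    def test_p1_reduces_to_univariate_extension(self, rng):
        x = rng.standard_normal(30)
        naive = mv.extend_naive(x[:, None], M=(2,), tau=(1,), channel=0)
        prop = mv.extend_proposed(x[:, None], M=(2,), tau=(1,))
        np.testing.assert_array_equal(naive.vectors, prop.vectors)
        expected = np.array([[x[i], x[i + 1], x[i + 2]] for i in range(30 - 2)])
        np.testing.assert_array_equal(prop.vectors, expected)


class TestMatchFraction:
    def test_all_pairs_match_when_r_huge(self, rng):
        dvs = mv.build_delay_vectors(rng.standard_normal((30, 2)))
        assert mv.match_fraction(dvs, r=100.0) == 1.0

    def test_no_pairs_match_when_r_tiny(self, rng):
        dvs = mv.build_delay_vectors(rng.standard_normal((30, 2)))
        assert mv.match_fraction(dvs, r=1e-9) == 0.0

    def test_equals_brute_force_enumeration(self, rng):
        for _ in range(10):
            vecs = rng.standard_normal((rng.integers(5, 30), 3))
            n = len(vecs)
            got = mv.match_fraction(vecs, r=0.5)
            assert got * n * (n - 1) / 2 == pytest.approx(brute_count_pairs(vecs, 0.5))

    def test_fewer_than_two_vectors_rejected(self):
        with pytest.raises(ValueError):
            mv.match_fraction(np.ones((1, 2)), r=0.5)


class TestMvSampleEntropy:
    @pytest.mark.parametrize("scheme", mv.SCHEMES)
    def test_equals_brute_force_all_schemes(self, rng, scheme):
        # exact agreement with a double-loop transcription, N <= 100
        for _ in range(5):
            n = int(rng.integers(30, 100))
            data = rng.standard_normal((n, 2))
            got = mv.mv_sample_entropy(
                data, M=(1, 1), tau=(1, 1), r=0.4, scheme=scheme,
                standardize_channels=False,
            )
            expected = brute_mv_sample_entropy(data, (1, 1), (1, 1), 0.4, scheme)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_heterogeneous_embedding_against_oracle(self, rng):
        data = rng.standard_normal((60, 2))
        for scheme in mv.SCHEMES:
            got = mv.mv_sample_entropy(
                data, M=(2, 1), tau=(1, 2), r=0.6, scheme=scheme,
                standardize_channels=False,
            )
            expected = brute_mv_sample_entropy(data, (2, 1), (1, 2), 0.6, scheme)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_channel_permutation_symmetry(self, rng):
        # naive and proposed schemes only compare corresponding channels,
        # so relabelling channels cannot change the result
        data = rng.standard_normal((300, 2))
        for scheme in ("naive", "proposed"):
            a = mv.mv_sample_entropy(data, r=0.3, scheme=scheme)
            b = mv.mv_sample_entropy(data[:, ::-1], r=0.3, scheme=scheme)
            assert a == pytest.approx(b, rel=1e-10)

    def test_full_scheme_depends_on_channel_order(self, rng):
        # the full scheme's cross-subspace distances compare elements of
        # *different* channels, so it is not invariant to channel
        # relabelling — the alignment inconsistency the proposed extension
        # removes.  Both orderings still agree with the brute transcription.
        data = rng.standard_normal((120, 2))
        a = mv.mv_sample_entropy(data, r=0.3, scheme="full", standardize_channels=False)
        b = mv.mv_sample_entropy(data[:, ::-1], r=0.3, scheme="full", standardize_channels=False)
        assert a != b
        assert b == pytest.approx(
            brute_mv_sample_entropy(np.ascontiguousarray(data[:, ::-1]),
                                    (1, 1), (1, 1), 0.3, "full"),
            rel=1e-12,
        )

    def test_proposed_entropy_nonnegative(self, rng):
        # extended vectors are coordinate supersets: Phi_ext <= Phi_unext
        for _ in range(10):
            v = mv.mv_sample_entropy(rng.standard_normal((100, 2)), r=0.5, scheme="proposed")
            assert np.isnan(v) or v >= 0.0

    def test_naive_blind_to_correlation(self):
        # naive subspace matching cannot separate rho=0.95 from rho=0
        a = [mv.mv_sample_entropy(mv.gen_correlated_wgn(5000, 0.95, s).data, r=0.15, scheme="naive")
             for s in range(10)]
        b = [mv.mv_sample_entropy(mv.gen_correlated_wgn(5000, 0.0, 100 + s).data, r=0.15, scheme="naive")
             for s in range(10)]
        assert abs(np.mean(a) - np.mean(b)) < np.std(a, ddof=1) + np.std(b, ddof=1)

    def test_proposed_correlation_reduces_entropy(self):
        a = [mv.mv_sample_entropy(mv.gen_correlated_wgn(5000, 0.95, s).data, r=0.15, scheme="proposed")
             for s in range(10)]
        b = [mv.mv_sample_entropy(mv.gen_correlated_wgn(5000, 0.0, 100 + s).data, r=0.15, scheme="proposed")
             for s in range(10)]
        assert max(a) < min(b)

    def test_proposed_iid_limit(self):
        # uncorrelated bivariate WGN: mSE -> -2 ln erf(r/2)
        r = 0.15
        vals = [
            mv.mv_sample_entropy(mv.gen_correlated_wgn(10000, 0.0, s).data, r=r, scheme="proposed")
            for s in range(10)
        ]
        mc_se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - (-2.0 * np.log(erf(r / 2.0)))) < 3.0 * mc_se


class TestMvMultiscale:
    def test_scale_one_equals_direct_value(self, rng):
        data = rng.standard_normal((800, 2))
        prof = mv.mv_multiscale_entropy(data, r=0.2, scheme="full", max_scale=3)
        assert prof.entropy[0] == pytest.approx(
            mv.mv_sample_entropy(data, r=0.2, scheme="full")
        )

    def test_full_scheme_correlation_raises_profile(self):
        # the full scheme reads correlation as increased entropy at all scales
        prof_c = np.mean([
            mv.mv_multiscale_entropy(mv.gen_correlated_wgn(5000, 0.95, s).data,
                                     r=0.15, scheme="full", max_scale=5).entropy
            for s in range(10)
        ], axis=0)
        prof_u = np.mean([
            mv.mv_multiscale_entropy(mv.gen_correlated_wgn(5000, 0.0, 100 + s).data,
                                     r=0.15, scheme="full", max_scale=5).entropy
            for s in range(10)
        ], axis=0)
        assert np.all(prof_c > prof_u)


class TestAnalyticModel:
    def test_independence_endpoint(self):
        for r in (0.15, 0.4):
            assert mv.analytic_proposed_mse_wgn(0.0, r) == pytest.approx(
                -2.0 * np.log(erf(r / 2.0)), abs=1e-8
            )

    def test_perfect_correlation_is_half_independent(self):
        for r in (0.15, 0.4):
            v1 = mv.analytic_proposed_mse_wgn(1.0, r)
            assert v1 == pytest.approx(-np.log(erf(r / 2.0)), abs=1e-10)
            assert v1 == pytest.approx(mv.analytic_proposed_mse_wgn(0.0, r) / 2.0, abs=1e-8)

    def test_strictly_decreasing_in_rho(self):
        rhos = np.linspace(0.0, 1.0, 21)
        vals = [mv.analytic_proposed_mse_wgn(rho, 0.15) for rho in rhos]
        assert np.all(np.diff(vals) < 0)

    def test_simulation_agreement(self):
        # quadrature vs simulated proposed-scheme mSE on generated WGN
        for rho in (0.3, 0.95):
            sims = [
                mv.mv_sample_entropy(mv.gen_correlated_wgn(10000, rho, s).data,
                                     r=0.4, scheme="proposed")
                for s in range(10)
            ]
            mc_se = np.std(sims, ddof=1) / np.sqrt(len(sims))
            assert abs(np.mean(sims) - mv.analytic_proposed_mse_wgn(rho, 0.4)) < 3 * mc_se

    def test_rho_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mv.analytic_proposed_mse_wgn(1.5, 0.2)
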