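import numpy as np
import pytest

import gamnorm as gn
from gamnorm.balance import BalanceError

from conftest import random_symmetric


def contact(a: np.ndarray, mask=None) -> gn.ContactMatrix:
    return gn.ContactMatrix(gn.GenomeBinning.single(a.shape[0]), "chr1", a,
                            mask=mask)


# ---------------------------------------------------------------------------
# Knight-Ruiz balancing
# ---------------------------------------------------------------------------

class TestKrBalance:
    def test_all_ones_closed_form(self):
        n = 8
        res = gn.kr_balance(np.ones((n, n)))
        np.testing.assert_allclose(res.x, np.full(n, 1 / np.sqrt(n)), rtol=1e-6)
        np.testing.assert_allclose(res.matrix, np.full((n, n), 1 / n), rtol=1e-6)
        assert res.converged

    def test_doubly_stochastic_fixed_point(self):
        d = np.array([[0.5, 0.5], [0.5, 0.5]])
        res = gn.kr_balance(d)
        np.testing.assert_allclose(res.x, [1.0, 1.0], atol=1e-7)
        np.testing.assert_allclose(res.matrix, d, atol=1e-7)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_row_sums_unit_by_direct_multiplication(self, seed):
        a = random_symmetric(10, seed)
        res = gn.kr_balance(a)
        balanced = np.diag(res.x) @ a @ np.diag(res.x)
        np.testing.assert_allclose(balanced.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(balanced, res.matrix, rtol=1e-12)

    def test_zero_row_is_structural_error(self):
        a = random_symmetric(5, 0)
        a[2, :] = a[:, 2] = 0
        with pytest.raises(BalanceError, match="mask"):
            gn.kr_balance(a)

    def test_negative_and_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            gn.kr_balance(np.array([[1.0, -1.0], [-1.0, 1.0]]))
        with pytest.raises(ValueError, match="symmetric"):
            gn.kr_balance(np.array([[1.0, 2.0], [0.5, 1.0]]))

    def test_non_convergence_warns_not_raises(self):
        a = random_symmetric(10, 3)
        with pytest.warns(UserWarning, match="did not converge"):
            res = gn.kr_balance(a, max_outer=1, tolerance=1e-12)
        assert not res.converged
        assert res.iterations == 1


# ---------------------------------------------------------------------------
# KR2
# ---------------------------------------------------------------------------

class TestKr2:
    def test_nonnegative_input_equals_kr_of_square(self):
        a = random_symmetric(8, 5)
        res = gn.normalize_kr2(contact(a))
        ref = gn.kr_balance(a * a)
        np.testing.assert_allclose(res.matrix.data, ref.matrix, rtol=1e-12)

    def test_signs_restored_magnitudes_balanced(self, signed_matrix):
        res = gn.normalize_kr2(signed_matrix)
        out = res.matrix.data
        d = signed_matrix.data
        assert np.all(np.sign(out) == np.sign(d))
        ref = gn.kr_balance(d * d)
        np.testing.assert_allclose(np.abs(out), ref.matrix, rtol=1e-12)

    def test_absolute_row_sums_unit(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(10, 10))
        a = (a + a.T) / 2
        res = gn.normalize_kr2(contact(a))
        np.testing.assert_allclose(
            np.abs(res.matrix.data).sum(axis=1), 1.0, atol=1e-5)


# ---------------------------------------------------------------------------
# VC / SCN / ICE
# ---------------------------------------------------------------------------

class TestFactorMethods:
    def test_vc_hand_example(self):
        res = gn.normalize_vc(contact(np.array([[4.0, 2.0], [2.0, 1.0]])))
        np.testing.assert_allclose(res.x, [6.0, 3.0])
        assert res.matrix.data[0, 1] == pytest.approx(1 / 9)

    def test_vc_all_ones(self):
        n = 5
        res = gn.normalize_vc(contact(np.ones((n, n))))
        np.testing.assert_allclose(res.matrix.data, 1 / n ** 2)

    def test_scn_hand_example(self):
        res = gn.normalize_scn(contact(np.array([[4.0, 2.0], [2.0, 1.0]])))
        assert res.matrix.data[0, 1] == pytest.approx(2 / 10)

    def test_scn_all_ones(self):
        n = 5
        res = gn.normalize_scn(contact(np.ones((n, n))))
        np.testing.assert_allclose(res.matrix.data, 1 / n)

    def test_scn_iteration_count_matters(self):
        a = random_symmetric(6, 1)
        one = gn.normalize_scn(contact(a), iterations=1)
        ten = gn.normalize_scn(contact(a), iterations=10)
        assert not np.allclose(one.matrix.data, ten.matrix.data)

    def test_ice_fixed_point_when_rows_balanced(self):
        # symmetric with equal row sums -> e_i = 1 immediately
        a = np.array([[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]])
        assert len(set(np.abs(a).sum(1))) == 1
        res = gn.normalize_ice(contact(a))
        np.testing.assert_allclose(res.matrix.data, a)
        assert res.converged
        assert res.iterations == 1

    def test_ice_equalizes_row_sums(self):
        a = random_symmetric(20, 12)
        res = gn.normalize_ice(contact(a))
        assert res.converged
        sums = np.abs(res.matrix.data).sum(axis=1)
        assert np.abs(sums / sums.mean() - 1).max() < 2e-3

    def test_ice_zero_budget_is_identity(self):
        a = random_symmetric(4, 2)
        res = gn.normalize_ice(contact(a), max_iter=0)
        np.testing.assert_array_equal(res.matrix.data, a)
        assert not res.converged
        assert res.iterations == 0

    def test_zero_norm_row_masked_with_warning(self):
        a = random_symmetric(4, 8)
        a[1, :] = a[:, 1] = 0.0
        with pytest.warns(UserWarning, match="zero-norm"):
            res = gn.normalize_vc(contact(a))
        assert not res.matrix.mask[1]
        assert np.isnan(res.matrix.data[1]).all()


# ---------------------------------------------------------------------------
# NLD
# ---------------------------------------------------------------------------

def freqs_from(f, f_pair):
    return gn.SegregationFrequencies(
        gn.GenomeBinning.single(len(f)), "chr1",
        np.asarray(f, float), np.asarray(f_pair, float), 100)


class TestNld:
    def nld_value(self, fa, fb, fab):
        """Scalar oracle straight from the sign-dependent definition."""
        d = fab - fa * fb
        if d > 0:
            return d / min(fb * (1 - fa), fa * (1 - fb))
        if d < 0:
            return d / min(fa * fb, (1 - fa) * (1 - fb))
        return 0.0

    def run_pair(self, fa, fb, fab):
        f = np.array([fa, fb])
        fp = np.array([[fa, fab], [fab, fb]])
        fr = freqs_from(f, fp)
        raw = gn.raw_contact_matrix(fr)
        return gn.normalize_nld(raw, fr).matrix.data[0, 1]

    def test_maximal_positive_ld(self):
        assert self.run_pair(0.5, 0.5, 0.5) == pytest.approx(1.0)

    def test_maximal_negative_ld(self):
        assert self.run_pair(0.5, 0.5, 0.0) == pytest.approx(-1.0)

    def test_zero_ld_maps_to_zero(self):
        assert self.run_pair(0.4, 0.5, 0.2) == 0.0

    def test_grid_bounded_and_matches_scalar_oracle(self):
        grid = np.linspace(0.05, 0.95, 19)
        for fa in grid:
            for fb in grid:
                lo = max(0.0, fa + fb - 1.0)
                hi = min(fa, fb)
                for fab in np.linspace(lo, hi, 7):
                    got = self.run_pair(fa, fb, fab)
                    assert -1.0 - 1e-9 <= got <= 1.0 + 1e-9
                    assert got == pytest.approx(
                        self.nld_value(fa, fb, fab), abs=1e-9)

    def test_degenerate_frequency_bins_masked(self):
        f = np.array([1.0, 0.5, 0.5])
        fp = np.array([[1.0, 0.5, 0.5], [0.5, 0.5, 0.3], [0.5, 0.3, 0.5]])
        fr = freqs_from(f, fp)
        res = gn.normalize_nld(gn.raw_contact_matrix(fr), fr)
        assert not res.matrix.mask[0]
        assert np.isnan(res.matrix.data[0]).all()

    def test_bin_mismatch_rejected(self, signed_matrix):
        fr = freqs_from([0.5, 0.5], [[0.5, 0.2], [0.2, 0.5]])
        with pytest.raises(ValueError, match="match"):
            gn.normalize_nld(signed_matrix, fr)


# ---------------------------------------------------------------------------
# dispatch + shared properties
# ---------------------------------------------------------------------------

class TestDispatchAndProperties:
    def test_dispatch_matches_direct_call(self):
        a = np.array([[4.0, 2.0], [2.0, 1.0]])
        via = gn.normalize(contact(a), "vc")
        direct = gn.normalize_vc(contact(a))
        np.testing.assert_array_equal(via.matrix.data, direct.matrix.data)

    def test_kr2_dispatch_on_all_ones(self):
        n = 4
        res = gn.normalize(contact(np.ones((n, n))), "kr2")
        np.testing.assert_allclose(res.matrix.data, 1 / n, rtol=1e-6)

    def test_unknown_method_rejected(self, signed_matrix):
        with pytest.raises(ValueError, match="hicnorm"):
            gn.normalize(signed_matrix, "hicnorm")

    @pytest.mark.parametrize("method", ["vc", "scn", "ice", "kr2"])
    def test_sign_and_symmetry_preserved(self, signed_matrix, method):
        res = gn.normalize(signed_matrix, method)
        out = res.matrix.data
        d = signed_matrix.data
        assert np.all((np.sign(out) == np.sign(d)) | (out == 0))
        np.testing.assert_allclose(out, out.T, rtol=1e-9, atol=1e-12)

    @pytest.mark.parametrize("method", ["nld", "vc", "scn", "ice", "kr2"])
    def test_mask_propagates(self, method):
        rng = np.random.default_rng(4)
        det = (rng.random((12, 30)) < 0.4).astype(np.uint8)
        det[5] = 0  # never detected -> masked in raw
        cs = gn.CosegregationMatrix(
            gn.GenomeBinning.single(12), tuple(f"n{i}" for i in range(30)), det)
        fr = gn.segregation_frequencies(cs, "chr1")
        raw = gn.raw_contact_matrix(fr)
        assert not raw.mask[5]
        res = gn.normalize(raw, method, freqs=fr)
        assert not res.matrix.mask[5]
        assert np.isnan(res.matrix.data[5]).all()
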