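"""Exactness of the kernel decomposition against brute-force oracles.

The oracle re-derives every contribution from first principles: explicit
loops over support vectors and over every (core feature, substituent
feature) pair, computing each cross-term from the raw set cardinalities
and splitting it in half — fully independent of the package's
aggregated implementation.
"""

import numpy as np
import pytest
from rdkit import Chem

from mmpcliff.exceptions import ConfigurationError
from mmpcliff.fingerprints import XOR, abstract_fingerprint, build_universe, fingerprint_mmp
from mmpcliff.fixtures import fig5_fixture
from mmpcliff.interpretation import (
    decompose_mmp,
    fc_tanimoto,
    frag_fc_mmp,
    frag_fc_tanimoto,
    map_to_structure,
)
from mmpcliff.kernel_svm import MMPKernelSVC, TanimotoKernelSVC, mmp_kernel, tanimoto_kernel
from conftest import random_abstract_fp
from test_fingerprints import make_mmp


def fitted_stub(cls, svs, coefs, bias=0.0):
    """Hand-assembled trained model (bypasses the solver)."""
    model = cls(C_grid=(1.0,))
    model.support_fingerprints_ = list(svs)
    model.dual_coefs_ = np.asarray(coefs, dtype=float)
    model.bias_ = float(bias)
    model.n_support_ = len(svs)
    model.classes_ = np.array([0, 1])
    return model


def oracle_decompose(svs, coefs, bias, x):
    """Triple-loop enumeration of half-split cross-terms."""
    per_feature = {}
    for sv, coef in zip(svs, coefs):
        inter_c = sv.core_ids & x.core_ids
        inter_s = sv.sub_ids & x.sub_ids
        denom_c = len(sv.core_ids) + len(x.core_ids) - len(inter_c)
        denom_s = len(sv.sub_ids) + len(x.sub_ids) - len(inter_s)
        for d_c in sv.core_ids:
            for d_s in sv.sub_ids:
                if d_c not in x.core_ids or d_s not in x.sub_ids:
                    continue
                cross = coef / (denom_c * denom_s)
                key_c, key_s = ("core", d_c), ("sub", d_s)
                per_feature[key_c] = per_feature.get(key_c, 0.0) + cross / 2
                per_feature[key_s] = per_feature.get(key_s, 0.0) + cross / 2
    kernel_sum = sum(c * mmp_kernel(sv, x) for sv, c in zip(svs, coefs))
    return per_feature, kernel_sum


class TestFig5WorkedExample:
    """The paper-sized single-support-vector example, in closed form."""

    def test_kernel_factors(self):
        sv, ts = fig5_fixture()
        assert tanimoto_kernel(sv.core_ids, ts.core_ids) == pytest.approx(2 / 3)
        assert tanimoto_kernel(sv.sub_ids, ts.sub_ids) == pytest.approx(2 / 3)
        assert mmp_kernel(sv, ts) == pytest.approx(4 / 9)

    def test_single_cross_term_is_one_ninth(self):
        sv, ts = fig5_fixture()
        assert frag_fc_mmp(sv, 1.0, ts, 1, (XOR, 3)) == pytest.approx(1 / 9)

    def test_all_cross_terms_sum_to_kernel(self):
        sv, ts = fig5_fixture()
        total = sum(
            frag_fc_mmp(sv, 1.0, ts, d_c, d_s)
            for d_c in ts.core_ids
            for d_s in ts.sub_ids
        )
        assert total == pytest.approx(4 / 9, abs=1e-15)

    def test_half_split_contributions(self):
        sv, ts = fig5_fixture()
        model = fitted_stub(MMPKernelSVC, [sv], [1.0], bias=0.0)
        cv = decompose_mmp(model, ts)
        expected = {
            ("core", 1): 1 / 9,
            ("core", 3): 1 / 9,
            ("sub", (XOR, 2)): 1 / 9,
            ("sub", (XOR, 3)): 1 / 9,
        }
        assert set(cv.per_feature) == set(expected)
        for key, value in expected.items():
            assert cv.per_feature[key] == pytest.approx(value, abs=1e-15)
        assert cv.total() == pytest.approx(4 / 9, abs=1e-15)
        assert cv.decision == pytest.approx(4 / 9, abs=1e-15)


class TestFragFcTanimoto:
    def test_fig5_core_term(self):
        assert frag_fc_tanimoto({1, 2, 3}, 1.0, {1, 3}, 1) == pytest.approx(1 / 3)

    def test_unshared_feature_contributes_nothing(self):
        assert frag_fc_tanimoto({2, 3}, 1.0, {1, 3}, 1) == 0.0

    def test_terms_sum_to_scaled_kernel(self):
        sv, x = {1, 2, 3}, {1, 3}
        total = sum(frag_fc_tanimoto(sv, 1.0, x, d) for d in x)
        assert total == pytest.approx(tanimoto_kernel(sv, x))


class TestFcTanimoto:
    def test_identical_sv_splits_kernel_evenly(self):
        x = frozenset({1, 5, 9})
        model = fitted_stub(TanimotoKernelSVC, [x], [1.0], bias=0.0)
        cv = fc_tanimoto(model, x)
        assert all(v == pytest.approx(1 / 3) for v in cv.per_feature.values())
        assert cv.decision == pytest.approx(1.0)

    def test_disjoint_instance_decision_is_minus_bias(self):
        model = fitted_stub(TanimotoKernelSVC, [frozenset({1, 2})], [1.0], bias=0.4)
        cv = fc_tanimoto(model, frozenset({8, 9}))
        assert cv.per_feature == {}
        assert cv.decision == pytest.approx(-0.4)

    def test_matches_direct_kernel_sum_on_random_instances(self, rng):
        for _ in range(50):
            svs = [
                frozenset(rng.choice(8, size=rng.integers(1, 9), replace=False).tolist())
                for _ in range(5)
            ]
            coefs = rng.uniform(-2, 2, size=5)
            x = frozenset(rng.choice(8, size=rng.integers(1, 9), replace=False).tolist())
            model = fitted_stub(TanimotoKernelSVC, svs, coefs, bias=0.1)
            cv = fc_tanimoto(model, x)
            direct = sum(c * tanimoto_kernel(sv, x) for sv, c in zip(svs, coefs))
            assert cv.total() == pytest.approx(direct, abs=1e-12)
            assert cv.kernel_sum == pytest.approx(direct, abs=1e-12)

    def test_kernel_mismatch_rejected(self):
        sv, ts = fig5_fixture()
        mmp_model = fitted_stub(MMPKernelSVC, [sv], [1.0])
        with pytest.raises(ConfigurationError):
            fc_tanimoto(mmp_model, frozenset({1}))


class TestDecomposeMMP:
    def test_exactness_on_random_models(self, rng):
        """Sum of contributions minus bias equals the decision value (1e-9 rel)."""
        for _ in range(200):
            n_sv = int(rng.integers(1, 7))
            svs = [random_abstract_fp(rng) for _ in range(n_sv)]
            coefs = rng.uniform(-2, 2, size=n_sv)
            bias = float(rng.uniform(-1, 1))
            x = random_abstract_fp(rng)
            model = fitted_stub(MMPKernelSVC, svs, coefs, bias=bias)
            cv = decompose_mmp(model, x)
            oracle_pf, oracle_ks = oracle_decompose(svs, coefs, bias, x)
            assert set(cv.per_feature) == set(oracle_pf)
            for key in oracle_pf:
                assert cv.per_feature[key] == pytest.approx(oracle_pf[key], abs=1e-12)
            expected_decision = oracle_ks - bias
            scale = max(1.0, abs(expected_decision))
            assert abs((cv.total() - bias) - expected_decision) <= 1e-9 * scale
            assert cv.kernel_sum == pytest.approx(oracle_ks, abs=1e-12)

    def test_zero_overlap_gives_empty_vector(self):
        sv = abstract_fingerprint(core=[1], sub=[(XOR, 1)])
        x = abstract_fingerprint(core=[2], sub=[(XOR, 2)])
        model = fitted_stub(MMPKernelSVC, [sv], [1.5], bias=0.3)
        cv = decompose_mmp(model, x)
        assert cv.per_feature == {}
        assert cv.decision == pytest.approx(-0.3)

    def test_degenerate_core_reduces_to_tanimoto_on_substituents(self, rng):
        """With identical fully-overlapping cores the product kernel collapses
        to the substituent Tanimoto kernel: the decomposition total equals the
        plain Tanimoto contribution total, with the even split putting exactly
        half of each feature's mass on the substituent side (the other half
        lands on the shared core features)."""
        core = [1, 2, 3]
        svs_sub = [
            frozenset({(XOR, int(i)) for i in rng.choice(6, size=3, replace=False)})
            for _ in range(4)
        ]
        coefs = rng.uniform(-2, 2, size=4)
        x_sub = frozenset({(XOR, 0), (XOR, 1), (XOR, 2)})
        mmp_model = fitted_stub(
            MMPKernelSVC,
            [abstract_fingerprint(core=core, sub=s) for s in svs_sub],
            coefs,
        )
        tan_model = fitted_stub(TanimotoKernelSVC, svs_sub, coefs)
        x_fp = abstract_fingerprint(core=core, sub=x_sub)
        cv_mmp = decompose_mmp(mmp_model, x_fp)
        cv_tan = fc_tanimoto(tan_model, x_sub)
        assert cv_mmp.kernel_sum == pytest.approx(cv_tan.kernel_sum, abs=1e-12)
        assert cv_mmp.total() == pytest.approx(cv_tan.total(), abs=1e-12)
        for token, value in cv_tan.per_feature.items():
            assert cv_mmp.per_feature[("sub", token)] == pytest.approx(
                value / 2, abs=1e-12
            )

    def test_kernel_mismatch_rejected(self):
        model = fitted_stub(TanimotoKernelSVC, [frozenset({1})], [1.0])
        with pytest.raises(ConfigurationError):
            decompose_mmp(model, abstract_fingerprint(core=[1], sub=[(XOR, 1)]))


class TestMapToStructure:
    def _chem_setup(self):
        mmp = make_mmp(sub_low="CCO[*:1]", sub_high="CCN[*:1]")
        universe = build_universe([mmp])
        fp = fingerprint_mmp(mmp, universe)
        sv = fp  # self-support keeps everything shared
        model = fitted_stub(MMPKernelSVC, [sv], [1.0], bias=0.2)
        cv = decompose_mmp(model, fp)
        return mmp, fp, cv

    def test_conservation(self):
        """Atom+bond weights sum to the mapped feature contributions exactly."""
        _, fp, cv = self._chem_setup()
        weights = map_to_structure(cv, fp)
        assert weights.total() + weights.remainder == pytest.approx(
            cv.total(), rel=1e-9
        )
        assert weights.remainder == 0.0

    def test_even_division_over_environment(self):
        from mmpcliff.fingerprints import Environment, MMPFingerprint
        from mmpcliff.interpretation import ContributionVector

        env = Environment(atoms=(0, 1), bonds=(0,))
        fp = MMPFingerprint(
            core_ids=frozenset({7}),
            sub_ids=frozenset(),
            backmap={("core", 7): (("core", env),)},
        )
        cv = ContributionVector(per_feature={("core", 7): 0.6}, bias=0.0, kernel_sum=0.6)
        weights = map_to_structure(cv, fp)
        assert weights.atom_weights[("core", 0)] == pytest.approx(0.2)
        assert weights.atom_weights[("core", 1)] == pytest.approx(0.2)
        assert weights.bond_weights[("core", 0)] == pytest.approx(0.2)

    def test_overlapping_features_accumulate(self):
        from mmpcliff.fingerprints import Environment, MMPFingerprint
        from mmpcliff.interpretation import ContributionVector

        env = Environment(atoms=(0,), bonds=())
        fp = MMPFingerprint(
            core_ids=frozenset({1, 2}),
            sub_ids=frozenset(),
            backmap={
                ("core", 1): (("core", env),),
                ("core", 2): (("core", env),),
            },
        )
        cv = ContributionVector(
            per_feature={("core", 1): 0.3, ("core", 2): -0.1}, bias=0.0, kernel_sum=0.2
        )
        weights = map_to_structure(cv, fp)
        assert weights.atom_weights[("core", 0)] == pytest.approx(0.2)

    def test_unmapped_feature_goes_to_remainder(self):
        from mmpcliff.fingerprints import MMPFingerprint
        from mmpcliff.interpretation import ContributionVector

        fp = MMPFingerprint(core_ids=frozenset({1}), sub_ids=frozenset(), backmap={})
        cv = ContributionVector(per_feature={("core", 1): 0.5}, bias=0.0, kernel_sum=0.5)
        weights = map_to_structure(cv, fp)
        assert weights.remainder == pytest.approx(0.5)
        assert weights.total() == 0.0

    def test_and_feature_splits_between_substituents(self):
        mmp = make_mmp(sub_low="CCCO[*:1]", sub_high="CCCN[*:1]")
        universe = build_universe([mmp])
        fp = fingerprint_mmp(mmp, universe)
        model = fitted_stub(MMPKernelSVC, [fp], [1.0], bias=0.0)
        cv = decompose_mmp(model, fp)
        weights = map_to_structure(cv, fp)
        low_mass = sum(w for (r, _), w in weights.atom_weights.items() if r == "sub_low")
        high_mass = sum(w for (r, _), w in weights.atom_weights.items() if r == "sub_high")
        assert low_mass > 0 and high_mass > 0
        assert weights.total() == pytest.approx(cv.total(), rel=1e-9)
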