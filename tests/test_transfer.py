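"""Three-step transfer estimator and transferable-source detection.

The heavier checks run on reduced designs (smaller p) so that the whole
suite stays fast; the full-scale study conditions are exercised in
tests/test_acceptance.py.
"""

import numpy as np
import pytest

from transptlr import (
    Dataset,
    EMConfig,
    SimulationConfig,
    TransferConfig,
    cv_select_lambda,
    detect_transferable,
    estimate_offset,
    fit_source_models,
    gen_multidata,
    joint_estimate,
    naive_transfer,
    trans_fit,
    transfer_fit_known,
)
from transptlr.transfer import SourceOffset


def _small_cfg(**kw):
    base = dict(n0=80, n_s=60, S=3, p=40, k=5, H_size=8, beta_val=0.6)
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture()
def small_transfer(fast_em):
    cfg = _small_cfg(error_family="t", seed=2, n_transferable=3)
    target, sources, truth = gen_multidata(cfg)
    tc = TransferConfig(em=fast_em, seed=2, family="t")
    return target, sources, truth, tc


class TestSourceModels:
    def test_empty_list(self, small_transfer):
        *_, tc = small_transfer
        assert fit_source_models([], tc) == []

    def test_target_as_its_own_source(self, small_transfer):
        target, _, _, tc = small_transfer
        fits = fit_source_models([target], tc)
        _, own, _ = cv_select_lambda(target, tc.em, family="t")
        np.testing.assert_allclose(fits[0].beta, own.beta, atol=1e-8)

    def test_source_fit_near_truth(self, small_transfer):
        target, sources, truth, tc = small_transfer
        fits = fit_source_models(sources[:1], tc)
        err = np.sum(np.abs(fits[0].beta - truth.betas[0]))
        # L1 error bounded by noise; the true offset mass is small here
        assert err < 3.0


class TestEstimateOffset:
    def test_zero_beta_reduces_to_target_fit(self, small_transfer):
        target, _, _, tc = small_transfer
        off = estimate_offset(target, np.zeros(target.p), tc)
        _, own, _ = cv_select_lambda(target, tc.em, family="t")
        np.testing.assert_allclose(off.delta_hat, own.beta, atol=1e-8)

    def test_true_beta_gives_sparse_offset(self, small_transfer):
        target, _, truth, tc = small_transfer
        off = estimate_offset(target, truth.beta0, tc)
        # the contrast between the target and its own truth is pure noise
        assert np.sum(np.abs(off.delta_hat)) < 0.5

    def test_dimension_mismatch(self, small_transfer):
        target, _, _, tc = small_transfer
        with pytest.raises(ValueError):
            estimate_offset(target, np.zeros(target.p + 2), tc)


class TestJointEstimate:
    def test_no_sources_equals_target_fit(self, small_transfer):
        target, _, _, tc = small_transfer
        fit = joint_estimate(target, [], [], tc)
        _, own, _ = cv_select_lambda(target, tc.em, family="t")
        np.testing.assert_allclose(fit.beta, own.beta, atol=1e-8)

    def test_misaligned_offsets_raise(self, small_transfer):
        target, sources, _, tc = small_transfer
        with pytest.raises(ValueError):
            joint_estimate(target, sources[:2], [], tc)

    def test_duplicated_target_source_with_zero_offset(self, small_transfer):
        """A source that is an exact copy of the target with delta = 0 is,
        by likelihood additivity, the same optimization as fitting the
        row-doubled target at the same lambda."""
        from transptlr.transfer import _run_stacked_em, _init_state, _stack

        target, _, truth, tc = small_transfer
        copy = Dataset(target.X.copy(), target.y.copy(), role="source:1")
        zero = SourceOffset(1, np.zeros(target.p), 0.0)
        lam = 6.0
        X, z, group = _stack(target, [copy], [zero])
        state = _init_state(X, z, group, lam, tc.em, "t")
        (beta_j, s2_j, nu_j), *_ = _run_stacked_em(
            X, z, group, lam, tc.em, "t", state, 1e-8, 500, polish=True)
        from transptlr import fit_ptlr

        doubled = Dataset(np.vstack([target.X, target.X]),
                          np.concatenate([target.y, target.y]))
        ref = fit_ptlr(doubled, lam, tc.em)
        np.testing.assert_allclose(beta_j, ref.beta, atol=1e-4)
        # the two groups carry identical data, hence identical scales
        assert s2_j[0] == pytest.approx(s2_j[1], rel=1e-6)


class TestTransferFitKnown:
    def test_empty_T_reduces_to_target_only(self, small_transfer):
        target, sources, _, tc = small_transfer
        res = transfer_fit_known(target, sources, [], tc)
        np.testing.assert_array_equal(res.beta_TL, res.target_only_fit.beta)
        assert res.detected_set == []

    def test_invalid_index(self, small_transfer):
        target, sources, _, tc = small_transfer
        with pytest.raises(ValueError):
            transfer_fit_known(target, sources, [7], tc)

    def test_positive_transfer_from_same_distribution_source(self, fast_em):
        """A source drawn from the target's own distribution lowers the mean
        estimation error across seeded replications."""
        err_solo, err_tl = [], []
        for seed in range(6):
            cfg = _small_cfg(error_family="t", seed=seed, n_transferable=3,
                             h=0)  # h=0: sources share the target coefficients
            target, sources, truth = gen_multidata(cfg)
            tc = TransferConfig(em=fast_em, seed=seed, family="t")
            res = transfer_fit_known(target, sources, [1], tc)
            err_solo.append(np.sum((res.target_only_fit.beta - truth.beta0) ** 2))
            err_tl.append(np.sum((res.beta_TL - truth.beta0) ** 2))
        assert np.mean(err_tl) <= np.mean(err_solo)


class TestDetection:
    def test_threshold_rule_application(self):
        # the detection rule: s kept iff T_hat_s <= t * max(|L0|, 0.01)
        t, L0 = 0.1, -100.0
        bound = t * max(abs(L0), 0.01)
        assert -5.0 <= bound      # improvement always kept
        assert not (12.0 <= bound)  # 12 > 10 excluded
        assert 9.9 <= bound       # small degradation tolerated

    def test_target_too_small(self, fast_em):
        d = Dataset(np.random.default_rng(0).standard_normal((3, 4)),
                    np.random.default_rng(1).standard_normal(3))
        with pytest.raises(ValueError):
            detect_transferable(d, [], TransferConfig(em=fast_em))

    def test_noise_source_scores_worst_and_fails_strict_threshold(self, fast_em):
        cfg = _small_cfg(error_family="N", seed=4, n_transferable=3)
        target, sources, truth = gen_multidata(cfg)
        rng = np.random.default_rng(99)
        noise = Dataset(sources[0].X, 3.0 * rng.standard_normal(sources[0].n),
                        role="source:junk")
        tc = TransferConfig(em=fast_em, seed=4, family="t", threshold_t=0.0)
        detected, stats, _ = detect_transferable(target, sources + [noise], tc)
        # under the strict threshold the junk source is excluded: it cannot
        # improve validation prediction
        assert 4 not in detected
        # and it scores worse than every genuine same-design source
        assert stats.loc[stats.source == 4, "T_hat"].iloc[0] > \
            stats.loc[stats.source != 4, "T_hat"].max()

    def test_monotone_in_threshold(self, small_transfer):
        target, sources, _, tc = small_transfer
        from dataclasses import replace

        sets = []
        fits = None
        for t in [0.0, 0.1, 0.3]:
            tc_t = replace(tc, threshold_t=t)
            detected, _, fits = detect_transferable(target, sources, tc_t,
                                                    source_fits=fits)
            sets.append(set(detected))
        assert sets[0] <= sets[1] <= sets[2]

    def test_split_is_seeded_and_balanced(self, small_transfer):
        target, sources, _, tc = small_transfer
        d1, s1, _ = detect_transferable(target, sources, tc)
        d2, s2, _ = detect_transferable(target, sources, tc)
        assert d1 == d2
        np.testing.assert_allclose(s1.T_hat.to_numpy(), s2.T_hat.to_numpy())


class TestTransFit:
    def test_records_detection_stats(self, small_transfer):
        target, sources, truth, tc = small_transfer
        res = trans_fit(target, sources, tc)
        assert res.stats is not None and len(res.stats) == len(sources)
        assert set(res.detected_set) <= set(range(1, len(sources) + 1))
        assert np.all(np.isfinite(res.beta_TL))

    def test_gaussian_family_runs_identically_shaped(self, small_transfer):
        target, sources, truth, tc = small_transfer
        from dataclasses import replace

        res = trans_fit(target, sources, replace(tc, family="gaussian"))
        assert res.beta_TL.shape == (target.p,)
        assert np.isfinite(res.target_only_fit.sigma2)

    def test_naive_equals_known_all_sources(self, small_transfer):
        target, sources, _, tc = small_transfer
        nv = naive_transfer(target, sources, tc)
        kn = transfer_fit_known(target, sources, [1, 2, 3], tc)
        np.testing.assert_allclose(nv.beta_TL, kn.beta_TL, atol=1e-10)

    def test_naive_single_source(self, small_transfer):
        target, sources, _, tc = small_transfer
        nv = naive_transfer(target, sources[:1], tc)
        kn = transfer_fit_known(target, sources[:1], [1], tc)
        np.testing.assert_allclose(nv.beta_TL, kn.beta_TL, atol=1e-10)
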