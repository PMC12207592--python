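"""Frame-weighted shape-GMM clustering against direct-formula oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal

from cvrefine.errors import EmptyComponentError, InvalidInputError
from cvrefine.geometry import COVAR_REGULARIZATION, align_ensemble, random_rotation
from cvrefine.shapegmm import (FrameWeights, Responsibilities, ShapeGMMModel,
                               predict_assignments, scan_num_clusters,
                               weighted_e_step, weighted_em_fit,
                               weighted_log_likelihood, weighted_m_step)
from cvrefine.toys import make_two_state_system, sample_iid


def random_spd(rng, N, scale=1.0):
    B = rng.standard_normal((N, N))
    return scale * (B @ B.T + N * np.eye(N))


def centered(x):
    return x - x.mean(axis=0)


def random_model(rng, K=2, N=4, sep=8.0):
    means = np.stack([centered(rng.standard_normal((N, 3)))
                      + sep * j * np.eye(N, 3) for j in range(K)])
    means = np.stack([centered(m) for m in means])
    covs = np.stack([random_spd(rng, N, scale=0.05) for _ in range(K)])
    phi = rng.uniform(0.3, 0.7, size=K)
    return ShapeGMMModel(phi=phi / phi.sum(), means=means, covariances_N=covs)


def oracle_logdens(model, centered_frames):
    """Independent density evaluator: explicit alignment, full Kronecker MVN."""
    from cvrefine.geometry import kronecker_rotation
    K, (M, N, _) = model.K, centered_frames.shape
    out = np.empty((K, M))
    for j in range(K):
        cov = model.covariances_N[j] + COVAR_REGULARIZATION * np.eye(N)
        prec = np.linalg.inv(cov)
        full = np.kron(cov, np.eye(3))
        mvn = multivariate_normal(mean=model.means[j].ravel(), cov=full)
        for i in range(M):
            t = kronecker_rotation(centered_frames[i], model.means[j], prec)
            out[j, i] = mvn.logpdf(t.apply(centered_frames[i]).ravel())
    return out


# ---------------------------------------------------------------------------
# FrameWeights
# ---------------------------------------------------------------------------

def test_weights_uniform_and_validation():
    w = FrameWeights.uniform(8)
    assert np.allclose(w.values, 1.0 / 8)
    with pytest.raises(InvalidInputError):
        FrameWeights(np.array([0.5, 0.6]))          # does not sum to 1
    with pytest.raises(InvalidInputError):
        FrameWeights(np.array([1.5, -0.5]))         # negative entry


@settings(max_examples=25, deadline=None)
@given(raw=st.lists(st.floats(min_value=1e-6, max_value=1e6),
                    min_size=1, max_size=40))
def test_weights_from_unnormalized_contract(raw):
    w = FrameWeights.from_unnormalized(np.array(raw))
    assert abs(w.values.sum() - 1.0) <= 1e-12
    assert np.all(w.values >= 0)


# ---------------------------------------------------------------------------
# weighted_e_step
# ---------------------------------------------------------------------------

def test_estep_single_component_returns_weights(system6):
    traj = sample_iid(system6, 20, seed=0)
    model = ShapeGMMModel(phi=[1.0], means=system6.means[:1],
                          covariances_N=system6.covariances_N[:1])
    w = FrameWeights.from_unnormalized(np.arange(1.0, 21.0))
    resp = weighted_e_step(model, traj.frames, w)
    assert np.allclose(resp.gamma[:, 0], w.values, atol=1e-14)


def test_estep_separated_component_wins(system6):
    model = ShapeGMMModel(phi=[0.5, 0.5], means=system6.means,
                          covariances_N=system6.covariances_N)
    resp = weighted_e_step(model, system6.means[0][None],
                           FrameWeights.uniform(1))
    assert resp.gamma[0, 0] > 0.999 * 1.0


def test_estep_matches_direct_formula_oracle():
    rng = np.random.default_rng(21)
    model = random_model(rng)
    frames = np.stack([centered(model.means[i % 2]
                                + 0.3 * rng.standard_normal((4, 3)))
                       for i in range(6)])
    w = FrameWeights.from_unnormalized(rng.uniform(0.5, 2.0, size=6))
    resp = weighted_e_step(model, frames, w)
    logd = oracle_logdens(model, frames)
    num = np.log(model.phi)[:, None] + logd
    gamma_oracle = (w.values * np.exp(num - np.logaddexp.reduce(num, axis=0))).T
    assert np.abs(resp.gamma - gamma_oracle).max() < 1e-10


def test_responsibility_rows_sum_to_weights(system6):
    traj = sample_iid(system6, 30, seed=1)
    model = ShapeGMMModel(phi=[0.5, 0.5], means=system6.means,
                          covariances_N=system6.covariances_N)
    w = FrameWeights.from_unnormalized(np.random.default_rng(2).uniform(
        0.1, 1.0, size=30))
    resp = weighted_e_step(model, traj.frames, w)
    assert np.abs(resp.gamma.sum(axis=1) - w.values).max() < 1e-10


# ---------------------------------------------------------------------------
# weighted_m_step
# ---------------------------------------------------------------------------

def test_mstep_uniform_single_component_mean_is_plain_average():
    rng = np.random.default_rng(22)
    frames = np.stack([centered(rng.standard_normal((4, 3))) for _ in range(9)])
    gamma = np.full((9, 1), 1.0 / 9)
    model = weighted_m_step(Responsibilities(gamma), frames)
    assert np.allclose(model.means[0], frames.mean(axis=0), atol=1e-12)


def test_mstep_weight_splitting_leaves_model_unchanged():
    rng = np.random.default_rng(23)
    frames = np.stack([centered(rng.standard_normal((4, 3))) for _ in range(6)])
    w = rng.uniform(0.5, 1.5, size=6)
    w /= w.sum()
    gamma = np.column_stack([w * 0.7, w * 0.3])
    dup_frames = np.concatenate([frames, frames[:1]])
    dup_gamma = np.concatenate([gamma, gamma[:1] / 2.0])
    dup_gamma[0] /= 2.0
    m1 = weighted_m_step(Responsibilities(gamma), frames)
    m2 = weighted_m_step(Responsibilities(dup_gamma), dup_frames)
    assert np.abs(m1.phi - m2.phi).max() < 1e-12
    assert np.abs(m1.means - m2.means).max() < 1e-12
    assert np.abs(m1.covariances_N - m2.covariances_N).max() < 1e-12


def test_mstep_hard_labels_match_weighted_statistics_oracle():
    rng = np.random.default_rng(24)
    frames = np.stack([centered(rng.standard_normal((5, 3))) for _ in range(12)])
    labels = rng.integers(0, 2, size=12)
    w = rng.uniform(0.2, 1.0, size=12)
    w /= w.sum()
    gamma = np.zeros((12, 2))
    gamma[np.arange(12), labels] = w
    model = weighted_m_step(Responsibilities(gamma), frames)
    for j in range(2):
        wk = w[labels == j]
        Xk = frames[labels == j]
        mu = np.einsum("m,mia->ia", wk, Xk) / wk.sum()
        dev = Xk - mu
        cov = np.einsum("m,mia,mja->ij", wk, dev, dev) / (3.0 * wk.sum())
        assert np.allclose(model.phi[j], wk.sum(), atol=1e-12)
        assert np.allclose(model.means[j], mu, atol=1e-12)
        assert np.allclose(model.covariances_N[j], cov, atol=1e-12)


def test_mstep_empty_component_raises():
    frames = np.zeros((4, 3, 3))
    gamma = np.zeros((4, 2))
    gamma[:, 0] = 0.25
    with pytest.raises(EmptyComponentError):
        weighted_m_step(Responsibilities(gamma), frames)


# ---------------------------------------------------------------------------
# weighted_log_likelihood
# ---------------------------------------------------------------------------

def test_ll_single_frame_at_mean_equals_log_normalization():
    rng = np.random.default_rng(25)
    mean = centered(rng.standard_normal((4, 3)))
    cov = random_spd(rng, 4, scale=0.1)
    model = ShapeGMMModel(phi=[1.0], means=mean[None],
                          covariances_N=cov[None])
    ll = weighted_log_likelihood(model, mean[None], FrameWeights.uniform(1))
    full = np.kron(cov + COVAR_REGULARIZATION * np.eye(4), np.eye(3))
    expected = multivariate_normal(mean=mean.ravel(), cov=full).logpdf(
        mean.ravel())
    assert abs(ll - expected) < 1e-10


def test_ll_zero_weight_excludes_frame(system6):
    traj = sample_iid(system6, 2, seed=3)
    model = ShapeGMMModel(phi=[0.5, 0.5], means=system6.means,
                          covariances_N=system6.covariances_N)
    both = weighted_log_likelihood(model, traj.frames,
                                   FrameWeights(np.array([1.0, 0.0])))
    only_first = weighted_log_likelihood(model, traj.frames.coords[:1],
                                         FrameWeights(np.array([1.0])))
    assert abs(both - only_first) < 1e-12


def test_ll_matches_direct_formula_oracle():
    rng = np.random.default_rng(26)
    model = random_model(rng)
    frames = np.stack([centered(model.means[i % 2]
                                + 0.3 * rng.standard_normal((4, 3)))
                       for i in range(5)])
    w = FrameWeights.from_unnormalized(rng.uniform(0.5, 2.0, size=5))
    ll = weighted_log_likelihood(model, frames, w)
    logd = oracle_logdens(model, frames)
    per_frame = np.logaddexp.reduce(np.log(model.phi)[:, None] + logd, axis=0)
    assert abs(ll - float(w.values @ per_frame)) < 1e-10


# ---------------------------------------------------------------------------
# weighted_em_fit
# ---------------------------------------------------------------------------

def test_em_single_gaussian_recovers_mean(system6):
    one_state = make_two_state_system(N=6, seed=1)
    from cvrefine.toys import ToyTwoStateSystem
    sys1 = ToyTwoStateSystem(mixture_weights=[1.0],
                             means=one_state.means[:1],
                             covariances_N=one_state.covariances_N[:1])
    traj = sample_iid(sys1, 2000, seed=4)
    model = weighted_em_fit(traj.frames, K=1, seeds=(0,))
    res = align_ensemble(model.means[0][None],
                         mean=centered(sys1.means[0]),
                         covariance_N=sys1.covariances_N[0])
    rmsd = np.sqrt(np.mean((res.aligned.coords[0] - centered(sys1.means[0])) ** 2))
    assert rmsd < 0.05


def test_em_two_components_recover_generator(system6):
    traj = sample_iid(system6, 1000, seed=5)
    model = weighted_em_fit(traj.frames, K=2, seeds=(0, 1))
    # pair components to generator states by mean proximity after alignment
    errs = np.zeros((2, 2))
    for j in range(2):
        for k in range(2):
            res = align_ensemble(model.means[j][None],
                                 mean=centered(system6.means[k]),
                                 covariance_N=system6.covariances_N[k])
            errs[j, k] = np.sqrt(np.mean(
                (res.aligned.coords[0] - centered(system6.means[k])) ** 2))
    best = min(errs[0, 0] + errs[1, 1], errs[0, 1] + errs[1, 0])
    assert best / 2.0 < 0.05
    assert np.abs(model.phi - 0.5).max() < 0.05


def test_em_monotonic_log_likelihood(system6):
    traj = sample_iid(system6, 400, seed=6)
    model = weighted_em_fit(traj.frames, K=2, seeds=(0,))
    diffs = np.diff(model.ll_history)
    assert np.all(diffs > -1e-9)


def test_em_uniform_weights_equal_default(system6):
    traj = sample_iid(system6, 300, seed=7)
    m1 = weighted_em_fit(traj.frames, None, K=2, seeds=(0,))
    m2 = weighted_em_fit(traj.frames, FrameWeights.uniform(300), K=2,
                         seeds=(0,))
    assert np.abs(m1.phi - m2.phi).max() < 1e-8
    assert np.abs(m1.means - m2.means).max() < 1e-8


def test_em_rigid_transform_invariance(system6):
    traj = sample_iid(system6, 400, seed=8)
    rng = np.random.default_rng(9)
    transformed = np.stack([f @ random_rotation(rng).T
                            + rng.normal(scale=2, size=3)
                            for f in traj.frames.coords])
    m1 = weighted_em_fit(traj.frames, K=2, seeds=(0,))
    m2 = weighted_em_fit(transformed, K=2, seeds=(0,))
    assert np.abs(np.sort(m1.phi) - np.sort(m2.phi)).max() < 1e-6
    assert abs(m1.train_log_likelihood - m2.train_log_likelihood) < 1e-6


def test_em_frame_order_invariance(system6):
    traj = sample_iid(system6, 400, seed=10)
    perm = np.random.default_rng(11).permutation(400)
    m1 = weighted_em_fit(traj.frames, K=2, seeds=(0,))
    m2 = weighted_em_fit(traj.frames.coords[perm], K=2, seeds=(0,))
    assert np.abs(np.sort(m1.phi) - np.sort(m2.phi)).max() < 1e-6
    assert abs(m1.train_log_likelihood - m2.train_log_likelihood) < 1e-4


def test_em_requires_more_frames_than_components():
    with pytest.raises(InvalidInputError):
        weighted_em_fit(np.zeros((2, 4, 3)), K=2)


# ---------------------------------------------------------------------------
# predict_assignments
# ---------------------------------------------------------------------------

def test_predict_frame_at_component_mean(system6):
    model = ShapeGMMModel(phi=[0.5, 0.5], means=system6.means,
                          covariances_N=system6.covariances_N)
    labels, post = predict_assignments(model, system6.means[1][None])
    assert labels[0] == 1
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-10)


def test_predict_tie_breaks_to_lowest_index():
    rng = np.random.default_rng(27)
    mean = centered(rng.standard_normal((4, 3)))
    cov = random_spd(rng, 4, scale=0.1)
    model = ShapeGMMModel(phi=[0.5, 0.5], means=np.stack([mean, mean]),
                          covariances_N=np.stack([cov, cov]))
    labels, _ = predict_assignments(model, mean[None])
    assert labels[0] == 0


def test_predict_matches_generator_labels(system6, iid_sample):
    model = ShapeGMMModel(phi=[0.5, 0.5], means=system6.means,
                          covariances_N=system6.covariances_N)
    labels, _ = predict_assignments(model, iid_sample.frames)
    agreement = np.mean(labels == iid_sample.labels)
    agreement = max(agreement, 1.0 - agreement)  # label permutation
    assert agreement >= 0.99


# ---------------------------------------------------------------------------
# scan_num_clusters
# ---------------------------------------------------------------------------

def test_scan_prefers_true_cluster_count(system6):
    traj = sample_iid(system6, 600, seed=11)
    table = scan_num_clusters(traj.frames, K_range=(1, 2), train_frac=0.8,
                              seeds=(0, 1, 2))
    means = table.groupby("K")["cv_ll"].mean()
    assert means[2] > means[1]


def test_scan_reports_errors_per_row_and_continues(system6):
    traj = sample_iid(system6, 20, seed=12)
    table = scan_num_clusters(traj.frames, K_range=(2, 50), train_frac=0.5,
                              seeds=(0,))
    bad = table[table["K"] == 50]
    assert bad["error"].notna().all()
    good = table[table["K"] == 2]
    assert np.isfinite(good["train_ll"]).all()
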