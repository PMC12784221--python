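"""Core decomposition: standardization, S/Q blocks, GEVD, components, maps.

Every fast-path computation is checked against an independent brute-force
oracle: the literal double loops over trial pairs for the S blocks, and a
dense eigensolve of inv(Q) @ S for the generalized eigenvalue problem.
"""

import numpy as np
import pytest

from gtrca.decomposition import (
    BlockMatrices,
    assemble_blocks,
    between_subject_block,
    component_timecourses,
    fit_gtrca,
    scalp_maps,
    solve_gevd,
    standardize_and_concatenate,
    within_subject_block,
)
from gtrca.epochs import EpochSet, GroupDataset
from gtrca.exceptions import (
    EpochMismatchError,
    TooFewTrialsError,
    ZeroVarianceChannelError,
)

from conftest import random_group


# ---------------------------------------------------------------- oracles

def brute_within(trials, tau):
    """Literal double loop over ordered trial pairs k != l."""
    K = len(trials)
    acc = np.zeros((trials[0].shape[0],) * 2)
    for k in range(K):
        for l in range(K):
            if k != l:
                acc += trials[k] @ trials[l].T
    return acc / (K * (K - 1) * tau)


def brute_between(trials_a, trials_b, tau):
    acc = np.zeros((trials_a[0].shape[0], trials_b[0].shape[0]))
    for xa in trials_a:
        for xb in trials_b:
            acc += xa @ xb.T
    return acc / (len(trials_a) * len(trials_b) * tau)


def _epochs(data, sfreq=64.0, subject_id="s"):
    tau = data.shape[1]
    return EpochSet(
        data=data, sfreq=sfreq, times=np.arange(tau) / sfreq, subject_id=subject_id
    )


# ------------------------------------------------------- standardization

def test_standardize_single_channel_example():
    data = np.array([[1.0, 2.0], [3.0, 4.0]]).T[None, :, :]  # 1 ch, 2 samples, 2 trials
    z = standardize_and_concatenate(_epochs(data))
    x = np.array([1.0, 2.0, 3.0, 4.0])
    expected = (x - 2.5) / x.std()
    np.testing.assert_allclose(z.concatenated[0], expected, atol=1e-12)


def test_standardize_moments_and_idempotence(rng):
    ep = _epochs(rng.standard_normal((4, 20, 5)))
    z = standardize_and_concatenate(ep)
    np.testing.assert_allclose(z.concatenated.mean(axis=1), 0, atol=1e-10)
    np.testing.assert_allclose(z.concatenated.std(axis=1), 1, atol=1e-10)
    # a second pass over already standardized data is the identity
    tau, K = z.n_samples, z.n_trials
    again = standardize_and_concatenate(
        _epochs(z.concatenated.reshape(4, K, tau).transpose(0, 2, 1))
    )
    np.testing.assert_allclose(again.concatenated, z.concatenated, atol=1e-12)


def test_standardize_rejects_degenerate_inputs(rng):
    with pytest.raises(TooFewTrialsError):
        standardize_and_concatenate(_epochs(rng.standard_normal((2, 8, 1))))
    data = rng.standard_normal((3, 8, 3))
    data[1] = 5.0  # constant channel
    with pytest.raises(ZeroVarianceChannelError) as err:
        standardize_and_concatenate(_epochs(data))
    assert "ch01" in str(err.value)


# ------------------------------------------------------------- S blocks

def test_within_block_identical_trials_is_one(rng):
    trial = rng.standard_normal((1, 16))
    data = np.repeat(trial[:, :, None], 4, axis=2)
    z = standardize_and_concatenate(_epochs(data))
    np.testing.assert_allclose(within_subject_block(z), [[1.0]], atol=1e-12)


def test_within_block_orthogonal_trials_is_zero():
    t = np.arange(32) / 32
    data = np.stack([np.sin(2 * np.pi * 2 * t), np.cos(2 * np.pi * 2 * t)], axis=1)[
        None, :, :
    ]
    z = standardize_and_concatenate(_epochs(data))
    assert abs(within_subject_block(z)[0, 0]) < 1e-10


def test_within_block_matches_brute_force(rng):
    z = standardize_and_concatenate(_epochs(rng.standard_normal((3, 16, 4))))
    fast = within_subject_block(z)
    np.testing.assert_allclose(
        fast, brute_within(list(z.trials()), z.n_samples), atol=1e-12
    )


def test_within_block_requires_two_trials(rng):
    z = standardize_and_concatenate(_epochs(rng.standard_normal((2, 8, 2))))
    z.n_trials = 1
    with pytest.raises(TooFewTrialsError):
        within_subject_block(z)


def test_between_block_identities(rng):
    trial = rng.standard_normal((1, 16))
    da = np.repeat(trial[:, :, None], 3, axis=2)
    za = standardize_and_concatenate(_epochs(da, subject_id="a"))
    zb = standardize_and_concatenate(_epochs(da.copy(), subject_id="b"))
    np.testing.assert_allclose(between_subject_block(za, zb), [[1.0]], atol=1e-12)
    # sign-flipped partner flips the block (linearity)
    zf = standardize_and_concatenate(_epochs(-da, subject_id="f"))
    np.testing.assert_allclose(
        between_subject_block(za, zf), -between_subject_block(za, zb), atol=1e-12
    )


def test_between_block_matches_brute_force_and_transposes(rng):
    za = standardize_and_concatenate(_epochs(rng.standard_normal((3, 16, 4)), subject_id="a"))
    zb = standardize_and_concatenate(_epochs(rng.standard_normal((2, 16, 5)), subject_id="b"))
    fast = between_subject_block(za, zb)
    np.testing.assert_allclose(
        fast, brute_between(list(za.trials()), list(zb.trials()), 16), atol=1e-12
    )
    np.testing.assert_allclose(fast, between_subject_block(zb, za).T, atol=1e-14)


def test_between_block_rejects_mismatched_epoch_length(rng):
    za = standardize_and_concatenate(_epochs(rng.standard_normal((2, 16, 3))))
    zb = standardize_and_concatenate(_epochs(rng.standard_normal((2, 8, 3)), sfreq=32))
    with pytest.raises(EpochMismatchError):
        between_subject_block(za, zb)


# ----------------------------------------------------------- assembly

def _identical_trial_group(rng, A=2, K=4, tau=16):
    trial = rng.standard_normal((1, tau))
    data = np.repeat(trial[:, :, None], K, axis=2)
    return GroupDataset(
        [_epochs(data.copy(), subject_id=f"s{a}") for a in range(A)]
    )


def test_assemble_blocks_toy_example(rng):
    """Two subjects with identical repeated trials: S=[[2,1],[1,2]], Q=I."""
    blocks = assemble_blocks(_identical_trial_group(rng))
    np.testing.assert_allclose(blocks.S, [[2, 1], [1, 2]], atol=1e-10)
    np.testing.assert_allclose(blocks.Q, np.eye(2), atol=1e-10)


def test_assemble_blocks_structure(rng):
    group = random_group(rng, n_subjects=3)
    blocks = assemble_blocks(group)
    np.testing.assert_allclose(blocks.S, blocks.S.T, atol=1e-10)
    for sl in blocks.slices():
        evals = np.linalg.eigvalsh(blocks.Q[sl, sl])
        assert evals.min() >= -1e-10


def test_offdiagonal_blocks_shrink_with_noise(rng):
    """Independent noise: ||S_ab|| decreases roughly as 1/sqrt(K_a K_b tau)."""
    norms = {}
    for tau in (64, 1024):
        vals = []
        for _ in range(20):
            group = random_group(rng, n_subjects=2, n_samples=tau, n_trials=4)
            blocks = assemble_blocks(group)
            sl = blocks.slices()
            vals.append(np.linalg.norm(blocks.S[sl[0], sl[1]]))
        norms[tau] = np.mean(vals)
    ratio = norms[64] / norms[1024]
    assert 2.0 < ratio < 8.0  # expected 4 for a 16x sample increase


# ---------------------------------------------------------------- GEVD

def test_solve_gevd_closed_form(rng):
    blocks = assemble_blocks(_identical_trial_group(rng))
    fit = solve_gevd(blocks)
    np.testing.assert_allclose(fit.eigenvalues, [3.0, 1.0], atol=1e-8)
    w = fit.stacked_filter(0)
    np.testing.assert_allclose(np.abs(w), [1, 1] / np.sqrt(2), atol=1e-8)
    np.testing.assert_allclose(fit.normalized_eigenvalues, fit.eigenvalues / 2)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_solve_gevd_matches_dense_oracle(seed):
    rng = np.random.default_rng(seed)
    dim = 8
    A_ = rng.standard_normal((dim, dim))
    S = 0.5 * (A_ + A_.T)
    B = rng.standard_normal((dim, dim + 4))
    Q = B @ B.T / (dim + 4)
    blocks = BlockMatrices(S=S, Q=Q, block_offsets=[0, dim // 2])
    fit = solve_gevd(blocks)
    oracle = np.sort(np.linalg.eigvals(np.linalg.inv(Q) @ S).real)[::-1]
    np.testing.assert_allclose(fit.eigenvalues, oracle, atol=1e-8)
    for j in range(dim):
        w = fit.stacked_filter(j)
        np.testing.assert_allclose(w @ Q @ w, 1.0, atol=1e-8)
        np.testing.assert_allclose(
            w @ S @ w, fit.eigenvalues[j], atol=1e-6 * max(1, abs(fit.eigenvalues[j]))
        )


def test_fit_invariants_and_rayleigh(rng):
    group = random_group(rng, n_subjects=3)
    fit = fit_gtrca(group, variance_fraction=1.0)
    blocks = assemble_blocks(group)
    for j in range(fit.n_components):
        w = fit.stacked_filter(j)
        np.testing.assert_allclose(w @ blocks.Q @ w, 1.0, atol=1e-8)
        lam = fit.eigenvalues[j]
        np.testing.assert_allclose(w @ blocks.S @ w, lam, atol=1e-6 * max(abs(lam), 1e-3))
    np.testing.assert_allclose(fit.normalized_eigenvalues, fit.eigenvalues / 3)
    assert np.all(np.diff(fit.eigenvalues) <= 1e-12)


def test_fit_matches_unregularized_solver(rng):
    """f=1 whitened path equals the direct dense generalized solve."""
    group = random_group(rng, n_subjects=2)
    fit = fit_gtrca(group, variance_fraction=1.0)
    direct = solve_gevd(assemble_blocks(group))
    np.testing.assert_allclose(fit.eigenvalues, direct.eigenvalues, atol=1e-8)


def test_eigenvalues_invariant_to_permutation_and_sign_flip(rng):
    group = random_group(rng, n_subjects=2)
    ref = fit_gtrca(group).eigenvalues
    perm = np.array([2, 0, 3, 1])
    flipped = GroupDataset(
        [
            EpochSet(
                data=group[0].data[perm],
                sfreq=group[0].sfreq,
                times=group[0].times,
                subject_id="p",
            ),
            EpochSet(
                data=-group[1].data,
                sfreq=group[1].sfreq,
                times=group[1].times,
                subject_id="f",
            ),
        ]
    )
    np.testing.assert_allclose(fit_gtrca(flipped).eigenvalues, ref, atol=1e-8)


def test_single_subject_fit_warns(rng):
    group = GroupDataset([random_group(rng, n_subjects=1)[0]])
    with pytest.warns(UserWarning, match="single-subject"):
        fit = fit_gtrca(group)
    assert fit.n_components > 0


def test_average_referenced_data_is_handled(rng):
    """Rank-deficient Q (average reference) must not break the solver."""
    data = rng.standard_normal((5, 32, 4))
    data -= data.mean(axis=0, keepdims=True)
    group = GroupDataset(
        [_epochs(data, subject_id="a"), _epochs(rng.standard_normal((5, 32, 4)), subject_id="b")]
    )
    fit = fit_gtrca(group, variance_fraction=0.999)
    assert fit.regularization[0]["rank"] <= 4
    assert np.all(np.isfinite(fit.eigenvalues))


# --------------------------------------------- components and scalp maps

def test_timecourse_projection_identities(rng):
    group = random_group(rng, n_subjects=2)
    fit = fit_gtrca(group)
    view = component_timecourses(fit, group, 0)
    za = standardize_and_concatenate(group[0])
    w = fit.filters[0][:, 0]
    expected = np.einsum("n,knt->kt", w, za.trials())
    np.testing.assert_allclose(view.timecourses[0], expected, atol=1e-12)
    # canonical basis filter picks out the standardized channel
    fit.filters[0][:, 0] = 0
    fit.filters[0][2, 0] = 1.0
    view = component_timecourses(fit, group, 0)
    np.testing.assert_allclose(
        view.timecourses[0], za.trials()[:, 2, :], atol=1e-12
    )
    # sign-flipped filter flips the time course
    fit.filters[0][:, 0] *= -1
    view2 = component_timecourses(fit, group, 0)
    np.testing.assert_allclose(view2.timecourses[0], -view.timecourses[0], atol=1e-12)


def test_scalp_maps_identity_q(rng):
    group = random_group(rng, n_subjects=2)
    fit = fit_gtrca(group)
    fit.q_blocks = [np.eye(4), np.eye(4)]
    maps = scalp_maps(fit, 1)
    np.testing.assert_allclose(maps[0], fit.filters[0][:, 1], atol=1e-14)


def test_scalp_maps_invariant_to_regularization_choice(rng):
    group = random_group(rng, n_subjects=2)
    m1 = scalp_maps(fit_gtrca(group, variance_fraction=1.0), 0)
    m2 = scalp_maps(solve_gevd(assemble_blocks(group)), 0)
    for a, b in zip(m1, m2):
        np.testing.assert_allclose(np.abs(a), np.abs(b), atol=1e-8)
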