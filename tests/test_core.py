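import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connectopy import (
    FingerprintMatrix,
    SpatialModes,
    TimeseriesMatrix,
    build_similarity,
    compute_spatial_modes,
    fingerprints,
    similarity,
    within_seed_fc,
)

from conftest import make_ts


# ---------------------------------------------------------------------------
# TimeseriesMatrix validation


def test_timeseries_rejects_constant_column(rng):
    data = rng.standard_normal((10, 4))
    data[:, 2] = 5.0
    with pytest.raises(ValueError, match=r"\[2\]"):
        TimeseriesMatrix(data=data, voxel_ids=np.arange(4))


def test_timeseries_rejects_few_timepoints(rng):
    with pytest.raises(ValueError, match="timepoints"):
        TimeseriesMatrix(data=rng.standard_normal((2, 4)), voxel_ids=np.arange(4))


def test_timeseries_rejects_duplicate_voxel_ids(rng):
    with pytest.raises(ValueError, match="unique"):
        TimeseriesMatrix(
            data=rng.standard_normal((10, 3)), voxel_ids=np.array([0, 1, 1])
        )


# ---------------------------------------------------------------------------
# spatial modes


def test_default_mode_count_is_t_minus_one_for_wide_targets(rng):
    target = make_ts(rng, 20, 40, "target")
    modes = compute_spatial_modes(target)
    assert modes.p == 19  # min(t-1, n) = t-1 when n >= t-1


def test_mode_count_capped_by_voxel_count(rng):
    target = make_ts(rng, 20, 10, "target")
    assert compute_spatial_modes(target).p == 10


def test_modes_reconstruct_standardized_target(rng):
    target = make_ts(rng, 20, 40, "target")
    modes = compute_spatial_modes(target)
    recon = modes.modes @ modes.right_vectors.T
    assert np.abs(recon - target.zscored()).max() < 1e-8


def test_mode_columns_orthogonal_with_singular_value_norms(rng):
    target = make_ts(rng, 30, 50, "target")
    modes = compute_spatial_modes(target)
    gram = modes.modes.T @ modes.modes
    assert np.allclose(gram, np.diag(modes.singular_values**2), atol=1e-8)
    assert np.all(np.diff(modes.singular_values) <= 1e-12)


def test_mode_truncation_and_bad_p(rng):
    target = make_ts(rng, 20, 40, "target")
    assert compute_spatial_modes(target, p=5).p == 5
    with pytest.raises(ValueError, match="exceeds"):
        compute_spatial_modes(target, p=25)


# ---------------------------------------------------------------------------
# fingerprints


def test_voxelwise_self_correlation_is_one(rng):
    target = make_ts(rng, 20, 6, "target")
    seed_data = rng.standard_normal((20, 3))
    seed_data[:, 0] = target.data[:, 4]
    seed = TimeseriesMatrix(seed_data, np.arange(3))
    fp = fingerprints(seed, target, "voxelwise")
    assert fp.data[0, 4] == pytest.approx(1.0, abs=1e-12)


def test_rescaled_equals_original_under_unit_singular_values(rng):
    seed = make_ts(rng, 20, 5)
    target = make_ts(rng, 20, 12, "target")
    modes = compute_spatial_modes(target)
    unit = SpatialModes(
        modes=modes.modes,
        singular_values=np.ones(modes.p),
        p=modes.p,
    )
    orig = fingerprints(seed, target, "original", modes=unit)
    resc = fingerprints(seed, target, "rescaled", modes=unit)
    assert np.array_equal(orig.data, resc.data)


def test_rescaled_row_gram_matches_voxelwise_up_to_global_factor(rng):
    """Row inner products agree up to one positive scalar (SVD identity)."""
    seed = make_ts(rng, 20, 15)
    target = make_ts(rng, 20, 40, "target")
    resc = fingerprints(seed, target, "rescaled").data
    vox = fingerprints(seed, target, "voxelwise").data
    g_resc = resc @ resc.T
    g_vox = vox @ vox.T
    ratio = g_resc.ravel() / g_vox.ravel()
    assert ratio.min() > 0
    assert np.abs(ratio / ratio.mean() - 1).max() < 1e-6


def test_fingerprints_timepoint_mismatch_errors(rng):
    with pytest.raises(ValueError, match="timepoints"):
        fingerprints(make_ts(rng, 20, 5), make_ts(rng, 21, 8, "target"), "voxelwise")


# ---------------------------------------------------------------------------
# within-seed FC


def test_within_seed_duplicate_and_flipped_voxels(rng):
    data = rng.standard_normal((30, 4))
    data[:, 1] = data[:, 0]
    data[:, 2] = -data[:, 0]
    fc = within_seed_fc(TimeseriesMatrix(data, np.arange(4)))
    assert fc.data[0, 1] == pytest.approx(1.0, abs=1e-12)
    assert fc.data[0, 2] == pytest.approx(-1.0, abs=1e-12)


def test_within_seed_matches_pairwise_loop_oracle():
    rng = np.random.default_rng(7)
    seed = make_ts(rng, 30, 10)
    fc = within_seed_fc(seed).data
    from scipy.stats import pearsonr

    for i in range(10):
        for j in range(10):
            expect = 1.0 if i == j else pearsonr(
                seed.data[:, i], seed.data[:, j]
            ).statistic
            assert fc[i, j] == pytest.approx(expect, abs=1e-12)


# ---------------------------------------------------------------------------
# similarity measures


def _eta2_two_loop(c):
    """Naive two-profile eta^2: within-pair SS around pairwise means over
    total SS around the pair grand mean."""
    m = c.shape[0]
    s = np.eye(m)
    for i in range(m):
        for j in range(m):
            mi = (c[i] + c[j]) / 2.0
            grand = mi.mean()
            num = np.sum((c[i] - mi) ** 2 + (c[j] - mi) ** 2)
            den = np.sum((c[i] - grand) ** 2 + (c[j] - grand) ** 2)
            s[i, j] = 1.0 - num / den
    return s


def test_eta2_hand_value():
    fp = FingerprintMatrix(np.array([[1.0, 2.0], [3.0, 4.0]]), "voxelwise")
    # pairwise means (2, 3), grand mean 2.5 -> 1 - 4/5
    assert similarity(fp, "eta2").data[0, 1] == pytest.approx(0.2, abs=1e-12)


def test_eta2_identical_rows_and_cosine_bounds(rng):
    c = rng.standard_normal((4, 6))
    c[1] = c[0]
    fp = FingerprintMatrix(c, "voxelwise")
    assert similarity(fp, "eta2").data[0, 1] == pytest.approx(1.0, abs=1e-9)
    assert similarity(fp, "cosine").data[0, 1] == pytest.approx(1.0, abs=1e-12)


def test_cosine_orthogonal_rows():
    fp = FingerprintMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]), "voxelwise")
    assert similarity(fp, "cosine").data[0, 1] == pytest.approx(0.0, abs=1e-15)


def test_eta2_matches_two_loop_oracle(rng):
    c = rng.standard_normal((5, 4))
    fp = FingerprintMatrix(c, "voxelwise")
    got = similarity(fp, "eta2").data
    expect = np.clip(_eta2_two_loop(c), 0, 1)
    assert np.abs(got - expect).max() < 1e-12


def test_cosine_zero_row_errors():
    fp = FingerprintMatrix(np.array([[0.0, 0.0], [1.0, 2.0]]), "voxelwise")
    with pytest.raises(ValueError, match="zero"):
        similarity(fp, "cosine")


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_similarity_invariants_on_random_fingerprints(seed):
    rng = np.random.default_rng(seed)
    c = rng.standard_normal((6, 5))
    fp = FingerprintMatrix(c, "voxelwise")
    for measure in ("eta2", "cosine"):
        s = similarity(fp, measure).data
        assert np.allclose(s, s.T, atol=1e-12)
        assert np.allclose(np.diag(s), 1.0)
        if measure == "eta2":
            assert s.min() >= 0 and s.max() <= 1
        else:
            assert s.min() >= -1 - 1e-12 and s.max() <= 1 + 1e-12


# ---------------------------------------------------------------------------
# build_similarity dispatcher and equivalence identities


def test_within_seed_route_matches_direct_call(rng):
    seed = make_ts(rng, 25, 8)
    s1 = build_similarity(seed, None, "within_seed")
    s2 = within_seed_fc(seed)
    assert np.array_equal(s1.data, s2.data)
    assert s1.measure == "pearson_fc"


def test_within_seed_rejects_foreign_measure(rng):
    with pytest.raises(ValueError, match="measure"):
        build_similarity(make_ts(rng, 25, 8), None, "within_seed", "cosine")


def test_original_cosine_equals_within_seed_fc_on_full_rank_target(rng):
    # target spans the centered time space (n >= t-1)
    seed = make_ts(rng, 40, 25)
    target = make_ts(rng, 40, 60, "target")
    s_orig = build_similarity(seed, target, "original", "cosine")
    s_ws = within_seed_fc(seed)
    assert np.abs(s_orig.data - s_ws.data).max() < 1e-8


def test_rescaled_cosine_equals_voxelwise_cosine(rng):
    seed = make_ts(rng, 40, 25)
    target = make_ts(rng, 40, 60, "target")
    # heteroscedastic target columns: the identity must survive scaling
    target = TimeseriesMatrix(
        target.data * rng.uniform(0.2, 5.0, 60), np.arange(60), "target"
    )
    s_resc = build_similarity(seed, target, "rescaled", "cosine")
    s_vox = build_similarity(seed, target, "voxelwise", "cosine")
    assert np.abs(s_resc.data - s_vox.data).max() < 1e-8


def test_svd_route_gram_invariant_to_target_rotation(rng):
    """The mode-based row Gram depends on the centered target only through
    its row space: rotating voxels leaves it unchanged (10x10 oracle)."""
    a = rng.standard_normal((10, 6))
    b = rng.standard_normal((10, 10))
    q, _ = np.linalg.qr(rng.standard_normal((10, 10)))

    def mode_gram(bmat):
        bc = bmat - bmat.mean(axis=0)
        u, s, _ = np.linalg.svd(bc, full_matrices=False)
        ac = a - a.mean(axis=0)
        c = (ac / np.linalg.norm(ac, axis=0)).T @ (u * s)
        return c @ c.T

    assert np.abs(mode_gram(b) - mode_gram(b @ q)).max() < 1e-8


def test_blockwise_path_matches_dense_path(rng):
    seed = make_ts(rng, 30, 12)
    target = make_ts(rng, 30, 45, "target")
    for variant in ("original", "rescaled", "voxelwise"):
        for measure in ("cosine", "eta2"):
            dense = build_similarity(seed, target, variant, measure)
            block = build_similarity(
                seed, target, variant, measure, dense_budget=10
            )
            assert np.abs(dense.data - block.data).max() < 1e-12


def test_unknown_variant_and_missing_target_error(rng):
    seed = make_ts(rng, 20, 5)
    with pytest.raises(ValueError, match="variant"):
        build_similarity(seed, None, "bogus")
    with pytest.raises(ValueError, match="target"):
        build_similarity(seed, None, "original")
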