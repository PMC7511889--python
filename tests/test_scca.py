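"""Block preparation and the sparse canonical decomposition: constraint
satisfaction, the dense-CCA oracle in the loose-penalty limit, deflation and
projection semantics."""

import numpy as np
import pytest
from scipy import linalg

from sccalink import (
    DataBlock, fit_scca, prepare_block, project, variance_explained,
)
from sccalink.scca import (
    SccaConvergenceWarning, _l1_unit, _l1_unit_rows, tune_penalties,
)
from tests.conftest import make_block


def dense_cca_first_r(Z1, Z2):
    """Independent generalized-eigenvalue oracle for the first canonical
    correlation of two column-centered matrices."""
    n = Z1.shape[0]
    C11 = Z1.T @ Z1 / (n - 1)
    C22 = Z2.T @ Z2 / (n - 1)
    C12 = Z1.T @ Z2 / (n - 1)
    A = C12 @ np.linalg.solve(C22, C12.T)
    w = linalg.eigh(A, C11, eigvals_only=True)
    return float(np.sqrt(w.max()))


# ---------------------------------------------------------------------------
# preparation
# ---------------------------------------------------------------------------

def test_standardization_is_idempotent(rng):
    X = rng.standard_normal((30, 5))
    b1 = make_block(X)
    b2 = prepare_block(b1.matrix, b1.variable_names, b1.participant_ids)
    assert np.allclose(b1.matrix, b2.matrix, atol=1e-12)
    assert np.allclose(b2.matrix.mean(axis=0), 0, atol=1e-8)
    assert np.allclose(b2.matrix.std(axis=0, ddof=1), 1, atol=1e-8)


def test_residuals_orthogonal_to_covariates(rng):
    X = rng.standard_normal((20, 5))
    cov = rng.standard_normal((20, 2))
    block = prepare_block(X, [f"v{j}" for j in range(5)], range(20),
                          covariates=cov)
    assert block.state == "residualized+standardized"
    for j in range(5):
        for q in range(2):
            r = np.corrcoef(block.matrix[:, j], cov[:, q])[0, 1]
            assert abs(r) < 1e-8


def test_column_linear_in_covariate_becomes_constant_error(rng):
    age = rng.uniform(20, 40, size=25)
    X = np.column_stack([2.0 * age + 1.0, rng.standard_normal(25)])
    with pytest.raises(ValueError, match="constant column.*v0"):
        prepare_block(X, ["v0", "v1"], range(25), covariates=age)


def test_rank_deficient_covariates_rejected(rng):
    X = rng.standard_normal((20, 3))
    c = rng.standard_normal(20)
    with pytest.raises(ValueError, match="rank-deficient"):
        prepare_block(X, list("abc"), range(20),
                      covariates=np.column_stack([c, 2 * c]))


# ---------------------------------------------------------------------------
# soft-threshold projection
# ---------------------------------------------------------------------------

def test_l1_projection_constraints_hold(rng):
    for _ in range(200):
        p = int(rng.integers(2, 70))
        a = rng.standard_normal(p) * rng.uniform(0.1, 10)
        c = float(rng.uniform(1.0, np.sqrt(p)))
        u = _l1_unit(a, c)
        assert np.abs(u).sum() <= c + 1e-6
        assert np.linalg.norm(u) <= 1 + 1e-9
    # loose bound leaves the direction untouched
    a = rng.standard_normal(12)
    u = _l1_unit(a, np.sqrt(12))
    assert np.allclose(u, a / np.linalg.norm(a))


def test_l1_projection_batch_matches_scalar(rng):
    A = rng.standard_normal((50, 20))
    c = 2.3
    batch = _l1_unit_rows(A, c)
    for i in range(50):
        assert np.allclose(batch[i], _l1_unit(A[i], c), atol=1e-10)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_identical_blocks_give_unit_first_correlation(rng):
    X = rng.standard_normal((40, 6))
    b1 = make_block(X, "a")
    b2 = make_block(X.copy(), "b")
    model = fit_scca(b1, b2, n_modes=1)
    assert model.modes[0].canonical_correlation == pytest.approx(1.0, abs=1e-8)


def test_loose_penalty_limit_equals_dense_cca(rng):
    for _ in range(10):
        b1 = make_block(rng.standard_normal((60, 4)), "a")
        b2 = make_block(rng.standard_normal((60, 5)), "b")
        model = fit_scca(b1, b2, n_modes=1, cov_shrinkage=0.0,
                         tol=1e-10, max_iter=20000)
        oracle = dense_cca_first_r(b1.matrix, b2.matrix)
        assert model.modes[0].canonical_correlation == pytest.approx(
            oracle, abs=1e-6)


def test_objective_monotone_and_constraints_per_mode(rng):
    b1 = make_block(rng.standard_normal((50, 10)), "a")
    b2 = make_block(rng.standard_normal((50, 12)), "b")
    model = fit_scca(b1, b2, c1=2.0, c2=2.5, n_modes=3,
                     track_objective=True)
    for mode in model.modes:
        obj = np.array(mode.objective_path)
        assert np.all(np.diff(obj) > -1e-9)
        assert np.abs(mode.u).sum() <= model.penalties[0] + 1e-6
        assert np.abs(mode.v).sum() <= model.penalties[1] + 1e-6
        assert np.linalg.norm(mode.u) <= 1 + 1e-9
        assert np.linalg.norm(mode.v) <= 1 + 1e-9


def test_active_penalty_produces_exact_zeros(planted_pair):
    b1, b2, _ = planted_pair
    model = fit_scca(b1, b2, c1=1.5, c2=2.0, n_modes=2)
    assert (model.modes[0].u == 0).sum() > 0
    assert (model.modes[0].v == 0).sum() > 0


def test_participant_permutation_equivariance(rng):
    b1 = make_block(rng.standard_normal((35, 6)), "a")
    b2 = make_block(rng.standard_normal((35, 7)), "b")
    model = fit_scca(b1, b2, c1=1.8, c2=2.0, n_modes=2)
    perm = rng.permutation(35)
    b1p = DataBlock(b1.matrix[perm], b1.variable_names,
                    [b1.participant_ids[i] for i in perm],
                    state=b1.state)
    b2p = DataBlock(b2.matrix[perm], b2.variable_names,
                    [b2.participant_ids[i] for i in perm],
                    state=b2.state)
    model_p = fit_scca(b1p, b2p, c1=1.8, c2=2.0, n_modes=2)
    for m, mp in zip(model.modes, model_p.modes):
        assert np.allclose(m.u, mp.u, atol=1e-8)
        assert np.allclose(m.v, mp.v, atol=1e-8)


def test_determinism_and_sign_convention(planted_pair):
    b1, b2, _ = planted_pair
    m1 = fit_scca(b1, b2, c1=2.0, c2=3.0, n_modes=4, seed=1)
    m2 = fit_scca(b1, b2, c1=2.0, c2=3.0, n_modes=4, seed=99)
    for a, b in zip(m1.modes, m2.modes):
        assert np.array_equal(a.u, b.u)
        assert np.array_equal(a.v, b.v)
        assert a.canonical_correlation >= 0
        assert a.u[np.argmax(np.abs(a.u))] >= 0


def test_penalty_bounds_and_mode_count_validated(rng):
    b1 = make_block(rng.standard_normal((30, 4)), "a")
    b2 = make_block(rng.standard_normal((30, 5)), "b")
    with pytest.raises(ValueError, match="c1"):
        fit_scca(b1, b2, c1=0.5, c2=2.0, n_modes=1)
    with pytest.raises(ValueError, match="c1"):
        fit_scca(b1, b2, c1=3.0, c2=2.0, n_modes=1)  # > sqrt(4)
    with pytest.raises(ValueError, match="n_modes"):
        fit_scca(b1, b2, n_modes=5)


def test_nonconvergence_warns(rng):
    b1 = make_block(rng.standard_normal((30, 8)), "a")
    b2 = make_block(rng.standard_normal((30, 9)), "b")
    with pytest.warns(SccaConvergenceWarning):
        fit_scca(b1, b2, c1=2.0, c2=2.0, n_modes=3, max_iter=2)


# ---------------------------------------------------------------------------
# variance explained
# ---------------------------------------------------------------------------

def test_single_mode_share_is_one(rng):
    b1 = make_block(rng.standard_normal((30, 4)), "a")
    b2 = make_block(rng.standard_normal((30, 5)), "b")
    model = fit_scca(b1, b2, n_modes=1)
    assert variance_explained(model) == pytest.approx([1.0])


def test_rank_one_cross_covariance_concentrates_share(rng):
    # block2 columns are noisy copies of one signal also present in block1
    n = 300
    s = rng.standard_normal(n)
    X1 = np.column_stack([s + 0.01 * rng.standard_normal(n) for _ in range(4)])
    X2 = np.column_stack([s + 0.01 * rng.standard_normal(n) for _ in range(5)])
    model = fit_scca(make_block(X1, "a"), make_block(X2, "b"), n_modes=3)
    shares = variance_explained(model)
    assert shares[0] > 0.99
    assert shares.sum() == pytest.approx(1.0, abs=1e-10)


def test_mode_truncation_logic_on_planted_instance():
    """Two strong planted modes, 10-mode fit: early modes dominate and the
    first seven cumulatively carry >99% of the captured cross-covariance.
    A large sample keeps the trailing modes down at the noise floor."""
    from sccalink import PlantedMode, SyntheticSpec, generate_blocks
    spec = SyntheticSpec(
        n_participants=1500,
        planted_modes=[PlantedMode(latent_correlation=0.8, strength=2.0),
                       PlantedMode(latent_correlation=0.6, strength=1.5)],
        seed=21,
    )
    b1r, b2r, _, _ = generate_blocks(spec)
    b1 = prepare_block(b1r.matrix, b1r.variable_names, b1r.participant_ids)
    b2 = prepare_block(b2r.matrix, b2r.variable_names, b2r.participant_ids)
    model = fit_scca(b1, b2, c1=2.5, c2=3.5, n_modes=10, max_iter=1000)
    shares = variance_explained(model)
    assert shares[:2].sum() > shares[2:].sum()
    assert shares[:7].sum() > 0.99


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def test_projection_reproduces_stored_correlation(planted_pair):
    b1, b2, _ = planted_pair
    model = fit_scca(b1, b2, c1=2.0, c2=3.0, n_modes=3)
    for k in (1, 2, 3):
        t1, t2 = project(model, b1, b2, k)
        r = np.corrcoef(t1, t2)[0, 1]
        assert r == pytest.approx(model.modes[k - 1].canonical_correlation,
                                  abs=1e-10)


def test_unit_weight_projection_is_column(rng):
    b1 = make_block(rng.standard_normal((30, 4)), "a")
    b2 = make_block(rng.standard_normal((30, 5)), "b")
    model = fit_scca(b1, b2, n_modes=1)
    model.modes[0].u = np.array([0.0, 1.0, 0.0, 0.0])
    t1, _ = project(model, b1, b2, 1)
    assert np.allclose(t1, b1.matrix[:, 1])


def test_projection_variable_mismatch_reported(planted_pair):
    b1, b2, _ = planted_pair
    model = fit_scca(b1, b2, n_modes=1)
    bad = DataBlock(b1.matrix, [f"w{j}" for j in range(b1.p)],
                    b1.participant_ids, state=b1.state)
    with pytest.raises(ValueError, match="block1 variables differ"):
        project(model, bad, b2, 1)


def test_heldout_projection_tracks_planted_correlation():
    from sccalink import SyntheticSpec, generate_blocks
    spec = SyntheticSpec(n_participants=400, seed=33)
    b1r, b2r, _, _ = generate_blocks(spec)
    half = 200
    tr1 = prepare_block(b1r.matrix[:half], b1r.variable_names,
                        b1r.participant_ids[:half])
    tr2 = prepare_block(b2r.matrix[:half], b2r.variable_names,
                        b2r.participant_ids[:half])
    te1 = prepare_block(b1r.matrix[half:], b1r.variable_names,
                        b1r.participant_ids[half:])
    te2 = prepare_block(b2r.matrix[half:], b2r.variable_names,
                        b2r.participant_ids[half:])
    model = fit_scca(tr1, tr2, c1=2.0, c2=3.0, n_modes=1)
    t1, t2 = project(model, te1, te2, 1)
    r = np.corrcoef(t1, t2)[0, 1]
    assert r > 0.5
    assert abs(r - 0.7) < 0.15  # within sampling error of the planted value


# ---------------------------------------------------------------------------
# penalty tuning
# ---------------------------------------------------------------------------

def test_tune_penalties_returns_grid_member_and_is_seeded(planted_pair):
    b1, b2, _ = planted_pair
    (c1, c2), table = tune_penalties(b1, b2, grid1=[0.3, 0.8],
                                     grid2=[0.3, 0.8], n_splits=2, seed=4)
    assert len(table) == 4
    assert ((table["c1"] == c1) & (table["c2"] == c2)).any()
    (c1b, c2b), _ = tune_penalties(b1, b2, grid1=[0.3, 0.8],
                                   grid2=[0.3, 0.8], n_splits=2, seed=4)
    assert (c1, c2) == (c1b, c2b)
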