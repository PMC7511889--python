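"""Sparse canonical correlation analysis via penalized matrix decomposition.

Two participant-aligned blocks ``X1`` (n x p1) and ``X2`` (n x p2) are related
through successive sparse rank-one factors of the cross-product matrix
``C12 = X1' X2 / (n-1)``.  Each mode maximizes ``u' C12 v`` subject to
``||u||_2 <= 1``, ``||v||_2 <= 1`` and L1 bounds ``||u||_1 <= c1``,
``||v||_1 <= c2``, by alternating soft-thresholded power iterations; the
soft-threshold level is found by binary search so the L1 constraint is tight
or inactive.  After each mode the cross-product matrix is deflated by the
fitted rank-one component.

A per-block covariance shrinkage parameter interpolates between the pure
penalized-matrix-decomposition solution (shrinkage 1, the working within-block
covariance is the identity — appropriate when variables rival or outnumber
participants) and classical CCA (shrinkage 0 on full-rank blocks, where the
loose-penalty limit of the iteration is exactly the generalized-eigenvalue
solution).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "DataBlock",
    "SccaMode",
    "SccaModel",
    "FitConfig",
    "prepare_block",
    "fit_scca",
    "variance_explained",
    "project",
    "tune_penalties",
    "SccaConvergenceWarning",
]


class SccaConvergenceWarning(UserWarning):
    """A mode's alternating iteration hit ``max_iter`` before converging."""


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class DataBlock:
    """A named participants x variables matrix with preparation state."""

    matrix: np.ndarray
    variable_names: list[str]
    participant_ids: list
    state: str = "raw"  # raw | standardized | residualized+standardized

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-dimensional")
        n, p = self.matrix.shape
        if len(self.variable_names) != p:
            raise ValueError(f"{len(self.variable_names)} names for {p} columns")
        if len(self.participant_ids) != n:
            raise ValueError(f"{len(self.participant_ids)} ids for {n} rows")
        if np.isnan(self.matrix).any():
            raise ValueError("DataBlock contains missing values")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, id_column: str = "participant_id",
                       state: str = "raw") -> "DataBlock":
        """Build a block from a wide table whose first column holds IDs."""
        if id_column in df.columns:
            ids = df[id_column].tolist()
            data = df.drop(columns=[id_column])
        else:
            ids = df.index.tolist()
            data = df
        return cls(data.to_numpy(dtype=float), list(data.columns), ids, state=state)

    def to_dataframe(self, id_column: str = "participant_id") -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.variable_names)
        df.insert(0, id_column, self.participant_ids)
        return df

    def subset(self, row_idx: np.ndarray, state: str | None = None) -> "DataBlock":
        ids = [self.participant_ids[i] for i in np.asarray(row_idx)]
        return DataBlock(self.matrix[row_idx], list(self.variable_names), ids,
                         state=state or self.state)


@dataclass
class SccaMode:
    index: int                       # 1-based
    u: np.ndarray                    # weights over block-1 variables
    v: np.ndarray                    # weights over block-2 variables
    d: float                         # u' C12 v on the deflated matrix
    canonical_correlation: float
    variance_explained_share: float
    converged: bool = True
    n_iter: int = 0
    objective_path: list[float] | None = None


@dataclass
class SccaModel:
    modes: list[SccaMode]
    penalties: tuple[float, float]
    n_modes: int
    prep: dict = field(default_factory=dict)
    variable_names1: list[str] = field(default_factory=list)
    variable_names2: list[str] = field(default_factory=list)
    cov_shrinkage: tuple[float, float] = (1.0, 1.0)

    def weights(self, block: int) -> np.ndarray:
        """Stacked weight matrix (p x n_modes) for block 1 or 2."""
        vecs = [(m.u if block == 1 else m.v) for m in self.modes]
        return np.column_stack(vecs)

    def canonical_correlations(self) -> np.ndarray:
        return np.array([m.canonical_correlation for m in self.modes])

    def to_dict(self) -> dict:
        return {
            "penalties": list(self.penalties),
            "n_modes": self.n_modes,
            "prep": self.prep,
            "cov_shrinkage": list(self.cov_shrinkage),
            "modes": [
                {
                    "index": m.index,
                    "d": m.d,
                    "canonical_correlation": m.canonical_correlation,
                    "variance_explained_share": m.variance_explained_share,
                    "converged": m.converged,
                    "n_iter": m.n_iter,
                    "u": dict(zip(self.variable_names1, m.u.tolist())),
                    "v": dict(zip(self.variable_names2, m.v.tolist())),
                }
                for m in self.modes
            ],
        }


@dataclass
class FitConfig:
    """Everything needed to refit the model on resampled data."""

    c1: float | None = None
    c2: float | None = None
    n_modes: int = 10
    tol: float = 1e-6
    max_iter: int = 500
    cov_shrinkage: float | tuple[float, float] = 1.0

    def kwargs(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# preparation
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray, names: list[str]) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    bad = np.where(sd < 1e-12)[0]
    if bad.size:
        raise ValueError(
            "constant column(s) cannot be standardized: "
            + ", ".join(names[i] for i in bad)
        )
    return (X - mu) / sd


def _residualize(X: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residuals of every column of X on covariates plus intercept."""
    Z = np.column_stack([np.ones(len(covariates)), covariates])
    beta, *_ = np.linalg.lstsq(Z, X, rcond=None)
    return X - Z @ beta


def prepare_block(matrix, variable_names, participant_ids,
                  covariates=None) -> DataBlock:
    """Residualize (optionally) each variable on covariates, then z-score.

    Parameters
    ----------
    covariates : array-like or DataFrame, optional
        One row per participant, aligned with ``participant_ids``.  When
        given, every column of ``matrix`` is replaced by its residual from an
        ordinary least-squares fit on the covariates plus an intercept before
        standardization.
    """
    X = np.asarray(matrix, dtype=float)
    names = list(variable_names)
    state = "standardized"
    if covariates is not None:
        if isinstance(covariates, pd.DataFrame):
            cov = covariates.to_numpy(dtype=float)
        else:
            cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if len(cov) != len(X):
            raise ValueError("covariate table not aligned with participants")
        Z = np.column_stack([np.ones(len(cov)), cov])
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError("rank-deficient covariates")
        X = _residualize(X, cov)
        state = "residualized+standardized"
    X = _standardize(X, names)
    return DataBlock(X, names, list(participant_ids), state=state)


def _check_pair(block1: DataBlock, block2: DataBlock) -> None:
    if list(block1.participant_ids) != list(block2.participant_ids):
        raise ValueError("blocks do not share identical participant order")
    for b in (block1, block2):
        if "standardized" not in b.state:
            raise ValueError(f"block in state '{b.state}'; standardize first")


# ---------------------------------------------------------------------------
# penalized matrix decomposition core
# ---------------------------------------------------------------------------

def _threshold_levels(A: np.ndarray, c: float) -> np.ndarray:
    """Soft-threshold level per row so that S(a, delta)/||.||_2 has L1 = c.

    Exact piecewise solve: with the row's absolute values sorted descending
    and the top-k entries surviving threshold delta, the L1 and squared-L2
    norms of S(a, delta) are linear resp. quadratic in delta, so the level at
    which the normalized L1 norm equals c solves
    ``k(k - c^2) d^2 + 2 S1 (c^2 - k) d + (S1^2 - c^2 S2) = 0``
    on the segment where the support size is k.  Rows already satisfying the
    bound get level 0.
    """
    A = np.abs(A)
    B, p = A.shape
    t = -np.sort(-A, axis=1)                      # descending
    S1 = np.cumsum(t, axis=1)
    S2 = np.cumsum(t ** 2, axis=1)
    k = np.arange(1, p + 1)
    t_low = np.concatenate([t[:, 1:], np.zeros((B, 1))], axis=1)
    # L1/L2 ratio of S(a, delta) at the lower end of each support segment
    l1 = S1 - k * t_low
    l2sq = S2 - 2 * t_low * S1 + k * t_low ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = l1 / np.sqrt(np.maximum(l2sq, 1e-300))
    # smallest support size whose segment reaches ratio >= c
    reach = ratio >= c - 1e-12
    reach[:, -1] = True
    kk = np.argmax(reach, axis=1)                 # 0-based: support = kk+1
    rows = np.arange(B)
    kf = (kk + 1).astype(float)
    s1 = S1[rows, kk]
    s2 = S2[rows, kk]
    a2 = kf * (kf - c ** 2)
    a1 = 2.0 * s1 * (c ** 2 - kf)
    a0 = s1 ** 2 - c ** 2 * s2
    lo = t_low[rows, kk]
    hi = np.where(kk > 0, t[rows, np.maximum(kk - 1, 0)], t[:, 0])
    delta = np.empty(B)
    with np.errstate(invalid="ignore", divide="ignore"):
        disc = np.sqrt(np.maximum(a1 ** 2 - 4 * a2 * a0, 0.0))
        quad = np.abs(a2) > 1e-12
        r1 = np.where(quad, (-a1 + disc) / (2 * a2), 0.0)
        r2 = np.where(quad, (-a1 - disc) / (2 * a2), 0.0)
        lin = np.abs(a1) > 1e-12
        rl = np.where(lin, -a0 / np.where(lin, a1, 1.0), 0.5 * (lo + hi))
    in1 = quad & (r1 >= lo - 1e-12) & (r1 <= hi + 1e-12)
    delta = np.where(in1, r1, np.where(quad, r2, rl))
    delta = np.clip(delta, lo, hi)
    # rows already inside the L1 ball keep level 0
    norm = np.sqrt(np.maximum(S2[:, -1], 1e-300))
    inside = S1[:, -1] / norm <= c
    delta[inside] = 0.0
    delta[S2[:, -1] < 1e-300] = 0.0
    return delta


def _l1_unit_rows(A: np.ndarray, c: float) -> np.ndarray:
    """Row-wise unit-L2 soft-thresholded vectors with ``||.||_1 <= c``."""
    delta = _threshold_levels(A, c)
    S = np.sign(A) * np.maximum(np.abs(A) - delta[:, None], 0.0)
    norms = np.linalg.norm(S, axis=1)
    zero = norms < 1e-300
    if zero.any():
        # threshold collapsed everything (ties at the top); keep the argmax
        for i in np.where(zero)[0]:
            j = int(np.argmax(np.abs(A[i])))
            S[i] = 0.0
            S[i, j] = np.sign(A[i, j]) if A[i, j] != 0 else 0.0
        norms = np.linalg.norm(S, axis=1)
        norms[norms < 1e-300] = 1.0
    return S / norms[:, None]


def _l1_unit(a: np.ndarray, c: float) -> np.ndarray:
    """Unit-L2 soft-thresholded vector with ``||.||_1 <= c``."""
    if np.linalg.norm(a) < 1e-300:
        return np.zeros_like(a)
    return _l1_unit_rows(a[None, :], c)[0]


def _pmd_factors_batch(Ms: np.ndarray, c1: float, c2: float, n_modes: int,
                       W1: np.ndarray | None, W2: np.ndarray | None,
                       tol: float, max_iter: int):
    """Batched sparse rank-one decomposition of a stack of matrices.

    Runs the same alternating soft-thresholded iteration as
    :func:`_pmd_factors` on ``Ms`` of shape (B, p1, p2) simultaneously —
    the workhorse of the permutation null, where thousands of refits share
    every setting but the cross-product matrix.  Iteration stops when the
    largest weight change across the whole batch drops below ``tol``.
    """
    Ms = Ms.copy()
    B, p1, p2 = Ms.shape
    U_all = np.zeros((B, p1, n_modes))
    V_all = np.zeros((B, p2, n_modes))
    d_all = np.zeros((B, n_modes))
    for k in range(n_modes):
        _, _, vt = np.linalg.svd(Ms, full_matrices=False)
        V = vt[:, 0, :]
        j = np.argmax(np.abs(V), axis=1)
        V = V * np.sign(V[np.arange(B), j] + 1e-300)[:, None]
        U = np.zeros((B, p1))
        active = np.arange(B)
        it = 0
        while active.size and it < max_iter:
            it += 1
            Ma = Ms[active]
            a = np.einsum("bij,bj->bi", Ma, V[active])
            if W1 is not None:
                a = a @ W1.T
            U_new = _l1_unit_rows(a, c1)
            b = np.einsum("bij,bi->bj", Ma, U_new)
            if W2 is not None:
                b = b @ W2.T
            V_new = _l1_unit_rows(b, c2)
            if it > 1:
                change = np.maximum(
                    np.max(np.abs(U_new - U[active]), axis=1),
                    np.max(np.abs(V_new - V[active]), axis=1))
            else:
                change = np.full(active.size, np.inf)
            U[active] = U_new
            V[active] = V_new
            active = active[change >= tol]
        d = np.einsum("bi,bij,bj->b", U, Ms, V)
        U_all[:, :, k], V_all[:, :, k], d_all[:, k] = U, V, d
        Ms -= d[:, None, None] * (U[:, :, None] * V[:, None, :])
    return U_all, V_all, d_all


def _init_v(M: np.ndarray) -> np.ndarray:
    """Leading right singular vector, sign-fixed deterministically."""
    _, _, vt = np.linalg.svd(M, full_matrices=False)
    v = vt[0]
    j = int(np.argmax(np.abs(v)))
    if v[j] < 0:
        v = -v
    return v


def _pmd_factors(M: np.ndarray, c1: float, c2: float, n_modes: int,
                 W1: np.ndarray | None, W2: np.ndarray | None,
                 tol: float, max_iter: int,
                 track_objective: bool = False):
    """Successive sparse rank-one factors of M with deflation.

    Returns (U, V, d, n_iters, converged, objectives).
    """
    p1, p2 = M.shape
    U = np.zeros((p1, n_modes))
    V = np.zeros((p2, n_modes))
    d = np.zeros(n_modes)
    iters = np.zeros(n_modes, dtype=int)
    converged = np.ones(n_modes, dtype=bool)
    objectives: list[list[float]] = []
    Mk = M.copy()
    for k in range(n_modes):
        v = _init_v(Mk)
        u = np.zeros(p1)
        path: list[float] = []
        it = 0
        for it in range(1, max_iter + 1):
            a = Mk @ v
            if W1 is not None:
                a = W1 @ a
            u_new = _l1_unit(a, c1)
            b = Mk.T @ u_new
            if W2 is not None:
                b = W2 @ b
            v_new = _l1_unit(b, c2)
            if track_objective:
                path.append(float(u_new @ Mk @ v_new))
            du = np.max(np.abs(u_new - u)) if it > 1 else np.inf
            dv = np.max(np.abs(v_new - v))
            u, v = u_new, v_new
            if max(du, dv) < tol:
                break
        else:  # pragma: no cover - loop exhausted without break (py quirk)
            pass
        if it >= max_iter and max(du, dv) >= tol:
            converged[k] = False
            warnings.warn(
                f"mode {k + 1} did not converge in {max_iter} iterations "
                f"(last change {max(du, dv):.2e})",
                SccaConvergenceWarning,
                stacklevel=3,
            )
        dk = float(u @ Mk @ v)
        U[:, k], V[:, k], d[k] = u, v, dk
        iters[k] = it
        if track_objective:
            objectives.append(path)
        Mk = Mk - dk * np.outer(u, v)
    return U, V, d, iters, converged, objectives


def _shrunk_inverse(X: np.ndarray, gamma: float) -> np.ndarray | None:
    """Inverse of the shrunk within-block covariance, or None when identity."""
    if gamma >= 1.0:
        return None
    n = X.shape[0]
    C = X.T @ X / (n - 1)
    W = (1.0 - gamma) * C + gamma * np.eye(C.shape[0])
    return linalg.pinvh(W)


def _variate_corrs(X1, X2, U, V) -> np.ndarray:
    T1 = X1 @ U
    T2 = X2 @ V
    T1 = T1 - T1.mean(axis=0)
    T2 = T2 - T2.mean(axis=0)
    n1 = np.linalg.norm(T1, axis=0)
    n2 = np.linalg.norm(T2, axis=0)
    denom = n1 * n2
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("ij,ij->j", T1, T2) / denom
    r[~np.isfinite(r)] = 0.0
    return r


def _resolve_penalty(c: float | None, p: int, name: str) -> float:
    limit = float(np.sqrt(p))
    if c is None:
        return limit
    if not (1.0 <= c <= limit + 1e-9):
        raise ValueError(f"{name}={c} outside [1, sqrt(p)={limit:.4f}]")
    return float(c)


def fit_scca(block1: DataBlock, block2: DataBlock,
             c1: float | None = None, c2: float | None = None,
             n_modes: int = 10, tol: float = 1e-6, max_iter: int = 500,
             seed: int | None = None,
             cov_shrinkage: float | tuple[float, float] = 1.0,
             track_objective: bool = False) -> SccaModel:
    """Fit successive sparse canonical modes to two standardized blocks.

    Parameters
    ----------
    c1, c2 : float, optional
        L1 bounds on the unit-L2 weight vectors, in ``[1, sqrt(p)]``.  At the
        upper bound the L1 constraint is inactive.  ``None`` means loose.
    cov_shrinkage : float or (float, float)
        Within-block covariance shrinkage toward the identity per block.
        1.0 (default) is the penalized-matrix-decomposition working
        assumption; 0.0 targets classical CCA on full-rank blocks.
    seed : int, optional
        Accepted for interface completeness; initialization is deterministic
        (leading singular vector), so the seed only matters for degenerate
        tie-breaking, which the sign convention already fixes.
    """
    _check_pair(block1, block2)
    X1, X2 = block1.matrix, block2.matrix
    n = X1.shape[0]
    p1, p2 = X1.shape[1], X2.shape[1]
    if n_modes < 1 or n_modes > min(p1, p2):
        raise ValueError(f"n_modes={n_modes} outside [1, min(p1,p2)={min(p1, p2)}]")
    c1 = _resolve_penalty(c1, p1, "c1")
    c2 = _resolve_penalty(c2, p2, "c2")
    g1, g2 = (cov_shrinkage if isinstance(cov_shrinkage, (tuple, list))
              else (cov_shrinkage, cov_shrinkage))
    W1 = _shrunk_inverse(X1, g1)
    W2 = _shrunk_inverse(X2, g2)
    M = X1.T @ X2 / (n - 1)
    U, V, d, iters, conv, objs = _pmd_factors(
        M, c1, c2, n_modes, W1, W2, tol, max_iter, track_objective)

    corrs = _variate_corrs(X1, X2, U, V)
    # sign convention: r >= 0 (flip v alone), then largest-|u| entry positive
    for k in range(n_modes):
        if corrs[k] < 0:
            V[:, k] = -V[:, k]
            d[k] = -d[k]
            corrs[k] = -corrs[k]
        j = int(np.argmax(np.abs(U[:, k]))) if np.any(U[:, k]) else 0
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
            V[:, k] = -V[:, k]

    total = float(np.sum(d ** 2))
    shares = (d ** 2 / total) if total > 0 else np.zeros(n_modes)
    modes = [
        SccaMode(index=k + 1, u=U[:, k].copy(), v=V[:, k].copy(), d=float(d[k]),
                 canonical_correlation=float(corrs[k]),
                 variance_explained_share=float(shares[k]),
                 converged=bool(conv[k]), n_iter=int(iters[k]),
                 objective_path=objs[k] if track_objective else None)
        for k in range(n_modes)
    ]
    return SccaModel(
        modes=modes, penalties=(c1, c2), n_modes=n_modes,
        prep={"block1": block1.state, "block2": block2.state, "n": n},
        variable_names1=list(block1.variable_names),
        variable_names2=list(block2.variable_names),
        cov_shrinkage=(float(g1), float(g2)),
    )


def variance_explained(model: SccaModel) -> np.ndarray:
    """Per-mode share of sum(d^2) over the computed modes (sums to 1)."""
    if not model.modes:
        raise ValueError("model has no fitted modes")
    d2 = np.array([m.d ** 2 for m in model.modes])
    total = d2.sum()
    if total == 0:
        return np.zeros_like(d2)
    return d2 / total


def project(model: SccaModel, block1: DataBlock, block2: DataBlock,
            mode_index: int):
    """Participant-level variate pair ``(X1 u_k, X2 v_k)`` for one mode.

    Works on held-out participants, which is the basis of the split-half
    reliability battery.
    """
    for names, have, label in (
        (model.variable_names1, block1.variable_names, "block1"),
        (model.variable_names2, block2.variable_names, "block2"),
    ):
        if list(names) != list(have):
            missing = sorted(set(names) - set(have))
            extra = sorted(set(have) - set(names))
            raise ValueError(
                f"{label} variables differ from the model's: "
                f"missing={missing} unexpected={extra}"
            )
    mode = model.modes[mode_index - 1]
    return block1.matrix @ mode.u, block2.matrix @ mode.v


def tune_penalties(block1: DataBlock, block2: DataBlock,
                   grid1=None, grid2=None, n_splits: int = 5,
                   seed: int | None = None, n_modes: int = 1,
                   cov_shrinkage: float | tuple[float, float] = 1.0,
                   tol: float = 1e-6, max_iter: int = 500):
    """Pick (c1, c2) maximizing mean out-of-sample mode-1 variate correlation.

    The grid is given as fractions in (0, 1]; fraction f maps to
    ``c = 1 + f * (sqrt(p) - 1)``.  Each candidate is scored over
    ``n_splits`` random half-splits: fit on one half, project the other,
    record the held-out Pearson correlation of the first variate pair.
    """
    _check_pair(block1, block2)
    if grid1 is None:
        grid1 = [0.2, 0.4, 0.6, 0.8]
    if grid2 is None:
        grid2 = [0.2, 0.4, 0.6, 0.8]
    rng = np.random.default_rng(seed)
    n = block1.n
    splits = []
    for _ in range(n_splits):
        order = rng.permutation(n)
        half = (n + 1) // 2
        splits.append((order[:half], order[half:]))

    def c_of(f, p):
        return 1.0 + f * (np.sqrt(p) - 1.0)

    rows = []
    best = (-np.inf, None, None)
    for f1 in grid1:
        for f2 in grid2:
            cc1 = c_of(f1, block1.p)
            cc2 = c_of(f2, block2.p)
            scores = []
            for train, test in splits:
                try:
                    b1t = DataBlock(_standardize(block1.matrix[train], block1.variable_names),
                                    block1.variable_names,
                                    [block1.participant_ids[i] for i in train],
                                    state="standardized")
                    b2t = DataBlock(_standardize(block2.matrix[train], block2.variable_names),
                                    block2.variable_names,
                                    [block2.participant_ids[i] for i in train],
                                    state="standardized")
                except ValueError:
                    continue  # constant column in this split
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", SccaConvergenceWarning)
                    m = fit_scca(b1t, b2t, cc1, cc2, n_modes=n_modes, tol=tol,
                                 max_iter=max_iter, cov_shrinkage=cov_shrinkage)
                t1 = block1.matrix[test] @ m.modes[0].u
                t2 = block2.matrix[test] @ m.modes[0].v
                if t1.std() > 0 and t2.std() > 0:
                    scores.append(float(np.corrcoef(t1, t2)[0, 1]))
            score = float(np.mean(scores)) if scores else -np.inf
            rows.append({"c1": cc1, "c2": cc2, "f1": f1, "f2": f2,
                         "mean_test_r": score})
            if score > best[0]:
                best = (score, cc1, cc2)
    table = pd.DataFrame(rows)
    return (best[1], best[2]), table
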