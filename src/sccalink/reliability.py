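"""Reliability battery for sparse canonical models.

Four screens of the same question — would the modes replicate? —

* leave-one-out influence of every participant on each mode's canonical
  correlation (outlier screen);
* split-half resampling: fit on a random half, project the held-out half
  with the training weights, record the out-of-sample variate correlation;
* the redundancy-reliability (RR) score: stability of the variable-to-variate
  correlations (loadings) between held-out data and the full sample;
* an overfitting index, mean(in-sample r - out-of-sample r), tracked across
  sample sizes to judge whether the study n is adequate.

Canonical modes permute and change sign freely across refits, so resampled
modes are matched to the full-sample modes by maximal absolute cosine of the
concatenated weight vectors and sign-aligned before any averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .scca import (
    DataBlock, FitConfig, SccaModel, SccaConvergenceWarning,
    _check_pair, _standardize, fit_scca,
)

__all__ = [
    "ReliabilityReport",
    "leave_one_out",
    "split_half",
    "rr_score",
    "loading_vector",
    "sample_size_check",
]


@dataclass
class ReliabilityReport:
    splithalf_r: np.ndarray          # (n_resamples, n_modes) test-half r
    train_r: np.ndarray              # (n_resamples, n_modes) training-half r
    rr: np.ndarray                   # (n_resamples, n_modes) RR-scores
    rr_mean: np.ndarray
    rr_sd: np.ndarray
    overfit_index: np.ndarray        # per mode, mean(train r - test r)
    mode_match: np.ndarray           # (n_resamples, n_modes) matched indices
    n_resamples: int
    seed: int | None
    n_redrawn: int = 0
    loo: pd.DataFrame | None = None

    def as_dict(self) -> dict:
        out = {
            "n_resamples": self.n_resamples,
            "seed": self.seed,
            "n_redrawn": self.n_redrawn,
            "splithalf_r_mean": np.nanmean(self.splithalf_r, axis=0).tolist(),
            "splithalf_r_sd": np.nanstd(self.splithalf_r, axis=0, ddof=1).tolist(),
            "train_r_mean": np.nanmean(self.train_r, axis=0).tolist(),
            "rr_mean": self.rr_mean.tolist(),
            "rr_sd": self.rr_sd.tolist(),
            "overfit_index": self.overfit_index.tolist(),
        }
        if self.loo is not None:
            out["loo_flagged"] = self.loo.loc[
                self.loo["flagged"], "participant_id"].tolist()
        return out


def _quiet_fit(b1: DataBlock, b2: DataBlock, cfg: FitConfig) -> SccaModel:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SccaConvergenceWarning)
        return fit_scca(b1, b2, **cfg.kwargs())


def loading_vector(u: np.ndarray, v: np.ndarray,
                   block1: DataBlock, block2: DataBlock) -> np.ndarray:
    """Correlation of every variable with its own block's variate,
    concatenated over both blocks (length p1 + p2).

    Returns NaNs when a variate has zero variance on the given data.
    """
    out = np.full(block1.p + block2.p, np.nan)
    for offset, (X, w) in enumerate(((block1.matrix, u), (block2.matrix, v))):
        t = X - X.mean(axis=0)
        s = t @ w
        ns = np.linalg.norm(s)
        if ns < 1e-12:
            continue
        col_norms = np.linalg.norm(t, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (t.T @ s) / (col_norms * ns)
        start = 0 if offset == 0 else block1.p
        out[start:start + X.shape[1]] = r
    return out


def rr_score(model: SccaModel, test_block1: DataBlock, test_block2: DataBlock,
             mode_index: int, reference_loadings: np.ndarray,
             reference_weights: np.ndarray | None = None) -> float:
    """Redundancy-reliability score of one mode on held-out data.

    The test-set loading vector (correlation of each variable with its
    block's test-set variate, both blocks concatenated) is correlated with
    the corresponding full-sample loading vector.  When
    ``reference_weights`` (concatenated ``[u_ref, v_ref]``) is supplied, the
    mode's weights are sign-aligned to it first, making the score invariant
    to a joint sign flip of the mode; otherwise the absolute correlation is
    returned.

    Returns NaN when a test variate has zero variance.
    """
    mode = model.modes[mode_index - 1]
    u, v = mode.u, mode.v
    if reference_weights is not None:
        w = np.concatenate([u, v])
        if w @ reference_weights < 0:
            u, v = -u, -v
    load = loading_vector(u, v, test_block1, test_block2)
    ok = np.isfinite(load) & np.isfinite(reference_loadings)
    if ok.sum() < 3 or np.all(np.isnan(load)):
        return float("nan")
    a, b = load[ok], reference_loadings[ok]
    if a.std() < 1e-12 or b.std() < 1e-12:
        return float("nan")
    r = float(np.corrcoef(a, b)[0, 1])
    return r if reference_weights is not None else abs(r)


def leave_one_out(block1: DataBlock, block2: DataBlock,
                  fit_config: FitConfig | None = None) -> pd.DataFrame:
    """Per-participant influence on each mode's canonical correlation.

    Influence is full-sample r minus the r refitted without the participant;
    a participant is flagged when, for any mode, their influence lies more
    than 3 SD from the mean influence of that mode.
    """
    _check_pair(block1, block2)
    if block1.n < 10:
        raise ValueError("leave-one-out needs at least 10 participants")
    cfg = fit_config or FitConfig()
    full = _quiet_fit(block1, block2, cfg)
    full_r = full.canonical_correlations()
    K = cfg.n_modes

    n = block1.n
    infl = np.empty((n, K))
    for i in range(n):
        keep = np.r_[0:i, i + 1:n]
        b1 = DataBlock(_standardize(block1.matrix[keep], block1.variable_names),
                       block1.variable_names,
                       [block1.participant_ids[j] for j in keep],
                       state=block1.state)
        b2 = DataBlock(_standardize(block2.matrix[keep], block2.variable_names),
                       block2.variable_names,
                       [block2.participant_ids[j] for j in keep],
                       state=block2.state)
        sub = _quiet_fit(b1, b2, cfg)
        infl[i] = full_r - sub.canonical_correlations()

    mean = infl.mean(axis=0)
    sd = infl.std(axis=0, ddof=1)
    sd[sd < 1e-15] = np.inf  # no dispersion -> nothing can be flagged
    flagged = (np.abs(infl - mean) > 3 * sd).any(axis=1)

    out = pd.DataFrame(
        infl, columns=[f"influence_mode{k + 1}" for k in range(K)])
    out.insert(0, "participant_id", block1.participant_ids)
    out["flagged"] = flagged
    out.attrs["full_r"] = full_r.tolist()
    return out


def _match_modes(model: SccaModel, reference: SccaModel):
    """Match modes to a reference by maximal |cosine| of stacked weights.

    Returns (permutation, signs): reference mode k corresponds to fitted
    mode permutation[k] with the given sign.
    """
    W = np.vstack([model.weights(1), model.weights(2)])        # (p1+p2, K)
    R = np.vstack([reference.weights(1), reference.weights(2)])
    norms_w = np.linalg.norm(W, axis=0)
    norms_r = np.linalg.norm(R, axis=0)
    norms_w[norms_w < 1e-15] = 1.0
    norms_r[norms_r < 1e-15] = 1.0
    cos = (R / norms_r).T @ (W / norms_w)                      # (Kref, Kfit)
    ref_idx, fit_idx = linear_sum_assignment(-np.abs(cos))
    perm = np.empty(len(ref_idx), dtype=int)
    signs = np.empty(len(ref_idx))
    for r, f in zip(ref_idx, fit_idx):
        perm[r] = f
        signs[r] = 1.0 if cos[r, f] >= 0 else -1.0
    return perm, signs


def split_half(block1: DataBlock, block2: DataBlock,
               fit_config: FitConfig | None = None,
               n_resamples: int = 10000, seed: int | None = None,
               compute_rr: bool = True,
               max_redraws: int = 100) -> ReliabilityReport:
    """Split-half weight-transfer reliability with mode matching.

    Each resample draws disjoint random halves (the training half gets the
    extra participant when n is odd), standardizes each half on its own
    statistics, fits the model on the training half, matches and sign-aligns
    its modes to the full-sample model, and projects the held-out half with
    the training weights.  A resample whose halves contain a constant column
    is redrawn and counted in ``n_redrawn``.
    """
    _check_pair(block1, block2)
    if block1.n < 20:
        raise ValueError("split-half reliability needs at least 20 participants")
    if n_resamples < 1:
        raise ValueError("n_resamples must be positive")
    cfg = fit_config or FitConfig()
    K = cfg.n_modes
    rng = np.random.default_rng(seed)

    full = _quiet_fit(block1, block2, cfg)
    full_loadings = [
        loading_vector(m.u, m.v, block1, block2) for m in full.modes
    ]
    n = block1.n
    half = (n + 1) // 2
    test_r = np.full((n_resamples, K), np.nan)
    train_r = np.full((n_resamples, K), np.nan)
    rr = np.full((n_resamples, K), np.nan)
    match_rec = np.full((n_resamples, K), -1, dtype=int)
    n_redrawn = 0

    for b in range(n_resamples):
        for _ in range(max_redraws):
            order = rng.permutation(n)
            tr, te = order[:half], order[half:]
            try:
                b1t = DataBlock(_standardize(block1.matrix[tr], block1.variable_names),
                                block1.variable_names,
                                [block1.participant_ids[i] for i in tr],
                                state="standardized")
                b2t = DataBlock(_standardize(block2.matrix[tr], block2.variable_names),
                                block2.variable_names,
                                [block2.participant_ids[i] for i in tr],
                                state="standardized")
                b1e = DataBlock(_standardize(block1.matrix[te], block1.variable_names),
                                block1.variable_names,
                                [block1.participant_ids[i] for i in te],
                                state="standardized")
                b2e = DataBlock(_standardize(block2.matrix[te], block2.variable_names),
                                block2.variable_names,
                                [block2.participant_ids[i] for i in te],
                                state="standardized")
                break
            except ValueError:
                n_redrawn += 1
        else:
            raise RuntimeError("could not draw non-degenerate halves")

        sub = _quiet_fit(b1t, b2t, cfg)
        perm, signs = _match_modes(sub, full)
        match_rec[b] = perm
        for k in range(K):
            m = sub.modes[perm[k]]
            u, v = signs[k] * m.u, signs[k] * m.v
            t1, t2 = b1e.matrix @ u, b2e.matrix @ v
            if t1.std() > 1e-12 and t2.std() > 1e-12:
                test_r[b, k] = float(np.corrcoef(t1, t2)[0, 1])
            s1, s2 = b1t.matrix @ u, b2t.matrix @ v
            if s1.std() > 1e-12 and s2.std() > 1e-12:
                train_r[b, k] = float(np.corrcoef(s1, s2)[0, 1])
            if compute_rr:
                load = loading_vector(u, v, b1e, b2e)
                ok = np.isfinite(load) & np.isfinite(full_loadings[k])
                if ok.sum() >= 3:
                    a, c = load[ok], full_loadings[k][ok]
                    if a.std() > 1e-12 and c.std() > 1e-12:
                        rr[b, k] = float(np.corrcoef(a, c)[0, 1])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rr_mean = np.nanmean(rr, axis=0)
        rr_sd = np.nanstd(rr, axis=0, ddof=1)
        overfit = np.nanmean(train_r - test_r, axis=0)
    return ReliabilityReport(
        splithalf_r=test_r, train_r=train_r, rr=rr,
        rr_mean=rr_mean, rr_sd=rr_sd, overfit_index=overfit,
        mode_match=match_rec, n_resamples=n_resamples, seed=seed,
        n_redrawn=n_redrawn,
    )


def sample_size_check(block1: DataBlock, block2: DataBlock,
                      fit_config: FitConfig | None = None,
                      n_grid=(30, 47, 100, 200), seed: int | None = None,
                      n_resamples: int = 50, n_repeats: int = 3,
                      marginal_threshold: float = 0.15):
    """Mode-1 overfitting index as a function of sample size.

    For each n in the grid (at most the available n), participants are
    subsampled ``n_repeats`` times and the split-half overfitting index is
    averaged.  The curve is flagged ``"marginal"`` when the index at the
    largest requested n falls below ``marginal_threshold``, and
    ``"substantial"`` otherwise.
    """
    _check_pair(block1, block2)
    cfg = fit_config or FitConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for n_sub in n_grid:
        if n_sub > block1.n:
            raise ValueError(f"grid n={n_sub} exceeds available n={block1.n}")
        vals = []
        for _ in range(n_repeats):
            idx = rng.choice(block1.n, size=n_sub, replace=False)
            b1 = DataBlock(_standardize(block1.matrix[idx], block1.variable_names),
                           block1.variable_names,
                           [block1.participant_ids[i] for i in idx],
                           state="standardized")
            b2 = DataBlock(_standardize(block2.matrix[idx], block2.variable_names),
                           block2.variable_names,
                           [block2.participant_ids[i] for i in idx],
                           state="standardized")
            rep = split_half(b1, b2, cfg, n_resamples=n_resamples,
                             seed=int(rng.integers(2 ** 31)), compute_rr=False)
            vals.append(rep.overfit_index[0])
        rows.append({"n": n_sub, "overfit_index": float(np.nanmean(vals))})
    curve = pd.DataFrame(rows)
    flag = ("marginal"
            if curve["overfit_index"].iloc[-1] < marginal_threshold
            else "substantial")
    curve.attrs["flag"] = flag
    return curve, flag
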