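"""Post hoc covariate-adjusted correlations and weight-table reporting.

Partial correlations between selected behavioral measures and regional
thickness control for height, weight, BMI, age and sex by residualizing both
sides on the covariates plus an intercept and correlating the residuals;
the p-value comes from the t distribution with n - 2 - q degrees of freedom.
Weight tables follow the reporting convention of listing variables with
|weight| above a threshold (default 0.2) in descending magnitude, while the
full table is always emitted.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .scca import DataBlock, SccaModel, _residualize

__all__ = ["posthoc_correlations", "weight_table", "partial_correlation"]


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        covariates: np.ndarray) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates, with its
    two-sided p-value from t with n - 2 - q df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    Z = np.asarray(covariates, float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n, q = Z.shape
    rx = _residualize(x[:, None], Z)[:, 0]
    ry = _residualize(y[:, None], Z)[:, 0]
    # a side fully explained by the covariates has no partial association left
    if rx.std() < 1e-10 * max(x.std(), 1e-300) or \
       ry.std() < 1e-10 * max(y.std(), 1e-300):
        return 0.0, 1.0
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - q
    if df <= 0:
        return r, float("nan")
    r_ = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_ * np.sqrt(df / (1 - r_ ** 2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p


def posthoc_correlations(measures: DataBlock, thickness: DataBlock,
                         covariates: pd.DataFrame,
                         p_threshold: float = 0.001) -> pd.DataFrame:
    """Partial correlation of every measure with every region.

    ``covariates`` must be complete (no missing values) for all
    participants, aligned with the blocks.  Exact collinearity among
    covariates (e.g. BMI with height and weight) is tolerated: the
    residualization uses a least-squares pseudoinverse and a warning is
    emitted.
    """
    if list(measures.participant_ids) != list(thickness.participant_ids):
        raise ValueError("measure and thickness blocks are not aligned")
    cov_df = covariates.drop(columns=["participant_id"], errors="ignore")
    if cov_df.isna().any().any():
        bad_rows = cov_df.isna().any(axis=1)
        bad = [measures.participant_ids[i] for i in np.where(bad_rows)[0]]
        raise ValueError(f"missing covariate values for participants {bad}")
    Z = cov_df.to_numpy(dtype=float)
    if len(Z) != measures.n:
        raise ValueError("covariate table not aligned with participants")
    Zi = np.column_stack([np.ones(len(Z)), Z])
    if np.linalg.matrix_rank(Zi) < Zi.shape[1]:
        warnings.warn(
            "covariates are exactly collinear; residualization uses a "
            "pseudoinverse", UserWarning, stacklevel=2)

    rows = []
    for i, mname in enumerate(measures.variable_names):
        for j, rname in enumerate(thickness.variable_names):
            r, p = partial_correlation(
                measures.matrix[:, i], thickness.matrix[:, j], Z)
            rows.append({
                "measure_name": mname, "region_name": rname,
                "partial_r": r, "p_uncorrected": p,
                "passes": bool(np.isfinite(p) and p < p_threshold),
            })
    return pd.DataFrame(rows)


def weight_table(model: SccaModel, threshold: float = 0.2) -> dict:
    """Per-mode weight tables for both blocks.

    Returns ``{"block1": {"full": df, "above_threshold": {mode: df}},
    "block2": ...}`` where ``full`` has one row per variable and one weight
    column per mode, and each above-threshold table lists variables with
    |weight| > threshold in descending magnitude.
    """
    out = {}
    for b, names in ((1, model.variable_names1), (2, model.variable_names2)):
        W = model.weights(b)
        full = pd.DataFrame(
            W, index=pd.Index(names, name="variable"),
            columns=[f"mode{m.index}" for m in model.modes]).reset_index()
        above = {}
        for k, m in enumerate(model.modes):
            w = W[:, k]
            sel = np.abs(w) > threshold
            tab = pd.DataFrame({"variable": np.asarray(names)[sel],
                                "weight": w[sel]})
            tab = tab.reindex(
                tab["weight"].abs().sort_values(ascending=False).index
            ).reset_index(drop=True)
            above[m.index] = tab
        out[f"block{b}"] = {"full": full, "above_threshold": above}
    return out
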