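"""Synthetic study generator: two linked data blocks plus raw task responses.

The generator emulates the shape of the study the pipeline targets: n = 47
participants, a 24-variable non-imaging block (8 task measures + 16
questionnaire scale scores), a 62-region cortical-thickness block on a
plausible 1.5-4.5 mm scale, a covariate table (age, sex, height, weight,
BMI) and raw 0-100 likelihood ratings for 4 characters x 32 events.

Cross-block structure follows a Gaussian latent-factor model: for each
planted mode k a latent score z_k and a correlated partner z'_k drive sparse
loading patterns u_k (block 1) and v_k (block 2), plus isotropic Gaussian
noise.  By default the inter-factor correlation is calibrated so that the
*population canonical correlation* between the blocks equals the requested
``latent_correlation`` — i.e. noise attenuation is compensated, within the
approximation of non-overlapping mode supports.

A truth record carries everything needed to score recovery (loading cosine,
support precision/recall, latent-correlation recovery) downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import dkt_region_names
from .scca import DataBlock
from .task_scores import BIAS_COLUMNS, CHARACTERS, TASK_COLUMNS

__all__ = [
    "QUESTIONNAIRE_VARIABLES",
    "NONIMAGING_VARIABLES",
    "PlantedMode",
    "TaskParams",
    "SyntheticSpec",
    "generate_blocks",
    "generate_task_responses",
    "generate_study",
]

QUESTIONNAIRE_VARIABLES = [
    "bas_total", "bis_total",
    "cos_optimism", "cos_pessimism",
    "lot_optimism", "lot_pessimism",
    "erq_suppression", "erq_reappraisal",
    "panas_positive", "panas_negative",
    "rses_total",
    "bfi_neuroticism", "bfi_extraversion", "bfi_openness",
    "bfi_agreeableness", "bfi_conscientiousness",
]

#: the 24 non-imaging variables: 8 task measures + 16 questionnaire scales
NONIMAGING_VARIABLES = BIAS_COLUMNS + QUESTIONNAIRE_VARIABLES


@dataclass
class PlantedMode:
    latent_correlation: float = 0.7
    u: np.ndarray | None = None        # sparse unit-L2 loading over block 1
    v: np.ndarray | None = None        # sparse unit-L2 loading over block 2
    n_nonzero_u: int = 5
    n_nonzero_v: int = 8
    strength: float = 1.0              # latent signal SD on supported columns


@dataclass
class TaskParams:
    """Character-level mean desirable/undesirable likelihoods (0-100 scale).

    Defaults order the group-level biases student ~ elderly > businessperson
    > 0 > alcoholic, the canonical warmth/competence pattern of the task.
    """

    character_means: dict = field(default_factory=lambda: {
        "student": (62.0, 38.0),
        "elderly": (61.0, 39.0),
        "businessperson": (55.0, 47.0),
        "alcoholic": (44.0, 54.0),
    })
    participant_sd: float = 8.0        # participant-level intercept SD
    rating_noise_sd: float = 10.0      # trial-level rating noise SD
    missing_fraction: float = 0.01     # fraction of unanswered trials
    degenerate_fraction: float = 0.0   # fraction of all-50 responders
    bias_coupling: float = 0.25        # latent modulation of bias amplitude


@dataclass
class SyntheticSpec:
    n_participants: int = 47
    n_nonimaging: int = 24
    n_regions: int = 62
    planted_modes: list[PlantedMode] | None = None
    noise_sd: float | tuple[float, float] = 0.3
    signal_strength: float = 1.0       # default PlantedMode strength override
    covariate_effects: dict | None = None
    task_params: TaskParams = field(default_factory=TaskParams)
    calibrate: bool = True
    seed: int = 0

    def modes(self) -> list[PlantedMode]:
        if self.planted_modes is None:
            return [PlantedMode(latent_correlation=0.7,
                                strength=self.signal_strength)]
        return list(self.planted_modes)

    def noise(self) -> tuple[float, float]:
        if isinstance(self.noise_sd, (tuple, list)):
            return float(self.noise_sd[0]), float(self.noise_sd[1])
        return float(self.noise_sd), float(self.noise_sd)


def _sparse_loading(rng, p: int, k_nonzero: int) -> np.ndarray:
    support = rng.choice(p, size=k_nonzero, replace=False)
    vals = rng.normal(size=k_nonzero)
    vals += np.sign(vals.sum() or 1.0) * 0.5  # avoid near-cancelling patterns
    w = np.zeros(p)
    w[support] = vals
    return w / np.linalg.norm(w)


def _participant_ids(n: int) -> list[str]:
    return [f"P{i + 1:03d}" for i in range(n)]


def generate_blocks(spec: SyntheticSpec, seed: int | None = None):
    """Draw the non-imaging and thickness blocks plus covariates and truth.

    Returns ``(nonimaging, thickness, covariates, truth)`` where the blocks
    are raw-state :class:`DataBlock` objects and ``truth`` is a plain dict.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n, p1, p2 = spec.n_participants, spec.n_nonimaging, spec.n_regions
    modes = spec.modes()
    if len(modes) > min(p1, p2):
        raise ValueError(
            f"{len(modes)} planted modes exceed min(p1, p2)={min(p1, p2)}")
    s1, s2 = spec.noise()

    U = np.zeros((p1, len(modes)))
    V = np.zeros((p2, len(modes)))
    rho_factor = np.zeros(len(modes))
    atten = np.zeros(len(modes))
    for k, m in enumerate(modes):
        if not 0.0 <= m.latent_correlation <= 1.0:
            raise ValueError("latent_correlation must lie in [0, 1]")
        u = (_sparse_loading(rng, p1, m.n_nonzero_u) if m.u is None
             else np.asarray(m.u, float) / np.linalg.norm(m.u))
        v = (_sparse_loading(rng, p2, m.n_nonzero_v) if m.v is None
             else np.asarray(m.v, float) / np.linalg.norm(m.v))
        U[:, k], V[:, k] = u, v
        a = m.strength
        a1 = a / np.hypot(a, s1)
        a2 = a / np.hypot(a, s2)
        atten[k] = a1 * a2
        if spec.calibrate:
            rho_f = m.latent_correlation / (a1 * a2)
            if rho_f > 1.0 + 1e-6:
                raise ValueError(
                    f"mode {k + 1}: latent_correlation "
                    f"{m.latent_correlation} not attainable at noise "
                    f"({s1}, {s2}); maximum is {a1 * a2:.3f}")
            rho_factor[k] = min(rho_f, 1.0)
        else:
            rho_factor[k] = m.latent_correlation

    z1 = rng.standard_normal((n, len(modes)))
    eps = rng.standard_normal((n, len(modes)))
    z2 = z1 * rho_factor + eps * np.sqrt(1.0 - rho_factor ** 2)
    strengths = np.array([m.strength for m in modes])

    X1 = (z1 * strengths) @ U.T + s1 * rng.standard_normal((n, p1))
    X2 = (z2 * strengths) @ V.T + s2 * rng.standard_normal((n, p2))

    ids = _participant_ids(n)
    covariates = _draw_covariates(rng, n, ids)

    # thickness on a plausible mm scale, optionally confounded by covariates
    thick = 2.7 + 0.25 * X2
    if spec.covariate_effects:
        for name, effect in spec.covariate_effects.items():
            if name not in covariates.columns:
                raise ValueError(f"unknown covariate {name!r}")
            c = covariates[name].to_numpy(dtype=float)
            c = (c - c.mean()) / (c.std() or 1.0)
            sensitivity = rng.uniform(0.5, 1.5, size=p2)
            thick = thick + effect * np.outer(c, sensitivity)
    thick = np.clip(thick, 1.5, 4.5)

    names1 = (list(NONIMAGING_VARIABLES) if p1 == len(NONIMAGING_VARIABLES)
              else [f"x{i + 1:03d}" for i in range(p1)])
    names2 = (dkt_region_names() if p2 == 62
              else [f"region{i + 1:03d}" for i in range(p2)])

    nonimaging = DataBlock(X1, names1, ids, state="raw")
    thickness = DataBlock(thick, names2, ids, state="raw")
    truth = {
        "u_true": U.T.tolist(),
        "v_true": V.T.tolist(),
        "latent_correlation": [m.latent_correlation for m in modes],
        "factor_correlation": rho_factor.tolist(),
        "attenuation": atten.tolist(),
        "strength": strengths.tolist(),
        "noise_sd": [s1, s2],
        "calibrated": spec.calibrate,
        "factors_block1": z1.tolist(),
        "factors_block2": z2.tolist(),
    }
    return nonimaging, thickness, covariates, truth


def _draw_covariates(rng, n: int, ids: list[str]) -> pd.DataFrame:
    age = np.clip(rng.normal(23.1, 4.0, size=n), 19, 36)
    sex = (rng.random(n) < 20 / 47).astype(int)  # 1 = male
    height = np.where(sex == 1, rng.normal(178, 7, n), rng.normal(165, 6, n))
    weight = 22.5 * (height / 100) ** 2 + rng.normal(0, 2.5, n)
    bmi = weight / (height / 100) ** 2
    return pd.DataFrame({
        "participant_id": ids,
        "height": np.round(height, 1),
        "weight": np.round(weight, 1),
        "bmi": np.round(bmi, 2),
        "age": np.round(age, 1),
        "sex": sex,
    })


def generate_task_responses(spec: SyntheticSpec, seed: int | None = None,
                            latent: np.ndarray | None = None) -> pd.DataFrame:
    """Raw per-trial likelihood ratings (long format).

    Ratings are character/valence mean + participant intercept + noise,
    clipped to [0, 100].  When ``latent`` (one score per participant) is
    given, each participant's desirable-undesirable gap is scaled by
    ``1 + bias_coupling * latent``, coupling the task-derived bias measures
    to the planted latent factor.  A configurable fraction of trials is
    unanswered and a configurable fraction of participants answers 50
    throughout, to exercise the cleaning rules.
    """
    tp = spec.task_params
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    n = spec.n_participants
    ids = _participant_ids(n)
    if latent is None:
        amplitude = np.ones(n)
    else:
        latent = np.asarray(latent, float)
        if latent.shape != (n,):
            raise ValueError("latent must have one score per participant")
        amplitude = 1.0 + tp.bias_coupling * latent
    intercept = rng.normal(0.0, tp.participant_sd, size=n)

    n_events = 32
    event_ids = np.arange(1, n_events + 1)
    valence = np.where(event_ids <= 16, "desirable", "undesirable")

    frames = []
    for char in CHARACTERS:
        des_mean, undes_mean = tp.character_means[char]
        base = 0.5 * (des_mean + undes_mean)
        gap = des_mean - undes_mean
        # (n, 32): per-participant bias amplitude scales the valence gap
        sign = np.where(valence == "desirable", 0.5, -0.5)
        mu = (base + intercept[:, None]
              + np.outer(amplitude, np.full(n_events, gap)) * sign)
        ratings = mu + rng.normal(0.0, tp.rating_noise_sd, size=(n, n_events))
        ratings = np.clip(ratings, 0.0, 100.0)
        frames.append(pd.DataFrame({
            "participant_id": np.repeat(ids, n_events),
            "character": char,
            "event_id": np.tile(event_ids, n),
            "valence": np.tile(valence, n),
            "likelihood": ratings.ravel(),
        }))
    table = pd.concat(frames, ignore_index=True)

    n_degenerate = int(round(tp.degenerate_fraction * n))
    if n_degenerate:
        chosen = rng.choice(ids, size=n_degenerate, replace=False)
        table.loc[table["participant_id"].isin(chosen), "likelihood"] = 50.0

    if tp.missing_fraction > 0:
        miss = rng.random(len(table)) < tp.missing_fraction
        table.loc[miss, "likelihood"] = np.nan

    return table[TASK_COLUMNS]


def generate_study(spec: SyntheticSpec, seed: int | None = None) -> dict:
    """All pipeline inputs at once, mutually consistent.

    Returns a dict with keys ``task``, ``questionnaire``, ``nonimaging``,
    ``thickness``, ``covariates``, ``truth``.  The questionnaire table holds
    the 16 scale columns of the non-imaging block; the raw task responses
    are coupled to the first planted latent factor through
    ``task_params.bias_coupling`` so the end-to-end pipeline (task scoring
    included) sees a real cross-block association.
    """
    base = spec.seed if seed is None else seed
    nonimaging, thickness, covariates, truth = generate_blocks(spec, seed=base)
    z1 = np.asarray(truth["factors_block1"])[:, 0]
    task = generate_task_responses(spec, seed=base + 1, latent=z1)
    q_cols = [c for c in nonimaging.variable_names
              if c in QUESTIONNAIRE_VARIABLES]
    qdf = nonimaging.to_dataframe()[["participant_id"] + q_cols]
    return {
        "task": task,
        "questionnaire": qdf,
        "nonimaging": nonimaging,
        "thickness": thickness,
        "covariates": covariates,
        "truth": truth,
    }
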