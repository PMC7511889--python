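"""Cleaning and scoring of the social-optimism-bias likelihood task.

Participants rate, on a 0-100 visual-analog scale, how likely each of four
fictional characters (student = implicit in-group; elderly, businessperson
and alcoholic = out-groups of increasing social distance) is to experience
each of 32 life events, 16 desirable and 16 undesirable.

Eight measures are derived per participant:

* ``desirable_avg`` / ``undesirable_avg`` — raw-scale mean likelihood across
  all characters for desirable and undesirable events;
* four per-character optimism biases — mean(desirable) - mean(undesirable)
  computed on likelihoods z-standardized across all of the participant's
  ratings (both valences, all characters);
* ``warmth_bias`` — (student + elderly) - (businessperson + alcoholic) biases;
* ``bias_magnitude`` — student + elderly + businessperson biases plus the
  inverted alcoholic bias (the alcoholic bias is typically a pessimism bias).

Cleaning removes participants who lean on the scale anchors or the default:
ratings equal to 1, 50 or 99 (after rounding) are pooled into one flag
proportion, and participants more than ``z_threshold`` sample SDs above the
sample mean proportion are excluded.  Trials without an answer are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CHARACTERS",
    "WARM_CHARACTERS",
    "COLD_CHARACTERS",
    "TASK_COLUMNS",
    "BIAS_COLUMNS",
    "BiasProfile",
    "CleaningReport",
    "clean_task_table",
    "compute_bias_profile",
    "compute_bias_profiles",
]

CHARACTERS = ("student", "elderly", "businessperson", "alcoholic")
WARM_CHARACTERS = ("student", "elderly")
COLD_CHARACTERS = ("businessperson", "alcoholic")
FLAG_VALUES = (1, 50, 99)

TASK_COLUMNS = ["participant_id", "character", "event_id", "valence", "likelihood"]

#: order of the eight task measures in the wide output table
BIAS_COLUMNS = [
    "desirable_avg", "undesirable_avg",
    "bias_student", "bias_elderly", "bias_business", "bias_alcoholic",
    "warmth_bias", "bias_magnitude",
]

_BIAS_KEY = {
    "student": "bias_student",
    "elderly": "bias_elderly",
    "businessperson": "bias_business",
    "alcoholic": "bias_alcoholic",
}


@dataclass
class BiasProfile:
    desirable_avg: float
    undesirable_avg: float
    bias_student: float
    bias_elderly: float
    bias_business: float
    bias_alcoholic: float
    warmth_bias: float
    bias_magnitude: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in BIAS_COLUMNS}


@dataclass
class CleaningReport:
    excluded_participants: list = field(default_factory=list)  # (id, rule)
    excluded_trial_fraction: float = 0.0
    flag_proportions: dict = field(default_factory=dict)
    z_threshold: float = 3.0
    flag_threshold: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "excluded_participants": [
                {"participant_id": pid, "rule": rule}
                for pid, rule in self.excluded_participants
            ],
            "excluded_trial_fraction": self.excluded_trial_fraction,
            "flag_proportions": {str(k): v for k, v in self.flag_proportions.items()},
            "z_threshold": self.z_threshold,
            "flag_threshold": self.flag_threshold,
        }


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TASK_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"task table lacks columns {missing}")
    if len(table) == 0:
        raise ValueError("task table is empty")
    bad_char = set(table["character"]) - set(CHARACTERS)
    if bad_char:
        raise ValueError(f"unknown character labels {sorted(bad_char)}")
    bad_val = set(table["valence"]) - {"desirable", "undesirable"}
    if bad_val:
        raise ValueError(f"unknown valence labels {sorted(bad_val)}")
    lk = table["likelihood"]
    present = lk.notna()
    if ((lk[present] < 0) | (lk[present] > 100)).any():
        raise ValueError("likelihood values outside [0, 100]")
    return table


def clean_task_table(raw: pd.DataFrame, z_threshold: float = 3.0
                     ) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the anchor/default exclusion rule and drop unanswered trials.

    Flag proportions are computed on answered trials, before unanswered
    trials are removed; a participant is excluded when their pooled
    proportion of ratings in {1, 50, 99} exceeds the sample mean plus
    ``z_threshold`` sample standard deviations.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    raw = _validate(raw)

    answered = raw[raw["likelihood"].notna()]
    flagged = answered["likelihood"].round().isin(FLAG_VALUES)
    prop = flagged.groupby(answered["participant_id"]).mean()
    prop = prop.reindex(raw["participant_id"].unique(), fill_value=0.0)

    mean, sd = float(prop.mean()), float(prop.std(ddof=1))
    if not np.isfinite(sd):
        sd = 0.0
    cutoff = mean + z_threshold * sd
    excluded_ids = prop.index[prop > cutoff].tolist()

    report = CleaningReport(
        excluded_participants=[
            (pid, f"flag proportion {prop[pid]:.3f} > mean+{z_threshold:g}SD "
                  f"({cutoff:.3f})")
            for pid in excluded_ids
        ],
        flag_proportions=prop.to_dict(),
        z_threshold=z_threshold,
        flag_threshold=cutoff,
    )

    kept = raw[~raw["participant_id"].isin(excluded_ids)]
    n_before = len(kept)
    cleaned = kept[kept["likelihood"].notna()].reset_index(drop=True)
    report.excluded_trial_fraction = (
        (n_before - len(cleaned)) / n_before if n_before else 0.0
    )

    if cleaned["participant_id"].nunique() < 3:
        raise ValueError(
            f"only {cleaned['participant_id'].nunique()} participants remain "
            "after cleaning; at least 3 required"
        )
    return cleaned, report


def compute_bias_profile(cleaned: pd.DataFrame, participant) -> BiasProfile:
    """The eight task measures for one participant of a cleaned table."""
    rows = cleaned[cleaned["participant_id"] == participant]
    if len(rows) == 0:
        raise KeyError(f"participant {participant!r} not in table")
    lk = rows["likelihood"].to_numpy(dtype=float)
    if np.isnan(lk).any():
        raise ValueError("table contains unanswered trials; clean it first")
    sd = lk.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(
            f"participant {participant!r} has zero rating variance; "
            "z-scores undefined"
        )
    z = (lk - lk.mean()) / sd

    des = rows["valence"].to_numpy() == "desirable"
    char = rows["character"].to_numpy()
    biases = {}
    for c in CHARACTERS:
        mask = char == c
        if not mask.any():
            raise ValueError(f"participant {participant!r} has no '{c}' trials")
        if not (mask & des).any() or not (mask & ~des).any():
            raise ValueError(
                f"participant {participant!r} lacks a valence for '{c}'"
            )
        biases[c] = float(z[mask & des].mean() - z[mask & ~des].mean())

    warmth = sum(biases[c] for c in WARM_CHARACTERS) - sum(
        biases[c] for c in COLD_CHARACTERS)
    magnitude = (biases["student"] + biases["elderly"]
                 + biases["businessperson"] - biases["alcoholic"])
    return BiasProfile(
        desirable_avg=float(lk[des].mean()),
        undesirable_avg=float(lk[~des].mean()),
        bias_student=biases["student"],
        bias_elderly=biases["elderly"],
        bias_business=biases["businessperson"],
        bias_alcoholic=biases["alcoholic"],
        warmth_bias=float(warmth),
        bias_magnitude=float(magnitude),
    )


def compute_bias_profiles(cleaned: pd.DataFrame) -> pd.DataFrame:
    """Wide table of the eight measures, one row per participant."""
    ids = cleaned["participant_id"].unique()
    records = {pid: compute_bias_profile(cleaned, pid).as_dict() for pid in ids}
    out = pd.DataFrame.from_dict(records, orient="index", columns=BIAS_COLUMNS)
    out.index.name = "participant_id"
    return out.reset_index()
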