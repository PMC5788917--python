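"""Domain types, rating transforms, participant filtering, and CSV I/O.

The experiment collects attractiveness ratings on a hidden 0-100 slider, one
trial per (participant, image).  Each trial records the rater's initial
rating, the peer rating displayed to them (formed from other group members'
initial ratings under one of three rules), and their final rating.  Before
modelling, raw ratings are squeezed into the open unit interval with the
affine map ``y = (x/100)*0.999 + 0.0005`` so a beta likelihood applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Stimulus conditions, in canonical order.
CONDITIONS = ("face", "hand", "art")

#: Rules for forming the displayed peer rating from the other group members'
#: initial ratings: mean of all, mean of the highest two, mean of the lowest two.
SOCIAL_RULES = ("all", "top2", "bottom2")

RATING_MAX = 100.0
#: Slope of the unit-interval squeeze.
SQUEEZE = 0.999
#: Offset of the unit-interval squeeze.
OFFSET = 0.0005
#: Image of 0 and 100 under the squeeze (0.9995 = SQUEEZE + OFFSET exactly
#: in decimal; binary rounding puts the computed sum one ulp below).
UNIT_MIN = OFFSET
UNIT_MAX = 0.9995
_UNIT_TOL = 1e-12

TRIAL_COLUMNS = [
    "participant_id",
    "group_id",
    "block_index",
    "condition",
    "image_id",
    "social_rule",
    "initial_raw",
    "social_raw",
    "final_raw",
]
PARTICIPANT_COLUMNS = ["participant_id", "group_id", "orientation_score"]

RATING_COLUMNS = ["initial_raw", "social_raw", "final_raw"]


class ValidationError(ValueError):
    """A value violates a domain invariant."""


class LoadError(ValueError):
    """A CSV file cannot be parsed into a valid trial table."""


def transform_rating(x):
    """Map a raw 0-100 rating onto (0, 1) via ``(x/100)*0.999 + 0.0005``.

    Accepts scalars or arrays; strictly increasing; [0, 100] maps onto
    [0.0005, 0.9995] so the endpoints stay interior to the beta support.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > RATING_MAX) or np.any(np.isnan(arr)):
        bad = arr[~((arr >= 0.0) & (arr <= RATING_MAX))]
        raise ValidationError(
            f"rating outside [0, {RATING_MAX:g}]: {np.atleast_1d(bad)[0]!r}"
        )
    out = (arr / RATING_MAX) * SQUEEZE + OFFSET
    return out if isinstance(x, np.ndarray) else float(out) if out.ndim == 0 else out


def inverse_transform(y):
    """Invert :func:`transform_rating`, mapping [0.0005, 0.9995] back to [0, 100]."""
    arr = np.asarray(y, dtype=float)
    ok = (arr >= UNIT_MIN - _UNIT_TOL) & (arr <= UNIT_MAX + _UNIT_TOL)
    if not np.all(ok) or np.any(np.isnan(arr)):
        bad = arr[~ok]
        raise ValidationError(
            f"unit value outside [{UNIT_MIN}, {UNIT_MAX}]: {np.atleast_1d(bad)[0]!r}"
        )
    out = np.clip((arr - OFFSET) / SQUEEZE * RATING_MAX, 0.0, RATING_MAX)
    return out if isinstance(y, np.ndarray) else float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RatingTrial:
    """One experimental observation: a participant rating one image."""

    participant_id: str
    group_id: str
    block_index: int
    condition: str
    image_id: str
    social_rule: str
    initial_raw: float
    social_raw: float
    final_raw: float

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.social_rule not in SOCIAL_RULES:
            raise ValidationError(f"unknown social rule {self.social_rule!r}")
        if self.block_index < 1:
            raise ValidationError(f"block_index must be >= 1, got {self.block_index}")
        for name in RATING_COLUMNS:
            v = getattr(self, name)
            if not 0.0 <= v <= RATING_MAX:
                raise ValidationError(f"{name}={v!r} outside [0, {RATING_MAX:g}]")


@dataclass(frozen=True)
class ParticipantRecord:
    """Participant metadata: group membership and sexual-orientation score.

    The orientation score is the 7-point self-report scale where 0 is
    exclusively heterosexual and 6 exclusively homosexual.
    """

    participant_id: str
    group_id: str
    orientation_score: int

    def __post_init__(self):
        if self.orientation_score not in range(7):
            raise ValidationError(
                f"orientation_score must be in 0..6, got {self.orientation_score!r}"
            )


def _validate_trials_frame(trials: pd.DataFrame, source: str = "trials") -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise LoadError(f"{source}: missing column(s) {missing}")
    trials = trials[TRIAL_COLUMNS].copy()
    for col in RATING_COLUMNS:
        vals = pd.to_numeric(trials[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals > RATING_MAX)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise LoadError(
                f"{source}: column {col!r}, row {row + 1}: "
                f"value {trials[col].iloc[row]!r} is not a rating in [0, 100]"
            )
        trials[col] = vals.astype(float)
    for col, allowed in [("condition", CONDITIONS), ("social_rule", SOCIAL_RULES)]:
        bad = ~trials[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise LoadError(
                f"{source}: column {col!r}, row {row + 1}: "
                f"value {trials[col].iloc[row]!r} not in {allowed}"
            )
    trials["block_index"] = pd.to_numeric(trials["block_index"]).astype(int)
    for col in ("participant_id", "group_id", "image_id"):
        trials[col] = trials[col].astype(str)
    return trials


def _validate_participants_frame(
    participants: pd.DataFrame, source: str = "participants"
) -> pd.DataFrame:
    missing = [c for c in PARTICIPANT_COLUMNS if c not in participants.columns]
    if missing:
        raise LoadError(f"{source}: missing column(s) {missing}")
    participants = participants[PARTICIPANT_COLUMNS].copy()
    scores = pd.to_numeric(participants["orientation_score"], errors="coerce")
    bad = scores.isna() | ~scores.isin(range(7))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise LoadError(
            f"{source}: column 'orientation_score', row {row + 1}: "
            f"value {participants['orientation_score'].iloc[row]!r} not in 0..6"
        )
    participants["orientation_score"] = scores.astype(int)
    for col in ("participant_id", "group_id"):
        participants[col] = participants[col].astype(str)
    return participants


@dataclass
class Dataset:
    """A trial table plus participant metadata, validated on construction.

    ``trials`` has one row per (participant, image) with the columns in
    :data:`TRIAL_COLUMNS`; ``participants`` has one row per participant with
    the columns in :data:`PARTICIPANT_COLUMNS`.
    """

    trials: pd.DataFrame
    participants: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.trials = _validate_trials_frame(pd.DataFrame(self.trials))
        if self.participants is None:
            # Derive minimal metadata (all exclusively heterosexual) from trials.
            self.participants = (
                self.trials[["participant_id", "group_id"]]
                .drop_duplicates()
                .assign(orientation_score=0)
            )
        self.participants = _validate_participants_frame(pd.DataFrame(self.participants))
        if self.participants["participant_id"].duplicated().any():
            raise ValidationError("duplicate participant_id in participants table")
        known = set(self.participants["participant_id"])
        unknown = set(self.trials["participant_id"]) - known
        if unknown:
            raise ValidationError(
                f"trials reference unknown participant(s): {sorted(unknown)[:5]}"
            )
        dup = self.trials.duplicated(subset=["participant_id", "image_id"])
        if dup.any():
            pair = self.trials.loc[dup, ["participant_id", "image_id"]].iloc[0]
            raise ValidationError(
                f"duplicate (participant_id, image_id) pair: {tuple(pair)}"
            )
        self.trials = self.trials.reset_index(drop=True)
        self.participants = self.participants.reset_index(drop=True)

    @classmethod
    def from_records(cls, trials, participants=None) -> "Dataset":
        """Build from iterables of :class:`RatingTrial` / :class:`ParticipantRecord`."""
        tdf = pd.DataFrame([vars(t) if not isinstance(t, dict) else t for t in trials])
        pdf = None
        if participants is not None:
            pdf = pd.DataFrame(
                [vars(p) if not isinstance(p, dict) else p for p in participants]
            )
        return cls(tdf, pdf)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def transformed(self) -> pd.DataFrame:
        """Trial table with unit-interval columns ``initial_u/social_u/final_u`` added."""
        out = self.trials.copy()
        for raw, unit in [
            ("initial_raw", "initial_u"),
            ("social_raw", "social_u"),
            ("final_raw", "final_u"),
        ]:
            out[unit] = transform_rating(out[raw].to_numpy())
        return out

    def copy(self) -> "Dataset":
        return Dataset(self.trials.copy(), self.participants.copy())


def filter_heterosexual(dataset: Dataset, max_score: int = 1) -> Dataset:
    """Keep participants with orientation_score <= ``max_score`` and their trials.

    The default threshold of 1 retains exclusively or near-exclusively
    heterosexual raters, the study's primary analysis sample; ``max_score=6``
    is the all-participants robustness variant.  The input is not modified.
    """
    if max_score not in range(7):
        raise ValidationError(f"max_score must be in 0..6, got {max_score!r}")
    keep = dataset.participants[
        dataset.participants["orientation_score"] <= max_score
    ].copy()
    ids = set(keep["participant_id"])
    trials = dataset.trials[dataset.trials["participant_id"].isin(ids)].copy()
    return Dataset(trials.reset_index(drop=True), keep.reset_index(drop=True))


def read_trials(trials_path, participants_path=None) -> Dataset:
    """Load a Dataset from a trial CSV and (optionally) a participant CSV.

    Raises :class:`LoadError` naming the column and 1-based data row for any
    missing column, unparseable rating, or rating outside [0, 100].
    """
    try:
        tdf = pd.read_csv(trials_path, dtype=str)
    except Exception as exc:  # pragma: no cover - passthrough context
        raise LoadError(f"cannot read {trials_path}: {exc}") from exc
    tdf = _validate_trials_frame(tdf, source=str(trials_path))
    pdf = None
    if participants_path is not None:
        try:
            pdf = pd.read_csv(participants_path, dtype=str)
        except Exception as exc:  # pragma: no cover
            raise LoadError(f"cannot read {participants_path}: {exc}") from exc
        pdf = _validate_participants_frame(pdf, source=str(participants_path))
    return Dataset(tdf, pdf)


def write_trials(dataset: Dataset, trials_path, participants_path=None) -> None:
    """Write the trial (and optionally participant) tables as CSV.

    Floats are written with ``repr`` precision so a read/write round trip is
    exact field-for-field.
    """
    dataset.trials.to_csv(trials_path, index=False)
    if participants_path is not None:
        dataset.participants.to_csv(participants_path, index=False)
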