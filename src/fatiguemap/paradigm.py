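"""Task-switching paradigm: event schedules and rating-derived regressor amplitudes.

The experimental design is a multi-run event-related task-switching paradigm.
Every trial occupies a fixed 8 s slot: a 500 ms cue, a jittered cue-to-target
interval (CTI), a 1 s imperative stimulus, and a filler inter-trial interval.
Each of the two tasks (a colour judgment and a speed judgment) is announced by
one of two synonymous cues so that task switches are not confounded with cue
switches; a fraction of trials are "empty" baseline trials that present the cue
word ``Empty`` and no stimulus.

Subjective state ratings (fatigue, happiness, sadness, tension, anger, pain)
are collected on a 0-100 visual-analogue scale before and after every run,
giving seven boundary values for a six-run session (the post-run-i rating is
the pre-run-(i+1) rating).  Per-event regressor amplitudes are obtained by
linear interpolation of the two boundary ratings across the run and division
by 100, so an event halfway through a run rated 0 before and 40 after receives
amplitude 0.20.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

#: canonical trial timing (seconds)
TRIAL_DURATION_S = 8.0
CUE_DURATION_S = 0.5
STIMULUS_DURATION_S = 1.0
CTI_RANGE_S = (1.5, 3.5)

#: the six rating scales collected at every run boundary
RATING_SCALES = ("fatigue", "happiness", "sadness", "tension", "anger", "pain")

#: cue synonyms per task; empty trials carry the cue "Empty" and no stimulus
TASK_CUES = {
    "color-judgment": ("color", "hue"),
    "speed-judgment": ("speed", "velocity"),
}
EMPTY_TASK = "empty"
EMPTY_CUE = "Empty"

#: number of rating boundaries for an ``n_runs``-run session is ``n_runs + 1``
N_BOUNDARIES = 7


@dataclass(frozen=True)
class EventSchedule:
    """Per-trial schedule of a multi-run event-related design.

    ``events`` has one row per trial with columns ``run`` (1-based),
    ``trial`` (1-based within run), ``onset_s`` (seconds from task-period
    start of the run), ``cue``, ``task``, ``cti_s``, ``cue_s``,
    ``stimulus_s`` and ``trial_s``.
    """

    events: pd.DataFrame
    trial_duration_s: float = TRIAL_DURATION_S

    @property
    def n_runs(self) -> int:
        return int(self.events["run"].max())

    @property
    def trials_per_run(self) -> int:
        return int((self.events["run"] == 1).sum())

    @property
    def n_trials(self) -> int:
        return len(self.events)

    @property
    def task_period_s(self) -> float:
        """Duration of the task period of one run (trials are contiguous)."""
        return self.trials_per_run * self.trial_duration_s

    def run_events(self, run: int) -> pd.DataFrame:
        return self.events[self.events["run"] == run]

    def to_tsv(self, path) -> None:
        cols = ["run", "trial", "onset_s", "cue", "task", "cti_s"]
        self.events[cols].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EventSchedule":
        df = pd.read_csv(path, sep="\t")
        required = {"run", "trial", "onset_s", "cue", "task", "cti_s"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"schedule table missing columns: {sorted(missing)}")
        return cls(events=df.reset_index(drop=True))


@dataclass(frozen=True)
class RatingSeries:
    """Run-boundary ratings for one subject on one 0-100 scale.

    ``values[t]`` is the rating at boundary ``t``; ``t = 0`` precedes run 1
    and ``t = i`` follows run ``i`` (identically preceding run ``i+1``).
    """

    subject_id: str
    scale: str
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def n_runs(self) -> int:
        return len(self.values) - 1

    def pre(self, run: int) -> float:
        return float(self.values[run - 1])

    def post(self, run: int) -> float:
        return float(self.values[run])


@dataclass(frozen=True)
class AmplitudeSeries:
    """Per-event regressor amplitudes in [0, 1], aligned with a schedule."""

    scale: str
    amplitudes: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=float))

    def __len__(self) -> int:
        return len(self.amplitudes)


def generate_schedule(
    n_runs: int = 6,
    trials_per_run: int = 32,
    trial_duration_s: float = TRIAL_DURATION_S,
    cue_duration_s: float = CUE_DURATION_S,
    cti_range_s: tuple[float, float] = CTI_RANGE_S,
    stimulus_duration_s: float = STIMULUS_DURATION_S,
    empty_trial_fraction: float = 1.0 / 8.0,
    seed: int = 0,
) -> EventSchedule:
    """Generate a randomized task-switching schedule.

    Trials are contiguous ``trial_duration_s`` slots; tasks are drawn
    uniformly (empty trials at ``empty_trial_fraction``), the cue is chosen
    uniformly between the two synonyms of the drawn task, and the CTI is
    drawn uniformly from ``cti_range_s``.  Deterministic given ``seed``.
    """
    if n_runs < 1 or trials_per_run < 1:
        raise ConfigurationError("n_runs and trials_per_run must be >= 1")
    if not 0 <= empty_trial_fraction < 1:
        raise ConfigurationError("empty_trial_fraction must be in [0, 1)")
    lo, hi = cti_range_s
    if not (0 < lo <= hi):
        raise ConfigurationError("cti_range_s must satisfy 0 < lo <= hi")
    budget = trial_duration_s - cue_duration_s - stimulus_duration_s
    if hi > budget:
        raise ConfigurationError(
            "invalid timing budget: cue_duration_s + max CTI + stimulus_duration_s "
            f"= {cue_duration_s + hi + stimulus_duration_s:g} s exceeds "
            f"trial_duration_s = {trial_duration_s:g} s"
        )

    rng = np.random.default_rng(seed)
    tasks = list(TASK_CUES)
    rows = []
    for run in range(1, n_runs + 1):
        for trial in range(1, trials_per_run + 1):
            onset = (trial - 1) * trial_duration_s
            if rng.random() < empty_trial_fraction:
                task, cue, stim = EMPTY_TASK, EMPTY_CUE, 0.0
            else:
                task = tasks[rng.integers(len(tasks))]
                cue = TASK_CUES[task][rng.integers(2)]
                stim = stimulus_duration_s
            cti = float(rng.uniform(lo, hi))
            rows.append(
                dict(
                    run=run,
                    trial=trial,
                    onset_s=onset,
                    cue=cue,
                    task=task,
                    cti_s=cti,
                    cue_s=cue_duration_s,
                    stimulus_s=stim,
                    trial_s=trial_duration_s,
                )
            )
    return EventSchedule(events=pd.DataFrame(rows), trial_duration_s=trial_duration_s)


def build_rating_series(
    values,
    subject_id: str = "sub-01",
    scale: str = "fatigue",
    n_boundaries: int = N_BOUNDARIES,
) -> RatingSeries:
    """Validate and package run-boundary ratings.

    Raises :class:`ValidationError` when the count differs from
    ``n_boundaries`` or any value leaves [0, 100], naming the offenders.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or len(arr) != n_boundaries:
        raise ValidationError(
            f"expected {n_boundaries} boundaries, got {arr.size} for "
            f"subject {subject_id!r} scale {scale!r}"
        )
    bad = np.flatnonzero((arr < 0) | (arr > 100) | ~np.isfinite(arr))
    if bad.size:
        offending = ", ".join(f"index {i}: {arr[i]!r}" for i in bad)
        raise ValidationError(f"ratings outside [0, 100]: {offending}")
    return RatingSeries(subject_id=subject_id, scale=scale, values=arr)


def interpolate_amplitudes(
    schedule: EventSchedule,
    ratings: RatingSeries,
    run_duration_s: float | None = None,
) -> AmplitudeSeries:
    """Linearly interpolate run-boundary ratings to per-event amplitudes.

    An event at fraction ``f = onset / run_duration`` of its run (the task
    period, ``trials_per_run * trial_duration`` by default) receives
    ``(pre + f * (post - pre)) / 100``, so amplitudes lie in [0, 1] for
    ratings in [0, 100] and match the boundary ratings exactly at ``f = 0``
    and ``f = 1``.
    """
    if ratings.n_runs != schedule.n_runs:
        raise ValidationError(
            f"rating series spans {ratings.n_runs} runs "
            f"but schedule has {schedule.n_runs}"
        )
    if np.any(ratings.values < 0) or np.any(ratings.values > 100):
        raise ValidationError("ratings outside [0, 100]")
    period = schedule.task_period_s if run_duration_s is None else float(run_duration_s)
    last = schedule.events.groupby("run")["onset_s"].max().max()
    if period < last + schedule.trial_duration_s - 1e-9:
        raise ValidationError(
            f"run_duration_s={period:g} shorter than the scheduled trials"
        )
    runs = schedule.events["run"].to_numpy()
    f = schedule.events["onset_s"].to_numpy() / period
    pre = ratings.values[runs - 1]
    post = ratings.values[runs]
    amps = (pre + f * (post - pre)) / 100.0
    return AmplitudeSeries(scale=ratings.scale, amplitudes=amps)


def ratings_to_tsv(series_list: list[RatingSeries], path) -> None:
    """Write rating series as a table (subject, scale, t0..t6)."""
    rows = []
    for s in series_list:
        row = {"subject": s.subject_id, "scale": s.scale}
        row.update({f"t{i}": v for i, v in enumerate(s.values)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def ratings_from_tsv(path) -> list[RatingSeries]:
    df = pd.read_csv(path, sep="\t")
    tcols = sorted((c for c in df.columns if c.startswith("t") and c[1:].isdigit()),
                   key=lambda c: int(c[1:]))
    out = []
    for _, row in df.iterrows():
        out.append(
            build_rating_series(
                [row[c] for c in tcols],
                subject_id=str(row["subject"]),
                scale=str(row["scale"]),
                n_boundaries=len(tcols),
            )
        )
    return out
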