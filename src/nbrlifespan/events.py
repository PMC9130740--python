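"""Event schedules for the rapid event-related sensorimotor paradigm.

The task is an audiovisual detection paradigm: brief (50 ms) stimuli on a 2 s
grid with pseudo-random null gaps, giving stimulus onset asynchronies from
2 s up to 26 s.  Five conditions are used: audio alone, visual alone, and
three audiovisual tone frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The five stimulus conditions (audio-only, visual-only, audiovisual tones).
CONDITIONS = ("audio", "visual", "av300", "av600", "av1200")

#: Conditions of bimodal (audiovisual) trials.
BIMODAL_CONDITIONS = ("av300", "av600", "av1200")

#: Minimal stimulus onset asynchrony enforced on every schedule, seconds.
MIN_SOA = 2.0

#: Default acquisition: 261 volumes at TR = 1.97 s.
DEFAULT_TR = 1.97
DEFAULT_N_VOLUMES = 261
DEFAULT_RUN_LENGTH = DEFAULT_TR * DEFAULT_N_VOLUMES

#: Stimulus (neural input) duration, seconds.
EVENT_DURATION = 0.05


@dataclass(frozen=True)
class EventSchedule:
    """Trial onsets, durations and condition labels for one fMRI run.

    Invariants: onsets strictly increasing, every inter-onset interval at
    least :data:`MIN_SOA`, and every trial finishes before ``run_length``.
    """

    onsets: np.ndarray
    durations: np.ndarray
    conditions: tuple[str, ...]
    run_length: float = DEFAULT_RUN_LENGTH

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "durations", durations)
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if onsets.ndim != 1 or durations.shape != onsets.shape:
            raise ValueError("onsets and durations must be 1-D and congruent")
        if len(self.conditions) != onsets.size:
            raise ValueError("one condition label per trial required")
        if not np.all(np.isfinite(onsets)) or not np.all(np.isfinite(durations)):
            raise ValueError("non-finite onset or duration")
        if onsets.size:
            soas = np.diff(onsets)
            if np.any(soas <= 0):
                raise ValueError("onsets must be strictly increasing")
            if np.any(soas < MIN_SOA - 1e-9):
                raise ValueError(f"inter-onset interval below {MIN_SOA} s")
            if np.any(onsets + durations >= self.run_length):
                raise ValueError("trial extends past the end of the run")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition labels: {sorted(unknown)}")

    @property
    def n_trials(self) -> int:
        return int(self.onsets.size)

    def soas(self) -> np.ndarray:
        """Observed stimulus onset asynchronies, seconds."""
        return np.diff(self.onsets)

    def onsets_for(self, condition: str) -> np.ndarray:
        mask = np.array([c == condition for c in self.conditions])
        return self.onsets[mask]

    def to_frame(self) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, trial_type)."""
        return pd.DataFrame(
            {
                "onset": self.onsets,
                "duration": self.durations,
                "trial_type": list(self.conditions),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, run_length: float) -> "EventSchedule":
        return cls(
            onsets=frame["onset"].to_numpy(float),
            durations=frame["duration"].to_numpy(float),
            conditions=tuple(frame["trial_type"].astype(str)),
            run_length=run_length,
        )


def _condition_labels(n_bimodal: int, n_unimodal: int, rng: np.random.Generator) -> list[str]:
    """Equal numbers of the three bimodal tones; unimodal split audio/visual."""
    labels: list[str] = []
    base, rem = divmod(n_bimodal, 3)
    for i, cond in enumerate(BIMODAL_CONDITIONS):
        labels.extend([cond] * (base + (1 if i < rem else 0)))
    half, odd = divmod(n_unimodal, 2)
    labels.extend(["audio"] * (half + odd))
    labels.extend(["visual"] * half)
    order = rng.permutation(len(labels))
    return [labels[i] for i in order]


def generate_paradigm(
    n_bimodal: int = 120,
    n_unimodal: int = 8,
    min_soa: float = MIN_SOA,
    max_soa: float = 26.0,
    seed: int = 0,
    run_length: float = DEFAULT_RUN_LENGTH,
    duration: float = EVENT_DURATION,
) -> EventSchedule:
    """Pseudo-random rapid event-related schedule on a ``min_soa`` grid.

    Trials are packed onto a ``min_soa``-second slot grid with pseudo-random
    null gaps such that the observed SOAs span ``[min_soa, max_soa]``; one
    gap is pinned at ``max_soa`` and the remaining slack is scattered
    uniformly.  Deterministic given ``seed``.
    """
    if min_soa <= 0:
        raise ValueError("min_soa must be positive")
    if max_soa < min_soa:
        raise ValueError("max_soa must be >= min_soa")
    if n_bimodal < 0 or n_unimodal < 0:
        raise ValueError("trial counts must be non-negative")
    n = n_bimodal + n_unimodal
    rng = np.random.default_rng(seed)
    if n == 0:
        return EventSchedule(
            onsets=np.empty(0), durations=np.empty(0), conditions=(), run_length=run_length
        )

    slot = float(min_soa)
    # last admissible onset slot: onset + duration must stay inside the run
    n_slots = int(np.floor((run_length - duration) / slot - 1e-9)) + 1
    max_gap = int(np.floor(max_soa / slot + 1e-9))  # in slots
    budget = (n_slots - 1) - (n - 1)  # slack slots beyond minimal packing
    if budget < 0:
        raise ValueError(
            f"cannot pack {n} trials at SOA {min_soa} s into a {run_length:.1f} s run"
        )
    gaps = np.ones(n - 1, dtype=int)
    if n >= 2:
        if budget < max_gap - 1:
            raise ValueError(
                f"run too short to realise a {max_soa} s SOA with {n} trials"
            )
        pin = int(rng.integers(n - 1))
        gaps[pin] = max_gap
        budget -= max_gap - 1
        # scatter remaining slack one slot at a time (multinomial-like), so
        # the gap distribution is ragged rather than uniform
        while budget > 0:
            room = np.flatnonzero(gaps < max_gap)
            if room.size == 0:
                break
            gaps[int(rng.choice(room))] += 1
            budget -= 1
    onsets = slot * np.concatenate(([0], np.cumsum(gaps)))
    labels = _condition_labels(n_bimodal, n_unimodal, rng)
    return EventSchedule(
        onsets=onsets,
        durations=np.full(n, duration),
        conditions=tuple(labels),
        run_length=run_length,
    )
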