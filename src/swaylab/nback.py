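"""Modified n-back letter task: schedules, stimulus streams, and scoring.

The task presents uppercase letters (``X`` excluded, as it resembles the
fixation cross ``+``) separated by fixation crosses.  Participants silently
count letter repetitions and report a single integer at the end of each
trial:

* **Easy** — count letters that repeat immediately (1-back: positions
  ``i`` and ``i+1`` equal).
* **Hard** — count letters that reappear with exactly one intervening
  letter (2-back: positions ``i`` and ``i+2`` equal).

Performance is scored as the absolute error between the true repeat count
of the presented stream and the reported count.

Overlapping repeats each count once per qualifying pair: ``AAA`` scores 2
under the Easy rule.  :func:`generate_letter_stream` plants repeats at
least three positions apart, so generated streams never contain such
overlaps and the planted ground truth is unambiguous.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "ALPHABET",
    "LETTERS_PER_TRIAL",
    "LETTER_DURATION_S",
    "CROSS_DURATION_S",
    "ScheduleEvent",
    "TrialSchedule",
    "StimulusSequence",
    "ResponseRecord",
    "GenerationError",
    "build_schedule",
    "count_easy_repeats",
    "count_hard_repeats",
    "absolute_error",
    "generate_letter_stream",
]

#: The 25 usable letters (A–Z without X).
ALPHABET: tuple[str, ...] = tuple(c for c in string.ascii_uppercase if c != "X")

#: Letters per 90-s trial: 34 letters and 35 crosses fill 87 s, leaving a
#: 3-s tail after the final cross.
LETTERS_PER_TRIAL = 34
LETTER_DURATION_S = 0.5
CROSS_DURATION_S = 2.0


class GenerationError(RuntimeError):
    """Raised when a stimulus stream with the requested ground truth
    cannot be constructed."""


@dataclass(frozen=True)
class ScheduleEvent:
    kind: str  # "cross" or "letter"
    onset: float  # seconds from trial start
    duration: float  # seconds


@dataclass(frozen=True)
class TrialSchedule:
    """Alternating cross/letter presentation schedule for one trial."""

    events: tuple[ScheduleEvent, ...]
    total_duration: float

    @property
    def n_letters(self) -> int:
        return sum(1 for e in self.events if e.kind == "letter")

    @property
    def n_crosses(self) -> int:
        return sum(1 for e in self.events if e.kind == "cross")

    def to_records(self) -> list[dict]:
        return [
            {"kind": e.kind, "onset": e.onset, "duration": e.duration}
            for e in self.events
        ]


@dataclass(frozen=True)
class StimulusSequence:
    """Ordered letters shown in one trial (fixation crosses implied)."""

    letters: tuple[str, ...]
    trial_id: str = ""

    def __post_init__(self) -> None:
        for c in self.letters:
            if c not in ALPHABET:
                raise ValueError(f"invalid stimulus letter {c!r} (X is excluded)")

    def __iter__(self) -> Iterator[str]:
        return iter(self.letters)

    def __len__(self) -> int:
        return len(self.letters)

    def to_line(self) -> str:
        """Serialize as a comma-separated plain-text line."""
        return ",".join(self.letters)

    @classmethod
    def from_line(cls, line: str, trial_id: str = "") -> "StimulusSequence":
        letters = tuple(tok.strip() for tok in line.strip().split(",") if tok.strip())
        return cls(letters=letters, trial_id=trial_id)


@dataclass(frozen=True)
class ResponseRecord:
    """A single scored trial response."""

    expected: int
    reported: int
    condition: str  # "Easy" or "Hard"
    abs_error: int = field(init=False)

    def __post_init__(self) -> None:
        if self.expected < 0 or self.reported < 0:
            raise ValueError("counts must be non-negative")
        if self.condition not in ("Easy", "Hard"):
            raise ValueError(f"unknown condition {self.condition!r}")
        object.__setattr__(
            self, "abs_error", absolute_error(self.expected, self.reported)
        )


def build_schedule(
    n_letters: int = LETTERS_PER_TRIAL,
    letter_dur: float = LETTER_DURATION_S,
    cross_dur: float = CROSS_DURATION_S,
) -> TrialSchedule:
    """Build the alternating cross/letter schedule for one trial.

    Every trial begins and ends with a fixation cross, so there are
    ``n_letters + 1`` crosses and the stimulus spans
    ``cross_dur + n_letters * (letter_dur + cross_dur)`` seconds
    (87 s at the defaults).
    """
    if n_letters < 0:
        raise ValueError("n_letters must be non-negative")
    if letter_dur <= 0 or cross_dur <= 0:
        raise ValueError("durations must be positive")
    events: list[ScheduleEvent] = []
    t = 0.0
    events.append(ScheduleEvent("cross", t, cross_dur))
    t += cross_dur
    for _ in range(n_letters):
        events.append(ScheduleEvent("letter", t, letter_dur))
        t += letter_dur
        events.append(ScheduleEvent("cross", t, cross_dur))
        t += cross_dur
    return TrialSchedule(events=tuple(events), total_duration=t)


def count_easy_repeats(letters: Sequence[str]) -> int:
    """Number of immediate (1-back) repeats: positions ``i`` and ``i+1`` equal."""
    return sum(1 for a, b in zip(letters, letters[1:]) if a == b)


def count_hard_repeats(letters: Sequence[str]) -> int:
    """Number of 2-back repeats: positions ``i`` and ``i+2`` equal
    (one intervening letter, two fixation crosses between the pair)."""
    return sum(1 for a, b in zip(letters, letters[2:]) if a == b)


def absolute_error(expected: int, reported: int) -> int:
    """Absolute difference between the true repeat count and the report."""
    if expected < 0 or reported < 0:
        raise ValueError("counts must be non-negative")
    return abs(int(expected) - int(reported))


def _spaced_positions(
    rng: np.random.Generator, n_letters: int, n_positions: int, min_gap: int = 3
) -> np.ndarray | None:
    """Sample ``n_positions`` indices in ``[2, n_letters)`` with pairwise
    distance >= ``min_gap``, uniformly via the gap transform; ``None`` if
    infeasible."""
    if n_positions == 0:
        return np.empty(0, dtype=int)
    lo, hi = 2, n_letters - 1  # inclusive bounds for plantable indices
    span = hi - lo - min_gap * (n_positions - 1)
    if span < 0:
        return None
    compressed = rng.choice(span + 1, size=n_positions, replace=False)
    compressed.sort()
    return lo + compressed + min_gap * np.arange(n_positions)


def generate_letter_stream(
    n_letters: int = LETTERS_PER_TRIAL,
    target_easy: int = 0,
    target_hard: int = 0,
    seed: int | np.random.Generator = 0,
    max_tries: int = 100,
) -> StimulusSequence:
    """Generate a letter stream scoring exactly the requested repeat counts.

    Repeat positions are planted at least three apart and all other
    positions avoid their two predecessors, so the Easy and Hard scorers
    return exactly ``target_easy`` and ``target_hard`` by construction
    (verified before returning).  Reproducible for a given ``seed``.

    Raises
    ------
    GenerationError
        If the targets cannot be satisfied for ``n_letters``.
    """
    if n_letters < 0 or target_easy < 0 or target_hard < 0:
        raise ValueError("n_letters and targets must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_plant = target_easy + target_hard
    for _ in range(max_tries):
        pos = _spaced_positions(rng, n_letters, n_plant)
        if pos is None:
            raise GenerationError(
                f"cannot plant {target_easy} easy + {target_hard} hard repeats "
                f"in {n_letters} letters"
            )
        which = rng.permutation(n_plant)
        easy_at = set(pos[which[:target_easy]].tolist())
        hard_at = set(pos[which[target_easy:]].tolist())
        letters: list[str] = []
        for i in range(n_letters):
            if i in easy_at:
                letters.append(letters[i - 1])
            elif i in hard_at:
                letters.append(letters[i - 2])
            else:
                forbidden = set(letters[max(0, i - 2) : i])
                choices = [c for c in ALPHABET if c not in forbidden]
                letters.append(choices[rng.integers(len(choices))])
        if (
            count_easy_repeats(letters) == target_easy
            and count_hard_repeats(letters) == target_hard
        ):
            return StimulusSequence(letters=tuple(letters))
    raise GenerationError(
        f"failed to generate stream (easy={target_easy}, hard={target_hard}, "
        f"n={n_letters}) within {max_tries} attempts"
    )
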