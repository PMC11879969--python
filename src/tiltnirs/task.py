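"""Toulouse N-back Task: stimulus generation, session design, and scoring.

The task presents two-operand arithmetic on multiples of 10 (e.g. ``10 + 40``,
``90 - 30``) and asks for an n-back match judgement on the *results*:

* ``control`` — the stimulus is ``00 + 00`` or ``00 - 00``; press any button
  (pure reaction-time condition, any press is correct).
* ``0back``  — yes iff the result equals 50.
* ``1back``  — yes iff the result equals the previous trial's result.
* ``2back``  — yes iff the result equals the result two trials earlier.

Each trial lasts 2 s followed by a 1 s inter-stimulus interval (3 s pitch);
a block holds 20 trials preceded by a 10 s countdown.  The first n trials of
an n-back block have no defined correct answer and are unscoreable, leaving
20/20/19/18 scoreable trials for control/0/1/2-back.

A session places one four-block task window at the end of each of four
head-down-tilt segments (0, -10, -20, back to 0 degrees; 20 min each), with
block order counterbalanced across tilts and participants by a Latin square.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LEVELS",
    "TILTS",
    "N_UNSCOREABLE",
    "TrialRecord",
    "BlockDesign",
    "SessionDesign",
    "BehavioralSummary",
    "TrialResponse",
    "generate_block",
    "build_session",
    "session_duration",
    "score_block",
]

LEVELS = ("control", "0back", "1back", "2back")
TILTS = ("pre0", "m10", "m20", "post0")

#: leading trials per block with no defined correct answer
N_UNSCOREABLE = {"control": 0, "0back": 0, "1back": 1, "2back": 2}

TRIAL_S = 2.0
ISI_S = 1.0
TRIAL_PITCH_S = TRIAL_S + ISI_S
COUNTDOWN_S = 10.0

_OPERANDS = tuple(range(10, 100, 10))


def _all_stimuli(restrict_results: bool = True) -> list[tuple[int, str, int, int]]:
    """Enumerate (a, op, b, result) over multiples of 10 in 10..90.

    With ``restrict_results`` (default) only stimuli whose result is itself a
    multiple of 10 in 10..90 are kept, so every result can recur as an n-back
    target and no stimulus has a negative or out-of-range answer.
    """
    out = []
    for a in _OPERANDS:
        for b in _OPERANDS:
            for op, r in (("+", a + b), ("-", a - b)):
                if restrict_results and not (10 <= r <= 90):
                    continue
                out.append((a, op, b, r))
    return out


@dataclass
class TrialRecord:
    """One arithmetic stimulus and (optionally) the recorded response."""

    index: int
    operand_a: int
    operand_b: int
    operator: str  # "+" or "-"
    result: int
    level: str
    correct_response: str | None  # "yes" / "no" / "any" / None (unscoreable)
    onset: float  # seconds from block task start (after countdown)
    response: str | None = None  # "yes" / "no" / "none"
    response_time: float | None = None

    @property
    def stimulus(self) -> str:
        if self.level == "control":
            return f"00 {self.operator} 00"
        return f"{self.operand_a} {self.operator} {self.operand_b}"

    @property
    def scoreable(self) -> bool:
        return self.correct_response is not None


@dataclass
class BlockDesign:
    """One difficulty block: a 10 s countdown followed by 20 three-second trials."""

    level: str
    trials: list[TrialRecord]
    countdown: float = COUNTDOWN_S

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_scoreable(self) -> int:
        return sum(t.scoreable for t in self.trials)

    @property
    def task_duration(self) -> float:
        """Trial-period duration excluding the countdown, seconds."""
        return self.n_trials * TRIAL_PITCH_S

    @property
    def duration(self) -> float:
        return self.countdown + self.task_duration


@dataclass
class SessionDesign:
    """Full 80-min protocol: four tilt segments, one task window per segment.

    ``task_offset_s`` places the task window inside each segment; with the
    default 20-min segments and a 900 s offset the 280 s window occupies the
    last five minutes (task from minute 15 to minute ~19:40).
    """

    participant_index: int
    blocks_by_tilt: dict[str, list[BlockDesign]]
    tilt_sequence: tuple[str, ...] = TILTS
    tilt_duration_s: float = 1200.0
    task_offset_s: float = 900.0
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = [t for t in self.tilt_sequence if t not in self.blocks_by_tilt]
        if missing:
            raise ValueError(f"no blocks for tilt(s): {missing}")

    @property
    def protocol_duration_s(self) -> float:
        return self.tilt_duration_s * len(self.tilt_sequence)

    def tilt_start(self, tilt: str) -> float:
        return self.tilt_sequence.index(tilt) * self.tilt_duration_s

    def task_start(self, tilt: str) -> float:
        return self.tilt_start(tilt) + self.task_offset_s

    def block_onset(self, tilt: str, slot: int) -> float:
        """Session time at which block ``slot`` (0-based) begins, countdown included."""
        blocks = self.blocks_by_tilt[tilt]
        return self.task_start(tilt) + sum(b.duration for b in blocks[:slot])

    def block_order(self, tilt: str) -> tuple[str, ...]:
        return tuple(b.level for b in self.blocks_by_tilt[tilt])

    def iter_blocks(self):
        """Yield (tilt, slot, block, trial_window_start_s, trial_window_end_s)."""
        for tilt in self.tilt_sequence:
            for slot, block in enumerate(self.blocks_by_tilt[tilt]):
                onset = self.block_onset(tilt, slot)
                start = onset + block.countdown
                yield tilt, slot, block, start, start + block.task_duration


@dataclass
class BehavioralSummary:
    level: str
    accuracy: float
    mean_correct_rt: float | None
    n_correct: int
    n_scoreable: int


@dataclass
class TrialResponse:
    trial_index: int
    response: str  # "yes" / "no" / "none"
    response_time: float | None = None


def generate_block(
    level: str,
    n_trials: int = 20,
    rng: np.random.Generator | int | None = None,
    match_rate: float = 0.5,
    restrict_results: bool = True,
) -> BlockDesign:
    """Generate one block with the target/non-target balance built in.

    For scoreable trials the match/non-match status is drawn first (Bernoulli
    ``match_rate``), then operands are sampled uniformly from the stimuli that
    realise it, so yes/no answers stay near 50/50 regardless of level and a
    random responder scores ~0.5.

    Raises
    ------
    ValueError
        If ``n_trials`` leaves no scoreable trial for the level.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    n_back = N_UNSCOREABLE[level]
    if n_trials <= n_back:
        raise ValueError(
            f"{level} needs more than {n_back} trials to have any scoreable trial; "
            f"got n_trials={n_trials}"
        )
    rng = np.random.default_rng(rng)

    trials: list[TrialRecord] = []
    if level == "control":
        for i in range(n_trials):
            op = "+" if rng.random() < 0.5 else "-"
            trials.append(
                TrialRecord(i, 0, 0, op, 0, level, "any", i * TRIAL_PITCH_S)
            )
        return BlockDesign(level=level, trials=trials)

    pool = _all_stimuli(restrict_results)
    by_result: dict[int, list[tuple[int, str, int, int]]] = {}
    for s in pool:
        by_result.setdefault(s[3], []).append(s)

    results: list[int] = []
    for i in range(n_trials):
        if level == "0back":
            target = 50
        elif i < n_back:
            target = None  # leading trial: no defined answer
        else:
            target = results[i - n_back]

        if target is None:
            a, op, b, r = pool[rng.integers(len(pool))]
            correct = None
        elif rng.random() < match_rate and target in by_result:
            a, op, b, r = by_result[target][rng.integers(len(by_result[target]))]
            correct = "yes"
        else:
            while True:
                a, op, b, r = pool[rng.integers(len(pool))]
                if r != target:
                    break
            correct = "no"
        results.append(r)
        trials.append(TrialRecord(i, a, b, op, r, level, correct, i * TRIAL_PITCH_S))
    return BlockDesign(level=level, trials=trials)


# Latin square: participant p at tilt t runs block order number (p + t) mod 4,
# where order k is the cyclic rotation of LEVELS by k.  Over any 4 consecutive
# participants each order appears once per tilt position, and each level
# appears once in each slot within a participant's session.
def _block_order(participant_index: int, tilt_index: int) -> tuple[str, ...]:
    k = (participant_index + tilt_index) % len(LEVELS)
    return LEVELS[k:] + LEVELS[:k]


def build_session(
    participant_index: int,
    rng_seed: int | None = None,
    n_trials: int = 20,
) -> SessionDesign:
    """Build a counterbalanced four-tilt session for one participant.

    All stimulus randomness flows from ``rng_seed`` combined with the
    participant index, so a (participant, seed) pair is fully reproducible.
    """
    if participant_index < 0:
        raise ValueError("participant_index must be >= 0")
    ss = np.random.SeedSequence([0 if rng_seed is None else rng_seed, participant_index])
    rng = np.random.default_rng(ss)
    blocks_by_tilt = {}
    for t_idx, tilt in enumerate(TILTS):
        order = _block_order(participant_index, t_idx)
        blocks_by_tilt[tilt] = [generate_block(lv, n_trials, rng) for lv in order]
    return SessionDesign(
        participant_index=participant_index,
        blocks_by_tilt=blocks_by_tilt,
        seed=rng_seed,
    )


def session_duration(design: SessionDesign, tilt: str | None = None) -> float:
    """Duration in seconds of one tilt's task window (countdowns + trials).

    With the default design (four blocks of 20 trials, 10 s countdowns) this
    is 4 * (10 + 60) = 280 s.
    """
    tilt = tilt or design.tilt_sequence[0]
    return float(sum(b.duration for b in design.blocks_by_tilt[tilt]))


def score_block(block: BlockDesign, responses: list[TrialResponse]) -> BehavioralSummary:
    """Score one block against recorded responses.

    Scoreable trials only enter the accuracy denominator; a missing response
    ("none") is incorrect and contributes no latency; for control trials any
    press is correct.  ``mean_correct_rt`` is None when nothing was answered
    correctly (or no correct response carried a latency).
    """
    by_index: dict[int, TrialResponse] = {}
    for resp in responses:
        if not 0 <= resp.trial_index < block.n_trials:
            raise ValueError(
                f"response for trial {resp.trial_index} outside block of {block.n_trials} trials"
            )
        by_index[resp.trial_index] = resp

    n_correct = 0
    rts: list[float] = []
    for trial in block.trials:
        if not trial.scoreable:
            continue
        resp = by_index.get(trial.index)
        answered = resp is not None and resp.response != "none"
        if trial.correct_response == "any":
            ok = answered
        else:
            ok = answered and resp.response == trial.correct_response
        if ok:
            n_correct += 1
            if resp.response_time is not None:
                rts.append(resp.response_time)
    n_scoreable = block.n_scoreable
    return BehavioralSummary(
        level=block.level,
        accuracy=n_correct / n_scoreable if n_scoreable else float("nan"),
        mean_correct_rt=float(np.mean(rts)) if rts else None,
        n_correct=n_correct,
        n_scoreable=n_scoreable,
    )
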