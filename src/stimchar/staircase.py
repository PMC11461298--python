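"""Between-subject up-down staircase for locating the frame of category recognition.

Each iteration of the staircase is one naive participant watching every clip
once, paused at a clip-specific frame, and classifying the action.  A correct
classification shortens the played segment on the next iteration, an error
lengthens it, by a step that decays geometrically with the iteration number:

    N(n) = Nframe / 2 * 2 ** (-(n - 2) / 2.5)

where ``Nframe`` is the clip's frame count and ``n`` the (1-based) iteration.
The first participant sees each clip up to its 50th-percentile frame.  The
procedure stops once N drops below one frame — reversals can then no longer
move the pause point — and the frame played on that final iteration is taken
as the frame on which the action category becomes recognizable.

The schedule is fixed: the number of iterations depends only on ``Nframe``,
never on the responses.  Step sizes are kept real-valued for the stopping
test but rounded half-up to whole frames when applied, and played frames are
clamped to ``[1, Nframe]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping

import numpy as np

from ._util import clamp, round_half_up

__all__ = [
    "StaircaseStep",
    "StaircaseState",
    "ObserverModel",
    "ConvergenceResult",
    "initial_played_frame",
    "step_size",
    "next_state",
    "convergence_iteration",
    "run_staircase",
    "simulate_observer",
    "run_session",
]


def initial_played_frame(n_frame: int) -> int:
    """Pause frame for the first iteration: the 50th percentile of the clip.

    Rounded half-up and clamped to the valid frame range.
    """
    if n_frame < 2:
        raise ValueError(f"a staircase needs at least 2 frames, got {n_frame}")
    return clamp(round_half_up(0.5 * n_frame), 1, n_frame)


def step_size(n_frame: int, n: int) -> float:
    """Real-valued step N(n) = Nframe/2 * 2**(-(n-2)/2.5).

    Defined for n >= 2: no step precedes the second iteration.
    """
    if n_frame < 2:
        raise ValueError(f"a staircase needs at least 2 frames, got {n_frame}")
    if n < 2:
        raise ValueError(f"step size is defined for iterations n >= 2, got {n}")
    return n_frame / 2 * 2.0 ** (-(n - 2) / 2.5)


def convergence_iteration(n_frame: int) -> int:
    """Smallest iteration n at which the step N(n) falls below one frame.

    Equivalently the smallest n > 2 + 2.5*log2(Nframe/2); computed by direct
    evaluation of the step formula so exact ties (N == 1) are respected.
    """
    if n_frame < 2:
        raise ValueError(f"a staircase needs at least 2 frames, got {n_frame}")
    # Closed-form lower bound, then walk to handle floating-point ties.
    n = max(2, int(2 + 2.5 * np.log2(n_frame / 2)) - 1)
    while not step_size(n_frame, n) < 1.0:
        n += 1
    return n


@dataclass(frozen=True)
class StaircaseStep:
    """One iteration's record: where the clip paused, the step taken to get
    there, and the participant's response (None until answered)."""

    iteration: int
    played_frame: int
    step: float | None
    correct: bool | None


@dataclass(frozen=True)
class StaircaseState:
    video_id: str
    n_frame: int
    n: int
    played_frame: int
    history: tuple[StaircaseStep, ...] = field(default=())

    @classmethod
    def initial(cls, n_frame: int, video_id: str = "") -> "StaircaseState":
        played = initial_played_frame(n_frame)
        return cls(
            video_id=video_id,
            n_frame=n_frame,
            n=1,
            played_frame=played,
            history=(StaircaseStep(1, played, None, None),),
        )


def next_state(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance one iteration after a response.

    The step applied when moving into iteration ``n+1`` is ``N(n+1)`` rounded
    half-up to whole frames; correct responses subtract it, errors add it,
    and the result is clamped to ``[1, Nframe]``.  Note the first adjustment
    (into iteration 2) therefore has magnitude ``Nframe/2``, which lands the
    second iteration on a clamped extreme — a direct consequence of the step
    formula's exponent being zero at n = 2.
    """
    n_next = state.n + 1
    raw = step_size(state.n_frame, n_next)
    step = round_half_up(raw)
    delta = -step if correct else step
    played = clamp(state.played_frame + delta, 1, state.n_frame)
    answered = replace(state.history[-1], correct=bool(correct))
    return StaircaseState(
        video_id=state.video_id,
        n_frame=state.n_frame,
        n=n_next,
        played_frame=played,
        history=state.history[:-1] + (answered, StaircaseStep(n_next, played, raw, None)),
    )


@dataclass(frozen=True)
class ConvergenceResult:
    video_id: str
    convergence_frame: int
    n_iterations: int
    state: StaircaseState = field(repr=False, compare=False, default=None)  # type: ignore[assignment]


def run_staircase(
    n_frame: int,
    responder: Callable[[int], bool],
    video_id: str = "",
    n_iterations: int | None = None,
) -> ConvergenceResult:
    """Run a full staircase for one clip against a responder.

    ``responder`` maps a played frame to a correct/incorrect classification;
    it is queried once per iteration except the last (the final iteration's
    response cannot move anything, since the schedule has ended).  By default
    the run lasts :func:`convergence_iteration` iterations; ``n_iterations``
    overrides the stopping rule.
    """
    total = n_iterations if n_iterations is not None else convergence_iteration(n_frame)
    if total < 1:
        raise ValueError("n_iterations must be >= 1")
    state = StaircaseState.initial(n_frame, video_id=video_id)
    while state.n < total:
        try:
            correct = responder(state.played_frame)
        except Exception as exc:
            raise RuntimeError(
                f"responder failed at iteration {state.n} "
                f"(video {video_id!r}, played frame {state.played_frame})"
            ) from exc
        state = next_state(state, correct)
    return ConvergenceResult(
        video_id=video_id,
        convergence_frame=state.played_frame,
        n_iterations=total,
        state=state,
    )


@dataclass
class ObserverModel:
    """Simulated participant whose recognition switches on at a true frame r.

    Shown a segment ending at or after ``r`` the observer classifies
    correctly except for lapses (probability ``lapse_rate``); shown a shorter
    segment they guess, succeeding with ``guess_rate`` (1/3 for a
    three-category task).  The response stream is a pure function of the seed.
    """

    r: int
    guess_rate: float = 1.0 / 3.0
    lapse_rate: float = 0.0
    seed: int | np.random.SeedSequence | None = None

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError(f"true recognition frame must be >= 1, got {self.r}")
        if not 0 <= self.guess_rate <= 1:
            raise ValueError(f"guess_rate must be in [0, 1], got {self.guess_rate}")
        if not 0 <= self.lapse_rate <= 1:
            raise ValueError(f"lapse_rate must be in [0, 1], got {self.lapse_rate}")
        self._rng = np.random.default_rng(self.seed)

    def respond(self, played_frame: int) -> bool:
        p = (1.0 - self.lapse_rate) if played_frame >= self.r else self.guess_rate
        return bool(self._rng.random() < p)

    def __call__(self, played_frame: int) -> bool:
        return self.respond(played_frame)


def simulate_observer(model: ObserverModel, played_frame: int) -> bool:
    """One simulated response; draws from the model's seeded stream."""
    return model.respond(played_frame)


def run_session(
    n_frames: Mapping[str, int],
    responders: Mapping[str, Callable[[int], bool]],
    seed: int | None = None,
    n_iterations: int | None = None,
) -> tuple[list[ConvergenceResult], list[dict]]:
    """Between-subject session over many clips.

    Each iteration (participant) plays every still-active clip once in a
    seeded pseudo-random order.  Returns one :class:`ConvergenceResult` per
    clip plus a flat session log with one record per (iteration, video)
    presentation — suitable for JSON-lines export when the engine drives a
    real experiment.
    """
    missing = sorted(set(n_frames) - set(responders))
    if missing:
        raise ValueError(f"no responder for videos: {missing}")
    rng = np.random.default_rng(seed)
    states = {vid: StaircaseState.initial(nf, video_id=vid) for vid, nf in n_frames.items()}
    totals = {
        vid: (n_iterations if n_iterations is not None else convergence_iteration(nf))
        for vid, nf in n_frames.items()
    }
    log: list[dict] = []
    for iteration in range(1, max(totals.values()) + 1):
        order = list(n_frames)
        rng.shuffle(order)
        for vid in order:
            state = states[vid]
            if iteration > totals[vid] or state.n != iteration:
                continue
            if state.n < totals[vid]:
                correct = responders[vid](state.played_frame)
                log.append(
                    {
                        "iteration": iteration,
                        "video_id": vid,
                        "played_frame": state.played_frame,
                        "correct": bool(correct),
                    }
                )
                states[vid] = next_state(state, correct)
            else:
                log.append(
                    {
                        "iteration": iteration,
                        "video_id": vid,
                        "played_frame": state.played_frame,
                        "correct": None,
                    }
                )
    results = [
        ConvergenceResult(
            video_id=vid,
            convergence_frame=states[vid].played_frame,
            n_iterations=totals[vid],
            state=states[vid],
        )
        for vid in n_frames
    ]
    return results, log
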