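"""Scripted therapist decision policies and cohort generation.

Policies stand in for human trainees: at each decision point they observe
the sampled SUDS, the current task, the offered moves, and the decision
index, and return a chosen position.  All stochastic policies draw from the
generator supplied by the session runner, so one seed reproduces a whole
cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .engine import SessionConfig, SessionLog, run_session
from .hierarchy import ExposureHierarchy

__all__ = [
    "Policy",
    "gradual_titration_policy",
    "random_policy",
    "avoidant_policy",
    "fixed_policy",
    "scripted_policy",
    "simulate_cohort",
    "CohortSession",
]

DecideFn = Callable[[int, int, Sequence[int], int, np.random.Generator], int]
InitialFn = Callable[[Sequence[int], np.random.Generator], int]


@dataclass(frozen=True)
class Policy:
    """A named decision rule with its parameters.

    ``decide`` validates that the underlying rule returned an offered move,
    so a buggy rule fails loudly instead of corrupting a session.
    """

    name: str
    params: dict
    _decide: DecideFn
    _initial: InitialFn

    def choose_initial(
        self, options: Sequence[int], rng: np.random.Generator
    ) -> int:
        choice = int(self._initial(options, rng))
        if choice not in options:
            raise ValueError(
                f"policy {self.name!r} chose initial {choice} outside {list(options)}"
            )
        return choice

    def decide(
        self,
        suds: int,
        position: int,
        allowed: Sequence[int],
        index: int,
        rng: np.random.Generator,
    ) -> int:
        choice = int(self._decide(suds, position, allowed, index, rng))
        if choice not in allowed:
            raise ValueError(
                f"policy {self.name!r} chose {choice} outside allowed {list(allowed)}"
            )
        return choice


def gradual_titration_policy(theta: int, start: int = 3) -> Policy:
    """Step up one position whenever observed SUDS <= theta; never move down."""

    def decide(suds, position, allowed, index, rng):
        if suds <= theta and position + 1 in allowed:
            return position + 1
        return position

    return Policy(
        name="titration",
        params={"theta": theta, "start": start},
        _decide=decide,
        _initial=lambda options, rng: start,
    )


def random_policy(seed: Optional[int] = None) -> Policy:
    """Choose uniformly among the offered moves (including "keep it the same").

    If ``seed`` is given the policy carries its own generator and ignores the
    runner's; otherwise it draws from the generator passed in by the runner.
    """
    own = np.random.default_rng(seed) if seed is not None else None

    def pick(options, rng):
        r = own if own is not None else rng
        return int(r.choice(list(options)))

    return Policy(
        name="random",
        params={"seed": seed},
        _decide=lambda suds, position, allowed, index, rng: pick(allowed, rng),
        _initial=pick,
    )


def avoidant_policy(panic_threshold: int, start: int = 5) -> Policy:
    """Ease one position whenever observed SUDS >= panic_threshold."""

    def decide(suds, position, allowed, index, rng):
        if suds >= panic_threshold and position - 1 in allowed:
            return position - 1
        return position

    return Policy(
        name="avoidant",
        params={"panic_threshold": panic_threshold, "start": start},
        _decide=decide,
        _initial=lambda options, rng: start,
    )


def fixed_policy(position: int) -> Policy:
    """Start at ``position`` and keep the same task at every decision point."""
    return Policy(
        name="fixed",
        params={"position": position},
        _decide=lambda suds, pos, allowed, index, rng: pos,
        _initial=lambda options, rng: position,
    )


def scripted_policy(decisions: Sequence[int]) -> Policy:
    """Replay a fixed decision sequence (index 1 = initial selection)."""
    decisions = [int(d) for d in decisions]

    def decide(suds, position, allowed, index, rng):
        return decisions[index - 1]

    return Policy(
        name="scripted",
        params={"decisions": decisions},
        _decide=decide,
        _initial=lambda options, rng: decisions[0],
    )


@dataclass(frozen=True)
class CohortSession:
    trainee: str
    repetition: int
    log: SessionLog


def simulate_cohort(
    h: ExposureHierarchy,
    cfg: SessionConfig,
    policy_mix: Union[Policy, Sequence[Policy]],
    n_trainees: int,
    seed: int = 0,
) -> list[CohortSession]:
    """Generate ``cfg.repetitions`` independent session logs per trainee.

    The program resets completely between repetitions: every session starts
    from a blank patient state.  ``policy_mix`` may be one policy for all
    trainees or a sequence cycled across trainees.  Deterministic under
    ``seed`` via per-session seed-sequence spawning.
    """
    if n_trainees < 1:
        raise ValueError("n_trainees must be >= 1")
    policies = [policy_mix] if isinstance(policy_mix, Policy) else list(policy_mix)
    if not policies:
        raise ValueError("policy_mix must contain at least one policy")
    root = np.random.SeedSequence(seed)
    children = iter(root.spawn(n_trainees * cfg.repetitions))
    out: list[CohortSession] = []
    for i in range(n_trainees):
        trainee = f"trainee{i + 1:03d}"
        policy = policies[i % len(policies)]
        for rep in range(1, cfg.repetitions + 1):
            log = run_session(
                h,
                cfg,
                policy,
                seed=next(children),
                session_id=f"{trainee}-rep{rep}",
            )
            out.append(CohortSession(trainee=trainee, repetition=rep, log=log))
    return out
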