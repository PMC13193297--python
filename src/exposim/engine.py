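"""Discrete-event virtual-patient session engine.

One simulated session is a fixed cadence of therapist decision points over a
task hierarchy.  Distress (SUDS, 0-10) is set when a task is entered and
decays by one point per habituation interval of continuous exposure to the
same task.  Verbalization cues fire on a fixed tick and are tagged with the
patient's current distress band.  Everything is logged to an append-only
event list that serializes to JSONL and can be replayed exactly.

Time is integer simulated seconds on the tick grid; nothing here waits on a
wall clock.  Engine dynamics are fully deterministic — randomness lives in
the decision policies only.
"""

from __future__ import annotations

import io
import json
import uuid
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

from .hierarchy import (
    ExposureHierarchy,
    allowed_moves,
    initial_options,
)

__all__ = [
    "SCHEMA_VERSION",
    "BANDS",
    "EVENT_KINDS",
    "SessionConfig",
    "SessionState",
    "SessionEvent",
    "SessionLog",
    "Session",
    "SessionError",
    "distress_band",
    "elicitation_level",
    "start_session",
    "advance",
    "apply_decision",
    "suds_check",
    "end_session",
    "run_session",
    "replay_session",
    "reset_for_repetition",
]

SCHEMA_VERSION = 1

BANDS = ("low", "moderate", "high")

EVENT_KINDS = (
    "session_start",
    "task_select",
    "decision_point",
    "verbalization_cue",
    "suds_update",
    "suds_check",
    "session_end",
)


class SessionError(RuntimeError):
    """Raised on misuse of the session engine (bad timing, bad choice, ...)."""


@dataclass(frozen=True)
class SessionConfig:
    """Timing, bound, and banding constants for one simulated session."""

    tick_seconds: int = 15
    decision_interval_seconds: int = 45
    n_decision_points: int = 9
    habituation_interval_seconds: int = 120
    suds_min: int = 0
    suds_max: int = 10
    band_edges: tuple[int, int] = (3, 7)  # low <= 3, moderate 4..7, high >= 8
    repetitions: int = 3

    def __post_init__(self) -> None:
        if self.tick_seconds <= 0:
            raise ValueError("tick_seconds must be positive")
        if self.decision_interval_seconds % self.tick_seconds != 0:
            raise ValueError("decision interval must be a multiple of the tick")
        if self.habituation_interval_seconds % self.tick_seconds != 0:
            raise ValueError("habituation interval must be a multiple of the tick")
        if self.suds_min >= self.suds_max:
            raise ValueError("suds_min must be < suds_max")
        lo, hi = self.band_edges
        if not (self.suds_min <= lo < hi < self.suds_max):
            raise ValueError(
                f"band_edges {self.band_edges} must be strictly increasing "
                f"within ({self.suds_min}, {self.suds_max})"
            )
        if self.n_decision_points < 1:
            raise ValueError("n_decision_points must be >= 1")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")

    @property
    def session_seconds(self) -> int:
        """Total simulated length: one decision interval after the last decision."""
        return self.n_decision_points * self.decision_interval_seconds

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band_edges"] = list(self.band_edges)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        d["band_edges"] = tuple(d["band_edges"])
        return cls(**d)


@dataclass
class SessionState:
    """Mutable per-session state advanced by the engine."""

    clock_seconds: int = 0
    current_position: int = 1
    suds: int = 0
    time_on_task_seconds: int = 0
    decisions_made: int = 0
    terminated: bool = False


@dataclass(frozen=True)
class SessionEvent:
    t: int
    kind: str
    payload: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"t": self.t, "kind": self.kind, **self.payload}

    @classmethod
    def from_dict(cls, d: dict) -> "SessionEvent":
        d = dict(d)
        return cls(t=int(d.pop("t")), kind=str(d.pop("kind")), payload=d)


def distress_band(suds: int, cfg: SessionConfig = SessionConfig()) -> str:
    """Map a SUDS value onto the low/moderate/high band given the config edges."""
    if not cfg.suds_min <= suds <= cfg.suds_max:
        raise ValueError(f"suds {suds} outside [{cfg.suds_min}, {cfg.suds_max}]")
    lo, hi = cfg.band_edges
    if suds <= lo:
        return "low"
    if suds <= hi:
        return "moderate"
    return "high"


def elicitation_level(position: int, cfg: SessionConfig) -> int:
    """SUDS evoked on entering a task: the task's position, clamped to bounds."""
    return max(cfg.suds_min, min(cfg.suds_max, position))


class Session:
    """One in-flight simulated session: hierarchy + config + state + events."""

    def __init__(
        self,
        hierarchy: ExposureHierarchy,
        config: SessionConfig,
        session_id: Optional[str] = None,
    ) -> None:
        self.hierarchy = hierarchy
        self.config = config
        self.session_id = session_id or uuid.uuid4().hex[:12]
        self.state = SessionState()
        self.events: list[SessionEvent] = []

    def _emit(self, kind: str, **payload) -> SessionEvent:
        ev = SessionEvent(t=self.state.clock_seconds, kind=kind, payload=payload)
        self.events.append(ev)
        return ev

    def to_log(self, complete: Optional[bool] = None) -> "SessionLog":
        if complete is None:
            complete = self.state.terminated
        return SessionLog(
            session_id=self.session_id,
            config=self.config,
            hierarchy=self.hierarchy,
            events=tuple(self.events),
            complete=complete,
        )


@dataclass(frozen=True)
class SessionLog:
    """Immutable, serializable record of one session."""

    session_id: str
    config: SessionConfig
    hierarchy: ExposureHierarchy
    events: tuple[SessionEvent, ...]
    complete: bool = True

    def events_of(self, kind: str) -> list[SessionEvent]:
        return [e for e in self.events if e.kind == kind]

    def decision_events(self) -> list[SessionEvent]:
        return self.events_of("decision_point")

    def decision_sequence(self) -> list[int]:
        """Chosen positions in decision order (index 1 = initial selection)."""
        return [e.payload["choice"] for e in self.decision_events()]

    def suds_trace(self) -> list[tuple[int, int]]:
        """(t, suds) at every suds_update, decision point, and session end."""
        out: list[tuple[int, int]] = []
        for e in self.events:
            if e.kind in ("suds_update", "decision_point"):
                out.append((e.t, e.payload["suds_after"] if e.kind == "decision_point" else e.payload["suds"]))
            elif e.kind == "session_end":
                out.append((e.t, e.payload["suds"]))
        return out

    def final_suds(self) -> int:
        end = self.events_of("session_end")
        if not end:
            raise SessionError("log has no session_end event")
        return end[-1].payload["suds"]

    def validate(self) -> None:
        """Check the structural log invariants; raise SessionError on violation."""
        kinds = [e.kind for e in self.events]
        if kinds.count("session_start") != 1:
            raise SessionError("log must contain exactly one session_start")
        if self.complete:
            if kinds.count("session_end") != 1:
                raise SessionError("complete log must contain exactly one session_end")
            n_dec = kinds.count("decision_point")
            if n_dec != self.config.n_decision_points:
                raise SessionError(
                    f"expected {self.config.n_decision_points} decision points, "
                    f"found {n_dec}"
                )
        ts = [e.t for e in self.events]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise SessionError("event timestamps must be non-decreasing")
        for e in self.decision_events():
            if "offered" not in e.payload or "choice" not in e.payload:
                raise SessionError("decision_point events must record offered set and choice")

    # ------------------------------------------------------------------ I/O
    def to_jsonl(self, sink: Union[str, Path, IO[str]]) -> None:
        header = {
            "schema_version": SCHEMA_VERSION,
            "session_id": self.session_id,
            "complete": self.complete,
            "config": self.config.to_dict(),
            "hierarchy": self.hierarchy.to_dict(),
        }
        own = isinstance(sink, (str, Path))
        fh: IO[str] = open(sink, "w", encoding="utf-8") if own else sink
        try:
            fh.write(json.dumps(header) + "\n")
            for e in self.events:
                fh.write(json.dumps(e.to_dict()) + "\n")
        finally:
            if own:
                fh.close()

    @classmethod
    def from_jsonl(cls, source: Union[str, Path, IO[str]]) -> "SessionLog":
        own = isinstance(source, (str, Path))
        fh: IO[str] = open(source, "r", encoding="utf-8") if own else source
        try:
            lines = [ln for ln in fh.read().splitlines() if ln.strip()]
        finally:
            if own:
                fh.close()
        if not lines:
            raise SessionError("empty session log")
        header = json.loads(lines[0])
        version = header.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SessionError(
                f"unsupported log schema version {version!r} "
                f"(reader supports {SCHEMA_VERSION})"
            )
        return cls(
            session_id=header["session_id"],
            config=SessionConfig.from_dict(header["config"]),
            hierarchy=ExposureHierarchy.from_dict(header["hierarchy"]),
            events=tuple(SessionEvent.from_dict(json.loads(ln)) for ln in lines[1:]),
            complete=bool(header.get("complete", True)),
        )

    def to_jsonl_str(self) -> str:
        buf = io.StringIO()
        self.to_jsonl(buf)
        return buf.getvalue()


# ---------------------------------------------------------------- operations

def start_session(
    h: ExposureHierarchy,
    cfg: SessionConfig,
    initial: int,
    session_id: Optional[str] = None,
) -> Session:
    """Open a session with the initial task selection as decision point 1.

    The initial selection may come from anywhere on the hierarchy.  Entry
    SUDS follows the elicitation rule (task position, clamped to bounds).
    """
    options = initial_options(h)
    if initial not in options:
        raise SessionError(f"initial position {initial} not in {sorted(options)}")
    s = Session(h, cfg, session_id)
    s.state.current_position = initial
    s.state.suds = elicitation_level(initial, cfg)
    s.state.decisions_made = 1
    s._emit("session_start")
    s._emit(
        "decision_point",
        index=1,
        offered=sorted(options),
        choice=initial,
        previous=None,
        suds_before=None,
        suds_after=s.state.suds,
    )
    s._emit("task_select", position=initial, suds=s.state.suds)
    return s


def advance(session: Session, seconds: int) -> list[SessionEvent]:
    """Advance simulated time tick by tick, emitting cues and habituation drops.

    ``seconds`` must be a positive multiple of the tick.  A verbalization cue
    (tagged with the current distress band) fires at every tick; whenever the
    continuous time on the current task crosses a habituation-interval
    multiple, SUDS drops one point (floored at ``suds_min``).
    """
    st, cfg = session.state, session.config
    if st.terminated:
        raise SessionError("cannot advance a terminated session")
    if seconds <= 0 or seconds % cfg.tick_seconds != 0:
        raise SessionError(
            f"advance of {seconds}s is not a positive multiple of the "
            f"{cfg.tick_seconds}s tick"
        )
    emitted: list[SessionEvent] = []
    for _ in range(seconds // cfg.tick_seconds):
        st.clock_seconds += cfg.tick_seconds
        st.time_on_task_seconds += cfg.tick_seconds
        if st.time_on_task_seconds % cfg.habituation_interval_seconds == 0:
            if st.suds > cfg.suds_min:
                st.suds -= 1
                emitted.append(
                    session._emit(
                        "suds_update",
                        suds=st.suds,
                        reason="habituation",
                        time_on_task=st.time_on_task_seconds,
                    )
                )
        band = distress_band(st.suds, cfg)
        emitted.append(
            session._emit("verbalization_cue", band=band, cue_id=f"cue_{band}")
        )
    return emitted


def apply_decision(session: Session, choice: int) -> None:
    """Consume one decision point: move up/down the hierarchy or hold.

    Entry SUDS on an upward move is the new task's elicitation level; easing
    never raises SUDS (min of current and the easier task's level); holding
    leaves SUDS to habituation.  The continuous-exposure clock resets on any
    task change.
    """
    st, cfg, h = session.state, session.config, session.hierarchy
    if st.terminated:
        raise SessionError("cannot decide in a terminated session")
    if st.decisions_made >= cfg.n_decision_points:
        raise SessionError(
            f"all {cfg.n_decision_points} decision points already consumed"
        )
    offered = allowed_moves(h, st.current_position)
    if choice not in offered:
        raise SessionError(
            f"choice {choice} outside allowed moves {sorted(offered)} "
            f"from position {st.current_position}"
        )
    previous = st.current_position
    suds_before = st.suds
    if choice > previous:
        st.suds = elicitation_level(choice, cfg)
    elif choice < previous:
        st.suds = min(st.suds, elicitation_level(choice, cfg))
    st.decisions_made += 1
    session._emit(
        "decision_point",
        index=st.decisions_made,
        offered=sorted(offered),
        choice=choice,
        previous=previous,
        suds_before=suds_before,
        suds_after=st.suds,
    )
    if choice != previous:
        st.current_position = choice
        st.time_on_task_seconds = 0
        session._emit("task_select", position=choice, suds=st.suds)


def suds_check(session: Session) -> int:
    """Sample the patient's current SUDS (logged; otherwise side-effect free)."""
    if session.state.terminated:
        raise SessionError("cannot check SUDS of a terminated session")
    session._emit("suds_check", suds=session.state.suds)
    return session.state.suds


def end_session(session: Session) -> SessionLog:
    """Terminate the session, emit session_end, and return the validated log."""
    st = session.state
    if st.terminated:
        raise SessionError("session already terminated")
    st.terminated = True
    session._emit("session_end", suds=st.suds, position=st.current_position)
    log = session.to_log(complete=True)
    log.validate()
    return log


def run_session(
    h: ExposureHierarchy,
    cfg: SessionConfig,
    policy,
    seed=None,
    session_id: Optional[str] = None,
) -> SessionLog:
    """Drive one full session under a decision policy.

    The initial selection is decision point 1; subsequent decisions fire every
    decision interval, with a SUDS check presented to the policy beforehand;
    one final interval elapses after the last decision before session end.
    The seed governs policy randomness only — engine dynamics are
    deterministic.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    initial = policy.choose_initial(sorted(initial_options(h)), rng)
    session = start_session(h, cfg, initial, session_id=session_id)
    for index in range(2, cfg.n_decision_points + 1):
        advance(session, cfg.decision_interval_seconds)
        suds = suds_check(session)
        allowed = sorted(allowed_moves(h, session.state.current_position))
        choice = policy.decide(suds, session.state.current_position, allowed, index, rng)
        apply_decision(session, choice)
    advance(session, cfg.decision_interval_seconds)
    return end_session(session)


def replay_session(log: SessionLog) -> SessionLog:
    """Re-run a log's decision sequence through the engine.

    Used to check the replay invariant: the reproduced SUDS trajectory must
    match the original log exactly.
    """
    from .policies import scripted_policy

    log.validate()
    if not log.complete:
        raise SessionError("cannot replay an incomplete log")
    policy = scripted_policy(log.decision_sequence())
    return run_session(
        log.hierarchy, log.config, policy, session_id=log.session_id + "-replay"
    )


def reset_for_repetition(
    previous: SessionLog,
) -> tuple[ExposureHierarchy, SessionConfig]:
    """Blank-slate reset between repetitions.

    Returns the shared hierarchy and config for the next session; no patient
    state carries over (the virtual patient has no memory of the previous
    session).  Refuses to reset an unfinished session.
    """
    if not previous.complete or not previous.events_of("session_end"):
        raise SessionError("cannot reset: previous session is still active/incomplete")
    return previous.hierarchy, previous.config
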