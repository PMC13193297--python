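"""Post-session feedback: SUDS trajectory plus per-decision classification.

Reconstructs the end-of-session feedback screen from a session log: the
distress trajectory over the whole experience and one rubric-classified
feedback item per decision point.  The rubric is rule-based and shares its
thresholds with the engine's distress bands; every threshold is
configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import IO, Optional, Union

from .engine import SessionConfig, SessionError, SessionLog, distress_band

__all__ = [
    "CLASSIFICATIONS",
    "FeedbackItem",
    "FeedbackReport",
    "classify_decision",
    "build_report",
    "render_trajectory",
    "render_text",
]

CLASSIFICATIONS = (
    "well_timed_advance",
    "supported_persistence",
    "acceptable",
    "missed_opportunity",
    "aggressive_advance",
    "avoidant_retreat",
    "start_level_note",
)

_ACTIONS = ("increase", "decrease", "same", "initial_select")

MESSAGES = {
    "well_timed_advance": "Good timing: distress was low, so stepping up kept the exposure challenging.",
    "supported_persistence": "Staying put under high distress let habituation do its work.",
    "acceptable": "A reasonable choice at this distress level.",
    "missed_opportunity": "Distress was already low; this was a chance to step up.",
    "aggressive_advance": "This jump risks overwhelming the patient; advance more gradually.",
    "avoidant_retreat": "Easing the task teaches avoidance; prolonged exposure works better.",
    "start_level_note": "Starting level noted; any point on the hierarchy is a valid opening.",
}


def classify_decision(
    action: str,
    magnitude: int,
    suds: Optional[int],
    thresholds: tuple[int, int] = (3, 7),
) -> str:
    """Classify one decision from its action, size, and the SUDS when taken.

    Rubric (low edge ``lo``: low band is suds <= lo; high band is
    suds > hi):

    * ``initial_select``             -> start_level_note
    * ``decrease`` (any SUDS)        -> avoidant_retreat
    * ``increase`` by >= 2 steps, or with SUDS in the high band
                                     -> aggressive_advance
    * ``increase`` with SUDS <= lo   -> well_timed_advance
    * ``same`` with SUDS in high band-> supported_persistence
    * ``same`` with SUDS <= lo       -> missed_opportunity
    * anything else                  -> acceptable

    The aggressive-advance rule takes precedence over well-timed so a
    two-step jump is always flagged, even from a calm patient.
    """
    if action not in _ACTIONS:
        raise ValueError(f"unknown action {action!r}; expected one of {_ACTIONS}")
    lo, hi = thresholds
    if action == "initial_select":
        return "start_level_note"
    if suds is None:
        raise ValueError("suds is required for non-initial decisions")
    if action == "decrease":
        return "avoidant_retreat"
    if action == "increase":
        if magnitude >= 2 or suds > hi:
            return "aggressive_advance"
        if suds <= lo:
            return "well_timed_advance"
        return "acceptable"
    # action == "same"
    if suds > hi:
        return "supported_persistence"
    if suds <= lo:
        return "missed_opportunity"
    return "acceptable"


@dataclass(frozen=True)
class FeedbackItem:
    decision_index: int
    t_seconds: int
    suds_at_decision: int
    action: str
    magnitude: int
    classification: str
    message: str


@dataclass(frozen=True)
class FeedbackReport:
    session_id: str
    trajectory: tuple[tuple[int, int], ...]
    items: tuple[FeedbackItem, ...]
    summary: dict

    def to_dict(self) -> dict:
        return {
            "session_id": self.session_id,
            "trajectory": [list(p) for p in self.trajectory],
            "items": [asdict(i) for i in self.items],
            "summary": self.summary,
        }

    def to_json(self, sink: Union[str, Path, IO[str], None] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if sink is not None:
            if isinstance(sink, (str, Path)):
                Path(sink).write_text(text + "\n", encoding="utf-8")
            else:
                sink.write(text + "\n")
        return text


def build_report(
    log: SessionLog, thresholds: Optional[tuple[int, int]] = None
) -> FeedbackReport:
    """Build the feedback report for one complete session log.

    Pure function of the log: trajectory from SUDS updates and decision
    points, one classified item per decision, plus summary statistics.
    """
    log.validate()
    if not log.complete or not log.events_of("session_end"):
        raise SessionError("feedback requires a complete log with session_end")
    cfg = log.config
    if thresholds is None:
        thresholds = cfg.band_edges

    items: list[FeedbackItem] = []
    for ev in log.decision_events():
        index = ev.payload["index"]
        choice = ev.payload["choice"]
        previous = ev.payload.get("previous")
        if previous is None:
            action, magnitude = "initial_select", 0
            suds_at = ev.payload["suds_after"]
        else:
            magnitude = choice - previous
            action = "increase" if magnitude > 0 else "decrease" if magnitude < 0 else "same"
            suds_at = ev.payload["suds_before"]
        cls = classify_decision(action, magnitude, suds_at, thresholds)
        message = MESSAGES[cls]
        if cls == "start_level_note":
            band = distress_band(suds_at, cfg)
            message = f"{message} (opening distress band: {band})"
        items.append(
            FeedbackItem(
                decision_index=index,
                t_seconds=ev.t,
                suds_at_decision=suds_at,
                action=action,
                magnitude=magnitude,
                classification=cls,
                message=message,
            )
        )

    trajectory = tuple(log.suds_trace())
    suds_values = [s for _, s in trajectory]
    counts = {c: 0 for c in CLASSIFICATIONS}
    for item in items:
        counts[item.classification] += 1
    summary = {
        "classification_counts": counts,
        "peak_suds": max(suds_values),
        "mean_suds": round(sum(suds_values) / len(suds_values), 3),
        "final_suds": log.final_suds(),
        "habituation_events": len(log.events_of("suds_update")),
        "n_decisions": len(items),
    }
    return FeedbackReport(
        session_id=log.session_id,
        trajectory=trajectory,
        items=tuple(items),
        summary=summary,
    )


def render_text(report: FeedbackReport, width: int = 10) -> str:
    """Monospaced feedback chart: one row per decision point."""
    lines = [f"session {report.session_id}  SUDS by decision point"]
    for item in report.items:
        bar = "#" * item.suds_at_decision + "." * (width - item.suds_at_decision)
        lines.append(
            f"D{item.decision_index} t={item.t_seconds:>3}s suds={item.suds_at_decision:>2} "
            f"|{bar}| {item.action:<14} {item.classification}"
        )
    s = report.summary
    lines.append(
        f"peak={s['peak_suds']} mean={s['mean_suds']} final={s['final_suds']} "
        f"habituations={s['habituation_events']}"
    )
    return "\n".join(lines)


def render_trajectory(
    report: FeedbackReport, sink: Union[str, Path, IO[bytes]]
) -> None:
    """Write a step plot of the SUDS trajectory with decision markers."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ts = [t for t, _ in report.trajectory]
    ss = [s for _, s in report.trajectory]
    fig, ax = plt.subplots(figsize=(7, 3.2))
    ax.step(ts, ss, where="post", lw=1.5)
    dec_t = [i.t_seconds for i in report.items]
    dec_s = []
    for item in report.items:
        # plot the post-decision level at each decision marker
        after = [s for t, s in report.trajectory if t == item.t_seconds]
        dec_s.append(after[-1] if after else item.suds_at_decision)
    ax.plot(dec_t, dec_s, "o", ms=6)
    for item, y in zip(report.items, dec_s):
        ax.annotate(f"D{item.decision_index}", (item.t_seconds, y),
                    textcoords="offset points", xytext=(0, 6), fontsize=7)
    ax.set_xlabel("simulated seconds")
    ax.set_ylabel("SUDS")
    ax.set_ylim(-0.5, 10.5)
    ax.set_title(f"session {report.session_id}")
    fig.tight_layout()
    fig.savefig(sink)
    plt.close(fig)
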