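"""Ordered exposure-task hierarchies and decision-point move constraints.

A hierarchy is an ordered set of exposure tasks ranked by difficulty
(position 1 = least difficult).  At a decision point the therapist may only
move to tasks within ``reach`` positions of the current task, which bounds
how fast exposure intensity can be escalated or eased.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

__all__ = [
    "ExposureTask",
    "ExposureHierarchy",
    "HierarchyError",
    "load_hierarchy",
    "initial_options",
    "allowed_moves",
    "DEFAULT_REACH",
    "DEFAULT_HIERARCHY",
    "BUILTIN_HIERARCHIES",
]

DEFAULT_REACH = 2
DEFAULT_HIERARCHY = "shoe_contamination"
BUILTIN_HIERARCHIES = {"shoe_contamination": "shoe_contamination.csv"}

_HEADER = ("position", "task_id", "label")


class HierarchyError(ValueError):
    """Raised when a hierarchy definition violates its invariants."""


@dataclass(frozen=True)
class ExposureTask:
    """One exposure task with its difficulty rank."""

    task_id: str
    label: str
    position: int

    def __post_init__(self) -> None:
        if not self.task_id:
            raise HierarchyError("task_id must be non-empty")
        if not self.label or not self.label.strip():
            raise HierarchyError(f"task {self.task_id!r}: label must be non-empty")
        if not isinstance(self.position, int) or self.position < 1:
            raise HierarchyError(
                f"task {self.task_id!r}: position must be a positive integer, "
                f"got {self.position!r}"
            )


@dataclass(frozen=True)
class ExposureHierarchy:
    """Validated, ordered set of exposure tasks plus the move radius."""

    tasks: tuple[ExposureTask, ...]
    reach: int = DEFAULT_REACH
    name: str = field(default="custom")

    def __post_init__(self) -> None:
        if not self.tasks:
            raise HierarchyError("hierarchy must contain at least one task")
        if self.reach < 1:
            raise HierarchyError(f"reach must be >= 1, got {self.reach}")
        positions = sorted(t.position for t in self.tasks)
        n = len(self.tasks)
        if positions != list(range(1, n + 1)):
            raise HierarchyError(
                f"positions must be consecutive 1..{n}, got {positions}"
            )
        ids = [t.task_id for t in self.tasks]
        if len(set(ids)) != n:
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise HierarchyError(f"duplicate task_id(s): {dupes}")
        # canonical storage order: ascending difficulty
        object.__setattr__(
            self, "tasks", tuple(sorted(self.tasks, key=lambda t: t.position))
        )

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    @property
    def positions(self) -> range:
        return range(1, self.n_tasks + 1)

    def task_at(self, position: int) -> ExposureTask:
        if position not in self.positions:
            raise HierarchyError(
                f"position {position} outside 1..{self.n_tasks}"
            )
        return self.tasks[position - 1]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "reach": self.reach,
            "tasks": [
                {"position": t.position, "task_id": t.task_id, "label": t.label}
                for t in self.tasks
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExposureHierarchy":
        tasks = tuple(
            ExposureTask(
                task_id=t["task_id"], label=t["label"], position=int(t["position"])
            )
            for t in d["tasks"]
        )
        return cls(tasks=tasks, reach=int(d["reach"]), name=d.get("name", "custom"))


def _parse_rows(rows: Iterable[dict], *, reach: int, name: str) -> ExposureHierarchy:
    tasks = []
    for row in rows:
        missing = [c for c in _HEADER if row.get(c) in (None, "")]
        if missing:
            raise HierarchyError(f"row {row!r} missing column(s) {missing}")
        try:
            position = int(row["position"])
        except ValueError as exc:
            raise HierarchyError(
                f"position {row['position']!r} is not an integer"
            ) from exc
        tasks.append(
            ExposureTask(
                task_id=row["task_id"].strip(),
                label=row["label"].strip(),
                position=position,
            )
        )
    return ExposureHierarchy(tasks=tuple(tasks), reach=reach, name=name)


def load_hierarchy(
    source: Union[str, Path] = DEFAULT_HIERARCHY, *, reach: int = DEFAULT_REACH
) -> ExposureHierarchy:
    """Load and validate a hierarchy from a built-in name or a CSV file.

    The file format is UTF-8 CSV with a header row ``position,task_id,label``,
    one task per line.  ``source`` may be the name of a packaged fixture
    (currently ``"shoe_contamination"``, a 10-task contamination ladder) or a
    path to a user file.
    """
    if isinstance(source, str) and source in BUILTIN_HIERARCHIES:
        ref = resources.files("exposim.data") / BUILTIN_HIERARCHIES[source]
        with ref.open("r", encoding="utf-8") as fh:
            return _parse_rows(csv.DictReader(fh), reach=reach, name=source)
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(
            f"hierarchy source {source!r} is neither a built-in name "
            f"({sorted(BUILTIN_HIERARCHIES)}) nor an existing file"
        )
    with path.open("r", encoding="utf-8", newline="") as fh:
        return _parse_rows(csv.DictReader(fh), reach=reach, name=path.stem)


def initial_options(h: ExposureHierarchy) -> set[int]:
    """Positions available for the initial task selection: the whole ladder."""
    return set(h.positions)


def allowed_moves(h: ExposureHierarchy, current: int) -> set[int]:
    """Positions reachable from ``current``: within ``reach``, clamped to the ladder.

    Always contains ``current`` itself (the "keep it the same" choice).
    """
    if current not in h.positions:
        raise HierarchyError(f"current position {current} outside 1..{h.n_tasks}")
    lo = max(1, current - h.reach)
    hi = min(h.n_tasks, current + h.reach)
    return set(range(lo, hi + 1))
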