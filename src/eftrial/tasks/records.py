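"""Trial-level data containers shared by all task engines.

A :class:`TrialLog` is the ordered record of one task administration; it is
what the scoring layer consumes.  Logs serialise to JSONL (one trial per
line) with a schema version field so stored logs remain parseable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Any, Iterator

SCHEMA_VERSION = 1


@dataclass
class TrialRecord:
    """One task trial.

    ``rt`` is milliseconds from trial onset, or ``None`` for an omission.
    ``trial_type`` carries the task-specific condition label (go/stop,
    congruent/incongruent, phase name, ...); extra stimulus parameters go in
    ``stimulus``.
    """

    task: str
    block: str
    index: int
    trial_type: str
    response: str | None = None
    rt: float | None = None
    correct: bool | None = None
    ssd: float | None = None
    stimulus: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rt is not None and self.rt < 0:
            raise ValueError("rt must be >= 0 or None (omission)")


@dataclass
class TrialLog:
    task: str
    trials: list[TrialRecord] = field(default_factory=list)
    meta: dict[str, Any] = field(default_factory=dict)

    def append(self, trial: TrialRecord) -> None:
        self.trials.append(trial)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[TrialRecord]:
        return iter(self.trials)

    def filter(self, **conditions: Any) -> list[TrialRecord]:
        """Trials whose attributes (or stimulus entries) match ``conditions``."""
        out = []
        for t in self.trials:
            ok = True
            for key, val in conditions.items():
                have = getattr(t, key) if hasattr(t, key) else t.stimulus.get(key)
                if have != val:
                    ok = False
                    break
            if ok:
                out.append(t)
        return out

    def to_jsonl(self, path: str) -> None:
        with open(path, "w") as fh:
            header = {"schema_version": SCHEMA_VERSION, "task": self.task, "meta": self.meta}
            fh.write(json.dumps(header) + "\n")
            for t in self.trials:
                fh.write(json.dumps(asdict(t)) + "\n")

    @classmethod
    def from_jsonl(cls, path: str) -> "TrialLog":
        with open(path) as fh:
            header = json.loads(fh.readline())
            log = cls(task=header["task"], meta=header.get("meta", {}))
            for line in fh:
                log.append(TrialRecord(**json.loads(line)))
        return log


@dataclass
class SessionLog:
    """One training session: six exercise blocks played in random order."""

    participant_id: str
    session_index: int
    exercise_order: list[str]
    blocks: dict[str, TrialLog]
    difficulty_start: dict[str, Any]
    difficulty_end: dict[str, Any]
    completed: bool = True
    minutes_active: float = 18.0

    def __post_init__(self) -> None:
        if self.completed and len(self.blocks) != 6:
            raise ValueError("a completed session must contain 6 exercise blocks")
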