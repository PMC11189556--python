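"""One-up/one-down staircase used by the stop-signal tasks.

The stop-signal delay (SSD) starts at 500 ms and moves in 50 ms steps:
a successful stop makes the next stop trial harder (SSD + step), a failed
stop makes it easier (SSD - step).  The delay is clamped to [300, 700] ms;
a 1-up-1-down rule converges on the delay at which stopping succeeds half
the time.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class StaircaseState:
    current_value: float = 500.0
    step: float = 50.0
    lower_bound: float = 300.0
    upper_bound: float = 700.0
    history: list[tuple[float, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if not self.lower_bound <= self.current_value <= self.upper_bound:
            raise ValueError("current_value outside bounds")

    def update(self, stopped: bool) -> float:
        """Record the outcome at the current value and step the staircase.

        ``stopped`` is True when the response was successfully inhibited.
        Returns the new value.
        """
        self.history.append((self.current_value, stopped))
        delta = self.step if stopped else -self.step
        self.current_value = min(self.upper_bound, max(self.lower_bound, self.current_value + delta))
        return self.current_value
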