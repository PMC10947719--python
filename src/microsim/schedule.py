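"""Process scheduling.

Within each global time step the registered processes fire in order of
(next due time, priority, insertion order).  Lower priority numbers fire
first when two processes are due simultaneously; ties beyond that are
broken by order of registration, which for protocol-defined processes is
their order of appearance in the document.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

__all__ = ["ProcessSchedule", "ScheduleEntry", "schedule_next"]


@dataclass(order=True)
class ScheduleEntry:
    due: float
    priority: int
    insertion: int
    process_id: str = field(compare=False)
    time_step: float = field(compare=False)


class ProcessSchedule:
    """Priority queue of processes keyed by (due, priority, insertion)."""

    def __init__(self) -> None:
        self._heap: list[ScheduleEntry] = []
        self._counter = 0

    def add(
        self,
        process_id: str,
        time_step: float,
        priority: int = 0,
        first_due: float | None = None,
    ) -> None:
        if time_step <= 0:
            raise ValueError(f"process {process_id!r}: time step must be positive")
        entry = ScheduleEntry(
            due=time_step if first_due is None else first_due,
            priority=priority,
            insertion=self._counter,
            process_id=process_id,
            time_step=time_step,
        )
        self._counter += 1
        heapq.heappush(self._heap, entry)

    def __len__(self) -> int:
        return len(self._heap)

    def __bool__(self) -> bool:
        return bool(self._heap)

    def peek(self) -> ScheduleEntry | None:
        return self._heap[0] if self._heap else None

    def next_due_time(self) -> float:
        return self._heap[0].due if self._heap else math.inf

    def pop_next(self) -> ScheduleEntry | None:
        """Pop the next-due entry and reschedule it one step later.

        Returns the popped entry (with its *current* due time) or ``None``
        for an empty schedule.
        """
        if not self._heap:
            return None
        entry = heapq.heappop(self._heap)
        heapq.heappush(
            self._heap,
            ScheduleEntry(
                due=entry.due + entry.time_step,
                priority=entry.priority,
                insertion=entry.insertion,
                process_id=entry.process_id,
                time_step=entry.time_step,
            ),
        )
        return entry

    def entries(self) -> list[ScheduleEntry]:
        return sorted(self._heap)

    # -- snapshot support --------------------------------------------------
    def state(self) -> list[dict]:
        return [
            {
                "process_id": e.process_id,
                "due": e.due,
                "priority": e.priority,
                "insertion": e.insertion,
                "time_step": e.time_step,
            }
            for e in sorted(self._heap)
        ]

    @classmethod
    def from_state(cls, rows: list[dict]) -> "ProcessSchedule":
        sched = cls()
        for row in rows:
            entry = ScheduleEntry(
                due=float(row["due"]),
                priority=int(row["priority"]),
                insertion=int(row["insertion"]),
                process_id=row["process_id"],
                time_step=float(row["time_step"]),
            )
            heapq.heappush(sched._heap, entry)
            sched._counter = max(sched._counter, entry.insertion + 1)
        return sched


def schedule_next(schedule: ProcessSchedule, now: float) -> str | None:
    """Return the id of the next process due at or before ``now``.

    The returned process's next-due time is advanced by its time step.
    Returns ``None`` ("no process due") when the schedule is empty or the
    earliest entry is due after ``now``.
    """
    entry = schedule.peek()
    if entry is None or entry.due > now:
        return None
    popped = schedule.pop_next()
    assert popped is not None
    return popped.process_id
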