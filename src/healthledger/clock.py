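"""Injectable clocks.

All latency semantics in the ledger (batch timeouts, lifecycle
timestamps, benchmark metrics) are expressed against an abstract clock so
that tests and benchmarks run on a deterministic simulated clock while a
deployment may use wall time.  Simulated time is a float in seconds from
an arbitrary epoch.
"""

from __future__ import annotations

import time
from datetime import datetime, timezone

#: Epoch that simulated second 0.0 maps to when rendering RFC 3339.
SIM_EPOCH = datetime(2021, 1, 22, tzinfo=timezone.utc).timestamp()


def rfc3339(t: float) -> str:
    """Render a clock reading as an RFC 3339 UTC timestamp (µs precision)."""
    dt = datetime.fromtimestamp(SIM_EPOCH + t, tz=timezone.utc)
    return dt.strftime("%Y-%m-%dT%H:%M:%S.%fZ")


class SimulatedClock:
    """Manually advanced monotone clock."""

    def __init__(self, start: float = 0.0):
        self._now = float(start)

    def now(self) -> float:
        return self._now

    def advance(self, dt: float) -> float:
        if dt < 0:
            raise ValueError("clock cannot go backwards")
        self._now += dt
        return self._now

    def advance_to(self, t: float) -> float:
        if t < self._now:
            raise ValueError("clock cannot go backwards")
        self._now = float(t)
        return self._now


class WallClock:
    """Real time, offset so runs start near t=0."""

    def __init__(self):
        self._t0 = time.time()

    def now(self) -> float:
        return time.time() - self._t0

    def advance(self, dt: float) -> float:
        if dt > 0:
            time.sleep(dt)
        return self.now()

    def advance_to(self, t: float) -> float:
        dt = t - self.now()
        if dt > 0:
            time.sleep(dt)
        return self.now()
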