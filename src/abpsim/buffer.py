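"""Bounded single-producer / single-consumer ring buffer.

Decouples the template feeder from the waveform consumer, mirroring the
circular buffer that carried the normalized pulse-wave array between
threads in the original interface.  Two overflow policies are supported:

``block``
    The producer waits for free space (lossless; the default).
``overwrite``
    The oldest samples are dropped to make room (emulates real-time
    dropout); drops are counted in :attr:`RingBuffer.dropped`.

Reads never observe uninitialized slots: a read of ``n`` samples blocks
until ``n`` samples have actually been written (or the buffer is closed).
"""

from __future__ import annotations

import threading
from collections import deque
from typing import Iterable

import numpy as np

from .errors import EngineError

__all__ = ["RingBuffer"]

_POLICIES = ("block", "overwrite")


class RingBuffer:
    """Bounded FIFO of float samples with SPSC discipline."""

    def __init__(self, capacity: int, policy: str = "block", timeout: float = 10.0):
        if capacity < 1:
            raise EngineError(f"ring buffer capacity must be >= 1, got {capacity}")
        if policy not in _POLICIES:
            raise EngineError(f"unknown buffer policy {policy!r}; choose from {_POLICIES}")
        self._capacity = int(capacity)
        self._policy = policy
        self._timeout = timeout
        self._data: deque[float] = deque()
        self._cond = threading.Condition()
        self._closed = False
        self.dropped = 0

    @property
    def capacity(self) -> int:
        return self._capacity

    @property
    def policy(self) -> str:
        return self._policy

    def __len__(self) -> int:
        with self._cond:
            return len(self._data)

    def close(self) -> None:
        """Wake all waiters; subsequent writes are refused, reads drain then fail."""
        with self._cond:
            self._closed = True
            self._cond.notify_all()

    @property
    def closed(self) -> bool:
        return self._closed

    def write(self, values: Iterable[float]) -> bool:
        """Append samples; returns False if the buffer was closed mid-write."""
        for value in np.asarray(list(values), dtype=float):
            with self._cond:
                if self._policy == "overwrite":
                    if self._closed:
                        return False
                    if len(self._data) >= self._capacity:
                        self._data.popleft()
                        self.dropped += 1
                else:
                    while len(self._data) >= self._capacity and not self._closed:
                        if not self._cond.wait(self._timeout):
                            raise EngineError(
                                "ring buffer write timed out waiting for space "
                                "(consumer stalled?)"
                            )
                    if self._closed:
                        return False
                self._data.append(float(value))
                self._cond.notify_all()
        return True

    def read(self, n: int) -> np.ndarray:
        """Pop exactly ``n`` samples in FIFO order, blocking until available."""
        if n < 0:
            raise EngineError(f"cannot read {n} samples")
        with self._cond:
            while len(self._data) < n and not self._closed:
                if not self._cond.wait(self._timeout):
                    raise EngineError(
                        "ring buffer read timed out waiting for data (producer stalled?)"
                    )
            if len(self._data) < n:
                raise EngineError(
                    f"ring buffer closed with {len(self._data)} samples, needed {n}"
                )
            out = np.array([self._data.popleft() for _ in range(n)], dtype=float)
            self._cond.notify_all()
            return out
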