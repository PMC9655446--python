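"""Video-sequence smoothing: frame sampling and buffered majority voting.

Per-frame identifications flicker — one missed frame in a run of hits makes
the on-screen label blink. A fixed-size FIFO buffer of the most recent
per-frame ``pipID`` values smooths this: once the buffer has filled, the
most frequent entry becomes ``bufID`` and the fraction of slots it occupies
becomes ``bufScore`` in [0, 1]. A second threshold (``bufThreshold``)
rejects low-consensus windows, mirroring the still-image threshold rule
(strict ``>`` to accept).

UNIDENTIFIED frames occupy buffer slots — they count in the denominator of
``bufScore`` — but cannot win the vote unless the buffer holds nothing else.
"""

from __future__ import annotations

import math
from collections import Counter, deque
from dataclasses import dataclass, replace

from .exceptions import InvalidInputError, InvalidStateError
from .lookup import UNIDENTIFIED

__all__ = [
    "StreamConfig",
    "Buffer",
    "BufferResult",
    "sample_indices",
    "buffer_push",
    "buffer_vote",
    "apply_buf_threshold",
]


@dataclass
class StreamConfig:
    """Sampling interval n, buffer capacity, and the buffer threshold."""

    sample_interval: int = 6
    buffer_size: int = 10
    buf_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_interval < 1:
            raise InvalidInputError("sample_interval must be >= 1")
        if self.buffer_size < 1:
            raise InvalidInputError("buffer_size must be >= 1")
        if not 0.0 <= self.buf_threshold <= 1.0:
            raise InvalidInputError("buf_threshold outside [0, 1]")


class Buffer:
    """Fixed-capacity FIFO of per-frame pipIDs."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise InvalidInputError("capacity must be >= 1")
        self.capacity = int(capacity)
        self._items: deque[str] = deque(maxlen=self.capacity)

    @property
    def contents(self) -> list[str]:
        return list(self._items)

    @property
    def full(self) -> bool:
        return len(self._items) == self.capacity

    def __len__(self) -> int:
        return len(self._items)

    def push(self, pip_id: str) -> "Buffer":
        self._items.append(str(pip_id))
        return self

    def __repr__(self) -> str:
        return f"Buffer(capacity={self.capacity}, contents={self.contents})"


@dataclass
class BufferResult:
    """Outcome of one buffer vote; no output until the buffer first fills."""

    buf_id: str
    buf_score: float
    ready: bool


def sample_indices(total_frames: int, n: int) -> list[int]:
    """Frame indices 0, n, 2n, ... below ``total_frames``.

    At 30 fps with n = 6 this is one sample every 200 ms — 100 samples
    across a 20 s clip.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if total_frames <= 0:
        return []
    return list(range(0, total_frames, n))


def buffer_push(buffer: Buffer, pip_id: str) -> Buffer:
    """Append a pipID, evicting the oldest entry when at capacity."""
    return buffer.push(pip_id)


def buffer_vote(buffer: Buffer) -> BufferResult:
    """Majority vote over a full buffer.

    ``ready`` is False until the buffer first fills. When full, ``bufID`` is
    the most frequent entry (UNIDENTIFIED is eligible only if it is the sole
    entry kind) and ``bufScore`` is its slot fraction count/capacity. Vote
    ties go to the identity pushed most recently among the tied ones.
    """
    if not buffer.full:
        return BufferResult(buf_id=UNIDENTIFIED, buf_score=math.nan, ready=False)
    items = buffer.contents
    counts = Counter(items)
    eligible = {k: v for k, v in counts.items() if k != UNIDENTIFIED} or dict(counts)
    last_seen = {ident: i for i, ident in enumerate(items)}
    winner = max(eligible, key=lambda ident: (eligible[ident], last_seen[ident]))
    return BufferResult(
        buf_id=winner, buf_score=eligible[winner] / buffer.capacity, ready=True
    )


def apply_buf_threshold(result: BufferResult, buf_threshold: float) -> BufferResult:
    """Reject a low-consensus window: keep bufID only when bufScore > threshold."""
    if not result.ready:
        raise InvalidStateError("buffer has not filled yet")
    if result.buf_score > buf_threshold:
        return result
    return replace(result, buf_id=UNIDENTIFIED)
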