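"""Temporal sampling schedules for dynamic OCT acquisition.

A dynamic OCT recording nominally consists of ``N`` B-mode frames collected
at a uniform interval ``ts`` (total span ``ttotal = N * ts``).  Temporal
compression retains only a subset of those frame slots.  Two schemes are
supported:

* **UTS** (uniform temporal sub-sampling): keep every ``r``-th frame.  The
  shortest measurable lag becomes ``r * ts``, which biases the lag-``ts``
  autocorrelation low for fluctuations faster than ``r * ts``.
* **NUTS** (non-uniform temporal sampling): keep *adjacent pairs* of frames
  separated by exactly ``ts``, with a dead time of ``2 r ts`` between pair
  starts — pairs ``(0, 1), (2r, 2r+1), (4r, 4r+1), ...``.  Each pair still
  probes the lag-``ts`` correlation, while the pairs spread over the full
  span preserve the long-term (mean-signal) estimate.

``r = 1`` reduces both schemes to full sampling (for even ``N`` in the NUTS
case).  Schedules are plain frozen dataclasses with 0-based frame indices and
serialize to/from a small JSON dialect used by the command-line tool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path


class Method(str, Enum):
    """Temporal sampling scheme identifier."""

    FULL = "full"
    UTS = "uts"
    NUTS = "nuts"


@dataclass(frozen=True)
class AcquisitionParams:
    """Uniform acquisition grid: frame interval and nominal frame count.

    Parameters
    ----------
    ts : float
        Frame (sampling) interval in seconds, > 0.
    n_frames : int
        Number of uniformly spaced frame slots N, >= 2 so at least one
        adjacent pair exists.
    """

    ts: float
    n_frames: int

    def __post_init__(self) -> None:
        if not self.ts > 0:
            raise ValueError(f"frame interval ts must be > 0, got {self.ts}")
        if self.n_frames < 2:
            raise ValueError(f"need at least 2 frame slots, got {self.n_frames}")

    @property
    def ttotal(self) -> float:
        """Total observation span N * ts in seconds (derived, never stored)."""
        return self.n_frames * self.ts


@dataclass(frozen=True)
class SamplingSchedule:
    """A validated set of retained frame slots for one compression scheme.

    Attributes
    ----------
    method : Method
        FULL, UTS or NUTS.
    r : int
        Compression ratio (>= 1); r = 1 means no compression.
    n_frames : int
        Nominal uncompressed frame count N the schedule was built for.
    indices : tuple of int
        Sorted retained frame slots, 0-based, all in [0, N-1].
    pair_starts : tuple of int
        First-of-pair slots (NUTS only; empty otherwise).
    """

    method: Method
    r: int
    n_frames: int
    indices: tuple[int, ...]
    pair_starts: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError(f"compression ratio must be >= 1, got {self.r}")
        if self.n_frames < 2:
            raise ValueError(f"need at least 2 frame slots, got {self.n_frames}")
        idx = self.indices
        if not idx:
            raise ValueError("schedule retains no frames")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("indices must be strictly increasing")
        if idx[0] < 0 or idx[-1] > self.n_frames - 1:
            raise ValueError("indices out of range [0, N-1]")
        if self.method is Method.NUTS:
            expected = tuple(
                i for s in self.pair_starts for i in (s, s + 1)
            )
            if expected != idx:
                raise ValueError("NUTS indices must be the pair starts and their successors")
        elif self.pair_starts:
            raise ValueError(f"pair_starts only meaningful for NUTS, not {self.method}")

    @property
    def n_samples(self) -> int:
        """Number of retained frames."""
        return len(self.indices)

    @property
    def n_pairs(self) -> int:
        """Number of adjacent sample pairs N' (NUTS only; 0 otherwise)."""
        return len(self.pair_starts)

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize as ``{method, r, N, indices}`` JSON; optionally write it."""
        payload = {
            "method": self.method.value,
            "r": self.r,
            "N": self.n_frames,
            "indices": list(self.indices),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SamplingSchedule":
        """Rebuild a schedule from :meth:`to_json` output (text or file path)."""
        p = Path(source) if not str(source).lstrip().startswith("{") else None
        payload = json.loads(p.read_text() if p else str(source))
        method = Method(payload["method"])
        sched = make_schedule(method, payload["N"], payload["r"])
        if list(sched.indices) != list(payload["indices"]):
            raise ValueError("stored indices do not match a valid schedule for (method, N, r)")
        return sched


def full_schedule(n_frames: int) -> SamplingSchedule:
    """Schedule retaining every frame slot (no compression)."""
    if n_frames < 2:
        raise ValueError(f"need at least 2 frame slots, got {n_frames}")
    return SamplingSchedule(Method.FULL, 1, n_frames, tuple(range(n_frames)))


def uts_schedule(n_frames: int, r: int) -> SamplingSchedule:
    """Uniform sub-sampling: keep slots 0, r, 2r, ... up to N-1.

    The retained series has an effective sampling interval of ``r * ts``;
    its adjacent-product autocorrelation therefore estimates the correlation
    at lag ``r * ts``, not ``ts`` — the deliberate bias of the UTS scheme.
    """
    if n_frames < 2:
        raise ValueError(f"need at least 2 frame slots, got {n_frames}")
    if r < 1:
        raise ValueError(f"compression ratio must be >= 1, got {r}")
    indices = tuple(range(0, n_frames, r))
    return SamplingSchedule(Method.UTS, r, n_frames, indices)


def nuts_schedule(n_frames: int, r: int) -> SamplingSchedule:
    """Pair sampling: pairs (2kr, 2kr+1) for k = 0, 1, ... while 2kr+1 <= N-1.

    A trailing slot that cannot complete a pair is never retained (no
    padding), so every retained pair spans exactly one ``ts``.
    """
    if n_frames < 2:
        raise ValueError(f"need at least 2 frame slots, got {n_frames}")
    if r < 1:
        raise ValueError(f"compression ratio must be >= 1, got {r}")
    pair_starts = []
    k = 0
    while 2 * k * r + 1 <= n_frames - 1:
        pair_starts.append(2 * k * r)
        k += 1
    starts = tuple(pair_starts)
    indices = tuple(i for s in starts for i in (s, s + 1))
    return SamplingSchedule(Method.NUTS, r, n_frames, indices, starts)


def make_schedule(method: Method | str, n_frames: int, r: int = 1) -> SamplingSchedule:
    """Factory dispatching on the method tag."""
    method = Method(method)
    if method is Method.FULL:
        return full_schedule(n_frames)
    if method is Method.UTS:
        return uts_schedule(n_frames, r)
    return nuts_schedule(n_frames, r)


def compression_achieved(schedule: SamplingSchedule, n_frames: int | None = None) -> float:
    """Realized compression N / n_samples as a real number.

    The nominal ratio ``r`` and the realized ratio differ slightly because
    retained counts are integers (e.g. NUTS at r=8, N=100 keeps 14 samples,
    a realized compression of about 7.14).
    """
    n = schedule.n_frames if n_frames is None else n_frames
    if n != schedule.n_frames:
        raise ValueError(
            f"schedule was built for N={schedule.n_frames}, not N={n}"
        )
    return n / schedule.n_samples
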