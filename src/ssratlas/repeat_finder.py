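"""Detection of perfect maximal microsatellites (SSRs).

An SSR here is a maximal run of perfectly tandem-repeated sequence with a
primitive (smallest) period between ``min_period`` and ``max_period`` bases,
a total length of at least ``min_size`` bases and at least ``min_exponent``
repeat units.  Runs never cross N or any other non-ACGT character, and each
run is reported exactly once, at its primitive period — a run of ``ATATATAT``
satisfies the period-4 equality too, but is reported only as a period-2
repeat.  Homopolymer runs (primitive period 1) are excluded by default, since
mononucleotide arrays are not useful 2–6 bp microsatellite markers; the
exclusion is configurable.

Two independent implementations are provided: :func:`find_repeats`, a
vectorised production scanner, and :func:`oracle_find_repeats`, a brute-force
positional enumeration used as a testing oracle.  Their outputs are equal by
contract.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, List, TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .io_formats import SequenceRecord

_ACGT_SEGMENT = re.compile(r"[ACGT]+")


@dataclass(frozen=True)
class ScanParams:
    """Thresholds for the repeat scan.

    Defaults match the marker-mining convention: perfect repeats of 12+
    bases, motif length 2–6, at least two repeat units.
    """

    min_size: int = 12
    min_period: int = 2
    max_period: int = 6
    min_exponent: float = 2.0
    exclude_primitive_period_1: bool = True

    def __post_init__(self) -> None:
        if self.min_period < 1:
            raise ValueError("min_period must be >= 1")
        if self.max_period < self.min_period:
            raise ValueError("max_period must be >= min_period")


@dataclass(frozen=True, order=True)
class RepeatHit:
    """One perfect maximal SSR.

    Coordinates are 0-based half-open on the scaffold.  ``period`` is the
    primitive period; ``motif`` is the first ``period`` bases of the run.
    """

    scaffold: str
    start: int
    end: int
    period: int
    motif: str = field(compare=False)

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def exponent(self) -> float:
        return self.size / self.period


def primitive_period(run: str) -> int:
    """Smallest p >= 1 with run[k] == run[k+p] for all valid k.

    Raises ``ValueError`` on empty or non-ACGT input.
    """
    if not run or any(c not in "ACGT" for c in run):
        raise ValueError("primitive_period requires a non-empty ACGT string")
    for p in range(1, len(run) + 1):
        if run[p:] == run[:-p] or p == len(run):
            return p
    raise AssertionError("unreachable")  # pragma: no cover


def _segments(sequence: str) -> Iterable[tuple[int, str]]:
    """Yield (offset, subsequence) for maximal ACGT stretches."""
    for m in _ACGT_SEGMENT.finditer(sequence):
        yield m.start(), m.group(0)


def _qualifies(size: int, period: int, params: ScanParams) -> bool:
    return size >= params.min_size and size / period >= params.min_exponent


def _emit(scaffold, seg, off, a, b, p, params, out) -> None:
    """Validate a p-maximal candidate run seg[a:b] and append if it belongs."""
    run = seg[a:b]
    q = primitive_period(run)
    if q == 1:
        # homopolymer: report once (during the first scanned period) if kept
        if params.exclude_primitive_period_1 or p != params.min_period:
            return
        if _qualifies(len(run), 1, params):
            out.append(RepeatHit(scaffold, off + a, off + b, 1, run[0]))
        return
    if q != p:
        return  # reported at its primitive period's own scan
    if _qualifies(len(run), p, params):
        out.append(RepeatHit(scaffold, off + a, off + b, p, run[:p]))


def find_repeats(record: "SequenceRecord | str", params: ScanParams | None = None,
                 scaffold: str | None = None) -> List[RepeatHit]:
    """Scan a sequence for perfect maximal SSRs.

    ``record`` may be a :class:`~ssratlas.io_formats.SequenceRecord` or a raw
    uppercase string (then ``scaffold`` names the output hits).  Hits are
    sorted by (start, period).
    """
    params = params or ScanParams()
    if isinstance(record, str):
        seq, name = record, scaffold or ""
    else:
        seq, name = record.sequence, record.id
    hits: List[RepeatHit] = []
    for off, seg in _segments(seq):
        arr = np.frombuffer(seg.encode("ascii"), dtype=np.uint8)
        n = len(arr)
        for p in range(params.min_period, params.max_period + 1):
            if n < p + 1:
                continue
            eq = arr[:-p] == arr[p:]
            padded = np.empty(len(eq) + 2, dtype=bool)
            padded[0] = padded[-1] = False
            padded[1:-1] = eq
            diffs = np.diff(padded.astype(np.int8))
            starts = np.flatnonzero(diffs == 1)
            ends = np.flatnonzero(diffs == -1)  # exclusive, in eq coordinates
            for a, b in zip(starts, ends):
                # equality block [a, b) ==> run covers seg[a : b+p]
                if b + p - a >= params.min_size or not params.exclude_primitive_period_1:
                    _emit(name, seg, off, int(a), int(b) + p, p, params, hits)
    hits = sorted(set(hits), key=lambda h: (h.scaffold, h.start, h.period))
    return hits


def oracle_find_repeats(record: "SequenceRecord | str", params: ScanParams | None = None,
                        scaffold: str | None = None) -> List[RepeatHit]:
    """Brute-force reference scanner (quadratic-ish; keep inputs small).

    Independently enumerates, for every period and every left-maximal start
    position, the maximal perfectly periodic run, reduces it to its primitive
    period and applies the thresholds.  Contractually identical in output to
    :func:`find_repeats`.
    """
    params = params or ScanParams()
    if isinstance(record, str):
        seq, name = record, scaffold or ""
    else:
        seq, name = record.sequence, record.id
    found = set()
    for off, seg in _segments(seq):
        n = len(seg)
        for p in range(params.min_period, params.max_period + 1):
            i = 0
            while i < n - p:
                if seg[i] != seg[i + p] or (i > 0 and seg[i - 1] == seg[i - 1 + p]):
                    i += 1
                    continue
                j = i
                while j < n - p and seg[j] == seg[j + p]:
                    j += 1
                run = seg[i:j + p]
                # smallest period by direct definition
                q = next(c for c in range(1, len(run) + 1)
                         if all(run[k] == run[k + c] for k in range(len(run) - c)))
                if q == p and _qualifies(len(run), p, params):
                    found.add(RepeatHit(name, off + i, off + j + p, p, run[:p]))
                elif q == 1 and not params.exclude_primitive_period_1 \
                        and p == params.min_period and _qualifies(len(run), 1, params):
                    found.add(RepeatHit(name, off + i, off + j + p, 1, run[0]))
                i = j + 1
        # leave homopolymer handling consistent with find_repeats
    return sorted(found, key=lambda h: (h.scaffold, h.start, h.period))
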