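"""Dual-buffer blocking, the embedded per-block index, and range planning.

Stream-0 lines are copied into buffer A; stream-1 lines put a bare
placeholder newline into A (preserving global line order) and their content
into buffer B. A buffer is flushed into a block when its byte size exceeds
the threshold; after three consecutive B flushes A is force-flushed, which
bounds the number of B blocks any A block can overlap by 3. That bound is
what caps a random-access plan at 4 blocks inside one A span and 8 across
one A/A boundary.

Buffers hold raw (unpacked) line bytes; packing and backend encoding happen
downstream at flush time, so index entries stay in raw line coordinates.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

from .errors import CorruptionError, QscompError, RangeError
from .partition import STREAM_A, STREAM_B
from .qsio import QualityRecord

DEFAULT_THRESHOLD = 8 * 1024 * 1024
FORCE_FLUSH_B_COUNT = 3


@dataclass
class BlockMeta:
    """Directory entry for one compressed block.

    ``start_line``/``end_line`` are inclusive global 0-based line ordinals:
    the full covered span for A blocks, the first/last stream-1 line for B
    blocks. ``s1_before`` counts stream-1 lines before ``start_line`` (A
    blocks only; 0 for B). ``n_lines`` is the number of lines stored in the
    block. ``offset``/``comp_len``/``raw_len`` locate the payload in the
    container and give its packed (pre-backend) size.
    """

    stream: int
    start_line: int
    end_line: int
    s1_before: int
    n_lines: int
    offset: int = 0
    comp_len: int = 0
    raw_len: int = 0


@dataclass
class FlushEvent:
    """One flushed buffer: the raw LF-terminated line bytes plus its meta."""

    meta: BlockMeta
    data: bytes

    @property
    def lines(self) -> List[bytes]:
        return self.data.split(b"\n")[:-1]


@dataclass
class BufferState:
    threshold_T: int = DEFAULT_THRESHOLD
    buf_A: bytearray = field(default_factory=bytearray)
    buf_B: bytearray = field(default_factory=bytearray)
    consecutive_B_flushes: int = 0
    next_index: int = 0          # expected global ordinal of the next record
    first_line_A: int = 0        # ordinal of A's first pending line
    s1_before_A: int = 0         # stream-1 lines before first_line_A
    s1_total: int = 0            # stream-1 lines seen so far
    lines_in_A: int = 0
    b_ordinals: List[int] = field(default_factory=list)  # pending B lines
    lines_in_B: int = 0

    def _flush_A(self) -> FlushEvent:
        meta = BlockMeta(
            stream=STREAM_A,
            start_line=self.first_line_A,
            end_line=self.next_index - 1,
            s1_before=self.s1_before_A,
            n_lines=self.lines_in_A,
        )
        ev = FlushEvent(meta, bytes(self.buf_A))
        self.buf_A = bytearray()
        self.first_line_A = self.next_index
        self.s1_before_A = self.s1_total
        self.lines_in_A = 0
        self.consecutive_B_flushes = 0
        return ev

    def _flush_B(self) -> FlushEvent:
        meta = BlockMeta(
            stream=STREAM_B,
            start_line=self.b_ordinals[0],
            end_line=self.b_ordinals[-1],
            s1_before=0,
            n_lines=self.lines_in_B,
        )
        ev = FlushEvent(meta, bytes(self.buf_B))
        self.buf_B = bytearray()
        self.b_ordinals = []
        self.lines_in_B = 0
        self.consecutive_B_flushes += 1
        return ev


def append(state: BufferState, record: QualityRecord, label: int) -> List[FlushEvent]:
    """Route one record into the buffers; return any flush events in order."""
    if record.index != state.next_index:
        raise QscompError(
            f"out-of-order record: got index {record.index}, "
            f"expected {state.next_index}"
        )
    state.next_index += 1
    if label == STREAM_A:
        state.buf_A += record.line
        state.buf_A += b"\n"
    else:
        state.buf_A += b"\n"  # placeholder keeps global order in A
        state.buf_B += record.line
        state.buf_B += b"\n"
        state.b_ordinals.append(record.index)
        state.lines_in_B += 1
        state.s1_total += 1
    state.lines_in_A += 1

    events: List[FlushEvent] = []
    if len(state.buf_B) > state.threshold_T:
        events.append(state._flush_B())
        if state.consecutive_B_flushes >= FORCE_FLUSH_B_COUNT:
            events.append(state._flush_A())
    if len(state.buf_A) > state.threshold_T:
        events.append(state._flush_A())
    return events


def finalize(state: BufferState) -> List[FlushEvent]:
    """Flush whatever is pending at end of input: B first, then A."""
    events: List[FlushEvent] = []
    if state.lines_in_B:
        events.append(state._flush_B())
    if state.lines_in_A:
        events.append(state._flush_A())
    return events


# ---------------------------------------------------------------------------
# range planning and merge
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RangePlan:
    a: int
    b: int
    a_blocks: List[BlockMeta]
    b_blocks: List[BlockMeta]

    @property
    def blocks(self) -> List[BlockMeta]:
        return self.a_blocks + self.b_blocks


def split_directory(directory: Sequence[BlockMeta]):
    a = [m for m in directory if m.stream == STREAM_A]
    b = [m for m in directory if m.stream == STREAM_B]
    return a, b


def total_lines(directory: Sequence[BlockMeta]) -> int:
    a_blocks, _ = split_directory(directory)
    return a_blocks[-1].end_line + 1 if a_blocks else 0


def plan_range(directory: Sequence[BlockMeta], a: int, b: int) -> RangePlan:
    """Choose the minimal block set whose decode reconstructs lines a..b."""
    n = total_lines(directory)
    if not (0 <= a <= b < n):
        raise RangeError(f"range [{a}, {b}] outside stored lines [0, {n - 1}]")
    a_blocks, b_blocks = split_directory(directory)
    sel_a = [m for m in a_blocks if m.start_line <= b and m.end_line >= a]
    sel_b = [m for m in b_blocks if m.start_line <= b and m.end_line >= a]
    return RangePlan(a, b, sel_a, sel_b)


def b_block_first_rank(directory: Sequence[BlockMeta], block: BlockMeta) -> int:
    """Stream-1 ordinal rank of a B block's first line (directory arithmetic)."""
    _, b_blocks = split_directory(directory)
    rank = 0
    for m in b_blocks:
        if m is block or m.start_line == block.start_line:
            return rank
        rank += m.n_lines
    raise CorruptionError("B block missing from directory")


def merge(
    decoded_A: Sequence[Sequence[bytes]],
    decoded_B: Sequence[Sequence[bytes]],
    plan: RangePlan,
    directory: Sequence[BlockMeta],
    has_stream1: Optional[bool] = None,
) -> List[bytes]:
    """Reassemble lines ``plan.a .. plan.b`` from decoded A and B blocks.

    A placeholder (empty A entry) is only possible when the container holds
    stream-1 content at all: with a positive threshold alpha, every empty
    line classifies to stream 1, so empty entries in A are unambiguous
    placeholders; with alpha=0 no stream-1 lines exist and empty A entries
    are genuine empty lines.
    """
    if has_stream1 is None:
        has_stream1 = any(m.stream == STREAM_B for m in directory)
    _, all_b = split_directory(directory)
    b_starts = [m.start_line for m in all_b]
    b_first_rank: List[int] = []
    rank = 0
    for m in all_b:
        b_first_rank.append(rank)
        rank += m.n_lines
    decoded_b_by_start = {
        m.start_line: decoded_B[i] for i, m in enumerate(plan.b_blocks)
    }

    out: List[bytes] = []
    for meta, lines in zip(plan.a_blocks, decoded_A):
        if len(lines) != meta.n_lines:
            raise CorruptionError(
                f"A block at line {meta.start_line}: expected {meta.n_lines} "
                f"lines, decoded {len(lines)}"
            )
        s1_rank = meta.s1_before
        for pos, line in enumerate(lines):
            ordinal = meta.start_line + pos
            is_placeholder = has_stream1 and line == b""
            if is_placeholder:
                bi = bisect.bisect_right(b_starts, ordinal) - 1
                if bi < 0 or all_b[bi].end_line < ordinal:
                    raise CorruptionError(
                        f"no B block covers stream-1 line {ordinal}"
                    )
                if plan.a <= ordinal <= plan.b:
                    bmeta = all_b[bi]
                    blines = decoded_b_by_start.get(bmeta.start_line)
                    if blines is None:
                        raise CorruptionError(
                            f"B block at line {bmeta.start_line} not in plan"
                        )
                    off = s1_rank - b_first_rank[bi]
                    if not (0 <= off < len(blines)):
                        raise CorruptionError(
                            f"stream-1 alignment failure at line {ordinal}"
                        )
                    out.append(blines[off])
                s1_rank += 1
            elif plan.a <= ordinal <= plan.b:
                out.append(line)
    return out


def check_structure(directory: Sequence[BlockMeta]) -> None:
    """Assert the directory invariants produced by the flush rules."""
    a_blocks, b_blocks = split_directory(directory)
    expect = 0
    for m in a_blocks:
        if m.start_line != expect or m.end_line < m.start_line:
            raise CorruptionError("A blocks do not tile the line range")
        if m.n_lines != m.end_line - m.start_line + 1:
            raise CorruptionError("A block line count mismatch")
        expect = m.end_line + 1
    prev_end = -1
    for m in b_blocks:
        if m.start_line <= prev_end:
            raise CorruptionError("B block spans overlap or are unordered")
        prev_end = m.end_line
    # forced-flush consequence: any A span overlaps at most 3 B spans
    for m in a_blocks:
        k = sum(
            1
            for bm in b_blocks
            if bm.start_line <= m.end_line and bm.end_line >= m.start_line
        )
        if k > FORCE_FLUSH_B_COUNT:
            raise CorruptionError(
                f"A block [{m.start_line}, {m.end_line}] overlaps {k} B blocks"
            )
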