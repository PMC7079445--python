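"""Adaptive packing of quality bytes into single code bytes 1..255.

The table is a pure function of the modal quality value C: four contiguous
code groups are enumerated in lexicographic order, clipping windows to the
legal alphabet [33, 104]:

  singles  every value 33..104               codes 1..72
  triples  (a,b,c), a,b,c in [C-1, C+1]      codes from 73
  pairs    (a,b),   a,b   in [C-5, C+6]      codes after triples
  runs     C repeated 4..15 times            final 12 codes

Code 0 is reserved as the line terminator inside packed blocks. Encoding is
greedy longest-match with priority run > triple > pair > single; decoding is
a pure table lookup, so the transform is bijective on packed streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Sequence, Tuple

from .errors import CorruptionError, ParameterError, ValidationError
from .qsio import QUAL_MAX, QUAL_MIN, QualityRecord

TERMINATOR = 0
RUN_MIN = 4
RUN_MAX = 15
TRIPLE_HALF_WIDTH = 1
PAIR_LO_OFFSET = 5
PAIR_HI_OFFSET = 6


def compute_mode(sample: Sequence[QualityRecord]) -> int:
    """Most frequent quality byte over the sample; ties -> smallest value."""
    counts = [0] * 256
    total = 0
    for rec in sample:
        for b in rec.line:
            counts[b] += 1
        total += len(rec.line)
    if total == 0:
        raise ParameterError("cannot compute modal value of an empty sample")
    best = max(range(QUAL_MIN, QUAL_MAX + 1), key=lambda v: (counts[v], -v))
    return best


def _window(lo: int, hi: int) -> List[int]:
    return list(range(max(lo, QUAL_MIN), min(hi, QUAL_MAX) + 1))


@dataclass(frozen=True)
class PackTable:
    """Bijective code<->tuple mapping anchored on modal value C."""

    C: int
    encode_map: Dict[Tuple[int, ...], int]
    decode_map: Dict[int, Tuple[int, ...]]
    triple_window: Tuple[int, int] = field(default=(0, 0))
    pair_window: Tuple[int, int] = field(default=(0, 0))
    run_code_base: int = 0  # code of the length-RUN_MIN run

    @property
    def n_codes(self) -> int:
        return len(self.decode_map)


def build_pack_table(C: int) -> PackTable:
    """Deterministically construct the packing table for modal value ``C``."""
    if not (QUAL_MIN <= C <= QUAL_MAX):
        raise ParameterError(f"modal value {C} outside [{QUAL_MIN}, {QUAL_MAX}]")

    encode: Dict[Tuple[int, ...], int] = {}
    code = 1
    for v in range(QUAL_MIN, QUAL_MAX + 1):  # singles: 33->1 ... 104->72
        encode[(v,)] = code
        code += 1

    tri = _window(C - TRIPLE_HALF_WIDTH, C + TRIPLE_HALF_WIDTH)
    for a in tri:
        for b in tri:
            for c in tri:
                encode[(a, b, c)] = code
                code += 1

    pair = _window(C - PAIR_LO_OFFSET, C + PAIR_HI_OFFSET)
    for a in pair:
        for b in pair:
            encode[(a, b)] = code
            code += 1

    run_base = code
    for length in range(RUN_MIN, RUN_MAX + 1):
        encode[(C,) * length] = code
        code += 1

    if code - 1 > 255:  # cannot happen for any C in [33, 104]; guard anyway
        raise ParameterError(f"table for C={C} needs {code - 1} codes > 255")

    decode = {v: k for k, v in encode.items()}
    return PackTable(
        C=C,
        encode_map=encode,
        decode_map=decode,
        triple_window=(tri[0], tri[-1]),
        pair_window=(pair[0], pair[-1]),
        run_code_base=run_base,
    )


def pack(line: bytes, table: PackTable) -> bytes:
    """Greedy longest-match packing of one line, terminator appended."""
    C = table.C
    t_lo, t_hi = table.triple_window
    p_lo, p_hi = table.pair_window
    enc = table.encode_map
    out = bytearray()
    n = len(line)
    i = 0
    while i < n:
        b0 = line[i]
        if not (QUAL_MIN <= b0 <= QUAL_MAX):
            raise ValidationError(
                f"byte value {b0} at column {i} outside [{QUAL_MIN}, {QUAL_MAX}]"
            )
        if b0 == C:
            run = 1
            while run < RUN_MAX and i + run < n and line[i + run] == C:
                run += 1
            if run >= RUN_MIN:
                out.append(table.run_code_base + run - RUN_MIN)
                i += run
                continue
        if (
            i + 2 < n
            and t_lo <= b0 <= t_hi
            and t_lo <= line[i + 1] <= t_hi
            and t_lo <= line[i + 2] <= t_hi
        ):
            out.append(enc[(b0, line[i + 1], line[i + 2])])
            i += 3
            continue
        if i + 1 < n and p_lo <= b0 <= p_hi and p_lo <= line[i + 1] <= p_hi:
            out.append(enc[(b0, line[i + 1])])
            i += 2
            continue
        out.append(b0 - QUAL_MIN + 1)
        i += 1
    out.append(TERMINATOR)
    return bytes(out)


def pack_block(lines: Sequence[bytes], table: PackTable) -> bytes:
    """Pack a block of lines; one terminator per line."""
    return b"".join(pack(line, table) for line in lines)


def unpack(packed: bytes, table: PackTable) -> List[bytes]:
    """Invert :func:`pack_block`: one output line per terminator byte."""
    dec = table.decode_map
    lines: List[bytes] = []
    cur = bytearray()
    for off, code in enumerate(packed):
        if code == TERMINATOR:
            lines.append(bytes(cur))
            cur = bytearray()
            continue
        try:
            cur.extend(dec[code])
        except KeyError:
            raise CorruptionError(f"unknown pack code {code} at offset {off}") from None
    if cur:
        raise CorruptionError("packed stream does not end at a line boundary")
    return lines


def iter_unpack(packed: bytes, table: PackTable) -> Iterator[bytes]:
    yield from unpack(packed, table)
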