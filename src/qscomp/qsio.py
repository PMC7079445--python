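"""Quality-score line I/O and synthetic fixture generation.

Quality lines are byte strings whose bytes lie in ``[QUAL_MIN, QUAL_MAX]``
(ASCII 33..104). Plain files hold one quality line per LF-terminated row;
FASTQ files contribute the quality row of each 4-line record.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, Union

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FormatError, ParameterError, ValidationError

QUAL_MIN = 33
QUAL_MAX = 104
#: number of distinct quality values
ALPHABET_SIZE = QUAL_MAX - QUAL_MIN + 1


@dataclass(frozen=True)
class QualityRecord:
    """One quality line plus its global 0-based ordinal in the file."""

    line: bytes
    index: int

    def validate(self) -> None:
        check_line(self.line, self.index)


def check_line(line: bytes, index: int) -> None:
    """Raise :class:`ValidationError` unless every byte is in [33, 104]."""
    if not line:
        return
    arr = np.frombuffer(line, dtype=np.uint8)
    bad = (arr < QUAL_MIN) | (arr > QUAL_MAX)
    if bad.any():
        pos = int(np.argmax(bad))
        raise ValidationError(
            f"line {index}: byte value {arr[pos]} at column {pos} "
            f"outside [{QUAL_MIN}, {QUAL_MAX}]"
        )


def _iter_plain(handle: io.BufferedReader, strip_cr: bool) -> Iterator[bytes]:
    for raw in handle:
        if raw.endswith(b"\n"):
            raw = raw[:-1]
        if strip_cr and raw.endswith(b"\r"):
            raw = raw[:-1]
        yield raw


def _iter_fastq(path: str) -> Iterator[bytes]:
    with open(path) as handle:
        try:
            n = 0
            for _title, _seq, qual in FastqGeneralIterator(handle):
                if not qual:
                    raise FormatError(f"record {n}: empty quality line in FASTQ")
                yield qual.encode("latin-1")
                n += 1
        except ValueError as exc:  # structural errors from the FASTQ parser
            raise FormatError(f"record {n}: {exc}") from exc


def read_quality_lines(
    path: str,
    mode: str = "plain",
    validate: bool = True,
    strip_cr: bool = False,
) -> Iterator[QualityRecord]:
    """Yield :class:`QualityRecord` objects from a plain or FASTQ file.

    Records arrive in file order with consecutive indices starting at 0. In
    ``fastq`` mode the quality row of each record is extracted; malformed
    structure raises :class:`FormatError` naming the offending record.
    With ``validate`` (default) every byte is checked against [33, 104];
    CR bytes are rejected unless ``strip_cr`` removes a single trailing CR.
    """
    if mode == "plain":
        with open(path, "rb") as handle:
            lines: Iterable[bytes] = _iter_plain(handle, strip_cr)
            yield from _make_records(lines, validate, strip_cr)
    elif mode == "fastq":
        yield from _make_records(_iter_fastq(path), validate, strip_cr)
    else:
        raise ParameterError(f"unknown mode {mode!r} (expected 'plain' or 'fastq')")


def _make_records(
    lines: Iterable[bytes], validate: bool, strip_cr: bool
) -> Iterator[QualityRecord]:
    for index, line in enumerate(lines):
        if b"\r" in line or b"\n" in line:
            raise ValidationError(
                f"line {index}: embedded CR/LF byte (rerun with strip_cr to "
                "normalize trailing CR)"
            )
        if validate:
            check_line(line, index)
        yield QualityRecord(line, index)


def write_quality_lines(records: Iterable[QualityRecord], path: str) -> int:
    """Write records as LF-joined lines with a trailing LF. Returns line count."""
    n = 0
    with open(path, "wb") as handle:
        for rec in records:
            handle.write(rec.line)
            handle.write(b"\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Source:
    """One mixture component: a discrete distribution over [33, 104]."""

    weight: float
    values: tuple = ()
    probs: tuple = ()

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=np.int64)
        pr = np.asarray(self.probs, dtype=np.float64)
        if vals.size == 0 or vals.size != pr.size:
            raise ParameterError("source needs matching non-empty values/probs")
        if vals.min() < QUAL_MIN or vals.max() > QUAL_MAX:
            raise ParameterError("source support must lie in [33, 104]")
        if (pr < 0).any() or not np.isclose(pr.sum(), 1.0, atol=1e-9):
            raise ParameterError("source probabilities must be >= 0 and sum to 1")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the mixture-of-sources line generator.

    ``length`` is either a single int (fixed line length) or an inclusive
    ``(L_min, L_max)`` pair for uniformly random variable lengths.
    """

    n_lines: int
    length: Union[int, tuple]
    sources: Sequence[Source] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self):
        if self.n_lines < 0:
            raise ParameterError("n_lines must be >= 0")
        if isinstance(self.length, tuple):
            lo, hi = self.length
            if not (0 <= lo <= hi):
                raise ParameterError("variable length needs 0 <= L_min <= L_max")
        elif self.length < 0:
            raise ParameterError("fixed length must be >= 0")
        if not self.sources:
            raise ParameterError("at least one source is required")
        total = sum(s.weight for s in self.sources)
        if any(s.weight < 0 for s in self.sources) or abs(total - 1.0) > 1e-9:
            raise ParameterError("mixture weights must be >= 0 and sum to 1")


def point_mass(value: int, weight: float = 1.0) -> Source:
    return Source(weight, (value,), (1.0,))


def peaked_source(center: int, spread: int, weight: float) -> Source:
    """Truncated-geometric peak around ``center``; handy default fixture."""
    vals = np.arange(max(QUAL_MIN, center - spread), min(QUAL_MAX, center + spread) + 1)
    pr = 0.5 ** np.abs(vals - center).astype(float)
    pr /= pr.sum()
    return Source(weight, tuple(int(v) for v in vals), tuple(float(p) for p in pr))


def generate_synthetic(spec: SyntheticSpec) -> list:
    """Return the list of quality lines (bytes) drawn from ``spec``.

    Deterministic for a fixed seed: lines are produced by first assigning a
    source to every line from the mixture weights, then drawing line lengths,
    then drawing all bytes for each source in a single batched call.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_lines
    if n == 0:
        return []

    weights = np.array([s.weight for s in spec.sources], dtype=np.float64)
    weights = weights / weights.sum()
    src_ids = rng.choice(len(spec.sources), size=n, p=weights)

    if isinstance(spec.length, tuple):
        lo, hi = spec.length
        lengths = rng.integers(lo, hi + 1, size=n)
    else:
        lengths = np.full(n, spec.length, dtype=np.int64)

    # batched per-source sampling, then scatter back into file order
    lines: list = [b""] * n
    for sid, source in enumerate(spec.sources):
        mask = src_ids == sid
        if not mask.any():
            continue
        idx = np.nonzero(mask)[0]
        lens = lengths[idx]
        total = int(lens.sum())
        vals = np.asarray(source.values, dtype=np.uint8)
        pr = np.asarray(source.probs, dtype=np.float64)
        pr = pr / pr.sum()
        flat = rng.choice(vals, size=total, p=pr)
        bounds = np.cumsum(lens)[:-1]
        for i, chunk in zip(idx, np.split(flat, bounds)):
            lines[int(i)] = chunk.tobytes()
    return lines


def generate_synthetic_file(spec: SyntheticSpec, path: str) -> int:
    """Generate and write the fixture; returns the number of lines."""
    lines = generate_synthetic(spec)
    return write_quality_lines(
        (QualityRecord(line, i) for i, line in enumerate(lines)), path
    )
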