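"""Single-file container: header, compressed blocks, trailing directory.

Layout (all integers little-endian):

  header   magic ``QSCF`` | u8 version | u8 k | u16 alpha (parts per 10^4)
           | u32 sample_lines | u8 C | u64 threshold | u8 backend-name len
           | backend name | u64 total_lines | u64 total_stream1_lines
           | u16 coder-constants JSON len | JSON
  blocks   backend-encoded packed payloads, written in flush order
  dir      varint block count, then per block: varints stream, start_line,
           end_line, s1_before (A blocks only), n_lines, offset, comp_len,
           raw_len
  footer   u64 directory offset | magic echo ``QSCF`` (12 bytes)

The directory is the only random-access metadata; there is no sidecar file.
Containers are byte-deterministic for a fixed input and configuration.
"""

from __future__ import annotations

import io
import itertools
import json
import logging
import os
import struct
from dataclasses import dataclass, field
from typing import BinaryIO, Iterable, List, Optional, Sequence

from . import blockstore, cmcodec, packing, partition, qsio
from .blockstore import BlockMeta, BufferState
from .errors import CorruptionError, FormatError, RangeError
from .partition import PartitionParams, STREAM_A
from .qsio import QualityRecord

logger = logging.getLogger(__name__)

MAGIC = b"QSCF"
VERSION = 1
FOOTER_SIZE = 12
_HEADER_FMT = "<4sBBHIBQ"  # magic, version, k, alpha_pp10k, M, C, threshold


@dataclass(frozen=True)
class ContainerConfig:
    k: int = 4
    alpha: float = 0.1
    sample_lines: int = 100_000
    threshold: int = blockstore.DEFAULT_THRESHOLD
    backend: str = "cm1"

    @property
    def partition_params(self) -> PartitionParams:
        return PartitionParams(k=self.k, sample_lines=self.sample_lines,
                               alpha=self.alpha)


@dataclass
class ContainerHeader:
    config: ContainerConfig
    C: int
    total_lines: int
    total_s1: int
    coder_constants: dict = field(default_factory=lambda: dict(cmcodec.CODER_CONSTANTS))

    def to_bytes(self) -> bytes:
        alpha_pp10k = round(self.config.alpha * 10_000)
        head = struct.pack(
            _HEADER_FMT, MAGIC, VERSION, self.config.k, alpha_pp10k,
            self.config.sample_lines, self.C, self.config.threshold,
        )
        backend = self.config.backend.encode("ascii")
        consts = json.dumps(self.coder_constants, sort_keys=True,
                            separators=(",", ":")).encode("ascii")
        return (
            head
            + struct.pack("<B", len(backend)) + backend
            + struct.pack("<QQ", self.total_lines, self.total_s1)
            + struct.pack("<H", len(consts)) + consts
        )

    @classmethod
    def from_stream(cls, fh: BinaryIO) -> "ContainerHeader":
        base = fh.read(struct.calcsize(_HEADER_FMT))
        if len(base) < struct.calcsize(_HEADER_FMT):
            raise CorruptionError("container header truncated")
        magic, version, k, alpha_pp10k, m, c, threshold = struct.unpack(
            _HEADER_FMT, base
        )
        if magic != MAGIC:
            raise FormatError(f"bad magic {magic!r}: not a qscomp container")
        if version != VERSION:
            raise FormatError(f"unsupported container version {version}")
        (blen,) = struct.unpack("<B", _must_read(fh, 1, "header"))
        backend = _must_read(fh, blen, "header").decode("ascii")
        total_lines, total_s1 = struct.unpack("<QQ", _must_read(fh, 16, "header"))
        (clen,) = struct.unpack("<H", _must_read(fh, 2, "header"))
        consts = json.loads(_must_read(fh, clen, "header"))
        cfg = ContainerConfig(
            k=k, alpha=alpha_pp10k / 10_000.0, sample_lines=m,
            threshold=threshold, backend=backend,
        )
        return cls(config=cfg, C=c, total_lines=total_lines, total_s1=total_s1,
                   coder_constants=consts)


def _must_read(fh: BinaryIO, n: int, section: str) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise CorruptionError(f"container {section} truncated")
    return data


# --- varints ---------------------------------------------------------------


def write_varint(buf: bytearray, value: int) -> None:
    if value < 0:
        raise ValueError("varints are unsigned")
    while True:
        b = value & 0x7F
        value >>= 7
        if value:
            buf.append(b | 0x80)
        else:
            buf.append(b)
            return


def read_varint(fh: io.BytesIO) -> int:
    shift = 0
    value = 0
    while True:
        raw = fh.read(1)
        if not raw:
            raise CorruptionError("container directory truncated")
        b = raw[0]
        value |= (b & 0x7F) << shift
        if not (b & 0x80):
            return value
        shift += 7


def encode_directory(directory: Sequence[BlockMeta]) -> bytes:
    buf = bytearray()
    write_varint(buf, len(directory))
    for m in directory:
        write_varint(buf, m.stream)
        write_varint(buf, m.start_line)
        write_varint(buf, m.end_line)
        if m.stream == STREAM_A:
            write_varint(buf, m.s1_before)
        write_varint(buf, m.n_lines)
        write_varint(buf, m.offset)
        write_varint(buf, m.comp_len)
        write_varint(buf, m.raw_len)
    return bytes(buf)


def decode_directory(data: bytes) -> List[BlockMeta]:
    fh = io.BytesIO(data)
    count = read_varint(fh)
    out: List[BlockMeta] = []
    for _ in range(count):
        stream = read_varint(fh)
        start = read_varint(fh)
        end = read_varint(fh)
        s1_before = read_varint(fh) if stream == STREAM_A else 0
        n_lines = read_varint(fh)
        offset = read_varint(fh)
        comp_len = read_varint(fh)
        raw_len = read_varint(fh)
        out.append(BlockMeta(stream, start, end, s1_before, n_lines,
                             offset, comp_len, raw_len))
    return out


# --- compression -----------------------------------------------------------


@dataclass
class CompressSummary:
    lines: int
    blocks: int
    input_bytes: int
    output_bytes: int
    C: int


def compress_records(
    records: Iterable[QualityRecord],
    output: str,
    config: ContainerConfig = ContainerConfig(),
) -> CompressSummary:
    """Run the full pipeline over an ordered record stream.

    Sample the head, estimate k-mer weights and the modal value, then make a
    single classify/buffer/flush pass; each flushed block is packed and
    backend-encoded before being appended. Directory and footer are written
    last. Partial output is removed on failure.
    """
    try:
        return _compress_records(records, output, config)
    except Exception:
        if os.path.exists(output):
            os.unlink(output)
        raise


def _compress_records(records, output, config) -> CompressSummary:
    params = config.partition_params
    it = iter(records)
    sample = list(itertools.islice(it, params.sample_lines))
    stream = itertools.chain(sample, it)

    if sample:
        model = partition.build_kmer_weights(sample, params)
        has_bytes = any(rec.line for rec in sample)
        C = packing.compute_mode(sample) if has_bytes else qsio.QUAL_MIN
    else:
        model = None
        C = qsio.QUAL_MIN
    table = packing.build_pack_table(C)
    backend = cmcodec.get_backend(config.backend)

    state = BufferState(threshold_T=config.threshold)
    directory: List[BlockMeta] = []
    input_bytes = 0
    n_lines = 0

    with open(output, "wb") as out:
        header_placeholder = ContainerHeader(config, C, 0, 0)
        header_len = len(header_placeholder.to_bytes())
        out.write(b"\0" * header_len)
        pos = header_len

        def emit(events):
            nonlocal pos
            for ev in events:
                packed = packing.pack_block(ev.lines, table)
                payload = backend.encode(packed)
                ev.meta.offset = pos
                ev.meta.comp_len = len(payload)
                ev.meta.raw_len = len(packed)
                out.write(payload)
                pos += len(payload)
                directory.append(ev.meta)

        for rec in stream:
            label = partition.classify_line(rec.line, model, params)
            emit(blockstore.append(state, rec, label))
            input_bytes += len(rec.line) + 1
            n_lines += 1
        emit(blockstore.finalize(state))

        blockstore.check_structure(directory)
        dir_offset = pos
        out.write(encode_directory(directory))
        out.write(struct.pack("<Q", dir_offset))
        out.write(MAGIC)

        header = ContainerHeader(config, C, n_lines, state.s1_total)
        hdr = header.to_bytes()
        assert len(hdr) == header_len
        out.seek(0)
        out.write(hdr)
        out.flush()
        output_bytes = os.path.getsize(output)

    return CompressSummary(lines=n_lines, blocks=len(directory),
                           input_bytes=input_bytes, output_bytes=output_bytes, C=C)


def compress_file(
    input_path: str,
    output: str,
    config: ContainerConfig = ContainerConfig(),
    mode: str = "plain",
    validate: bool = True,
    strip_cr: bool = False,
) -> CompressSummary:
    records = qsio.read_quality_lines(input_path, mode=mode, validate=validate,
                                      strip_cr=strip_cr)
    return compress_records(records, output, config)


# --- reading ---------------------------------------------------------------


@dataclass
class ContainerReader:
    path: str
    header: ContainerHeader
    directory: List[BlockMeta]
    header_size: int
    dir_offset: int
    file_size: int
    blocks_touched: int = 0  # instrumentation for block-bound checks
    _table: Optional[packing.PackTable] = None

    @classmethod
    def open(cls, path: str) -> "ContainerReader":
        size = os.path.getsize(path)
        with open(path, "rb") as fh:
            header = ContainerHeader.from_stream(fh)
            header_size = fh.tell()
            if size < header_size + FOOTER_SIZE:
                raise CorruptionError("container footer truncated")
            fh.seek(size - FOOTER_SIZE)
            footer = fh.read(FOOTER_SIZE)
            (dir_offset,) = struct.unpack("<Q", footer[:8])
            if footer[8:] != MAGIC:
                raise CorruptionError("container footer magic mismatch")
            if not (header_size <= dir_offset <= size - FOOTER_SIZE):
                raise CorruptionError("container directory offset out of bounds")
            fh.seek(dir_offset)
            directory = decode_directory(fh.read(size - FOOTER_SIZE - dir_offset))
        return cls(path=path, header=header, directory=directory,
                   header_size=header_size, dir_offset=dir_offset, file_size=size)

    def _decode_block(self, fh: BinaryIO, meta: BlockMeta) -> List[bytes]:
        self.blocks_touched += 1
        fh.seek(meta.offset)
        payload = _must_read(fh, meta.comp_len, "block payload")
        backend = cmcodec.get_backend(self.header.config.backend)
        packed = backend.decode(payload, meta.raw_len)
        if len(packed) != meta.raw_len:
            raise CorruptionError(
                f"block at offset {meta.offset}: raw length mismatch"
            )
        if self._table is None:
            self._table = packing.build_pack_table(self.header.C)
        lines = packing.unpack(packed, self._table)
        if len(lines) != meta.n_lines:
            raise CorruptionError(
                f"block at offset {meta.offset}: expected {meta.n_lines} lines,"
                f" decoded {len(lines)}"
            )
        return lines

    def read_range(self, a: int, b: int) -> List[bytes]:
        """Lines a..b (0-based inclusive) via the minimal block plan."""
        plan = blockstore.plan_range(self.directory, a, b)
        with open(self.path, "rb") as fh:
            decoded_A = [self._decode_block(fh, m) for m in plan.a_blocks]
            decoded_B = [self._decode_block(fh, m) for m in plan.b_blocks]
        return blockstore.merge(decoded_A, decoded_B, plan, self.directory)

    def read_all(self) -> Iterable[bytes]:
        """Full decompression: merge over consecutive A spans in order."""
        if self.header.total_lines == 0:
            return
        a_blocks, _ = blockstore.split_directory(self.directory)
        with open(self.path, "rb") as fh:
            decoded_b_cache = {}

            for ameta in a_blocks:
                plan = blockstore.plan_range(
                    self.directory, ameta.start_line, ameta.end_line
                )
                decoded_A = [self._decode_block(fh, m) for m in plan.a_blocks]
                decoded_B = []
                for m in plan.b_blocks:
                    if m.start_line not in decoded_b_cache:
                        decoded_b_cache[m.start_line] = self._decode_block(fh, m)
                    decoded_B.append(decoded_b_cache[m.start_line])
                yield from blockstore.merge(decoded_A, decoded_B, plan,
                                            self.directory)

    def payload_bytes(self) -> int:
        return sum(m.comp_len for m in self.directory)

    def index_overhead_bytes(self) -> int:
        return self.file_size - self.payload_bytes() - self.header_size


def decompress_file(container: str, output: str) -> int:
    reader = ContainerReader.open(container)
    n = 0
    with open(output, "wb") as out:
        for line in reader.read_all():
            out.write(line)
            out.write(b"\n")
            n += 1
    if n != reader.header.total_lines:
        raise CorruptionError(
            f"decoded {n} lines, header records {reader.header.total_lines}"
        )
    return n


def range_decompress(container: str, a: int, b: int) -> List[bytes]:
    """Lines a..b, 1-based inclusive (the CLI convention)."""
    reader = ContainerReader.open(container)
    total = reader.header.total_lines
    if not (1 <= a <= b <= total):
        raise RangeError(
            f"range [{a}, {b}] invalid for a container of {total} lines"
        )
    return reader.read_range(a - 1, b - 1)


def info(container: str) -> dict:
    reader = ContainerReader.open(container)
    h = reader.header
    overhead = reader.index_overhead_bytes()
    a_blocks, b_blocks = blockstore.split_directory(reader.directory)
    return {
        "path": container,
        "version": VERSION,
        "k": h.config.k,
        "alpha": h.config.alpha,
        "sample_lines": h.config.sample_lines,
        "C": h.C,
        "threshold": h.config.threshold,
        "backend": h.config.backend,
        "total_lines": h.total_lines,
        "stream1_lines": h.total_s1,
        "blocks": len(reader.directory),
        "a_blocks": len(a_blocks),
        "b_blocks": len(b_blocks),
        "file_size": reader.file_size,
        "header_bytes": reader.header_size,
        "payload_bytes": reader.payload_bytes(),
        "index_overhead_bytes": overhead,
        "block_spans": [
            {"stream": m.stream, "start": m.start_line, "end": m.end_line,
             "lines": m.n_lines, "comp_len": m.comp_len, "raw_len": m.raw_len}
            for m in reader.directory
        ],
    }
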