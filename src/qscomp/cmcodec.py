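"""Exactly invertible byte-stream backends: context mixing + arithmetic coding.

The ``cm1`` backend predicts each bit (MSB first) by logistically mixing
three context models (orders 0, 1, 2 over preceding bytes plus the partial
byte) and drives a carryless 32-bit binary arithmetic coder. The decoder
replays the identical predict/update trajectory, so symmetry — not any
in-stream framing — guarantees inversion; the caller supplies the raw
length (the container stores it per block).

The ``store`` backend is the identity; ``zlib`` adapts the stdlib codec.
Every backend encodes each block with fresh state, so blocks are
independently compressible (the contract that enables parallel execution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict

from .errors import ParameterError

# model constants; recorded in the container header for forward compatibility
TABLE_BITS = 16
TABLE_SIZE = 1 << TABLE_BITS
ADAPT_SHIFT = 5            # probability step (bit - p) / 32
MIX_RATE = 0.002           # mixer learning rate
CLAMP = 1.0 / 4096.0       # 2^-12 probability clamp

CODER_CONSTANTS = {
    "orders": [0, 1, 2],
    "table_bits": TABLE_BITS,
    "adapt_shift": ADAPT_SHIFT,
    "mix_rate": MIX_RATE,
    "clamp_bits": 12,
}

_MASK = TABLE_SIZE - 1


def stretch(p: float) -> float:
    return math.log(p / (1.0 - p))


def squash(x: float) -> float:
    if x > 30.0:
        return 1.0 - CLAMP
    if x < -30.0:
        return CLAMP
    return 1.0 / (1.0 + math.exp(-x))


class Predictor:
    """Order-0/1/2 adaptive bit model with a logistic mixer.

    All probabilities start at 1/2 and mixer weights at 0, so a fresh state
    predicts exactly 1/2. Encoder and decoder run bit-identical updates.
    """

    __slots__ = ("t0", "t1", "t2", "w", "c0", "h1", "h2", "_ctx", "_st", "_pr")

    def __init__(self):
        self.t0 = [0.5] * 256
        self.t1 = [0.5] * TABLE_SIZE
        self.t2 = [0.5] * TABLE_SIZE
        self.w = [0.0, 0.0, 0.0]
        self.c0 = 1          # partial byte with a leading 1 sentinel
        self.h1 = 0          # previous byte
        self.h2 = 0          # hash of previous two bytes
        self._ctx = (0, 0, 0)
        self._st = (0.0, 0.0, 0.0)
        self._pr = (0.5, 0.5, 0.5)

    def predict(self) -> float:
        c0 = self.c0
        i0 = c0 & 0xFF
        i1 = ((self.h1 << 8) | c0) & _MASK
        i2 = (self.h2 * 769 + c0) & _MASK
        p0 = self.t0[i0]
        p1 = self.t1[i1]
        p2 = self.t2[i2]
        s0 = math.log(p0 / (1.0 - p0))
        s1 = math.log(p1 / (1.0 - p1))
        s2 = math.log(p2 / (1.0 - p2))
        w = self.w
        x = w[0] * s0 + w[1] * s1 + w[2] * s2
        if x > 30.0:
            p = 1.0 - CLAMP
        elif x < -30.0:
            p = CLAMP
        else:
            p = 1.0 / (1.0 + math.exp(-x))
            if p < CLAMP:
                p = CLAMP
            elif p > 1.0 - CLAMP:
                p = 1.0 - CLAMP
        self._ctx = (i0, i1, i2)
        self._st = (s0, s1, s2)
        self._pr = (p0, p1, p2)
        return p

    def update(self, bit: int, p: float) -> None:
        i0, i1, i2 = self._ctx
        p0, p1, p2 = self._pr
        self.t0[i0] = p0 + (bit - p0) / 32.0
        self.t1[i1] = p1 + (bit - p1) / 32.0
        self.t2[i2] = p2 + (bit - p2) / 32.0
        s0, s1, s2 = self._st
        err = MIX_RATE * (bit - p)
        w = self.w
        w[0] += err * s0
        w[1] += err * s1
        w[2] += err * s2
        c0 = (self.c0 << 1) | bit
        if c0 >= 256:  # byte boundary: roll contexts
            byte = c0 & 0xFF
            self.h2 = ((self.h1 << 8) | byte) & 0xFFFF
            self.h1 = byte
            self.c0 = 1
        else:
            self.c0 = c0


class ArithmeticEncoder:
    """Carryless 32-bit binary range coder, byte-wise renormalization."""

    def __init__(self):
        self.x1 = 0
        self.x2 = 0xFFFFFFFF
        self.out = bytearray()

    def encode_bit(self, bit: int, p: float) -> None:
        """Encode one bit given probability ``p`` that it is 1."""
        p16 = int(p * 65536.0)
        if p16 < 1:
            p16 = 1
        elif p16 > 65535:
            p16 = 65535
        x1, x2 = self.x1, self.x2
        xmid = x1 + ((x2 - x1) >> 16) * p16
        if bit:
            x2 = xmid
        else:
            x1 = xmid + 1
        while (x1 ^ x2) & 0xFF000000 == 0:
            self.out.append(x2 >> 24)
            x1 = (x1 << 8) & 0xFFFFFFFF
            x2 = ((x2 << 8) | 0xFF) & 0xFFFFFFFF
        self.x1, self.x2 = x1, x2

    def flush(self) -> bytes:
        # emit x1 in full: 4 bytes pin the interval for the decoder
        x1 = self.x1
        for shift in (24, 16, 8, 0):
            self.out.append((x1 >> shift) & 0xFF)
        return bytes(self.out)


class ArithmeticDecoder:
    """Mirror of :class:`ArithmeticEncoder`; zero-fills past end of input."""

    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0
        self.x1 = 0
        self.x2 = 0xFFFFFFFF
        x = 0
        for _ in range(4):
            x = (x << 8) | self._next_byte()
        self.x = x

    def _next_byte(self) -> int:
        if self.pos < len(self.data):
            b = self.data[self.pos]
            self.pos += 1
            return b
        return 0

    def decode_bit(self, p: float) -> int:
        p16 = int(p * 65536.0)
        if p16 < 1:
            p16 = 1
        elif p16 > 65535:
            p16 = 65535
        x1, x2 = self.x1, self.x2
        xmid = x1 + ((x2 - x1) >> 16) * p16
        if self.x <= xmid:
            bit = 1
            x2 = xmid
        else:
            bit = 0
            x1 = xmid + 1
        while (x1 ^ x2) & 0xFF000000 == 0:
            x1 = (x1 << 8) & 0xFFFFFFFF
            x2 = ((x2 << 8) | 0xFF) & 0xFFFFFFFF
            self.x = ((self.x << 8) & 0xFFFFFFFF) | self._next_byte()
        self.x1, self.x2 = x1, x2
        return bit


def cm_encode(data: bytes) -> bytes:
    pred = Predictor()
    enc = ArithmeticEncoder()
    predict = pred.predict
    update = pred.update
    encode_bit = enc.encode_bit
    for byte in data:
        for shift in (7, 6, 5, 4, 3, 2, 1, 0):
            bit = (byte >> shift) & 1
            p = predict()
            encode_bit(bit, p)
            update(bit, p)
    return enc.flush()


def cm_decode(data: bytes, raw_len: int) -> bytes:
    pred = Predictor()
    dec = ArithmeticDecoder(data)
    predict = pred.predict
    update = pred.update
    decode_bit = dec.decode_bit
    out = bytearray()
    for _ in range(raw_len):
        byte = 0
        for _ in range(8):
            p = predict()
            bit = decode_bit(p)
            update(bit, p)
            byte = (byte << 1) | bit
        out.append(byte)
    return bytes(out)


# ---------------------------------------------------------------------------
# backend registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Backend:
    name: str
    encode: Callable[[bytes], bytes]
    decode: Callable[[bytes, int], bytes]


def _store_encode(data: bytes) -> bytes:
    return data


def _store_decode(data: bytes, raw_len: int) -> bytes:
    return data[:raw_len]


def _zlib_encode(data: bytes) -> bytes:
    import zlib

    return zlib.compress(data, 6)


def _zlib_decode(data: bytes, raw_len: int) -> bytes:
    import zlib

    return zlib.decompress(data)


_REGISTRY: Dict[str, Backend] = {}


def register_backend(backend: Backend) -> None:
    _REGISTRY[backend.name] = backend


def get_backend(name: str) -> Backend:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ParameterError(
            f"unknown backend {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None


register_backend(Backend("store", _store_encode, _store_decode))
register_backend(Backend("cm1", cm_encode, cm_decode))
register_backend(Backend("zlib", _zlib_encode, _zlib_decode))


def encode(data: bytes, backend: str = "cm1") -> bytes:
    return get_backend(backend).encode(data)


def decode(data: bytes, raw_len: int, backend: str = "cm1") -> bytes:
    return get_backend(backend).decode(data, raw_len)
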