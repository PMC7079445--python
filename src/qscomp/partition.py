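"""Two-way partition of quality lines by normalized k-mer-frequency weight.

A k-mer weight model is estimated once from the first ``sample_lines`` lines
of the file. Each line's raw weight is the mean weight of its overlapping
k-mers; weights are normalized by the maximum raw weight seen in the sample
and thresholded at ``alpha``: normalized weight >= alpha routes the line to
stream 0 (buffer A, the order-keeping stream), otherwise stream 1 (buffer B).
The model is frozen after sampling, so classification is single-pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Sequence

import numpy as np

from .errors import ParameterError
from .qsio import ALPHABET_SIZE, QUAL_MIN, QualityRecord

logger = logging.getLogger(__name__)

STREAM_A = 0  # high-weight cluster, order-keeping buffer
STREAM_B = 1  # low-weight cluster

_SEP_CODE = np.int64(-1)


@dataclass(frozen=True)
class PartitionParams:
    k: int = 4
    sample_lines: int = 100_000
    alpha: float = 0.1

    def __post_init__(self):
        if self.k < 1:
            raise ParameterError("k must be >= 1")
        if self.sample_lines < 1:
            raise ParameterError("sample_lines must be >= 1")
        if not (0.0 <= self.alpha <= 1.0):
            raise ParameterError("alpha must lie in [0, 1]")


def _line_codes(line: bytes, k: int) -> np.ndarray:
    """Integer codes of all overlapping k-mers of ``line`` (base-72 packing)."""
    n = len(line) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    arr = np.frombuffer(line, dtype=np.uint8).astype(np.int64) - QUAL_MIN
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = codes * ALPHABET_SIZE + arr[j : j + n]
    return codes


@dataclass
class KmerWeightModel:
    """Frozen k-mer frequency weights estimated from the sampled file head."""

    k: int
    weight: Dict[bytes, float]
    total_kmer_count: int
    w_max: float
    # sorted code/weight arrays for vectorized lookups
    _codes: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0, np.int64))
    _weights: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))

    def line_weight(self, line: bytes) -> float:
        """Mean weight of the line's overlapping k-mers (0 if none)."""
        codes = _line_codes(line, self.k)
        if codes.size == 0 or self._codes.size == 0:
            return 0.0
        pos = np.searchsorted(self._codes, codes)
        pos[pos == self._codes.size] = 0
        hit = self._codes[pos] == codes
        # left-to-right accumulation: bit-identical to a naive per-k-mer sum,
        # so labels match brute-force reimplementations exactly at thresholds
        return sum(self._weights[pos[hit]].tolist()) / codes.size


def build_kmer_weights(
    sample: Sequence[QualityRecord], params: PartitionParams
) -> KmerWeightModel:
    """Count all overlapping k-mers of the sampled lines and derive weights.

    Each k-mer's weight is its occurrence count divided by the total k-mer
    count; ``w_max`` is the maximum raw line weight over the sample and is
    later used as the normalizer. When every sampled line is shorter than k
    the model is empty and ``w_max`` is 0.
    """
    if not sample:
        raise ParameterError("sample must be non-empty")
    k = params.k

    # single concatenated code pass: join lines with a sentinel so windows
    # crossing line boundaries can be masked out in one shot
    per_line_codes = [_line_codes(rec.line, k) for rec in sample]
    nonempty = [c for c in per_line_codes if c.size]
    if not nonempty:
        logger.warning("all %d sampled lines shorter than k=%d", len(sample), k)
        return KmerWeightModel(k=k, weight={}, total_kmer_count=0, w_max=0.0)

    allcodes = np.concatenate(nonempty)
    uniq, counts = np.unique(allcodes, return_counts=True)
    total = int(counts.sum())
    wvals = counts.astype(np.float64) / total

    weight_map: Dict[bytes, float] = {
        _code_to_kmer(int(c), k): float(w) for c, w in zip(uniq, wvals)
    }

    model = KmerWeightModel(
        k=k,
        weight=weight_map,
        total_kmer_count=total,
        w_max=0.0,
        _codes=uniq,
        _weights=wvals,
    )
    w_max = 0.0
    for codes in per_line_codes:
        if codes.size == 0:
            continue
        pos = np.searchsorted(uniq, codes)
        w = sum(wvals[pos].tolist()) / codes.size
        if w > w_max:
            w_max = w
    model.w_max = w_max
    return model


def _code_to_kmer(code: int, k: int) -> bytes:
    out = bytearray(k)
    for j in range(k - 1, -1, -1):
        out[j] = code % ALPHABET_SIZE + QUAL_MIN
        code //= ALPHABET_SIZE
    return bytes(out)


def line_weight(line: bytes, model: KmerWeightModel) -> float:
    return model.line_weight(line)


def classify_line(
    line: bytes, model: KmerWeightModel, params: PartitionParams
) -> int:
    """Return stream label 0 or 1 for one line.

    The normalized weight is ``line_weight / w_max`` (0 when ``w_max`` is 0);
    values above 1 are possible for post-sample lines and are not clamped —
    the ``>= alpha`` rule gives them label 0 regardless.
    """
    if model.w_max > 0.0:
        w_n = model.line_weight(line) / model.w_max
    else:
        w_n = 0.0
    return STREAM_A if w_n >= params.alpha else STREAM_B


def classify_all(
    records: Iterable[QualityRecord],
    model: KmerWeightModel,
    params: PartitionParams,
) -> Iterable[tuple]:
    """Yield ``(record, label)`` pairs in order; convenience for pipelines."""
    for rec in records:
        yield rec, classify_line(rec.line, model, params)
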