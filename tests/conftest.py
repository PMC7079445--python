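import numpy as np
import pytest

from qscomp import qsio
from qscomp.qsio import QUAL_MAX, QUAL_MIN, SyntheticSpec


def mixture_spec(n_lines, length, seed, weights=(0.8, 0.2), centers=(70, 45),
                 spreads=(6, 15)):
    sources = [
        qsio.peaked_source(c, s, w)
        for c, s, w in zip(centers, spreads, weights)
    ]
    return SyntheticSpec(n_lines=n_lines, length=length, sources=sources,
                         seed=seed)


def random_lines(rng, n, max_len=120, lo=QUAL_MIN, hi=QUAL_MAX):
    """Uniform random quality lines, including empty ones."""
    out = []
    for _ in range(n):
        ln = int(rng.integers(0, max_len + 1))
        out.append(rng.integers(lo, hi + 1, size=ln).astype(np.uint8).tobytes())
    return out


def write_lines(path, lines):
    with open(path, "wb") as fh:
        for line in lines:
            fh.write(line)
            fh.write(b"\n")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_mixture_file(tmp_path):
    """200-line fixed-length mixture fixture on disk."""
    path = tmp_path / "fixture.qs"
    lines = qsio.generate_synthetic(mixture_spec(200, 40, seed=7))
    write_lines(path, lines)
    return path, lines
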