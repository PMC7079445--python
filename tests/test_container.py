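import json
import os

import numpy as np
import pytest

from qscomp import blockstore, cmcodec, container, packing, qsio
from qscomp.container import (
    ContainerConfig,
    ContainerReader,
    compress_file,
    decompress_file,
    info,
    range_decompress,
)
from qscomp.errors import CorruptionError, FormatError, RangeError
from qscomp.qsio import QUAL_MAX, QUAL_MIN

from conftest import mixture_spec, write_lines

STORE = ContainerConfig(backend="store", threshold=2048, sample_lines=100)


def roundtrip(tmp_path, lines, config=STORE, tag="x"):
    src = tmp_path / f"{tag}.qs"
    cont = tmp_path / f"{tag}.qsc"
    out = tmp_path / f"{tag}.out"
    write_lines(src, lines)
    summary = compress_file(str(src), str(cont), config)
    n = decompress_file(str(cont), str(out))
    assert n == len(lines)
    assert out.read_bytes() == src.read_bytes()
    return src, cont, summary


class TestRoundTrip:
    def test_empty_input(self, tmp_path):
        roundtrip(tmp_path, [])

    def test_single_line(self, tmp_path):
        roundtrip(tmp_path, [b"IIII"])

    def test_empty_lines_mixed_in(self, tmp_path):
        lines = [b"", b"IIIII", b"", b"", b"JJJJ", b""]
        roundtrip(tmp_path, lines)

    def test_full_alphabet(self, tmp_path):
        lines = [bytes(range(QUAL_MIN, QUAL_MAX + 1))] * 5
        lines += [bytes([v]) * 12 for v in range(QUAL_MIN, QUAL_MAX + 1)]
        roundtrip(tmp_path, lines)

    def test_variable_lengths_long(self, tmp_path, rng):
        # long-read-like: lengths 1..500
        lines = [
            rng.integers(QUAL_MIN, QUAL_MAX + 1,
                         size=int(rng.integers(1, 501)))
            .astype(np.uint8).tobytes()
            for _ in range(120)
        ]
        roundtrip(tmp_path, lines)

    def test_mixture_fixture(self, tmp_path):
        lines = qsio.generate_synthetic(mixture_spec(400, (0, 80), seed=13))
        roundtrip(tmp_path, lines)

    def test_determinism(self, tmp_path):
        lines = qsio.generate_synthetic(mixture_spec(200, 30, seed=7))
        src = tmp_path / "a.qs"
        write_lines(src, lines)
        c1, c2 = tmp_path / "c1.qsc", tmp_path / "c2.qsc"
        compress_file(str(src), str(c1), STORE)
        compress_file(str(src), str(c2), STORE)
        assert c1.read_bytes() == c2.read_bytes()

    def test_cm1_roundtrip(self, tmp_path):
        cfg = ContainerConfig(backend="cm1", threshold=2048, sample_lines=50)
        lines = qsio.generate_synthetic(mixture_spec(150, 40, seed=21))
        _, cont, _ = roundtrip(tmp_path, lines, cfg, tag="cm")
        assert info(str(cont))["backend"] == "cm1"

    def test_cross_backend_identical_output(self, tmp_path):
        lines = qsio.generate_synthetic(mixture_spec(120, 30, seed=5))
        src = tmp_path / "a.qs"
        write_lines(src, lines)
        outs = []
        for backend in ("store", "cm1", "zlib"):
            cfg = ContainerConfig(backend=backend, threshold=1024,
                                  sample_lines=50)
            cont = tmp_path / f"{backend}.qsc"
            out = tmp_path / f"{backend}.out"
            compress_file(str(src), str(cont), cfg)
            decompress_file(str(cont), str(out))
            outs.append(out.read_bytes())
        assert outs[0] == outs[1] == outs[2] == src.read_bytes()

    def test_alpha_zero_single_stream(self, tmp_path):
        cfg = ContainerConfig(backend="store", threshold=512,
                              sample_lines=50, alpha=0.0)
        lines = [b"", b"IIII", b""] * 20  # empty lines land in stream 0
        _, cont, _ = roundtrip(tmp_path, lines, cfg)
        assert info(str(cont))["b_blocks"] == 0

    def test_partial_output_removed_on_failure(self, tmp_path):
        src = tmp_path / "bad.qs"
        src.write_bytes(b"II\n\x10\x10\n")  # invalid bytes
        cont = tmp_path / "c.qsc"
        with pytest.raises(Exception):
            compress_file(str(src), str(cont), STORE)
        assert not cont.exists()


class TestHeader:
    def test_header_round_trip(self, tmp_path):
        cfg = ContainerConfig(k=5, alpha=0.1234, sample_lines=777,
                              threshold=4096, backend="store")
        lines = [b"IIIIII"] * 10
        src, cont, _ = roundtrip(tmp_path, lines, cfg)
        h = ContainerReader.open(str(cont)).header
        assert h.config == cfg
        assert h.total_lines == 10
        assert h.coder_constants == cmcodec.CODER_CONSTANTS

    def test_bad_magic(self, tmp_path):
        p = tmp_path / "x.qsc"
        p.write_bytes(b"NOPE" + b"\0" * 60)
        with pytest.raises(FormatError, match="magic"):
            ContainerReader.open(str(p))

    def test_truncated_footer(self, tmp_path):
        lines = [b"IIII"] * 5
        _, cont, _ = roundtrip(tmp_path, lines)
        data = cont.read_bytes()
        cont.write_bytes(data[:-6])
        with pytest.raises(CorruptionError):
            ContainerReader.open(str(cont))

    def test_truncated_header(self, tmp_path):
        p = tmp_path / "x.qsc"
        p.write_bytes(b"QS")
        with pytest.raises(CorruptionError):
            ContainerReader.open(str(p))


class TestCorruption:
    def test_flipped_payload_byte_detected_or_differs(self, tmp_path):
        lines = qsio.generate_synthetic(mixture_spec(100, 25, seed=3))
        src, cont, _ = roundtrip(tmp_path, lines)
        reader = ContainerReader.open(str(cont))
        target = reader.directory[0]
        data = bytearray(cont.read_bytes())
        data[target.offset] ^= 0x5A
        bad = tmp_path / "bad.qsc"
        bad.write_bytes(bytes(data))
        out = tmp_path / "bad.out"
        try:
            decompress_file(str(bad), str(out))
        except Exception:
            return  # detected: fine
        assert out.read_bytes() != src.read_bytes()  # never silently equal


class TestRange:
    def test_first_line(self, small_mixture_file, tmp_path):
        path, lines = small_mixture_file
        cont = tmp_path / "c.qsc"
        compress_file(str(path), str(cont), STORE)
        assert range_decompress(str(cont), 1, 1) == [lines[0]]

    def test_exhaustive_small(self, tmp_path):
        lines = qsio.generate_synthetic(mixture_spec(60, (0, 20), seed=17))
        src = tmp_path / "a.qs"
        write_lines(src, lines)
        cont = tmp_path / "c.qsc"
        cfg = ContainerConfig(backend="store", threshold=256, sample_lines=30)
        compress_file(str(src), str(cont), cfg)
        reader = ContainerReader.open(str(cont))
        for a in range(60):
            for b in range(a, 60):
                assert reader.read_range(a, b) == lines[a : b + 1], (a, b)

    def test_out_of_range(self, small_mixture_file, tmp_path):
        path, lines = small_mixture_file
        cont = tmp_path / "c.qsc"
        compress_file(str(path), str(cont), STORE)
        with pytest.raises(RangeError, match="200"):
            range_decompress(str(cont), 1, 201)
        with pytest.raises(RangeError):
            range_decompress(str(cont), 0, 5)

    def test_block_touch_bound(self, tmp_path):
        lines = qsio.generate_synthetic(mixture_spec(150, 40, seed=19))
        src = tmp_path / "a.qs"
        write_lines(src, lines)
        cont = tmp_path / "c.qsc"
        cfg = ContainerConfig(backend="store", threshold=512, sample_lines=50)
        compress_file(str(src), str(cont), cfg)
        reader = ContainerReader.open(str(cont))
        a_blocks, _ = blockstore.split_directory(reader.directory)
        assert len(a_blocks) > 3  # threshold small enough to force blocks
        for a in range(0, 150, 7):
            for b in range(a, min(a + 30, 150), 5):
                plan = blockstore.plan_range(reader.directory, a, b)
                if len(plan.a_blocks) == 1:
                    assert len(plan.blocks) <= 4
                if len(plan.a_blocks) <= 2:
                    assert len(plan.blocks) <= 8


class TestInfo:
    def test_overhead_identity(self, tmp_path):
        lines = qsio.generate_synthetic(mixture_spec(300, 40, seed=23))
        _, cont, _ = roundtrip(tmp_path, lines)
        i = info(str(cont))
        reader = ContainerReader.open(str(cont))
        dir_bytes = container.encode_directory(reader.directory)
        assert i["index_overhead_bytes"] == len(dir_bytes) + container.FOOTER_SIZE
        assert i["file_size"] == (
            i["header_bytes"] + i["payload_bytes"] + i["index_overhead_bytes"]
        )

    def test_store_payloads_equal_packed_sizes(self, tmp_path):
        lines = qsio.generate_synthetic(mixture_spec(200, 30, seed=29))
        _, cont, _ = roundtrip(tmp_path, lines)
        reader = ContainerReader.open(str(cont))
        assert all(m.comp_len == m.raw_len for m in reader.directory)

    def test_single_output_file(self, tmp_path):
        lines = qsio.generate_synthetic(mixture_spec(100, 30, seed=31))
        src = tmp_path / "in.qs"
        write_lines(src, lines)
        workdir = tmp_path / "work"
        workdir.mkdir()
        cont = workdir / "only.qsc"
        compress_file(str(src), str(cont), STORE)
        assert os.listdir(workdir) == ["only.qsc"]

    def test_json_serializable(self, tmp_path):
        lines = [b"IIII"] * 10
        _, cont, _ = roundtrip(tmp_path, lines)
        json.dumps(info(str(cont)))


class TestParallelContract:
    def test_blocks_independently_encoded(self, tmp_path):
        # re-encoding each block's packed bytes with a fresh coder state
        # reproduces the stored payload exactly
        cfg = ContainerConfig(backend="cm1", threshold=1024, sample_lines=50)
        lines = qsio.generate_synthetic(mixture_spec(120, 40, seed=37))
        src = tmp_path / "a.qs"
        write_lines(src, lines)
        cont = tmp_path / "c.qsc"
        compress_file(str(src), str(cont), cfg)
        reader = ContainerReader.open(str(cont))
        table = packing.build_pack_table(reader.header.C)
        with open(cont, "rb") as fh:
            for meta in reader.directory:
                fh.seek(meta.offset)
                payload = fh.read(meta.comp_len)
                packed = cmcodec.decode(payload, meta.raw_len, "cm1")
                assert cmcodec.encode(packed, "cm1") == payload
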