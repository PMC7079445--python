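# qscomp

Lossless compression of FASTQ quality-score lines with line-range random
access from a single self-indexed container file.

The pipeline has four stages:

1. **Partition** — quality lines are split into two streams by normalized
   k-mer-frequency weight. A frozen weight model is estimated from the first
   `sample_lines` lines (default 100 000, `k=4`); lines whose normalized
   weight is at least `alpha` (default 0.1) go to stream 0, the rest to
   stream 1. Classification is single-pass: the model never adapts after the
   sample.
2. **Blocking + embedded index** — stream-0 content fills buffer A (with a
   bare placeholder newline for every stream-1 line, preserving global
   order); stream-1 content fills buffer B. A buffer is flushed into a block
   when it exceeds the block-size threshold, and A is force-flushed after
   three consecutive B flushes, which caps how many B blocks any A block can
   overlap at 3. Per-block line spans are recorded in a directory appended
   to the container — there is no sidecar index file, and a line-range query
   never decodes more than 8 blocks (4 if the range sits inside one A-block
   span).
3. **Adaptive packing** — groups of quality values are replaced by single
   code bytes 1..255 using a table derived deterministically from the modal
   quality value `C`: 72 single-value codes, triples over `[C-1, C+1]`,
   pairs over `[C-5, C+6]`, and run codes for 4..15 repeats of `C`; code 0
   terminates each line. The transform is bijective, so decoding is a table
   lookup.
4. **Backend coding** — each packed block is compressed independently
   (fresh coder state per block) by a pluggable backend: `cm1`, a
   context-mixing bit predictor (logistic mixing of order-0/1/2 models)
   driving a carryless 32-bit binary arithmetic coder; `store` (identity);
   or `zlib`.

Inputs are plain quality files (one LF-terminated line per record, bytes
ASCII 33–104) or uncompressed FASTQ (quality row of each record). A
synthetic fixture generator produces mixture-of-sources quality files with
fixed or variable line lengths.

## CLI

```sh
# generate a synthetic fixture (deterministic for a given seed)
qscomp synth -o sample.qs --lines 10000 --length 100 --seed 1

# compress / decompress
qscomp compress -i sample.qs -o sample.qsc --backend cm1
qscomp decompress -i sample.qsc -o restored.qs

# FASTQ input: extract and compress the quality rows
qscomp compress -i reads.fastq --fastq -o reads.qsc

# random access: lines 1000..1020 (1-based inclusive), no full decompression
qscomp range -i sample.qsc -a 1000 -b 1020

# container metadata (params, block spans, index overhead) as JSON
qscomp info -i sample.qsc
```

Useful compression flags: `--k`, `--alpha`, `--sample-lines`,
`--block-size` (bytes, default 8 MiB), `--backend cm1|store|zlib`,
`--no-validate`, `--strip-cr`. Exit codes: 0 success, 1 usage,
2 format/validation error, 3 corruption/range error.

The `cm1` backend is a pure-Python coder and is deliberately simple; use
`--backend zlib` or `store` when throughput matters more than ratio.

## Library

```python
import qscomp

cfg = qscomp.ContainerConfig(backend="cm1", alpha=0.1, k=4)
qscomp.compress_file("sample.qs", "sample.qsc", cfg)
lines = qscomp.range_decompress("sample.qsc", 5, 9)  # 1-based inclusive
```

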