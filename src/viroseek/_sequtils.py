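"""Low-level sequence utilities shared across modules.

Nucleotides are handled as plain Python strings over {A,C,G,T,N}; hot paths
(read simulation, background subtraction) additionally use a 2-bit-ish uint8
encoding (A=0, C=1, G=2, T=3, N=4) for vectorised comparison.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: uint8 code used for each base byte; everything non-ACGT maps to 4 ("N").
_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0 C=1 G=2 T=3, N/other=4)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of every k-mer of an encoded sequence.

    Windows containing an N (code 4) get code -1.  Uses base-4 positional
    encoding, so k must satisfy 4**k < 2**63 (k <= 31).
    """
    n = codes.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64)
    valid = codes < 4
    c = np.where(valid, codes, 0).astype(np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(c, k)
    out = win @ powers
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    return np.where(ok, out, -1)


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


# --- minimal FASTQ / FASTA text IO -----------------------------------------
# FASTQ is parsed directly (4-line records, Phred+33); at the read counts this
# package handles, a dependency-free parser keeps the pipeline fast.

def write_fastq(path, reads) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.bases}\n+\n")
            fh.write((np.asarray(r.quals, dtype=np.uint8) + 33).tobytes().decode("latin1"))
            fh.write("\n")


def read_fastq(path):
    """Yield (id, bases, quals-uint8-array) from a Phred+33 FASTQ file."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            bases = fh.readline().strip()
            fh.readline()
            qline = fh.readline().rstrip("\n")
            quals = np.frombuffer(qline.encode("latin1"), dtype=np.uint8) - 33
            yield header[1:].strip(), bases, quals


def write_fasta(path, records, width: int = 80) -> None:
    """Write (name_or_header, sequence) pairs as FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path):
    """Yield (header, sequence) pairs from a FASTA file."""
    header, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(chunks)
                header, chunks = line[1:], []
            elif line:
                chunks.append(line.strip())
    if header is not None:
        yield header, "".join(chunks)
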