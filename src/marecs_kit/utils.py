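"""Small shared helpers: sequence alphabet, reverse complement, Phred codecs, seeding."""

from __future__ import annotations

import numpy as np

BASES = b"ACGT"

_COMP = bytes.maketrans(b"ACGTacgtNn", b"TGCAtgcaNn")


def revcomp(seq: bytes) -> bytes:
    """Reverse complement of a DNA sequence given as bytes."""
    return seq.translate(_COMP)[::-1]


def phred_to_qual_string(q: int, length: int) -> str:
    """Constant-quality Phred+33 string."""
    return chr(min(q, 93) + 33) * length


def mean_phred(qual: str) -> float:
    """Mean Phred score of a FASTQ quality string (Phred+33)."""
    if not qual:
        return 0.0
    arr = np.frombuffer(qual.encode("ascii"), dtype=np.uint8)
    return float(arr.mean() - 33.0)


def child_rng(seed: int, *tags: int) -> np.random.Generator:
    """Derive an independent, reproducible generator from a base seed and integer tags.

    Keeps every source of randomness traceable to one user-supplied seed while
    decorrelating stages (reads vs embryos vs counts).
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tags))
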