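"""Small sequence utilities used by the simulator and the callers."""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"
_BASE_TO_INT = {b: i for i, b in enumerate(BASES)}
_BASE_TO_INT["N"] = 4


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    """Translate a CDS; trailing stop (if any) is stripped."""
    prot = str(Seq(seq[: len(seq) - len(seq) % 3]).translate())
    return prot[:-1] if prot.endswith("*") else prot.split("*")[0] if "*" in prot else prot


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=n)])


STOP_CODONS = {"TAA", "TAG", "TGA"}


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random codons with no in-frame stop."""
    codons = []
    while len(codons) < n_codons:
        c = random_dna(rng, 3)
        if c not in STOP_CODONS:
            codons.append(c)
    return "".join(codons)


def encode(seq: str) -> np.ndarray:
    """Encode DNA to int8 (A=0 C=1 G=2 T=3, other=4)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
        out[arr == ord(base)] = code
    return out


def homopolymer_mask(ref_seq: str, min_run: int = 4, flank: int = 1) -> np.ndarray:
    """Boolean mask over 0-based positions inside or within ``flank``
    bases of a run of >= ``min_run`` identical reference bases."""
    n = len(ref_seq)
    mask = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        j = i + 1
        while j < n and ref_seq[j] == ref_seq[i]:
            j += 1
        if j - i >= min_run:
            mask[max(0, i - flank) : min(n, j + flank)] = True
        i = j
    return mask


def longest_unit_run(seq: str, unit: str) -> int:
    """Maximum number of consecutive exact copies of ``unit`` in ``seq``."""
    if not unit:
        raise ValueError("empty repeat unit")
    best = 0
    k = len(unit)
    i = 0
    n = len(seq)
    while i < n:
        run = 0
        j = i
        while seq[j : j + k] == unit:
            run += 1
            j += k
        if run > best:
            best = run
        i += 1 if run == 0 else 1  # slide by one; runs re-checked from every offset
    return best
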