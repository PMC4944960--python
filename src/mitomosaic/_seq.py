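"""Internal DNA helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = ("TAA", "TAG", "TGA")

# A 5-codon run that is all sense codons in its own reading frame (L,I,N,N,Y)
# but contains a stop codon in each of the five other frames (both shifted
# plus frames and all three minus frames).  Peppered through engineered
# coding sequence it confines out-of-frame open reading frames without
# touching the encoded frame.
STOP_SHIELD_CODONS = ("TTA", "ATT", "AAT", "AAT", "TAC")
STOP_SHIELD = "".join(STOP_SHIELD_CODONS)

# All six frames of this 12-mer (its own reverse complement) contain a stop:
# used to pad engineered cassettes so no reading frame runs across them.
CASSETTE_PAD = "TTAATTAATTAA"

# Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    """GC over A+C+G+T; N excluded from numerator and denominator."""
    atgc = sum(seq.count(b) for b in "ACGT")
    if atgc == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (seq.count("G") + seq.count("C")) / atgc


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """I.i.d. bases with P(G) = P(C) = gc/2."""
    cum = np.cumsum([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = np.searchsorted(cum, rng.random(length), side="right")
    return np.frombuffer(b"ACGT", dtype=np.uint8)[idx].tobytes().decode()


def random_orf_codons(rng: np.random.Generator, n_codons: int, gc: float = 0.5) -> str:
    """``n_codons`` random sense (non-stop) codons."""
    out = []
    while len(out) < n_codons:
        chunk = random_dna(rng, 3 * (n_codons - len(out)), gc)
        for i in range(0, len(chunk), 3):
            codon = chunk[i:i + 3]
            if codon not in STOP_CODONS:
                out.append(codon)
            if len(out) == n_codons:
                break
    return "".join(out)


def scrub_motif(seq: str, motif: str, replacement_base: str = "C") -> str:
    """Destroy every occurrence of ``motif`` (and its reverse complement) by
    mutating the motif's central base.  Used to keep planted restriction maps
    exact within engineered windows."""
    rc = revcomp(motif)
    mid = len(motif) // 2
    s = list(seq)
    changed = True
    while changed:
        changed = False
        text = "".join(s)
        for m in (motif, rc):
            idx = text.find(m)
            while idx != -1:
                pos = idx + mid
                s[pos] = replacement_base if s[pos] != replacement_base else "G"
                changed = True
                text = "".join(s)
                idx = text.find(m, idx + 1)
    return "".join(s)
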