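"""Small shared sequence helpers: complements and IUPAC degeneracy."""

from __future__ import annotations

import re

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile a degenerate DNA word into a regex over ACGT (N never matches N)."""
    parts = []
    for ch in to_dna(pattern):
        bases = IUPAC.get(ch)
        if bases is None:
            raise ValueError(f"not an IUPAC nucleotide code: {ch!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def iupac_match(pattern: str, seq: str) -> bool:
    """True if the degenerate word matches ``seq`` exactly (equal lengths)."""
    pattern, seq = to_dna(pattern), to_dna(seq)
    if len(pattern) != len(seq):
        return False
    return all(b in IUPAC.get(p, "") for p, b in zip(pattern, seq))
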