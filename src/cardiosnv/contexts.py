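"""Trinucleotide mutation-context machinery.

Somatic single-base substitutions are conventionally collapsed onto the
pyrimidine strand and binned into 96 classes: 6 substitution types
(C>A, C>G, C>T, T>A, T>C, T>G) x 16 flanking-base combinations. This module
defines the canonical class order used throughout the package and the
mapping from a (ref, alt, 5'-base, 3'-base) observation to its class.
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINES = ("C", "T")
SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")

#: The 96 class labels, e.g. "A[C>T]G", ordered by substitution type then
#: alphabetically by (5', 3') flanking bases. This matches the column order
#: of COSMIC-style signature matrices.
CONTEXT_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five in BASES
    for three in BASES
)

CONTEXT_INDEX = {label: i for i, label in enumerate(CONTEXT_96)}


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def class_label(five: str, ref: str, alt: str, three: str) -> str:
    """Return the pyrimidine-strand 96-class label for a substitution.

    If ``ref`` is a purine the triplet and the substitution are reverse
    complemented so the mutated base is reported as C or T.
    """
    if ref not in BASES or alt not in BASES or ref == alt:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if ref in PYRIMIDINES:
        return f"{five}[{ref}>{alt}]{three}"
    return f"{COMPLEMENT[three]}[{COMPLEMENT[ref]}>{COMPLEMENT[alt]}]{COMPLEMENT[five]}"


def class_of_variant(chrom_seq: str, pos: int, ref: str, alt: str) -> str:
    """96-class of a variant given its chromosome sequence (0-based ``pos``).

    Raises ``ValueError`` at chromosome ends (no flanking base) and if the
    reference base does not match the genome.
    """
    if pos <= 0 or pos >= len(chrom_seq) - 1:
        raise ValueError(f"position {pos} lacks a flanking base")
    if chrom_seq[pos] != ref:
        raise ValueError(
            f"reference mismatch at {pos}: genome={chrom_seq[pos]} variant={ref}"
        )
    return class_label(chrom_seq[pos - 1], ref, alt, chrom_seq[pos + 1])


def parse_class(label: str) -> tuple[str, str, str, str]:
    """Split "A[C>T]G" into (five, ref, alt, three)."""
    return label[0], label[2], label[4], label[6]


def pyrimidine_triplet(label: str) -> str:
    """The reference triplet of a class on the pyrimidine strand."""
    five, ref, _, three = parse_class(label)
    return five + ref + three


def substitution_type(label: str) -> str:
    """Collapse a 96-class label to its 6-type substitution, e.g. "C>T"."""
    return label[2:5]


_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i


def encode_triplets(seq: str) -> np.ndarray:
    """Integer code (0..63) of the triplet centred at each internal position.

    Entry ``i`` codes ``seq[i-1:i+2]`` for 1 <= i <= len-2; the two boundary
    entries are -1.
    """
    codes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int32)
    trip = np.full(len(seq), -1, dtype=np.int32)
    if len(seq) >= 3:
        trip[1:-1] = codes[:-2] * 16 + codes[1:-1] * 4 + codes[2:]
    return trip


def triplet_code(triplet: str) -> int:
    """Code of a 3-mer consistent with :func:`encode_triplets`."""
    a, b, c = (BASES.index(x) for x in triplet)
    return a * 16 + b * 4 + c
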