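"""The 96 trinucleotide substitution classes and strand-collapsing rules.

Somatic single-nucleotide variants are classified by the substituted base
together with its immediate 5' and 3' neighbours.  Because a substitution on
one strand is indistinguishable from its complement on the other, mutations
at purine reference bases (A, G) are reverse-complemented so that every
class has a pyrimidine (C or T) reference.  This collapses the 192 raw
(substitution, flank) encodings to 96 canonical classes such as ``A[C>T]G``.
"""

from __future__ import annotations

import re

BASES: tuple[str, ...] = ("A", "C", "G", "T")
PYRIMIDINES: frozenset[str] = frozenset("CT")

COMPLEMENT: dict[str, str] = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The six pyrimidine-referenced substitutions, in conventional order.
SUBSTITUTIONS: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Canonical column order: substitution is the outer (slowest-varying) key,
#: then the 5' flank, then the 3' flank, each in A,C,G,T order.  This is the
#: layout used by published signature tables, so they load without
#: reindexing.
CONTEXT_ORDER: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

#: The 32 pyrimidine-centered trinucleotides (e.g. ACA ... TTT) over which
#: genomic occurrence counts are tabulated for territory normalization.
PYRIMIDINE_TRIPLETS: tuple[str, ...] = tuple(
    sorted({five + mid + three for mid in "CT" for five in BASES for three in BASES})
)

_CONTEXT_RE = re.compile(r"^([ACGT])\[([CT])>([ACGT])\]([ACGT])$")


def reverse_complement(seq: str) -> str:
    """Reverse-complement an A/C/G/T string."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def collapse_context(five: str, ref: str, alt: str, three: str) -> str:
    """Map a raw (flank, substitution, flank) encoding to its canonical class.

    Pyrimidine references pass through unchanged; purine references are
    reverse-complemented, which swaps and complements the flanks.
    """
    if ref in PYRIMIDINES:
        return f"{five}[{ref}>{alt}]{three}"
    return (
        f"{COMPLEMENT[three]}[{COMPLEMENT[ref]}>{COMPLEMENT[alt]}]{COMPLEMENT[five]}"
    )


def parse_context(label: str) -> tuple[str, str, str, str]:
    """Split ``"A[C>T]G"`` into (five, ref, alt, three); raises on bad labels."""
    m = _CONTEXT_RE.match(label)
    if m is None or m.group(2) == m.group(3):
        raise ValueError(f"not a valid trinucleotide context label: {label!r}")
    return m.group(1), m.group(2), m.group(3), m.group(4)


def context_triplet(label: str) -> str:
    """The pyrimidine-centered reference trinucleotide of a context class."""
    five, ref, _alt, three = parse_context(label)
    return five + ref + three


#: Context label -> reference trinucleotide, precomputed for normalization.
CONTEXT_TRIPLETS: dict[str, str] = {c: context_triplet(c) for c in CONTEXT_ORDER}

CONTEXT_INDEX: dict[str, int] = {c: i for i, c in enumerate(CONTEXT_ORDER)}
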