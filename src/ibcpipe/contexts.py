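"""Trinucleotide-context conventions shared across modules.

Single-base substitutions are reported on the pyrimidine strand, giving six
substitution classes (C>A, C>G, C>T, T>A, T>C, T>G). Combined with the 4 x 4
possible flanking bases this yields the standard 96 mutation categories.
Bin order is fixed: substitution-major, then 5' base, then 3' base, each in
alphabetical order, and labels follow the "A[C>A]A" convention.
"""

from __future__ import annotations

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def context_labels() -> list[str]:
    """The 96 category labels in canonical order, e.g. ``A[C>A]A``."""
    labels = []
    for sub in SUBSTITUTIONS:
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{sub}]{three}")
    return labels


CONTEXT_LABELS = context_labels()
CONTEXT_INDEX = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}


def normalize_snv(ref: str, alt: str, five: str, three: str) -> tuple[str, str]:
    """Collapse an SNV onto the pyrimidine strand.

    Returns ``(substitution, context)`` where context is the 3-base string
    5'-base + ref + 3'-base after strand normalization. Raises ValueError for
    non-SNV input.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not an SNV: {ref}>{alt}")
    five, three = five.upper(), three.upper()
    if ref in ("A", "G"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        five, three = _COMPLEMENT[three], _COMPLEMENT[five]
    return f"{ref}>{alt}", f"{five}{ref}{three}"


def label_for(substitution: str, context: str) -> str:
    """Build the ``A[C>A]A`` label from a substitution and 3-base context."""
    return f"{context[0]}[{substitution}]{context[2]}"


def bin_index(substitution: str, context: str) -> int:
    return CONTEXT_INDEX[label_for(substitution, context)]


def parse_label(label: str) -> tuple[str, str]:
    """Inverse of :func:`label_for`: ``A[C>T]G`` -> (``C>T``, ``ACG``)."""
    five, rest = label[0], label[2:]
    sub, three = rest[:3], rest[4]
    return sub, f"{five}{sub[0]}{three}"
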