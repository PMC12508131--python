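"""Single-base-substitution trinucleotide contexts (the 96-class SBS convention).

Every SNV is described by its substituted pyrimidine and the two flanking
bases, written ``5'[REF>ALT]3'`` (e.g. ``A[C>T]G``).  Variants whose reference
base is a purine are reverse-complemented onto the pyrimidine strand first.
The 96 classes are ordered the way COSMIC SBS matrices order them:
substitution-major (C>A, C>G, C>T, T>A, T>C, T>G), then 5' flank, then 3'
flank, each in A, C, G, T order.
"""

from __future__ import annotations

BASES = "ACGT"
PYRIMIDINES = "CT"
PURINES = "AG"

SUBSTITUTIONS: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

CONTEXTS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)

CONTEXT_INDEX: dict[str, int] = {c: i for i, c in enumerate(CONTEXTS_96)}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: The 32 trinucleotides with a pyrimidine centre, in a stable order.
PYRIMIDINE_TRINUCS: tuple[str, ...] = tuple(
    f"{five}{centre}{three}" for centre in PYRIMIDINES for five in BASES for three in BASES
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_trinucleotide(trinuc: str) -> str:
    """Map a trinucleotide to its pyrimidine-centre representative.

    ``TGC`` (centre G) becomes ``GCA``; pyrimidine-centred input is returned
    unchanged (upper-cased).
    """
    trinuc = trinuc.upper()
    if len(trinuc) != 3:
        raise ValueError(f"expected a trinucleotide, got {trinuc!r}")
    return revcomp(trinuc) if trinuc[1] in PURINES else trinuc


def classify_substitution(trinuc: str, alt: str) -> str:
    """96-class label for a substitution observed in reference context.

    Parameters
    ----------
    trinuc : reference trinucleotide centred on the variant position, as it
        appears on the reference strand.
    alt : alternate base on the reference strand.

    A purine reference base sends both the context and the alternate allele
    through the reverse complement, e.g. a G>A change at 5'-TGC-3' is the
    pyrimidine-strand class ``G[C>T]A``.
    """
    trinuc = trinuc.upper()
    alt = alt.upper()
    if len(trinuc) != 3 or alt not in BASES:
        raise ValueError(f"bad substitution context {trinuc!r}>{alt!r}")
    ref = trinuc[1]
    if ref == alt:
        raise ValueError(f"reference and alternate base identical ({ref})")
    if ref in PURINES:
        trinuc = revcomp(trinuc)
        alt = alt.translate(_COMPLEMENT)
        ref = trinuc[1]
    if "N" in trinuc:
        raise AmbiguousContextError(f"context {trinuc} contains N")
    return f"{trinuc[0]}[{ref}>{alt}]{trinuc[2]}"


class AmbiguousContextError(ValueError):
    """Raised when a context contains an ambiguous (N) base."""


def context_trinucleotide(context: str) -> str:
    """``A[C>T]G`` -> ``ACG`` (the pyrimidine-strand reference trinucleotide)."""
    return context[0] + context[2] + context[6]


def context_ref(context: str) -> str:
    return context[2]


def context_alt(context: str) -> str:
    return context[4]
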