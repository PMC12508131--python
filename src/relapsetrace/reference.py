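"""Reference sequence handling: synthetic FASTA generation and context lookup.

The simulator places mutations at loci whose reference trinucleotide matches
a drawn substitution context.  A ~1 Mb synthetic contig is enough: every one
of the 32 pyrimidine-centre trinucleotides occurs tens of thousands of times
in random sequence, and generation appends a guarantee cassette in the
(astronomically unlikely) event one is missing.  Coordinates are 1-based
throughout, as in VCF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pyfaidx import Fasta

from .contexts import (
    PYRIMIDINE_TRINUCS,
    canonical_trinucleotide,
    context_trinucleotide,
    revcomp,
)

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ReferenceGenome:
    name: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)

    def trinucleotide(self, pos: int) -> str:
        """Reference trinucleotide centred at 1-based ``pos``."""
        if not 2 <= pos <= len(self.seq) - 1:
            raise IndexError(f"position {pos} lacks flanking bases")
        return self.seq[pos - 2 : pos + 1].upper()

    def base(self, pos: int) -> str:
        return self.seq[pos - 1].upper()


def synthesize_reference(
    length: int = 1_000_000, seed: int = 20_240, name: str = "chrS"
) -> ReferenceGenome:
    """Generate a random contig containing all 32 canonical trinucleotides."""
    rng = np.random.default_rng(seed)
    arr = _BASE_ARR[rng.integers(0, 4, size=length)]
    seq = arr.tobytes().decode("ascii")
    present = {
        canonical_trinucleotide(seq[i : i + 3]) for i in range(len(seq) - 2)
    }
    missing = [t for t in PYRIMIDINE_TRINUCS if t not in present]
    if missing:  # pragma: no cover - unreachable at default length
        seq += "".join(f"TT{t}TT" for t in missing)
    return ReferenceGenome(name=name, seq=seq)


def write_fasta(ref: ReferenceGenome, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{ref.name}\n")
        for i in range(0, len(ref.seq), width):
            fh.write(ref.seq[i : i + width] + "\n")


def load_fasta(path, contig: str | None = None) -> ReferenceGenome:
    """Load one contig from a FASTA file (first contig by default)."""
    fa = Fasta(str(path), rebuild=True)
    keys = list(fa.keys())
    if not keys:
        raise ValueError(f"{path}: empty FASTA")
    name = contig if contig is not None else keys[0]
    return ReferenceGenome(name=name, seq=str(fa[name][:]).upper())


class ContextLocusIndex:
    """Positions of each canonical trinucleotide in a reference contig.

    Maps a pyrimidine-centre trinucleotide to the sorted 1-based positions
    whose reference trinucleotide equals it on either strand.  Positions with
    N in the context are skipped.
    """

    def __init__(self, ref: ReferenceGenome) -> None:
        self.ref = ref
        seq = np.frombuffer(ref.seq.upper().encode("ascii"), dtype=np.uint8)
        code = np.full(seq.shape, -1, dtype=np.int64)
        for i, b in enumerate("ACGT"):
            code[seq == ord(b)] = i
        valid = code >= 0
        tri_ok = valid[:-2] & valid[1:-1] & valid[2:]
        tri_code = code[:-2] * 16 + code[1:-1] * 4 + code[2:]
        tri_code[~tri_ok] = -1
        self._positions: dict[str, np.ndarray] = {}
        # canonical code for every possible trinucleotide
        for t in PYRIMIDINE_TRINUCS:
            codes = [_tri_code(t), _tri_code(revcomp(t))]
            mask = np.isin(tri_code, codes)
            self._positions[t] = np.flatnonzero(mask) + 2  # centre, 1-based

    def positions(self, trinuc: str) -> np.ndarray:
        return self._positions[canonical_trinucleotide(trinuc)]

    def positions_for_context(self, context: str) -> np.ndarray:
        return self.positions(context_trinucleotide(context))

    def counts(self) -> dict[str, int]:
        return {t: int(p.size) for t, p in self._positions.items()}


def _tri_code(trinuc: str) -> int:
    return ("ACGT".index(trinuc[0]) * 16 + "ACGT".index(trinuc[1]) * 4
            + "ACGT".index(trinuc[2]))
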