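"""Mutational-signature refitting and etiology attribution.

A sample's SNVs in non-repetitive regions are reduced to a 96-class
trinucleotide substitution spectrum, decomposed against a signature catalog
by non-negative least squares, and summarized per etiology class.  Each
patient gets a primary signature (the largest etiology class, with and
without the Unknown class), each of the 96 motifs a most-likely signature
(the catalog column with the highest probability at that motif), and
relapse-specific spectra are compared to diagnostic profiles by squared
Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .catalog import SignatureCatalog
from .contexts import CONTEXT_INDEX, CONTEXTS_96, classify_substitution, AmbiguousContextError
from .reference import ReferenceGenome


@dataclass
class ContextSpectrum:
    """96-class mutation counts in catalog context order."""

    counts: np.ndarray
    excluded: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (96,):
            raise ValueError(f"expected 96 counts, got shape {c.shape}")
        if (c < 0).any():
            raise ValueError("negative counts")
        self.counts = c

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        n = self.n
        return self.counts / n if n > 0 else np.zeros(96)

    @staticmethod
    def from_contexts(contexts) -> "ContextSpectrum":
        counts = np.zeros(96, dtype=np.int64)
        for c in contexts:
            counts[CONTEXT_INDEX[c]] += 1
        return ContextSpectrum(counts)


@dataclass
class ExposureProfile:
    """Normalized signature contributions plus the NNLS fit residual."""

    contributions: dict[str, float]
    residual: float = 0.0
    n: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.contributions.values()):
            raise ValueError("contributions must be non-negative")
        if self.contributions:
            total = sum(self.contributions.values())
            if self.n > 0 and abs(total - 1.0) > 1e-6:
                raise ValueError(f"contributions sum to {total}, expected 1")


def build_spectrum(
    snvs,
    reference: ReferenceGenome,
    include_repeats: bool = False,
) -> ContextSpectrum:
    """Trinucleotide spectrum of SNVs, pyrimidine-strand convention.

    Restricted to SNVs outside repeat-masked regions unless
    ``include_repeats``; variants whose context contains an N are excluded
    and tallied in ``excluded``.  Counts conserve: n equals the number of
    contributing SNVs.
    """
    counts = np.zeros(96, dtype=np.int64)
    excluded = 0
    for v in snvs:
        if not v.is_snv:
            continue
        if not include_repeats and v.region_class == "repeat":
            continue
        trinuc = reference.trinucleotide(v.pos)
        if trinuc[1] != v.ref.upper():
            raise ValueError(
                f"{v.id}: reference base mismatch ({trinuc[1]} != {v.ref})"
            )
        try:
            ctx = classify_substitution(trinuc, v.alt)
        except AmbiguousContextError:
            excluded += 1
            continue
        counts[CONTEXT_INDEX[ctx]] += 1
    return ContextSpectrum(counts, excluded=excluded)


def refit_exposures(
    spectrum: ContextSpectrum, catalog: SignatureCatalog
) -> ExposureProfile:
    """Non-negative least-squares decomposition of a spectrum.

    Solves min ||counts - M x||_2 with x >= 0 over the catalog columns and
    normalizes x to sum 1.  An empty spectrum yields a defined empty profile.
    """
    if spectrum.n == 0:
        return ExposureProfile(contributions={}, residual=0.0, n=0)
    x, residual = optimize.nnls(catalog.matrix, spectrum.counts.astype(float))
    total = x.sum()
    if total <= 0:
        # counts orthogonal to every signature; report uniform-zero profile
        return ExposureProfile(
            contributions={n: 0.0 for n in catalog.names},
            residual=float(residual),
            n=spectrum.n,
        )
    contributions = {n: float(v / total) for n, v in zip(catalog.names, x)}
    return ExposureProfile(
        contributions=contributions, residual=float(residual), n=spectrum.n
    )


def classify_etiology(
    profile: ExposureProfile, catalog: SignatureCatalog
) -> dict[str, float]:
    """Sum contributions per etiology class; conserves total mass exactly."""
    sums: dict[str, float] = {}
    for sig, contrib in profile.contributions.items():
        if sig not in catalog.etiology:
            raise ValueError(f"signature {sig!r} has no etiology in the catalog")
        cls = catalog.etiology[sig]
        sums[cls] = sums.get(cls, 0.0) + contrib
    return sums


@dataclass(frozen=True)
class PrimaryCall:
    primary: str
    primary_known: str | None
    tie: bool = False


def primary_signature(class_sums: dict[str, float]) -> PrimaryCall:
    """Largest etiology class, overall and excluding Unknown.

    Exact ties resolve alphabetically and are flagged.
    """
    if not class_sums:
        raise ValueError("empty etiology summary")

    def argmax(items):
        best = max(items, key=lambda kv: (kv[1], ))
        winners = sorted(k for k, v in items if v == best[1])
        return winners[0], len(winners) > 1

    items = sorted(class_sums.items())
    primary, tie = argmax(items)
    known_items = [(k, v) for k, v in items if k != "Unknown"]
    if known_items:
        primary_known, tie_known = argmax(known_items)
    else:
        primary_known, tie_known = None, False
    return PrimaryCall(primary=primary, primary_known=primary_known,
                       tie=tie or tie_known)


def motif_signature_map(
    catalog: SignatureCatalog,
    exposure_weights: dict[str, float] | None = None,
) -> dict[str, str]:
    """Most-likely signature for each of the 96 motifs.

    By default each motif maps to the signature whose raw catalog column has
    the highest probability there.  ``exposure_weights`` optionally rescales
    columns by a sample's exposures first (attribution conditioned on the
    signatures actually present).  Ties break by signature order in the
    catalog; tied motifs are recorded on the returned dict under the
    attribute-free key convention of :func:`motif_signature_ties`.
    """
    m = catalog.matrix
    if exposure_weights is not None:
        w = np.array([exposure_weights.get(n, 0.0) for n in catalog.names])
        m = m * w[np.newaxis, :]
    best = m.argmax(axis=1)
    return {CONTEXTS_96[i]: catalog.names[best[i]] for i in range(96)}


def motif_signature_ties(
    catalog: SignatureCatalog,
    exposure_weights: dict[str, float] | None = None,
) -> set[str]:
    """Motifs where the most-likely signature is tied."""
    m = catalog.matrix
    if exposure_weights is not None:
        w = np.array([exposure_weights.get(n, 0.0) for n in catalog.names])
        m = m * w[np.newaxis, :]
    top = m.max(axis=1, keepdims=True)
    return {
        CONTEXTS_96[i] for i in range(96) if (m[i] == top[i]).sum() > 1
    }


def average_vaf_per_signature(
    mutations, motif_map: dict[str, str]
) -> dict[str, float]:
    """Mean VAF per most-likely signature.

    ``mutations`` is an iterable of (context, vaf) pairs; each mutation is
    attributed to its motif's most-likely signature and VAFs are averaged
    within signatures.  Signatures with no mutations are absent.
    """
    sums: dict[str, list[float]] = {}
    for context, vaf in mutations:
        sig = motif_map[context]
        sums.setdefault(sig, []).append(float(vaf))
    return {sig: float(np.mean(v)) for sig, v in sums.items()}


def compare_profiles(
    diagnostic: ContextSpectrum, relapse_specific: ContextSpectrum
) -> float:
    """Squared Spearman rank correlation of two 96-class spectra.

    The relapse-specific spectrum must be built from variants absent at
    diagnosis.  A constant spectrum has no defined rank correlation and
    returns NaN rather than 0.
    """
    a = diagnostic.counts.astype(float)
    b = relapse_specific.counts.astype(float)
    if np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan")
    rho = stats.spearmanr(a, b).statistic
    return float(rho * rho)


def relapse_specific_ids(
    diag_vafs: dict[str, float | None], relapse_vafs: dict[str, float | None]
) -> set[str]:
    """Variants present at relapse but absent at diagnosis.

    Inputs are variant-id -> VAF maps *after* the depth gate (gated-out
    observations passed as None are ignored on that side).
    """
    out = set()
    for vid, rv in relapse_vafs.items():
        if rv is None or rv <= 0:
            continue
        dv = diag_vafs.get(vid)
        if dv is not None and dv == 0:
            out.add(vid)
    return out
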