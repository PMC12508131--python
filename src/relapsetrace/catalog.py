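"""SBS signature catalogs: COSMIC-layout readers, etiology labels, bundled fixture.

A catalog is a column-stochastic 96 x S probability matrix over the
trinucleotide substitution classes, with one proposed etiology per signature.
Etiologies are collapsed onto the seven classes used for per-patient
summaries: Chemotherapy, MMR, APOBEC_AID, UV, Clock_like, Miscellaneous and
Unknown, where Miscellaneous aggregates chemical exposure, tobacco, reactive
oxygen species and biological/bacterial causes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .contexts import CONTEXTS_96, CONTEXT_INDEX

ETIOLOGY_CLASSES: tuple[str, ...] = (
    "APOBEC_AID",
    "Chemotherapy",
    "Clock_like",
    "MMR",
    "Miscellaneous",
    "UV",
    "Unknown",
)

#: Finer-grained labels accepted in etiology files, folded into the summary
#: classes (chemical exposure, tobacco, ROS and biological/bacterial causes
#: are grouped as Miscellaneous).
RAW_ETIOLOGY_MAP: dict[str, str] = {
    "apobec_aid": "APOBEC_AID",
    "apobec/aid": "APOBEC_AID",
    "apobec": "APOBEC_AID",
    "chemotherapy": "Chemotherapy",
    "chemotherapy treatment": "Chemotherapy",
    "thiopurine": "Chemotherapy",
    "mmr": "MMR",
    "mismatch repair": "MMR",
    "mismatch repair (mmr)": "MMR",
    "uv": "UV",
    "clock_like": "Clock_like",
    "clock-like": "Clock_like",
    "miscellaneous": "Miscellaneous",
    "chemical exposure": "Miscellaneous",
    "tobacco": "Miscellaneous",
    "ros": "Miscellaneous",
    "biological": "Miscellaneous",
    "bacterial": "Miscellaneous",
    "unknown": "Unknown",
}

_COLSUM_TOL = 1e-6


class CatalogError(ValueError):
    pass


def normalize_etiology(label: str) -> str:
    try:
        return RAW_ETIOLOGY_MAP[label.strip().lower()]
    except KeyError:
        raise CatalogError(
            f"unrecognized etiology label {label!r}; expected one of "
            f"{sorted(set(RAW_ETIOLOGY_MAP))}"
        ) from None


@dataclass(frozen=True)
class SignatureCatalog:
    """An ordered set of SBS signatures with per-signature etiology classes.

    Attributes
    ----------
    names : signature names, column order of ``matrix``.
    matrix : float array of shape (96, S); each column sums to 1.
    etiology : signature name -> etiology class (one of ETIOLOGY_CLASSES).
    """

    names: tuple[str, ...]
    matrix: np.ndarray
    etiology: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (96, len(self.names)):
            raise CatalogError(
                f"matrix shape {m.shape} does not match 96 x {len(self.names)}"
            )
        if (m < 0).any():
            raise CatalogError("catalog contains negative probabilities")
        colsums = m.sum(axis=0)
        bad = np.flatnonzero(np.abs(colsums - 1.0) > _COLSUM_TOL)
        if bad.size:
            raise CatalogError(
                f"columns not summing to 1: {[self.names[i] for i in bad]}"
            )
        missing = [n for n in self.names if n not in self.etiology]
        if missing:
            raise CatalogError(f"signatures without etiology: {missing}")
        unknown_cls = {
            n: c for n, c in self.etiology.items() if c not in ETIOLOGY_CLASSES
        }
        if unknown_cls:
            raise CatalogError(f"etiology classes outside the schema: {unknown_cls}")
        object.__setattr__(self, "matrix", m)

    @property
    def n_signatures(self) -> int:
        return len(self.names)

    def column(self, name: str) -> np.ndarray:
        try:
            return self.matrix[:, self.names.index(name)]
        except ValueError:
            raise CatalogError(f"no signature named {name!r}") from None

    def subset(self, names: list[str] | tuple[str, ...]) -> "SignatureCatalog":
        cols = [self.names.index(n) for n in names]
        return SignatureCatalog(
            names=tuple(names),
            matrix=self.matrix[:, cols],
            etiology={n: self.etiology[n] for n in names},
        )


def read_catalog_tsv(path: str | Path, etiology: dict[str, str]) -> SignatureCatalog:
    """Read a COSMIC v3 style SBS matrix (tab-separated, 96 rows).

    The first column holds the substitution class (``A[C>A]A`` style, any row
    order); remaining columns are signatures.  ``etiology`` maps each
    signature name to an etiology label (fine-grained labels accepted).
    """
    df = pd.read_csv(path, sep="\t")
    type_col = df.columns[0]
    rows = df[type_col].astype(str).str.strip()
    unknown = sorted(set(rows) - set(CONTEXTS_96))
    if unknown:
        raise CatalogError(f"unrecognized context rows: {unknown[:5]}")
    if len(rows) != 96 or len(set(rows)) != 96:
        raise CatalogError(f"expected the 96 contexts exactly once, got {len(rows)} rows")
    order = [CONTEXT_INDEX[r] for r in rows]
    names = tuple(str(c) for c in df.columns[1:])
    matrix = np.zeros((96, len(names)))
    matrix[order, :] = df[list(df.columns[1:])].to_numpy(dtype=float)
    # renormalize printed-precision columns
    matrix = matrix / matrix.sum(axis=0, keepdims=True)
    eti = {n: normalize_etiology(etiology[n]) for n in names if n in etiology}
    missing = [n for n in names if n not in eti]
    if missing:
        raise CatalogError(f"no etiology provided for: {missing}")
    return SignatureCatalog(names=names, matrix=matrix, etiology=eti)


def read_etiology_tsv(path: str | Path) -> dict[str, str]:
    """Two-column TSV (signature, etiology label) -> normalized mapping."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise CatalogError("etiology file needs two columns: signature, etiology")
    sig_col, cls_col = df.columns[:2]
    return {
        str(r[sig_col]).strip(): str(r[cls_col]).strip() for _, r in df.iterrows()
    }


def write_catalog_tsv(catalog: SignatureCatalog, path: str | Path) -> None:
    df = pd.DataFrame(catalog.matrix, columns=list(catalog.names))
    df.insert(0, "Type", list(CONTEXTS_96))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def bundled_catalog() -> SignatureCatalog:
    """The miniature synthetic six-signature catalog shipped with the package.

    Six synthetic signatures cover the etiology classes relevant to relapsed
    leukemia, including a thiopurine-like chemotherapy signature.  They are a
    synthetic stand-in for a COSMIC catalog: block-concentrated profiles with
    mostly disjoint support, so refitting on them is well conditioned.  Real
    COSMIC SBS files load through :func:`read_catalog_tsv` unchanged.
    """
    pkg = resources.files("relapsetrace.data")
    with resources.as_file(pkg / "synthetic_sbs_etiology.tsv") as p:
        etiology = read_etiology_tsv(p)
    with resources.as_file(pkg / "synthetic_sbs_catalog.tsv") as p:
        return read_catalog_tsv(p, etiology)
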