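"""Readers and writers for the on-disk formats and the shared domain types.

The canonical exchange format is TSV. Count matrices may also be read from
MatrixMarket coordinate files (``<stem>.mtx`` plus ``<stem>.rownames.txt`` /
``<stem>.colnames.txt``) for interoperability with GEO supplementary data.

Gene identifiers are HGNC-style symbols throughout; canonicalization is
uppercase + whitespace strip and is idempotent. Sample metadata and qPCR Ct
tables are handled as validated :class:`pandas.DataFrame` objects.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger(__name__)

#: qPCR target genes: numerator / denominator of the quiescence ratio.
ANCHOR_NUMERATOR = "ATP2B4"
ANCHOR_DENOMINATOR = "ATP2A2"
#: qPCR reference (housekeeping) genes.
REFERENCE_GENES = ("B2M", "RPL30")

SAMPLE_GROUPS = {"TL", "TNL", "PTB-sPTL", "PTB-PPROM", "PTB-PI", "PTB", "unknown"}

#: Mandatory columns of a sample table.
SAMPLE_REQUIRED = ("sample_id", "group")
#: Mandatory columns of a Ct table.
CT_REQUIRED = ("sample_id", "assay", "well", "ct")
#: Recognised qPCR assay symbols; others are retained with a warning.
KNOWN_ASSAYS = frozenset({ANCHOR_NUMERATOR, ANCHOR_DENOMINATOR, *REFERENCE_GENES})


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain-type invariant."""


def canonical_symbol(symbol: str) -> str:
    """Canonicalize a gene symbol (strip whitespace, uppercase). Idempotent."""
    return str(symbol).strip().upper()


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with optional per-sample batch labels.

    Invariants (enforced on construction): unique canonical gene symbols,
    unique sample ids, all counts integral and >= 0, consistent dimensions.
    """

    genes: list[str]
    samples: list[str]
    counts: np.ndarray
    batch: list[str] | None = None

    def __post_init__(self) -> None:
        self.genes = [canonical_symbol(g) for g in self.genes]
        self.samples = [str(s) for s in self.samples]
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ValidationError(f"duplicate gene symbols after canonicalization: {dupes[:5]}")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample IDs")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            bad = ~np.isclose(self.counts.astype(float), rounded)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValidationError(
                    f"non-integer count at gene {self.genes[i]!r}, sample {self.samples[j]!r}"
                )
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.genes[i]!r}, sample {self.samples[j]!r}"
            )
        if self.batch is not None:
            if len(self.batch) != len(self.samples):
                raise ValidationError("batch labels do not match number of samples")
            self.batch = [str(b) for b in self.batch]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_index(self, gene: str) -> int:
        gene = canonical_symbol(gene)
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present in count matrix") from None

    def to_frame(self) -> pd.DataFrame:
        """Genes x samples DataFrame view of the counts."""
        return pd.DataFrame(self.counts, index=self.genes, columns=self.samples)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, batch: list[str] | None = None) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(), batch=batch)

    def subset_samples(self, samples: list[str]) -> "CountMatrix":
        idx = [self.samples.index(s) for s in samples]
        batch = [self.batch[i] for i in idx] if self.batch is not None else None
        return CountMatrix(list(self.genes), list(samples), self.counts[:, idx], batch=batch)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon: dict[str, frozenset[str]] = {}
        for name, members in self.sets.items():
            members = frozenset(canonical_symbol(m) for m in members)
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            canon[name] = members
        self.sets = canon

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Sum duplicate gene rows (transcript-to-gene collapse), warning once."""
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        logger.warning(
            "collapsing %d duplicated gene symbol(s) by summation: %s%s",
            len(dupes), dupes[:5], "..." if len(dupes) > 5 else "",
        )
        df = df.groupby(level=0, sort=False).sum()
    return df


def read_counts(path: str | os.PathLike, format: str | None = None) -> CountMatrix:
    """Read a gene x sample count matrix from TSV or MatrixMarket.

    TSV dialect: header row of sample IDs with first column named ``gene``;
    integer cells. MTX: coordinate MatrixMarket file accompanied by
    ``<stem>.rownames.txt`` and ``<stem>.colnames.txt`` (one name per line).
    Duplicate gene rows are collapsed by summation with a logged warning.
    """
    path = os.fspath(path)
    if format is None:
        format = "mtx" if path.endswith(".mtx") else "tsv"
    if format == "tsv":
        if os.path.getsize(path) == 0:
            raise FormatError(f"{path}: empty file")
        df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
        if df.shape[1] < 2 or df.columns[0] != "gene":
            raise FormatError(
                f"{path}: malformed header; expected first column 'gene' followed by sample IDs"
            )
        df = df.set_index("gene")
        for col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                row = df.index[vals.isna()][0]
                raise ValidationError(f"{path}: non-numeric count at gene {row!r}, sample {col!r}")
            df[col] = vals
    elif format == "mtx":
        raw = mmread(path)
        mat = np.asarray(raw.todense() if hasattr(raw, "todense") else raw)
        stem = path[:-4] if path.endswith(".mtx") else path
        with open(stem + ".rownames.txt") as fh:
            genes = [line.strip() for line in fh if line.strip()]
        with open(stem + ".colnames.txt") as fh:
            samples = [line.strip() for line in fh if line.strip()]
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown counts format {format!r}")
    df.index = [canonical_symbol(g) for g in df.index]
    df = _collapse_duplicate_genes(df)
    return CountMatrix.from_frame(df)


def write_counts(cm: CountMatrix, path: str | os.PathLike) -> None:
    df = cm.to_frame()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read a Broad-style GMT file: ``name<TAB>description<TAB>member...``."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            members = [m for m in members if m.strip()]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = frozenset(canonical_symbol(m) for m in members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(gsc: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, members in gsc.items():
            desc = gsc.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_ct_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a qPCR Ct table: columns sample_id, assay, well, ct (empty = missing).

    Invariants checked: ct > 0 where present; each (sample, assay) pair has at
    least one non-missing well. Unknown assay symbols are retained with a warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    missing_cols = [c for c in CT_REQUIRED if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing mandatory column(s): {missing_cols}")
    df["assay"] = df["assay"].map(canonical_symbol)
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    if (df["ct"].dropna() <= 0).any():
        raise ValidationError(f"{path}: Ct values must be > 0")
    unknown = sorted(set(df["assay"]) - KNOWN_ASSAYS)
    if unknown:
        logger.warning("%s: unknown assay symbol(s) retained: %s", path, unknown)
    ok = df.groupby(["sample_id", "assay"])["ct"].apply(lambda s: s.notna().any())
    if not ok.all():
        bad = ok[~ok].index[0]
        raise ValidationError(f"{path}: no non-missing well for sample/assay {bad}")
    return df


def read_sample_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sample metadata table; requires sample_id and group columns."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    missing_cols = [c for c in SAMPLE_REQUIRED if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing mandatory column(s): {missing_cols}")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample_id values")
    return df


def write_table(obj, path: str | os.PathLike) -> None:
    """Write a domain object to TSV; ``write_table o read_*`` is the identity."""
    if isinstance(obj, CountMatrix):
        write_counts(obj, path)
    elif isinstance(obj, GeneSetCollection):
        write_gmt(obj, path)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", index=False)
    else:
        raise TypeError(f"cannot serialize object of type {type(obj).__name__}")
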