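"""Readers, writers and the shared domain types of the kinome pipeline.

Every external format the pipeline touches (FASTA proteomes, aligned-FASTA
seed alignments, taxonomy TSVs, count matrices, catalog exports) is parsed
here into plain dataclasses; the analysis modules never read files
themselves.  FASTA parsing is delegated to Biopython.

Sequences are normalized on read: uppercased, terminal ``'*'`` stop symbols
stripped, and the ambiguous amino-acid codes B, Z, U and O mapped to X so
that downstream scoring matrices only ever see the 20 canonical residues
plus X.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino acids, in alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Alphabet used by scoring code: canonical residues plus the wildcard X.
ALPHABET = AMINO_ACIDS + "X"

#: Closed set of kinase classification groups: the nine conventional
#: eukaryotic-protein-kinase (ePK) groups plus the atypical kinases (aPK).
KINASE_GROUPS = (
    "AGC", "CAMK", "CMGC", "CK1", "RGC", "TK", "TKL", "STE", "Other", "aPK",
)

_AMBIGUOUS = str.maketrans({"B": "X", "Z": "X", "U": "X", "O": "X", "J": "X"})


def normalize_sequence(seq: str) -> str:
    """Uppercase, strip terminal stops and map ambiguity codes to X."""
    return seq.upper().rstrip("*").translate(_AMBIGUOUS)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """One entry of a predicted proteome."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record requires a non-empty id")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        if "-" in self.sequence:
            raise ValueError(f"protein {self.id!r} contains gap characters")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReferenceKinase:
    """A labeled catalog entry carrying the group/family/subfamily taxonomy."""

    id: str
    species: str
    group: str
    family: str
    subfamily: str
    domain_sequence: str

    def __post_init__(self) -> None:
        if self.group not in KINASE_GROUPS:
            raise ValueError(
                f"reference {self.id!r}: unknown group {self.group!r}; "
                f"expected one of {KINASE_GROUPS}"
            )
        if not 50 <= len(self.domain_sequence) <= 600:
            raise ValueError(
                f"reference {self.id!r}: domain sequence length "
                f"{len(self.domain_sequence)} outside [50, 600]"
            )


@dataclass(frozen=True)
class AlignmentResult:
    """Score and identity of one local alignment of a query against a subject."""

    query_id: str
    subject_id: str
    score: float            # bit score
    e_value: float
    percent_identity: float  # 100 * identities / aligned columns
    aligned_length: int


#: Allowed values of :attr:`Classification.status`.
CLASSIFICATION_STATUSES = (
    "classified", "species_specific", "ambiguous", "reclassified_by_phylogeny",
)


@dataclass
class Classification:
    """Per-protein group/family/subfamily assignment with its evidence."""

    protein_id: str
    group: str = ""
    family: str = ""
    subfamily: str = ""
    status: str = "species_specific"
    evidence: AlignmentResult | None = None
    annotation_note: str = ""

    def __post_init__(self) -> None:
        if self.status not in CLASSIFICATION_STATUSES:
            raise ValueError(f"unknown classification status {self.status!r}")


@dataclass
class CountMatrix:
    """Gene-level RNA-seq counts with gene lengths and per-sample library sizes.

    ``library_sizes`` are total mapped reads per sample and may exceed the
    corresponding column sum (reads mapping outside the gene set are allowed).
    """

    counts: pd.DataFrame          # genes x samples, non-negative integers
    gene_lengths: pd.Series       # base pairs, indexed like counts rows
    library_sizes: pd.Series      # indexed like counts columns

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if self.gene_lengths.isna().any():
            missing = self.gene_lengths.index[self.gene_lengths.isna()]
            raise ValueError(f"missing gene lengths for {list(missing[:5])}")
        if self.library_sizes.isna().any():
            missing = self.library_sizes.index[self.library_sizes.isna()]
            raise ValueError(f"missing library sizes for {list(missing[:5])}")
        self.gene_lengths = self.gene_lengths.astype(np.int64)
        self.library_sizes = self.library_sizes.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.gene_lengths < 1).any():
            raise ValueError("gene lengths must be >= 1 bp")
        short = self.library_sizes < self.counts.sum(axis=0)
        if short.any():
            bad = list(self.library_sizes.index[short])
            raise ValueError(
                f"library size smaller than column sum for samples {bad}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into normalized :class:`ProteinRecord`s.

    Duplicate ids are a hard error; an empty file yields an empty list with
    a warning.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        records.append(
            ProteinRecord(rec.id, normalize_sequence(str(rec.seq)), desc)
        )
    if not records:
        warnings.warn(f"FASTA file {path} contains no records", stacklevel=2)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as 60-column wrapped FASTA."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_alignment(path: str | Path) -> tuple[list[str], list[str]]:
    """Read an aligned FASTA (``'-'`` gaps) as ``(ids, rows)``.

    Rows are normalized like unaligned sequences but gaps are preserved;
    all rows must share one aligned length.
    """
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise ValueError(f"duplicate alignment id {rec.id!r} in {path}")
        ids.append(rec.id)
        rows.append(str(rec.seq).upper().translate(_AMBIGUOUS))
    if rows and len({len(r) for r in rows}) != 1:
        raise ValueError(f"alignment rows in {path} have unequal lengths")
    return ids, rows


def write_alignment(ids: Sequence[str], rows: Sequence[str],
                    path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, row in zip(ids, rows):
            fh.write(f">{name}\n")
            for i in range(0, len(row), width):
                fh.write(row[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# reference catalog
# ---------------------------------------------------------------------------

def read_reference_catalog(fasta: str | Path,
                           taxonomy_tsv: str | Path) -> list[ReferenceKinase]:
    """Join catalog domain sequences with their taxonomy labels.

    The TSV must carry columns ``id, species, group, family, subfamily``;
    every FASTA id must appear exactly once in the TSV and every group label
    must come from the closed ten-label set.
    """
    tax = pd.read_csv(taxonomy_tsv, sep="\t", dtype=str).fillna("")
    required = {"id", "species", "group", "family", "subfamily"}
    if not required.issubset(tax.columns):
        raise ValueError(
            f"taxonomy TSV {taxonomy_tsv} missing columns "
            f"{sorted(required - set(tax.columns))}"
        )
    if tax["id"].duplicated().any():
        dups = list(tax.loc[tax["id"].duplicated(), "id"])
        raise ValueError(f"duplicate taxonomy ids {dups}")
    by_id = tax.set_index("id")

    records = read_fasta(fasta)
    missing = [r.id for r in records if r.id not in by_id.index]
    if missing:
        raise ValueError(
            f"FASTA ids missing from taxonomy TSV: {missing}"
        )
    catalog: list[ReferenceKinase] = []
    for rec in records:
        row = by_id.loc[rec.id]
        catalog.append(
            ReferenceKinase(
                id=rec.id,
                species=row["species"],
                group=row["group"],
                family=row["family"],
                subfamily=row["subfamily"],
                domain_sequence=rec.sequence,
            )
        )
    return catalog


# ---------------------------------------------------------------------------
# classification catalog TSV
# ---------------------------------------------------------------------------

_CATALOG_COLUMNS = (
    "accession", "group", "family", "subfamily",
    "best_hit_id", "percent_identity", "e_value", "status",
)


def write_catalog_tsv(classifications: Iterable[Classification],
                      path: str | Path) -> None:
    """Write the classification catalog, one row per protein, sorted by accession."""
    rows = []
    for c in sorted(classifications, key=lambda c: c.protein_id):
        ev = c.evidence
        rows.append({
            "accession": c.protein_id,
            "group": c.group,
            "family": c.family,
            "subfamily": c.subfamily,
            "best_hit_id": ev.subject_id if ev else "",
            "percent_identity": repr(ev.percent_identity) if ev else "",
            "e_value": repr(ev.e_value) if ev else "",
            "status": c.status,
        })
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_CATALOG_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in _CATALOG_COLUMNS) + "\n")


def read_catalog_tsv(path: str | Path) -> list[Classification]:
    """Re-read a catalog TSV; float fields round-trip bit-exactly via ``repr``."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: list[Classification] = []
    for _, row in df.iterrows():
        evidence = None
        if row["best_hit_id"]:
            evidence = AlignmentResult(
                query_id=row["accession"],
                subject_id=row["best_hit_id"],
                score=float("nan"),
                e_value=float(row["e_value"]),
                percent_identity=float(row["percent_identity"]),
                aligned_length=1,
            )
        out.append(Classification(
            protein_id=row["accession"],
            group=row["group"],
            family=row["family"],
            subfamily=row["subfamily"],
            status=row["status"],
            evidence=evidence,
        ))
    return out


# ---------------------------------------------------------------------------
# count matrices and sample metadata
# ---------------------------------------------------------------------------

def read_counts_tsv(counts_tsv: str | Path,
                    metadata_tsv: str | Path) -> tuple[CountMatrix, pd.DataFrame]:
    """Read a counts TSV (``gene_id, length_bp``, one column per sample) and a
    sample-metadata TSV (``sample_id, condition, timepoint, tissue,
    library_size``); returns the matrix and the metadata frame."""
    counts = pd.read_csv(counts_tsv, sep="\t")
    if "gene_id" not in counts.columns or "length_bp" not in counts.columns:
        raise ValueError(f"{counts_tsv}: expected 'gene_id' and 'length_bp' columns")
    counts = counts.set_index("gene_id")
    lengths = counts.pop("length_bp")

    meta = pd.read_csv(metadata_tsv, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns or "library_size" not in meta.columns:
        raise ValueError(
            f"{metadata_tsv}: expected 'sample_id' and 'library_size' columns"
        )
    meta = meta.set_index("sample_id")
    matrix = CountMatrix(
        counts=counts,
        gene_lengths=lengths,
        library_sizes=meta["library_size"],
    )
    return matrix, meta


def write_counts_tsv(matrix: CountMatrix, counts_tsv: str | Path,
                     metadata_tsv: str | Path | None = None,
                     metadata: pd.DataFrame | None = None) -> None:
    out = matrix.counts.copy()
    out.insert(0, "length_bp", matrix.gene_lengths)
    out.index.name = "gene_id"
    out.to_csv(counts_tsv, sep="\t")
    if metadata_tsv is not None:
        if metadata is None:
            metadata = pd.DataFrame(index=matrix.library_sizes.index)
        meta = metadata.copy()
        meta["library_size"] = matrix.library_sizes
        meta.index.name = "sample_id"
        meta.to_csv(metadata_tsv, sep="\t")
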