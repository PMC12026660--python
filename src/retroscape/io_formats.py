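"""Readers and writers for the external text formats the pipeline consumes.

Everything entering the package is converted to a single coordinate
convention: 0-based, half-open intervals on named chromosomes.
RepeatMasker ``.out`` tables and GFF3 (both 1-based, inclusive) are
converted at this boundary and nowhere else.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeIndex",
    "TECopy",
    "GeneModel",
    "ContactMatrix",
    "MethylSite",
    "CountMatrix",
    "IntervalSet",
    "read_repeatmasker_out",
    "read_gff3_genes",
    "read_contact_matrix",
    "read_methylation_table",
    "read_fasta",
    "write_fasta",
    "write_bed",
    "read_bed",
]

# LINE/SINE family vocabulary observed in hedgehog-style RepeatMasker output;
# anything else (DNA transposons, LTRs, "Unknown", simple repeats) is `other`.
LINE_CLASSES = {"LINE"}
SINE_CLASSES = {"SINE"}


@dataclass(frozen=True)
class GenomeIndex:
    """Chromosome names and lengths (bp)."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for name, n in self.lengths.items():
            if n <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {n}")

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    @classmethod
    def from_sequences(cls, seqs: dict[str, str]) -> "GenomeIndex":
        return cls({name: len(s) for name, s in seqs.items()})


@dataclass
class TECopy:
    """One annotated transposable-element insertion."""

    copy_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    te_class: str = "other"
    family: str = ""
    consensus_id: str = ""
    divergence_pct: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.copy_id}: invalid interval [{self.start},{self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.copy_id}: strand must be + or -, got {self.strand!r}")
        if self.divergence_pct is not None and not (0.0 <= self.divergence_pct <= 100.0):
            raise ValueError(
                f"{self.copy_id}: divergence_pct {self.divergence_pct} outside [0,100]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GeneModel:
    """One gene with its representative (longest) transcript structure."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    annotation_label: str | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside transcript")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        ]

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tes(self) -> int:
        """Transcript end site (last transcribed base)."""
        return self.tx_end - 1 if self.strand == "+" else self.tx_start


@dataclass
class ContactMatrix:
    """Symmetric binned chromatin-interaction matrix for one chromosome."""

    chrom: str
    resolution: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("contact matrix must be symmetric within 1e-9")
        if (self.values < 0).any():
            raise ValueError("contact matrix must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def bin_of(self, pos: int) -> int:
        return pos // self.resolution


@dataclass(frozen=True)
class MethylSite:
    """One CpG site with read coverage and methylated-read fraction."""

    chrom: str
    pos: int
    coverage: int
    methyl_fraction: float

    def __post_init__(self) -> None:
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if not (0.0 <= self.methyl_fraction <= 1.0):
            raise ValueError(f"methyl_fraction {self.methyl_fraction} outside [0,1]")


@dataclass
class CountMatrix:
    """Features x samples read counts with per-sample metadata.

    ``sample_meta`` is a DataFrame indexed like ``sample_ids`` with columns
    ``tissue`` (dorsal/abdominal), ``stage`` (I/II/III) and ``replicate``.
    """

    feature_ids: list[str]
    feature_lengths: np.ndarray
    sample_ids: list[str]
    counts: np.ndarray
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.feature_lengths = np.asarray(self.feature_lengths, dtype=float)
        nf, ns = self.counts.shape
        if nf != len(self.feature_ids) or ns != len(self.sample_ids):
            raise ValueError("counts shape inconsistent with feature/sample ids")
        if len(self.feature_lengths) != nf:
            raise ValueError("feature_lengths inconsistent with feature_ids")
        if (self.feature_lengths <= 0).any():
            raise ValueError("feature lengths must be positive")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if list(self.sample_meta.index) != list(self.sample_ids):
            raise ValueError("sample_meta index must match sample_ids")


@dataclass
class IntervalSet:
    """Plain genomic intervals, optionally paired loop anchors."""

    intervals: list[tuple[str, int, int]]
    anchor_pairs: list[tuple[tuple[str, int, int], tuple[str, int, int]]] | None = None

    def __post_init__(self) -> None:
        for chrom, s, e in self.intervals:
            if not (0 <= s < e):
                raise ValueError(f"invalid interval {chrom}:{s}-{e}")


# ---------------------------------------------------------------------------
# RepeatMasker
# ---------------------------------------------------------------------------

def _split_class_family(token: str) -> tuple[str, str]:
    if "/" in token:
        cls, fam = token.split("/", 1)
    else:
        cls, fam = token, token
    if cls in LINE_CLASSES:
        return "LINE", fam
    if cls in SINE_CLASSES:
        return "SINE", fam
    return "other", fam


def read_repeatmasker_out(path: str | Path) -> list[TECopy]:
    """Parse a standard 15-column RepeatMasker ``.out`` annotation table.

    The three banner lines are skipped; 1-based inclusive query coordinates
    become 0-based half-open; strand ``C`` (complement) maps to ``-``; the
    "class/family" token is split into te_class and family; the per-copy
    percent-divergence column is kept as ``divergence_pct``.
    """
    tes: list[TECopy] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 3 or not line.strip():
                continue
            fields = line.split()
            if len(fields) not in (15, 16):  # optional trailing '*' column
                raise ValueError(
                    f"{path}: line {lineno}: expected 15 columns, got {len(fields)}"
                )
            try:
                div = float(fields[1])
                chrom = fields[4]
                begin = int(fields[5])
                end = int(fields[6])
                strand = "-" if fields[8] in {"C", "-"} else "+"
                name = fields[9]
                te_class, family = _split_class_family(fields[10])
                rm_id = fields[14]
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            tes.append(
                TECopy(
                    copy_id=f"{te_class}_{rm_id}_{lineno}",
                    chrom=chrom,
                    start=begin - 1,
                    end=end,
                    strand=strand,
                    te_class=te_class,
                    family=family,
                    consensus_id=name,
                    divergence_pct=div,
                )
            )
    return tes


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Load gene models from GFF3; the longest transcript represents a gene.

    Exons/CDS without a resolvable parent raise a warning and are skipped.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    claimed_parents: set[str] = set()
    for gene in db.features_of_type("gene"):
        transcripts = list(db.children(gene, featuretype=("mRNA", "transcript")))
        if transcripts:
            tx = max(transcripts, key=lambda t: t.end - t.start)
            exon_parent = tx
        else:
            exon_parent = gene
        claimed_parents.add(exon_parent.id)
        exons = [
            (e.start - 1, e.end) for e in db.children(exon_parent, featuretype="exon")
        ]
        cds = [(c.start - 1, c.end) for c in db.children(exon_parent, featuretype="CDS")]
        tx_start, tx_end = gene.start - 1, gene.end
        if not exons:
            exons = [(tx_start, tx_end)]
        label = gene.attributes.get("annotation", [None])[0]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                tx_start=tx_start,
                tx_end=tx_end,
                exons=sorted(set(exons)),
                cds=sorted(set(cds)),
                annotation_label=label,
            )
        )
    for exon in db.features_of_type("exon"):
        parents = list(db.parents(exon))
        if not parents:
            warnings.warn(f"orphan exon {exon.id} skipped", stacklevel=2)
    return genes


# ---------------------------------------------------------------------------
# Contact matrices
# ---------------------------------------------------------------------------

def read_contact_matrix(
    path: str | Path,
    resolution: int,
    dialect: str = "dense",
    chrom: str = "chr1",
    chrom_length: int | None = None,
    atol: float = 1e-6,
) -> ContactMatrix:
    """Read a binned contact matrix from dense-TSV or (i, j, value) triplets.

    Triplet input is mirrored across the diagonal. When ``chrom_length`` is
    given, the bin count must satisfy ``n_bins == ceil(chrom_length /
    resolution)`` and any out-of-range bin index is an error.
    """
    n_required = (
        math.ceil(chrom_length / resolution) if chrom_length is not None else None
    )
    if dialect == "dense":
        values = np.loadtxt(path, ndmin=2)
        if not np.allclose(values, values.T, atol=atol):
            raise ValueError("dense contact matrix is asymmetric beyond tolerance")
        values = (values + values.T) / 2.0
    elif dialect == "triplet":
        df = pd.read_csv(
            path, sep=r"\s+", header=None, names=["i", "j", "value"], comment="#"
        )
        max_idx = int(max(df["i"].max(), df["j"].max()))
        n = n_required if n_required is not None else max_idx + 1
        if max_idx >= n:
            raise ValueError(
                f"bin index {max_idx} out of range: n_bins={n} required for "
                f"chrom_length={chrom_length}, resolution={resolution}"
            )
        values = np.zeros((n, n))
        for i, j, v in df.itertuples(index=False):
            values[int(i), int(j)] = v
            values[int(j), int(i)] = v
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if n_required is not None and values.shape[0] != n_required:
        raise ValueError(
            f"matrix has {values.shape[0]} bins, expected {n_required} "
            f"(= ceil({chrom_length}/{resolution}))"
        )
    return ContactMatrix(chrom=chrom, resolution=resolution, values=values)


def write_contact_matrix(m: ContactMatrix, path: str | Path, dialect: str = "dense") -> None:
    if dialect == "dense":
        np.savetxt(path, m.values, fmt="%.8g", delimiter="\t")
    elif dialect == "triplet":
        with open(path, "w") as fh:
            for i in range(m.n_bins):
                for j in range(i, m.n_bins):
                    if m.values[i, j] != 0:
                        fh.write(f"{i}\t{j}\t{m.values[i, j]:.8g}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Methylation, FASTA, BED
# ---------------------------------------------------------------------------

def read_methylation_table(path: str | Path) -> list[MethylSite]:
    """TSV of (chrom, pos, coverage, methylated fraction), 0-based positions."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "pos", "coverage", "fraction"],
        comment="#",
    )
    if ((df["fraction"] < 0) | (df["fraction"] > 1)).any():
        bad = df.loc[(df["fraction"] < 0) | (df["fraction"] > 1)].iloc[0]
        raise ValueError(f"methylation fraction {bad['fraction']} outside [0,1]")
    return [
        MethylSite(str(r.chrom), int(r.pos), int(r.coverage), float(r.fraction))
        for r in df.itertuples(index=False)
    ]


def write_methylation_table(sites: Sequence[MethylSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.coverage}\t{s.methyl_fraction:.6g}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_bed(intervals: Iterable, path: str | Path) -> None:
    """Write TECopy objects or (chrom, start, end[, name[, strand]]) tuples as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            if isinstance(iv, TECopy):
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.copy_id}\t.\t{iv.strand}\n"
                )
            else:
                chrom, start, end, *rest = iv
                name = rest[0] if rest else "."
                strand = rest[1] if len(rest) > 1 else "."
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\t.\t{strand}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            name = f[3] if len(f) > 3 else "."
            strand = f[5] if len(f) > 5 else "."
            out.append((f[0], int(f[1]), int(f[2]), name, strand))
    return out
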