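"""Genome/annotation/16S-tail input handling and strand-resolved gene extraction.

Coordinate conventions used throughout the package:

* Genomic coordinates are 1-based inclusive (GFF3 convention) on the forward
  strand of the annotated contig.
* Gene-relative positions: upstream bases are numbered -1 (adjacent to the
  start codon) down to -100; downstream positions start at +1 = first base of
  the start codon (+2, +3 complete it, +4 is the first base of codon 2).
  There is no position 0.
* All extracted sequences are RNA (``ACGU`` plus IUPAC ambiguity codes, which
  are tolerated on read and handled downstream).
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import (
    AlphabetError,
    CoordinateError,
    EmptyTailError,
    InputError,
    UnknownContigError,
)

#: Start codons accepted for protein-coding genes (RNA alphabet).
ALLOWED_START_CODONS = frozenset({"AUG", "GUG", "UUG", "AUA", "AUU", "AUC"})

#: Stop codons terminating a valid CDS.
STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})

#: Maximum length of the extracted upstream window.
UPSTREAM_LENGTH = 100

_RNA_AMBIGUITY = set("ACGURYSWKMBDHVN")


Annotation = tuple[str, str, int, int, str]


@dataclass(frozen=True)
class SpeciesInput:
    """A species' genome, CDS annotations and 16S rRNA 3' tail.

    ``annotations`` rows are ``(contig, strand, cds_start, cds_end, gene_id)``
    with 1-based inclusive coordinates; ``anti_sd_tail`` is the 13-nt (by
    default) 3' tail of the species' 16S rRNA written 5'->3' in RNA.
    """

    species_id: str
    genome: dict[str, str]
    annotations: list[Annotation]
    anti_sd_tail: str

    def __post_init__(self) -> None:
        if len(self.anti_sd_tail) < 3:
            raise EmptyTailError(
                f"{self.species_id}: anti-SD tail must be >= 3 nt, "
                f"got {len(self.anti_sd_tail)}"
            )
        bad = set(self.anti_sd_tail) - set("ACGU")
        if bad:
            raise AlphabetError(f"anti-SD tail has non-RNA characters: {sorted(bad)}")
        for contig, strand, start, end, gene_id in self.annotations:
            if contig not in self.genome:
                raise UnknownContigError(
                    f"gene {gene_id!r} annotated on unknown contig {contig!r}"
                )
            if strand not in "+-":
                raise CoordinateError(f"gene {gene_id!r}: strand must be + or -")
            if not (1 <= start <= end <= len(self.genome[contig])):
                raise CoordinateError(
                    f"gene {gene_id!r}: invalid CDS coordinates {start}..{end} "
                    f"on contig of length {len(self.genome[contig])}"
                )


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene, strand-resolved, in RNA.

    ``upstream`` holds up to 100 nt immediately 5' of the start codon
    (gene positions -len..-1); ``cds`` runs from the first base of the start
    codon through the stop codon.
    """

    gene_id: str
    upstream: str
    cds: str

    @property
    def start_codon(self) -> str:
        return self.cds[:3]

    @property
    def has_ambiguity(self) -> bool:
        return bool(set(self.upstream + self.cds) - set("ACGU"))

    def base_at(self, position: int) -> str | None:
        """Base at a gene-relative position, or None if not covered."""
        if position == 0:
            raise ValueError("position 0 does not exist; use -1 or +1")
        if position < 0:
            if -position > len(self.upstream):
                return None
            return self.upstream[len(self.upstream) + position]
        if position > len(self.cds):
            return None
        return self.cds[position - 1]

    def upstream_slice(self, start: int, stop: int) -> str:
        """Upstream bases covering positions ``start..stop`` (both < 0).

        Truncated at the 5' end if the stored upstream window is shorter;
        never padded.
        """
        if not (start <= stop < 0):
            raise ValueError("need start <= stop < 0")
        n = len(self.upstream)
        lo = max(0, n + start)
        hi = n + stop + 1
        if hi <= 0:
            return ""
        return self.upstream[lo:hi]


@dataclass
class ExtractionResult:
    """Gene records plus a tally of annotations dropped and why."""

    records: list[GeneRecord]
    dropped: collections.Counter = field(default_factory=collections.Counter)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _revcomp_dna(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA into a contig-name -> uppercase-DNA dict."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise InputError(f"no FASTA records found in {path}")
    return genome


def read_tail(path: str | Path) -> str:
    """Read the 16S rRNA 3' tail from FASTA or a bare-sequence text file."""
    text = Path(path).read_text().strip()
    if not text:
        raise EmptyTailError(f"tail file {path} is empty")
    if text.startswith(">"):
        recs = list(SeqIO.parse(str(path), "fasta"))
        if not recs:
            raise EmptyTailError(f"tail file {path} has no sequence")
        seq = str(recs[0].seq)
    else:
        seq = "".join(text.split())
    return _to_rna(seq)


def read_annotations(path: str | Path) -> list[Annotation]:
    """Read CDS annotations from GFF3 or the 5-column TSV dialect.

    The TSV dialect is tab-separated ``contig, strand, start, end, gene_id``
    with ``#`` comment lines; coordinates are 1-based inclusive in both
    dialects.
    """
    path = Path(path)
    head = ""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                head = line
                break
    if head.startswith("##gff-version") or len(head.split("\t")) == 9:
        return _read_gff3(path)
    return _read_tsv(path)


def _read_tsv(path: Path) -> list[Annotation]:
    rows: list[Annotation] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise InputError(f"{path}:{ln}: expected 5 tab-separated columns")
            contig, strand, start, end, gene_id = parts
            try:
                rows.append((contig, strand, int(start), int(end), gene_id))
            except ValueError as exc:
                raise CoordinateError(f"{path}:{ln}: non-integer coordinate") from exc
    return rows


def _read_gff3(path: Path) -> list[Annotation]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise InputError(f"could not parse GFF3 file {path}: {exc}") from exc
    rows: list[Annotation] = []
    auto = 0
    for feat in db.features_of_type("CDS"):
        gene_id = (
            feat.attributes.get("ID", [None])[0]
            or feat.attributes.get("locus_tag", [None])[0]
            or feat.attributes.get("Parent", [None])[0]
        )
        if gene_id is None:
            auto += 1
            gene_id = f"cds_{auto:05d}"
        rows.append((feat.seqid, feat.strand, feat.start, feat.end, gene_id))
    return rows


def load_species(
    genome_path: str | Path,
    annotation_path: str | Path,
    tail_path: str | Path,
    species_id: str | None = None,
) -> SpeciesInput:
    """Load and validate one species' genome, annotation and 16S tail files."""
    genome = read_fasta(genome_path)
    annotations = read_annotations(annotation_path)
    tail = read_tail(tail_path)
    if species_id is None:
        species_id = Path(genome_path).stem
    return SpeciesInput(
        species_id=species_id,
        genome=genome,
        annotations=annotations,
        anti_sd_tail=tail,
    )


def extract_gene_records(
    sp: SpeciesInput,
    upstream_length: int = UPSTREAM_LENGTH,
) -> ExtractionResult:
    """Extract strand-resolved GeneRecords from a validated SpeciesInput.

    For + strand genes the upstream window is the genomic slice
    ``cds_start-upstream_length .. cds_start-1``; for - strand genes it is the
    reverse complement of ``cds_end+1 .. cds_end+upstream_length``. Windows
    are truncated (never padded) at contig edges. Genes failing the
    start-codon whitelist, the stop-codon rule or the length-multiple-of-3
    rule are dropped and tallied.
    """
    records: list[GeneRecord] = []
    dropped: collections.Counter = collections.Counter()
    for contig, strand, start, end, gene_id in sp.annotations:
        seq = sp.genome[contig]
        if strand == "+":
            cds_dna = seq[start - 1 : end]
            up_dna = seq[max(0, start - 1 - upstream_length) : start - 1]
        else:
            cds_dna = _revcomp_dna(seq[start - 1 : end])
            up_dna = _revcomp_dna(seq[end : end + upstream_length])
        cds = _to_rna(cds_dna)
        upstream = _to_rna(up_dna)
        bad = (set(cds) | set(upstream)) - _RNA_AMBIGUITY
        if bad:
            dropped["invalid_characters"] += 1
            continue
        if len(cds) < 6 or len(cds) % 3 != 0:
            dropped["length_not_multiple_of_3"] += 1
            continue
        if cds[:3] not in ALLOWED_START_CODONS:
            dropped["disallowed_start_codon"] += 1
            continue
        if cds[-3:] not in STOP_CODONS:
            dropped["no_stop_codon"] += 1
            continue
        records.append(GeneRecord(gene_id=gene_id, upstream=upstream, cds=cds))
    return ExtractionResult(records=records, dropped=dropped)


def records_to_table(records: Iterable[GeneRecord]):
    """GeneRecords as a pandas DataFrame (gene_id, start_codon, upstream, cds)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "start_codon": r.start_codon,
                "upstream": r.upstream,
                "cds": r.cds,
            }
            for r in records
        ]
    )


def records_from_table(df) -> list[GeneRecord]:
    """Inverse of :func:`records_to_table`."""
    return [
        GeneRecord(gene_id=row.gene_id, upstream=row.upstream, cds=row.cds)
        for row in df.itertuples()
    ]
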