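"""Sequence and gene-model I/O shared by the whole toolkit.

Protein sequences come in as FASTA, gene models as GFF3, and everything
downstream works on the small record types defined here.  Coordinates are
1-based inclusive on disk (FASTA residue numbering, GFF3) and 0-based
half-open in memory; report layers convert back to 1-based for printing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

log = logging.getLogger(__name__)

#: the 20 canonical amino acids; anything else is rejected at load time
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: ambiguity / non-standard letters that trigger record-level rejection
NON_CANONICAL = frozenset("BJOUXZ")


class SeqIOError(ValueError):
    """Malformed input that cannot be attributed to a single record."""


@dataclass(frozen=True)
class ProteinRecord:
    """One candidate MIP protein sequence.

    ``sequence`` is upper-case, canonical residues only; a terminal stop
    ('*') is stripped at load.  ``id`` must be unique within a run.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - CANONICAL_AA
        if bad:
            raise ValueError(f"{self.id}: non-canonical residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A transcript's exon structure, 0-based half-open internally."""

    gene_id: str
    transcript_id: str
    exons: tuple[tuple[int, int], ...]
    strand: str
    utr5_present: bool = False
    utr3_present: bool = False

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has zero exons")
        exons = tuple(sorted(self.exons))
        prev_end = None
        for start, end in exons:
            if end <= start:
                raise ValueError(
                    f"transcript {self.transcript_id}: empty exon ({start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
            prev_end = end
        object.__setattr__(self, "exons", exons)

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Sequences are upper-cased and a single trailing '*' is stripped.
    Records containing non-canonical residues (B, J, O, U, X, Z ... or any
    letter outside the 20 canonical amino acids) are rejected individually
    with a logged reason; the rest of the file still loads.

    Raises
    ------
    SeqIOError
        If the file is empty, contains no FASTA records, or holds duplicate
        record ids.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    n_parsed = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_parsed += 1
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if rec.id in seen:
            raise SeqIOError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        bad = set(seq) - CANONICAL_AA
        if bad or not seq:
            reason = "empty sequence" if not seq else f"non-canonical residues {sorted(bad)}"
            log.warning("rejecting record %s: %s", rec.id, reason)
            continue
        records.append(ProteinRecord(rec.id, seq, rec.description))
    if n_parsed == 0:
        raise SeqIOError(f"{path}: empty or non-FASTA file")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA; round-trips byte-identically modulo wrapping."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/UTR features from a GFF3 file.

    GFF3 coordinates are 1-based inclusive; exons are converted to 0-based
    half-open intervals.  Each mRNA feature yields one :class:`GeneModel`;
    the gene id is taken from the mRNA's Parent attribute (falling back to
    the mRNA id itself for orphan transcripts).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        exons = tuple(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        if not exons:
            raise SeqIOError(f"transcript {mrna.id} has zero exons")
        utr5 = any(True for _ in db.children(mrna, featuretype="five_prime_UTR"))
        utr3 = any(True for _ in db.children(mrna, featuretype="three_prime_UTR"))
        parents = mrna.attributes.get("Parent", [mrna.id])
        models.append(
            GeneModel(
                gene_id=parents[0],
                transcript_id=mrna.id,
                exons=exons,
                strand=mrna.strand,
                utr5_present=utr5,
                utr3_present=utr3,
            )
        )
    return models


def count_introns(models: Sequence[GeneModel]) -> pd.DataFrame:
    """Tabulate intron counts and UTR presence per transcript.

    intron_count = exon_count - 1; order of exons in the source file is
    irrelevant because :class:`GeneModel` sorts them.
    """
    rows = [
        {
            "transcript_id": m.transcript_id,
            "gene_id": m.gene_id,
            "intron_count": m.intron_count,
            "has_utr5": m.utr5_present,
            "has_utr3": m.utr3_present,
        }
        for m in models
    ]
    return pd.DataFrame(rows, columns=["transcript_id", "gene_id", "intron_count", "has_utr5", "has_utr3"])


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

def make_aligner(free_end_gaps: bool = False, open_gap: float = 10.0, extend_gap: float = 1.0) -> Align.PairwiseAligner:
    """Global protein aligner: BLOSUM62, affine gaps (default open 10, extend 1).

    With ``free_end_gaps`` terminal gaps are not penalised (used for
    projecting marked alignment columns onto possibly truncated queries).
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    if free_end_gaps:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    return aligner


def pairwise_similarity(a: ProteinRecord, b: ProteinRecord, aligner: Align.PairwiseAligner | None = None) -> float:
    """Percent identity between two proteins after global alignment.

    Identity is counted over aligned columns (pairwise alignments contain
    no dual-gap columns); single-sided gap columns enter the denominator.
    Symmetric in its arguments.
    """
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(a.sequence, b.sequence)[0]
    counts = aln.counts()
    ncols = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / ncols


__all__ = [
    "CANONICAL_AA",
    "GeneModel",
    "ProteinRecord",
    "SeqIOError",
    "count_introns",
    "make_aligner",
    "pairwise_similarity",
    "read_fasta",
    "read_gff3",
    "write_fasta",
]
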