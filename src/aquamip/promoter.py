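"""IUPAC-consensus scanning of promoter sequences for cis-regulatory elements.

Promoters (conventionally the 2 kb upstream of the start codon) are
scanned on both strands against a table of named IUPAC consensus motifs
(ABRE, ARE, G-box, MBS, ...).  Every position is tested, all overlapping
matches are reported, and 'N' in the promoter matches nothing.  The
packaged default motif table is a curated approximation of the commonly
cited PlantCARE stress/hormone/light elements; users can substitute
their own TSV (name, consensus, category).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_DNA_ALPHABET = frozenset("ACGTN")


def reverse_complement(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CisMotif:
    name: str
    consensus: str
    category: str

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"motif {self.name}: empty consensus")
        bad = set(self.consensus) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"motif {self.name}: non-IUPAC letters {sorted(bad)}")


@dataclass(frozen=True)
class CisHit:
    gene_id: str
    motif: str
    strand: str
    start: int  # 0-based offset in the promoter


def load_motif_table(path: str | Path | None = None) -> list[CisMotif]:
    """Load a motif TSV (name, consensus, category); default: packaged table."""
    if path is None:
        path = resources.files("aquamip") / "data" / "cis_motifs.tsv"
    motifs = []
    seen = set()
    with open(str(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            name, consensus, category = line.split("\t")[:3]
            if name in seen:
                raise ValueError(f"duplicate motif name {name}")
            seen.add(name)
            motifs.append(CisMotif(name, consensus.upper(), category))
    return motifs


def _matches(window: str, consensus: str) -> bool:
    # 'N' in the promoter matches nothing: promoter base must be in the set
    return all(b in IUPAC_SETS[c] for b, c in zip(window, consensus))


def scan_promoter(
    seq: str, motifs: Sequence[CisMotif], gene_id: str = ""
) -> list[CisHit]:
    """All motif matches on both strands, overlapping hits included.

    A minus-strand hit at ``start`` means the reverse complement of
    ``seq[start:start+len]`` matches the consensus.  Raises on characters
    outside A/C/G/T/N (gene-level rejection is the caller's policy).
    """
    seq = seq.upper()
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise ValueError(f"{gene_id or 'promoter'}: invalid DNA characters {sorted(bad)}")
    hits: list[CisHit] = []
    n = len(seq)
    for motif in motifs:
        cons = motif.consensus
        rc = reverse_complement(cons)
        L = len(cons)
        palindromic = rc == cons
        for i in range(n - L + 1):
            win = seq[i : i + L]
            if _matches(win, cons):
                hits.append(CisHit(gene_id, motif.name, "+", i))
            if not palindromic and _matches(win, rc):
                hits.append(CisHit(gene_id, motif.name, "-", i))
    hits.sort(key=lambda h: (h.start, h.motif, h.strand))
    return hits


def summarize_counts(
    hits: Iterable[CisHit],
    genes: Sequence[str],
    motifs: Sequence[CisMotif],
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene x motif hit-count matrix plus per-category totals.

    Genes with zero hits are retained as zero rows.  Category totals sum
    the matrix over each category's member motifs.
    """
    names = [m.name for m in motifs]
    counts = pd.DataFrame(0, index=list(genes), columns=names, dtype=int)
    for h in hits:
        if h.gene_id in counts.index and h.motif in counts.columns:
            counts.loc[h.gene_id, h.motif] += 1
    cat_of = {m.name: m.category for m in motifs}
    totals = (
        counts.sum(axis=0)
        .groupby(cat_of)
        .sum()
        .astype(int)
    )
    totals.name = "total_hits"
    return counts, totals


def hits_to_bed(hits: Iterable[CisHit], motifs: Sequence[CisMotif]) -> pd.DataFrame:
    """BED-like table (0-based half-open) of hits for TSV export."""
    length = {m.name: len(m.consensus) for m in motifs}
    rows = [
        {
            "gene_id": h.gene_id,
            "start": h.start,
            "end": h.start + length[h.motif],
            "motif": h.motif,
            "strand": h.strand,
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=["gene_id", "start", "end", "motif", "strand"])


__all__ = [
    "CisHit",
    "CisMotif",
    "IUPAC_SETS",
    "hits_to_bed",
    "load_motif_table",
    "reverse_complement",
    "scan_promoter",
    "summarize_counts",
]
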