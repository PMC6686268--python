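"""Alignment-anchored extraction of ar/R selectivity-filter and Froger residues.

The four ar/R constriction residues (helix 2, helix 5, loop E positions 1
and 2) and the five Froger positions (P1-P5) are defined as columns of a
curated reference alignment, not as fixed offsets, because truncated
isoforms break offset arithmetic.  A query is pairwise-aligned to the
best-scoring panel member (global, BLOSUM62, affine 10/1, free end gaps)
and the marked columns are projected through that alignment; regions the
query lacks project onto gaps and are reported as "/".

The packaged panel is a synthetic, clearly-labelled reference set built
by ``scripts/build_panel.py`` from the generator's subfamily templates;
any aligned FASTA + marked-column TSV with the same shape can substitute.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from Bio import Align

from .seqio import ProteinRecord, make_aligner

ARR_LABELS = ("H2", "H5", "LE1", "LE2")
FROGER_LABELS = ("P1", "P2", "P3", "P4", "P5")
SUBFAMILIES = ("PIP", "TIP", "NIP", "SIP", "XIP")

#: minimum raw alignment score for a projection to be trusted
DEFAULT_MIN_SCORE = 50.0


@dataclass(frozen=True)
class PanelMember:
    id: str
    aligned_seq: str
    subfamily: str
    subgroup: str

    @property
    def sequence(self) -> str:
        return self.aligned_seq.replace("-", "")

    def column_to_residue(self, col: int) -> int | None:
        """Ungapped residue index at alignment column ``col`` (None if gap)."""
        if self.aligned_seq[col] == "-":
            return None
        return col - self.aligned_seq.count("-", 0, col)


@dataclass(frozen=True)
class ArRFilter:
    """Four ar/R residues ("/" where absent) + 1-based query positions."""

    residues: str
    positions: tuple[int | None, ...]
    reason: str = ""


@dataclass(frozen=True)
class FrogerPositions:
    """Five Froger residues ("/" where absent) + 1-based query positions."""

    residues: str
    positions: tuple[int | None, ...]
    reason: str = ""


class ReferencePanel:
    """Aligned, subfamily-labelled reference MIPs with marked columns."""

    def __init__(self, members: list[PanelMember], columns: dict[str, int]):
        self.members = list(members)
        self.columns = dict(columns)
        self.validate()

    def validate(self) -> None:
        lengths = {len(m.aligned_seq) for m in self.members}
        if len(lengths) != 1:
            raise ValueError("panel members must share one alignment length")
        (length,) = lengths
        for label, col in self.columns.items():
            if not 0 <= col < length:
                raise ValueError(f"marked column {label}={col} outside alignment")
            if all(m.aligned_seq[col] == "-" for m in self.members):
                raise ValueError(f"marked column {label}={col} is all-gap")
        missing = set(SUBFAMILIES) - {m.subfamily for m in self.members}
        if missing:
            raise ValueError(f"panel lacks subfamilies: {sorted(missing)}")

    @classmethod
    def from_files(cls, afa_path: str | Path, columns_path: str | Path) -> "ReferencePanel":
        """Load from aligned FASTA (headers carry ``subfamily=`` and
        ``subgroup=`` tags) plus a TSV of (label, 0-based column)."""
        members = []
        with open(afa_path) as fh:
            pid, desc, chunks = None, "", []
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    if pid is not None:
                        members.append(_make_member(pid, desc, "".join(chunks)))
                    head = line[1:].split(None, 1)
                    pid = head[0]
                    desc = head[1] if len(head) > 1 else ""
                    chunks = []
                else:
                    chunks.append(line)
            if pid is not None:
                members.append(_make_member(pid, desc, "".join(chunks)))
        columns: dict[str, int] = {}
        with open(columns_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("label\t"):
                    continue
                label, col = line.split("\t")[:2]
                columns[label] = int(col)
        return cls(members, columns)

    @classmethod
    def default(cls) -> "ReferencePanel":
        """The packaged synthetic panel."""
        data = resources.files("aquamip") / "data"
        return cls.from_files(
            str(data / "panel_synthetic.afa"),
            str(data / "panel_synthetic_columns.tsv"),
        )

    def get(self, member_id: str) -> PanelMember:
        for m in self.members:
            if m.id == member_id:
                return m
        raise KeyError(member_id)


def _make_member(pid: str, desc: str, seq: str) -> PanelMember:
    tags = dict(
        item.split("=", 1) for item in desc.split() if "=" in item
    )
    return PanelMember(pid, seq.upper(), tags.get("subfamily", "?"), tags.get("subgroup", "?"))


def rank_members(
    query: ProteinRecord, panel: ReferencePanel, aligner: Align.PairwiseAligner | None = None
) -> list[tuple[PanelMember, float]]:
    """Panel members sorted by pairwise alignment score to the query."""
    if aligner is None:
        aligner = make_aligner(free_end_gaps=True)
    scored = [(m, float(aligner.score(m.sequence, query.sequence))) for m in panel.members]
    scored.sort(key=lambda t: (-t[1], t[0].id))
    return scored


def _member_to_query_map(member: PanelMember, query: ProteinRecord, aligner: Align.PairwiseAligner) -> dict[int, int]:
    aln = aligner.align(member.sequence, query.sequence)[0]
    mapping: dict[int, int] = {}
    tblocks, qblocks = aln.aligned
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        for k in range(int(te) - int(ts)):
            mapping[int(ts) + k] = int(qs) + k
    return mapping


def project_columns(
    query: ProteinRecord,
    panel: ReferencePanel,
    labels: tuple[str, ...],
    aligner: Align.PairwiseAligner | None = None,
    min_score: float = DEFAULT_MIN_SCORE,
) -> tuple[str, tuple[int | None, ...], str]:
    """Project marked alignment columns onto the query.

    Returns (residues, 1-based positions, reason).  Columns where the
    best-scoring member is gapped fall back to the next best member that
    is not; columns that project onto a query gap yield "/" and None.
    """
    if aligner is None:
        aligner = make_aligner(free_end_gaps=True)
    ranked = rank_members(query, panel, aligner)
    if not ranked or ranked[0][1] < min_score:
        return "/" * len(labels), (None,) * len(labels), "no panel member aligns above threshold"
    maps: dict[str, dict[int, int]] = {}
    residues = []
    positions: list[int | None] = []
    for label in labels:
        col = panel.columns[label]
        res, pos = "/", None
        for member, _score in ranked:
            ridx = member.column_to_residue(col)
            if ridx is None:
                continue
            if member.id not in maps:
                maps[member.id] = _member_to_query_map(member, query, aligner)
            qidx = maps[member.id].get(ridx)
            if qidx is not None:
                res, pos = query.sequence[qidx], qidx + 1
            break  # only the best non-gapped member decides
        residues.append(res)
        positions.append(pos)
    return "".join(residues), tuple(positions), ""


def locate_arR(
    query: ProteinRecord,
    panel: ReferencePanel,
    aligner: Align.PairwiseAligner | None = None,
    min_score: float = DEFAULT_MIN_SCORE,
) -> ArRFilter:
    """The query's four ar/R selectivity-filter residues (H2, H5, LE1, LE2)."""
    residues, positions, reason = project_columns(query, panel, ARR_LABELS, aligner, min_score)
    return ArRFilter(residues, positions, reason)


def locate_froger(
    query: ProteinRecord,
    panel: ReferencePanel,
    aligner: Align.PairwiseAligner | None = None,
    min_score: float = DEFAULT_MIN_SCORE,
) -> FrogerPositions:
    """The query's five Froger discriminant residues (P1-P5)."""
    residues, positions, reason = project_columns(query, panel, FROGER_LABELS, aligner, min_score)
    return FrogerPositions(residues, positions, reason)


def thread_query(
    query: ProteinRecord,
    panel: ReferencePanel,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[str, str, float]:
    """Thread the query into panel alignment coordinates.

    The query is aligned to the best-scoring member; each alignment column
    receives the query residue aligned to that member's residue there (or
    a gap).  Query insertions relative to the member are dropped, as in
    profile threading.  Returns (aligned_query_row, best_member_id, score).
    """
    if aligner is None:
        aligner = make_aligner(free_end_gaps=True)
    ranked = rank_members(query, panel, aligner)
    best, score = ranked[0]
    mapping = _member_to_query_map(best, query, aligner)
    row = []
    ridx = 0
    for ch in best.aligned_seq:
        if ch == "-":
            row.append("-")
        else:
            qidx = mapping.get(ridx)
            row.append(query.sequence[qidx] if qidx is not None else "-")
            ridx += 1
    return "".join(row), best.id, score


__all__ = [
    "ARR_LABELS",
    "ArRFilter",
    "DEFAULT_MIN_SCORE",
    "FROGER_LABELS",
    "FrogerPositions",
    "PanelMember",
    "ReferencePanel",
    "locate_arR",
    "locate_froger",
    "project_columns",
    "rank_members",
    "thread_query",
]
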