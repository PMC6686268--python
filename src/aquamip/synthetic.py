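"""Seeded generators for every input class the toolkit consumes.

The protein generator emulates the canonical MIP architecture: six
transmembrane helices (TM1-TM6) joined by five loops, with the two
NPA-like boxes in loops B and E, the four ar/R selectivity-filter
residues (H2, H5, LE1, LE2) and the five Froger positions (P1-P5)
planted at known coordinates.  TM stretches draw from a strongly
hydrophobic pool, loops from a polar pool, so hydropathy-based TM
segmentation sees the planted signal.  Every generated object carries a
ground-truth record sufficient to score the downstream operation that
consumes it.

All sequences here are synthetic: subfamily "templates" are invented
consensus backbones carrying the subfamily-typical marker residues, not
database sequences.  The shipped reference panel is rendered from these
same templates (see ``scripts/build_panel.py``).

Determinism: one user seed fans out to per-object child seeds by CRC32
hashing of object tags, so adding an object never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .seqio import ProteinRecord

# residue pools (Kyte-Doolittle strongly hydrophobic vs polar/charged)
HYDROPHOBIC_POOL = "ILVF"
POLAR_POOL = "DEKRNQHSTGP"

TM_LEN = 23
LOOP_A = 12
PRE_B = 6
LOOP_C = 8
LOOP_D = 8
PRE_E = 4
LOOP_E2 = 14  # loop E downstream of the LE box (holds LE1/LE2/P2/P3)
CTAIL = 16

#: residues between the boxes contributed by the fixed architecture
#: (TM3 + loopC + TM4 + loopD + TM5 + preE); spacing = post-LB loop + this
INTER_BOX_FIXED = TM_LEN + LOOP_C + TM_LEN + LOOP_D + TM_LEN + PRE_E

MIN_SPACING = INTER_BOX_FIXED + 1

# offsets of special sites inside their segments
H2_OFFSET = 14      # in TM2
H5_OFFSET = 14      # in TM5
P1_OFFSET = 4       # in loopC
LOOPE2_LAYOUT = {"LE1": 2, "LE2": 3, "P2": 7, "P3": 9}
CTAIL_LAYOUT = {"P4": 4, "P5": 6}

NPA_PATTERN_FIRST = "NS"
NPA_PATTERN_THIRD = "ASTVLIC"


@dataclass(frozen=True)
class SubfamilyTemplate:
    subfamily: str
    subgroup: str
    ntail: int
    spacing: int
    triplets: tuple[str, str]
    arR: str
    froger: str
    n_members: int


#: invented subfamily templates; marker residues follow the subfamily-typical
#: patterns (PIP: F-H-T-R + (Q)S-A-F-W; NIP2: G-S-G-R Si signature, spacing 108)
TEMPLATES: dict[str, SubfamilyTemplate] = {
    "PIP1": SubfamilyTemplate("PIP", "PIP1", 45, 96, ("NPA", "NPA"), "FHTR", "QSAFW", 2),
    "PIP2": SubfamilyTemplate("PIP", "PIP2", 20, 96, ("NPA", "NPA"), "FHTR", "QSAFW", 2),
    "TIP1": SubfamilyTemplate("TIP", "TIP1", 14, 100, ("NPA", "NPA"), "HIAV", "FASYW", 2),
    "TIP2": SubfamilyTemplate("TIP", "TIP2", 14, 100, ("NPA", "NPA"), "HIGR", "FSAYW", 2),
    "NIP1": SubfamilyTemplate("NIP", "NIP1", 20, 104, ("NPA", "NPA"), "WVAR", "FSAYI", 2),
    "NIP2": SubfamilyTemplate("NIP", "NIP2", 20, 108, ("NPA", "NPV"), "GSGR", "LTAYF", 2),
    "SIP1": SubfamilyTemplate("SIP", "SIP1", 10, 94, ("NPT", "NPA"), "VTPN", "FAAYW", 1),
    "SIP2": SubfamilyTemplate("SIP", "SIP2", 10, 94, ("NPL", "NPA"), "FKGS", "FVAYW", 1),
    "XIP1": SubfamilyTemplate("XIP", "XIP1", 24, 102, ("SPI", "SPA"), "VIVR", "YCAFW", 2),
}

NTAIL_MAX = max(t.ntail for t in TEMPLATES.values())
POSTB_MAX = max(t.spacing for t in TEMPLATES.values()) - INTER_BOX_FIXED


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying one generated object."""

    kind: str
    data: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.data[key]


def _child_rng(seed: int, tag: str) -> np.random.Generator:
    child = zlib.crc32(tag.encode()) & 0x7FFFFFFF
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, child])


def _segments(ntail: int, post_b: int) -> list[tuple[str, str, int]]:
    """(name, kind, length) in sequence order; kind is 'tm' or 'loop'."""
    return [
        ("ntail", "loop", ntail),
        ("TM1", "tm", TM_LEN),
        ("loopA", "loop", LOOP_A),
        ("TM2", "tm", TM_LEN),
        ("preB", "loop", PRE_B),
        ("LB", "loop", 3),
        ("postB", "loop", post_b),
        ("TM3", "tm", TM_LEN),
        ("loopC", "loop", LOOP_C),
        ("TM4", "tm", TM_LEN),
        ("loopD", "loop", LOOP_D),
        ("TM5", "tm", TM_LEN),
        ("preE", "loop", PRE_E),
        ("LE", "loop", 3),
        ("loopE2", "loop", LOOP_E2),
        ("TM6", "tm", TM_LEN),
        ("ctail", "loop", CTAIL),
    ]


def _layout(ntail: int, post_b: int) -> dict:
    """Segment spans, per-position class, and special-site coordinates."""
    spans: dict[str, tuple[int, int]] = {}
    classes: list[str] = []
    pos = 0
    for name, kind, length in _segments(ntail, post_b):
        spans[name] = (pos, pos + length)
        classes.extend([kind] * length)
        pos += length
    special = {
        "LB": spans["LB"][0],
        "LE": spans["LE"][0],
        "H2": spans["TM2"][0] + H2_OFFSET,
        "H5": spans["TM5"][0] + H5_OFFSET,
        "P1": spans["loopC"][0] + P1_OFFSET,
    }
    for label, off in LOOPE2_LAYOUT.items():
        special[label] = spans["loopE2"][0] + off
    for label, off in CTAIL_LAYOUT.items():
        special[label] = spans["ctail"][0] + off
    return {"spans": spans, "classes": classes, "special": special, "length": pos}


def _consensus_segment(template: str, segment: str, kind: str, length: int, max_length: int | None = None) -> str:
    """Deterministic per-template segment consensus (independent of run seed)."""
    rng = _child_rng(0, f"consensus:{template}:{segment}")
    pool = HYDROPHOBIC_POOL if kind == "tm" else POLAR_POOL
    draw = max_length if max_length is not None else length
    letters = rng.choice(list(pool), size=draw)
    return "".join(letters[:length])


def _spurious_matches(seq: list[str], planted_starts: set[int]) -> list[int]:
    out = []
    for i in range(len(seq) - 2):
        if i in planted_starts:
            continue
        if seq[i] in NPA_PATTERN_FIRST and seq[i + 1] == "P" and seq[i + 2] in NPA_PATTERN_THIRD:
            out.append(i)
    return out


def _repair(seq: list[str], layout: dict, protected: set[int], planted_starts: set[int]) -> None:
    """Deterministically mutate away accidental NPA-like triplets."""
    classes = layout["classes"]
    for _ in range(10 * len(seq)):
        bad = _spurious_matches(seq, planted_starts)
        if not bad:
            return
        i = bad[0]
        # prefer breaking the middle 'P', then the first, then the third char
        for j in (i + 1, i, i + 2):
            if j not in protected:
                seq[j] = "F" if classes[j] == "tm" else "E"
                break
        else:  # pragma: no cover - planted sites never form a full triplet
            raise RuntimeError("cannot repair spurious NPA-like triplet")
    raise RuntimeError("repair loop did not converge")  # pragma: no cover


def build_scaffold(
    template: str,
    member: int = 0,
    spacing: int | None = None,
    triplets: tuple[str, str] | None = None,
    member_divergence: float = 0.08,
) -> tuple[str, SyntheticTruth]:
    """Render one synthetic MIP from a subfamily template.

    ``member`` indexes deterministic within-subgroup variants (about
    ``member_divergence`` substitutions from the subgroup consensus, away
    from marker sites).  ``spacing``/``triplets`` override the template's
    planted NPA geometry; spacing below the architectural minimum
    (:data:`MIN_SPACING`) is an error.
    """
    t = TEMPLATES[template]
    spacing = t.spacing if spacing is None else int(spacing)
    triplets = t.triplets if triplets is None else triplets
    post_b = spacing - INTER_BOX_FIXED
    if post_b < 1:
        raise ValueError(
            f"spacing {spacing} incompatible with scaffold (minimum {MIN_SPACING})"
        )
    layout = _layout(t.ntail, post_b)
    seq: list[str] = []
    for name, kind, length in _segments(t.ntail, post_b):
        max_len = POSTB_MAX + 30 if name == "postB" else None
        seq.extend(_consensus_segment(template, name, kind, length, max_len))

    special = layout["special"]
    protected: set[int] = set()
    for idx, box in enumerate(("LB", "LE")):
        start = special[box]
        for k, aa in enumerate(triplets[idx]):
            seq[start + k] = aa
            protected.add(start + k)
    for k, label in enumerate(("H2", "H5", "LE1", "LE2")):
        seq[special[label]] = t.arR[k]
        protected.add(special[label])
    for k, label in enumerate(("P1", "P2", "P3", "P4", "P5")):
        seq[special[label]] = t.froger[k]
        protected.add(special[label])

    if member:
        rng = _child_rng(0, f"member:{template}:{member}")
        classes = layout["classes"]
        for i in range(len(seq)):
            if i in protected:
                continue
            if rng.random() < member_divergence:
                pool = HYDROPHOBIC_POOL if classes[i] == "tm" else POLAR_POOL
                choices = [c for c in pool if c != seq[i]]
                seq[i] = choices[rng.integers(len(choices))]

    planted_starts = {special["LB"], special["LE"]}
    _repair(seq, layout, protected, planted_starts)

    spans = layout["spans"]
    truth = SyntheticTruth(
        kind="protein",
        data={
            "subfamily": t.subfamily,
            "subgroup": t.subgroup,
            "template": template,
            "member": member,
            "ntail": t.ntail,
            "tm_segments": [spans[f"TM{i}"] for i in range(1, 7)],
            "box_starts": (special["LB"], special["LE"]),
            "triplets": tuple(triplets),
            "spacing": spacing,
            "arR": t.arR,
            "arR_positions": tuple(special[x] for x in ("H2", "H5", "LE1", "LE2")),
            "froger": t.froger,
            "froger_positions": tuple(special[x] for x in ("P1", "P2", "P3", "P4", "P5")),
            "protected": protected,
            "layout": layout,
        },
    )
    return "".join(seq), truth


def generate_mip_protein(
    template: str,
    npa_triplets: tuple[str, str] | None = None,
    spacing: int | None = None,
    mutation_rate: float = 0.0,
    seed: int = 0,
    member: int = 0,
    decoys: Sequence[str] = (),
    record_id: str | None = None,
) -> tuple[ProteinRecord, SyntheticTruth]:
    """A synthetic MIP with planted, truth-annotated features.

    Substitution-only noise at ``mutation_rate`` is applied away from the
    marker sites, class-preservingly (TM positions stay hydrophobic, loop
    positions stay polar), then accidental NPA-like triplets are repaired
    so the planted boxes remain the only matches.  ``decoys`` may name
    ``"ntail"`` and/or ``"ctail"`` to plant an extra NPA triplet outside
    the canonical inter-box region.
    """
    if not 0.0 <= mutation_rate <= 0.3:
        raise ValueError("mutation_rate must be in [0, 0.3]")
    seq_str, truth = build_scaffold(template, member=member, spacing=spacing, triplets=npa_triplets)
    seq = list(seq_str)
    layout = truth["layout"]
    protected = set(truth["protected"])
    classes = layout["classes"]
    rng = _child_rng(seed, f"mip:{template}:{member}")
    if mutation_rate > 0:
        for i in range(len(seq)):
            if i in protected:
                continue
            if rng.random() < mutation_rate:
                pool = HYDROPHOBIC_POOL if classes[i] == "tm" else POLAR_POOL
                choices = [c for c in pool if c != seq[i]]
                seq[i] = choices[rng.integers(len(choices))]

    spans = layout["spans"]
    decoy_starts = []
    for where in decoys:
        if where == "ntail":
            start = 1
        elif where == "ctail":
            start = spans["ctail"][0] + 8
        else:
            raise ValueError(f"unknown decoy site {where!r}")
        for k, aa in enumerate("NPA"):
            seq[start + k] = aa
            protected.add(start + k)
        decoy_starts.append(start)

    planted = set(truth["box_starts"]) | set(decoy_starts)
    _repair(seq, layout, protected, planted)

    truth.data["decoy_starts"] = tuple(decoy_starts)
    truth.data["mutation_rate"] = mutation_rate
    rid = record_id or f"SYN-{template}-m{member}-s{seed}"
    return ProteinRecord(rid, "".join(seq), f"synthetic {template} MIP"), truth


# ---------------------------------------------------------------------------
# reference panel rendering
# ---------------------------------------------------------------------------

def panel_members() -> list[tuple[str, str, str, str, SyntheticTruth]]:
    """All (id, sequence, subfamily, subgroup, truth) templates render."""
    out = []
    for name, t in TEMPLATES.items():
        for m in range(t.n_members):
            seq, truth = build_scaffold(name, member=m)
            out.append((f"SYN-{name}-{m + 1}", seq, t.subfamily, t.subgroup, truth))
    return out


def panel_alignment() -> tuple[list[tuple[str, str, str, str]], dict[str, int]]:
    """The synthetic panel as a gapped alignment plus marked columns.

    Members share the architecture, so alignment is by construction: the
    variable-length N-tail is right-aligned against TM1 (leading gaps) and
    the variable post-LB loop is padded with gaps before TM3.  Marked
    columns are the special-site coordinates of the maximal layout.
    """
    aligned: list[tuple[str, str, str, str]] = []
    for pid, seq, subfamily, subgroup, truth in panel_members():
        spans = truth["layout"]["spans"]
        ntail = spans["ntail"][1]
        postb_start, postb_end = spans["postB"]
        row = (
            "-" * (NTAIL_MAX - ntail)
            + seq[:postb_end]
            + "-" * (POSTB_MAX - (postb_end - postb_start))
            + seq[postb_end:]
        )
        aligned.append((pid, row, subfamily, subgroup))
    ref_layout = _layout(NTAIL_MAX, POSTB_MAX)
    columns = {
        label: ref_layout["special"][label]
        for label in ("H2", "H5", "LE1", "LE2", "P1", "P2", "P3", "P4", "P5")
    }
    lengths = {len(row) for _, row, _, _ in aligned}
    assert lengths == {ref_layout["length"]}
    return aligned, columns


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _iupac_match(window: str, consensus: str) -> bool:
    return len(window) == len(consensus) and all(
        b in _IUPAC[c] for b, c in zip(window, consensus)
    )


def _scan_all(seq: str, consensi: Iterable[str]) -> list[tuple[str, str, int]]:
    hits = []
    for cons in consensi:
        L = len(cons)
        rc = _revcomp(cons)
        for i in range(len(seq) - L + 1):
            win = seq[i : i + L]
            if _iupac_match(win, cons):
                hits.append((cons, "+", i))
            if _iupac_match(win, rc) and rc != cons:
                hits.append((cons, "-", i))
            elif _iupac_match(win, rc) and rc == cons:
                # palindromic consensus: one biological site, count once
                pass
    return hits


def generate_promoter(
    plants: Sequence[tuple[str, int, str]],
    length: int = 2000,
    seed: int = 0,
    screen: Sequence[str] = (),
    tag: str = "promoter",
) -> tuple[str, SyntheticTruth]:
    """Random promoter DNA with planted IUPAC motif instances.

    ``plants`` holds (consensus, count, strand) triples.  The uniform
    background is rejection-screened so the only matches to the planted
    consensi (and to any extra ``screen`` consensi) are the planted ones,
    whose offsets are recorded in the truth.  Raises if the requested
    instances cannot be placed without overlap.
    """
    rng = _child_rng(seed, f"promoter:{tag}")
    consensi = list(dict.fromkeys([c for c, _, _ in plants] + list(screen)))
    total = sum(len(c) * n for c, n, _ in plants)
    if total > length // 2:
        raise ValueError("cannot place planted motifs without forced overlap")

    for _attempt in range(50):
        seq = list("".join(rng.choice(list("ACGT"), size=length)))
        # screen background
        for _ in range(200):
            bad = _scan_all("".join(seq), consensi)
            if not bad:
                break
            cons, strand, pos = bad[0]
            mid = pos + len(cons) // 2
            cur = seq[mid]
            seq[mid] = {"A": "C", "C": "A", "G": "T", "T": "G"}[cur]
        occupied: list[tuple[int, int]] = []
        planted: list[tuple[str, str, int]] = []
        ok = True
        for cons, count, strand in plants:
            L = len(cons)
            for _ in range(count):
                placed = False
                for _try in range(200):
                    pos = int(rng.integers(0, length - L + 1))
                    if any(pos < e and pos + L > s for s, e in occupied):
                        continue
                    realization = "".join(
                        c if c in "ACGT" else seq_choice(rng, _IUPAC[c]) for c in cons
                    )
                    insert = realization if strand == "+" else _revcomp(realization)
                    seq[pos : pos + L] = insert
                    occupied.append((pos, pos + L))
                    planted.append((cons, strand, pos))
                    placed = True
                    break
                if not placed:
                    ok = False
            if not ok:
                break
        if not ok:
            raise ValueError("cannot place planted motifs without overlap")
        hits = _scan_all("".join(seq), consensi)
        expected = sorted(planted)
        if sorted(hits) == expected:
            truth = SyntheticTruth(kind="promoter", data={"plants": expected, "length": length})
            return "".join(seq), truth
    raise RuntimeError("promoter generation did not converge")  # pragma: no cover


def seq_choice(rng: np.random.Generator, letters: str) -> str:
    return letters[int(rng.integers(len(letters)))]


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def generate_fpkm(
    n_genes: int = 20,
    n_samples: int = 12,
    planted_pairs: Sequence[float] = (),
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """FPKM matrix with planted Pearson-correlated gene pairs.

    ``planted_pairs`` lists a target correlation per pair; pair k couples
    genes (2k, 2k+1).  The partner is a scaled copy of the base profile
    plus Gaussian noise whose variance is calibrated so the expected
    correlation equals the target (``noise_sd`` rescales that calibrated
    noise; 0 gives r = 1 exactly).  Values are clipped at 0.

    Because log-normal profiles are heavy-tailed, small-sample chance
    correlations between independent genes can be large; the background
    is rejection-screened so that no unplanted pair exceeds
    ``background_r_max`` (0.6), keeping the planted pairs the only
    structure above conventional calling thresholds.
    """
    import pandas as pd

    background_r_max = 0.6
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    for r in planted_pairs:
        if not 0.0 < r <= 1.0:
            raise ValueError(f"target r {r} outside (0, 1]")
    if 2 * len(planted_pairs) > n_genes:
        raise ValueError("too many planted pairs for n_genes")
    rng = _child_rng(seed, "fpkm")
    genes = [f"G{i + 1:03d}" for i in range(n_genes)]
    samples = [f"S{j + 1:02d}" for j in range(n_samples)]
    planted_of: dict[int, int] = {}
    for k in range(len(planted_pairs)):
        planted_of[2 * k] = k
        planted_of[2 * k + 1] = k

    def draw_gene() -> np.ndarray:
        return np.exp(rng.normal(3.0, 1.0, size=n_samples))

    def set_pair(mat: np.ndarray, k: int) -> None:
        a, b = 2 * k, 2 * k + 1
        mat[a] = draw_gene()
        base = mat[a]
        sd = float(np.std(base, ddof=1))
        sigma = noise_sd * sd * np.sqrt(max(1.0 / planted_pairs[k] ** 2 - 1.0, 0.0))
        mat[b] = np.clip(1.5 * base + rng.normal(0.0, sigma, size=n_samples) * 1.5, 0.0, None)

    mat = np.empty((n_genes, n_samples))
    for i in range(n_genes):
        mat[i] = draw_gene()
    for k in range(len(planted_pairs)):
        set_pair(mat, k)

    for _ in range(500):
        corr = np.corrcoef(mat)
        offender = None
        for i in range(n_genes):
            for j in range(i + 1, n_genes):
                if planted_of.get(i) is not None and planted_of.get(i) == planted_of.get(j):
                    continue
                if abs(corr[i, j]) > background_r_max:
                    offender = (i, j)
                    break
            if offender:
                break
        if offender is None:
            break
        _, j = offender
        if j in planted_of:
            set_pair(mat, planted_of[j])
        else:
            mat[j] = draw_gene()
    else:  # pragma: no cover
        raise RuntimeError("background screening did not converge")

    pairs = [(genes[2 * k], genes[2 * k + 1], r) for k, r in enumerate(planted_pairs)]
    df = pd.DataFrame(mat, index=genes, columns=samples)
    truth = SyntheticTruth(kind="fpkm", data={"pairs": pairs})
    return df, truth


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def generate_gene_models(
    intron_count_distribution: dict[int, int],
    seed: int = 0,
    no_utr_transcripts: int = 0,
) -> tuple[str, SyntheticTruth]:
    """Valid GFF3 text with known per-transcript intron counts.

    The distribution maps intron count (1-4) to the number of transcripts
    with that count.  ``no_utr_transcripts`` of the transcripts (taken
    from the start) omit both UTR features.
    """
    for k in intron_count_distribution:
        if not 1 <= k <= 4:
            raise ValueError("intron counts must be in 1..4")
    rng = _child_rng(seed, "genemodels")
    lines = ["##gff-version 3"]
    truth_rows = []
    pos = 1000
    idx = 0
    counts = [
        k for k, n in sorted(intron_count_distribution.items()) for _ in range(n)
    ]
    for introns in counts:
        idx += 1
        gid, tid = f"gene{idx:03d}", f"gene{idx:03d}.1"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = introns + 1
        exon_lens = rng.integers(100, 301, size=n_exons)
        intron_lens = rng.integers(77, 501, size=introns)
        has_utr = idx > no_utr_transcripts
        exons = []
        p = pos
        for e in range(n_exons):
            exons.append((p, p + int(exon_lens[e]) - 1))
            p = exons[-1][1] + 1 + (int(intron_lens[e]) if e < introns else 0)
        gstart, gend = exons[0][0], exons[-1][1]
        lines.append(f"chr1\tsyn\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\tID={gid}")
        lines.append(f"chr1\tsyn\tmRNA\t{gstart}\t{gend}\t.\t{strand}\t.\tID={tid};Parent={gid}")
        for e, (s, t) in enumerate(exons, 1):
            lines.append(
                f"chr1\tsyn\texon\t{s}\t{t}\t.\t{strand}\t.\tID={tid}.exon{e};Parent={tid}"
            )
        if has_utr:
            u5 = (exons[0][0], exons[0][0] + 49)
            u3 = (exons[-1][1] - 49, exons[-1][1])
            lines.append(
                f"chr1\tsyn\tfive_prime_UTR\t{u5[0]}\t{u5[1]}\t.\t{strand}\t.\tID={tid}.utr5;Parent={tid}"
            )
            lines.append(
                f"chr1\tsyn\tthree_prime_UTR\t{u3[0]}\t{u3[1]}\t.\t{strand}\t.\tID={tid}.utr3;Parent={tid}"
            )
        truth_rows.append(
            {"transcript_id": tid, "intron_count": introns, "has_utr5": has_utr, "has_utr3": has_utr}
        )
        pos = gend + int(rng.integers(500, 2001))
    truth = SyntheticTruth(kind="gene_models", data={"transcripts": truth_rows})
    return "\n".join(lines) + "\n", truth


__all__ = [
    "HYDROPHOBIC_POOL",
    "MIN_SPACING",
    "POLAR_POOL",
    "SubfamilyTemplate",
    "SyntheticTruth",
    "TEMPLATES",
    "build_scaffold",
    "generate_fpkm",
    "generate_gene_models",
    "generate_mip_protein",
    "generate_promoter",
    "panel_alignment",
    "panel_members",
]
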