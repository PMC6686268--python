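"""NPA-box detection, inter-box spacing, and the silicon-permeability rule.

Plant MIPs carry two short Asn-Pro-Ala ("NPA") boxes, one in cytosolic
loop B (LB) and one in loop E (LE), that form the first pore constriction.
Family members vary the first position (Ser in XIPs) and the third
position (NPS/NPV/NPT/NPL), so detection uses a configurable degenerate
pattern.  NIP2-type silicon channels additionally combine a Gly-Ser-Gly-Arg
ar/R filter with a characteristic inter-box spacing near 108 residues;
``si_permeability_call`` encodes that rule.

Spacing convention: the number of residues strictly between the two
triplets, i.e. ``start(LE) - start(LB) - 3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

#: third-position alphabet covering observed variants (NPA/NPS/NPV/NPT/NPL)
#: plus Cys as a conservative extension
DEFAULT_THIRD = "ASTVLIC"

#: first-position alphabet; "NS" additionally catches XIP-type SPI/SPA boxes
DEFAULT_FIRST = "NS"

DEFAULT_CANONICAL_RANGE = (90, 130)


@dataclass(frozen=True)
class NPABox:
    """One detected box: 0-based triplet start, the triplet, LB or LE label."""

    start: int
    triplet: str
    loop_label: str  # "LB" or "LE"


@dataclass(frozen=True)
class NPAProfile:
    """0-2 detected boxes and the residues strictly between them."""

    boxes: tuple[NPABox, ...]
    spacing: int | None
    flags: tuple[str, ...] = ()

    @property
    def lb(self) -> NPABox | None:
        return next((b for b in self.boxes if b.loop_label == "LB"), None)

    @property
    def le(self) -> NPABox | None:
        return next((b for b in self.boxes if b.loop_label == "LE"), None)


@dataclass(frozen=True)
class SiPermeabilityCall:
    """Outcome of the GSGR + spacing silicon-permeability screen."""

    arR_is_GSGR: bool
    spacing: int | None
    verdict: str  # canonical_108 | variant_spacing | not_si_type
    reason: str = ""


def _candidates(seq: str, first: str, third: str) -> list[tuple[int, str]]:
    out = []
    for i in range(len(seq) - 2):
        if seq[i] in first and seq[i + 1] == "P" and seq[i + 2] in third:
            out.append((i, seq[i : i + 3]))
    return out


def _pair_score(
    i: int, j: int, seqlen: int, canonical_range: tuple[int, int]
) -> float:
    """Positional plausibility: one box per sequence half, spacing near the
    canonical 90-130 band."""
    spacing = j - i - 3
    lo, hi = canonical_range
    if spacing < lo:
        dist = lo - spacing
    elif spacing > hi:
        dist = spacing - hi
    else:
        dist = 0
    half = seqlen / 2.0
    return (1.0 if i < half else 0.0) + (1.0 if j >= half else 0.0) - dist / 50.0


def find_npa_boxes(
    seq: str,
    first: str = DEFAULT_FIRST,
    third: str = DEFAULT_THIRD,
    canonical_range: tuple[int, int] = DEFAULT_CANONICAL_RANGE,
) -> NPAProfile:
    """Scan for NPA-like boxes and keep the most plausible LB/LE pair.

    With zero matches the profile is flagged ``truncated_or_atypical``
    (such fragments are conventionally excluded from family tables).  With
    one match a single LB box is reported.  With more than two candidates
    the pair maximising :func:`_pair_score` wins; ties break to the
    leftmost pair.
    """
    cands = _candidates(seq, first, third)
    if not cands:
        return NPAProfile(boxes=(), spacing=None, flags=("truncated_or_atypical",))
    if len(cands) == 1:
        start, trip = cands[0]
        return NPAProfile(
            boxes=(NPABox(start, trip, "LB"),),
            spacing=None,
            flags=("single_box",),
        )
    if len(cands) == 2:
        pair = (cands[0], cands[1])
    else:
        best = None
        best_score = None
        for a, b in combinations(cands, 2):
            score = _pair_score(a[0], b[0], len(seq), canonical_range)
            if best_score is None or score > best_score:
                best, best_score = (a, b), score
        pair = best
    (i, trip_i), (j, trip_j) = pair
    boxes = (NPABox(i, trip_i, "LB"), NPABox(j, trip_j, "LE"))
    return NPAProfile(boxes=boxes, spacing=npa_spacing_from_starts(i, j))


def npa_spacing_from_starts(start_lb: int, start_le: int) -> int:
    """Residues strictly between two triplets given their 0-based starts."""
    return start_le - start_lb - 3


def npa_spacing(profile: NPAProfile) -> int | None:
    """Inter-box spacing of a two-box profile; None with fewer boxes."""
    if len(profile.boxes) < 2:
        return None
    return npa_spacing_from_starts(profile.boxes[0].start, profile.boxes[1].start)


def si_permeability_call(arR: str | None, spacing: int | None) -> SiPermeabilityCall:
    """Silicon-permeability screen: GSGR ar/R filter + inter-NPA spacing.

    GSGR with spacing exactly 108 is the canonical silicon-channel
    signature; GSGR with spacing 107 or 109 is called ``variant_spacing``
    (known Si accumulators deviate by one residue); everything else,
    including a missing ar/R filter, is ``not_si_type``.
    """
    if arR is None or "/" in arR or len(arR) != 4:
        return SiPermeabilityCall(False, spacing, "not_si_type", reason="ar/R filter missing")
    is_gsgr = arR == "GSGR"
    if is_gsgr and spacing == 108:
        return SiPermeabilityCall(True, spacing, "canonical_108")
    if is_gsgr and spacing in (107, 109):
        return SiPermeabilityCall(True, spacing, "variant_spacing")
    return SiPermeabilityCall(is_gsgr, spacing, "not_si_type")


__all__ = [
    "DEFAULT_CANONICAL_RANGE",
    "DEFAULT_FIRST",
    "DEFAULT_THIRD",
    "NPABox",
    "NPAProfile",
    "SiPermeabilityCall",
    "find_npa_boxes",
    "npa_spacing",
    "npa_spacing_from_starts",
    "si_permeability_call",
]
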