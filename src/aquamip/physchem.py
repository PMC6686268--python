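"""Physicochemical profiling of candidate MIP proteins.

Covers the classic per-sequence descriptors used to characterise an
aquaporin family table: length, molecular weight (average isotopic, kD),
isoelectric point, GRAVY (grand average of hydropathy, Kyte-Doolittle),
and a hydropathy-based transmembrane segmentation.

The isoelectric point is found by bisection on the Henderson-Hasselbalch
net charge over the ionisable side chains (D, E, C, Y, K, R, H) plus the
free termini; the pKa set is a named, swappable config block.  The TM
segmentation is a sliding-window hydropathy rule, which approximates but
does not reproduce HMM-based topology predictors; TM counts should be
treated as indicative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

#: simplified Henderson-Hasselbalch pKa sets.  Keys: side chains + termini.
PKA_SETS: dict[str, dict[str, float]] = {
    # values as tabulated by ExPASy's compute-pI documentation lineage
    "expasy": {
        "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
        "H": 5.98, "K": 10.0, "R": 12.0,
        "Nterm": 7.5, "Cterm": 3.55,
    },
    # EMBOSS iep defaults
    "emboss": {
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
        "H": 6.5, "K": 10.8, "R": 12.5,
        "Nterm": 8.6, "Cterm": 3.6,
    },
}

_ACIDIC = ("D", "E", "C", "Y")
_BASIC = ("K", "R", "H")


@dataclass(frozen=True)
class PhyschemProfile:
    """Length (aa), MW (kD, average masses), pI (pH units), GRAVY."""

    length: int
    mw: float
    pi: float
    gravy: float


@dataclass(frozen=True)
class TMSegment:
    """A predicted transmembrane stretch, 0-based half-open residue interval."""

    start: int
    end: int
    mean_hydropathy: float

    def __len__(self) -> int:
        return self.end - self.start


def _require_sequence(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")


def compute_gravy(seq: str) -> float:
    """Arithmetic mean of Kyte-Doolittle hydropathy over all residues."""
    _require_sequence(seq)
    return float(np.mean([KYTE_DOOLITTLE[aa] for aa in seq]))


def compute_mw(seq: str) -> float:
    """Molecular weight in kilodaltons: average residue masses + one water."""
    _require_sequence(seq)
    return ProteinAnalysis(seq).molecular_weight() / 1000.0


def net_charge(seq: str, ph: float, pka_set: str = "expasy") -> float:
    """Henderson-Hasselbalch net charge of ``seq`` at ``ph``.

    Positive contributions from K/R/H and the free N-terminus, negative from
    D/E/C/Y and the free C-terminus.  Vectorised over ``ph`` if an array is
    passed (used by the brute-force pI oracle).
    """
    _require_sequence(seq)
    pka = PKA_SETS[pka_set]
    ph = np.asarray(ph, dtype=float)
    pos = 1.0 / (1.0 + 10.0 ** (ph - pka["Nterm"]))
    for aa in _BASIC:
        n = seq.count(aa)
        if n:
            pos = pos + n / (1.0 + 10.0 ** (ph - pka[aa]))
    neg = 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - ph))
    for aa in _ACIDIC:
        n = seq.count(aa)
        if n:
            neg = neg + n / (1.0 + 10.0 ** (pka[aa] - ph))
    charge = pos - neg
    return float(charge) if charge.ndim == 0 else charge


def compute_pi(seq: str, pka_set: str = "expasy", tol: float = 1e-4) -> float:
    """Isoelectric point by bisection on the net-charge curve.

    The charge is strictly decreasing in pH, so bisection on [0, 14]
    converges; iteration stops when \\|charge\\| < ``tol``.
    """
    _require_sequence(seq)
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(seq, mid, pka_set)
        if abs(q) < tol:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return mid


def predict_tm_segments(
    seq: str,
    window: int = 19,
    threshold: float = 1.6,
    min_length: int = 15,
    merge_gap: int = 4,
) -> list[TMSegment]:
    """Hydropathy-based transmembrane segmentation.

    A centred ``window``-residue Kyte-Doolittle mean is computed at every
    position with a full window; maximal runs of positions at or above
    ``threshold`` become candidate segments, segments separated by at most
    ``merge_gap`` residues are merged, and segments shorter than
    ``min_length`` are discarded.  Returns an empty list with a warning for
    sequences shorter than the window.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    n = len(seq)
    if n < window:
        warnings.warn(f"sequence length {n} < window {window}: no TM prediction")
        return []
    values = np.array([KYTE_DOOLITTLE[aa] for aa in seq])
    csum = np.concatenate([[0.0], np.cumsum(values)])
    half = window // 2
    centers = np.arange(half, n - half)
    means = (csum[centers + half + 1] - csum[centers - half]) / window
    above = means >= threshold

    # maximal runs of qualifying centres -> raw intervals in residue coords
    raw: list[list[int]] = []
    run_start = None
    for idx, flag in enumerate(above):
        if flag and run_start is None:
            run_start = idx
        elif not flag and run_start is not None:
            raw.append([int(centers[run_start]), int(centers[idx - 1]) + 1])
            run_start = None
    if run_start is not None:
        raw.append([int(centers[run_start]), int(centers[-1]) + 1])

    merged: list[list[int]] = []
    for start, end in raw:
        if merged and start - merged[-1][1] <= merge_gap:
            merged[-1][1] = end
        else:
            merged.append([start, end])

    segments = []
    for start, end in merged:
        if end - start >= min_length:
            segments.append(TMSegment(start, end, float(np.mean(values[start:end]))))
    return segments


def profile(seq: str, pka_set: str = "expasy") -> PhyschemProfile:
    """Convenience bundle of length, MW, pI and GRAVY."""
    return PhyschemProfile(
        length=len(seq),
        mw=compute_mw(seq),
        pi=compute_pi(seq, pka_set=pka_set),
        gravy=compute_gravy(seq),
    )


__all__ = [
    "KYTE_DOOLITTLE",
    "PKA_SETS",
    "PhyschemProfile",
    "TMSegment",
    "compute_gravy",
    "compute_mw",
    "compute_pi",
    "net_charge",
    "predict_tm_segments",
    "profile",
]
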