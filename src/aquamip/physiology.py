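"""Closed-form physiology and quantification formulas.

Small audited utilities used around aquaporin physiology experiments:
leaf-specific conductivity of a stem segment, qRT-PCR fold change by the
2^-ddCt method, and hourly leaf water-loss rate on a dry-weight basis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ConductivityInput:
    """F: flow (kg/s); SL: stem length (m); dP: gradient (MPa); A_leaf: m^2."""

    F: float
    SL: float
    dP: float
    A_leaf: float

    def __post_init__(self) -> None:
        for name in ("F", "SL", "dP", "A_leaf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class CtQuad:
    """qRT-PCR cycle thresholds: target/reference in treated/control."""

    target_treated: float
    ref_treated: float
    target_control: float
    ref_control: float

    def __post_init__(self) -> None:
        for name in ("target_treated", "ref_treated", "target_control", "ref_control"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite")


def leaf_specific_conductivity(x: ConductivityInput) -> float:
    """L_sc = F * SL / (dP * A_leaf), in kg H2O s^-1 m^-1 MPa^-1."""
    return x.F * x.SL / (x.dP * x.A_leaf)


def ddct_fold_change(q: CtQuad) -> float:
    """2^-ddCt relative expression.

    ddCt = (Ct_target,treated - Ct_ref,treated)
         - (Ct_target,control - Ct_ref,control); one cycle of advantage
    doubles the estimate.
    """
    ddct = (q.target_treated - q.ref_treated) - (q.target_control - q.ref_control)
    return float(2.0 ** (-ddct))


def water_loss_rate(
    weights: Sequence[float],
    dry_weight: float,
    interval_hours: float = 1.0,
) -> list[float]:
    """Per-interval water loss in g H2O per g dry weight per hour.

    ``weights`` are fresh masses (g) at evenly spaced time points;
    loss_i = (w_i - w_{i+1}) / dry_weight / interval_hours.  Weights are
    not assumed monotone (weighing noise may produce negative rates).
    """
    if dry_weight <= 0:
        raise ValueError("dry_weight must be positive")
    if len(weights) < 2:
        raise ValueError("need at least two time points")
    if interval_hours <= 0:
        raise ValueError("interval_hours must be positive")
    w = np.asarray(weights, dtype=float)
    return list((w[:-1] - w[1:]) / dry_weight / interval_hours)


__all__ = [
    "ConductivityInput",
    "CtQuad",
    "ddct_fold_change",
    "leaf_specific_conductivity",
    "water_loss_rate",
]
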