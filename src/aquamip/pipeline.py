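"""End-to-end annotation pipeline and the consolidated family report.

Per protein: physicochemical profile -> TM segmentation -> NPA profile ->
ar/R + Froger projection -> subfamily call -> silicon-permeability
verdict.  Proteins with zero NPA-like boxes are excluded from the family
report and listed separately (the convention for truncated fragments).
Module errors are recorded per record; the pipeline continues.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from . import npa as npa_mod
from . import physchem
from .classify import assign_subfamily
from .residue_profile import ReferencePanel, locate_arR, locate_froger
from .seqio import ProteinRecord, make_aligner, read_fasta

log = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "id", "length", "mw_kd", "pi", "gravy", "tm_count",
    "arR_H2", "arR_H5", "arR_LE1", "arR_LE2",
    "npa_LB", "npa_LE", "npa_spacing",
    "froger_P1", "froger_P2", "froger_P3", "froger_P4", "froger_P5",
    "subfamily", "subgroup", "support", "si_verdict", "flags",
]


@dataclass
class RunConfig:
    """Pipeline configuration; unknown keys are rejected at load."""

    proteins: str = ""
    panel: str = ""
    gff: str = ""
    promoters: str = ""
    out_dir: str = "aquamip_run"
    seed: int = 0
    bootstrap_n: int = 0
    pka_set: str = "expasy"
    tm_window: int = 19
    tm_threshold: float = 1.6
    npa_pattern_first: str = npa_mod.DEFAULT_FIRST
    npa_pattern_third: str = npa_mod.DEFAULT_THIRD

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class AnnotationReport:
    """Consolidated per-protein annotation; every field populated or
    explicitly marked missing via ``flags``."""

    id: str
    length: int | None = None
    mw_kd: float | None = None
    pi: float | None = None
    gravy: float | None = None
    tm_count: int | None = None
    tm_segments: list = field(default_factory=list)
    arR: str = "////"
    arR_positions: tuple = ()
    npa_lb: str = "/"
    npa_le: str = "/"
    npa_spacing: int | None = None
    froger: str = "/////"
    froger_positions: tuple = ()
    subfamily: str = ""
    subgroup: str = ""
    support: float | None = None
    si_verdict: str = ""
    flags: list = field(default_factory=list)

    def to_row(self) -> dict:
        return {
            "id": self.id,
            "length": self.length,
            "mw_kd": None if self.mw_kd is None else round(self.mw_kd, 2),
            "pi": None if self.pi is None else round(self.pi, 2),
            "gravy": None if self.gravy is None else round(self.gravy, 3),
            "tm_count": self.tm_count,
            "arR_H2": self.arR[0], "arR_H5": self.arR[1],
            "arR_LE1": self.arR[2], "arR_LE2": self.arR[3],
            "npa_LB": self.npa_lb, "npa_LE": self.npa_le,
            "npa_spacing": self.npa_spacing,
            "froger_P1": self.froger[0], "froger_P2": self.froger[1],
            "froger_P3": self.froger[2], "froger_P4": self.froger[3],
            "froger_P5": self.froger[4],
            "subfamily": self.subfamily, "subgroup": self.subgroup,
            "support": self.support, "si_verdict": self.si_verdict,
            "flags": ";".join(self.flags),
        }

    def to_json_dict(self) -> dict:
        d = self.to_row()
        d["tm_segments"] = [[s.start, s.end] for s in self.tm_segments]
        d["arR_positions"] = list(self.arR_positions)
        d["froger_positions"] = list(self.froger_positions)
        return d


def annotate_record(
    rec: ProteinRecord,
    panel: ReferencePanel,
    config: RunConfig | None = None,
    aligner=None,
) -> AnnotationReport:
    """Run every annotation stage for one protein, recording failures."""
    cfg = config or RunConfig()
    if aligner is None:
        aligner = make_aligner(free_end_gaps=True)
    report = AnnotationReport(id=rec.id)
    try:
        report.length = len(rec)
        report.mw_kd = physchem.compute_mw(rec.sequence)
        report.pi = physchem.compute_pi(rec.sequence, pka_set=cfg.pka_set)
        report.gravy = physchem.compute_gravy(rec.sequence)
    except Exception as exc:  # noqa: BLE001 - per-record isolation
        report.flags.append(f"physchem_error:{exc}")
    try:
        segs = physchem.predict_tm_segments(
            rec.sequence, window=cfg.tm_window, threshold=cfg.tm_threshold
        )
        report.tm_segments = segs
        report.tm_count = len(segs)
    except Exception as exc:  # noqa: BLE001
        report.flags.append(f"tm_error:{exc}")
        segs = []
    profile = npa_mod.find_npa_boxes(
        rec.sequence, first=cfg.npa_pattern_first, third=cfg.npa_pattern_third
    )
    report.flags.extend(profile.flags)
    if profile.lb:
        report.npa_lb = profile.lb.triplet
    if profile.le:
        report.npa_le = profile.le.triplet
    report.npa_spacing = profile.spacing
    try:
        arr = locate_arR(rec, panel, aligner)
        report.arR = arr.residues
        report.arR_positions = arr.positions
        if arr.reason:
            report.flags.append(f"arR:{arr.reason}")
        froger = locate_froger(rec, panel, aligner)
        report.froger = froger.residues
        report.froger_positions = froger.positions
    except Exception as exc:  # noqa: BLE001
        report.flags.append(f"projection_error:{exc}")
    try:
        call = assign_subfamily(
            rec, panel, bootstrap_n=cfg.bootstrap_n, seed=cfg.seed,
            tm_segments=segs, aligner=aligner,
        )
        report.subfamily = call.subfamily
        report.subgroup = call.subgroup
        report.support = call.support
        report.flags.extend(call.flags)
    except Exception as exc:  # noqa: BLE001
        report.flags.append(f"classify_error:{exc}")
    si = npa_mod.si_permeability_call(report.arR, report.npa_spacing)
    report.si_verdict = si.verdict
    return report


def annotate_pipeline(
    records: Sequence[ProteinRecord],
    panel: ReferencePanel,
    config: RunConfig | None = None,
) -> tuple[list[AnnotationReport], list[AnnotationReport]]:
    """Annotate all records; returns (family reports, NPA-less exclusions)."""
    cfg = config or RunConfig()
    aligner = make_aligner(free_end_gaps=True)
    reports, excluded = [], []
    for rec in records:
        report = annotate_record(rec, panel, cfg, aligner)
        if "truncated_or_atypical" in report.flags:
            excluded.append(report)
        else:
            reports.append(report)
    return reports, excluded


def _json_scalar(o):
    import numpy as np

    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_reports(
    reports: Sequence[AnnotationReport],
    excluded: Sequence[AnnotationReport],
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> None:
    """Write the consolidated TSV + JSON report and the exclusions list."""
    cfg = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = (
        f"# aquamip {__version__} config={cfg.digest()} "
        f"aligner=global/BLOSUM62/10/1 spacing=strictly-between\n"
    )
    df = pd.DataFrame([r.to_row() for r in reports], columns=REPORT_COLUMNS)
    with open(out / "annotation_report.tsv", "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)
    with open(out / "annotation_report.json", "w") as fh:
        json.dump(
            {
                "version": __version__,
                "config": dataclasses.asdict(cfg),
                "records": [r.to_json_dict() for r in reports],
                "excluded": [r.to_json_dict() for r in excluded],
            },
            fh,
            indent=2,
            default=_json_scalar,
        )
    if excluded:
        edf = pd.DataFrame([r.to_row() for r in excluded], columns=REPORT_COLUMNS)
        with open(out / "excluded_records.tsv", "w") as fh:
            fh.write(header)
            edf.to_csv(fh, sep="\t", index=False)


__all__ = [
    "AnnotationReport",
    "REPORT_COLUMNS",
    "RunConfig",
    "annotate_pipeline",
    "annotate_record",
    "write_reports",
]
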