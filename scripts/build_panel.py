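"""Regenerate the packaged synthetic reference panel fixture.

Renders the generator's subfamily templates into an aligned FASTA plus a
marked-column TSV under ``src/aquamip/data/``.  The output is
deterministic; re-running must be a no-op unless the templates changed.

Usage: python scripts/build_panel.py
"""

from __future__ import annotations

from pathlib import Path

from aquamip.synthetic import panel_alignment

DATA = Path(__file__).resolve().parent.parent / "src" / "aquamip" / "data"


def main() -> None:
    aligned, columns = panel_alignment()
    afa = DATA / "panel_synthetic.afa"
    with open(afa, "w") as fh:
        fh.write(
            "; synthetic reference panel rendered from aquamip.synthetic templates\n"
        )
        for pid, row, subfamily, subgroup in aligned:
            fh.write(f">{pid} subfamily={subfamily} subgroup={subgroup} synthetic=true\n")
            for i in range(0, len(row), 60):
                fh.write(row[i : i + 60] + "\n")
    cols = DATA / "panel_synthetic_columns.tsv"
    with open(cols, "w") as fh:
        fh.write("# 0-based alignment-column indices of marked residue sites\n")
        fh.write("label\tcolumn\n")
        for label, col in columns.items():
            fh.write(f"{label}\t{col}\n")
    print(f"wrote {afa} ({len(aligned)} members) and {cols} ({len(columns)} columns)")


if __name__ == "__main__":
    main()
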