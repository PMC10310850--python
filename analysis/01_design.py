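#!/usr/bin/env python
"""Build the L8 exposure design, its alias structure and the sample sheet.

Constructs the 8-run orthogonal array for the six exposures (Pb, VPA,
BPA, EtOH, FH, Zn-), reports which two-way interactions are estimable on
the free column, compares the sampling cost against a one-factor-at-a-
time study, and writes the wet-lab sample sheet (4 cell lines, a full
extra replicate for CTRL_Male and a 4-run partial for CTRL_Female).
"""

from pathlib import Path

from ffed import design as D
from ffed.io import write_design, write_sheet

OUT = Path("results/design")
OUT.mkdir(parents=True, exist_ok=True)

table = D.assign_factors(D.build_l8(), D.default_factors())
write_design(table, OUT / "design.csv", OUT / "design.yaml")

print("L8 orthogonal array: 8 runs x 7 columns, factors on columns "
      f"{sorted(table.assignment.values())}, free column {table.free_columns}")

pairs = D.estimable_interactions(table)
print("Estimable (mutually aliased) two-way interactions:",
      ", ".join("-".join(sorted(p)) for p in pairs))

with open(OUT / "alias_structure.txt", "w") as fh:
    for group in D.alias_structure(table):
        effects = [e if isinstance(e, str) else ":".join(sorted(e))
                   for e in group.effects]
        fh.write(f"column {group.column_label}: {', '.join(effects)}"
                 f"{'  [' + group.flag + ']' if group.flag else ''}\n")

ffed_n = D.sample_count("ffed", 6, 8, 4, 1)
ofat_n = D.sample_count("ofat", 6, 8, 4, 5)
print(f"Sampling cost: {ffed_n} samples (L8 x 4 lines) vs {ofat_n} for a "
      "one-factor-at-a-time study (6 factors x 4 lines x 5 replicates)")

sheet = D.make_sample_sheet(
    table, D.default_cell_lines(),
    replicates={"CTRL_Male": 2}, partial={"CTRL_Female": [1, 2, 3, 4]},
)
write_sheet(sheet, OUT / "sample_sheet.csv")
print(f"Sample sheet: {len(sheet)} rows -> {OUT / 'sample_sheet.csv'}")
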