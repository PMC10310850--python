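"""Two-level orthogonal-array designs and their alias structure.

The workhorse is the L8 array: 8 runs, 7 mutually orthogonal two-level
columns. Columns are labelled 1..7 by the binary/XOR convention: the entry
of column ``j`` in run ``r`` is ``(-1)**popcount((r-1) & j)``, so the
elementwise product of two columns is again a column and its label is the
XOR of theirs. That single identity makes confounding exact integer
algebra: a two-way interaction {A, B} is aliased onto the column whose
label is ``label(A) ^ label(B)``.

With six factors on six of the seven columns, one column stays free and
exactly three of the fifteen two-way interactions land on it; those three
pairs always partition the six factors. Under the default assignment the
pairs are (Pb, Zn-), (VPA, FH) and (BPA, EtOH).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "CellLine",
    "DesignTable",
    "AliasGroup",
    "build_l8",
    "assign_factors",
    "alias_structure",
    "sample_count",
    "make_sample_sheet",
    "default_factors",
    "default_cell_lines",
]


@dataclass(frozen=True)
class FactorSpec:
    """One two-level exposure factor.

    ``control_dose``/``treated_dose`` are (value, unit) pairs. For zinc
    deficiency the convention inverts: the control medium carries the
    1.5 µM ZnSO4 supplement and the treated level is its absence.
    """

    name: str
    control_label: str = "control"
    treated_label: str = "treated"
    treated_dose: tuple[float, str] = (0.0, "")
    control_dose: tuple[float, str] = (0.0, "")


@dataclass(frozen=True)
class CellLine:
    name: str
    clinical_background: str  # "ASD" or "Non-ASD"


@dataclass(frozen=True)
class AliasGroup:
    """Effects sharing one contrast column (hence mutually indistinguishable)."""

    column_label: int
    effects: tuple = ()  # str for main effects, frozenset of 2 names for pairs
    flag: str = ""


@dataclass
class DesignTable:
    """A run x column matrix with entries in {-1, +1}.

    -1 codes the control level and +1 the treated level for every factor,
    including zinc deficiency (treated = deprivation).
    """

    entries: np.ndarray
    column_index: list[int]
    assignment: dict[str, int] = field(default_factory=dict)
    factors: dict[str, FactorSpec] = field(default_factory=dict)

    @property
    def n_runs(self) -> int:
        return self.entries.shape[0]

    @property
    def free_columns(self) -> list[int]:
        used = set(self.assignment.values())
        return [c for c in self.column_index if c not in used]

    def column(self, label: int) -> np.ndarray:
        return self.entries[:, self.column_index.index(label)]

    def factor_column(self, name: str) -> np.ndarray:
        return self.column(self.assignment[name])

    def validate(self) -> None:
        e = self.entries
        if not np.isin(e, (-1, 1)).all():
            raise ValueError("design entries must be -1/+1")
        if e.sum(axis=0).any():
            raise ValueError("unbalanced column")
        gram = e.T @ e
        if (gram - np.diag(np.diag(gram))).any():
            raise ValueError("columns are not orthogonal")
        if len({tuple(r) for r in e}) != e.shape[0]:
            raise ValueError("duplicate runs")


def build_l8() -> DesignTable:
    """Construct the canonical 8-run, 7-column orthogonal array.

    Column ``j``'s run-``r`` entry is ``(-1)**popcount((r-1) & j)``; columns
    1, 2 and 4 are the three generators, every other column the product of
    the generators in its binary expansion. Runs come out in Yates order.
    """
    labels = list(range(1, 8))
    entries = np.array(
        [[(-1) ** ((r & j).bit_count()) for j in labels] for r in range(8)],
        dtype=int,
    )
    table = DesignTable(entries=entries, column_index=labels)
    table.validate()
    return table


def assign_factors(
    table: DesignTable,
    factors: list[FactorSpec],
    column_map: dict[str, int] | None = None,
) -> DesignTable:
    """Attach factors to columns; unassigned columns remain free.

    The default map assigns factors to columns 1, 2, ... in the order
    given. Supplying the six exposures in the study's order
    (Pb, VPA, BPA, EtOH, FH, Zn-) then aliases exactly the pairs
    (Pb, Zn-), (VPA, FH), (BPA, EtOH) onto the free column 7, because
    1^6 = 2^5 = 3^4 = 7.
    """
    names = [f.name for f in factors]
    if len(set(names)) != len(names):
        raise ValueError("factor names must be unique")
    if len(factors) > len(table.column_index):
        raise ValueError(
            f"{len(factors)} factors exceed the {len(table.column_index)} columns"
        )
    if column_map is None:
        column_map = dict(zip(names, table.column_index))
    else:
        if set(column_map) != set(names):
            raise ValueError("column_map keys must match factor names")
        if len(set(column_map.values())) != len(column_map):
            raise ValueError("duplicate column assignment")
        bad = set(column_map.values()) - set(table.column_index)
        if bad:
            raise ValueError(f"unknown column labels: {sorted(bad)}")
    return replace(
        table,
        entries=table.entries.copy(),
        assignment=dict(column_map),
        factors={f.name: f for f in factors},
    )


def alias_structure(table: DesignTable, max_order: int = 2) -> list[AliasGroup]:
    """Map every main effect and interaction up to ``max_order`` to its column.

    An order-k interaction's contrast is the elementwise product of its
    factors' columns, whose label is the XOR of their labels. Groups are
    returned sorted by column label. An interaction sharing a column with
    an assigned main effect is flagged ``"confounded with main effect"``;
    interactions on a free column are flagged
    ``"estimable (mutually aliased)"`` — they can be tested, but only as
    one contrast shared by every pair in the group.
    """
    if not table.assignment:
        raise ValueError("no factors assigned to the design")
    by_column: dict[int, list] = {}
    for name, col in table.assignment.items():
        by_column.setdefault(col, []).append(name)
    names = sorted(table.assignment)
    for order in range(2, max_order + 1):
        for combo in itertools.combinations(names, order):
            col = 0
            for name in combo:
                col ^= table.assignment[name]
            by_column.setdefault(col, []).append(frozenset(combo))
    main_columns = set(table.assignment.values())
    free = set(table.free_columns)
    groups = []
    for col in sorted(by_column):
        effects = by_column[col]
        has_interaction = any(isinstance(e, frozenset) for e in effects)
        if col in main_columns and has_interaction:
            flag = "confounded with main effect"
        elif col in free and has_interaction:
            flag = "estimable (mutually aliased)"
        else:
            flag = ""
        groups.append(AliasGroup(column_label=col, effects=tuple(effects), flag=flag))
    return groups


def estimable_interactions(table: DesignTable) -> list[frozenset]:
    """The two-way interactions aliased onto free columns (testable contrasts)."""
    free = set(table.free_columns)
    pairs = []
    for group in alias_structure(table, max_order=2):
        if group.column_label in free:
            pairs.extend(e for e in group.effects if isinstance(e, frozenset))
    return pairs


def sample_count(
    design_kind: str,
    n_factors: int,
    n_runs: int,
    n_cell_lines: int,
    n_replicates: int,
) -> int:
    """Total samples for a fractional-factorial vs one-factor-at-a-time study.

    ``ffed``: every run of the array is one sample per (cell line,
    replicate), so runs x lines x replicates. ``ofat``: each factor needs
    its own exposed condition, so factors x lines x replicates.
    The study's comparison: an L8 across 4 lines with one replicate takes
    32 samples, where a 6-factor OFAT with 5 replicates would take 120.
    """
    for arg in (n_factors, n_runs, n_cell_lines, n_replicates):
        if arg <= 0:
            raise ValueError("all design dimensions must be positive")
    if design_kind == "ffed":
        return n_runs * n_cell_lines * n_replicates
    if design_kind == "ofat":
        return n_factors * n_cell_lines * n_replicates
    raise ValueError(f"unknown design kind: {design_kind!r}")


def _format_dose(dose: tuple[float, str]) -> str:
    value, unit = dose
    text = f"{value:g}"
    return f"{text} {unit}".strip()


def make_sample_sheet(
    table: DesignTable,
    cell_lines: list[CellLine],
    replicates: dict[str, int] | None = None,
    partial: dict[str, list[int]] | None = None,
    randomize_runs: bool = False,
    seed: int | None = None,
) -> pd.DataFrame:
    """Expand a design into a wet-lab sample sheet.

    One row per (cell line, replicate, run). ``replicates`` gives the
    number of full replicates per line (default 1); ``partial`` adds one
    extra partial replicate restricted to the listed run indices — the
    study ran the full array once per line plus a full extra replicate for
    CTRL_Male and a 4-run partial for CTRL_Female. Runs are emitted in
    Yates order unless ``randomize_runs`` (seeded) is set.
    """
    if not table.assignment:
        raise ValueError("assign factors before building a sample sheet")
    replicates = replicates or {}
    partial = partial or {}
    known = {line.name for line in cell_lines}
    unknown = set(partial) - known
    if unknown:
        raise ValueError(f"unknown cell line(s) in partial map: {sorted(unknown)}")
    for line, runs in partial.items():
        if not set(runs) <= set(range(1, table.n_runs + 1)):
            raise ValueError(f"invalid run indices for {line}: {runs}")

    rng = np.random.default_rng(seed)
    rows = []
    for line in cell_lines:
        n_rep = replicates.get(line.name, 1)
        blocks = [(rep, list(range(1, table.n_runs + 1))) for rep in range(1, n_rep + 1)]
        if line.name in partial:
            blocks.append((n_rep + 1, sorted(partial[line.name])))
        for rep, runs in blocks:
            if randomize_runs:
                runs = list(rng.permutation(runs))
            for run in runs:
                row = {
                    "sample_id": f"{line.name}_rep{rep}_run{run}",
                    "cell_line": line.name,
                    "clinical_background": line.clinical_background,
                    "replicate": rep,
                    "run_index": run,
                }
                for name, col in table.assignment.items():
                    level = table.column(col)[run - 1]
                    spec = table.factors.get(name, FactorSpec(name))
                    treated = level == 1
                    row[f"{name}_level"] = (
                        spec.treated_label if treated else spec.control_label
                    )
                    row[f"{name}_dose"] = _format_dose(
                        spec.treated_dose if treated else spec.control_dose
                    )
                    row[f"{name}_code"] = int(level)
                rows.append(row)
    return pd.DataFrame(rows)


def default_factors() -> list[FactorSpec]:
    """The study's six exposures, in its order, with the applied doses.

    Pb, VPA, BPA and FH at 3 µM, EtOH at 3 mM. Zinc deficiency is coded
    with the supplement on the control side: control medium carries
    1.5 µM ZnSO4, the treated level withdraws it.
    """
    um, mm = "µM", "mM"
    return [
        FactorSpec("Pb", treated_dose=(3.0, um), control_dose=(0.0, um)),
        FactorSpec("VPA", treated_dose=(3.0, um), control_dose=(0.0, um)),
        FactorSpec("BPA", treated_dose=(3.0, um), control_dose=(0.0, um)),
        FactorSpec("EtOH", treated_dose=(3.0, mm), control_dose=(0.0, mm)),
        FactorSpec("FH", treated_dose=(3.0, um), control_dose=(0.0, um)),
        FactorSpec(
            "Zn-",
            control_label="supplemented",
            treated_label="deprived",
            treated_dose=(0.0, um),
            control_dose=(1.5, um),
        ),
    ]


def default_cell_lines() -> list[CellLine]:
    """The four iPSC-derived NES lines: two neurotypical, two ASD."""
    return [
        CellLine("CTRL_Male", "Non-ASD"),
        CellLine("CTRL_Female", "Non-ASD"),
        CellLine("ASD_HNRNPU", "ASD"),
        CellLine("ASD_CASK", "ASD"),
    ]


def default_sample_sheet(seed: int | None = None) -> pd.DataFrame:
    """The study layout: 4 lines x L8, plus a full extra replicate for
    CTRL_Male and a 4-run partial for CTRL_Female (44 rows)."""
    table = assign_factors(build_l8(), default_factors())
    return make_sample_sheet(
        table,
        default_cell_lines(),
        replicates={"CTRL_Male": 2},
        partial={"CTRL_Female": [1, 2, 3, 4]},
        seed=seed,
    )
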