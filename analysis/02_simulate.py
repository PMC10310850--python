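#!/usr/bin/env python
"""Generate every synthetic dataset the downstream stages consume.

Counts (2,000 genes x 44 samples, NB with dominant cell-line variance and
50 spiked genes per factor at log2FC 1), exon-bin counts with planted
usage switches, metabolite features with internal standards and a 1.5x
FH response, and a region x period expression matrix with a planted +2
shift. Ground truth is written next to each dataset.
"""

from pathlib import Path

from ffed import design as D
from ffed.io import write_bins, write_counts, write_sheet
from ffed.simulate import (
    SimulationConfig, metab_sample_sheet, simulate_counts,
    simulate_exon_counts, simulate_metabolites, simulate_spatiotemporal,
)

SEED = 11
OUT = Path("results/data")
OUT.mkdir(parents=True, exist_ok=True)

sheet = D.default_sample_sheet()
write_sheet(sheet, OUT / "sample_sheet.csv", {"seed": SEED})

cfg = SimulationConfig(n_genes=2000, seed=SEED)
gene_ids = cfg.gene_ids()
cfg.causal_sets = {
    f: {g: 1.0 for g in gene_ids[i * 50:(i + 1) * 50]}
    for i, f in enumerate(("Pb", "VPA", "BPA", "EtOH", "FH", "Zn-"))
}
counts, truth = simulate_counts(cfg, sheet)
write_counts(counts, OUT / "counts.tsv", {"seed": SEED})
truth.gene_effects.to_csv(OUT / "truth_gene_effects.tsv", sep="\t")
print(f"Counts: {counts.shape[0]} genes x {counts.shape[1]} samples, "
      f"{sum(len(v) for v in cfg.causal_sets.values())} spiked gene-factor effects")

deu_cfg = SimulationConfig(n_genes=60, seed=SEED + 1, cell_line_effect_sd=0.5,
                           baseline_log2_mean=8.0, baseline_log2_sd=1.0)
switch = deu_cfg.gene_ids()[:6]
bins, deu_truth = simulate_exon_counts(
    deu_cfg, sheet, switch_genes=switch, switch_factor="BPA", switch_fraction=0.3
)
write_bins(bins, OUT / "exon_bins.tsv", {"seed": SEED + 1})
deu_truth.exon_switches.to_csv(OUT / "truth_exon_switches.tsv", sep="\t", index=False)
print(f"Exon bins: {len(bins)} bins, usage switch planted in {len(switch)} genes")

msheet = metab_sample_sheet()
intens, is_map, m_truth = simulate_metabolites(SimulationConfig(seed=SEED + 2), msheet)
write_sheet(msheet, OUT / "metab_sheet.csv")
intens.rename_axis("feature").to_csv(OUT / "metab_intensities.csv")
is_map.to_csv(OUT / "metab_is_map.csv", index=False)
m_truth.metabolite_ratios.rename("ratio").to_csv(OUT / "truth_metab_ratios.csv")
print(f"Metabolites: {intens.shape[0]} features x {intens.shape[1]} samples "
      f"({int((m_truth.metabolite_ratios != 1).sum())} FH-responsive)")

genes = [f"g{i:03d}" for i in range(1, 401)]
expr, meta = simulate_spatiotemporal(
    400, enriched_group=(genes[:30], ["FC", "TC"], ["P1", "P2", "P3"], 2.0),
    seed=SEED + 3,
)
expr.rename_axis("gene").to_csv(OUT / "spatial_expression.tsv", sep="\t")
meta.to_csv(OUT / "spatial_meta.csv", index=False)
(OUT / "spatial_group.txt").write_text("\n".join(genes[:30]) + "\n")
print(f"Spatio-temporal matrix: {expr.shape[0]} genes x {expr.shape[1]} samples, "
      "+2 shift planted in FC/TC x P1-P3")
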