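"""Readers/writers for the pipeline's text formats and the umbrella workflow.

Formats: counts TSV (genes x samples), sample-sheet CSV, design CSV with
a YAML sidecar (factor assignment and doses), GMT gene-set collections,
RNK ranked lists, GFF3 gene models, exon-bin TSV, feature CSV,
expression TSV with metadata CSV, and GraphML (via networkx). Writers
prepend a ``#``-comment provenance header (config hash and seed) where
the format allows; readers skip comment lines, so write-then-read is the
identity on the canonical in-memory form. Malformed lines raise errors
naming the offending line number.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from ffed import design as design_mod
from ffed.deu import GeneModel

__all__ = [
    "read_counts", "write_counts",
    "read_sheet", "write_sheet",
    "read_design", "write_design",
    "read_gmt", "write_gmt",
    "read_rnk", "write_rnk",
    "read_gff3", "write_gff3",
    "read_bins", "write_bins",
    "read_graphml", "write_graphml",
    "PipelineConfig", "run_pipeline",
]


def _header(provenance: dict | None) -> str:
    if not provenance:
        return ""
    items = " ".join(f"{k}={v}" for k, v in provenance.items())
    return f"# {items}\n"


def write_counts(counts: pd.DataFrame, path, provenance: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(provenance))
        counts.rename_axis("gene").to_csv(fh, sep="\t")


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return df


def write_sheet(sheet: pd.DataFrame, path, provenance: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(provenance))
        sheet.to_csv(fh, index=False)


def read_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_design(table: design_mod.DesignTable, csv_path, yaml_path=None) -> None:
    """Design as run x factor CSV (entries -1/+1) plus a YAML sidecar with
    the column assignment, free columns and doses."""
    cols = {}
    for name, col in table.assignment.items():
        cols[name] = table.column(col)
    df = pd.DataFrame(cols)
    df.insert(0, "run", np.arange(1, table.n_runs + 1))
    df.to_csv(csv_path, index=False)
    if yaml_path is not None:
        side = {
            "assignment": {k: int(v) for k, v in table.assignment.items()},
            "free_columns": [int(c) for c in table.free_columns],
            "n_runs": int(table.n_runs),
            "factors": {
                name: {
                    "control_label": f.control_label,
                    "treated_label": f.treated_label,
                    "control_dose": list(f.control_dose),
                    "treated_dose": list(f.treated_dose),
                }
                for name, f in table.factors.items()
            },
        }
        Path(yaml_path).write_text(yaml.safe_dump(side, allow_unicode=True))


def read_design(csv_path, yaml_path) -> design_mod.DesignTable:
    side = yaml.safe_load(Path(yaml_path).read_text())
    table = design_mod.build_l8() if side["n_runs"] == 8 else None
    if table is None:
        raise ValueError("only the 8-run array is supported on read")
    factors = [
        design_mod.FactorSpec(
            name,
            control_label=spec["control_label"],
            treated_label=spec["treated_label"],
            control_dose=tuple(spec["control_dose"]),
            treated_dose=tuple(spec["treated_dose"]),
        )
        for name, spec in side["factors"].items()
    ]
    assigned = design_mod.assign_factors(table, factors, column_map=side["assignment"])
    df = pd.read_csv(csv_path)
    for name in assigned.assignment:
        expected = assigned.factor_column(name)
        if not (df[name].to_numpy() == expected).all():
            raise ValueError(f"design CSV column {name!r} disagrees with the sidecar")
    return assigned


def read_gmt(path) -> dict[str, set]:
    collection: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT lines need name, description, >=1 gene")
            name, _desc, *genes = parts
            if name in collection:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            collection[name] = set(g for g in genes if g)
    return collection


def write_gmt(collection: dict[str, set], path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_rnk(path) -> list[tuple[str, float]]:
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: RNK lines are gene<TAB>score")
            try:
                pairs.append((parts[0], float(parts[1])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad score {parts[1]!r}") from exc
    pairs.sort(key=lambda kv: (-kv[1], kv[0]))
    return pairs


def write_rnk(result: pd.DataFrame, path, metric: str = "stat",
              provenance: dict | None = None) -> None:
    """Export a ranked list from a differential-expression table.

    Default ranking metric: the Wald statistic, descending; NaN entries
    (untestable genes) are dropped.
    """
    ranked = result[metric].dropna().sort_values(ascending=False)
    with open(path, "w") as fh:
        fh.write(_header(provenance))
        for gene, score in ranked.items():
            fh.write(f"{gene}\t{score:.6g}\n")


def write_gff3(gene_models: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in gene_models:
            span = (
                min(s for ex in gm.transcripts.values() for s, _ in ex),
                max(e for ex in gm.transcripts.values() for _, e in ex),
            )
            fh.write(
                f"{gm.chrom}\tffed\tgene\t{span[0]}\t{span[1]}\t.\t{gm.strand}\t.\t"
                f"ID={gm.gene_id}\n"
            )
            for tx, exons in gm.transcripts.items():
                t0 = min(s for s, _ in exons)
                t1 = max(e for _, e in exons)
                fh.write(
                    f"{gm.chrom}\tffed\tmRNA\t{t0}\t{t1}\t.\t{gm.strand}\t.\t"
                    f"ID={tx};Parent={gm.gene_id}\n"
                )
                for s, e in sorted(exons):
                    fh.write(
                        f"{gm.chrom}\tffed\texon\t{s}\t{e}\t.\t{gm.strand}\t.\t"
                        f"Parent={tx}\n"
                    )


def _gff_attrs(field9: str) -> dict:
    out = {}
    for item in field9.strip().split(";"):
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def read_gff3(path) -> list[GeneModel]:
    """Minimal three-level (gene/mRNA/exon) GFF3 reader."""
    tx_parent: dict[str, str] = {}
    gene_meta: dict[str, tuple[str, str]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")
            a = _gff_attrs(attrs)
            if ftype == "gene":
                gene_meta[a["ID"]] = (chrom, strand)
            elif ftype in ("mRNA", "transcript"):
                tx_parent[a["ID"]] = a["Parent"]
            elif ftype == "exon":
                exons.setdefault(a["Parent"], []).append((start, end))
    models = []
    for gene, (chrom, strand) in gene_meta.items():
        txs = {tx: sorted(exons.get(tx, [])) for tx, parent in tx_parent.items()
               if parent == gene}
        models.append(GeneModel(gene, chrom, strand, txs))
    return models


def write_bins(bins: pd.DataFrame, path, provenance: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(provenance))
        bins.to_csv(fh, sep="\t")


def read_bins(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.set_index(["gene", "bin"])


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


# --------------------------------------------------------------------------
# umbrella workflow


@dataclass
class PipelineConfig:
    """End-to-end workflow configuration with the study's thresholds."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    n_genes: int = 2000
    n_causal_per_factor: int = 50
    effect_log2fc: float = 1.0
    include_blocking: bool = True  # block cell line in Level I/II fits
    padj_threshold: float = 0.05
    gsea_fdr_threshold: float = 0.05
    network_cutoff: float = 0.375
    deu_padj: float = 0.05
    deu_basemean: float = 10.0
    deu_lfc: float = 1.5
    background_basemean: float = 20.0
    n_perm_gsea: int = 1000
    n_perm_spatial: int = 2000
    factors: tuple = ("Pb", "VPA", "BPA", "EtOH", "FH", "Zn-")
    deu_n_genes: int = 80
    spatial_n_genes: int = 400

    def validate(self) -> None:
        for name in ("padj_threshold", "gsea_fdr_threshold", "network_cutoff",
                     "deu_padj"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]: {v}")
        if self.n_genes <= 0 or self.n_perm_gsea <= 0 or self.n_perm_spatial <= 0:
            raise ValueError("sizes and permutation counts must be positive")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.factors = tuple(cfg.factors)
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), allow_unicode=True))


def run_pipeline(config: PipelineConfig, dry_run: bool = False) -> dict:
    """Run the layered workflow on a fresh synthetic dataset.

    Stages: design + sample sheet; count simulation with planted main
    effects; differential expression Level I per factor (Level IV for
    the first aliased pair); RNK export and preranked enrichment of
    truth-derived and random gene sets; similarity network and its
    global metrics; differential exon usage on a planted switch;
    metabolite quantification and testing; spatio-temporal permutation
    enrichment. Every output carries the config hash and seed, and the
    returned report summarizes each stage.
    """
    from ffed import deu as deu_mod
    from ffed import dge as dge_mod
    from ffed import enrich as enrich_mod
    from ffed import metab as metab_mod
    from ffed import simulate as sim_mod
    from ffed import spatiotemporal as st_mod

    config.validate()
    if dry_run:
        return {"status": "config ok", "config_hash": config.config_hash()}

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"config_hash": config.config_hash(), "seed": config.seed}
    report: dict = {"provenance": dict(prov)}
    rng = np.random.default_rng(config.seed)

    # design and sheet
    table = design_mod.assign_factors(design_mod.build_l8(), design_mod.default_factors())
    sheet = design_mod.make_sample_sheet(
        table, design_mod.default_cell_lines(),
        replicates={"CTRL_Male": 2}, partial={"CTRL_Female": [1, 2, 3, 4]},
    )
    write_design(table, out / "design.csv", out / "design.yaml")
    write_sheet(sheet, out / "sample_sheet.csv", prov)
    pairs = design_mod.estimable_interactions(table)
    report["design"] = {
        "n_samples": len(sheet),
        "estimable_interactions": ["-".join(sorted(p)) for p in pairs],
    }

    # counts with planted effects
    sim_cfg = sim_mod.SimulationConfig(n_genes=config.n_genes, seed=config.seed)
    gene_ids = sim_cfg.gene_ids()
    causal: dict[str, dict[str, float]] = {}
    pool = list(gene_ids)
    rng.shuffle(pool)
    for i, f in enumerate(config.factors):
        chunk = pool[i * config.n_causal_per_factor:(i + 1) * config.n_causal_per_factor]
        causal[f] = {g: config.effect_log2fc for g in chunk}
    sim_cfg.causal_sets = causal
    counts, truth = sim_mod.simulate_counts(sim_cfg, sheet)
    write_counts(counts, out / "counts.tsv", prov)

    # differential expression, Level I per factor
    dge_summary = {}
    rnk_tables = {}
    for f in config.factors:
        res = dge_mod.run_level(
            counts, sheet, level="I", factor=f,
            include_blocking=config.include_blocking,
        )
        res.to_csv(out / f"dge_levelI_{f.replace('-', 'minus')}.tsv", sep="\t")
        sig = res[res["padj"] < config.padj_threshold]
        spiked = set(causal[f])
        dge_summary[f] = {
            "n_significant": int(len(sig)),
            "recovered_frac": float(len(spiked & set(sig.index)) / len(spiked)),
        }
        rnk_tables[f] = res
        write_rnk(res, out / f"levelI_{f.replace('-', 'minus')}.rnk", provenance=prov)
    report["dge_level_I"] = dge_summary

    try:
        pair = sorted(pairs[0])
        dge_mod.run_level(counts, sheet, level="IV", factor=pair)
        report["dge_level_IV"] = {"pair": "-".join(pair), "estimable": True}
    except dge_mod.RankDeficiencyError as exc:
        report["dge_level_IV"] = {"pair": "-".join(pair), "estimable": False,
                                  "error": str(exc)}

    # enrichment on truth-derived + random sets
    focus = config.factors[0]
    ranked = [(g, s) for g, s in rnk_tables[focus]["stat"].dropna()
              .sort_values(ascending=False).items()]
    collection = {f"{f}_response_targets": set(causal[f]) for f in config.factors}
    for i in range(6):
        collection[f"random_set_{i + 1}"] = set(
            rng.choice(gene_ids, size=config.n_causal_per_factor, replace=False)
        )
    write_gmt(collection, out / "genesets.gmt")
    enr = enrich_mod.gsea_significance(
        ranked, collection, n_perm=config.n_perm_gsea, seed=config.seed
    )
    enr.to_csv(out / "gsea.tsv", sep="\t")
    net = enrich_mod.build_similarity_network(
        enr, collection, q_threshold=config.gsea_fdr_threshold,
        cutoff=config.network_cutoff,
    )
    write_graphml(net, out / "network.graphml")
    metrics = enrich_mod.network_metrics(net)
    report["enrichment"] = {
        "n_sets_q_below_threshold": int((enr["q"] < config.gsea_fdr_threshold).sum()),
        "focus_set_q": float(enr.loc[f"{focus}_response_targets", "q"]),
        "network": asdict(metrics) if hasattr(metrics, "__dataclass_fields__")
        else metrics.__dict__,
    }

    # differential exon usage on a planted switch
    deu_cfg = sim_mod.SimulationConfig(
        n_genes=config.deu_n_genes, seed=config.seed + 1, cell_line_effect_sd=0.5,
        baseline_log2_mean=8.0, baseline_log2_sd=1.0,
    )
    switch = deu_cfg.gene_ids()[: max(4, config.deu_n_genes // 10)]
    bins, deu_truth = sim_mod.simulate_exon_counts(
        deu_cfg, sheet, switch_genes=switch, switch_factor="BPA",
        switch_fraction=0.3,
    )
    write_bins(bins, out / "exon_bins.tsv", prov)
    deu_res = deu_mod.test_deu(bins, sheet, level="I", factor="BPA")
    calls = deu_mod.call_deu_genes(
        deu_res, config.deu_padj, config.deu_basemean, config.deu_lfc
    )
    called = set(calls[calls["deu"]].index)
    report["deu"] = {
        "n_called": len(called),
        "recovered_frac": float(len(called & set(switch)) / len(switch)),
    }
    calls.to_csv(out / "deu_calls.tsv", sep="\t")

    # metabolites
    msheet = sim_mod.metab_sample_sheet()
    intens, is_map, m_truth = sim_mod.simulate_metabolites(
        sim_mod.SimulationConfig(seed=config.seed + 2), msheet
    )
    conc = metab_mod.quantify_table(intens, is_map)
    mres = metab_mod.test_metabolites(conc, msheet, level="global")
    mres.to_csv(out / "metabolites_global.tsv", sep="\t")
    truly = set(m_truth.metabolite_ratios[m_truth.metabolite_ratios != 1].index)
    sig_feats = set(
        mres[mres["padj"] < config.padj_threshold].index.get_level_values("feature")
    )
    report["metabolites"] = {
        "n_significant": len(sig_feats),
        "recovered_frac": float(len(sig_feats & truly) / len(truly)) if truly else 0.0,
    }

    # spatio-temporal enrichment
    st_genes = [f"g{i:03d}" for i in range(1, config.spatial_n_genes + 1)]
    group = st_genes[:30]
    expr, meta = sim_mod.simulate_spatiotemporal(
        n_genes=config.spatial_n_genes,
        enriched_group=(group, ["FC", "TC"], ["P1", "P2", "P3"], 2.0),
        seed=config.seed + 3,
    )
    expr_f, meta_f = st_mod.filter_samples(expr, meta)
    grid = st_mod.permutation_enrichment(
        expr_f, meta_f, group, n_perm=config.n_perm_spatial, seed=config.seed + 4
    )
    grid.to_csv(out / "spatiotemporal_grid.tsv", sep="\t", index=False)
    hot = grid[grid["padj"] < 0.05]
    report["spatiotemporal"] = {
        "n_enriched_cells": int(len(hot)),
        "target_cells_recovered": int(
            (hot["region"].isin(["FC", "TC"]) & hot["period"].isin(["P1", "P2", "P3"])).sum()
        ),
    }

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
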