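"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order: input parsing, synteny detection and
classification, GC3 metrics, copy-number classification, 5'-end
methylation, and the association statistics.  Every output file starts
with a provenance comment (package version, config hash, seed) and reruns
with identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from syngc import __version__
from syngc.assoc_stats import (
    compare_groups,
    correlate,
    cross_species_counts,
    gc3_50_distribution,
    go_enrichment,
    methylation_by_gc3_bins,
)
from syngc.copy_number import GenomeIndex, classify_copy_number
from syngc.formats_io import (
    GeneMetrics,
    read_anchor_pairs,
    read_gene_models,
    read_methylation_calls,
    write_gene_table,
)
from syngc.gc_metrics import PASS, compute_gc_table
from syngc.methylation import (
    aggregate_methylation_by_class,
    methylation_for_gene_set,
    write_class_summary_tsv,
)
from syngc.synteny import (
    ChainParams,
    classify_synteny,
    detect_synteny,
    synteny_summary_matrix,
    write_block_anchors_tsv,
    write_blocks_tsv,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("synteny", "metrics", "methylation", "stats")


class PipelineError(Exception):
    """A user-correctable configuration or input problem."""


@dataclass
class SpeciesInputs:
    gff3: str
    cds: str
    genome: Optional[str] = None
    allc: Optional[str] = None
    go: Optional[str] = None


@dataclass
class PipelineConfig:
    species: dict[str, SpeciesInputs]
    comparisons: list[dict]  # each: {a, b, anchors}
    chain: ChainParams = field(default_factory=ChainParams)
    region_len: int = 150
    copy_query_len: int = 150
    copy_min_identity: float = 0.90
    copy_min_coverage: float = 0.90
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.species:
            raise PipelineError("config declares no species")
        if not self.comparisons:
            raise PipelineError("config declares no comparisons")
        for comp in self.comparisons:
            for side in ("a", "b"):
                if comp[side] not in self.species:
                    raise PipelineError(
                        f"comparison references undeclared species {comp[side]!r}"
                    )

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = os.path.dirname(os.path.abspath(path))

        def resolve(p):
            return p if p is None or os.path.isabs(p) else os.path.join(base, p)

        species = {
            tag: SpeciesInputs(
                gff3=resolve(entry["gff3"]),
                cds=resolve(entry["cds"]),
                genome=resolve(entry.get("genome")),
                allc=resolve(entry.get("allc")),
                go=resolve(entry.get("go")),
            )
            for tag, entry in (raw.get("species") or {}).items()
        }
        comparisons = [
            {"a": c["a"], "b": c["b"], "anchors": resolve(c["anchors"])}
            for c in (raw.get("comparisons") or [])
        ]
        chain = ChainParams(**(raw.get("chain") or {}))
        return cls(
            species=species,
            comparisons=comparisons,
            chain=chain,
            region_len=int(raw.get("region_len", 150)),
            copy_query_len=int(raw.get("copy_query_len", 150)),
            copy_min_identity=float(raw.get("copy_min_identity", 0.90)),
            copy_min_coverage=float(raw.get("copy_min_coverage", 0.90)),
            seed=int(raw.get("seed", 0)),
        )

    def digest(self) -> str:
        payload = {
            "species": {t: vars(s) for t, s in sorted(self.species.items())},
            "comparisons": self.comparisons,
            "chain": vars(self.chain),
            "region_len": self.region_len,
            "copy_query_len": self.copy_query_len,
            "copy_min_identity": self.copy_min_identity,
            "copy_min_coverage": self.copy_min_coverage,
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def _check_inputs(config: PipelineConfig) -> None:
    for tag, sp in config.species.items():
        for name in ("gff3", "cds", "genome", "allc", "go"):
            path = getattr(sp, name)
            if path is not None and not os.path.exists(path):
                raise PipelineError(f"species {tag}: missing {name} file {path}")
    for comp in config.comparisons:
        if not os.path.exists(comp["anchors"]):
            raise PipelineError(
                f"comparison {comp['a']}-{comp['b']}: missing anchors file "
                f"{comp['anchors']}"
            )


def run_pipeline(
    config: PipelineConfig, outdir: str, stages: Optional[set[str]] = None
) -> dict:
    """Execute the analysis and write the result bundle to ``outdir``.

    ``stages`` restricts which outputs are written (upstream results are
    still computed when a requested stage depends on them).  Returns a
    dictionary with the in-memory results keyed by stage.
    """
    stages = set(stages or ALL_STAGES)
    _check_inputs(config)
    os.makedirs(outdir, exist_ok=True)
    header = f"# syngc {__version__} config={config.digest()} seed={config.seed}\n"

    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    gene_sets = {
        tag: read_gene_models(sp.gff3, sp.cds, tag)
        for tag, sp in config.species.items()
    }
    for tag, gs in gene_sets.items():
        log(f"{tag}: {len(gs)} genes on {len(gs.chrom_order)} chromosomes")

    results = []
    for comp in config.comparisons:
        tag = f"{comp['a']}-{comp['b']}"
        anchors = read_anchor_pairs(
            comp["anchors"], gene_sets[comp["a"]], gene_sets[comp["b"]]
        )
        res = detect_synteny(
            anchors, gene_sets[comp["a"]], gene_sets[comp["b"]], config.chain, tag
        )
        results.append(res)
        log(f"{tag}: {len(anchors)} anchors -> {len(res.blocks)} blocks")
        if "synteny" in stages:
            with open(os.path.join(outdir, f"blocks_{tag}.tsv"), "w") as fh:
                fh.write(header)
                write_blocks_tsv(
                    res.blocks, gene_sets[comp["a"]], gene_sets[comp["b"]], tag, fh
                )
            with open(os.path.join(outdir, f"block_anchors_{tag}.tsv"), "w") as fh:
                fh.write(header)
                write_block_anchors_tsv(res.blocks, tag, fh)

    statuses = {
        tag: classify_synteny(gs, results) for tag, gs in gene_sets.items()
    }
    if "synteny" in stages:
        matrix = synteny_summary_matrix(statuses)
        with open(os.path.join(outdir, "synteny_summary.tsv"), "w") as fh:
            fh.write(header)
            matrix.to_csv(fh, sep="\t", index_label="species")

    gc_tables = {tag: compute_gc_table(gs) for tag, gs in gene_sets.items()}

    copy_results: dict[str, dict] = {}
    if stages & {"metrics", "stats"}:
        for tag, sp in config.species.items():
            if sp.genome is None:
                continue
            index = GenomeIndex(_read_fasta(sp.genome))
            per_gene = {}
            for gid, gene in gene_sets[tag].genes.items():
                r = classify_copy_number(
                    gid, gene.cds, index,
                    config.copy_query_len, config.copy_min_identity,
                    config.copy_min_coverage,
                )
                if r is not None:
                    per_gene[gid] = r
            copy_results[tag] = per_gene
            log(f"{tag}: copy number classified for {len(per_gene)} genes")

    meth_results: dict[str, dict] = {}
    if stages & {"methylation", "stats"}:
        for tag, sp in config.species.items():
            if sp.allc is None:
                continue
            calls = read_methylation_calls(sp.allc)
            meth_results[tag] = methylation_for_gene_set(
                gene_sets[tag], calls, config.region_len
            )
            log(f"{tag}: methylation over {len(calls)} cytosine calls")

    metrics: dict[str, list[GeneMetrics]] = {}
    for tag, gs in gene_sets.items():
        rows = []
        for gid in sorted(gs.genes):
            gene = gs[gid]
            gc = gc_tables[tag][gid]
            cn = copy_results.get(tag, {}).get(gid)
            gm = meth_results.get(tag, {}).get(gid)
            rows.append(
                GeneMetrics(
                    gene_id=gid, species=tag, chrom=gene.chrom, ordinal=gene.ordinal,
                    syntenic=statuses[tag][gid].syntenic,
                    gc3_50=gc.gc3_50, gc3_full=gc.gc3_full,
                    copy_class=cn.copy_class if cn else None,
                    mCG=gm.mCG if gm else None,
                    mCHG=gm.mCHG if gm else None,
                    mCHH=gm.mCHH if gm else None,
                    filter_status=gc.filter_status,
                )
            )
        metrics[tag] = rows
        if stages & {"metrics", "methylation", "stats"}:
            with open(os.path.join(outdir, f"gene_metrics_{tag}.tsv"), "w") as fh:
                fh.write(header)
                write_gene_table(rows, fh)

    stats_out: dict[str, dict] = {}
    if "stats" in stages:
        stats_out = _run_stats(
            config, outdir, header, gene_sets, statuses, gc_tables,
            copy_results, meth_results,
        )

    with open(os.path.join(outdir, "run.log"), "w") as fh:
        fh.write(header)
        fh.write("\n".join(log_lines) + "\n")

    return {
        "gene_sets": gene_sets,
        "synteny": results,
        "statuses": statuses,
        "gc": gc_tables,
        "copy_number": copy_results,
        "methylation": meth_results,
        "metrics": metrics,
        "stats": stats_out,
    }


def _run_stats(
    config, outdir, header, gene_sets, statuses, gc_tables, copy_results, meth_results
):
    from syngc.methylation import CONTEXTS

    out: dict[str, dict] = {}
    comp_rows = []
    corr_rows = []
    enrich_rows_all = []

    for tag, gs in gene_sets.items():
        gc = gc_tables[tag]
        passing = {g: r.gc3_50 for g, r in gc.items() if r.filter_status == PASS}
        syn_vals = [v for g, v in passing.items() if statuses[tag][g].syntenic]
        non_vals = [v for g, v in passing.items() if not statuses[tag][g].syntenic]
        species_stats: dict = {}
        if syn_vals and non_vals:
            cmp_res = compare_groups(
                syn_vals, non_vals, "syntenic", "non-syntenic", mode="normal-approx"
            )
            species_stats["synteny_gc3_50"] = cmp_res
            comp_rows.append((tag, "gc3_50", cmp_res))

        if tag in copy_results:
            by_class: dict[str, list[float]] = {}
            for g, v in passing.items():
                cn = copy_results[tag].get(g)
                if cn is not None:
                    by_class.setdefault(cn.copy_class, []).append(v)
            present = [c for c in ("single", "moderate", "repetitive") if by_class.get(c)]
            for i, cx in enumerate(present):
                for cy in present[i + 1:]:
                    r = compare_groups(by_class[cx], by_class[cy], cx, cy,
                                       mode="normal-approx")
                    comp_rows.append((tag, "gc3_50_copy", r))
            species_stats["copy_gc3_50"] = {c: by_class.get(c, []) for c in present}

        if tag in meth_results:
            gms = meth_results[tag]
            labels = {
                g: ("syntenic" if statuses[tag][g].syntenic else "non-syntenic")
                for g in gs.genes
            }
            species_stats["meth_by_synteny"] = aggregate_methylation_by_class(gms, labels)
            with open(os.path.join(outdir, f"meth_by_synteny_{tag}.tsv"), "w") as fh:
                fh.write(header)
                write_class_summary_tsv(species_stats["meth_by_synteny"], fh)
            if tag in copy_results:
                clabels = {
                    g: r.copy_class for g, r in copy_results[tag].items()
                }
                species_stats["meth_by_copy"] = aggregate_methylation_by_class(gms, clabels)
                with open(os.path.join(outdir, f"meth_by_copy_{tag}.tsv"), "w") as fh:
                    fh.write(header)
                    write_class_summary_tsv(species_stats["meth_by_copy"], fh)

            for ctx in CONTEXTS:
                pairs = [
                    (passing[g], gms[g].levels.get(ctx))
                    for g in passing
                    if g in gms and gms[g].levels.get(ctx) is not None
                ]
                if len(pairs) >= 3:
                    x = [p[0] for p in pairs]
                    y = [p[1] for p in pairs]
                    for method in ("pearson", "spearman"):
                        r, p = correlate(x, y, method)
                        corr_rows.append((tag, ctx, method, r, p, len(pairs)))

            curves = []
            for ctx in CONTEXTS:
                curves.extend(methylation_by_gc3_bins(gms, passing, ctx))
            species_stats["binned_curves"] = curves
            with open(os.path.join(outdir, f"meth_by_gc3_bins_{tag}.tsv"), "w") as fh:
                fh.write(header)
                fh.write("bin_pct\tcontext\tmean_level\tn_genes\tn_context_sites\tshown\n")
                for c in curves:
                    lvl = "NA" if c.mean_level is None else f"{c.mean_level:.4f}"
                    fh.write(
                        f"{c.bin_pct}\t{c.context}\t{lvl}\t{c.n_genes}\t"
                        f"{c.n_context_sites}\t{int(c.shown)}\n"
                    )

        hist = gc3_50_distribution(
            passing,
            {
                g: ("syntenic" if statuses[tag][g].syntenic else "non-syntenic")
                for g in passing
            },
        )
        species_stats["gc3_histogram"] = hist
        with open(os.path.join(outdir, f"gc3_50_hist_{tag}.tsv"), "w") as fh:
            fh.write(header)
            hist.to_csv(fh, sep="\t")

        sp = config.species[tag]
        if sp.go is not None:
            go_map: dict[str, list[str]] = {}
            with open(sp.go) as fh:
                for line in fh:
                    if not line.strip() or line.startswith("#"):
                        continue
                    gid, term = line.rstrip("\n").split("\t")[:2]
                    go_map.setdefault(gid, []).append(term)
            rows = go_enrichment(go_map, statuses[tag], tag)
            enrich_rows_all.extend(rows)
            species_stats["go_enrichment"] = rows

        out[tag] = species_stats

    with open(os.path.join(outdir, "comparisons.tsv"), "w") as fh:
        fh.write(header)
        fh.write(
            "species\tmetric\tgroup_x\tgroup_y\tn_x\tn_y\tmean_x\tmean_y\t"
            "median_x\tmedian_y\tmean_difference\tstatistic\tp_value\tmode\n"
        )
        for tag, metric, r in comp_rows:
            fh.write(
                f"{tag}\t{metric}\t{r.group_x}\t{r.group_y}\t{r.n_x}\t{r.n_y}\t"
                f"{r.mean_x:.4f}\t{r.mean_y:.4f}\t{r.median_x:.4f}\t{r.median_y:.4f}\t"
                f"{r.mean_difference:.4f}\t{r.statistic:.1f}\t{r.p_value:.3e}\t{r.mode}\n"
            )
    with open(os.path.join(outdir, "correlations.tsv"), "w") as fh:
        fh.write(header)
        fh.write("species\tcontext\tmethod\tr\tp_value\tn\n")
        for tag, ctx, method, r, p, n in corr_rows:
            rs = "NA" if r is None else f"{r:.4f}"
            ps = "NA" if p is None else f"{p:.3e}"
            fh.write(f"{tag}\t{ctx}\t{method}\t{rs}\t{ps}\t{n}\n")
    if enrich_rows_all:
        with open(os.path.join(outdir, "go_enrichment.tsv"), "w") as fh:
            fh.write(header)
            fh.write(
                "species\tgo_term\ta\tb\tc\td\tdirection\tp_value\tp_adjusted\t"
                "significant\n"
            )
            for r in enrich_rows_all:
                fh.write(
                    f"{r.species}\t{r.go_term}\t{r.a}\t{r.b}\t{r.c}\t{r.d}\t"
                    f"{r.direction}\t{r.p_value:.3e}\t{r.p_adjusted:.3e}\t"
                    f"{int(r.significant)}\n"
                )
        counts = cross_species_counts(enrich_rows_all)
        with open(os.path.join(outdir, "go_cross_species.tsv"), "w") as fh:
            fh.write(header)
            counts.to_csv(fh, sep="\t", index=False)
        out["go_cross_species"] = counts

    return out


def fixture_run_config(fixture_dir: str, seed: int = 0) -> PipelineConfig:
    """Pipeline config wired to a directory written by the simulator."""
    def p(name: str) -> str:
        return os.path.join(fixture_dir, name)

    species = {}
    for tag in ("A", "B"):
        go = p(f"go_{tag}.tsv")
        species[tag] = SpeciesInputs(
            gff3=p(f"genes_{tag}.gff3"),
            cds=p(f"cds_{tag}.fa"),
            genome=p(f"genome_{tag}.fa"),
            allc=p(f"allc_{tag}.tsv"),
            go=go if os.path.exists(go) else None,
        )
    return PipelineConfig(
        species=species,
        comparisons=[{"a": "A", "b": "B", "anchors": p("anchors_A_B.tsv")}],
        seed=seed,
    )
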