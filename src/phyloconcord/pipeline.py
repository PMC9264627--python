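"""Orchestration: species phylogeny, gene ranking, consensus, HVR/masking,
HGT screening, saturation curves and report emission.

The pipeline mirrors a core-genome concordance study: build the species
phylogeny from the concatenation of single-copy core genes that passed
external recombination/HGT screens, estimate one tree per gene, rank genes by
clade concordance with the species phylogeny, cross-check against a
majority-rule extended consensus of the gene trees, analyse the 16S-like
locus (hypervariable regions, 10% entropy masking), screen the multi-copy
operon for monophyly violations, and fit the concordance-vs-SNP-count curve.

Recombination/HGT verdicts are *inputs* (an :class:`ExclusionTable`), never
computed here; on synthetic data the generator's truth record stands in for
the external screening programs.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .alignment import (
    Alignment,
    concatenate,
    count_snps,
    default_hvr_regions,
    entropy_mask,
    extract_region,
    extract_snp_category,
)
from .estimate import Estimator, nj_estimator
from .hgt import detect_hgt_monophyly, tabulate_copy_number
from .simulate import SimulationConfig, simulate_dataset
from .snp_curve import (
    cross_validate_select,
    invert_for_target,
    predict_at,
    subsample_curve,
)
from .trees import (
    ConcordanceResult,
    concordance,
    majority_rule_extended_consensus,
    write_newick,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExclusionTable",
    "build_species_phylogeny",
    "rank_genes",
    "consensus_check",
    "go_term_concordance",
    "run_pipeline",
    "PipelineResult",
]

_VERDICTS = {"pos", "neg", "NA"}


@dataclass
class ExclusionTable:
    """Per-gene recombination/HGT verdicts: phi, sbp, hgt in {pos, neg, NA}.

    A gene positive for *any* test is excluded from the species-phylogeny
    concatenation; NA (e.g. too few informative sites to run a test) does not
    exclude.
    """

    verdicts: dict[str, dict[str, str]]  # gene_id -> {phi, sbp, hgt}

    def __post_init__(self):
        for gene, v in self.verdicts.items():
            bad = set(v.values()) - _VERDICTS
            if bad:
                raise ValueError(f"bad verdicts for {gene}: {sorted(bad)}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExclusionTable":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("NA")
        return cls({
            r["gene_id"]: {"phi": r["phi"], "sbp": r["sbp"], "hgt": r["hgt"]}
            for _, r in df.iterrows()
        })

    def to_tsv(self, path: str | Path) -> None:
        rows = [{"gene_id": g, **v} for g, v in sorted(self.verdicts.items())]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def validate_against(self, gene_ids: Sequence[str]) -> None:
        unknown = sorted(set(self.verdicts) - set(gene_ids))
        if unknown:
            raise ValueError(f"exclusion table names unknown genes: {unknown}")

    def exclusion_reason(self, gene_id: str) -> str | None:
        v = self.verdicts.get(gene_id)
        if not v:
            return None
        positive = sorted(t for t, verdict in v.items() if verdict == "pos")
        return "+".join(positive) + " positive" if positive else None


def build_species_phylogeny(
    genes: Mapping[str, Alignment],
    estimator: Estimator,
    exclusions: ExclusionTable | None = None,
) -> tuple[dendropy.Tree, list[str], dict[str, str]]:
    """Concatenate included genes and estimate the species phylogeny.

    Returns (tree, included gene ids, excluded gene id -> reason).
    """
    if exclusions is not None:
        exclusions.validate_against(list(genes))
    included, excluded = [], {}
    for name in sorted(genes):
        reason = exclusions.exclusion_reason(name) if exclusions else None
        if reason:
            excluded[name] = reason
            logger.info("excluding %s from concatenation: %s", name, reason)
        else:
            included.append(name)
    if not included:
        raise ValueError("all genes excluded; nothing to concatenate")
    concat = concatenate([genes[n] for n in included], names=included)
    return estimator(concat), included, excluded


def rank_genes(
    genes: Mapping[str, Alignment],
    species_tree: dendropy.Tree,
    estimator: Estimator,
    exclusions: ExclusionTable | None = None,
    categories: Mapping[str, str] | None = None,
    consensus_tree: dendropy.Tree | None = None,
) -> tuple[pd.DataFrame, dict[str, dendropy.Tree]]:
    """Per-gene tree, concordance and dense rank.

    Genes are ranked on concordance with the species tree, descending; equal
    concordance shares a rank (dense ranking) and rows order lexicographically
    by gene id within a rank.  Excluded genes still get a tree and a
    concordance but no rank.  If a consensus tree is supplied, concordance
    with it is reported alongside (the paired-dots layout of a
    species-vs-consensus comparison).
    """
    if not genes:
        raise ValueError("no genes to rank")
    trees: dict[str, dendropy.Tree] = {}
    rows = []
    for name in sorted(genes):
        aln = genes[name]
        reason = exclusions.exclusion_reason(name) if exclusions else None
        try:
            tree = estimator(aln)
            conc = concordance(species_tree, tree).concordance
        except ValueError as exc:
            logger.warning("gene %s: tree estimation failed (%s)", name, exc)
            tree, conc = None, np.nan
        if tree is not None:
            trees[name] = tree
        row = {
            "gene_id": name,
            "category": (categories or {}).get(name, ""),
            "length": aln.length,
            "snp_count": count_snps(aln),
            "concordance": conc,
            "excluded": bool(reason),
            "reason": reason or "",
        }
        if consensus_tree is not None and tree is not None:
            row["consensus_concordance"] = concordance(
                consensus_tree, tree).concordance
        rows.append(row)
    df = pd.DataFrame(rows)
    ranked = df[~df["excluded"] & df["concordance"].notna()].copy()
    levels = sorted(ranked["concordance"].unique(), reverse=True)
    level_rank = {c: i + 1 for i, c in enumerate(levels)}
    df["rank"] = [
        level_rank.get(c) if not exc and pd.notna(c) else None
        for c, exc in zip(df["concordance"], df["excluded"])
    ]
    df = df.sort_values(
        ["concordance", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return df, trees


def consensus_check(
    gene_trees: Sequence[dendropy.Tree], species_tree: dendropy.Tree
) -> tuple[ConcordanceResult, dendropy.Tree]:
    """Concordance of the species tree's clades with the gene-tree consensus."""
    if not gene_trees:
        raise ValueError("no gene trees")
    cons = majority_rule_extended_consensus(list(gene_trees))
    return concordance(species_tree, cons), cons


def go_term_concordance(
    gene_terms: Mapping[str, Mapping[str, set[str]]],
    gene_concordance: Mapping[str, Mapping[str, float]],
) -> pd.DataFrame:
    """Universal-term concordance aggregation across datasets.

    ``gene_terms[dataset][gene]`` is the set of functional terms annotated to
    a gene; ``gene_concordance[dataset][gene]`` its concordance.  A term is
    *universal* when it is assigned to at least one gene in every dataset;
    only universal terms are reported.  Each term's concordance is averaged
    over its genes within each dataset, then grand-averaged across datasets
    and ranked (dense) on the grand mean.
    """
    if not gene_terms:
        raise ValueError("need at least one dataset")
    per_dataset_terms = {
        ds: set().union(*genes.values()) if genes else set()
        for ds, genes in gene_terms.items()
    }
    universal = set.intersection(*per_dataset_terms.values())
    rows = []
    for term in sorted(universal):
        means = {}
        for ds, genes in gene_terms.items():
            vals = [
                gene_concordance[ds][g]
                for g, terms in genes.items()
                if term in terms and g in gene_concordance.get(ds, {})
            ]
            means[ds] = float(np.mean(vals)) if vals else np.nan
        rows.append({
            "term": term,
            **{f"mean_{ds}": m for ds, m in sorted(means.items())},
            "grand_mean": float(np.nanmean(list(means.values()))),
        })
    df = pd.DataFrame(rows)
    if len(df):
        levels = sorted(df["grand_mean"].unique(), reverse=True)
        level_rank = {v: i + 1 for i, v in enumerate(levels)}
        df["rank"] = df["grand_mean"].map(level_rank)
        df = df.sort_values(["grand_mean", "term"],
                            ascending=[False, True]).reset_index(drop=True)
    return df


@dataclass
class PipelineResult:
    outdir: Path
    report_paths: list[Path] = field(default_factory=list)
    species_tree: dendropy.Tree | None = None
    consensus_tree: dendropy.Tree | None = None
    gene_report: pd.DataFrame | None = None
    curve_fit: dict | None = None


def _truth_exclusions(dataset) -> ExclusionTable:
    """Exclusion verdicts derived from the generator's truth record.

    Plays the role of the external recombination screens on synthetic data:
    genes carrying a planted breakpoint are marked sbp-positive.
    """
    recomb = {e["gene"] for e in dataset.truth.events
              if e["type"] == "recombination"}
    return ExclusionTable({
        name: {
            "phi": "neg",
            "sbp": "pos" if name in recomb else "neg",
            "hgt": "neg",
        }
        for name in dataset.genes
    })


def run_pipeline(
    config: SimulationConfig,
    outdir: str | Path,
    estimator: Estimator | None = None,
    exclusions: ExclusionTable | None = None,
    curve_sizes: Sequence[int] | None = None,
    gene_terms: Mapping[str, Mapping[str, set[str]]] | None = None,
) -> PipelineResult:
    """Run the full analysis on a simulated dataset and emit reports.

    Deterministic given the configuration (which carries the seed): report
    files hash identically across reruns.  Stage timings go to the log file
    and stderr only, never into report artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    estimator = estimator or nj_estimator()
    result = PipelineResult(outdir=outdir)
    log_lines: list[str] = []
    t_start = time.perf_counter()

    def stage(name: str):
        dt = time.perf_counter() - t_start
        line = f"[{dt:8.2f}s] {name}"
        print(line, file=sys.stderr)
        log_lines.append(line)

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        result.report_paths.append(path)
        return path

    stage("simulate dataset")
    ds = simulate_dataset(config)
    ds.write(outdir / "inputs")
    if exclusions is None:
        exclusions = _truth_exclusions(ds)
    emit("exclusions.tsv", exclusions.to_tsv)

    stage("species phylogeny")
    # the multi-copy operon never enters the concatenation; the single-copy
    # rRNA locus is analysed per-gene but the species tree uses coding genes
    coding = {n: a for n, a in ds.genes.items() if not n.startswith("rrna")}
    coding_excl = ExclusionTable({g: v for g, v in exclusions.verdicts.items()
                                  if g in coding})
    species_tree, included, excluded = build_species_phylogeny(
        coding, estimator, coding_excl)
    result.species_tree = species_tree
    emit("species_tree.nwk",
         lambda p: Path(p).write_text(write_newick(species_tree) + "\n"))

    stage("gene ranking + consensus")
    report, gene_trees = rank_genes(
        ds.genes, species_tree, estimator,
        exclusions=exclusions, categories=ds.categories)
    included_trees = [gene_trees[n] for n in sorted(gene_trees)
                      if n in included]
    cons_result, cons_tree = consensus_check(included_trees, species_tree)
    result.consensus_tree = cons_tree
    emit("consensus_tree.nwk",
         lambda p: Path(p).write_text(write_newick(cons_tree,
                                                   branch_lengths=False) + "\n"))
    def _vs_consensus(g: str) -> float:
        if g not in gene_trees:
            return np.nan
        try:
            return concordance(cons_tree, gene_trees[g]).concordance
        except ValueError:  # consensus collapsed to a star
            return np.nan

    report["consensus_concordance"] = [
        _vs_consensus(g) for g in report["gene_id"]
    ]
    result.gene_report = report
    emit("gene_report.tsv",
         lambda p: report.to_csv(p, sep="\t", index=False))
    emit("consensus_check.json", lambda p: Path(p).write_text(json.dumps({
        "reference_clades": cons_result.reference_clades,
        "shared": cons_result.shared,
        "concordance": cons_result.concordance,
    }, indent=2)))

    stage("16S hypervariable regions + masking")
    rrna_name = next((n for n in sorted(ds.genes) if n.startswith("rrna")), None)
    if rrna_name is not None:
        rrna = ds.genes[rrna_name]
        ref_id = rrna.ids[0]
        hvr_rows = []
        for region in default_hvr_regions(ref_id):
            sub = extract_region(rrna, region)
            row = {"region": region.name, "start": region.start,
                   "end": region.end, "length": sub.length,
                   "snp_count": count_snps(sub)}
            try:
                row["concordance"] = concordance(
                    species_tree, estimator(sub)).concordance
            except ValueError:
                row["concordance"] = np.nan
            hvr_rows.append(row)
        emit("hvr_report.tsv", lambda p: pd.DataFrame(hvr_rows)
             .to_csv(p, sep="\t", index=False))

        masked = entropy_mask(rrna, 0.10)
        mask_rows = [{
            "alignment": rrna_name,
            "fraction": 0.10,
            "columns_masked": len(masked.masked_columns),
            "snps_before": count_snps(rrna),
            "snps_after": count_snps(masked.alignment),
            "concordance_before": concordance(
                species_tree, estimator(rrna)).concordance,
            "concordance_after": concordance(
                species_tree, estimator(masked.alignment)).concordance,
        }]
        emit("mask_report.tsv", lambda p: pd.DataFrame(mask_rows)
             .to_csv(p, sep="\t", index=False))

    stage("operon HGT screen")
    operon_tree = estimator(ds.operon_alignment)
    emit("operon_tree.nwk",
         lambda p: Path(p).write_text(write_newick(operon_tree) + "\n"))
    hgt_report = detect_hgt_monophyly(operon_tree, ds.species_map)
    emit("hgt_report.json", hgt_report.to_json)
    emit("hgt_report.tsv", lambda p: hgt_report.to_frame()
         .to_csv(p, sep="\t", index=False))
    copies = tabulate_copy_number([ds.species_map])
    emit("copy_number.tsv", lambda p: copies.per_species
         .to_csv(p, sep="\t", index=False))
    emit("copy_number_histogram.tsv", lambda p: copies.histogram_frame()
         .to_csv(p, sep="\t", index=False))

    stage("concordance-vs-SNP curve")
    names = sorted(ds.genes)
    snp_matrix = extract_snp_category(
        [ds.genes[n] for n in names], [ds.annotations[n] for n in names],
        "core")
    if curve_sizes is None:
        top = min(250, snp_matrix.length)
        curve_sizes = np.unique(
            np.linspace(5, top, 20).astype(int)).tolist()
    curve = subsample_curve(snp_matrix, curve_sizes, seed=config.seed,
                            estimator=estimator, reference=species_tree,
                            category="core")
    emit("curve.tsv", lambda p: curve.to_frame()
         .to_csv(p, sep="\t", index=False))
    fit = cross_validate_select(curve, k=5, seed=config.seed)
    fit_payload = fit.to_dict()
    try:
        fit_payload["x_at_80"] = invert_for_target(fit, 0.80)
    except ValueError as exc:
        fit_payload["x_at_80"] = None
        logger.info("curve not invertible at 80%%: %s", exc)
    fit_payload["y_at_266"] = predict_at(fit, 266)
    result.curve_fit = fit_payload
    emit("curve_fit.json",
         lambda p: Path(p).write_text(json.dumps(fit_payload, indent=2)))

    if gene_terms is not None:
        stage("GO-term aggregation")
        conc_map = {
            ds_name: dict(zip(result.gene_report["gene_id"],
                              result.gene_report["concordance"]))
            for ds_name in gene_terms
        }
        go = go_term_concordance(gene_terms, conc_map)
        emit("go_report.tsv", lambda p: go.to_csv(p, sep="\t", index=False))

    stage("done")
    (outdir / "log.txt").write_text("\n".join(log_lines) + "\n")
    return result
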