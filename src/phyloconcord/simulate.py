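"""Synthetic sequence-evolution generator with planted-event ground truth.

Emulates the statistical structure a concordance analysis sees in bacterial
core genomes: a known species tree; core genes of heterogeneous length and
rate (non-ribosomal genes roughly twice as long as coding-ribosomal ones);
an rRNA-like locus dominated by invariant sites; a multi-copy rRNA operon
with small within-genome divergence; and, on request, planted inter-species
copy transfers and segmental recombination, each echoed in a truth record.

Sequences evolve under the Jukes-Cantor substitution process along the tree's
branch lengths scaled by a per-locus rate; a configurable fraction of sites
is frozen invariant before evolution starts.  Everything is deterministic
given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .alignment import Alignment, SiteAnnotation, count_snps
from .hgt import LeafSpeciesMap
from .trees import parse_newick, write_newick

__all__ = [
    "GeneSpec",
    "OperonSpec",
    "HGTEventSpec",
    "RecombinationEventSpec",
    "SimulationConfig",
    "SimTruth",
    "SimDataset",
    "simulate_species_tree",
    "evolve_alignment",
    "simulate_operon_copies",
    "inject_hgt",
    "inject_recombination",
    "spr_move",
    "simulate_dataset",
    "default_config",
    "demo_config",
]

_BASES = np.array(["A", "C", "G", "T"])
_SEED_MOD = 2**31 - 1


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, _SEED_MOD))


# ---------------------------------------------------------------------------
# species trees


class _Lineage:
    __slots__ = ("birth", "length", "children", "label")

    def __init__(self, birth: float):
        self.birth = birth
        self.length = 0.0
        self.children: list["_Lineage"] = []
        self.label: str | None = None


def _emit(node: _Lineage) -> str:
    if not node.children:
        return f"{node.label}:{node.length:.10g}"
    inner = ",".join(_emit(c) for c in node.children)
    return f"({inner}):{node.length:.10g}"


def simulate_species_tree(
    n: int,
    model: str = "yule",
    seed: int = 0,
    birth_rate: float = 1.0,
    min_branch: float = 0.0,
) -> dendropy.Tree:
    """Simulate a rooted binary ultrametric species tree with n >= 4 tips.

    ``model="yule"``: pure-birth process with the stated birth rate,
    conditioned on n tips, with an extra exponential interval after the last
    split so every terminal branch is positive; the expected root-to-tip
    depth is (1/lambda) * sum_{k=2}^{n} 1/k.  ``model="coalescent"``:
    Kingman coalescent with unit population size (expected depth
    2 * (1 - 1/n)).  Tips are labelled sp01..spNN left to right.

    ``min_branch`` > 0 resamples (deterministically) until every branch is at
    least that long — expressing that recognised species are separated by a
    minimum divergence, the precondition for screening multi-copy loci whose
    within-genome heterogeneity must stay small against between-species
    distances.  Note this conditions the process, so depth expectations above
    hold only for ``min_branch=0``.
    """
    if n < 4:
        raise ValueError("need n >= 4 species")
    if min_branch > 0.0:
        attempt_rng = np.random.default_rng(seed)
        for _ in range(1000):
            t = simulate_species_tree(n, model, seed=_child_seed(attempt_rng),
                                      birth_rate=birth_rate)
            lengths = [e.length for e in t.preorder_edge_iter()
                       if e.length is not None]
            if min(lengths) >= min_branch:
                return t
        raise RuntimeError(
            f"could not draw a tree with min branch {min_branch} "
            f"in 1000 attempts"
        )
    rng = np.random.default_rng(seed)
    if model == "yule":
        t = 0.0
        root = _Lineage(0.0)
        a, b = _Lineage(0.0), _Lineage(0.0)
        root.children = [a, b]
        active = [a, b]
        while len(active) < n:
            k = len(active)
            t += rng.exponential(1.0 / (k * birth_rate))
            idx = int(rng.integers(0, k))
            parent = active.pop(idx)
            parent.length = t - parent.birth
            c1, c2 = _Lineage(t), _Lineage(t)
            parent.children = [c1, c2]
            active.extend([c1, c2])
        t += rng.exponential(1.0 / (n * birth_rate))
        for leaf in active:
            leaf.length = t - leaf.birth
    elif model == "coalescent":
        # backwards in time: tips at 0, merge random pairs
        t = 0.0
        active = [_Lineage(0.0) for _ in range(n)]
        while len(active) > 1:
            k = len(active)
            t += rng.exponential(2.0 / (k * (k - 1)))
            i, j = sorted(rng.choice(k, size=2, replace=False).tolist())
            b_ = active.pop(j)
            a_ = active.pop(i)
            a_.length = t - a_.birth
            b_.length = t - b_.birth
            parent = _Lineage(t)
            parent.children = [a_, b_]
            active.append(parent)
        root = active[0]
        root.length = 0.0
    else:
        raise ValueError(f"unknown tree model {model!r}")

    width = max(2, len(str(n)))
    counter = iter(range(1, n + 1))

    def label_leaves(node: _Lineage) -> None:
        if not node.children:
            node.label = f"sp{next(counter):0{width}d}"
        for c in node.children:
            label_leaves(c)

    label_leaves(root)
    inner = ",".join(_emit(c) for c in root.children)
    return parse_newick(f"({inner});")


# ---------------------------------------------------------------------------
# sequence evolution


def _jc_prob(expected_subs: float) -> float:
    """Probability a site differs after expected_subs substitutions/site."""
    return 0.75 * (1.0 - np.exp(-4.0 * expected_subs / 3.0))


def evolve_alignment(
    tree: dendropy.Tree,
    length: int,
    rate: float,
    invariant_fraction: float = 0.0,
    seed: int = 0,
) -> Alignment:
    """Evolve one alignment along a tree under Jukes-Cantor.

    The root sequence is uniform over A/C/G/T; a seeded ``invariant_fraction``
    of sites is frozen before evolution; the remaining sites change along
    each branch with probability (3/4)(1 - exp(-4 r t / 3)) where t is the
    branch length and r the per-locus rate, substituting to one of the three
    other bases uniformly.  Output rows are sorted by leaf label.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if not 0.0 <= invariant_fraction <= 1.0:
        raise ValueError("invariant_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    variable = rng.random(length) >= invariant_fraction
    root_seq = rng.integers(0, 4, size=length)
    seqs: dict[str, np.ndarray] = {}

    def descend(node: dendropy.Node, seq: np.ndarray) -> None:
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            p = _jc_prob(rate * t)
            child_seq = seq.copy()
            hit = (rng.random(length) < p) & variable
            k = int(hit.sum())
            if k:
                child_seq[hit] = (child_seq[hit]
                                  + rng.integers(1, 4, size=k)) % 4
            if child.is_leaf():
                seqs[child.taxon.label] = child_seq
            else:
                descend(child, child_seq)

    descend(tree.seed_node, root_seq)
    ids = sorted(seqs)
    data = np.stack([_BASES[seqs[i]] for i in ids])
    return Alignment(ids=ids, data=data)


# ---------------------------------------------------------------------------
# operons and planted events


def simulate_operon_copies(
    tree: dendropy.Tree,
    copy_range: tuple[int, int],
    intragenomic_divergence: float,
    length: int = 1542,
    rate: float = 0.15,
    invariant_fraction: float = 0.83,
    seed: int = 0,
) -> tuple[Alignment, LeafSpeciesMap]:
    """Simulate a multi-copy locus: species x copy leaves on an expanded tree.

    Each species receives a seeded copy count uniform over ``copy_range``;
    copies hang off the species tip on branches sized so the expected
    copy-to-copy divergence equals ``intragenomic_divergence`` substitutions
    per site (at variable sites).  Leaf labels are ``species|copyN``.
    """
    lo, hi = copy_range
    if not 1 <= lo <= hi:
        raise ValueError(f"bad copy range {copy_range}")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    rng = np.random.default_rng(seed)
    t = parse_newick(write_newick(tree))
    copy_bl = intragenomic_divergence / (2.0 * rate)
    mapping: dict[str, str] = {}
    for leaf in sorted(t.leaf_node_iter(), key=lambda n: n.taxon.label):
        sp = leaf.taxon.label
        k = int(rng.integers(lo, hi + 1))
        if k == 1:
            leaf.taxon.label = f"{sp}|copy1"
            mapping[f"{sp}|copy1"] = sp
            continue
        leaf.taxon = None
        for i in range(1, k + 1):
            label = f"{sp}|copy{i}"
            child = leaf.new_child(edge_length=copy_bl)
            child.taxon = t.taxon_namespace.new_taxon(label=label)
            mapping[label] = sp
    expanded = parse_newick(write_newick(t))
    aln = evolve_alignment(expanded, length, rate, invariant_fraction,
                           seed=_child_seed(rng))
    return aln, LeafSpeciesMap(mapping)


def inject_hgt(
    operon_aln: Alignment,
    species_map: LeafSpeciesMap,
    donor: str,
    recipient: str,
    copy_index: int,
    seed: int = 0,
    perturb_rate: float = 0.005,
) -> tuple[Alignment, dict]:
    """Plant one inter-species copy transfer into an operon alignment.

    The recipient's chosen copy is overwritten with the donor's first copy,
    lightly perturbed (JC at ``perturb_rate`` expected substitutions/site) so
    the transferred copy is similar but not identical to its source.
    """
    if donor == recipient:
        raise ValueError("donor and recipient must differ")
    donor_leaf = f"{donor}|copy1"
    rec_leaf = f"{recipient}|copy{copy_index}"
    for leaf, who in ((donor_leaf, donor), (rec_leaf, recipient)):
        if leaf not in operon_aln.ids:
            raise ValueError(f"unknown species/copy: {leaf!r} (species {who!r})")
    rng = np.random.default_rng(seed)
    data = operon_aln.data.copy()
    src = data[operon_aln.ids.index(donor_leaf)].copy()
    p = _jc_prob(perturb_rate)
    hit = rng.random(len(src)) < p
    if hit.any():
        codes = np.searchsorted(_BASES, src[hit])
        src[hit] = _BASES[(codes + rng.integers(1, 4, size=int(hit.sum()))) % 4]
    data[operon_aln.ids.index(rec_leaf)] = src
    truth = {
        "type": "hgt",
        "donor": donor,
        "recipient": recipient,
        "copy_index": copy_index,
        "perturb_rate": perturb_rate,
    }
    return Alignment(ids=list(operon_aln.ids), data=data), truth


def spr_move(
    tree: dendropy.Tree, taxon: str, attach_to: str
) -> dendropy.Tree:
    """Prune a leaf and regraft it as sister to another leaf (copy returned)."""
    t = parse_newick(write_newick(tree))
    leaf = t.find_node_with_taxon_label(taxon)
    target = t.find_node_with_taxon_label(attach_to)
    if leaf is None or target is None:
        raise ValueError(f"taxon not in tree: {taxon!r} or {attach_to!r}")
    if leaf is target:
        raise ValueError("cannot attach a taxon to itself")
    moved_bl = leaf.edge.length or 0.0
    leaf.parent_node.remove_child(leaf)
    t.suppress_unifurcations()
    target = t.find_node_with_taxon_label(attach_to)
    gp = target.parent_node
    tgt_bl = target.edge.length or 0.0
    joint = dendropy.Node()
    gp.remove_child(target)
    gp.add_child(joint)
    joint.edge.length = tgt_bl / 2.0
    joint.add_child(target)
    target.edge.length = tgt_bl / 2.0
    joint.add_child(leaf)
    leaf.edge.length = moved_bl
    return parse_newick(write_newick(t))


def inject_recombination(
    species_tree: dendropy.Tree,
    length: int,
    rate: float,
    breakpoint: int,
    seed: int = 0,
    moved_taxon: str | None = None,
    attach_to: str | None = None,
    invariant_fraction: float = 0.0,
) -> tuple[Alignment, dict]:
    """Simulate a gene with a segmental recombination breakpoint.

    Columns left of the breakpoint (0-based; the breakpoint column starts the
    right segment) evolve on the species tree; columns from the breakpoint on
    evolve on an SPR-modified tree in which ``moved_taxon`` is regrafted as
    sister to ``attach_to`` (both seeded-random when not given).
    """
    if not 0 < breakpoint < length:
        raise ValueError(
            f"breakpoint {breakpoint} must be strictly inside (0, {length})"
        )
    rng = np.random.default_rng(seed)
    labels = sorted(lf.taxon.label for lf in species_tree.leaf_node_iter())
    if moved_taxon is None:
        moved_taxon = labels[int(rng.integers(0, len(labels)))]
    if attach_to is None:
        others = [x for x in labels if x != moved_taxon]
        attach_to = others[int(rng.integers(0, len(others)))]
    if moved_taxon == attach_to:
        raise ValueError("moved_taxon and attach_to must differ")
    alt_tree = spr_move(species_tree, moved_taxon, attach_to)
    left = evolve_alignment(species_tree, breakpoint, rate,
                            invariant_fraction, seed=_child_seed(rng))
    right = evolve_alignment(alt_tree, length - breakpoint, rate,
                             invariant_fraction, seed=_child_seed(rng))
    data = np.concatenate([left.data, right.reorder(left.ids).data], axis=1)
    truth = {
        "type": "recombination",
        "breakpoint_column": breakpoint,
        "moved_taxon": moved_taxon,
        "attached_to": attach_to,
    }
    return Alignment(ids=left.ids, data=data), truth


# ---------------------------------------------------------------------------
# whole-dataset simulation


@dataclass(frozen=True)
class GeneSpec:
    """One family of core genes to simulate.

    ``length_bp`` is the mean length; realised lengths are jittered +-25%
    (coding genes rounded to a codon multiple) and realised rates drawn
    lognormally around ``subst_rate`` to give the heterogeneity real core
    genomes show.
    """

    category: str  # NR, CR or rRNA
    count: int
    length_bp: int
    subst_rate: float
    invariant_fraction: float = 0.0


@dataclass(frozen=True)
class OperonSpec:
    copy_range: tuple[int, int] = (1, 8)
    intragenomic_divergence: float = 0.005
    length_bp: int = 1542
    subst_rate: float = 0.15
    invariant_fraction: float = 0.83


@dataclass(frozen=True)
class HGTEventSpec:
    donor: str
    recipient: str
    copy_index: int = 1


@dataclass(frozen=True)
class RecombinationEventSpec:
    gene: str
    breakpoint_column: int
    moved_taxon: str | None = None
    attach_to: str | None = None


def _default_gene_specs() -> tuple[GeneSpec, ...]:
    return (
        GeneSpec("NR", count=20, length_bp=928, subst_rate=0.15),
        GeneSpec("CR", count=8, length_bp=434, subst_rate=0.10,
                 invariant_fraction=0.2),
        GeneSpec("rRNA", count=1, length_bp=1542, subst_rate=0.15,
                 invariant_fraction=0.83),
    )


@dataclass
class SimulationConfig:
    n_species: int = 17
    tree_model: str = "yule"
    gene_specs: tuple[GeneSpec, ...] = field(default_factory=_default_gene_specs)
    operon_spec: OperonSpec = field(default_factory=OperonSpec)
    hgt_events: tuple[HGTEventSpec, ...] = ()
    recombination_events: tuple[RecombinationEventSpec, ...] = ()
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.operon_spec.copy_range
        if not 1 <= lo <= hi <= 27:
            raise ValueError("operon copy range must lie within [1, 27]")
        for spec in self.gene_specs:
            if spec.subst_rate <= 0:
                raise ValueError("substitution rates must be > 0")
            if not 0.0 <= spec.invariant_fraction < 1.0:
                raise ValueError("invariant_fraction must be in [0, 1)")


def default_config(n_species: int = 17, seed: int = 0) -> SimulationConfig:
    return SimulationConfig(n_species=n_species, seed=seed)


def demo_config(n_species: int = 17, seed: int = 0) -> SimulationConfig:
    """Default dataset plus one planted copy transfer and one recombinant gene."""
    width = max(2, len(str(n_species)))
    sp = lambda i: f"sp{i:0{width}d}"
    return SimulationConfig(
        n_species=n_species,
        seed=seed,
        hgt_events=(HGTEventSpec(donor=sp(2), recipient=sp(5), copy_index=1),),
        recombination_events=(
            RecombinationEventSpec(gene="nr05", breakpoint_column=400,
                                   moved_taxon=sp(3), attach_to=sp(n_species)),
        ),
    )


@dataclass
class SimTruth:
    """Ground truth echoed by the generator for downstream validation."""

    species_tree_newick: str
    events: list[dict]
    gene_lengths: dict[str, int]
    gene_rates: dict[str, float]
    snp_counts: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SimDataset:
    species_tree: dendropy.Tree
    genes: dict[str, Alignment]
    annotations: dict[str, SiteAnnotation]
    categories: dict[str, str]
    operon_alignment: Alignment
    species_map: LeafSpeciesMap
    truth: SimTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "species_tree.nwk").write_text(
            write_newick(self.species_tree) + "\n")
        for name, aln in sorted(self.genes.items()):
            aln.write_fasta(outdir / f"{name}.fasta")
            self.annotations[name].to_tsv(outdir / f"{name}.annot.tsv")
        self.operon_alignment.write_fasta(outdir / "operon.fasta")
        self.species_map.to_tsv(outdir / "operon.species_map.tsv")
        self.truth.to_json(outdir / "truth.json")


def simulate_dataset(config: SimulationConfig) -> SimDataset:
    """Generate a full synthetic dataset per the configuration.

    Gene names are nr01.., cr01.. and rrna_16S; the multi-copy operon is
    emitted separately with its leaf-to-species map.  Planted events are
    applied after the clean simulation and echoed in the truth record.
    """
    master = np.random.default_rng(config.seed)
    tree = simulate_species_tree(config.n_species, config.tree_model,
                                 seed=_child_seed(master))

    genes: dict[str, Alignment] = {}
    annots: dict[str, SiteAnnotation] = {}
    categories: dict[str, str] = {}
    lengths: dict[str, int] = {}
    rates: dict[str, float] = {}
    prefix = {"NR": "nr", "CR": "cr", "rRNA": "rrna_16S"}
    counters = {"NR": 0, "CR": 0, "rRNA": 0}

    for spec in config.gene_specs:
        for _ in range(spec.count):
            counters[spec.category] += 1
            if spec.category == "rRNA":
                name = ("rrna_16S" if counters["rRNA"] == 1
                        else f"rrna_16S_{counters['rRNA']}")
            else:
                name = f"{prefix[spec.category]}{counters[spec.category]:02d}"
            if spec.category == "rRNA":
                # rRNA length is strongly conserved; keep the stated length
                # so reference-based region coordinates stay valid
                length = spec.length_bp
                rate = spec.subst_rate
            else:
                length = int(round(spec.length_bp
                                   * master.uniform(0.75, 1.25)))
                length = max(3, 3 * round(length / 3))
                rate = float(spec.subst_rate
                             * np.exp(master.normal(0.0, 0.35)))
            genes[name] = evolve_alignment(
                tree, length, rate, spec.invariant_fraction,
                seed=_child_seed(master),
            )
            if spec.category == "rRNA":
                structure = np.where(master.random(length) < 0.6,
                                     "stem", "loop")
                consistent = master.random(length) < 0.95
                annots[name] = SiteAnnotation.for_rrna_gene(
                    name, length, structure.tolist(), consistent.tolist())
            else:
                annots[name] = SiteAnnotation.for_coding_gene(
                    name, length, spec.category)
            categories[name] = spec.category
            lengths[name] = length
            rates[name] = rate

    events: list[dict] = []
    for rec in config.recombination_events:
        if rec.gene not in genes:
            raise ValueError(f"recombination event names unknown gene {rec.gene!r}")
        length = lengths[rec.gene]
        if not 0 < rec.breakpoint_column < length:
            raise ValueError(
                f"breakpoint {rec.breakpoint_column} outside gene "
                f"{rec.gene} of length {length}"
            )
        aln, truth = inject_recombination(
            tree, length, rates[rec.gene], rec.breakpoint_column,
            seed=_child_seed(master),
            moved_taxon=rec.moved_taxon, attach_to=rec.attach_to,
        )
        genes[rec.gene] = aln
        truth["gene"] = rec.gene
        events.append(truth)

    op = config.operon_spec
    operon, species_map = simulate_operon_copies(
        tree, op.copy_range, op.intragenomic_divergence,
        length=op.length_bp, rate=op.subst_rate,
        invariant_fraction=op.invariant_fraction,
        seed=_child_seed(master),
    )
    for ev in config.hgt_events:
        operon, truth = inject_hgt(
            operon, species_map, ev.donor, ev.recipient, ev.copy_index,
            seed=_child_seed(master),
        )
        events.append(truth)

    snp_counts = {name: count_snps(aln) for name, aln in sorted(genes.items())}
    snp_counts["operon"] = count_snps(operon)
    sim_truth = SimTruth(
        species_tree_newick=write_newick(tree),
        events=events,
        gene_lengths=lengths,
        gene_rates=rates,
        snp_counts=snp_counts,
    )
    return SimDataset(
        species_tree=tree,
        genes=genes,
        annotations=annots,
        categories=categories,
        operon_alignment=operon,
        species_map=species_map,
        truth=sim_truth,
    )
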