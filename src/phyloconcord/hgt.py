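"""Monophyly screening of multi-copy gene trees for horizontal transfer.

For genes that exist in several copies per genome (classically the
16S-23S-5S rRNA operon), all copies from all genomes are placed on one gene
tree.  If a species' copies form an exclusive clade, the gene was inherited
vertically; if the minimal clade containing its copies also contains copies
from other species, that is phylogenetic evidence for between-species
transfer.  Direction cannot be read off a monophyly violation, so foreign
species are reported as donor *candidates*, and any species whose copies fall
entirely inside another species' minimal clade is additionally reported as
nested within it.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import pandas as pd

from .trees import leaf_labels

__all__ = [
    "LeafSpeciesMap",
    "SpeciesStatus",
    "HGTReport",
    "CopyNumberTable",
    "detect_hgt_monophyly",
    "tabulate_copy_number",
]


@dataclass
class LeafSpeciesMap:
    """Mapping from gene-tree leaf labels to species ids."""

    leaf_to_species: dict[str, str]

    def species(self) -> list[str]:
        return sorted(set(self.leaf_to_species.values()))

    def copy_counts(self) -> dict[str, int]:
        return dict(sorted(Counter(self.leaf_to_species.values()).items()))

    def leaves_of(self, species: str) -> frozenset[str]:
        return frozenset(
            leaf for leaf, sp in self.leaf_to_species.items() if sp == species
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LeafSpeciesMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(dict(zip(df["leaf_label"], df["species"])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.leaf_to_species.items()),
            columns=["leaf_label", "species"],
        ).to_csv(path, sep="\t", index=False)


@dataclass
class SpeciesStatus:
    species: str
    n_copies: int
    monophyletic: bool
    intruding_species: frozenset[str]
    nested_in: str | None = None


@dataclass
class HGTReport:
    """Per-species monophyly verdicts plus flagged putative transfer events."""

    statuses: dict[str, SpeciesStatus]
    flagged_events: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)

    @property
    def flagged_species(self) -> list[str]:
        return sorted({r for r, _ in self.flagged_events})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "species": s.species,
                "n_copies": s.n_copies,
                "monophyletic": s.monophyletic,
                "intruding_species": ",".join(sorted(s.intruding_species)),
                "nested_in": s.nested_in or "",
            }
            for s in self.statuses.values()
        ]
        return pd.DataFrame(rows).sort_values("species").reset_index(drop=True)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "species": {
                s.species: {
                    "n_copies": s.n_copies,
                    "monophyletic": s.monophyletic,
                    "intruding_species": sorted(s.intruding_species),
                    "nested_in": s.nested_in,
                }
                for s in self.statuses.values()
            },
            "flagged_events": [
                {"recipient": r, "donor_candidates": list(d)}
                for r, d in self.flagged_events
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def detect_hgt_monophyly(
    gene_tree: dendropy.Tree, species_map: LeafSpeciesMap
) -> HGTReport:
    """Screen a multi-copy gene tree for monophyly violations.

    For every species with >= 2 copies, the minimal clade (MRCA leaf set)
    spanning its copies is computed; the species is monophyletic iff that
    clade contains no foreign leaves, otherwise the foreign species are
    recorded as intruders and a flagged event (recipient, donor candidates)
    is emitted.  Any species — single-copy included — whose leaves fall
    strictly inside another species' minimal clade is reported nested within
    that species (the tightest such host).
    """
    leaves = leaf_labels(gene_tree)
    if len(leaves) < 4:
        raise ValueError("gene tree must have >= 4 leaves")
    unmapped = [lf for lf in leaves if lf not in species_map.leaf_to_species]
    if unmapped:
        raise ValueError(f"unmapped leaves: {sorted(unmapped)}")

    node_sets = [frozenset(leaves)]
    for node in gene_tree.preorder_internal_node_iter(exclude_seed_node=True):
        node_sets.append(frozenset(lf.taxon.label for lf in node.leaf_iter()))

    present = sorted({species_map.leaf_to_species[lf] for lf in leaves})
    sp_leaves = {sp: frozenset(lf for lf in leaves
                               if species_map.leaf_to_species[lf] == sp)
                 for sp in present}

    def minimal_clade(target: frozenset[str]) -> frozenset[str]:
        if len(target) == 1:
            return target
        candidates = [s for s in node_sets if target <= s]
        return min(candidates, key=len)

    min_clades = {sp: minimal_clade(sp_leaves[sp]) for sp in present}

    statuses: dict[str, SpeciesStatus] = {}
    events: list[tuple[str, tuple[str, ...]]] = []
    for sp in present:
        own = sp_leaves[sp]
        foreign = min_clades[sp] - own
        intruders = frozenset(species_map.leaf_to_species[lf] for lf in foreign)
        mono = not intruders
        statuses[sp] = SpeciesStatus(
            species=sp, n_copies=len(own),
            monophyletic=mono, intruding_species=intruders,
        )
        if not mono:
            events.append((sp, tuple(sorted(intruders))))

    for sp in present:
        own = sp_leaves[sp]
        hosts = [
            t for t in present
            if t != sp and len(sp_leaves[t]) >= 2
            and own <= min_clades[t] and min_clades[t] != own
        ]
        if hosts:
            host = min(hosts, key=lambda t: (len(min_clades[t]), t))
            statuses[sp].nested_in = host
            ev = (sp, (host,))
            if not any(r == sp and host in d for r, d in events):
                events.append(ev)

    return HGTReport(statuses=statuses, flagged_events=sorted(set(events)))


@dataclass
class CopyNumberTable:
    per_species: pd.DataFrame  # columns: species, copies
    histogram: dict[int, int]  # copy count -> number of species
    min_copies: int
    max_copies: int

    def histogram_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.histogram.items()), columns=["copies", "n_species"]
        )


def tabulate_copy_number(maps: Sequence[LeafSpeciesMap]) -> CopyNumberTable:
    """Aggregate per-species gene copy counts across one or more datasets."""
    counts: Counter[str] = Counter()
    for m in maps:
        for sp, k in m.copy_counts().items():
            counts[sp] += k
    if not counts:
        return CopyNumberTable(
            per_species=pd.DataFrame(columns=["species", "copies"]),
            histogram={}, min_copies=0, max_copies=0,
        )
    per = pd.DataFrame(sorted(counts.items()), columns=["species", "copies"])
    hist = dict(sorted(Counter(counts.values()).items()))
    return CopyNumberTable(
        per_species=per,
        histogram=hist,
        min_copies=min(counts.values()),
        max_copies=max(counts.values()),
    )
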