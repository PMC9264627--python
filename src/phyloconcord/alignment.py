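"""Alignment container and per-column diagnostics.

An :class:`Alignment` is an ordered set of equal-length nucleotide sequences
over {A, C, G, T, N, -}.  The diagnostics here are the ones a concordance
analysis needs: segregating-site (SNP) counting, Shannon column entropy and
top-fraction entropy masking, hypervariable-region extraction against an
ungapped reference coordinate system, SNP-category extraction (codon position,
coding vs ribosomal vs rRNA, stem vs loop), and column-wise concatenation.

A SNP column is a column with two or more distinct bases among A/C/G/T;
variation involving only gaps or N does not count.  Column entropy is Shannon
entropy (base 2) of the A/C/G/T frequencies with gaps and N excluded, so it
ranges over [0, 2] bits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

BASES = np.array(["A", "C", "G", "T"])
ALPHABET = set("ACGTN-")

__all__ = [
    "Alignment",
    "SiteAnnotation",
    "RegionDefinition",
    "MaskResult",
    "SNP_CATEGORIES",
    "read_fasta",
    "count_snps",
    "snp_column_mask",
    "column_entropy",
    "entropy_mask",
    "extract_region",
    "extract_snp_category",
    "concatenate",
    "load_regions",
    "default_hvr_regions",
]


@dataclass
class Alignment:
    """Equal-length aligned sequences with unique ids.

    ``data`` is an (n_taxa, n_columns) array of single uppercase characters.
    ``column_sources`` optionally records, per column, the (gene, column)
    provenance after concatenation.
    """

    ids: list[str]
    data: np.ndarray
    column_sources: list[tuple[str, int]] | None = field(default=None, repr=False)

    @classmethod
    def from_sequences(cls, ids: Sequence[str], seqs: Sequence[str]) -> "Alignment":
        ids = [str(i) for i in ids]
        if len(ids) != len(set(ids)):
            raise ValueError("sequence ids are not unique")
        if not seqs:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        if lengths == {0}:
            raise ValueError("zero-length alignment")
        arr = np.array([list(s.upper()) for s in seqs], dtype="U1")
        bad = set(np.unique(arr)) - ALPHABET
        if bad:
            raise ValueError(f"illegal characters in alignment: {sorted(bad)}")
        return cls(ids=ids, data=arr)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def length(self) -> int:
        return self.data.shape[1]

    def sequence(self, seq_id: str) -> str:
        return "".join(self.data[self.ids.index(seq_id)])

    def sequences(self) -> list[str]:
        return ["".join(row) for row in self.data]

    def take_columns(self, cols: Sequence[int]) -> "Alignment":
        cols = list(cols)
        sub = Alignment(ids=list(self.ids), data=self.data[:, cols].copy())
        if self.column_sources is not None:
            sub.column_sources = [self.column_sources[c] for c in cols]
        return sub

    def reorder(self, ids: Sequence[str]) -> "Alignment":
        idx = [self.ids.index(i) for i in ids]
        return Alignment(ids=list(ids), data=self.data[idx].copy(),
                         column_sources=self.column_sources)

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq("".join(row)), id=sid, description="")
            for sid, row in zip(self.ids, self.data)
        ]
        SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return Alignment.from_sequences(
        [r.id for r in records], [str(r.seq) for r in records]
    )


def _base_counts(aln: Alignment) -> np.ndarray:
    """(4, L) counts of A/C/G/T per column."""
    return np.stack([(aln.data == b).sum(axis=0) for b in BASES])


def snp_column_mask(aln: Alignment) -> np.ndarray:
    """Boolean mask over columns: True where >= 2 distinct A/C/G/T present."""
    return (_base_counts(aln) > 0).sum(axis=0) >= 2


def count_snps(aln: Alignment) -> int:
    """Number of segregating columns (>= 2 distinct bases among A/C/G/T)."""
    return int(snp_column_mask(aln).sum())


def column_entropy(aln: Alignment) -> np.ndarray:
    """Shannon entropy (bits) of each column's A/C/G/T frequencies.

    Gaps and N are excluded from the frequency denominator; a column with no
    called base at all has entropy 0 by convention.
    """
    counts = _base_counts(aln).astype(float)
    totals = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, counts / np.where(totals == 0, 1, totals), 0.0)
        terms = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return terms.sum(axis=0)


@dataclass
class MaskResult:
    """Masked alignment plus the 0-based indices and entropies of masked columns."""

    alignment: Alignment
    masked_columns: list[int]
    entropy: np.ndarray

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column_index": [c + 1 for c in self.masked_columns],
                "entropy": [self.entropy[c] for c in self.masked_columns],
            }
        )


def entropy_mask(
    aln: Alignment, fraction: float, mode: str = "N"
) -> MaskResult:
    """Mask the top ``fraction`` most entropic columns.

    Exactly ``ceil(fraction * length)`` columns are masked; ties at the
    threshold entropy resolve to the lower column index.  ``mode="N"``
    (default) overwrites masked columns with N, preserving coordinates;
    ``mode="remove"`` deletes them.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if mode not in ("N", "remove"):
        raise ValueError(f"unknown mask mode {mode!r}")
    ent = column_entropy(aln)
    k = math.ceil(fraction * aln.length)
    if np.all(ent == 0):
        logger.warning(
            "all %d columns have zero entropy; masking first %d anyway",
            aln.length, k,
        )
    order = np.lexsort((np.arange(aln.length), -ent))
    masked = sorted(int(c) for c in order[:k])
    if mode == "N":
        data = aln.data.copy()
        data[:, masked] = "N"
        out = Alignment(ids=list(aln.ids), data=data,
                        column_sources=aln.column_sources)
    else:
        keep = [c for c in range(aln.length) if c not in set(masked)]
        out = aln.take_columns(keep)
    return MaskResult(alignment=out, masked_columns=masked, entropy=ent)


@dataclass(frozen=True)
class RegionDefinition:
    """A named span on the *ungapped* reference sequence, 1-based inclusive.

    Used for 16S hypervariable regions (V1..V9 and combinations) and
    gene subsections such as a ~440 bp stretch of rpoB.
    """

    name: str
    reference_id: str
    start: int
    end: int

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad region bounds {self.start}..{self.end}")


def extract_region(aln: Alignment, region: RegionDefinition) -> Alignment:
    """Slice the alignment columns spanned by a reference-coordinate region.

    Positions are mapped through the reference sequence's gaps; gap columns of
    the reference inside the span are retained for all taxa.
    """
    if region.reference_id not in aln.ids:
        raise ValueError(f"reference id {region.reference_id!r} not in alignment")
    ref = aln.data[aln.ids.index(region.reference_id)]
    ungapped_cols = np.flatnonzero(ref != "-")
    if region.end > len(ungapped_cols):
        raise ValueError(
            f"region {region.name} end {region.end} exceeds ungapped "
            f"reference length {len(ungapped_cols)}"
        )
    lo = int(ungapped_cols[region.start - 1])
    hi = int(ungapped_cols[region.end - 1])
    return aln.take_columns(range(lo, hi + 1))


def load_regions(path: str | Path, reference_id: str) -> list[RegionDefinition]:
    """Read a region table (columns: name, start, end) bound to a reference id."""
    df = pd.read_csv(path, sep="\t")
    return [
        RegionDefinition(str(r["name"]), reference_id, int(r["start"]), int(r["end"]))
        for _, r in df.iterrows()
    ]


def default_hvr_regions(reference_id: str) -> list[RegionDefinition]:
    """Packaged default 16S hypervariable-region boundaries (E. coli numbering)."""
    path = Path(__file__).parent / "data" / "hvr_regions.tsv"
    return load_regions(path, reference_id)


class SiteAnnotation:
    """Per-column labels for one gene alignment.

    Columns of the underlying frame: ``column`` (0-based), ``gene_id``,
    ``category`` (NR / CR / rRNA), ``codon_position`` (1, 2, 3 or 0 for
    non-coding), ``structure`` (stem / loop / none) and
    ``structure_consistent`` (whether the stem/loop call agrees across all
    taxa; only consistent columns enter the stem/loop SNP categories).
    """

    CATEGORIES = ("NR", "CR", "rRNA")

    def __init__(self, frame: pd.DataFrame):
        required = {"column", "gene_id", "category", "codon_position",
                    "structure", "structure_consistent"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        frame = frame.sort_values("column").reset_index(drop=True)
        if list(frame["column"]) != list(range(len(frame))):
            raise ValueError("annotation must cover columns 0..L-1 exactly once")
        bad = set(frame["category"]) - set(self.CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories: {sorted(bad)}")
        nonr = frame[(frame["category"] != "rRNA") & (frame["structure"] != "none")]
        if len(nonr):
            raise ValueError("structure labels only allowed on rRNA columns")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def for_coding_gene(cls, gene_id: str, length: int, category: str) -> "SiteAnnotation":
        """Frame-1 ORF annotation: codon positions cycle 1,2,3 across columns."""
        return cls(pd.DataFrame({
            "column": range(length),
            "gene_id": gene_id,
            "category": category,
            "codon_position": [(i % 3) + 1 for i in range(length)],
            "structure": "none",
            "structure_consistent": True,
        }))

    @classmethod
    def for_rrna_gene(
        cls, gene_id: str, length: int,
        structure: Sequence[str], consistent: Sequence[bool],
    ) -> "SiteAnnotation":
        return cls(pd.DataFrame({
            "column": range(length),
            "gene_id": gene_id,
            "category": "rRNA",
            "codon_position": 0,
            "structure": list(structure),
            "structure_consistent": list(consistent),
        }))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SiteAnnotation":
        df = pd.read_csv(path, sep="\t")
        df["column"] = df["column_index"] - 1
        df = df.drop(columns=["column_index"])
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.insert(0, "column_index", out.pop("column") + 1)
        out.to_csv(path, sep="\t", index=False)


SNP_CATEGORIES = (
    "NR", "NR 1-2", "NR 3",
    "CR", "CR 1-2", "CR 3",
    "rRNA", "16S", "16S stem", "16S loop",
    "core",
)


def _category_mask(annot: SiteAnnotation, category: str) -> np.ndarray:
    f = annot.frame
    is_16s = f["gene_id"].str.contains("16S", case=False, regex=False)
    cons = f["structure_consistent"].astype(bool)
    if category == "core":
        return np.ones(len(f), dtype=bool)
    if category in ("NR", "CR"):
        return (f["category"] == category).to_numpy()
    if category in ("NR 1-2", "CR 1-2"):
        base = category.split()[0]
        return ((f["category"] == base) & f["codon_position"].isin([1, 2])).to_numpy()
    if category in ("NR 3", "CR 3"):
        base = category.split()[0]
        return ((f["category"] == base) & (f["codon_position"] == 3)).to_numpy()
    if category == "rRNA":
        return (f["category"] == "rRNA").to_numpy()
    if category == "16S":
        return ((f["category"] == "rRNA") & is_16s).to_numpy()
    if category == "16S stem":
        return ((f["category"] == "rRNA") & is_16s
                & (f["structure"] == "stem") & cons).to_numpy()
    if category == "16S loop":
        return ((f["category"] == "rRNA") & is_16s
                & (f["structure"] == "loop") & cons).to_numpy()
    raise ValueError(f"unknown SNP category {category!r}; "
                     f"choose one of {SNP_CATEGORIES}")


def extract_snp_category(
    alns: Sequence[Alignment],
    annots: Sequence[SiteAnnotation],
    category: str,
) -> Alignment:
    """Concatenate all SNP columns matching one of the eleven SNP categories.

    Gene alignments and annotations are parallel sequences; taxa must be
    identical across alignments.  The 16S gene is recognised by a gene_id
    containing "16S".  Stem/loop columns are admitted only when the structure
    call is consistent across taxa.
    """
    if len(alns) != len(annots):
        raise ValueError("alignments and annotations must be parallel")
    ref_ids = sorted(alns[0].ids)
    pieces, sources = [], []
    for aln, annot in zip(alns, annots):
        if sorted(aln.ids) != ref_ids:
            raise ValueError(
                f"taxa mismatch: {sorted(set(aln.ids) ^ set(alns[0].ids))}"
            )
        if len(annot) != aln.length:
            raise ValueError("annotation does not cover every column")
        aln = aln.reorder(sorted(aln.ids))
        keep = snp_column_mask(aln) & _category_mask(annot, category)
        cols = np.flatnonzero(keep)
        if len(cols):
            pieces.append(aln.take_columns(cols))
            gene = str(annot.frame["gene_id"].iloc[0])
            sources.extend((gene, int(c)) for c in cols)
    if not pieces:
        return Alignment(ids=ref_ids,
                         data=np.empty((len(ref_ids), 0), dtype="U1"),
                         column_sources=[])
    out = concatenate(pieces)
    out.column_sources = sources
    return out


def concatenate(alns: Sequence[Alignment], names: Sequence[str] | None = None) -> Alignment:
    """Column-wise concatenation of alignments sharing a taxon set.

    Sequences are harmonised to the first alignment's id order; per-gene
    column provenance is recorded in ``column_sources``.
    """
    if not alns:
        raise ValueError("nothing to concatenate")
    ids = list(alns[0].ids)
    idset = set(ids)
    blocks, sources = [], []
    names = list(names) if names is not None else [f"aln{i}" for i in range(len(alns))]
    for name, aln in zip(names, alns):
        if set(aln.ids) != idset:
            raise ValueError(
                f"taxa mismatch in {name}: {sorted(set(aln.ids) ^ idset)}"
            )
        blocks.append(aln.reorder(ids).data)
        sources.extend((name, c) for c in range(aln.length))
    return Alignment(ids=ids, data=np.concatenate(blocks, axis=1),
                     column_sources=sources)
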