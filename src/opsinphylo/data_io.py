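"""Alignment, tree, gene-model and configuration I/O.

Coordinate convention used across the whole package: alignment columns are
1-based and inclusive, so a four-column deletion spanning the 270th..273rd
columns is reported as ``270-273``.  Any half-open arithmetic is internal and
converted at the API boundary.

Gap character is ``-`` only; ``.`` is normalized to ``-`` and ``?`` to ``N``
on read (logged).  Reading-frame questions are always anchored on the
reference taxon (an intact outgroup), never on a potentially lesion-bearing
ingroup row.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import yaml
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment

logger = logging.getLogger("opsinphylo")

NUCLEOTIDES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

#: IUPAC ambiguity codes mapped to compatible nucleotides.
AMBIGUITY = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def translate_codon(codon: str) -> str:
    """Translate one codon; returns 'X' for gapped/ambiguous codons."""
    return GENETIC_CODE.get(codon.upper(), "X")


class FormatError(ValueError):
    """Raised when an input file violates its dialect or our invariants."""


# ---------------------------------------------------------------------------
# CodonAlignment
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """A gapped, codon-aware multiple sequence alignment.

    ``taxa`` preserves input order; ``rows`` maps taxon label to its aligned
    sequence (uppercase, gap ``-``).  All rows have equal length and labels
    are unique.
    """

    taxa: list[str]
    rows: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise FormatError(f"duplicate taxon labels: {dupes}")
        lengths = {len(self.rows[t]) for t in self.taxa}
        if len(lengths) > 1:
            ref = len(self.rows[self.taxa[0]])
            bad = [t for t in self.taxa if len(self.rows[t]) != ref]
            raise FormatError(f"ragged alignment rows for taxa: {bad}")

    @property
    def length(self) -> int:
        """Number of columns."""
        return len(self.rows[self.taxa[0]]) if self.taxa else 0

    def __len__(self) -> int:
        return self.length

    def __getitem__(self, taxon: str) -> str:
        return self.rows[taxon]

    def column(self, col: int) -> dict[str, str]:
        """Characters at a 1-based column, per taxon."""
        return {t: self.rows[t][col - 1] for t in self.taxa}

    def subcolumns(self, cols: Sequence[int]) -> "CodonAlignment":
        """New alignment restricted to the given 1-based columns, in order."""
        idx = [c - 1 for c in cols]
        return CodonAlignment(
            list(self.taxa),
            {t: "".join(self.rows[t][i] for i in idx) for t in self.taxa},
        )


def _normalize(seq: str, taxon: str) -> str:
    s = seq.upper()
    if "." in s:
        logger.info("taxon %s: normalizing '.' to '-'", taxon)
        s = s.replace(".", "-")
    if "?" in s:
        logger.info("taxon %s: normalizing '?' to 'N'", taxon)
        s = s.replace("?", "N")
    return s


def read_alignment(path: str | Path, format: str = "fasta") -> CodonAlignment:
    """Read a FASTA or NEXUS alignment into a :class:`CodonAlignment`.

    NEXUS DATA/CHARACTERS blocks are supported in both interleaved and
    sequential form (ASSUMPTIONS/TREES blocks are ignored by the parser).
    Ragged rows and duplicate labels raise :class:`FormatError` naming the
    offending taxa.
    """
    path = Path(path)
    if format not in ("fasta", "nexus"):
        raise ValueError(f"unsupported alignment format: {format}")
    if format == "fasta":
        # parse record-wise so ragged inputs can be reported by taxon
        records = list(SeqIO.parse(str(path), "fasta"))
    else:
        try:
            records = list(AlignIO.read(str(path), "nexus"))
        except Exception as exc:  # noqa: BLE001 - re-raise with file context
            raise FormatError(f"{path}: not a parseable NEXUS matrix: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no sequences found")
    taxa = [r.id for r in records]
    rows = {r.id: _normalize(str(r.seq), r.id) for r in records}
    return CodonAlignment(taxa, rows)


def write_alignment(aln: CodonAlignment, path: str | Path, format: str = "fasta") -> None:
    """Write FASTA or (sequential) NEXUS; round-trips with :func:`read_alignment`."""
    path = Path(path)
    records = [
        SeqRecord(Seq(aln.rows[t]), id=t, description="",
                  annotations={"molecule_type": "DNA"})
        for t in aln.taxa
    ]
    msa = MultipleSeqAlignment(records)
    with open(path, "w") as fh:
        AlignIO.write(msa, fh, format)


# ---------------------------------------------------------------------------
# GeneModel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    kind: str  # "exon" | "intron"
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.kind not in ("exon", "intron"):
            raise ValueError(f"segment kind must be exon|intron, got {self.kind}")
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")

    @property
    def columns(self) -> range:
        return range(self.start, self.end + 1)


@dataclass
class GeneModel:
    """Exon/intron layout of one gene in alignment coordinates.

    ``numbering_map`` maps 1-based CDS codon index to a reference residue
    number (e.g. bovine rhodopsin numbering for key tuning sites), and
    ``frame_anchor`` is the alignment column of the first codon position of
    the CDS in the reference taxon.
    """

    gene_name: str
    segments: list[Segment]
    frame_anchor: int
    numbering_map: dict[int, int]
    reference_taxon: str

    def __post_init__(self) -> None:
        prev_end = 0
        for seg in self.segments:
            if seg.start <= prev_end:
                raise ValueError(
                    f"{self.gene_name}: segments overlap or are out of order at {seg}")
            prev_end = seg.end
        values = list(self.numbering_map.values())
        if len(set(values)) != len(values):
            raise ValueError(f"{self.gene_name}: numbering_map is not injective")

    @property
    def exon_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == "exon"]

    @property
    def intron_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == "intron"]

    def exon_columns(self) -> list[int]:
        """All exon columns (1-based, ascending), restricted to >= frame_anchor
        handling left at the CDS projection level."""
        cols: list[int] = []
        for seg in self.exon_segments:
            cols.extend(seg.columns)
        return cols

    def residue_to_codon(self, residue_number: int) -> int:
        """Invert numbering_map: reference residue number -> CDS codon index."""
        for codon_idx, res in self.numbering_map.items():
            if res == residue_number:
                return codon_idx
        raise KeyError(f"residue number {residue_number} not in numbering map of "
                       f"{self.gene_name}")

    def to_dict(self) -> dict:
        return {
            "gene_name": self.gene_name,
            "segments": [[s.kind, s.start, s.end] for s in self.segments],
            "frame_anchor": self.frame_anchor,
            "numbering_map": dict(self.numbering_map),
            "reference_taxon": self.reference_taxon,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneModel":
        return cls(
            gene_name=d["gene_name"],
            segments=[Segment(k, int(a), int(b)) for k, a, b in d["segments"]],
            frame_anchor=int(d["frame_anchor"]),
            numbering_map={int(k): int(v) for k, v in d["numbering_map"].items()},
            reference_taxon=d["reference_taxon"],
        )


def load_gene_model(path: str | Path) -> GeneModel:
    with open(path) as fh:
        return GeneModel.from_dict(yaml.safe_load(fh))


def save_gene_model(model: GeneModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=False)


def reference_codon_columns(aln: CodonAlignment, model: GeneModel) -> list[tuple[int, int, int]]:
    """Alignment columns of each reference-taxon codon, in CDS order.

    Codon ``i`` (1-based) of the reference CDS occupies three exon columns in
    which the reference is non-gap; the first codon starts at
    ``frame_anchor``.
    """
    ref = aln[model.reference_taxon]
    cols = [c for c in model.exon_columns()
            if c >= model.frame_anchor and ref[c - 1] != "-"]
    if len(cols) % 3:
        cols = cols[: len(cols) - len(cols) % 3]
    return [tuple(cols[i:i + 3]) for i in range(0, len(cols), 3)]  # type: ignore[misc]


def cds_projection(aln: CodonAlignment, model: GeneModel) -> tuple[CodonAlignment, list[int]]:
    """Concatenate exon columns into the "virtual mRNA" alignment.

    Returns the exon-only alignment and a column map: ``column_map[j-1]`` is
    the source alignment column (1-based) of projected column ``j``.  The
    reference taxon's projected sequence must translate without internal
    stop codons, otherwise the gene model (or reference) is misconfigured.
    """
    cols = model.exon_columns()
    projected = aln.subcolumns(cols)
    ref_codons = reference_codon_columns(aln, model)
    ref = aln[model.reference_taxon]
    for i, triple in enumerate(ref_codons[:-1]):  # terminal stop is allowed
        codon = "".join(ref[c - 1] for c in triple)
        if codon in STOP_CODONS:
            raise FormatError(
                f"{model.gene_name}: reference taxon {model.reference_taxon} has a "
                f"premature stop at codon {i + 1} (columns {triple[0]}-{triple[2]}); "
                "gene model or reference misconfigured")
    return projected, list(cols)


# ---------------------------------------------------------------------------
# SpeciesTree
# ---------------------------------------------------------------------------

_TIP_ID_RE = re.compile(r"^(\d+)[_ ]")


@dataclass
class TreeNode:
    node_id: int
    label: str | None
    parent: int | None
    children: list[int] = field(default_factory=list)
    edge_length: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children


class SpeciesTree:
    """Rooted species tree with integer node ids and branch addressing.

    Node ids can be supplied directly in the newick labels: a tip
    label carrying a leading integer prefix (``13_Mesoplodon_bidens``) or a
    purely numeric internal label supplies the id; remaining nodes get
    deterministic post-order ids above the largest assigned one.  Every
    branch is addressable as ``ancestor_id:descendant_id``.
    """

    def __init__(self, nodes: dict[int, TreeNode], root_id: int):
        self.nodes = nodes
        self.root_id = root_id
        self._by_label = {n.label: n.node_id for n in nodes.values() if n.label}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "SpeciesTree":
        dnodes = list(tree.preorder_node_iter())
        assigned: dict[int, int] = {}
        used: set[int] = set()
        for i, nd in enumerate(dnodes):
            label = nd.taxon.label if nd.taxon else nd.label
            nid = None
            if label:
                if nd.is_leaf():
                    m = _TIP_ID_RE.match(label)
                    if m:
                        nid = int(m.group(1))
                elif label.isdigit():
                    nid = int(label)
            if nid is not None and nid not in used:
                assigned[i] = nid
                used.add(nid)
        nxt = max(used, default=0) + 1
        order = {id(nd): i for i, nd in enumerate(dnodes)}
        for i, nd in enumerate(tree.postorder_node_iter()):
            j = order[id(nd)]
            if j not in assigned:
                assigned[j] = nxt
                used.add(nxt)
                nxt += 1
        nodes: dict[int, TreeNode] = {}
        root_id = None
        for i, nd in enumerate(dnodes):
            nid = assigned[i]
            label = nd.taxon.label if nd.taxon else nd.label
            parent = assigned[order[id(nd.parent_node)]] if nd.parent_node else None
            nodes[nid] = TreeNode(
                node_id=nid,
                label=label.replace(" ", "_") if label else None,
                parent=parent,
                edge_length=float(nd.edge.length or 0.0),
            )
            if parent is None:
                root_id = nid
        for nid, node in nodes.items():
            if node.parent is not None:
                nodes[node.parent].children.append(nid)
        assert root_id is not None
        return cls(nodes, root_id)

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        return cls.from_dendropy(tree)

    # -- queries -----------------------------------------------------------

    @property
    def leaf_ids(self) -> list[int]:
        return [nid for nid in self.postorder() if self.nodes[nid].is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [self.nodes[nid].label or str(nid) for nid in self.leaf_ids]

    def id_of_label(self, label: str) -> int:
        return self._by_label[label]

    def postorder(self) -> list[int]:
        out: list[int] = []

        def rec(nid: int) -> None:
            for c in self.nodes[nid].children:
                rec(c)
            out.append(nid)

        rec(self.root_id)
        return out

    def preorder(self) -> list[int]:
        out: list[int] = []
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(reversed(self.nodes[nid].children))
        return out

    def branches(self) -> list[tuple[int, int]]:
        """All (ancestor_id, descendant_id) pairs."""
        return [(self.nodes[nid].parent, nid) for nid in self.preorder()
                if self.nodes[nid].parent is not None]

    def has_branch(self, ancestor: int, descendant: int) -> bool:
        nd = self.nodes.get(descendant)
        return nd is not None and nd.parent == ancestor

    def subtree_leaf_ids(self, nid: int) -> list[int]:
        out = []
        stack = [nid]
        while stack:
            n = stack.pop()
            if self.nodes[n].is_leaf:
                out.append(n)
            else:
                stack.extend(self.nodes[n].children)
        return out

    def path_to_root(self, nid: int) -> list[int]:
        out = [nid]
        while self.nodes[out[-1]].parent is not None:
            out.append(self.nodes[out[-1]].parent)
        return out

    def to_newick(self, annotations: Mapping[int, str] | None = None) -> str:
        """Newick string; optional per-node comment annotations in brackets."""

        def rec(nid: int) -> str:
            node = self.nodes[nid]
            if node.is_leaf:
                s = node.label or str(nid)
            else:
                s = "(" + ",".join(rec(c) for c in node.children) + ")" + \
                    (node.label if node.label and node.label.isdigit() else str(nid))
            if annotations and nid in annotations:
                s += f"[&{annotations[nid]}]"
            if node.parent is not None:
                s += f":{node.edge_length:g}"
            return s

        return rec(self.root_id) + ";"


def read_tree(path: str | Path, alignment_taxa: Iterable[str] | None = None) -> SpeciesTree:
    """Read a rooted newick tree; optionally cross-check taxa against an alignment.

    Raises :class:`FormatError` listing the symmetric difference when tree
    tips and alignment taxa disagree.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    st = SpeciesTree.from_dendropy(tree)
    if alignment_taxa is not None:
        check_taxa(st, alignment_taxa)
    return st


def check_taxa(tree: SpeciesTree, alignment_taxa: Iterable[str]) -> None:
    tree_set = set(tree.leaf_labels)
    aln_set = set(alignment_taxa)
    if tree_set != aln_set:
        only_tree = sorted(tree_set - aln_set)
        only_aln = sorted(aln_set - tree_set)
        raise FormatError(
            f"tree/alignment taxa mismatch; only in tree: {only_tree}; "
            f"only in alignment: {only_aln}")


# ---------------------------------------------------------------------------
# RunConfig
# ---------------------------------------------------------------------------

@dataclass
class GeneConfig:
    name: str
    alignment: Path
    format: str
    gene_model: Path
    tuning_table: str | None = None  # "rh1" | "lws" | None
    key_residue_rules: list[dict] = field(default_factory=list)


@dataclass
class RunConfig:
    """Validated run configuration: genes, tree, branch categories, output."""

    genes: list[GeneConfig]
    tree: Path
    outdir: Path
    seed: int = 0
    branch_categories: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def resolve(p: str) -> Path:
            q = Path(p)
            return q if q.is_absolute() else base / q

        genes = [
            GeneConfig(
                name=g["name"],
                alignment=resolve(g["alignment"]),
                format=g.get("format", "fasta"),
                gene_model=resolve(g["gene_model"]),
                tuning_table=g.get("tuning_table"),
                key_residue_rules=g.get("key_residue_rules", []),
            )
            for g in raw.get("genes", [])
        ]
        cfg = cls(
            genes=genes,
            tree=resolve(raw["tree"]),
            outdir=resolve(raw.get("outdir", "results")),
            seed=int(raw.get("seed", 0)),
            branch_categories=raw.get("branch_categories", {}),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        missing = [str(p) for p in
                   [self.tree, *[g.alignment for g in self.genes],
                    *[g.gene_model for g in self.genes]]
                   if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"config references missing paths: {missing}")
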