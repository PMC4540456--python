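"""Reference database construction.

A reference package bundles the objects every downstream stage consumes: a
set of annotated genomes (one 16S rRNA gene and a CDS inventory each), an
unrooted reference tree whose edges are numbered deterministically, a map
from each edge to the leaf genomes of the clade below it, and the aligned
16S sequences.

Edge numbering convention: edges are numbered by depth-first preorder over
the newick as written, root-adjacent edge first.  Every non-root node of the
parsed tree defines one edge (the branch to its parent).  jplace files carry
their own edge numbers; those are remapped by topology, never by index.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import pandas as pd
from Bio import Phylo, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: characters treated as alignment gaps (Mothur/Silva dialect uses both)
GAP_CHARS = frozenset("-.")

#: dotted EC number, trailing levels may be unresolved ("1.1.1.-")
EC_PATTERN = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")

GENE_TABLE_COLUMNS = ["gene_id", "product", "ec_numbers", "aa_sequence"]


class Gene(NamedTuple):
    """One coding sequence of a reference genome."""

    gene_id: str
    product: str
    ec_numbers: tuple[str, ...]
    aa_sequence: str


@dataclass
class ReferenceGenome:
    """An annotated genome: one 16S rRNA gene plus its CDS inventory."""

    genome_id: str
    taxon_name: str
    ssu_sequence: str
    cds: list[Gene]

    def __post_init__(self) -> None:
        for gene in self.cds:
            for ec in gene.ec_numbers:
                if not EC_PATTERN.match(ec):
                    raise ValueError(
                        f"genome {self.genome_id}: gene {gene.gene_id} has "
                        f"malformed EC number {ec!r}"
                    )

    @property
    def gene_count(self) -> int:
        return len(self.cds)

    @property
    def gene_ids(self) -> set[str]:
        return {g.gene_id for g in self.cds}

    @property
    def proteome(self) -> list[str]:
        return [g.aa_sequence for g in self.cds]


def _ungapped_length(seq: str) -> int:
    return sum(1 for c in seq if c not in GAP_CHARS)


def load_genomes(genome_dir: str | Path, min_ssu_len: int = 1200) -> list[ReferenceGenome]:
    """Load annotated genomes from a directory.

    Each genome is a pair of files ``<id>.ssu.fasta`` (16S rRNA records;
    only the first record is used when several copies are present) and
    ``<id>.genes.tsv`` (columns: gene_id, product, semicolon-joined EC
    numbers, aa_sequence).  Genomes whose 16S (ungapped) is shorter than
    ``min_ssu_len`` or that lack a 16S record are excluded with a warning;
    a malformed gene table is fatal.
    """
    genome_dir = Path(genome_dir)
    genomes: list[ReferenceGenome] = []
    for table_path in sorted(genome_dir.glob("*.genes.tsv")):
        genome_id = table_path.name[: -len(".genes.tsv")]
        ssu_path = genome_dir / f"{genome_id}.ssu.fasta"
        if not ssu_path.exists():
            log.warning("genome %s: no 16S record file, excluded", genome_id)
            continue
        records = list(SeqIO.parse(str(ssu_path), "fasta"))
        if not records:
            log.warning("genome %s: empty 16S file, excluded", genome_id)
            continue
        ssu = str(records[0].seq)  # first-found rule
        if _ungapped_length(ssu) < min_ssu_len:
            log.warning(
                "genome %s: 16S length %d < %d, excluded",
                genome_id, _ungapped_length(ssu), min_ssu_len,
            )
            continue
        taxon = records[0].description.partition(" ")[2] or genome_id
        genomes.append(
            ReferenceGenome(genome_id, taxon, ssu, read_gene_table(table_path))
        )
    return genomes


def read_gene_table(path: str | Path) -> list[Gene]:
    """Read a 4-column gene table TSV; any structural defect is fatal."""
    try:
        frame = pd.read_csv(
            path, sep="\t", dtype=str, keep_default_na=False, header=0
        )
        if list(frame.columns) != GENE_TABLE_COLUMNS:
            raise ValueError(f"expected columns {GENE_TABLE_COLUMNS}, got {list(frame.columns)}")
        genes = []
        for row in frame.itertuples(index=False):
            ecs = tuple(e for e in row.ec_numbers.split(";") if e)
            genes.append(Gene(row.gene_id, row.product, ecs, row.aa_sequence))
    except Exception as exc:
        raise ValueError(f"malformed gene table {path}: {exc}") from exc
    return genes


def write_genomes(genomes: list[ReferenceGenome], out_dir: str | Path) -> None:
    """Write genomes in the on-disk layout ``load_genomes`` reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for g in genomes:
        rec = SeqRecord(Seq(g.ssu_sequence), id=g.genome_id, description=g.taxon_name)
        SeqIO.write([rec], str(out_dir / f"{g.genome_id}.ssu.fasta"), "fasta")
        frame = pd.DataFrame(
            [(x.gene_id, x.product, ";".join(x.ec_numbers), x.aa_sequence) for x in g.cds],
            columns=GENE_TABLE_COLUMNS,
        )
        frame.to_csv(out_dir / f"{g.genome_id}.genes.tsv", sep="\t", index=False)


def trim_alignment(alignment: dict[str, str]) -> dict[str, str]:
    """Trim all sequences to the latest start / earliest end non-gap position.

    Columns before the maximum first-non-gap position and after the minimum
    last-non-gap position are removed for every sequence.  A sequence that
    is entirely gaps, or an empty overlap window, is fatal.
    """
    if not alignment:
        return {}
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment sequences differ in length")
    starts, ends = [], []
    for name, seq in alignment.items():
        non_gap = [i for i, c in enumerate(seq) if c not in GAP_CHARS]
        if not non_gap:
            raise ValueError(f"sequence {name} is entirely gaps")
        starts.append(non_gap[0])
        ends.append(non_gap[-1])
    start, end = max(starts), min(ends)
    if start > end:
        raise ValueError("no common alignment region")
    return {name: seq[start : end + 1] for name, seq in alignment.items()}


@dataclass
class ReferencePackage:
    """Reference tree with numbered edges, clade maps, and aligned 16S set."""

    tree: Phylo.BaseTree.Tree
    edges: dict[int, tuple[str, str]]  # edge -> (parent node name, child node name)
    clade_map: dict[int, frozenset[str]]  # edge -> descendant leaf genome_ids
    alignment: dict[str, str]  # genome_id -> aligned 16S
    edge_of_node: dict[str, int] = field(default_factory=dict)  # child node -> edge

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferencePackage):
            return NotImplemented
        return (
            self.edges == other.edges
            and self.clade_map == other.clade_map
            and self.alignment == other.alignment
        )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def leaves(self) -> frozenset[str]:
        return frozenset().union(*self.clade_map.values())

    def is_terminal(self, edge: int) -> bool:
        return len(self.clade_map[edge]) == 1

    @property
    def terminal_edge_of_leaf(self) -> dict[str, int]:
        return {
            next(iter(members)): e
            for e, members in self.clade_map.items()
            if len(members) == 1
        }

    def children_edges(self, edge: int) -> list[int]:
        _, child = self.edges[edge]
        return [e for e, (p, _) in self.edges.items() if p == child]

    def smallest_containing_edge(self, leaves: set[str]) -> int:
        """Edge of the smallest clade containing all given leaves."""
        candidates = [
            (len(m), e) for e, m in self.clade_map.items() if leaves <= m
        ]
        if not candidates:
            raise ValueError(f"no clade contains leaves {sorted(leaves)}")
        return min(candidates)[1]


def build_package(
    genomes: list[ReferenceGenome],
    tree_file,
) -> ReferencePackage:
    """Number tree edges and build clade maps for a set of genomes.

    ``tree_file`` is a newick path or open handle.  Tree leaf labels must be
    a subset of the genome ids; edges are numbered by depth-first preorder
    (root-adjacent edge first), so re-reading the same file yields identical
    numbers.
    """
    if isinstance(tree_file, (str, Path)):
        tree = Phylo.read(str(tree_file), "newick")
    else:
        tree = Phylo.read(tree_file, "newick")
    by_id = {g.genome_id: g for g in genomes}
    leaf_names = [t.name for t in tree.get_terminals()]
    missing = sorted(set(leaf_names) - set(by_id))
    if missing:
        raise ValueError(f"tree leaves with no genome: {missing}")
    if len(set(leaf_names)) != len(leaf_names):
        raise ValueError("duplicate leaf labels in tree")

    # name unnamed internal nodes so edges are addressable
    counter = 0
    for clade in tree.find_clades(order="preorder"):
        if not clade.name:
            clade.name = f"node{counter}"
            counter += 1

    parent_of = {}
    for clade in tree.find_clades(order="preorder"):
        for child in clade.clades:
            parent_of[child] = clade

    edges: dict[int, tuple[str, str]] = {}
    clade_map: dict[int, frozenset[str]] = {}
    edge_of_node: dict[str, int] = {}
    number = 0
    for clade in tree.find_clades(order="preorder"):
        if clade is tree.root:
            continue
        edges[number] = (parent_of[clade].name, clade.name)
        clade_map[number] = frozenset(t.name for t in clade.get_terminals())
        edge_of_node[clade.name] = number
        number += 1

    alignment = {name: by_id[name].ssu_sequence for name in leaf_names}
    if len({len(s) for s in alignment.values()}) > 1:
        raise ValueError("16S sequences are not aligned to uniform length")
    return ReferencePackage(tree, edges, clade_map, alignment, edge_of_node)


def package_newick(pkg: ReferencePackage, edge_numbers: bool = False) -> str:
    """Serialize the package tree to newick, optionally with ``{N}`` edge tags."""

    def render(clade) -> str:
        if clade.clades:
            inner = ",".join(render(c) for c in clade.clades)
            label = f"({inner})"
        else:
            label = clade.name
        bl = clade.branch_length if clade.branch_length is not None else 1.0
        out = f"{label}:{bl:g}"
        if edge_numbers and clade.name in pkg.edge_of_node:
            out += "{%d}" % pkg.edge_of_node[clade.name]
        return out

    root = pkg.tree.root
    inner = ",".join(render(c) for c in root.clades)
    return f"({inner});"


def write_package(pkg: ReferencePackage, out_dir: str | Path) -> None:
    """Serialize a package as a directory with a plain-JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "tree.nwk").write_text(package_newick(pkg) + "\n")
    with open(out_dir / "alignment.fasta", "w") as fh:
        for name, seq in pkg.alignment.items():
            fh.write(f">{name}\n{seq}\n")
    rows = [
        (e, pkg.edges[e][0], pkg.edges[e][1], ",".join(sorted(pkg.clade_map[e])))
        for e in sorted(pkg.edges)
    ]
    pd.DataFrame(rows, columns=["edge_number", "parent", "child", "leaves"]).to_csv(
        out_dir / "clade_map.tsv", sep="\t", index=False
    )
    manifest = {
        "format": "metastruct-refpkg-1",
        "tree": "tree.nwk",
        "alignment": "alignment.fasta",
        "clade_map": "clade_map.tsv",
        "n_edges": pkg.n_edges,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_package(pkg_dir: str | Path) -> ReferencePackage:
    """Read a serialized package; edge numbering is recomputed from the tree
    and verified against the stored clade map."""
    pkg_dir = Path(pkg_dir)
    manifest = json.loads((pkg_dir / "manifest.json").read_text())
    alignment = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(str(pkg_dir / manifest["alignment"]), "fasta")
    }
    dummy = [
        ReferenceGenome(name, name, seq, []) for name, seq in alignment.items()
    ]
    pkg = build_package(dummy, pkg_dir / manifest["tree"])
    stored = pd.read_csv(pkg_dir / manifest["clade_map"], sep="\t")
    for row in stored.itertuples(index=False):
        if pkg.clade_map[row.edge_number] != frozenset(row.leaves.split(",")):
            raise ValueError(
                f"stored clade map disagrees with tree at edge {row.edge_number}"
            )
    return pkg
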