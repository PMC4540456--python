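"""Complete-pathway prediction and pathway abundance matrices.

A pathway is defined as an ordered list of reaction slots, each slot a set
of acceptable identifiers (EC numbers and/or normalised product-name keys).
A pathway is called present for a genome only when the fraction of covered
slots reaches the completeness threshold — by default every slot, the
conservative stance that a metabolism is not predicted unless the full
pathway is accounted for.  Matching is EC-first with product-name fallback;
partial EC codes (``1.1.1.-``) match any completion.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .placement import EdgeAbundanceMatrix
from .refpkg import EC_PATTERN, Gene

log = logging.getLogger(__name__)


@dataclass
class PathwayDefinition:
    pathway_id: str
    name: str
    reactions: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.reactions:
            raise ValueError(f"pathway {self.pathway_id}: no reaction slots")
        if any(not slot for slot in self.reactions):
            raise ValueError(f"pathway {self.pathway_id}: empty reaction slot")


@dataclass
class PathwayAbundanceMatrix:
    """Samples × pathways counts plus per-cell contributing-edge provenance."""

    abundance: pd.DataFrame  # index: samples, columns: pathway ids
    provenance: dict[tuple[str, str], list[int]]

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def pathways(self) -> list[str]:
        return list(self.abundance.columns)


def normalize_product(name: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace."""
    return re.sub(r"\s+", " ", re.sub(r"[^a-z0-9 ]", " ", name.lower())).strip()


def is_ec(identifier: str) -> bool:
    return bool(EC_PATTERN.match(identifier))


def ec_match(a: str, b: str) -> bool:
    """EC equality with ``-`` wildcard at any level, on either side."""
    fa, fb = a.split("."), b.split(".")
    if len(fa) != 4 or len(fb) != 4:
        return False
    return all(x == y or x == "-" or y == "-" for x, y in zip(fa, fb))


def inventory(cds: list[Gene]) -> set[str]:
    """Enzyme inventory of a CDS set: EC numbers plus normalised products."""
    inv: set[str] = set()
    for gene in cds:
        inv.update(gene.ec_numbers)
        if gene.product:
            inv.add(normalize_product(gene.product))
    return inv


def predict_pathways(
    inv: set[str],
    ontology: list[PathwayDefinition],
    completeness: float = 1.0,
) -> set[str]:
    """Pathways whose covered-slot fraction reaches ``completeness``."""
    if not ontology:
        raise ValueError("empty pathway ontology")
    if not 0 < completeness <= 1:
        raise ValueError("completeness must be in (0, 1]")
    inv_ecs = [x for x in inv if is_ec(x)]
    inv_products = {x for x in inv if not is_ec(x)}

    def covered(slot: frozenset[str]) -> bool:
        for ident in slot:
            if is_ec(ident):
                if any(ec_match(ident, e) for e in inv_ecs):
                    return True
            elif normalize_product(ident) in inv_products:
                return True
        return False

    present = set()
    for pw in ontology:
        n_cov = sum(1 for slot in pw.reactions if covered(slot))
        if n_cov / len(pw.reactions) >= completeness - 1e-12:
            present.add(pw.pathway_id)
    return present


def pathway_matrix(
    edge_mat: EdgeAbundanceMatrix,
    edge_pathways: dict[int, set[str]],
) -> PathwayAbundanceMatrix:
    """abundance(s, p) = Σ over edges e predicting p of counts(s, e)."""
    counts = edge_mat.counts
    nonzero_edges = [e for e in counts.columns if counts[e].sum() > 0]
    missing = sorted(e for e in nonzero_edges if e not in edge_pathways)
    if missing:
        raise ValueError(f"edges with placements but no pathway prediction: {missing}")
    pathway_ids = sorted({p for e in nonzero_edges for p in edge_pathways[e]})
    data = np.zeros((len(counts.index), len(pathway_ids)), dtype=int)
    col = {p: j for j, p in enumerate(pathway_ids)}
    provenance: dict[tuple[str, str], list[int]] = {}
    for i, sample in enumerate(counts.index):
        for e in nonzero_edges:
            c = int(counts.at[sample, e])
            if c == 0:
                continue
            for p in edge_pathways[e]:
                data[i, col[p]] += c
                provenance.setdefault((sample, p), []).append(e)
    frame = pd.DataFrame(data, index=list(counts.index), columns=pathway_ids)
    return PathwayAbundanceMatrix(frame, {k: sorted(v) for k, v in provenance.items()})


def pooled_inventory(
    partitions: list[set[str]],
    ontology: list[PathwayDefinition],
    completeness: float = 1.0,
) -> set[str]:
    """Non-partitioned prediction: one artificial genome holding every
    unique identifier found across all partitions."""
    if not partitions:
        raise ValueError("at least one partition required")
    pooled: set[str] = set().union(*partitions)
    return predict_pathways(pooled, ontology, completeness)


def redundancy_profile(matrix: PathwayAbundanceMatrix) -> pd.DataFrame:
    """Per-sample (pathway, abundance, n_edges) table.

    n_edges is the number of distinct placed edges predicting the pathway in
    that sample — low values flag abundant functions carried by few genomes,
    the low-functional-redundancy signature.
    """
    rows = []
    for sample in matrix.samples:
        for pathway in matrix.pathways:
            a = int(matrix.abundance.at[sample, pathway])
            if a == 0:
                continue
            rows.append(
                (sample, pathway, a, len(matrix.provenance[(sample, pathway)]))
            )
    return pd.DataFrame(rows, columns=["sample", "pathway", "abundance", "n_edges"])


def read_ontology(path) -> list[PathwayDefinition]:
    """Pathway ontology TSV: pathway_id, name, slot_index, identifier."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["pathway_id", "name", "slot_index", "identifier"]
    if list(frame.columns) != required:
        raise ValueError(f"ontology {path}: expected columns {required}")
    out = []
    for pid, grp in frame.groupby("pathway_id", sort=True):
        name = grp["name"].iloc[0]
        slots = []
        for _, slot_grp in grp.groupby(grp["slot_index"].astype(int), sort=True):
            slots.append(frozenset(slot_grp["identifier"]))
        out.append(PathwayDefinition(pid, name, tuple(slots)))
    return out


def write_ontology(ontology: list[PathwayDefinition], path) -> None:
    rows = [
        (pw.pathway_id, pw.name, i, ident)
        for pw in ontology
        for i, slot in enumerate(pw.reactions)
        for ident in sorted(slot)
    ]
    pd.DataFrame(rows, columns=["pathway_id", "name", "slot_index", "identifier"]).to_csv(
        path, sep="\t", index=False
    )
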