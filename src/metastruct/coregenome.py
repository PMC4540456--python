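"""Per-edge core genomes and the inference quality score q.

A read placed on a terminal edge is assigned the full genome of that leaf.
A read placed on an internal edge is assigned the *core genome* of the
clade below the edge: one clade member's CDS set trimmed to the genes shared
by every member.  Confidence in each inference is

    q = (S_core / S_clade) · (1 − φ)

where S_core is the retained gene count, S_clade the mean genome size of
the clade, and φ the genomic plasticity index; the first factor is 1 on
terminal edges.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .plasticity import PlasticityIndex
from .refpkg import ReferenceGenome, ReferencePackage

log = logging.getLogger(__name__)


class ExactGeneFamilySearch:
    """Similarity-search engine matching genes by shared family label.

    The test oracle and the default for synthetic data, where ``gene_id``
    is a family identifier common to all genomes carrying the gene.
    """

    engine_id = "exact"

    def hits(
        self,
        query: ReferenceGenome,
        database: ReferenceGenome,
        evalue_cutoff: float = 1.0,
    ) -> set[str]:
        """Database gene ids with at least one exact family match in query."""
        return database.gene_ids & query.gene_ids


class BlastSearch:
    """External-aligner adapter: blastp of query CDS against a database
    genome's proteome, any hit at or below the e-value cutoff counts."""

    engine_id = "blast"

    def __init__(self) -> None:
        if shutil.which("makeblastdb") is None or shutil.which("blastp") is None:
            raise RuntimeError("blast binaries not found on PATH")

    def hits(
        self,
        query: ReferenceGenome,
        database: ReferenceGenome,
        evalue_cutoff: float = 1.0,
    ) -> set[str]:
        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            db_fa = tmp / "db.faa"
            q_fa = tmp / "query.faa"
            db_fa.write_text(
                "".join(f">{g.gene_id}\n{g.aa_sequence}\n" for g in database.cds)
            )
            q_fa.write_text(
                "".join(f">{g.gene_id}\n{g.aa_sequence}\n" for g in query.cds)
            )
            try:
                subprocess.run(
                    ["makeblastdb", "-in", str(db_fa), "-dbtype", "prot"],
                    check=True, capture_output=True, text=True,
                )
                proc = subprocess.run(
                    [
                        "blastp", "-query", str(q_fa), "-db", str(db_fa),
                        "-evalue", str(evalue_cutoff), "-outfmt", "6 sseqid",
                    ],
                    check=True, capture_output=True, text=True,
                )
            except subprocess.CalledProcessError as exc:
                raise RuntimeError(f"blast search failed: {exc.stderr}") from exc
        return {line.strip() for line in proc.stdout.splitlines() if line.strip()}


@dataclass
class CoreGenome:
    """Genes of one reference genome shared by every member of a clade."""

    edge_number: int
    reference_genome_id: str
    retained_cds: list[str]
    s_core: int
    s_clade: float
    clade_members: frozenset[str] = field(default_factory=frozenset)


@dataclass
class QualityScore:
    edge_number: int
    q: float


def shared_cds(
    reference: ReferenceGenome,
    others: list[ReferenceGenome],
    search,
    evalue_cutoff: float = 1.0,
) -> list[str]:
    """Reference CDS hit by *every* other clade member.

    With no others (terminal case) the full CDS list is returned.
    """
    retained = reference.gene_ids
    for other in others:
        retained &= search.hits(other, reference, evalue_cutoff)
        if not retained:
            break
    return [g.gene_id for g in reference.cds if g.gene_id in retained]


def build_core_genomes(
    pkg: ReferencePackage,
    genomes: list[ReferenceGenome],
    search=None,
    evalue_cutoff: float = 1.0,
) -> dict[int, CoreGenome]:
    """Core genome for every edge of the reference package.

    Terminal edges carry the leaf genome verbatim.  For internal edges the
    database genome is the clade member with the largest gene count (ties
    by lexicographic genome_id) and the retained set is the intersection of
    per-member hit sets; pairwise hit sets are memoised since clades nest.
    """
    if search is None:
        search = ExactGeneFamilySearch()
    by_id = {g.genome_id: g for g in genomes}
    missing = sorted(set().union(*pkg.clade_map.values()) - set(by_id))
    if missing:
        raise ValueError(f"clade members with no genome: {missing}")

    hit_cache: dict[tuple[str, str], set[str]] = {}

    def hits(query_id: str, db_id: str) -> set[str]:
        key = (query_id, db_id)
        if key not in hit_cache:
            hit_cache[key] = search.hits(by_id[query_id], by_id[db_id], evalue_cutoff)
        return hit_cache[key]

    cores: dict[int, CoreGenome] = {}
    for edge in sorted(pkg.clade_map):
        members = pkg.clade_map[edge]
        s_clade = float(np.mean([by_id[m].gene_count for m in members]))
        if len(members) == 1:
            ref = by_id[next(iter(members))]
            retained = [g.gene_id for g in ref.cds]
        else:
            ref = by_id[min(members, key=lambda m: (-by_id[m].gene_count, m))]
            kept = ref.gene_ids
            for m in sorted(members):
                if m == ref.genome_id:
                    continue
                kept &= hits(m, ref.genome_id)
            retained = [g.gene_id for g in ref.cds if g.gene_id in kept]
        cores[edge] = CoreGenome(
            edge, ref.genome_id, retained, len(retained), s_clade, members
        )
    return cores


def quality(
    core: CoreGenome,
    phi: PlasticityIndex,
    is_terminal: bool,
    aggregate: str = "mean",
) -> QualityScore:
    """q = (S_core/S_clade)·(1−φ), clipped to [0, 1].

    The size ratio is 1 on terminal edges (genome size gives no stability
    signal there).  φ for an internal edge is the mean (or, with
    ``aggregate="max"``, the maximum) of its clade members' φ.
    """
    members = core.clade_members or frozenset([core.reference_genome_id])
    missing = sorted(m for m in members if m not in phi.phi)
    if missing:
        raise ValueError(f"phi missing for genomes: {missing}")
    values = [phi.phi[m] for m in members]
    phi_eff = max(values) if aggregate == "max" else float(np.mean(values))
    ratio = 1.0 if is_terminal else (core.s_core / core.s_clade if core.s_clade > 0 else 0.0)
    q = ratio * (1.0 - phi_eff)
    return QualityScore(core.edge_number, float(min(1.0, max(0.0, q))))


def quality_scores(
    cores: dict[int, CoreGenome],
    phi: PlasticityIndex,
    pkg: ReferencePackage,
    aggregate: str = "mean",
) -> dict[int, QualityScore]:
    return {
        e: quality(core, phi, pkg.is_terminal(e), aggregate)
        for e, core in cores.items()
    }


def sample_quality(
    placements: dict[int, int | float],
    scores: dict[int, QualityScore],
    weighted: bool = True,
) -> float:
    """Mean q over a sample's placed reads.

    Default weights each placement by its read abundance; ``weighted=False``
    averages once per distinct placed edge instead.
    """
    placed = {e: a for e, a in placements.items() if a > 0}
    if not placed:
        raise ValueError("empty sample: no placed reads")
    unscored = sorted(e for e in placed if e not in scores)
    if unscored:
        raise ValueError(f"edges with placements but no quality score: {unscored}")
    if weighted:
        total = sum(placed.values())
        return float(sum(a * scores[e].q for e, a in placed.items()) / total)
    return float(np.mean([scores[e].q for e in placed]))
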