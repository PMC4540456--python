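"""Synthetic reference packages, genomes, placements, and pathway ontologies.

Everything downstream of external tools (alignment, tree inference,
likelihood placement) is generated here with known ground truth so the full
pipeline is testable offline: genomes evolve down a tree with per-site 16S
substitution and gene-content churn (loss/replacement from a global gene
pool), communities are drawn from group-specific Dirichlet edge profiles,
and pathway definitions are seeded from genes the genomes actually carry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from . import refpkg
from .pathways import PathwayDefinition
from .refpkg import Gene, ReferenceGenome, ReferencePackage

AA_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
NT_ALPHABET = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Sizes are desk-scale stand-ins for a genome collection: tens of genomes
    of ~120 genes, hundreds of reads per sample, two environment types.
    """

    n_genomes: int = 16
    tree_shape: str = "random"  # "balanced" | "caterpillar" | "random"
    ssu_mutation_rate: float = 0.05  # substitutions per site per branch
    gene_churn_rates: dict[str, float] | None = None  # leaf -> fraction replaced
    plastic_fraction: float = 0.2
    background_churn: float = 0.02
    plastic_multiplier: float = 10.0
    n_pathways: int = 40
    pathway_size_range: tuple[int, int] = (2, 5)
    n_samples: int = 12
    reads_per_sample: int = 300
    group_effect: float = 5.0  # Dirichlet weight difference between groups
    seed: int = 0
    genome_size: int = 120
    gene_length: int = 60
    ssu_length: int = 1500
    ec_fraction: float = 0.7
    gene_pool_factor: int = 5

    def __post_init__(self) -> None:
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")
        for name in ("ssu_mutation_rate", "background_churn", "group_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimulationTruth:
    """Ground truth recorded during simulation."""

    churn_rates: dict[str, float]
    true_cores: dict[int, frozenset[str]]  # edge -> intersected gene families
    newick: str


def _leaf_names(n: int) -> list[str]:
    return [f"G{i:03d}" for i in range(n)]


def _topology(names: list[str], shape: str, rng: np.random.Generator):
    """Nested-list tree topology over the leaf names."""
    if shape == "balanced":

        def split(part):
            if len(part) == 1:
                return part[0]
            mid = len(part) // 2
            return [split(part[:mid]), split(part[mid:])]

        return split(names)
    if shape == "caterpillar":
        node = [names[0], names[1]]
        for name in names[2:]:
            node = [node, name]
        return node
    if shape == "random":
        nodes = list(names)
        while len(nodes) > 2:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            merged = [nodes[i], nodes[j]]
            nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
            nodes.append(merged)
        return [nodes[0], nodes[1]] if len(nodes) == 2 else nodes[0]
    raise ValueError(f"unknown tree shape {shape!r}")


def _to_newick(node) -> str:
    def render(x) -> str:
        if isinstance(x, str):
            return f"{x}:1"
        return "(" + ",".join(render(c) for c in x) + "):1"

    return "(" + ",".join(render(c) for c in node) + ");"


def _make_gene_pool(cfg: SimulationConfig, rng: np.random.Generator) -> dict[str, Gene]:
    n_pool = cfg.gene_pool_factor * cfg.genome_size
    pool: dict[str, Gene] = {}
    for i in range(n_pool):
        fam = f"fam{i:04d}"
        seq = "".join(rng.choice(AA_ALPHABET, size=cfg.gene_length))
        if rng.random() < cfg.ec_fraction:
            ecs = (
                f"{rng.integers(1, 7)}.{rng.integers(1, 21)}."
                f"{rng.integers(1, 21)}.{rng.integers(1, 51)}",
            )
        else:
            ecs = ()
        pool[fam] = Gene(fam, f"enzyme family {i}", ecs, seq)
    return pool


def _mutate_ssu(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = NT_ALPHABET[NT_ALPHABET != out[i]]
        out[i] = rng.choice(choices)
    return out


def _churn_genes(
    genes: set[str],
    rate: float,
    pool_ids: list[str],
    rng: np.random.Generator,
) -> set[str]:
    n_replace = int(rng.binomial(len(genes), min(rate, 1.0)))
    if n_replace == 0:
        return set(genes)
    out = set(genes)
    lose = rng.choice(sorted(out), size=n_replace, replace=False)
    out -= set(lose)
    novel = [f for f in pool_ids if f not in out]
    gain = rng.choice(novel, size=min(n_replace, len(novel)), replace=False)
    out |= set(gain)
    return out


def simulate_package(
    cfg: SimulationConfig,
) -> tuple[ReferencePackage, list[ReferenceGenome], SimulationTruth]:
    """Evolve genomes down a tree and assemble the reference package.

    16S evolves by per-site substitution (no indels, so sequences stay
    aligned); gene content churns at the background rate on internal
    branches and at each leaf's own rate on its terminal branch.  A plastic
    subset of leaves receives ``plastic_multiplier`` × the background rate.
    The truth record stores per-leaf churn rates and the brute-force
    per-edge core gene sets.
    """
    rng = np.random.default_rng(cfg.seed)
    names = _leaf_names(cfg.n_genomes)
    topo = _topology(names, cfg.tree_shape, rng)
    newick = _to_newick(topo)

    pool = _make_gene_pool(cfg, rng)
    pool_ids = sorted(pool)

    if cfg.gene_churn_rates is not None:
        leaf_rates = dict(cfg.gene_churn_rates)
    else:
        n_plastic = int(round(cfg.plastic_fraction * cfg.n_genomes))
        plastic = set(
            rng.choice(names, size=n_plastic, replace=False)
        ) if n_plastic else set()
        leaf_rates = {
            name: cfg.background_churn * (cfg.plastic_multiplier if name in plastic else 1.0)
            for name in names
        }

    root_genes = set(rng.choice(pool_ids, size=cfg.genome_size, replace=False))
    root_ssu = rng.choice(NT_ALPHABET, size=cfg.ssu_length)

    leaf_state: dict[str, tuple[set[str], np.ndarray]] = {}

    def walk(node, genes: set[str], ssu: np.ndarray) -> None:
        for child in node:
            rate = leaf_rates[child] if isinstance(child, str) else cfg.background_churn
            child_genes = _churn_genes(genes, rate, pool_ids, rng)
            child_ssu = _mutate_ssu(ssu, cfg.ssu_mutation_rate, rng)
            if isinstance(child, str):
                leaf_state[child] = (child_genes, child_ssu)
            else:
                walk(child, child_genes, child_ssu)

    walk(topo, root_genes, root_ssu)

    genomes = [
        ReferenceGenome(
            name,
            f"synthetic taxon {name}",
            "".join(leaf_state[name][1]),
            [pool[f] for f in sorted(leaf_state[name][0])],
        )
        for name in names
    ]
    pkg = refpkg.build_package(genomes, StringIO(newick))
    true_cores = {
        e: frozenset.intersection(
            *(frozenset(leaf_state[m][0]) for m in members)
        )
        for e, members in pkg.clade_map.items()
    }
    truth = SimulationTruth({n: leaf_rates[n] for n in names}, true_cores, newick)
    return pkg, genomes, truth


def simulate_ontology(
    genomes: list[ReferenceGenome],
    cfg: SimulationConfig,
    seed: int | None = None,
) -> list[PathwayDefinition]:
    """Pathway definitions seeded from genes the genomes actually carry.

    Each pathway's slots are drawn from one host genome's CDS (EC number
    when annotated, product name otherwise), so the pathway is complete in
    its host by construction and complete elsewhere only where the genes
    are shared.
    """
    rng = np.random.default_rng(cfg.seed + 101 if seed is None else seed)
    lo, hi = cfg.pathway_size_range
    ontology = []
    for i in range(cfg.n_pathways):
        host = genomes[int(rng.integers(len(genomes)))]
        size = int(rng.integers(lo, hi + 1))
        size = min(size, host.gene_count)
        picks = rng.choice(len(host.cds), size=size, replace=False)
        slots = tuple(
            frozenset(
                {host.cds[j].ec_numbers[0]}
                if host.cds[j].ec_numbers
                else {host.cds[j].product}
            )
            for j in sorted(picks)
        )
        ontology.append(PathwayDefinition(f"pwy{i:03d}", f"pathway {i:03d}", slots))
    return ontology


def simulate_communities(
    pkg: ReferencePackage,
    cfg: SimulationConfig,
    out_dir: str | Path,
) -> tuple[dict[str, Path], dict[str, Path], dict[str, str]]:
    """Write per-sample jplace and metadata files for two environment types.

    Terminal-edge profiles come from group-specific Dirichlet weights: one
    half of the edges gets weight 1 + ``group_effect`` in group A, the other
    half in group B (with ``group_effect`` 0 the groups are exchangeable).
    Reads are drawn multinomially and placed with like-weight ratio 1.0 on
    their true edge.  Returns (jplace paths, metadata paths, truth groups).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2029]))
    terminal = sorted(e for e in pkg.clade_map if pkg.is_terminal(e))
    half = len(terminal) // 2
    alpha_a = np.ones(len(terminal))
    alpha_b = np.ones(len(terminal))
    alpha_a[:half] += cfg.group_effect
    alpha_b[half:] += cfg.group_effect

    tree_str = refpkg.package_newick(pkg, edge_numbers=True)
    n_a = cfg.n_samples - cfg.n_samples // 2
    groups: dict[str, str] = {}
    jplace_paths: dict[str, Path] = {}
    meta_paths: dict[str, Path] = {}
    leaf_of_edge = {e: next(iter(pkg.clade_map[e])) for e in terminal}

    for s in range(cfg.n_samples):
        group = "A" if s < n_a else "B"
        sample = f"sample_{group}{s:02d}"
        groups[sample] = group
        profile = rng.dirichlet(alpha_a if group == "A" else alpha_b)
        counts = rng.multinomial(cfg.reads_per_sample, profile)
        placements = []
        meta_rows = []
        read_no = 0
        for edge, count in zip(terminal, counts):
            for _ in range(count):
                read_id = f"{sample}_r{read_no:05d}"
                read_no += 1
                placements.append(
                    {"p": [[int(edge), -1.0, 1.0, 0.0, 0.0]], "n": [read_id]}
                )
                meta_rows.append(
                    (
                        read_id, 150, 1, 150,
                        f"Bacteria;SynthPhylum;{leaf_of_edge[edge]}",
                    )
                )
        doc = {
            "version": 3,
            "tree": tree_str,
            "fields": [
                "edge_num", "likelihood", "like_weight_ratio",
                "distal_length", "pendant_length",
            ],
            "placements": placements,
            "metadata": {"invocation": "metastruct simulate"},
        }
        jpath = out_dir / f"{sample}.jplace"
        jpath.write_text(json.dumps(doc, indent=1, sort_keys=True))
        mpath = out_dir / f"{sample}.meta.tsv"
        pd.DataFrame(
            meta_rows,
            columns=["read_id", "length", "align_start", "align_end", "classification"],
        ).to_csv(mpath, sep="\t", index=False)
        jplace_paths[sample] = jpath
        meta_paths[sample] = mpath

    pd.DataFrame(
        sorted(groups.items()), columns=["sample", "group"]
    ).to_csv(out_dir / "groups.tsv", sep="\t", index=False)
    return jplace_paths, meta_paths, groups
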