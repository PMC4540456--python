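"""Ingest phylogenetic placements and build sample × edge count matrices.

Primary input is jplace (versions 2 and 3): the placer's tree with
``{N}``-annotated edges plus per-read placement records.  jplace edge
numbers are remapped onto the package's own numbering by matching each
edge's descendant leaf set, so any placer's numbering scheme works.  A
naive fallback placer (best aligned identity against the reference leaves)
is bundled so the pipeline runs without an external placement binary.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .refpkg import GAP_CHARS, ReferencePackage

log = logging.getLogger(__name__)


@dataclass
class PlacedRead:
    read_id: str
    edge_number: int
    like_weight_ratio: float
    classification: str = "unclassified"


@dataclass
class EdgeAbundanceMatrix:
    """Samples × edges integer count matrix (all-zero edges dropped)."""

    counts: pd.DataFrame  # index: samples, columns: edge numbers

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def edges(self) -> list[int]:
        return list(self.counts.columns)


def _jplace_edge_leafsets(tree_str: str) -> dict[int, frozenset[str]]:
    """Leaf set below each ``{N}``-annotated edge of a jplace tree string."""
    leafsets: dict[int, frozenset[str]] = {}
    stack: list[set[str]] = []
    last: set[str] | None = None  # leaf set of the most recently closed element
    i, n = 0, len(tree_str)
    while i < n:
        c = tree_str[i]
        if c == "(":
            stack.append(set())
            i += 1
        elif c == ")":
            last = stack.pop()
            if stack:
                stack[-1] |= last
            i += 1
        elif c in ",;":
            i += 1
        elif c == "{":
            j = tree_str.index("}", i)
            edge = int(tree_str[i + 1 : j])
            if last is None:
                raise ValueError(f"malformed jplace tree near offset {i}")
            leafsets[edge] = frozenset(last)
            i = j + 1
        elif c == ":":
            # branch length: skip to next structural character
            i += 1
            while i < n and tree_str[i] not in "(),;{":
                i += 1
        else:
            j = i
            while j < n and tree_str[j] not in "(),;:{":
                j += 1
            name = tree_str[i:j].strip()
            if name:
                last = {name}
                if stack:
                    stack[-1].add(name)
            i = j
    return leafsets


def _edge_map(tree_str: str, pkg: ReferencePackage) -> dict[int, int]:
    """Map jplace edge numbers to package edge numbers by leaf-set identity.

    A jplace edge whose leaf set is the complement of a package clade (the
    root-adjacent edge seen from the other side of an unrooted tree) maps to
    that clade's edge.
    """
    leafsets = _jplace_edge_leafsets(tree_str)
    jplace_leaves = frozenset().union(*leafsets.values()) if leafsets else frozenset()
    if jplace_leaves != pkg.leaves:
        raise ValueError(
            "jplace tree topology does not match the reference package: "
            f"leaf sets differ ({len(jplace_leaves)} vs {len(pkg.leaves)} leaves)"
        )
    by_clade = {members: e for e, members in pkg.clade_map.items()}
    mapping: dict[int, int] = {}
    for jedge, leaves in leafsets.items():
        if leaves in by_clade:
            mapping[jedge] = by_clade[leaves]
        else:
            complement = pkg.leaves - leaves
            if complement in by_clade:
                mapping[jedge] = by_clade[complement]
    return mapping


def read_jplace(file: str | Path, pkg: ReferencePackage) -> list[PlacedRead]:
    """Read placements from a jplace file, keeping one placement per read.

    For multi-placement records the placement with the highest like-weight
    ratio is kept (ties broken by the lowest jplace edge number); edge
    numbers are then remapped onto the package numbering by topology.
    """
    path = Path(file)
    try:
        doc = json.loads(path.read_text())
        fields = doc["fields"]
        edge_idx = fields.index("edge_num")
        lwr_idx = fields.index("like_weight_ratio")
        tree_str = doc["tree"]
        records = doc["placements"]
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise ValueError(f"malformed jplace file {path}: {exc}") from exc

    mapping = _edge_map(tree_str, pkg)
    reads: list[PlacedRead] = []
    for rec in records:
        if "n" in rec:
            names = rec["n"]
        elif "nm" in rec:
            names = [nm[0] for nm in rec["nm"]]
        else:
            raise ValueError(f"malformed jplace file {path}: record without names")
        best = min(rec["p"], key=lambda p: (-p[lwr_idx], p[edge_idx]))
        jedge = int(best[edge_idx])
        if jedge not in mapping:
            raise ValueError(
                f"jplace edge {jedge} in {path} has no topological match "
                "in the reference package"
            )
        for name in names:
            reads.append(PlacedRead(name, mapping[jedge], float(best[lwr_idx])))
    return reads


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sidecar read-metadata TSV: read_id, length, align_start, align_end,
    classification; indexed by read_id."""
    frame = pd.read_csv(path, sep="\t", dtype={"read_id": str, "classification": str})
    required = {"read_id", "length", "align_start", "align_end", "classification"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"metadata {path} missing columns: {sorted(missing)}")
    return frame.set_index("read_id")


def _classified_below_domain(classification: str) -> bool:
    levels = [
        t for t in str(classification).split(";")
        if t and t.lower() not in {"unclassified", "unknown"}
    ]
    return len(levels) >= 2


def filter_reads(
    reads: list[PlacedRead],
    meta: pd.DataFrame,
    min_len: int = 100,
    region: tuple[int, int] | None = None,
) -> list[PlacedRead]:
    """Apply the read filters: minimum length, optional alignment-region
    containment, and classification below the domain level.

    ``meta`` is the sidecar table from :func:`read_metadata`.  A read
    missing from the table is fatal.  Removal counts per reason are logged.
    """
    if meta is None:
        raise ValueError("read metadata required for filtering")
    absent = sorted(r.read_id for r in reads if r.read_id not in meta.index)
    if absent:
        raise ValueError(f"reads missing from metadata: {absent[:5]}...")
    kept: list[PlacedRead] = []
    removed = {"length": 0, "region": 0, "classification": 0}
    for read in reads:
        row = meta.loc[read.read_id]
        if int(row["length"]) < min_len:
            removed["length"] += 1
            continue
        if region is not None:
            start, end = region
            if int(row["align_start"]) < start or int(row["align_end"]) > end:
                removed["region"] += 1
                continue
        if not _classified_below_domain(row["classification"]):
            removed["classification"] += 1
            continue
        read.classification = str(row["classification"])
        kept.append(read)
    log.info("filter_reads removed %s; kept %d", removed, len(kept))
    return kept


def _sample_rng(seed: int, sample: str) -> np.random.Generator:
    # child seed from (master seed, sample name) so adding a sample never
    # reshuffles the others; crc32 keeps it stable across interpreter runs
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(sample.encode())])
    )


def rarefy(
    reads_by_sample: dict[str, list[PlacedRead]],
    depth: int,
    seed: int = 0,
) -> dict[str, list[PlacedRead]]:
    """Subsample every sample to the same depth, without replacement."""
    out: dict[str, list[PlacedRead]] = {}
    for sample, reads in reads_by_sample.items():
        if depth > len(reads):
            raise ValueError(
                f"sample {sample}: depth {depth} exceeds library size {len(reads)}"
            )
        rng = _sample_rng(seed, sample)
        idx = rng.choice(len(reads), size=depth, replace=False)
        out[sample] = [reads[i] for i in sorted(idx)]
    return out


def edge_matrix(samples: dict[str, list[PlacedRead]]) -> EdgeAbundanceMatrix:
    """Tabulate placements: counts(s, e) = reads of sample s on edge e."""
    edges = sorted({r.edge_number for reads in samples.values() for r in reads})
    data = np.zeros((len(samples), len(edges)), dtype=int)
    col = {e: j for j, e in enumerate(edges)}
    for i, (_, reads) in enumerate(samples.items()):
        for r in reads:
            data[i, col[r.edge_number]] += 1
    frame = pd.DataFrame(data, index=list(samples), columns=edges)
    frame = frame.loc[:, frame.sum(axis=0) > 0]
    return EdgeAbundanceMatrix(frame)


def naive_place(
    queries: dict[str, str], pkg: ReferencePackage
) -> list[PlacedRead]:
    """Fallback placer: best aligned identity against the reference leaves.

    A query identical (or closest) to a single leaf goes on that leaf's
    terminal edge; ties among several leaves go on the edge of the smallest
    clade containing them all.  Queries must be in the package alignment's
    coordinate system (same length).
    """
    leaf_edge = pkg.terminal_edge_of_leaf
    names = list(pkg.alignment)
    ref = np.array([list(pkg.alignment[n]) for n in names])
    ref_gap = np.isin(ref, list(GAP_CHARS))
    placed: list[PlacedRead] = []
    for read_id, seq in queries.items():
        if len(seq) != ref.shape[1]:
            raise ValueError(
                f"query {read_id}: length {len(seq)} does not match "
                f"alignment width {ref.shape[1]}"
            )
        q = np.array(list(seq))
        q_gap = np.isin(q, list(GAP_CHARS))
        scores = []
        for i in range(len(names)):
            ok = ~ref_gap[i] & ~q_gap
            scores.append((ref[i, ok] == q[ok]).mean() if ok.any() else 0.0)
        scores = np.asarray(scores)
        best = scores.max()
        winners = {names[i] for i in np.flatnonzero(scores == best)}
        if len(winners) == 1:
            edge = leaf_edge[next(iter(winners))]
        else:
            edge = pkg.smallest_containing_edge(winners)
        placed.append(PlacedRead(read_id, edge, 1.0))
    return placed
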