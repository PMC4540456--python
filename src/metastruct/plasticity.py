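"""Genomic plasticity index (φ) from proteome composition vs 16S divergence.

The idea: two genomes whose proteomes have drifted far apart (measured by
Bray-Curtis distance between 5-amino-acid k-mer frequency vectors) should
also show large 16S rRNA gene distance.  Genomes whose 16S distances are
systematically *smaller* than an exponential model d16 = a·exp(b·dcv)
predicts have gained/lost/duplicated genes faster than their marker gene
diverged — high genomic plasticity.  φ is the min-max-scaled mean model
residual (predicted − observed) per genome.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.decomposition import PCA

from .refpkg import GAP_CHARS, ReferenceGenome

log = logging.getLogger(__name__)

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class CompositionalVector:
    """Overlapping amino-acid k-mer counts for one genome's full proteome."""

    genome_id: str
    counts: dict[str, int]

    @property
    def normalized(self) -> dict[str, float]:
        total = sum(self.counts.values())
        if total == 0:
            return {}
        return {k: v / total for k, v in self.counts.items()}


@dataclass
class KmerReduction:
    """K-mers ranked by their variance-weighted loading magnitude."""

    selected_kmers: list[str]
    magnitudes: dict[str, float]
    n_components: int
    variance_explained: float


@dataclass
class DistanceModel:
    """Fitted exponential d16 = a·exp(b·dcv) and its residuals."""

    a: float
    b: float
    r_squared: float
    d16_matrix: np.ndarray | None = None
    dcv_matrix: np.ndarray | None = None
    residuals: np.ndarray | None = None
    genome_ids: list[str] | None = None

    def predict(self, dcv):
        """Model 16S distance at a given compositional-vector distance."""
        return self.a * np.exp(self.b * np.asarray(dcv, dtype=float))


@dataclass
class PlasticityIndex:
    """φ per genome: 0 = most stable observed, 1 = most plastic observed."""

    phi: dict[str, float]


def count_kmers(
    aa_sequences: list[str], k: int = 5, genome_id: str = ""
) -> CompositionalVector:
    """Count overlapping k-mers across all CDS of one genome.

    K-mers containing letters outside the 20 standard amino acids are
    dropped; sequences shorter than ``k`` contribute nothing.  An empty
    proteome yields an empty vector (flagged, not fatal).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    for seq in aa_sequences:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if set(kmer) <= STANDARD_AA:
                counts[kmer] = counts.get(kmer, 0) + 1
    if not counts:
        log.warning("genome %s: empty proteome or no valid k-mers", genome_id)
    return CompositionalVector(genome_id, counts)


def frequency_matrix(
    vectors: list[CompositionalVector], kmers: list[str] | None = None
) -> pd.DataFrame:
    """Genomes × k-mers frequency matrix (union of k-mers, sorted)."""
    if kmers is None:
        universe: set[str] = set()
        for v in vectors:
            universe.update(v.counts)
        kmers = sorted(universe)
    data = np.zeros((len(vectors), len(kmers)))
    index = {k: j for j, k in enumerate(kmers)}
    for i, v in enumerate(vectors):
        for kmer, freq in v.normalized.items():
            j = index.get(kmer)
            if j is not None:
                data[i, j] = freq
    return pd.DataFrame(data, index=[v.genome_id for v in vectors], columns=kmers)


def reduce_kmers(
    vectors: list[CompositionalVector],
    n_sample: int,
    variance_target: float = 0.9,
    n_keep: int = 100_000,
    seed: int = 0,
    scale: bool = False,
) -> KmerReduction:
    """Rank k-mers by PCA loading magnitude on a random genome subsample.

    PCA is run on the centred frequency matrix of ``n_sample`` randomly
    chosen genomes; components are retained until cumulative explained
    variance reaches ``variance_target``; each k-mer is scored by the sum
    over retained components of |loading| × component variance fraction.
    The top ``n_keep`` k-mers by score are returned in descending order.
    """
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must be in (0, 1]")
    if n_sample > len(vectors):
        raise ValueError("n_sample exceeds number of vectors")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(vectors), size=n_sample, replace=False)
    matrix = frequency_matrix([vectors[i] for i in sorted(chosen)])
    kmers = list(matrix.columns)
    if n_keep > len(kmers):
        log.warning("n_keep %d exceeds k-mer universe %d; keeping all", n_keep, len(kmers))
        n_keep = len(kmers)

    values = matrix.to_numpy()
    if scale:
        sd = values.std(axis=0)
        sd[sd == 0] = 1.0
        values = values / sd
    if np.allclose(values.var(axis=0), 0):
        log.warning("degenerate PCA: identical vectors; lexicographic order")
        sel = sorted(kmers)[:n_keep]
        return KmerReduction(sel, {k: 0.0 for k in sel}, 0, 0.0)

    pca = PCA(n_components=min(len(values) - 1, len(kmers)))
    pca.fit(values)
    evr = pca.explained_variance_ratio_
    n_comp = int(np.searchsorted(np.cumsum(evr), variance_target) + 1)
    n_comp = min(n_comp, len(evr))
    score = (np.abs(pca.components_[:n_comp]) * evr[:n_comp, None]).sum(axis=0)
    order = sorted(range(len(kmers)), key=lambda j: (-score[j], kmers[j]))
    selected = [kmers[j] for j in order[:n_keep]]
    return KmerReduction(
        selected,
        {kmers[j]: float(score[j]) for j in order[:n_keep]},
        n_comp,
        float(np.cumsum(evr)[n_comp - 1]),
    )


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity 1 − 2·Σmin(x,y)/Σ(x+y) in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must share an index space")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def cv_distance_matrix(
    vectors: list[CompositionalVector], kmers: list[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Pairwise Bray-Curtis distances between compositional vectors.

    When ``kmers`` is given (a reduction), frequencies are restricted to
    those k-mers without renormalising — the partial-vector convention.
    """
    matrix = frequency_matrix(vectors, kmers)
    values = matrix.to_numpy()
    n = len(values)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(values[i], values[j])
    return list(matrix.index), d


def ssu_distance_matrix(alignment: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Pairwise p-distances on aligned 16S sequences.

    Distance is mismatches / compared sites over columns where both
    sequences are non-gap; a pair with no shared columns is fatal.
    """
    names = list(alignment)
    arr = np.array([list(alignment[n]) for n in names])
    gap = np.isin(arr, list(GAP_CHARS))
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            if not ok.any():
                raise ValueError(f"no shared columns between {names[i]} and {names[j]}")
            d[i, j] = d[j, i] = float((arr[i, ok] != arr[j, ok]).mean())
    return names, d


def normalize_distances(d: np.ndarray) -> np.ndarray:
    """Z-score then min-max scale a distance matrix to [0, 1].

    Statistics are computed over the upper triangle excluding the diagonal;
    the output is symmetric with zero diagonal, min 0 and max 1.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(d, d.T):
        raise ValueError("matrix is not symmetric")
    iu = np.triu_indices_from(d, k=1)
    vals = d[iu]
    if len(vals) < 2 or vals.std() == 0:
        raise ValueError("degenerate distance matrix: zero variance")
    z = (vals - vals.mean()) / vals.std()
    scaled = (z - z.min()) / (z.max() - z.min())
    out = np.zeros_like(d)
    out[iu] = scaled
    out = out + out.T
    return out


def fit_exponential(
    dcv: np.ndarray,
    d16: np.ndarray,
    seed: int = 0,
    max_restarts: int = 10,
    genome_ids: list[str] | None = None,
) -> DistanceModel:
    """Nonlinear least squares for d16 = a·exp(b·dcv).

    Square symmetric matrices are fitted on upper-triangle pairs only;
    1-D arrays are used as-is.  Initialisation a₀ = min positive d16,
    b₀ = log(max d16 / a₀), with up to ``max_restarts`` jittered restarts.
    """
    dcv = np.asarray(dcv, dtype=float)
    d16 = np.asarray(d16, dtype=float)
    if dcv.shape != d16.shape:
        raise ValueError("dcv and d16 shapes differ")
    square = dcv.ndim == 2
    if square:
        iu = np.triu_indices_from(dcv, k=1)
        x, y = dcv[iu], d16[iu]
    else:
        x, y = dcv, d16

    positive = y[y > 0]
    if len(positive) == 0:
        raise ValueError("all observed distances are zero; cannot fit")
    a0 = float(positive.min())
    ymax = float(y.max())
    b0 = math.log(ymax / a0) if ymax > a0 else 0.0

    rng = np.random.default_rng(seed)
    errors = []
    for attempt in range(max_restarts):
        if attempt == 0:
            p0 = (a0, b0)
        else:
            p0 = (a0 * rng.lognormal(0, 0.5), b0 + rng.normal(0, 1.0))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    lambda t, a, b: a * np.exp(b * t), x, y, p0=p0, maxfev=20_000
                )
            a, b = float(popt[0]), float(popt[1])
            break
        except RuntimeError as exc:  # pragma: no cover - depends on data
            errors.append(str(exc))
    else:
        raise RuntimeError(
            f"exponential fit failed after {max_restarts} restarts: {errors[-1]}"
        )

    pred = a * np.exp(b * x)
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DistanceModel(
        a, b, r2,
        d16_matrix=d16 if square else None,
        dcv_matrix=dcv if square else None,
        genome_ids=genome_ids,
    )


def residual_matrix(model: DistanceModel) -> np.ndarray:
    """Residuals predicted − observed: entry(i,j) = a·exp(b·dcv) − d16.

    Positive entries mark pairs whose 16S distance is smaller than the
    proteome composition predicts.  The diagonal evaluates to ``a`` (model
    at self-distance 0 minus observed 0) and is excluded downstream.
    """
    if model.dcv_matrix is None or model.d16_matrix is None:
        raise ValueError("model was fitted on 1-D data; matrices unavailable")
    res = model.predict(model.dcv_matrix) - model.d16_matrix
    model.residuals = res
    return res


def phi_index(
    residuals: np.ndarray, genome_ids: list[str]
) -> PlasticityIndex:
    """φ: min-max-scaled off-diagonal row means of the residual matrix."""
    res = np.asarray(residuals, dtype=float)
    n = res.shape[0]
    if n < 2:
        raise ValueError("phi requires at least 2 genomes")
    if len(genome_ids) != n:
        raise ValueError("genome_ids length mismatch")
    row_means = (res.sum(axis=1) - np.diag(res)) / (n - 1)
    span = row_means.max() - row_means.min()
    if span == 0:
        raise ValueError("degenerate: identical row means")
    phi = (row_means - row_means.min()) / span
    return PlasticityIndex(dict(zip(genome_ids, phi.astype(float))))


def compute_plasticity(
    genomes: list[ReferenceGenome],
    k: int = 5,
    n_sample: int | None = None,
    variance_target: float = 0.9,
    n_keep: int | None = None,
    seed: int = 0,
) -> tuple[PlasticityIndex, DistanceModel, KmerReduction | None]:
    """Full φ pipeline: k-mer vectors (optionally reduced), Bray-Curtis and
    16S distance matrices, normalisation, exponential fit, residuals, φ.

    ``n_keep=None`` skips the reduction and uses full-length vectors —
    appropriate when the k-mer universe is small enough to handle directly.
    """
    vectors = [count_kmers(g.proteome, k=k, genome_id=g.genome_id) for g in genomes]
    reduction = None
    kmers = None
    if n_keep is not None:
        n_sample = min(n_sample or 200, len(vectors))
        reduction = reduce_kmers(vectors, n_sample, variance_target, n_keep, seed)
        kmers = reduction.selected_kmers
    ids, dcv = cv_distance_matrix(vectors, kmers)
    alignment = {g.genome_id: g.ssu_sequence for g in genomes}
    ssu_ids, d16 = ssu_distance_matrix(alignment)
    order = [ssu_ids.index(i) for i in ids]
    d16 = d16[np.ix_(order, order)]
    dcv_n = normalize_distances(dcv)
    d16_n = normalize_distances(d16)
    model = fit_exponential(dcv_n, d16_n, seed=seed, genome_ids=ids)
    res = residual_matrix(model)
    return phi_index(res, ids), model, reduction
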