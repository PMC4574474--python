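"""Network-based stratification (NBS) of samples from binary gene events.

Sparse binary breakpoint and mutation events are merged per gene, smoothed
over a protein-interaction network by random-walk-with-restart propagation,
and samples are clustered by consensus over subsampled graph-regularized
non-negative matrix factorizations.  The per-iteration factor products
``V_i = W_i H_i`` are additionally averaged into per-sample gene-aberration
scores ``R_s``, which support rank-based tests of which genes drive each
subtype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu

from .profiles_io import BinaryEventMatrix

__all__ = [
    "GeneNetwork",
    "NBSConfig",
    "NBSRun",
    "GeneScoreMatrix",
    "SubtypeAssignment",
    "merge_events",
    "propagate",
    "netnmf",
    "consensus_cluster",
    "extract_gene_scores",
    "subtype_gene_association",
]

logger = logging.getLogger(__name__)
_EPS = 1e-12


@dataclass
class GeneNetwork:
    """Undirected weighted gene-interaction network.

    Built from an edge list; exposes the symmetric degree-normalized
    adjacency ``D^{-1/2} A D^{-1/2}`` used for propagation and the graph
    Laplacian used for factorization regularization.
    """

    genes: list[str]
    adjacency: np.ndarray  # dense symmetric, zero diagonal, weights >= 0

    @classmethod
    def from_edges(cls, edges: pd.DataFrame) -> "GeneNetwork":
        genes = sorted(set(edges["gene_a"]) | set(edges["gene_b"]))
        idx = {g: i for i, g in enumerate(genes)}
        A = np.zeros((len(genes), len(genes)))
        for a, b, w in edges[["gene_a", "gene_b", "weight"]].itertuples(index=False):
            if a == b:
                continue
            i, j = idx[a], idx[b]
            A[i, j] = A[j, i] = max(A[i, j], float(w))
        return cls(genes, A)

    def __post_init__(self):
        if not np.allclose(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(self.adjacency < 0):
            raise ValueError("edge weights must be non-negative")
        np.fill_diagonal(self.adjacency, 0.0)

    def normalized_adjacency(self) -> np.ndarray:
        deg = self.adjacency.sum(axis=1)
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, _EPS)), 0.0)
        return self.adjacency * inv_sqrt[:, None] * inv_sqrt[None, :]

    def laplacian(self, genes: list[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(degree matrix D, adjacency A) of the subgraph on ``genes``."""
        if genes is None:
            A = self.adjacency
        else:
            pos = [self.genes.index(g) for g in genes]
            A = self.adjacency[np.ix_(pos, pos)]
        D = np.diag(A.sum(axis=1))
        return D, A


@dataclass
class NBSConfig:
    """Consensus-NBS settings.

    ``k`` subtypes (study convention: 4), ``n_iter`` subsampled
    factorizations, restart weight ``alpha`` of the propagation, Laplacian
    weight ``lam``, per-iteration sample/gene subsample fractions, and the
    NMF stopping rule.
    """

    k: int = 4
    n_iter: int = 1000
    alpha: float = 0.7
    lam: float = 1.0
    sample_frac: float = 0.8
    gene_frac: float = 0.8
    seed: int = 0
    tol: float = 1e-5
    max_iter: int = 500
    prop_tol: float = 1e-6
    store_factors: bool = False

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        for frac in (self.sample_frac, self.gene_frac):
            if not 0 < frac <= 1:
                raise ValueError("subsample fractions must be in (0, 1]")


@dataclass
class NBSRun:
    """Accumulated state of a consensus-NBS run."""

    samples: list[str]
    genes: list[str]
    score_accum: np.ndarray          # samples × genes, running sum of V_i rows
    selection_counts: np.ndarray     # C_s: iterations in which sample s was selected
    similarity: np.ndarray           # co-cluster / co-selection, in [0, 1]
    config: NBSConfig
    factors: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=list)  # (sample_idx, gene_idx, W, H) when stored


@dataclass
class GeneScoreMatrix:
    """Samples × genes averaged network-based gene-aberration scores R_s."""

    scores: pd.DataFrame
    selection_counts: pd.Series
    never_selected: list[str]


@dataclass
class SubtypeAssignment:
    """Subtype labels (1..k) with the consensus similarity matrix."""

    labels: pd.Series
    similarity: pd.DataFrame


def merge_events(
    breakpoint_matrix: BinaryEventMatrix,
    mutation_matrix: BinaryEventMatrix,
) -> tuple[BinaryEventMatrix, list[str]]:
    """Merge breakpoint and mutation events into one binary gene × sample matrix.

    Samples are intersected (with a warning when the sets differ); genes are
    unioned, with element-wise OR for genes present in both (a gene can
    acquire both breakpoints and mutations).  Returns the merged matrix plus
    the list of samples carrying no event in any gene — retained, but
    flagged so callers can drop them before clustering.
    """
    s_bp, s_mut = set(breakpoint_matrix.samples), set(mutation_matrix.samples)
    shared = sorted(s_bp & s_mut)
    if not shared:
        raise ValueError("breakpoint and mutation matrices share no samples")
    if s_bp != s_mut:
        logger.warning("sample sets differ; intersecting to %d samples", len(shared))
    bp = breakpoint_matrix.data[shared]
    mut = mutation_matrix.data[shared]
    all_genes = sorted(set(bp.index) | set(mut.index))
    merged = pd.DataFrame(0, index=pd.Index(all_genes, name="gene"), columns=shared,
                          dtype=np.int8)
    merged.loc[bp.index] |= bp.astype(np.int8)
    merged.loc[mut.index] |= mut.astype(np.int8)
    zero_event = [s for s in shared if merged[s].sum() == 0]
    return BinaryEventMatrix(merged), zero_event


def _quantile_normalize(F: np.ndarray) -> np.ndarray:
    """Map each row (sample) onto the mean empirical distribution."""
    order = np.argsort(F, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(F.shape[0])[:, None]
    ranks[rows, order] = np.arange(F.shape[1])[None, :]
    mean_sorted = np.sort(F, axis=1, kind="stable").mean(axis=0)
    return mean_sorted[ranks]


def propagate(
    events: BinaryEventMatrix,
    network: GeneNetwork,
    alpha: float = 0.7,
    tol: float = 1e-6,
    max_iter: int = 1000,
    quantile_norm: bool = True,
) -> pd.DataFrame:
    """Random-walk-with-restart smoothing of events over the network.

    Iterates ``F <- alpha * F @ A_norm + (1 - alpha) * F0`` to its fixed
    point (a contraction for ``alpha < 1``), where ``F0`` is the samples ×
    network-genes event matrix and ``A_norm`` the symmetric degree-normalized
    adjacency.  Event genes absent from the network are dropped (logged);
    afterwards each sample's vector is quantile-normalized to the mean
    empirical distribution, so per-sample event burden does not dominate.
    """
    net_genes = network.genes
    overlap = [g for g in events.rows if g in set(net_genes)]
    if not overlap:
        raise ValueError("no event gene maps onto the network")
    dropped = len(events.rows) - len(overlap)
    if dropped:
        logger.info("dropping %d event genes absent from the network", dropped)
    F0 = pd.DataFrame(0.0, index=events.samples, columns=net_genes)
    F0[overlap] = events.data.loc[overlap].T.astype(float)
    A = network.normalized_adjacency()
    F = F0.to_numpy().copy()
    F0v = F0.to_numpy()
    for _ in range(max_iter):
        F_new = alpha * F @ A + (1.0 - alpha) * F0v
        delta = np.abs(F_new - F).max()
        F = F_new
        if delta < tol:
            break
    if quantile_norm:
        F = _quantile_normalize(F)
    return pd.DataFrame(F, index=events.samples, columns=net_genes)


def netnmf(
    V: np.ndarray,
    degree: np.ndarray,
    adjacency: np.ndarray,
    k: int,
    lam: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Graph-regularized NMF by multiplicative updates.

    Minimizes ``||V - W H||_F^2 + lam * tr(H L H^T)`` with ``L = D - A`` the
    Laplacian on the gene set (columns of V); the updates keep W, H
    non-negative and the objective non-increasing.  Returns (W, H,
    objective trace).
    """
    V = np.asarray(V, dtype=float)
    if np.any(V < 0):
        raise ValueError("V must be non-negative")
    m, n = V.shape
    if k > min(m, n):
        raise ValueError(f"k={k} exceeds min(V.shape)={min(m, n)}")
    rng = rng or np.random.default_rng()
    scale = np.sqrt(V.mean() / k) if V.mean() > 0 else 1.0
    W = rng.uniform(0.1, 1.0, size=(m, k)) * scale
    H = rng.uniform(0.1, 1.0, size=(k, n)) * scale
    L = degree - adjacency

    def objective(W, H):
        R = V - W @ H
        return float(np.sum(R * R) + lam * np.trace(H @ L @ H.T))

    trace = [objective(W, H)]
    for _ in range(max_iter):
        W *= (V @ H.T) / np.maximum(W @ (H @ H.T), _EPS)
        num = W.T @ V + lam * (H @ adjacency)
        den = (W.T @ W) @ H + lam * (H @ degree)
        H *= num / np.maximum(den, _EPS)
        obj = objective(W, H)
        trace.append(obj)
        if abs(trace[-2] - obj) <= tol * max(abs(trace[-2]), 1.0):
            break
    return W, H, trace


def consensus_cluster(
    smoothed: pd.DataFrame,
    network: GeneNetwork,
    config: NBSConfig,
) -> tuple[NBSRun, SubtypeAssignment]:
    """Consensus clustering over subsampled graph-regularized NMF runs.

    Each iteration subsamples samples and genes, factorizes the submatrix,
    assigns selected samples to their dominant factor (argmax of W, ties to
    the lowest index), and accumulates co-clustering counts.  The similarity
    matrix (co-clustered / co-selected) is cut by average-linkage
    hierarchical clustering of ``1 - similarity`` into ``k`` subtypes.
    Fully reproducible under a fixed seed.
    """
    samples = list(smoothed.index)
    genes = list(smoothed.columns)
    n, p = len(samples), len(genes)
    rng = np.random.default_rng(config.seed)
    n_sub = max(config.k, int(round(config.sample_frac * n)))
    p_sub = max(2, int(round(config.gene_frac * p)))
    V_full = smoothed.to_numpy()
    D_full, A_full = network.laplacian(genes)

    co_cluster = np.zeros((n, n))
    co_select = np.zeros((n, n))
    score_accum = np.zeros((n, p))
    sel_counts = np.zeros(n)
    factors = []

    for _ in range(config.n_iter):
        s_idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        g_idx = np.sort(rng.choice(p, size=p_sub, replace=False))
        V = V_full[np.ix_(s_idx, g_idx)]
        if V.sum() == 0:
            logger.warning("skipping iteration with all-zero submatrix")
            continue
        D = np.diag(np.diag(D_full)[g_idx])  # degrees from the full graph
        A = A_full[np.ix_(g_idx, g_idx)]
        W, H, _ = netnmf(V, D, A, config.k, lam=config.lam,
                         max_iter=config.max_iter, tol=config.tol, rng=rng)
        labels = np.argmax(W, axis=1)
        same = labels[:, None] == labels[None, :]
        co_cluster[np.ix_(s_idx, s_idx)] += same
        co_select[np.ix_(s_idx, s_idx)] += 1.0
        score_accum[np.ix_(s_idx, g_idx)] += W @ H
        sel_counts[s_idx] += 1
        if config.store_factors:
            factors.append((s_idx, g_idx, W.copy(), H.copy()))

    with np.errstate(invalid="ignore", divide="ignore"):
        similarity = np.where(co_select > 0, co_cluster / np.maximum(co_select, 1), 0.0)
    np.fill_diagonal(similarity, (sel_counts > 0).astype(float))
    similarity = (similarity + similarity.T) / 2.0

    dist = squareform(1.0 - similarity, checks=False)
    Z = linkage(dist, method="average")
    labels = fcluster(Z, t=config.k, criterion="maxclust")

    run = NBSRun(samples, genes, score_accum, sel_counts, similarity, config, factors)
    assignment = SubtypeAssignment(
        labels=pd.Series(labels, index=samples, name="subtype"),
        similarity=pd.DataFrame(similarity, index=samples, columns=samples),
    )
    return run, assignment


def extract_gene_scores(run: NBSRun) -> GeneScoreMatrix:
    """Average reconstructed inputs ``V_i = W_i H_i`` into per-sample scores.

    ``R_s = (1 / C_s) * sum_i V_is`` with ``C_s`` the number of iterations
    in which sample s was selected; a sample never selected receives an
    all-zero vector and is flagged.  Uses stored factors when available,
    otherwise the streaming accumulator — both paths agree exactly.
    """
    if run.factors:
        accum = np.zeros_like(run.score_accum)
        counts = np.zeros(len(run.samples))
        for s_idx, g_idx, W, H in run.factors:
            accum[np.ix_(s_idx, g_idx)] += W @ H
            counts[s_idx] += 1
    else:
        accum, counts = run.score_accum, run.selection_counts
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(counts[:, None] > 0, accum / np.maximum(counts[:, None], 1), 0.0)
    never = [s for s, c in zip(run.samples, counts) if c == 0]
    return GeneScoreMatrix(
        scores=pd.DataFrame(R, index=run.samples, columns=run.genes),
        selection_counts=pd.Series(counts, index=run.samples, name="C_s"),
        never_selected=never,
    )


def subtype_gene_association(
    scores: GeneScoreMatrix,
    subtypes: SubtypeAssignment,
    adjust: bool = False,
) -> pd.DataFrame:
    """Two-sided Mann–Whitney U tests of gene scores per subtype vs the rest.

    Returns a genes × subtypes table of p-values (optionally BH-adjusted
    across the whole grid).  A subtype with fewer than 2 samples yields NaN.
    """
    S = scores.scores
    labels = subtypes.labels.reindex(S.index)
    out = {}
    for subtype in sorted(labels.unique()):
        mask = (labels == subtype).to_numpy()
        if mask.sum() < 2 or (~mask).sum() < 2:
            logger.warning("subtype %s has < 2 samples; skipping", subtype)
            out[subtype] = np.full(S.shape[1], np.nan)
            continue
        res = mannwhitneyu(S.to_numpy()[mask], S.to_numpy()[~mask],
                           alternative="two-sided", axis=0)
        out[subtype] = res.pvalue
    table = pd.DataFrame(out, index=S.columns)
    table.columns.name = "subtype"
    if adjust:
        from statsmodels.stats.multitest import multipletests
        flat = table.to_numpy().ravel()
        ok = ~np.isnan(flat)
        adj = np.full_like(flat, np.nan)
        adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
        table = pd.DataFrame(adj.reshape(table.shape), index=table.index,
                             columns=table.columns)
    return table
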