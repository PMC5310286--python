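"""From paired two-sample expression data to signed z-scores.

For each gene in each dataset a paired t-statistic is computed from the
per-pair case-minus-control differences.  Its one-sided upper-tail
p-value is evaluated against a pooled permutation null built by
randomly sign-flipping each pair's labels, so no normality assumption
is placed on the differences and p-values far below 1/n_perm are
attainable (all m * n_perm permuted statistics form one pooled null).
The signed z-score is the inverse-normal transform

    z = Phi^{-1}(1 - p_upper)

so strong up-regulation (tiny upper-tail p) maps to a large positive z
and strong down-regulation to a large negative z.  Note the transform
is applied to 1 - p: applying it to the upper-tail p itself would flip
the sign and contradict the up/down reading of the score.

The module also carries the cohort-partition utility: per-pair log2
case/control ratios of a reference gene, clustered 1-D with median
linkage, cut at a fixed height, singletons merged into their nearest
cluster — the device used to split one large paired cohort into an
ordered series of subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import norm

from .mixture import DiscosetError


class DegenerateGeneError(DiscosetError):
    """Per-pair differences have zero variance; the t-statistic is undefined."""


class InsufficientPairsError(DiscosetError):
    pass


class UnknownGeneError(DiscosetError):
    pass


@dataclass
class PairedExpressionDataset:
    """Expression of m genes across n matched case/control pairs."""

    gene_ids: list[str]
    case: np.ndarray      # (m, n)
    control: np.ndarray   # (m, n)
    pair_ids: list[str]

    def __post_init__(self) -> None:
        self.case = np.asarray(self.case, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        if self.case.shape != self.control.shape:
            raise ValueError("case and control matrices must have equal shape")
        if self.case.shape != (len(self.gene_ids), len(self.pair_ids)):
            raise ValueError("matrix shape inconsistent with gene/pair ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if self.n_pairs < 2:
            raise InsufficientPairsError("need at least 2 pairs")

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)


@dataclass
class ZScoreMatrix:
    """Signed z-scores for m genes across K datasets; entries finite."""

    gene_ids: list[str]
    dataset_ids: list[str]
    z: np.ndarray  # (m, K)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (len(self.gene_ids), len(self.dataset_ids)):
            raise ValueError("z shape inconsistent with gene/dataset ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z-scores must be finite")


# ---------------------------------------------------------------------------
# paired t and permutation p-values

def _t_from_differences(d: np.ndarray) -> np.ndarray:
    """Row-wise paired t: mean(d) / (sd(d)/sqrt(n)), sd with ddof=1."""
    n = d.shape[-1]
    sd = d.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return d.mean(axis=-1) / (sd / np.sqrt(n))


def paired_t_score(dataset: PairedExpressionDataset, gene_index: int) -> float:
    """Paired t-statistic of one gene; positive when case > control."""
    d = dataset.case[gene_index] - dataset.control[gene_index]
    if np.allclose(d.std(ddof=1), 0.0):
        raise DegenerateGeneError(
            f"gene {dataset.gene_ids[gene_index]!r} has zero-variance "
            "paired differences")
    return float(_t_from_differences(d))


def paired_t_scores(dataset: PairedExpressionDataset):
    """t-statistics for all genes plus a mask of degenerate (zero-variance)
    genes, whose statistic is NaN and must be handled by the caller."""
    d = dataset.case - dataset.control
    degenerate = np.isclose(d.std(axis=1, ddof=1), 0.0)
    t = _t_from_differences(d)
    t[degenerate] = np.nan
    return t, degenerate


def pooled_permutation_pvalues(dataset: PairedExpressionDataset,
                               n_perm: int = 1000,
                               seed: int | None = None) -> np.ndarray:
    """Upper-tail p-values from a pooled sign-flip permutation null.

    Each permutation independently flips every pair's case/control labels
    with probability 1/2 (a sign flip of that pair's difference, shared
    across genes).  All m * n_perm permuted t-statistics are pooled and
    each observed t is ranked against the pool with the continuity-
    corrected rule p = (1 + #{pooled >= t}) / (1 + m * n_perm), clamped
    away from 1 so the inverse-normal transform stays finite.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d = dataset.case - dataset.control
    m, n = d.shape
    degenerate = np.isclose(d.std(axis=1, ddof=1), 0.0)
    if degenerate.any():
        bad = [g for g, f in zip(dataset.gene_ids, degenerate) if f]
        raise DegenerateGeneError(
            f"zero-variance paired differences for genes: {bad[:10]}")

    t_obs = _t_from_differences(d)
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    pooled = np.empty((n_perm, m))
    for b in range(n_perm):
        pooled[b] = _t_from_differences(d * signs[b][None, :])
    pooled = np.sort(pooled.ravel())
    total = pooled.size
    count_ge = total - np.searchsorted(pooled, t_obs, side="left")
    p = (1.0 + count_ge) / (1.0 + total)
    return np.minimum(p, total / (1.0 + total))


def z_transform(p: np.ndarray) -> np.ndarray:
    """Signed z from upper-tail p: z = Phi^{-1}(1 - p), finite in (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p-values must lie strictly inside (0, 1)")
    return norm.isf(p)


def build_zscore_matrix(datasets: list[PairedExpressionDataset],
                        dataset_ids: list[str] | None = None,
                        n_perm: int = 1000,
                        seed: int | None = None) -> ZScoreMatrix:
    """Full pipeline over K paired datasets, restricted to common genes.

    Genes missing from any dataset are dropped before z-scores are
    assembled (order follows the first dataset).  Each dataset's
    permutation stream is seeded independently from ``seed``.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    if dataset_ids is None:
        dataset_ids = [f"z{k + 1}" for k in range(len(datasets))]
    common = set(datasets[0].gene_ids)
    for ds in datasets[1:]:
        common &= set(ds.gene_ids)
    gene_ids = [g for g in datasets[0].gene_ids if g in common]
    if not gene_ids:
        raise DiscosetError("no genes are common to all datasets")

    seeds = np.random.SeedSequence(seed).spawn(len(datasets))
    cols = []
    for ds, ss in zip(datasets, seeds):
        keep = [ds.gene_ids.index(g) for g in gene_ids]
        sub = PairedExpressionDataset(
            gene_ids=gene_ids,
            case=ds.case[keep], control=ds.control[keep],
            pair_ids=ds.pair_ids)
        p = pooled_permutation_pvalues(
            sub, n_perm=n_perm, seed=int(ss.generate_state(1)[0] % (2**31)))
        cols.append(z_transform(p))
    return ZScoreMatrix(gene_ids=gene_ids, dataset_ids=dataset_ids,
                        z=np.column_stack(cols))


# ---------------------------------------------------------------------------
# cohort partition by a reference gene's paired ratio

def log2_paired_ratio(dataset: PairedExpressionDataset, gene_id: str,
                      scale: str = "ratio") -> np.ndarray:
    """Per-pair log2(case/control) for a named reference gene.

    ``scale="ratio"`` takes log2 of the case/control quotient (values
    must be positive); ``scale="log2"`` assumes expression is already
    log2 and takes the difference.
    """
    try:
        i = dataset.gene_ids.index(gene_id)
    except ValueError:
        raise UnknownGeneError(f"gene {gene_id!r} not in dataset") from None
    case, control = dataset.case[i], dataset.control[i]
    if scale == "ratio":
        if np.any(case <= 0) or np.any(control <= 0):
            raise ValueError("ratio-scale expression must be strictly positive")
        return np.log2(case / control)
    if scale == "log2":
        return case - control
    raise ValueError(f"scale must be 'ratio' or 'log2', got {scale!r}")


def cluster_partition(ratios: np.ndarray, cut_height: float) -> np.ndarray:
    """Partition pairs by 1-D median-linkage clustering of their ratios.

    The tree (Euclidean distance, median agglomeration) is cut at
    ``cut_height``; singleton clusters are merged into the cluster with
    the nearest centroid; final labels 1..K are ordered by increasing
    cluster median, so subset 1 is the most down-regulated.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size < 2:
        raise ValueError("need at least 2 ratio values")
    if cut_height <= 0:
        raise ValueError("cut_height must be positive")
    if np.allclose(ratios, ratios[0]):
        warnings.warn("all ratios identical; returning a single cluster",
                      RuntimeWarning)
        return np.ones(ratios.size, dtype=int)

    Z = linkage(ratios[:, None], method="median", metric="euclidean")
    labels = fcluster(Z, t=cut_height, criterion="distance")

    # merge singletons into the nearest cluster by centroid distance
    while True:
        uniq, counts = np.unique(labels, return_counts=True)
        if len(uniq) == 1 or counts.min() > 1:
            break
        singles = uniq[counts == 1]
        # most isolated first for determinism: process by ratio value
        s = min(singles, key=lambda c: ratios[labels == c][0])
        others = [c for c in uniq if c != s]
        centroids = {c: ratios[labels == c].mean() for c in others}
        val = ratios[labels == s][0]
        nearest = min(others, key=lambda c: abs(centroids[c] - val))
        labels[labels == s] = nearest

    # relabel 1..K by increasing cluster median ratio
    uniq = np.unique(labels)
    order = sorted(uniq, key=lambda c: np.median(ratios[labels == c]))
    remap = {old: new for new, old in enumerate(order, start=1)}
    return np.array([remap[c] for c in labels], dtype=int)
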