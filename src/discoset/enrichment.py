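"""Discordance proportion, per-gene posteriors, gene-set DES and FDR.

A gene is *clearly discordant* across the K datasets when its latent
regulation-state list contains at least one "up" and at least one
"down".  Lists that are all one state, or that mix only null with up
(or only null with down), are excluded: the sign of a z-score separates
up from down visually, but null is hard to distinguish from a weak up
or down, so those mixed lists are not counted as discordance.

Working from the fitted two-level mixture:

* ``discordance_theta`` — the marginal probability theta that a random
  gene's latent list is clearly discordant;
* ``gene_discordance_prob`` — the posterior zeta_i of that event given
  the gene's observed z-scores;
* ``des_exact`` / ``des_monte_carlo`` — the Discordance Enrichment
  Score of a gene set S, the tail probability
  Pr(sum_i U_i > m_S * theta) of the heterogeneous-Bernoulli
  (Poisson-binomial) count of discordant genes in S;
* ``fdr_from_des`` — the model-based FDR 1 - mean(DES) of a reported
  top list, since each DES is itself a true-positive probability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .mixture import (
    MixtureParams,
    _component_logpdf,
    _log_cc_rows,
    _log_two_level_rows,
    DiscosetError,
)
from scipy.special import logsumexp


class EmptyGeneSetError(DiscosetError):
    pass


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. a KEGG pathway collection parsed from GMT)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            seen: dict[str, None] = {}
            for g in genes:
                g = g.strip()
                if g and g not in seen:
                    seen[g] = None
            self.sets[name] = list(seen)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class SetRecord:
    name: str
    m_S: int
    des: float
    method: str
    B: int | None = None


@dataclass
class DiscordanceResult:
    theta: float
    zeta: np.ndarray
    gene_ids: list[str]
    records: list[SetRecord]
    fdr_at_rank: np.ndarray
    skipped_sets: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# theta and zeta

def discordance_theta(params: MixtureParams) -> float:
    """Probability that a random gene's latent state list is discordant.

    The exclusion sums over concordant lists and over lists mixing only
    {null, up} or only {null, down} telescope into products over subset
    probabilities, giving the closed form

        theta = (1-lam) * [1 + prod_k rho0k
                             - prod_k (rho0k + rho1k)
                             - prod_k (rho0k + rho2k)]

    which avoids enumerating the 3**K lists.
    """
    params.validate()
    r0, r1, r2 = params.rho[0], params.rho[1], params.rho[2]
    bracket = 1.0 + np.prod(r0) - np.prod(r0 + r1) - np.prod(r0 + r2)
    return float((1.0 - params.lam) * max(bracket, 0.0))


def _zeta_from_logpdf(logpdf: np.ndarray, params: MixtureParams) -> np.ndarray:
    """Vectorised posterior discordance probabilities from (m,3,K) logpdfs."""
    with np.errstate(divide="ignore"):
        a = logpdf + np.log(params.rho)[None, :, :]       # log rho_jk phi_jk
    # subset products over states: all three, {0,1}, {0,2}, {0}
    l_all = logsumexp(a, axis=1).sum(axis=1)
    l_01 = logsumexp(a[:, [0, 1], :], axis=1).sum(axis=1)
    l_02 = logsumexp(a[:, [0, 2], :], axis=1).sum(axis=1)
    l_0 = a[:, 0, :].sum(axis=1)
    log_cc = _log_cc_rows(logpdf, params)
    log_f = _log_two_level_rows(log_cc, l_all, params.lam)

    ref = l_all  # dominates the other three subset terms
    num = (np.exp(l_all - ref) - np.exp(l_01 - ref)
           - np.exp(l_02 - ref) + np.exp(l_0 - ref))
    zeta = (1.0 - params.lam) * num * np.exp(ref - log_f)
    return np.clip(zeta, 0.0, 1.0)


def gene_discordance_prob(z_row: np.ndarray, params: MixtureParams) -> float:
    """Posterior probability zeta that one gene is clearly discordant."""
    params.validate()
    return float(_zeta_from_logpdf(_component_logpdf(z_row, params), params)[0])


def gene_discordance_probs(z: np.ndarray, params: MixtureParams) -> np.ndarray:
    """zeta for every row of an (m, K) z-score matrix."""
    params.validate()
    return _zeta_from_logpdf(_component_logpdf(z, params), params)


# ---------------------------------------------------------------------------
# DES

def _count_threshold(m_S: int, theta: float, tie: str = "strict") -> int:
    """Smallest integer count that qualifies as exceeding m_S * theta.

    With the strict event {X > m_S*theta}, an integer bound c requires
    X >= c + 1; the "ge" option implements {X >= m_S*theta} instead.
    """
    t = m_S * theta
    near = round(t)
    is_integer = abs(t - near) < 1e-9
    if tie == "strict":
        return int(near) + 1 if is_integer else math.ceil(t)
    if tie == "ge":
        return int(near) if is_integer else math.ceil(t)
    raise ValueError(f"tie must be 'strict' or 'ge', got {tie!r}")


def des_exact(zetas: np.ndarray, theta: float, tie: str = "strict") -> float:
    """Exact DES by dynamic-programming convolution of the Bernoulli zetas.

    O(m_S^2): iteratively convolve the count distribution of
    X = sum_i Bernoulli(zeta_i), then sum the qualifying tail.
    """
    zetas = np.asarray(zetas, dtype=float)
    if zetas.size == 0:
        raise EmptyGeneSetError("DES is undefined for an empty gene set")
    if np.any((zetas < 0) | (zetas > 1)):
        raise ValueError("zetas must lie in [0, 1]")
    m_S = zetas.size
    kmin = _count_threshold(m_S, theta, tie)
    if kmin > m_S:
        return 0.0
    if kmin <= 0:
        return 1.0
    pmf = np.zeros(m_S + 1)
    pmf[0] = 1.0
    for idx, p in enumerate(zetas):
        pmf[1:idx + 2] = pmf[1:idx + 2] * (1 - p) + pmf[:idx + 1] * p
        pmf[0] *= 1 - p
    return float(pmf[kmin:].sum())


def des_monte_carlo(zetas: np.ndarray, theta: float, B: int = 2000,
                    seed: int | None = None, tie: str = "strict") -> float:
    """Monte-Carlo DES: fraction of B simulated Bernoulli vectors whose
    discordant count exceeds m_S * theta."""
    zetas = np.asarray(zetas, dtype=float)
    if zetas.size == 0:
        raise EmptyGeneSetError("DES is undefined for an empty gene set")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    kmin = _count_threshold(zetas.size, theta, tie)
    counts = (rng.random((B, zetas.size)) < zetas[None, :]).sum(axis=1)
    return float(np.mean(counts >= kmin))


def fdr_from_des(sorted_des: np.ndarray) -> float:
    """FDR of a top-T list: 1 - mean DES (each DES is a TP probability)."""
    sorted_des = np.asarray(sorted_des, dtype=float)
    if sorted_des.size == 0:
        raise ValueError("FDR is undefined for an empty list")
    return float(1.0 - sorted_des.mean())


def fdr_per_rank(sorted_des: np.ndarray) -> np.ndarray:
    """Running FDR at every rank of a DES-sorted (decreasing) list."""
    sorted_des = np.asarray(sorted_des, dtype=float)
    if sorted_des.size == 0:
        return np.empty(0)
    prefix_mean = np.cumsum(sorted_des) / np.arange(1, sorted_des.size + 1)
    return 1.0 - prefix_mean


# ---------------------------------------------------------------------------
# collection scoring

def score_collection(z: np.ndarray, gene_ids: list[str], params: MixtureParams,
                     sets: GeneSetCollection, method: str = "exact",
                     B: int = 2000, seed: int | None = None,
                     tie: str = "strict") -> DiscordanceResult:
    """Score every gene set: theta once, zeta per universe gene, DES per set.

    Set membership is intersected with the z-score universe (the
    intersection size becomes m_S); sets with an empty intersection are
    skipped with a warning.  Records are sorted by decreasing DES, ties
    broken by set name.
    """
    if method not in ("exact", "monte_carlo"):
        raise ValueError(f"unknown method {method!r}")
    z = np.asarray(z, dtype=float)
    theta = discordance_theta(params)
    zeta = gene_discordance_probs(z, params)
    index = {g: i for i, g in enumerate(gene_ids)}

    records: list[SetRecord] = []
    skipped: list[str] = []
    rng = np.random.default_rng(seed)
    for name in sets.sets:
        idx = [index[g] for g in sets.sets[name] if g in index]
        if not idx:
            warnings.warn(f"gene set {name!r} has no genes in the z-score "
                          "universe; skipped", RuntimeWarning)
            skipped.append(name)
            continue
        zs = zeta[idx]
        if method == "exact":
            des = des_exact(zs, theta, tie=tie)
            records.append(SetRecord(name, len(idx), des, "exact"))
        else:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            des = des_monte_carlo(zs, theta, B=B, seed=sub_seed, tie=tie)
            records.append(SetRecord(name, len(idx), des, "monte_carlo", B=B))
    if not records:
        raise EmptyGeneSetError("no gene set intersects the z-score universe")

    records.sort(key=lambda r: (-r.des, r.name))
    fdr = fdr_per_rank(np.array([r.des for r in records]))
    return DiscordanceResult(theta=theta, zeta=zeta, gene_ids=list(gene_ids),
                             records=records, fdr_at_rank=fdr,
                             skipped_sets=skipped)


# ---------------------------------------------------------------------------
# descriptive utility

def flag_clear_discordance(z: np.ndarray, threshold: float = 4.0):
    """Flag genes with at least one z above ``threshold`` and one below
    ``-threshold`` — the eyeball definition of clear discordance used to
    motivate the model-based analysis.

    Returns (flags, count).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    z = np.asarray(z, dtype=float)
    flags = (z > threshold).any(axis=1) & (z < -threshold).any(axis=1)
    return flags, int(flags.sum())
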