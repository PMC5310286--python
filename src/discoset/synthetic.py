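"""Ground-truth simulation of z-score matrices and gene-set collections.

The generator draws rows exactly from the two-level mixture's generative
process: with probability ``lam`` a gene is complete-concordance (one
state j ~ pi shared by all K datasets), otherwise complete-independence
(a state j_k ~ rho[:, k] per dataset); z-scores are then sampled from
the per-state normals.  The full latent truth (high-level indicator,
state lists, the derived clear-discordance label) is returned so every
downstream quantity — theta, zeta, DES, FDR — can be checked against
counts over known labels.

Gene sets are planted by latent-label-aware sampling: a planted set
draws the requested fraction of its members from genes whose latent
lists are truly discordant, never by shifting z values, so the
generative model (and every oracle built on it) remains valid.

Default study conditions (``default_truth``): K=5 datasets, lam=0.6,
pi=(0.8, 0.1, 0.1), every rho column (0.6, 0.2, 0.2), means +/-2.5,
unit variances — a null-heavy genomic regime with well-separated
up/down components whose discordance proportion is theta ~ 0.17.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .enrichment import GeneSetCollection, discordance_theta
from .mixture import MixtureParams, DiscosetError
from .zscores import ZScoreMatrix


class InfeasibleScenarioError(DiscosetError):
    pass


@dataclass
class LatentTruth:
    """Latent labels accompanying a simulated z-score matrix."""

    omega: np.ndarray        # (m,) bool: True = CC gene
    cc_state: np.ndarray     # (m,) int: shared state for CC genes, -1 for CI
    ci_states: np.ndarray    # (m, K) int: per-dataset states for CI, -1 for CC
    discordant: np.ndarray   # (m,) bool: latent list has >=1 up and >=1 down


@dataclass
class SimulationScenario:
    """A replayable simulation: mixture truth, universe size, set layout."""

    params: MixtureParams
    m: int
    planted_sets: list[tuple[str, int, float]] = field(default_factory=list)
    n_background_sets: int = 0
    background_set_size: int = 40
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps({
            "params": self.params.to_dict(),
            "m": self.m,
            "planted_sets": [list(t) for t in self.planted_sets],
            "n_background_sets": self.n_background_sets,
            "background_set_size": self.background_set_size,
            "seed": self.seed,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationScenario":
        d = json.loads(text)
        return cls(params=MixtureParams.from_dict(d["params"]), m=d["m"],
                   planted_sets=[tuple(t) for t in d["planted_sets"]],
                   n_background_sets=d["n_background_sets"],
                   background_set_size=d["background_set_size"],
                   seed=d["seed"])


def default_truth(K: int = 5, lam: float = 0.6) -> MixtureParams:
    """Null-heavy truth with well-separated up/down components."""
    return MixtureParams(
        lam=lam,
        pi=np.array([0.8, 0.1, 0.1]),
        rho=np.tile(np.array([0.6, 0.2, 0.2])[:, None], (1, K)),
        mu=np.vstack([np.zeros(K), np.full(K, 2.5), np.full(K, -2.5)]),
        sigma2=np.ones((3, K)),
    )


def sample_zscores(params: MixtureParams, m: int,
                   seed: int | None = None) -> tuple[ZScoreMatrix, LatentTruth]:
    """Draw m gene rows from the two-level mixture, returning latent truth."""
    params.validate()
    K = params.K
    rng = np.random.default_rng(seed)

    omega = rng.random(m) < params.lam
    cc_state = np.full(m, -1, dtype=int)
    ci_states = np.full((m, K), -1, dtype=int)

    n_cc = int(omega.sum())
    cc_state[omega] = rng.choice(3, size=n_cc, p=params.pi)
    for k in range(K):
        ci_states[~omega, k] = rng.choice(3, size=m - n_cc, p=params.rho[:, k])

    states = np.where(omega[:, None], cc_state[:, None], ci_states)  # (m, K)
    z = rng.normal(loc=params.mu[states, np.arange(K)[None, :]],
                   scale=np.sqrt(params.sigma2[states, np.arange(K)[None, :]]))

    discordant = (states == 1).any(axis=1) & (states == 2).any(axis=1)
    gene_ids = [f"g{i + 1}" for i in range(m)]
    dataset_ids = [f"z{k + 1}" for k in range(K)]
    zm = ZScoreMatrix(gene_ids=gene_ids, dataset_ids=dataset_ids, z=z)
    return zm, LatentTruth(omega=omega, cc_state=cc_state,
                           ci_states=ci_states, discordant=discordant)


def plant_discordant_sets(scenario: SimulationScenario, zm: ZScoreMatrix,
                          truth: LatentTruth,
                          seed: int | None = None):
    """Build a gene-set collection with planted discordance-enriched sets.

    Each planted (name, m_S, rate) set draws round(rate * m_S) members
    from latently discordant genes and the rest from non-discordant
    genes; background sets sample the whole universe uniformly.  Returns
    (GeneSetCollection, truth_table) where the truth table maps set name
    to its realised discordant fraction.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    gene_ids = np.asarray(zm.gene_ids)
    disc_pool = gene_ids[truth.discordant]
    conc_pool = gene_ids[~truth.discordant]

    sets: dict[str, list[str]] = {}
    table: dict[str, float] = {}
    for name, m_S, rate in scenario.planted_sets:
        n_disc = int(round(rate * m_S))
        if n_disc > disc_pool.size or (m_S - n_disc) > conc_pool.size:
            raise InfeasibleScenarioError(
                f"set {name!r} requests {n_disc} discordant genes but only "
                f"{disc_pool.size} are available")
        members = np.concatenate([
            rng.choice(disc_pool, size=n_disc, replace=False),
            rng.choice(conc_pool, size=m_S - n_disc, replace=False),
        ])
        sets[name] = members.tolist()
        table[name] = n_disc / m_S
    disc_set = set(disc_pool.tolist())
    for b in range(scenario.n_background_sets):
        name = f"background_{b + 1:03d}"
        members = rng.choice(gene_ids, size=scenario.background_set_size,
                             replace=False)
        sets[name] = members.tolist()
        table[name] = float(np.mean([g in disc_set for g in sets[name]]))
    return GeneSetCollection(sets=sets, source="synthetic"), table


def theoretical_theta(scenario: SimulationScenario) -> float:
    return discordance_theta(scenario.params)


# ---------------------------------------------------------------------------
# worked-example fixture: 9 genes x 6 datasets of illustrative z-scores

_TABLE1 = np.array([
    [6.4, 8.8, 6.8, 8.4, 10.4, 1.2],
    [5.2, 4.5, 7.0, 5.5, 3.3, 6.3],
    [-0.3, -1.9, 1.8, 2.9, 6.7, 1.5],
    [4.8, 7.7, 2.3, -4.9, -7.6, 2.2],
    [1.9, 6.5, -1.2, 0.9, -8.1, 2.1],
    [4.0, -8.9, -1.1, 5.0, -8.6, 7.9],
    [3.7, -5.6, -1.6, -0.6, -9.0, 4.6],
    [-3.1, -4.8, -1.6, 5.3, -2.9, -4.1],
    [-6.3, -9.7, -1.1, -6.4, -8.4, -7.1],
])


def table1_fixture() -> ZScoreMatrix:
    """The 9-gene, 6-dataset illustrative z-score matrix used to motivate
    clear discordance (genes G4-G8 mix clearly positive and clearly
    negative scores)."""
    return ZScoreMatrix(
        gene_ids=[f"G{i + 1}" for i in range(9)],
        dataset_ids=[f"z{k + 1}" for k in range(6)],
        z=_TABLE1.copy(),
    )
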