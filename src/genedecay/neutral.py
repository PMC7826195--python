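"""Inferring how many genes evolve neutrally from LoF mutations per gene.

Given T surveyed genes of which V are free to accumulate loss-of-function
mutations and m mutations landed among them, the probability that a gene
carries X mutations is

    p(X=0) = (V/T) (1 - 1/V)^m + (T - V)/T
    p(X=i) = (V/T) C(m, i) (1/V)^i (1 - 1/V)^(m-i),   i >= 1

i.e. a mutable gene receives a Binomial(m, 1/V) share and a constrained gene
receives none. A simulation variant drops the equal-rates assumption by
weighting genes by their individual LoF mutation rates (CDS length and
intron count). ``NeutralGeneCountModel.fit`` profiles a multinomial
log-likelihood over candidate V and reports the best-fitting count; because
the likelihood typically plateaus, the whole profile matters more than the
argmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .scan import LoFCountDistribution

__all__ = [
    "LoFCountDistribution",
    "expected_lof_profile",
    "simulate_lof_profile",
    "NeutralGeneCountModel",
    "NeutralGeneCountResults",
]


def expected_lof_profile(T: int, V: int, m: int) -> np.ndarray:
    """Analytic probability vector over X = 0..m LoF mutations per gene."""
    if not 1 <= V <= T:
        if V == 0 and m == 0:
            return np.array([1.0])
        raise ValueError(f"require 1 <= V <= T (got V={V}, T={T})")
    if m < 0:
        raise ValueError("m must be nonnegative")
    x = np.arange(m + 1)
    binom_pmf = stats.binom.pmf(x, m, 1.0 / V)
    p = (V / T) * binom_pmf
    p[0] += (T - V) / T
    return p


@dataclass
class SimulatedProfile:
    """Mean per-x gene counts over replicates with a 2.5/97.5% envelope."""

    mean_counts: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_sims: int

    @property
    def probabilities(self) -> np.ndarray:
        return self.mean_counts / self.mean_counts.sum()


def simulate_lof_profile(
    weights: np.ndarray,
    V: int,
    m: int,
    n_sims: int = 10_000,
    seed: int | None = None,
) -> SimulatedProfile:
    """Monte-Carlo expected distribution of LoF mutations per gene.

    Each replicate samples V genes uniformly without replacement from the T
    genes behind ``weights``, then scatters m mutations multinomially with
    probability proportional to each sampled gene's weight.
    """
    weights = np.asarray(weights, dtype=float)
    T = weights.size
    if V > T:
        raise ValueError(f"V={V} exceeds T={T}")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if np.any(weights <= 0):
        raise ValueError("per-gene weights must be positive")
    rng = np.random.default_rng(seed)
    counts = np.zeros((n_sims, m + 1), dtype=np.int64)
    for s in range(n_sims):
        chosen = rng.choice(T, size=V, replace=False)
        w = weights[chosen]
        per_gene = rng.multinomial(m, w / w.sum())
        hist = np.bincount(per_gene, minlength=m + 1)[: m + 1]
        hist[0] += T - V
        counts[s] = hist
    return SimulatedProfile(
        mean_counts=counts.mean(axis=0),
        lower=np.percentile(counts, 2.5, axis=0),
        upper=np.percentile(counts, 97.5, axis=0),
        n_sims=n_sims,
    )


def _pooled_loglik(n_x: np.ndarray, probs: np.ndarray) -> float:
    """Multinomial log-likelihood over the observed classes.

    Every observed mutation count x = 0..K keeps its own bin (they are the
    categories the distribution is drawn with); x > K is pooled into a tail
    bin, which carries zero observed genes and so drops out of the sum.
    """
    K = len(n_x) - 1
    p_bins = np.clip(probs[: K + 1], 1e-300, None)
    return float(np.sum(n_x * np.log(p_bins)))


@dataclass
class NeutralGeneCountResults:
    """Likelihood profile of the neutral gene count V."""

    v_grid: np.ndarray
    loglik: np.ndarray
    best_v: int
    mode: str
    observed: LoFCountDistribution
    expected_analytic: dict[int, np.ndarray]
    expected_simulated: dict[int, SimulatedProfile]
    indeterminate: bool = False

    def plateau(self, delta: float = 2.0) -> tuple[int, int]:
        """Range of V whose log-likelihood is within ``delta`` of the maximum."""
        ok = self.v_grid[self.loglik >= self.loglik.max() - delta]
        return int(ok.min()), int(ok.max())

    def summary(self) -> str:
        obs = self.observed
        lo, hi = self.plateau()
        lines = [
            "Neutral gene count fit",
            "=" * 46,
            f"observed: T={obs.T} genes, m={obs.m} LoF mutations, D={obs.D} pseudogenes",
            f"mode: {self.mode}",
            f"best-fitting V: {self.best_v}",
            f"V within 2 log-likelihood units of best: [{lo}, {hi}]",
        ]
        if self.indeterminate:
            lines.append("NOTE: m=0 observed; V is indeterminate")
        return "\n".join(lines)


class NeutralGeneCountModel:
    """Estimate the number of neutrally evolving genes V among T.

    Parameters
    ----------
    observed : LoFCountDistribution
        Genes tabulated by their number of LoF mutations.
    weights : array-like, optional
        Per-gene relative LoF mutation rates (length T) used by the
        simulated mode; equal weights assumed when omitted.
    """

    def __init__(
        self,
        observed: LoFCountDistribution,
        weights: np.ndarray | None = None,
    ) -> None:
        self.observed = observed
        if weights is None:
            weights = np.ones(observed.T)
        self.weights = np.asarray(weights, dtype=float)
        if self.weights.size != observed.T:
            raise ValueError(
                f"{self.weights.size} weights for T={observed.T} genes"
            )

    @classmethod
    def from_counts(cls, n_x: list[int], weights=None) -> "NeutralGeneCountModel":
        return cls(LoFCountDistribution(list(n_x)), weights)

    def fit(
        self,
        v_grid: np.ndarray | None = None,
        mode: str = "analytic",
        n_sims: int = 10_000,
        seed: int | None = None,
    ) -> NeutralGeneCountResults:
        obs = self.observed
        T, m, D = obs.T, obs.m, obs.D
        if v_grid is None:
            v_grid = np.arange(max(D, 1), T + 1)
        v_grid = np.asarray(v_grid, dtype=int)
        if np.any(v_grid < D):
            raise ValueError(
                f"candidate V below the observed pseudogene count D={D}"
            )
        if mode not in ("analytic", "simulated"):
            raise ValueError(f"unknown mode {mode!r}")

        n_x = np.asarray(obs.n_x, dtype=float)
        loglik = np.empty(v_grid.size)
        expected_analytic: dict[int, np.ndarray] = {}
        expected_simulated: dict[int, SimulatedProfile] = {}
        for i, V in enumerate(v_grid):
            analytic = expected_lof_profile(T, int(V), m)
            expected_analytic[int(V)] = analytic
            if mode == "analytic":
                probs = analytic
            else:
                sim = simulate_lof_profile(
                    self.weights, int(V), m, n_sims=n_sims,
                    seed=None if seed is None else seed + i,
                )
                expected_simulated[int(V)] = sim
                probs = sim.probabilities
            loglik[i] = _pooled_loglik(n_x, probs)
        best_v = int(v_grid[int(np.argmax(loglik))])
        return NeutralGeneCountResults(
            v_grid=v_grid,
            loglik=loglik,
            best_v=best_v,
            mode=mode,
            observed=obs,
            expected_analytic=expected_analytic,
            expected_simulated=expected_simulated,
            indeterminate=(m == 0),
        )
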