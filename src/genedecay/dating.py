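"""Dating the relaxation of purifying selection.

Three independent routes are implemented:

1. **Pseudogene-count likelihood.** Once selection is fully relaxed, a gene
   fixes at least one LoF mutation within t generations with probability
   p(t) = 1 - exp(-mu_LoF * t) (valid while Ne << 1/mu_LoF). Observing D
   pseudogenes among T neutral genes is then Binomial(T, p(t)), and the
   maximum-likelihood relaxation time has the closed form
   t_hat = ln(T / (T - D)) / mu_LoF. A simulation variant lets every gene
   mutate at its own rate and optionally adds a crude 4*Ne fixation lag.

2. **Mixed-branch omega interpolation.** A branch spanning a functional
   period followed by a neutral period shows a duration-weighted omega, so
   t_n / T_d = (omega_mixed - omega_functional) / (omega_neutral - omega_functional).

3. **Score-mixture proportions.** If a fraction p_n of the nonsynonymous
   substitutions on the branch accumulated neutrally and p_s under
   selection, then p_s / p_n = (t_s * omega_s) / (t_n * omega_n); jointly
   with t_s + t_n = T_d this gives
   t_n = T_d * omega_s * p_n / (omega_n * p_s + omega_s * p_n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "fixation_probability",
    "PseudogeneDatingModel",
    "RelaxationDatingResults",
    "simulated_dating_curve",
    "OmegaShiftInputs",
    "mixed_branch_time",
    "mixture_proportion_time",
    "OmegaDatingResult",
]


def fixation_probability(t: float, mu_lof: float) -> float:
    """Probability that a neutrally evolving gene has fixed >= 1 LoF mutation
    after t generations: 1 - exp(-mu_lof * t)."""
    if t < 0 or mu_lof < 0:
        raise ValueError("t and mu_lof must be nonnegative")
    return -np.expm1(-mu_lof * t)


def _log_binom_pmf(D: int, T: int, p: float) -> float:
    if p <= 0.0:
        return 0.0 if D == 0 else -np.inf
    if p >= 1.0:
        return 0.0 if D == T else -np.inf
    return float(
        gammaln(T + 1) - gammaln(D + 1) - gammaln(T - D + 1)
        + D * np.log(p) + (T - D) * np.log1p(-p)
    )


@dataclass
class RelaxationDatingResults:
    """Likelihood profile of time since relaxation with MLE and interval."""

    T: int
    D: int
    mu_lof: float
    t_grid: np.ndarray
    pmf: np.ndarray
    mle_t: float
    interval: tuple[float, float] | None
    threshold: float
    pmf_at_mle: float
    unbounded: bool = False

    def to_years(self, generation_time: float) -> dict:
        """Report the estimate and interval in years for a generation time."""
        out = {"mle_years": self.mle_t * generation_time}
        if self.interval is not None:
            out["interval_years"] = (
                self.interval[0] * generation_time,
                self.interval[1] * generation_time,
            )
        return out

    def summary(self, generation_time: float | None = None) -> str:
        lines = [
            "Pseudogene-count dating of relaxed selection",
            "=" * 46,
            f"T={self.T} neutral genes, D={self.D} pseudogenes, "
            f"mu_LoF={self.mu_lof:.4g} per gene per generation",
            f"MLE of time since relaxation: {self.mle_t:,.0f} generations",
        ]
        if self.unbounded:
            lines.append("D = T: likelihood increases without bound in t")
        elif self.interval is not None:
            lo, hi = self.interval
            lines.append(
                f"P(X={self.D}) > {self.threshold:g} for t in "
                f"({lo:,.0f}; {hi:,.0f}) generations"
            )
        else:
            lines.append(
                f"no t reaches P(X={self.D}) > {self.threshold:g} "
                f"(max {self.pmf_at_mle:.3g})"
            )
        if generation_time is not None and not self.unbounded:
            years = self.to_years(generation_time)
            lines.append(
                f"at {generation_time:g} yr/generation: "
                f"{years['mle_years']:,.0f} years"
            )
        return "\n".join(lines)


class PseudogeneDatingModel:
    """Binomial model for the number of pseudogenes among T neutral genes.

    Parameters
    ----------
    T : int
        Number of genes free to accumulate LoF mutations.
    D : int
        Observed pseudogene count (genes carrying >= 1 LoF mutation).
    mu_lof : float
        LoF mutation rate per gene per generation.
    """

    def __init__(self, T: int, D: int, mu_lof: float) -> None:
        if not 0 <= D <= T:
            raise ValueError(f"require 0 <= D <= T, got D={D}, T={T}")
        if mu_lof <= 0:
            raise ValueError("mu_lof must be positive")
        self.T, self.D, self.mu_lof = T, D, mu_lof

    def pmf(self, t) -> np.ndarray | float:
        """P(X = D | t): binomial pmf in p(t), exact via log-gamma."""
        scalar = np.isscalar(t)
        ts = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.array(
            [
                np.exp(_log_binom_pmf(self.D, self.T, fixation_probability(x, self.mu_lof)))
                for x in ts
            ]
        )
        return float(out[0]) if scalar else out

    def mle(self) -> float:
        """Closed-form MLE: ln(T / (T - D)) / mu_LoF."""
        if self.D == self.T:
            return np.inf
        return np.log(self.T / (self.T - self.D)) / self.mu_lof

    def _bisect_threshold(self, lo: float, hi: float, threshold: float,
                          rising: bool, rtol: float = 1e-6) -> float:
        """Crossing point of pmf(t) = threshold on a monotone flank."""
        while hi - lo > rtol * max(hi, 1.0):
            mid = 0.5 * (lo + hi)
            above = self.pmf(mid) > threshold
            if above == rising:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    def fit(
        self,
        threshold: float = 0.05,
        t_grid: np.ndarray | None = None,
        n_grid: int = 512,
    ) -> RelaxationDatingResults:
        """Profile the likelihood over t and locate the > threshold interval.

        The closed-form MLE is cross-checked against the grid argmax; the
        interval endpoints are found by bisection to relative precision 1e-6.
        """
        mle_t = self.mle()
        if np.isinf(mle_t):
            grid = np.linspace(0, 10.0 / self.mu_lof, n_grid) if t_grid is None else t_grid
            return RelaxationDatingResults(
                self.T, self.D, self.mu_lof, np.asarray(grid), self.pmf(grid),
                np.inf, None, threshold, 1.0, unbounded=True,
            )
        if self.D == 0:
            grid = (
                np.linspace(0, 3.0 / (self.T * self.mu_lof), n_grid)
                if t_grid is None
                else t_grid
            )
            return RelaxationDatingResults(
                self.T, self.D, self.mu_lof, np.asarray(grid), self.pmf(grid),
                0.0, (0.0, self._upper_from(0.0, threshold)) if threshold < 1.0 else None,
                threshold, 1.0,
            )
        if t_grid is None:
            t_grid = np.linspace(max(mle_t * 0.2, 0.0), mle_t * 3.0, n_grid)
        t_grid = np.asarray(t_grid, dtype=float)
        pmf = self.pmf(t_grid)
        pmf_at_mle = self.pmf(mle_t)

        interval = None
        if threshold < pmf_at_mle:
            lower = self._bisect_threshold(0.0, mle_t, threshold, rising=True)
            interval = (lower, self._upper_from(mle_t, threshold))
        return RelaxationDatingResults(
            self.T, self.D, self.mu_lof, t_grid, pmf, mle_t, interval,
            threshold, pmf_at_mle,
        )

    def _upper_from(self, start: float, threshold: float) -> float:
        hi = max(start, 1.0 / self.mu_lof * 0.1)
        while self.pmf(hi) > threshold:
            hi *= 2.0
        return self._bisect_threshold(start, hi, threshold, rising=False)


def simulated_dating_curve(
    mu_lof_per_gene: np.ndarray,
    D_obs: int,
    t_grid: np.ndarray,
    n_sims: int = 10_000,
    ne: float | None = None,
    seed: int | None = None,
) -> dict:
    """Probability of observing exactly D_obs pseudogenes at each t, from
    replicate simulations in which every gene mutates independently at its
    own per-generation LoF rate (optionally lagged by 4*Ne generations of
    drift before a mutation counts as fixed).

    Returns a dict with keys ``t_grid``, ``prob`` and ``argmax_t``.
    """
    mu = np.asarray(mu_lof_per_gene, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    rng = np.random.default_rng(seed)
    prob = np.empty(t_grid.size)
    for i, t in enumerate(t_grid):
        t_eff = max(t - 4.0 * ne, 0.0) if ne is not None else t
        p = -np.expm1(-mu * t_eff)
        draws = rng.random((n_sims, mu.size)) < p
        prob[i] = float(np.mean(draws.sum(axis=1) == D_obs))
    return {
        "t_grid": t_grid,
        "prob": prob,
        "argmax_t": float(t_grid[int(np.argmax(prob))]),
    }


@dataclass
class OmegaShiftInputs:
    """Inputs shared by the two omega-shift dating equations.

    ``omega_functional`` (omega_s) is the dN/dS of a fully functional branch,
    ``omega_neutral`` (omega_n, default 1) the neutral expectation, and
    ``divergence_time`` (T_d) the total duration of the mixed branch, in any
    time unit. ``omega_mixed`` feeds the interpolation route;
    ``p_selected``/``p_neutral`` (summing to 1) feed the mixture route.
    """

    omega_functional: float
    divergence_time: float
    omega_mixed: float | None = None
    omega_neutral: float = 1.0
    p_selected: float | None = None
    p_neutral: float | None = None

    def __post_init__(self) -> None:
        if self.omega_functional < 0 or self.omega_neutral <= 0:
            raise ValueError("omega values must be nonnegative (neutral > 0)")
        if self.divergence_time <= 0:
            raise ValueError("divergence_time must be positive")
        if self.p_selected is not None or self.p_neutral is not None:
            if self.p_selected is None or self.p_neutral is None:
                raise ValueError("give both p_selected and p_neutral")
            if not np.isclose(self.p_selected + self.p_neutral, 1.0):
                raise ValueError("p_selected + p_neutral must equal 1")


@dataclass
class OmegaDatingResult:
    """Neutral-period estimate from an omega-shift method."""

    t_n: float
    ratio: float  # t_n / divergence_time
    method: str
    inputs: OmegaShiftInputs = field(repr=False, default=None)

    def summary(self) -> str:
        return (
            f"{self.method}: neutral period t_n = {self.t_n:.4g} "
            f"(t_n/T_d = {self.ratio:.4g})"
        )


def mixed_branch_time(inputs: OmegaShiftInputs) -> OmegaDatingResult:
    """Linear interpolation of a mixed branch's omega between the functional
    and neutral values."""
    w_f, w_m, w_n = inputs.omega_functional, inputs.omega_mixed, inputs.omega_neutral
    if w_m is None:
        raise ValueError("omega_mixed is required for mixed-branch dating")
    if not w_f < w_n:
        raise ValueError("omega_functional must be below omega_neutral")
    if not w_f <= w_m <= w_n:
        raise ValueError(
            f"omega_mixed={w_m} outside [omega_functional={w_f}, omega_neutral={w_n}]"
        )
    ratio = (w_m - w_f) / (w_n - w_f)
    return OmegaDatingResult(
        t_n=ratio * inputs.divergence_time,
        ratio=ratio,
        method="mixed-branch omega interpolation",
        inputs=inputs,
    )


def mixture_proportion_time(inputs: OmegaShiftInputs) -> OmegaDatingResult:
    """Neutral period from the fitted neutral/selected substitution mixture."""
    p_s, p_n = inputs.p_selected, inputs.p_neutral
    if p_s is None or p_n is None:
        raise ValueError("p_selected and p_neutral are required")
    w_s, w_n = inputs.omega_functional, inputs.omega_neutral
    if w_s <= 0:
        raise ValueError("omega under selection must be positive")
    if p_s == 0.0:
        t_n = inputs.divergence_time
    else:
        t_n = inputs.divergence_time * w_s * p_n / (w_n * p_s + w_s * p_n)
    return OmegaDatingResult(
        t_n=t_n,
        ratio=t_n / inputs.divergence_time,
        method="score-mixture proportion dating",
        inputs=inputs,
    )
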