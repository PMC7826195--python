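"""Plot helpers: LoF-per-gene profiles, dating likelihood curves, score KDEs."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .dating import RelaxationDatingResults  # noqa: E402
from .neutral import NeutralGeneCountResults  # noqa: E402


def plot_lof_profile(results: NeutralGeneCountResults, v_values=None, ax=None):
    """Observed vs expected LoF-mutations-per-gene distributions for a few
    candidate neutral gene counts V."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    obs = results.observed
    xs = np.arange(len(obs.n_x))
    ax.plot(xs, obs.n_x, "r-o", label="observed", lw=2)
    if v_values is None:
        v_values = [int(results.v_grid[0]), results.best_v, int(results.v_grid[-1])]
    for V in v_values:
        profile = results.expected_analytic.get(V)
        if profile is None:
            continue
        ax.plot(xs, profile[: len(xs)] * obs.T, "--.", label=f"expected, V={V}")
    ax.set_xlabel("LoF mutations per gene")
    ax.set_ylabel("number of genes")
    ax.legend()
    return ax


def plot_dating_curve(results: RelaxationDatingResults, ax=None, label=None):
    """P(X=D | t) against t with the MLE and >threshold interval marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(results.t_grid, results.pmf, label=label or f"T={results.T}, D={results.D}")
    if np.isfinite(results.mle_t):
        ax.axvline(results.mle_t, color="k", ls=":", lw=1)
    if results.interval is not None:
        ax.axvspan(*results.interval, alpha=0.15)
    ax.axhline(results.threshold, color="grey", ls="--", lw=1)
    ax.set_xlabel("generations since relaxation")
    ax.set_ylabel(f"P(X = {results.D})")
    ax.legend()
    return ax


def plot_score_kde(samples: dict[str, np.ndarray], ax=None):
    """Gaussian-kernel densities of deleteriousness scores (bandwidth by
    Scott's reference rule)."""
    from scipy import stats

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for name, scores in samples.items():
        scores = np.asarray(scores, float)
        kde = stats.gaussian_kde(scores)
        grid = np.linspace(scores.min(), scores.max(), 256)
        ax.plot(grid, kde(grid), label=name)
    ax.set_xlabel("deleteriousness score")
    ax.set_ylabel("density")
    ax.legend()
    return ax
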