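"""Deleteriousness scores of amino acid substitutions and mixture fitting.

Neutral expectations come from simulating random nonsynonymous (non-LoF)
nucleotide changes on a gene set; each substitution is scored by a pluggable
scorer. Grantham's (1974) physicochemical distance is bundled: the published
integer table is the authoritative lookup, and the underlying
composition/polarity/volume formula

    D(a, b) = rho * [alpha (c_a - c_b)^2 + beta (p_a - p_b)^2
                     + gamma (v_a - v_b)^2]^(1/2)

(alpha=1.833, beta=0.1018, gamma=0.000399, rho=50.723) is also exposed; the
table differs from the formula by at most one unit of rounding. Observed
score distributions are compared with ECDF-based two-sample KS tests, and
the fraction of substitutions that accumulated under purifying selection is
estimated by matching the observed ECDF against weighted mixtures of a
neutral and a selected pool ECDF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .gene_models import START_CODON, STOP_CODONS, translate_codon
from .simulate import SyntheticGeneSet, _draw_alt

AA_ORDER = "SRLPTAVGIFYCHQNKDEMW"

# Published Grantham (1974) distance table, lower triangle in AA_ORDER.
_GRANTHAM_TRIANGLE = """
110
145 102
74 103 98
58 71 92 38
99 112 96 27 58
124 96 32 68 69 64
56 125 138 42 59 60 109
142 97 5 95 89 94 29 135
155 97 22 114 103 113 50 153 21
144 77 36 110 92 112 55 147 33 22
112 180 198 169 149 195 192 159 198 205 194
89 29 99 77 47 86 84 98 94 100 83 174
68 43 113 76 42 91 96 87 109 116 99 154 24
46 86 153 91 65 111 133 80 149 158 143 139 68 46
121 26 107 103 78 106 97 127 102 102 85 202 32 53 94
65 96 172 108 85 126 152 94 168 177 160 154 81 61 23 101
80 54 138 93 65 107 121 98 134 140 122 170 40 29 42 56 45
135 91 15 87 81 84 21 127 10 28 36 196 87 101 142 95 160 126
177 101 61 147 128 148 88 184 61 40 37 215 115 130 174 110 181 152 67
"""

GRANTHAM_TABLE: dict[frozenset, int] = {}
for _i, _line in enumerate(_GRANTHAM_TRIANGLE.strip().splitlines(), start=1):
    for _j, _val in enumerate(_line.split()):
        GRANTHAM_TABLE[frozenset((AA_ORDER[_i], AA_ORDER[_j]))] = int(_val)

# Grantham's amino acid properties: composition, polarity, volume.
GRANTHAM_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32), "R": (0.65, 10.5, 124), "L": (0.0, 4.9, 111),
    "P": (0.39, 8.0, 32.5), "T": (0.71, 8.6, 61), "A": (0.0, 8.1, 31),
    "V": (0.0, 5.9, 84), "G": (0.74, 9.0, 3), "I": (0.0, 5.2, 111),
    "F": (0.0, 5.2, 132), "Y": (0.20, 6.2, 136), "C": (2.75, 5.5, 55),
    "H": (0.58, 10.4, 96), "Q": (0.89, 10.5, 85), "N": (1.33, 11.6, 56),
    "K": (0.33, 11.3, 119), "D": (1.38, 13.0, 54), "E": (0.92, 12.3, 83),
    "M": (0.0, 5.7, 105), "W": (0.13, 5.4, 170),
}

_ALPHA, _BETA, _GAMMA, _RHO = 1.833, 0.1018, 0.000399, 50.723


def grantham_distance(ref_aa: str, alt_aa: str) -> int:
    """Published Grantham distance between two standard amino acids
    (symmetric; range 5-215)."""
    for aa in (ref_aa, alt_aa):
        if aa not in GRANTHAM_PROPERTIES:
            raise ValueError(f"non-standard residue {aa!r}")
    if ref_aa == alt_aa:
        return 0
    return GRANTHAM_TABLE[frozenset((ref_aa, alt_aa))]


def grantham_formula(ref_aa: str, alt_aa: str) -> float:
    """Unrounded Grantham distance from the physicochemical formula."""
    c1, p1, v1 = GRANTHAM_PROPERTIES[ref_aa]
    c2, p2, v2 = GRANTHAM_PROPERTIES[alt_aa]
    return _RHO * math.sqrt(
        _ALPHA * (c1 - c2) ** 2 + _BETA * (p1 - p2) ** 2 + _GAMMA * (v1 - v2) ** 2
    )


@dataclass(frozen=True)
class SubstitutionRecord:
    """One amino acid substitution, optionally scored."""

    gene_id: str
    cds_position: int
    ref_aa: str
    alt_aa: str
    score: float | None = None

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref_aa and alt_aa must differ")


def simulate_neutral_nonsyn(
    gene_set: SyntheticGeneSet | dict[str, str],
    n_mutations: int,
    kappa: float,
    seed: int | None = None,
) -> list[SubstitutionRecord]:
    """Random nonsynonymous, non-LoF single-nucleotide changes on a gene set.

    Sites are picked with probability proportional to CDS length, the
    alternative base with transition weight kappa/(kappa+2); candidates that
    are synonymous or loss-of-function (stop gains, start/stop codon
    lesions) are redrawn until ``n_mutations`` records accumulate.
    """
    cds_by_gene = gene_set.cds if isinstance(gene_set, SyntheticGeneSet) else gene_set
    if n_mutations < 0:
        raise ValueError("n_mutations must be nonnegative")
    if n_mutations == 0:
        return []
    gene_ids = list(cds_by_gene)
    lengths = np.array([len(cds_by_gene[g]) for g in gene_ids], dtype=float)
    rng = np.random.default_rng(seed)
    records: list[SubstitutionRecord] = []
    attempts = 0
    max_attempts = 10_000 * n_mutations
    p_gene = lengths / lengths.sum()
    while len(records) < n_mutations:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "gene set yielded no acceptable nonsynonymous change after "
                f"{max_attempts} attempts"
            )
        g = gene_ids[int(rng.choice(len(gene_ids), p=p_gene))]
        cds = cds_by_gene[g]
        pos = int(rng.integers(0, len(cds)))
        c, j = divmod(pos, 3)
        n_codons = len(cds) // 3
        codon = cds[3 * c : 3 * c + 3]
        alt = _draw_alt(codon[j], kappa, rng)
        mutant = codon[:j] + alt + codon[j + 1 :]
        if c == 0 or c == n_codons - 1:
            continue  # start/stop codon changes are LoF or untranslatable
        if mutant in STOP_CODONS:
            continue
        ref_aa, alt_aa = translate_codon(codon), translate_codon(mutant)
        if ref_aa == alt_aa:
            continue
        records.append(SubstitutionRecord(g, pos, ref_aa, alt_aa))
    return records


def score_substitutions(
    records: list[SubstitutionRecord], scorer=None
) -> list[SubstitutionRecord]:
    """Attach a score to each record. ``scorer`` maps (ref_aa, alt_aa) to a
    value; Grantham distance is the default."""
    if scorer is None:
        scorer = grantham_distance
    return [
        SubstitutionRecord(r.gene_id, r.cds_position, r.ref_aa, r.alt_aa,
                           float(scorer(r.ref_aa, r.alt_aa)))
        for r in records
    ]


def load_score_table(path: str | Path):
    """Scorer backed by a per-substitution TSV (columns ref_aa, alt_aa,
    score; e.g. externally computed machine-learning scores)."""
    df = pd.read_csv(path, sep="\t")
    table = {
        (row.ref_aa, row.alt_aa): float(row.score) for row in df.itertuples()
    }

    def scorer(ref_aa: str, alt_aa: str) -> float:
        try:
            return table[(ref_aa, alt_aa)]
        except KeyError:
            raise KeyError(f"no score for substitution {ref_aa}->{alt_aa}") from None

    return scorer


def ks_two_sample(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: exact sup-distance between the
    ECDFs, asymptotic two-sided p-value."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def _ecdf_at(sample_sorted: np.ndarray, x: np.ndarray) -> np.ndarray:
    return np.searchsorted(sample_sorted, x, side="right") / sample_sorted.size


def _mixture_ks(
    obs_sorted: np.ndarray,
    neutral_sorted: np.ndarray,
    selected_sorted: np.ndarray,
    p_s: float,
    grid: np.ndarray,
) -> float:
    f_obs = _ecdf_at(obs_sorted, grid)
    f_mix = p_s * _ecdf_at(selected_sorted, grid) + (1 - p_s) * _ecdf_at(
        neutral_sorted, grid
    )
    # check both sides of every jump
    f_obs_left = np.concatenate(([0.0], f_obs[:-1]))
    f_mix_left = np.concatenate(([0.0], f_mix[:-1]))
    return float(
        max(np.abs(f_obs - f_mix).max(), np.abs(f_obs_left - f_mix_left).max())
    )


@dataclass
class MixtureFitResults:
    """Fitted proportion of substitutions drawn under purifying selection."""

    proportion_grid: np.ndarray
    ks_distance: np.ndarray
    best_p_s: float
    ks_vs_neutral: tuple[float, float]
    p_s_band: tuple[float, float] | None = None

    def summary(self) -> str:
        stat, pval = self.ks_vs_neutral
        lines = [
            "Score-mixture fit",
            "=" * 46,
            f"best-fitting fraction under selection p_s = {self.best_p_s:.2f}",
            f"KS vs fully neutral pool: D = {stat:.3f}, p = {pval:.3g}",
        ]
        if self.p_s_band is not None:
            lines.append(
                f"resampling 95% band on p_s: "
                f"({self.p_s_band[0]:.2f}, {self.p_s_band[1]:.2f})"
            )
        return "\n".join(lines)


class ScoreMixtureModel:
    """Fit the neutral/selected mixture that best matches observed scores.

    The candidate mixture ECDF is the p_s-weighted average of the selected
    and neutral pool ECDFs; the best p_s minimises the KS sup-distance to
    the observed ECDF.
    """

    def __init__(self, observed, neutral_pool, selected_pool) -> None:
        self.observed = np.sort(np.asarray(observed, dtype=float))
        self.neutral_pool = np.sort(np.asarray(neutral_pool, dtype=float))
        self.selected_pool = np.sort(np.asarray(selected_pool, dtype=float))
        for name, arr in (
            ("observed", self.observed),
            ("neutral_pool", self.neutral_pool),
            ("selected_pool", self.selected_pool),
        ):
            if arr.size == 0:
                raise ValueError(f"{name} sample is empty")

    def _fit_p(self, obs_sorted: np.ndarray, grid_step: float) -> tuple[np.ndarray, np.ndarray, float]:
        p_grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
        eval_grid = np.unique(
            np.concatenate([obs_sorted, self.neutral_pool, self.selected_pool])
        )
        dists = np.array(
            [
                _mixture_ks(obs_sorted, self.neutral_pool, self.selected_pool, p, eval_grid)
                for p in p_grid
            ]
        )
        return p_grid, dists, float(p_grid[int(np.argmin(dists))])

    def fit(
        self,
        grid_step: float = 0.01,
        n_resamples: int = 0,
        seed: int | None = None,
    ) -> MixtureFitResults:
        if not 0 < grid_step < 1:
            raise ValueError("grid_step must lie in (0, 1)")
        p_grid, dists, best = self._fit_p(self.observed, grid_step)
        band = None
        if n_resamples > 0:
            rng = np.random.default_rng(seed)
            n = self.observed.size
            refits = np.empty(n_resamples)
            for r in range(n_resamples):
                from_sel = rng.random(n) < best
                draw = np.where(
                    from_sel,
                    rng.choice(self.selected_pool, size=n),
                    rng.choice(self.neutral_pool, size=n),
                )
                _, _, refits[r] = self._fit_p(np.sort(draw), grid_step)
            band = (
                float(np.percentile(refits, 2.5)),
                float(np.percentile(refits, 97.5)),
            )
        return MixtureFitResults(
            proportion_grid=p_grid,
            ks_distance=dists,
            best_p_s=best,
            ks_vs_neutral=ks_two_sample(self.observed, self.neutral_pool),
            p_s_band=band,
        )
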