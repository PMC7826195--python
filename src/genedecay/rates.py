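"""Relative rates of each LoF mutation class and per-gene LoF mutation rates.

Every single-nucleotide change in a CDS is enumerated and weighted under a
two-parameter mutation model: each site mutates at total rate mu, split
kappa:1:1 over its three alternatives (transition weight kappa/(kappa+2),
each transversion 1/(kappa+2)), so per-site weights sum to 1. Summing the
weights of changes that create a premature stop, destroy the start codon or
destroy the stop codon gives those class rates in units of mu; dividing by
the CDS length expresses them per coding site. Splice-site rates follow from
the 2+2 bp canonical dinucleotide target per intron. The frameshift class
rate is an input parameter because it reflects the indel spectrum, not point
mutation pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gene_models import BASES, STOP_CODONS, GeneModel, is_transition

LOF_CLASSES = ("premature_stop", "frameshift", "splice_site", "start_loss", "stop_loss")

#: Frameshift-causing indel rate per coding site in units of mu, as estimated
#: in Lucifuga-type data; used as the default when no indel spectrum is given.
DEFAULT_FRAMESHIFT_RATE = 0.0143


def _site_weights(kappa: float) -> dict[bool, float]:
    return {True: kappa / (kappa + 2.0), False: 1.0 / (kappa + 2.0)}


def point_lof_rate(cds: str, kappa: float) -> dict[str, float]:
    """Per-site rates (units of mu) of premature_stop, start_loss, stop_loss
    from exhaustive enumeration of all 3L single-nucleotide changes.

    Raises ``ValueError`` if the CDS carries an internal stop codon (not a
    functional reference).
    """
    cds = cds.upper()
    L = len(cds)
    if L < 6 or L % 3:
        raise ValueError(f"CDS length {L} is not a valid coding length")
    n_codons = L // 3
    for c in range(1, n_codons - 1):
        if cds[3 * c : 3 * c + 3] in STOP_CODONS:
            raise ValueError(f"internal stop codon at position {3 * c}")

    w = _site_weights(kappa)
    per_gene = {"premature_stop": 0.0, "start_loss": 0.0, "stop_loss": 0.0}
    for c in range(n_codons):
        codon = cds[3 * c : 3 * c + 3]
        for j in range(3):
            ref = codon[j]
            for alt in BASES:
                if alt == ref:
                    continue
                weight = w[is_transition(ref, alt)]
                mutant = codon[:j] + alt + codon[j + 1 :]
                if c == 0:
                    # any change to the initiation codon destroys it
                    per_gene["start_loss"] += weight
                elif c == n_codons - 1:
                    if codon in STOP_CODONS and mutant not in STOP_CODONS:
                        per_gene["stop_loss"] += weight
                else:
                    if mutant in STOP_CODONS:
                        per_gene["premature_stop"] += weight
    return {k: v / L for k, v in per_gene.items()}


def splice_lof_rate(model: GeneModel | int, cds_length: int) -> float:
    """Splice-site LoF rate per coding site: 4 bp of canonical GT/AG target
    per intron, every change disruptive."""
    introns = model.intron_count if isinstance(model, GeneModel) else int(model)
    if cds_length <= 0:
        raise ValueError("cds_length must be positive")
    return 4.0 * introns / cds_length


@dataclass
class LoFRateTable:
    """Per-class relative LoF rates (units of mu per coding site) plus the
    mutation-model parameters needed to turn them into absolute per-gene
    rates."""

    relative_rates: dict[str, float]
    mu: float
    kappa: float
    indel_rate_ratio: float = 0.0
    mean_cds_length: float = 0.0
    per_gene_weights: dict[str, float] = field(default_factory=dict)

    @property
    def total_relative_rate(self) -> float:
        return float(sum(self.relative_rates.values()))

    @property
    def mean_mu_lof(self) -> float:
        """LoF mutation rate per gene per generation at the mean CDS length."""
        return per_gene_mu_lof(self, self.mean_cds_length)


def per_gene_mu_lof(table: LoFRateTable, gene_length: float) -> float:
    """LoF mutation rate per gene per generation:
    (sum of per-site class rates) x CDS length x mu."""
    return table.total_relative_rate * gene_length * table.mu


def gene_lof_weight(
    cds: str,
    model: GeneModel | None,
    kappa: float,
    frameshift_rate: float = DEFAULT_FRAMESHIFT_RATE,
) -> float:
    """Relative LoF mutation rate of one gene (units of mu): point-mutation
    classes from enumeration, frameshift at the given per-site rate, splice
    target 4 bp per intron."""
    L = len(cds)
    point = point_lof_rate(cds, kappa)
    introns = model.intron_count if model is not None else 0
    per_site = sum(point.values()) + frameshift_rate + splice_lof_rate(introns, L)
    return per_site * L


def build_rate_table(
    cds_by_gene: dict[str, str],
    models: dict[str, GeneModel] | None,
    kappa: float,
    mu: float,
    frameshift_rate: float = DEFAULT_FRAMESHIFT_RATE,
    indel_rate_ratio: float = 0.0,
) -> LoFRateTable:
    """Estimate the LoF rate table from a reference gene set.

    Class rates are averaged over genes weighted by CDS length (so the table
    describes the pooled coding sequence); per-gene weights are also kept for
    simulation use.
    """
    if not cds_by_gene:
        raise ValueError("empty gene set")
    lengths = {g: len(s) for g, s in cds_by_gene.items()}
    total_len = sum(lengths.values())
    pooled = {"premature_stop": 0.0, "start_loss": 0.0, "stop_loss": 0.0}
    total_introns = 0
    weights = {}
    for gene_id, cds in cds_by_gene.items():
        point = point_lof_rate(cds, kappa)
        for k in pooled:
            pooled[k] += point[k] * lengths[gene_id]
        model = models.get(gene_id) if models else None
        introns = model.intron_count if model is not None else 0
        total_introns += introns
        weights[gene_id] = gene_lof_weight(cds, model, kappa, frameshift_rate)
    relative = {k: v / total_len for k, v in pooled.items()}
    relative["frameshift"] = frameshift_rate
    relative["splice_site"] = 4.0 * total_introns / total_len
    return LoFRateTable(
        relative_rates=relative,
        mu=mu,
        kappa=kappa,
        indel_rate_ratio=indel_rate_ratio,
        mean_cds_length=total_len / len(cds_by_gene),
        per_gene_weights=weights,
    )


def calibrate_indel_rate_ratio(
    target_frameshift_rate: float,
    length_probs: np.ndarray | None = None,
) -> float:
    """Indel rate per site (units of mu) that yields the target per-site
    frameshift rate, given the indel length distribution.

    By default lengths follow the simulator's truncated geometric (mean 2 bp,
    support 1-12); only lengths not divisible by 3 shift the frame.
    """
    if length_probs is None:
        from .simulate import indel_length_pmf

        length_probs = indel_length_pmf()
    lengths = np.arange(1, len(length_probs) + 1)
    frameshift_fraction = float(length_probs[(lengths % 3) != 0].sum())
    if frameshift_fraction <= 0:
        raise ValueError("indel length distribution has no frameshifting support")
    return target_frameshift_rate / frameshift_fraction
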