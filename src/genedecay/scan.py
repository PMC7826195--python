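"""Loss-of-function mutation calling on aligned reference/query CDS.

Five LoF classes are called: premature STOP codons, loss of the initiation
codon, loss of the STOP codon, small indels causing a frameshift, and
disrupted intron splice sites. Incomplete genes are excluded from calling.
All query codons are read in reference-aligned coordinates, so an upstream
indel does not scramble downstream calls; premature stops downstream of the
first frameshift are treated as consequences of the shifted frame and are
not counted as independent lesions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .gene_models import (
    CANONICAL_ACCEPTOR,
    CANONICAL_DONOR,
    START_CODON,
    STOP_CODONS,
    Completeness,
    GeneModel,
    GeneSequencePair,
)

logger = logging.getLogger(__name__)

AMBIGUOUS = "N"


class LoFCategory(str, Enum):
    PREMATURE_STOP = "PREMATURE_STOP"
    START_LOSS = "START_LOSS"
    STOP_LOSS = "STOP_LOSS"
    FRAMESHIFT_INDEL = "FRAMESHIFT_INDEL"
    SPLICE_SITE = "SPLICE_SITE"


@dataclass(frozen=True)
class LoFEvent:
    """One classified loss-of-function mutation.

    ``cds_position`` is the 0-based offset in reference CDS coordinates; for
    SPLICE_SITE events it is the intron index, with ``splice_side`` and
    ``splice_offset`` locating the changed base within the dinucleotide.
    ``indel_length`` is signed (insertions positive) and nonzero only for
    FRAMESHIFT_INDEL.
    """

    gene_id: str
    category: LoFCategory
    cds_position: int
    ref_allele: str
    alt_allele: str
    indel_length: int = 0
    splice_side: str = ""
    splice_offset: int = 0

    def __post_init__(self) -> None:
        if self.category is LoFCategory.FRAMESHIFT_INDEL:
            if self.indel_length == 0 or self.indel_length % 3 == 0:
                raise ValueError(
                    f"frameshift indel must have length not divisible by 3, "
                    f"got {self.indel_length}"
                )
        elif self.indel_length != 0:
            raise ValueError(f"{self.category.value} events carry indel_length 0")


@dataclass
class GeneScanReport:
    """Scan outcome for one gene: its LoF events plus bookkeeping counts."""

    gene_id: str
    completeness: Completeness
    lof_events: list[LoFEvent] = field(default_factory=list)
    in_frame_indels: int = 0

    @property
    def n_lof(self) -> int:
        return len(self.lof_events)


@dataclass
class LoFCountDistribution:
    """Number of genes carrying x LoF mutations, x = 0..max observed.

    Totals: T genes, m mutations, D pseudogenes (genes with >= 1 LoF).
    """

    n_x: list[int]

    @property
    def T(self) -> int:
        return int(sum(self.n_x))

    @property
    def m(self) -> int:
        return int(sum(x * n for x, n in enumerate(self.n_x)))

    @property
    def D(self) -> int:
        return self.T - (self.n_x[0] if self.n_x else 0)


GAP_FRACTION_INCOMPLETE = 0.10


def assess_completeness(pair: GeneSequencePair) -> Completeness:
    """A pair is INCOMPLETE if any exon is fully missing or more than 10% of
    aligned columns are gapped or ambiguous in the query."""
    if pair.missing_exons or pair.completeness is Completeness.INCOMPLETE:
        return Completeness.INCOMPLETE
    n = len(pair.query_cds)
    bad = sum(1 for c in pair.query_cds if c == "-" or c == AMBIGUOUS)
    if n and bad / n > GAP_FRACTION_INCOMPLETE:
        return Completeness.INCOMPLETE
    return Completeness.COMPLETE


def _indel_runs(ref: str, query: str) -> list[tuple[int, int, int]]:
    """Maximal runs of gapped columns, merged across adjacent insertion and
    deletion columns. Returns (ref_position_of_run_start, net_length,
    run_start_column); net length is insertions minus deletions."""
    runs = []
    i = 0
    ref_pos = 0
    n = len(ref)
    while i < n:
        if ref[i] == "-" or query[i] == "-":
            start_col = i
            start_ref_pos = ref_pos
            ins = dele = 0
            while i < n and (ref[i] == "-" or query[i] == "-"):
                if ref[i] == "-":
                    ins += 1
                else:
                    dele += 1
                    ref_pos += 1
                i += 1
            runs.append((start_ref_pos, ins - dele, start_col))
        else:
            ref_pos += 1
            i += 1
    return runs


def scan_cds(pair: GeneSequencePair) -> GeneScanReport:
    """Call LoF mutations in one aligned reference/query CDS pair.

    INCOMPLETE pairs return a report with the flag set and zero events.
    The reference CDS must be a functional coding sequence (no internal
    stop codon).
    """
    completeness = assess_completeness(pair)
    if completeness is Completeness.INCOMPLETE:
        return GeneScanReport(pair.gene_id, completeness)

    ref, query = pair.reference_cds, pair.query_cds
    events: list[LoFEvent] = []
    in_frame = 0

    runs = _indel_runs(ref, query)
    first_fs = np.inf
    for ref_pos, net, _col in runs:
        if net != 0 and net % 3 != 0:
            events.append(
                LoFEvent(
                    gene_id=pair.gene_id,
                    category=LoFCategory.FRAMESHIFT_INDEL,
                    cds_position=ref_pos,
                    ref_allele="-" if net > 0 else "",
                    alt_allele="",
                    indel_length=net,
                )
            )
            first_fs = min(first_fs, ref_pos)
        else:
            in_frame += 1

    # Map each ungapped reference position to its query character.
    ref_len = sum(1 for c in ref if c != "-")
    query_at = [""] * ref_len
    rp = 0
    for rc, qc in zip(ref, query):
        if rc != "-":
            query_at[rp] = qc
            rp += 1
    ref_ungapped = ref.replace("-", "")
    if len(ref_ungapped) % 3 != 0:
        raise ValueError(f"{pair.gene_id}: reference CDS length not divisible by 3")
    n_codons = len(ref_ungapped) // 3

    for c in range(n_codons):
        ref_codon = ref_ungapped[3 * c : 3 * c + 3]
        q = query_at[3 * c : 3 * c + 3]
        if "-" in q or AMBIGUOUS in q:
            continue
        q_codon = "".join(q)
        pos = 3 * c
        if c == 0:
            if q_codon != START_CODON:
                events.append(
                    LoFEvent(pair.gene_id, LoFCategory.START_LOSS, pos, ref_codon, q_codon)
                )
        elif c == n_codons - 1:
            if ref_codon in STOP_CODONS and q_codon not in STOP_CODONS:
                events.append(
                    LoFEvent(pair.gene_id, LoFCategory.STOP_LOSS, pos, ref_codon, q_codon)
                )
        else:
            if ref_codon in STOP_CODONS:
                raise ValueError(
                    f"{pair.gene_id}: internal stop codon in reference CDS at {pos}"
                )
            if q_codon in STOP_CODONS and q_codon != ref_codon and pos < first_fs:
                events.append(
                    LoFEvent(
                        pair.gene_id, LoFCategory.PREMATURE_STOP, pos, ref_codon, q_codon
                    )
                )

    report = GeneScanReport(pair.gene_id, completeness, events, in_frame)
    return report


def scan_splice_sites(
    model: GeneModel, query_dinucleotides: list[tuple[str, str]]
) -> list[LoFEvent]:
    """Call SPLICE_SITE events where a query intron's donor is not GT or its
    acceptor is not AG. GC donors (minor spliceosome) are logged, not called."""
    if len(query_dinucleotides) != model.intron_count:
        raise ValueError(
            f"{model.gene_id}: {len(query_dinucleotides)} dinucleotide pairs for "
            f"{model.intron_count} introns"
        )
    events = []
    for idx, (donor, acceptor) in enumerate(query_dinucleotides):
        donor, acceptor = donor.upper(), acceptor.upper()
        if donor != CANONICAL_DONOR:
            if donor == "GC":
                logger.warning(
                    "gene %s intron %d: GC donor (minor spliceosome), not called",
                    model.gene_id,
                    idx,
                )
            else:
                offset = 0 if donor[0] != CANONICAL_DONOR[0] else 1
                events.append(
                    LoFEvent(
                        model.gene_id,
                        LoFCategory.SPLICE_SITE,
                        idx,
                        CANONICAL_DONOR,
                        donor,
                        splice_side="donor",
                        splice_offset=offset,
                    )
                )
        if acceptor != CANONICAL_ACCEPTOR:
            offset = 0 if acceptor[0] != CANONICAL_ACCEPTOR[0] else 1
            events.append(
                LoFEvent(
                    model.gene_id,
                    LoFCategory.SPLICE_SITE,
                    idx,
                    CANONICAL_ACCEPTOR,
                    acceptor,
                    splice_side="acceptor",
                    splice_offset=offset,
                )
            )
    return events


def scan_gene(
    pair: GeneSequencePair, model: GeneModel | None = None
) -> GeneScanReport:
    """Full scan of one gene: CDS lesions plus splice-site lesions when the
    pair carries query splice dinucleotides and a model is supplied."""
    report = scan_cds(pair)
    if (
        report.completeness is Completeness.COMPLETE
        and model is not None
        and pair.query_splice_dinucleotides is not None
    ):
        report.lof_events.extend(
            scan_splice_sites(model, pair.query_splice_dinucleotides)
        )
    return report


_EVENT_KEY = ("gene_id", "category", "cds_position", "ref_allele", "alt_allele", "splice_side")


def shared_lof(reports_by_species: dict[str, list[GeneScanReport]]) -> pd.DataFrame:
    """Flag LoF events identical (gene, class, position, alleles) in >= 2
    species — candidate ancestral mutations.

    Returns a table with one row per shared event and the species carrying it.
    """
    rows = []
    for species, reports in reports_by_species.items():
        for rep in reports:
            for ev in rep.lof_events:
                rows.append(
                    {
                        "species": species,
                        **{k: getattr(ev, k) for k in _EVENT_KEY},
                    }
                )
    if not rows or len(reports_by_species) < 2:
        return pd.DataFrame(columns=[*_EVENT_KEY, "species_list", "n_species"])
    df = pd.DataFrame(rows)
    df["category"] = df["category"].map(lambda c: c.value if isinstance(c, LoFCategory) else c)
    grouped = (
        df.groupby(list(_EVENT_KEY))["species"]
        .agg(lambda s: sorted(set(s)))
        .reset_index()
        .rename(columns={"species": "species_list"})
    )
    grouped["n_species"] = grouped["species_list"].map(len)
    return grouped[grouped["n_species"] >= 2].reset_index(drop=True)


def lof_count_distribution(reports: list[GeneScanReport]) -> LoFCountDistribution:
    """Tabulate the number of genes carrying x LoF mutations.

    Only COMPLETE genes enter the distribution.
    """
    counts = [
        r.n_lof for r in reports if r.completeness is Completeness.COMPLETE
    ]
    if not counts:
        return LoFCountDistribution([])
    n_x = [0] * (max(counts) + 1)
    for c in counts:
        n_x[c] += 1
    return LoFCountDistribution(n_x)
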