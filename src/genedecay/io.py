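"""Readers and writers for the formats the pipeline touches.

FASTA is handled by Biopython, GFF3 by gffutils (in-memory database); all
tabular results are tab-separated files with a header row, and fit/dating
results are JSON. Every writer round-trips through the matching reader.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .gene_models import (
    Completeness,
    GeneModel,
    GeneSequencePair,
    reverse_complement,
)

logger = logging.getLogger(__name__)


@dataclass
class ReferenceGeneSet:
    """Reference gene models plus their CDS, all stored 5'->3'."""

    models: dict[str, GeneModel]
    cds: dict[str, str]
    incomplete: set[str]

    def __len__(self) -> int:
        return len(self.models)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_gene_models(
    gff3_path: str | Path, fasta_path: str | Path
) -> ReferenceGeneSet:
    """Read gene models (GFF3) and scaffolds (FASTA) into a ReferenceGeneSet.

    Only gene/mRNA/exon/CDS features are honoured; others are ignored with a
    debug log line. One GeneModel is produced per mRNA; CDS segments are
    assembled in transcription order and minus-strand CDS are
    reverse-complemented so every stored CDS reads 5'->3'. Splice-site
    dinucleotides are lifted from the scaffold sequence flanking each intron.

    Raises
    ------
    KeyError
        If the GFF3 references a seqid absent from the FASTA.
    """
    scaffolds = read_fasta(fasta_path)
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: dict[str, GeneModel] = {}
    cds: dict[str, str] = {}
    incomplete: set[str] = set()

    for feature in db.all_features():
        if feature.featuretype not in ("gene", "mRNA", "exon", "CDS"):
            logger.debug("ignoring %s feature %s", feature.featuretype, feature.id)

    for mrna in db.features_of_type("mRNA"):
        seqid = mrna.seqid
        if seqid not in scaffolds:
            raise KeyError(
                f"GFF3 seqid {seqid!r} (mRNA {mrna.id}) has no sequence in the FASTA"
            )
        scaffold = scaffolds[seqid]
        segments = sorted(
            db.children(mrna, featuretype="CDS"), key=lambda f: f.start
        )
        if not segments:
            logger.warning("mRNA %s has no CDS features; skipped", mrna.id)
            continue
        # GFF3 is 1-based inclusive; convert to 0-based half-open.
        coords = [(f.start - 1, f.end) for f in segments]
        pieces = [scaffold[s:e] for s, e in coords]
        strand = mrna.strand if mrna.strand in "+-" else "+"

        donors_acceptors: list[tuple[str, str]] = []
        for (s1, e1), (s2, e2) in zip(coords, coords[1:]):
            intron = scaffold[e1:s2]
            donors_acceptors.append((intron[:2], intron[-2:]))
        seq = "".join(pieces)
        exon_lengths = [e - s for s, e in coords]
        if strand == "-":
            seq = reverse_complement(seq)
            exon_lengths = exon_lengths[::-1]
            donors_acceptors = [
                (reverse_complement(acc), reverse_complement(don))
                for don, acc in donors_acceptors[::-1]
            ]
        gene_id = mrna.id
        model = GeneModel(
            gene_id=gene_id,
            exon_lengths=exon_lengths,
            strand=strand,
            cds_start_offset=coords[0][0],
            splice_dinucleotides=donors_acceptors,
        )
        if len(seq) % 3 != 0 or len(seq) < 6:
            logger.warning(
                "gene %s: CDS length %d not a valid coding length; flagged INCOMPLETE",
                gene_id,
                len(seq),
            )
            incomplete.add(gene_id)
        models[gene_id] = model
        cds[gene_id] = seq

    return ReferenceGeneSet(models=models, cds=cds, incomplete=incomplete)


def build_sequence_pairs(
    reference: ReferenceGeneSet | dict[str, str],
    query_aligned: dict[str, str],
    reference_aligned: dict[str, str] | None = None,
) -> list[GeneSequencePair]:
    """Pair reference CDS with aligned query CDS by gene id.

    ``reference_aligned`` supplies gapped reference strings when the query
    carries insertions; otherwise the plain reference CDS is used and the
    query must be the same aligned length.
    """
    ref_cds = reference.cds if isinstance(reference, ReferenceGeneSet) else reference
    incomplete = reference.incomplete if isinstance(reference, ReferenceGeneSet) else set()
    pairs = []
    for gene_id, query in query_aligned.items():
        if gene_id not in ref_cds:
            logger.warning("query %s has no reference CDS; skipped", gene_id)
            continue
        ref = (reference_aligned or {}).get(gene_id, ref_cds[gene_id])
        completeness = (
            Completeness.INCOMPLETE if gene_id in incomplete else Completeness.COMPLETE
        )
        pairs.append(
            GeneSequencePair(
                gene_id=gene_id,
                reference_cds=ref.upper(),
                query_cds=query.upper(),
                completeness=completeness,
            )
        )
    return pairs


def _to_record(obj: Any) -> dict:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = dataclasses.asdict(obj)
    elif isinstance(obj, dict):
        d = dict(obj)
    else:
        raise TypeError(f"cannot serialise {type(obj).__name__} to a table row")
    return {k: (v.value if isinstance(v, Enum) else v) for k, v in d.items()}


def write_results(records: Iterable[Any], path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write records (dataclasses or dicts) as a TSV with a header row.

    An empty record set still produces a header-only file when ``columns``
    is given (or an empty file otherwise).
    """
    rows = [_to_record(r) for r in records]
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")


def write_json(payload: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_run_manifest(path: str | Path, *, inputs: dict, parameters: dict, seed: int | None) -> None:
    """Machine-readable record of a run: inputs, parameters, seed, version."""
    from . import __version__

    write_json(
        {
            "inputs": inputs,
            "parameters": parameters,
            "seed": seed,
            "genedecay_version": __version__,
        },
        path,
    )
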