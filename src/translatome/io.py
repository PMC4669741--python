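"""Readers and writers for the pipeline's tabular and sequence formats.

TSV schemas:

* expression: ``transcript_id  sample_id  mean_log_expr  sd_log_expr``
* design:     ``sample_id  condition  fraction  replicate``
* gene map:   ``transcript_id  gene_id`` (two columns, no header needed)
* truth:      ``transcript_id  true_delta  true_class``

UTR sequences travel as FASTA; headers are ``>transcript_id gene=GENE``
(the gene tag is optional when a separate gene map is supplied).
Ranked gene lists are written as two-column ``.rnk`` files compatible
with pre-ranked enrichment tools.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from translatome.design import SampleDesign
from translatome.utr import UTRRecord

EXPRESSION_COLUMNS = ["transcript_id", "sample_id", "mean_log_expr", "sd_log_expr"]
DESIGN_COLUMNS = ["sample_id", "condition", "fraction", "replicate"]


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EXPRESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: expression TSV missing columns {sorted(missing)}")
    bad = df.index[df["sd_log_expr"] < 0]
    if len(bad):
        raise ValueError(
            f"{path}: negative sd_log_expr at data row(s) {list(bad[:5] + 2)}"
        )
    return df[EXPRESSION_COLUMNS]


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df[EXPRESSION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t")
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: design TSV missing columns {sorted(missing)}")
    return SampleDesign(df[DESIGN_COLUMNS])


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.table[DESIGN_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: gene map needs two columns (transcript, gene)")
    if list(df.iloc[0])[:2] == ["transcript_id", "gene_id"]:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_utr_fasta(
    path: str | Path, gene_map: dict[str, str] | None = None
) -> list[UTRRecord]:
    """Load UTR records; gene ids come from a ``gene=`` tag in the FASTA
    description or from ``gene_map``, defaulting to the transcript id."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = None
        for token in rec.description.split():
            if token.startswith("gene="):
                gene = token[5:]
        if gene_map is not None:
            gene = gene_map.get(rec.id, gene)
        records.append(UTRRecord(rec.id, gene or rec.id, str(rec.seq)))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_utr_fasta(
    records: Iterable[tuple[str, str, str] | UTRRecord], path: str | Path
) -> None:
    seqrecs = []
    for rec in records:
        if isinstance(rec, UTRRecord):
            tid, gene, seq = rec.transcript_id, rec.gene_id, rec.sequence
        else:
            tid, gene, seq = rec
        seqrecs.append(
            SeqRecord(Seq(seq), id=tid, description=f"gene={gene}")
        )
    SeqIO.write(seqrecs, str(path), "fasta")


def write_rnk(scores: pd.DataFrame, path: str | Path) -> None:
    """Two-column pre-ranked list (id, score), best-ranked first."""
    ordered = scores.sort_values(scores.columns[-1], ascending=False)
    ordered.to_csv(path, sep="\t", index=False, header=False)
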