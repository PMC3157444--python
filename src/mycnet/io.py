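"""Readers/writers for the plain-text formats the pipeline exchanges.

TSV matrices (feature ids in the first column), promoter/UTR/miRNA FASTA
(promoter descriptions carry ``id|tss_offset|exon_end``), GMT gene sets,
and two-column design/mapping tables. All coordinates in files are 0-based
half-open.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrichment import GeneSetAnnotation
from .pwm import PromoterRegion
from .targets import MiRNARecord, UTRRecord


def read_matrix(path, index_name: str = "feature") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = index_name
    return df


def write_matrix(df: pd.DataFrame, path, index_name: str = "feature") -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")


def read_two_column(path) -> dict[str, str]:
    """Two-column TSV with a header row → dict of first → second column."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_two_column(mapping: dict[str, str], path,
                     columns=("key", "value")) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for k, v in mapping.items():
            fh.write(f"{k}\t{v}\n")


def read_promoters(path) -> list[PromoterRegion]:
    """FASTA with headers ``gene|tss_offset|exon_end``."""
    regions = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            gene, tss, exon_end = rec.description.split("|")
        except ValueError as err:
            raise ValueError(
                f"promoter header {rec.description!r} is not gene|tss_offset|exon_end"
            ) from err
        regions.append(PromoterRegion(gene, str(rec.seq), int(tss), int(exon_end)))
    return regions


def write_promoters(regions: list[PromoterRegion], path) -> None:
    records = [
        SeqRecord(Seq(r.seq), id=f"{r.gene_id}|{r.tss_offset}|{r.exon_end}",
                  description="")
        for r in regions
    ]
    SeqIO.write(records, str(path), "fasta")


def read_utrs(path) -> list[UTRRecord]:
    return [UTRRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_utrs(utrs: list[UTRRecord], path) -> None:
    SeqIO.write([SeqRecord(Seq(u.seq), id=u.gene_id, description="")
                 for u in utrs], str(path), "fasta")


def read_mirnas(path) -> list[MiRNARecord]:
    return [MiRNARecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_mirnas(mirnas: list[MiRNARecord], path) -> None:
    SeqIO.write([SeqRecord(Seq(m.seq), id=m.id, description="")
                 for m in mirnas], str(path), "fasta")


def read_gmt(path) -> list[GeneSetAnnotation]:
    terms = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
        terms.append(GeneSetAnnotation(fields[0], fields[1],
                                       frozenset(fields[2:])))
    return terms


def write_gmt(terms: list[GeneSetAnnotation], path) -> None:
    with open(path, "w") as fh:
        for t in terms:
            fh.write("\t".join([t.term_id, t.name, *sorted(t.genes)]) + "\n")
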