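"""Genome annotation container and delimited-text readers/writers.

Holds the RegulonDB-style inputs the cohort analyses need: per-gene records
(strand, TSS, body bounds, function tag, fitness, reporter-library flag,
optimal-condition expression), operon membership in transcription order, TF
regulator->target edges, terminator coordinates, and upstream promoter
sequences.  Files are plain TSV plus a FASTA of promoter sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["GenomeAnnotation", "read_annotation", "write_annotation"]

_GENE_COLUMNS = ["gene_id", "strand", "tss", "left", "right", "function_tag",
                 "fitness", "in_yfp_library", "expression_level"]


@dataclass
class GenomeAnnotation:
    """Validated genome annotation.

    genes: DataFrame with columns gene_id, strand (+/-), tss, left, right
    (1-based inclusive body bounds), function_tag, fitness, in_yfp_library,
    expression_level.  operons: ordered member lists (first member is the
    promoter-proximal gene).  tf_edges: columns regulator, target.
    terminators: columns position, strand.  promoter_sequences: gene_id ->
    upstream nucleotide string.
    """

    genes: pd.DataFrame
    operons: List[List[str]]
    tf_edges: pd.DataFrame
    terminators: pd.DataFrame
    promoter_sequences: Dict[str, str]
    genome_length: int = 0
    fixtures: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(_GENE_COLUMNS) - set(self.genes.columns)
        if missing:
            raise ValueError(f"genes table missing columns: {sorted(missing)}")
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids")
        if (self.genes["tss"] <= 0).any() or (self.genes["left"] <= 0).any():
            raise ValueError("coordinates must be positive (1-based)")
        universe = set(self.genes["gene_id"])
        seen: set = set()
        for members in self.operons:
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"genes in multiple operons: {sorted(overlap)}")
            seen |= set(members)
            unknown = set(members) - universe
            if unknown:
                raise ValueError(f"operon members not in gene table: {sorted(unknown)}")
        for gid, seq in self.promoter_sequences.items():
            if set(seq.upper()) - set("ACGTN"):
                raise ValueError(f"promoter sequence of {gid} has non-nucleotide chars")

    @property
    def gene_universe(self) -> set:
        return set(self.genes["gene_id"])

    def operon_of(self) -> Dict[str, int]:
        """gene_id -> operon index (genes outside operons absent)."""
        return {g: i for i, members in enumerate(self.operons) for g in members}


def read_annotation(directory) -> GenomeAnnotation:
    d = Path(directory)
    genes = pd.read_csv(d / "genes.tsv", sep="\t")
    genes["in_yfp_library"] = genes["in_yfp_library"].astype(bool)
    operons_df = pd.read_csv(d / "operons.tsv", sep="\t")
    operons = [row.split(",") for row in operons_df["members"]]
    tf_edges = pd.read_csv(d / "tf_edges.tsv", sep="\t")
    terminators = pd.read_csv(d / "terminators.tsv", sep="\t")
    promoters = {rec.id: str(rec.seq).upper()
                 for rec in SeqIO.parse(str(d / "promoters.fasta"), "fasta")}
    meta_path = d / "meta.tsv"
    genome_length = 0
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t")
        genome_length = int(meta["genome_length"].iloc[0])
    return GenomeAnnotation(genes=genes, operons=operons, tf_edges=tf_edges,
                            terminators=terminators,
                            promoter_sequences=promoters,
                            genome_length=genome_length)


def write_annotation(ann: GenomeAnnotation, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    ann.genes.to_csv(d / "genes.tsv", sep="\t", index=False)
    pd.DataFrame({"operon_id": range(len(ann.operons)),
                  "members": [",".join(m) for m in ann.operons]}
                 ).to_csv(d / "operons.tsv", sep="\t", index=False)
    ann.tf_edges.to_csv(d / "tf_edges.tsv", sep="\t", index=False)
    ann.terminators.to_csv(d / "terminators.tsv", sep="\t", index=False)
    records = [SeqRecord(Seq(seq), id=gid, description="")
               for gid, seq in ann.promoter_sequences.items()]
    SeqIO.write(records, str(d / "promoters.fasta"), "fasta")
    pd.DataFrame({"genome_length": [ann.genome_length]}
                 ).to_csv(d / "meta.tsv", sep="\t", index=False)
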