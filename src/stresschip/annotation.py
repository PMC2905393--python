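"""Gene annotation containers and plain-text genome I/O.

Coordinates are 0-based half-open internally.  GFF3 output/input is 1-based
inclusive; BED is 0-based half-open, matching the usual conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class Gene:
    """A gene model: ``start``/``end`` bound the ORF (0-based half-open).

    The translation start (ATG) sits at ``start`` for '+' genes and at
    ``end`` for '-' genes.  ``tss`` is optional (transcription start site,
    a single bp position); ``coding=False`` marks ncRNA features (tRNA,
    5S rRNA) that occupy annotation space but are never promoter targets.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    tss: int | None = None
    coding: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.end <= self.start:
            raise ValueError(f"empty gene body for {self.gene_id}")

    @property
    def atg(self) -> int:
        """Position of the translation start in genome coordinates."""
        return self.start if self.strand == "+" else self.end


class GeneAnnotation:
    """Ordered collection of genes, indexed per chromosome."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: list[Gene] = sorted(
            genes, key=lambda g: (g.chromosome, g.start, g.gene_id)
        )
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chromosome, []).append(g)
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValueError("duplicate gene ids in annotation")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def on_chromosome(self, chromosome: str) -> list[Gene]:
        """Genes on one chromosome, sorted by start."""
        return self._by_chrom.get(chromosome, [])

    def gene_ids(self, coding_only: bool = False) -> list[str]:
        return [g.gene_id for g in self.genes if g.coding or not coding_only]

    # ------------------------------------------------------------------ I/O

    def to_gff3(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                gtype = "gene" if g.coding else "ncRNA_gene"
                attrs = f"ID={g.gene_id}"
                if g.tss is not None:
                    attrs += f";tss={g.tss + 1}"
                fh.write(
                    f"{g.chromosome}\tstresschip\t{gtype}\t{g.start + 1}\t"
                    f"{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )

    @classmethod
    def from_gff3(cls, path: str) -> "GeneAnnotation":
        cols = ["seqid", "source", "type", "start", "end",
                "score", "strand", "phase", "attributes"]
        df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
        genes = []
        for row in df.itertuples(index=False):
            attrs = dict(
                kv.split("=", 1) for kv in str(row.attributes).split(";") if "=" in kv
            )
            tss = int(attrs["tss"]) - 1 if "tss" in attrs else None
            genes.append(
                Gene(
                    gene_id=attrs["ID"],
                    chromosome=str(row.seqid),
                    start=int(row.start) - 1,
                    end=int(row.end),
                    strand=str(row.strand),
                    tss=tss,
                    coding=row.type == "gene",
                )
            )
        return cls(genes)


def write_fasta(genome: dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


@dataclass
class SiteRecord:
    """A genomic point feature (planted or called binding site) for BED I/O."""

    chromosome: str
    start: int
    end: int
    name: str
    score: float = 0.0
    strand: str = "."
    extra: dict = field(default_factory=dict)


def write_bed(sites: Iterable[SiteRecord], path: str) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chromosome}\t{s.start}\t{s.end}\t{s.name}\t"
                f"{s.score:.6g}\t{s.strand}\n"
            )


def read_bed(path: str) -> list[SiteRecord]:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chromosome", "start", "end", "name", "score", "strand"],
    )
    return [
        SiteRecord(r.chromosome, int(r.start), int(r.end), str(r.name),
                   float(r.score), str(r.strand))
        for r in df.itertuples(index=False)
    ]
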