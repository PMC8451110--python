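"""File I/O: FASTA, GFF3, annotation tables and config files.

FASTA parsing goes through Biopython; GFF3 through gffutils (in-memory
database).  GFF3 is 1-based inclusive on disk and converted to the
package's internal 0-based half-open convention here, at the boundary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import GeneModel, ProteinRecord
from .screen import ScreenConfig

__all__ = [
    "read_protein_fasta",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "read_gff3",
    "write_gff3",
    "load_screen_config",
    "load_nsltp_catalog",
]


def load_nsltp_catalog() -> pd.DataFrame:
    """The packaged barley/Qingke nsLTP catalog (one row per protein).

    Columns: gene, gene_id, source (barley|qingke), type (1|2|D|G),
    chromosome, aa (mature length), pi, mass (Da), instability,
    aliphatic, gravy — the published physicochemical characterization of
    the 40 barley and 35 Qingke family members.
    """
    from importlib import resources

    with resources.as_file(resources.files("nsltpkit.data") / "nsltp_catalog.tsv") as path:
        return pd.read_csv(path, sep="\t", dtype={"type": str, "chromosome": str})


def read_protein_fasta(path: str | Path, source: str = "") -> list[ProteinRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                source=source,
                description=rec.description,
            )
        )
    return records


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, entries: Iterable[Sequence[str]]) -> None:
    """Write (id, sequence[, description]) tuples as FASTA."""
    records = []
    for entry in entries:
        name, sequence = entry[0], entry[1]
        description = entry[2] if len(entry) > 2 else ""
        records.append(SeqRecord(Seq(sequence), id=name, description=description))
    SeqIO.write(records, str(path), "fasta")


def read_annotations(path: str | Path) -> dict[str, dict[str, Optional[int]]]:
    """External predictor calls: TSV with columns id, nss_cleavage, gpi_omega."""
    table = pd.read_csv(path, sep="\t")
    if "id" not in table.columns:
        raise ValueError("annotations table needs an 'id' column")
    out: dict[str, dict[str, Optional[int]]] = {}
    for _, row in table.iterrows():
        entry: dict[str, Optional[int]] = {}
        for column in ("nss_cleavage", "gpi_omega"):
            if column in table.columns and pd.notna(row[column]):
                entry[column] = int(row[column])
        out[str(row["id"])] = entry
    return out


def read_gff3(path: str | Path) -> dict[str, GeneModel]:
    """Gene models from GFF3 (gene/mRNA/exon/CDS), keyed by gene id."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        exons, cds = [], []
        protein_id = ""
        for child in db.children(gene.id, featuretype=("exon", "CDS")):
            interval = (child.start - 1, child.end)  # to 0-based half-open
            if child.featuretype == "exon":
                exons.append(interval)
            else:
                cds.append(interval)
                protein_id = child.attributes.get("protein_id", [protein_id])[0]
        exons.sort()
        cds.sort()
        chromosome = None if gene.seqid in (".", "chrUn") else gene.seqid
        genes[gene.id] = GeneModel(
            gene_id=gene.id,
            chromosome=chromosome,
            strand=gene.strand,
            exons=exons or list(cds),
            cds=cds,
            protein_id=protein_id or gene.id,
        )
    return genes


def write_gff3(path: str | Path, genes: Iterable[GeneModel]) -> None:
    lines = ["##gff-version 3"]
    for gene in sorted(genes, key=lambda g: (g.chromosome or "chrUn", g.start)):
        seqid = gene.chromosome or "chrUn"
        lines.append(
            "\t".join(
                [
                    seqid, "nsltpkit", "gene", str(gene.start + 1), str(gene.end),
                    ".", gene.strand, ".", f"ID={gene.gene_id}",
                ]
            )
        )
        mrna_id = gene.gene_id + ".t1"
        lines.append(
            "\t".join(
                [
                    seqid, "nsltpkit", "mRNA", str(gene.start + 1), str(gene.end),
                    ".", gene.strand, ".", f"ID={mrna_id};Parent={gene.gene_id}",
                ]
            )
        )
        for kind, intervals in (("exon", gene.exons), ("CDS", gene.cds)):
            for start, end in intervals:
                attrs = f"Parent={mrna_id}"
                if kind == "CDS":
                    attrs += f";protein_id={gene.protein_id or gene.gene_id}"
                phase = "0" if kind == "CDS" else "."
                lines.append(
                    "\t".join(
                        [seqid, "nsltpkit", kind, str(start + 1), str(end),
                         ".", gene.strand, phase, attrs]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def load_screen_config(path: str | Path) -> ScreenConfig:
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    if "gap_bounds" in raw:
        raw["gap_bounds"] = tuple(tuple(pair) for pair in raw["gap_bounds"])
    if "exclusion_exemplars" in raw and isinstance(raw["exclusion_exemplars"], str):
        raw["exclusion_exemplars"] = read_fasta(raw["exclusion_exemplars"])
    return ScreenConfig(**raw)
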