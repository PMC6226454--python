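"""Readers and writers for the pipeline's on-disk formats.

FASTA goes through Biopython, GFF3 reading through gffutils; the GFF3
writer emits gene/mRNA/exon/CDS features with correct CDS phases.
All tables are plain TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import gffutils
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import CtRecord, CtTable, GeneModel, MotifDefinition, ProteinRecord



# ---------------------------------------------------------------------------
# FASTA

def write_fasta(proteins: list[ProteinRecord], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description=p.description)
        for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    return [
        ProteinRecord(rec.id, str(rec.seq), rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_cds_fasta(cds: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in cds.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3

def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """GFF3 (1-based inclusive); CDS features carry the GFF3 phase column
    (bases to skip to reach the next codon start)."""
    lines = ["##gff-version 3"]
    for gene in genes:
        attrs = f"ID={gene.id}"
        lines.append(
            "\t".join(
                [gene.chromosome, "famscan", "gene", str(gene.start), str(gene.end),
                 ".", gene.strand, ".", attrs]
            )
        )
        mrna_id = f"{gene.id}.t1"
        lines.append(
            "\t".join(
                [gene.chromosome, "famscan", "mRNA", str(gene.start), str(gene.end),
                 ".", gene.strand, ".", f"ID={mrna_id};Parent={gene.id}"]
            )
        )
        cumulative = 0
        ordered = sorted(gene.exons, reverse=(gene.strand == "-"))
        for start, end in ordered:
            phase = (3 - cumulative % 3) % 3
            lines.append(
                "\t".join(
                    [gene.chromosome, "famscan", "exon", str(start), str(end),
                     ".", gene.strand, ".", f"Parent={mrna_id}"]
                )
            )
            lines.append(
                "\t".join(
                    [gene.chromosome, "famscan", "CDS", str(start), str(end),
                     ".", gene.strand, str(phase), f"ID={mrna_id}.cds;Parent={mrna_id}"]
                )
            )
            cumulative += end - start + 1
        for start, end in gene.utrs:
            lines.append(
                "\t".join(
                    [gene.chromosome, "famscan", "three_prime_UTR", str(start), str(end),
                     ".", gene.strand, ".", f"Parent={mrna_id}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feature in db.features_of_type("gene"):
        exons = [
            (cds.start, cds.end)
            for cds in db.children(feature, featuretype="CDS", order_by="start")
        ]
        utrs = [
            (u.start, u.end)
            for u in db.children(feature, featuretype="three_prime_UTR", order_by="start")
        ]
        genes.append(
            GeneModel(
                id=feature.id,
                chromosome=feature.seqid,
                start=feature.start,
                end=feature.end,
                strand=feature.strand,
                exons=exons,
                utrs=utrs,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# tables

def write_motifs_tsv(motifs: tuple[MotifDefinition, ...], path: str | Path) -> None:
    frame = pd.DataFrame(
        {"index": [m.index for m in motifs],
         "width": [m.width for m in motifs],
         "consensus": [m.consensus for m in motifs]}
    )
    frame.to_csv(path, sep="\t", index=False)


def read_motifs_tsv(path: str | Path) -> tuple[MotifDefinition, ...]:
    frame = pd.read_csv(path, sep="\t")
    motifs = tuple(
        MotifDefinition(int(row["index"]), str(row["consensus"]))
        for _, row in frame.iterrows()
    )
    for motif, (_, row) in zip(motifs, frame.iterrows()):
        if motif.width != int(row["width"]):
            raise ValueError(
                f"motif {motif.index}: stated width {row['width']} != "
                f"consensus length {motif.width}"
            )
    return motifs


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_ct_tsv(table: CtTable, path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "gene": r.gene_id,
                "treatment": r.treatment,
                "biological_replicate": r.biological_replicate,
                "technical_replicate": r.technical_replicate,
                "ct_target": r.ct_target,
                "ct_reference": r.ct_reference,
                "reference_gene": table.reference_gene,
            }
            for r in table.records
        ]
    )
    frame.to_csv(path, sep="\t", index=False)


def read_ct_tsv(path: str | Path, control_label: str = "control") -> CtTable:
    frame = pd.read_csv(path, sep="\t")
    records = [
        CtRecord(
            gene_id=str(row["gene"]),
            treatment=str(row["treatment"]),
            biological_replicate=int(row["biological_replicate"]),
            technical_replicate=int(row["technical_replicate"]),
            ct_target=float(row["ct_target"]),
            ct_reference=float(row["ct_reference"]),
        )
        for _, row in frame.iterrows()
    ]
    reference = str(frame["reference_gene"].iloc[0]) if "reference_gene" in frame else "EF1a"
    return CtTable(records, reference_gene=reference, control_label=control_label)


def write_truth_json(truth, path: str | Path) -> None:
    payload = {
        "family_members": sorted(truth.family_members),
        "subfamily_of": truth.subfamily_of,
        "decoy_kind": truth.decoy_kind,
        "planted_pairs": [list(p) for p in truth.planted_pairs],
        "expression_pattern": truth.expression_pattern,
        "regulation_pattern": truth.regulation_pattern,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_yaml_config(path: str | Path) -> dict:
    with open(path) as handle:
        return yaml.safe_load(handle) or {}
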