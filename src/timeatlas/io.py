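"""Readers and writers for the pipeline's plain-text formats.

Cell event tables, mutation catalogs, peptide peaks, HLA typing and
clinical tables travel as CSV; expression matrices as TSV (first column =
gene symbol); protein sequences as FASTA (Biopython); signatures and
scaffold graphs as JSON (node-link via networkx).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cytof import SAMPLE_COL, CellEventTable, ScaffoldGraph
from .neoantigen import HlaType, MutationRecord, allele_locus
from .signature import ExpressionMatrix, TimeSignature


# -- cytometry event tables -------------------------------------------------

def write_cell_events(table: CellEventTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def read_cell_events(
    path: str | Path, transformed: bool, markers: Sequence[str] | None = None
) -> CellEventTable:
    """CSV with a ``sample_id`` column and one column per marker."""
    data = pd.read_csv(path)
    if markers is None:
        markers = [c for c in data.columns if c != SAMPLE_COL]
    return CellEventTable(data=data, markers=tuple(markers), transformed=transformed)


# -- proteins and mutations -------------------------------------------------

def write_fasta(proteins: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="") for acc, seq in proteins.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def mutations_to_frame(mutations: Iterable[MutationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": m.gene,
                "accession": m.accession,
                "protein_change": f"p.{m.wt_aa}{m.position}{m.mut_aa}",
                "source": "|".join(m.sources),
            }
            for m in mutations
        ],
        columns=["gene", "accession", "protein_change", "source"],
    )


def write_mutations(mutations: Iterable[MutationRecord], path: str | Path) -> None:
    mutations_to_frame(mutations).to_csv(path, index=False)


def read_mutation_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- peaks, HLA, clinical ---------------------------------------------------

def write_peaks(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks.to_csv(path, index=False)


def read_peaks(path: str | Path) -> pd.DataFrame:
    """Either precomputed (peptide,sample_id,auc) or long-format
    chromatograms (peptide,sample_id,time,intensity) reduced to AUC."""
    df = pd.read_csv(path)
    if "auc" in df.columns:
        return df[["peptide", "sample_id", "auc"]]
    from .neoantigen import quantify_abundance

    rows = []
    for (pep, sample), sub in df.groupby(["peptide", "sample_id"]):
        rows.append(
            {
                "peptide": pep,
                "sample_id": sample,
                "auc": quantify_abundance(sub["time"].to_numpy(), sub["intensity"].to_numpy()),
            }
        )
    return pd.DataFrame(rows, columns=["peptide", "sample_id", "auc"])


def write_hla(types: Iterable[HlaType], path: str | Path) -> None:
    rows = [
        {"patient": t.patient_id, "locus": allele_locus(a), "allele": a}
        for t in types
        for a in t.alleles
    ]
    pd.DataFrame(rows, columns=["patient", "locus", "allele"]).to_csv(path, index=False)


def read_hla(path: str | Path) -> list[HlaType]:
    df = pd.read_csv(path)
    return [
        HlaType(patient_id=str(patient), alleles=tuple(sub["allele"]))
        for patient, sub in df.groupby("patient", sort=True)
    ]


# -- expression, signature, graphs ------------------------------------------

def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.rename_axis("gene").to_csv(path, sep="\t")


def read_expression(path: str | Path, level: str, platform: str = "") -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=values, level=level, platform=platform)


def write_signature(signature: TimeSignature, path: str | Path) -> None:
    Path(path).write_text(json.dumps(signature.to_dict(), indent=2, sort_keys=True))


def read_signature(path: str | Path) -> TimeSignature:
    return TimeSignature.from_dict(json.loads(Path(path).read_text()))


def write_graph(graph: ScaffoldGraph, path: str | Path, retention_quantile: float = 0.0) -> None:
    import networkx as nx

    g = graph.to_networkx(retention_quantile=retention_quantile)
    payload = nx.node_link_data(g, edges="links")
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
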