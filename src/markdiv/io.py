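"""Readers and writers for the pipeline's plain-text interchange formats.

Formats:

- mark target list: one gene id per line, ``#`` comments and blank lines
  allowed;
- paralog pair list: TSV with header columns ``gene_a``, ``gene_b``;
- sequence sets: FASTA keyed by gene id (via Bio.SeqIO);
- expression matrix: TSV, first column gene id, header row of sample ids,
  optionally gzip-compressed;
- per-stage outputs: TSV tables and JSON summaries.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coding_divergence import DivergenceEstimate
from .expression_divergence import ExpressionMatrix, NullDistribution
from .mark_classes import ParalogPair
from .upstream_divergence import DSMResult

__all__ = [
    "read_gene_list",
    "write_gene_list",
    "read_pair_list",
    "write_pair_list",
    "read_fasta",
    "write_fasta",
    "read_expression_matrix",
    "write_expression_matrix",
    "write_classified_pairs",
    "read_classified_pairs",
    "write_divergence_table",
    "write_null_distribution",
    "write_motif_table",
    "write_json",
]


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; '#' comments and blank lines skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def write_gene_list(path: str | Path, gene_ids: Iterable[str]) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in gene_ids))


def read_pair_list(path: str | Path) -> list[tuple[str, str]]:
    """TSV pair list with mandatory header gene_a/gene_b.

    Duplicate pairs (order-insensitive) are rejected: each pair is analyzed
    once and the pair key is the sorted id tuple.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_a", "gene_b"}.issubset(df.columns):
        raise ValueError(f"{path}: pair list must have columns gene_a, gene_b")
    pairs = list(zip(df["gene_a"], df["gene_b"]))
    seen: set[tuple[str, str]] = set()
    for a, b in pairs:
        key = tuple(sorted((a, b)))
        if key in seen:
            raise ValueError(f"{path}: duplicate pair {key}")
        seen.add(key)
    return pairs


def write_pair_list(path: str | Path, pairs: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA to {gene_id: sequence} (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=gene, description="")
               for gene, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Genes x samples TSV (first column gene id); '.gz' handled transparently."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(data=df)


def write_expression_matrix(path: str | Path, matrix: ExpressionMatrix) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id")


def write_classified_pairs(path: str | Path, pairs: Sequence[ParalogPair],
                           support: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tmark_class\tsupport_a\tsupport_b\n")
        for p in pairs:
            fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.mark_class}"
                     f"\t{support.get(p.gene_a, 0)}\t{support.get(p.gene_b, 0)}\n")


def read_classified_pairs(path: str | Path) -> list[ParalogPair]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [ParalogPair(gene_a=r.gene_a, gene_b=r.gene_b, mark_class=r.mark_class)
            for r in df.itertuples()]


def write_divergence_table(path: str | Path,
                           estimates: Sequence[DivergenceEstimate]) -> None:
    with open(path, "w") as fh:
        fh.write("pair_id\tN\tS\tNd\tSd\tpN\tpS\tdN\tdS\tn_codons\tstatus\n")
        for e in estimates:
            dn = "" if e.dn is None else f"{e.dn:.6f}"
            ds = "" if e.ds is None else f"{e.ds:.6f}"
            fh.write(f"{e.pair_id}\t{e.n_sites:.4f}\t{e.s_sites:.4f}"
                     f"\t{e.n_diffs:.4f}\t{e.s_diffs:.4f}\t{e.p_n:.6f}\t{e.p_s:.6f}"
                     f"\t{dn}\t{ds}\t{e.n_codons}\t{e.status}\n")


def write_null_distribution(path: str | Path, null: NullDistribution) -> None:
    with open(path, "w") as fh:
        fh.write(f"# statistic={null.statistic} n_draws={null.n_draws} seed={null.seed}\n")
        fh.write("value\n")
        for v in null.values:
            fh.write(f"{v:.6f}\n")


def write_motif_table(path: str | Path, results: Sequence[DSMResult],
                      pair_genes: Mapping[str, tuple[str, str]]) -> None:
    """BED-like shared-motif table, 0-based half-open coordinates."""
    with open(path, "w") as fh:
        fh.write("gene_a\tstart_a\tend_a\tgene_b\tstart_b\tend_b\tlength\n")
        for res in results:
            ga, gb = pair_genes[res.pair_id]
            for m in res.motifs:
                fh.write(f"{ga}\t{m.start_a}\t{m.end_a}"
                         f"\t{gb}\t{m.start_b}\t{m.end_b}\t{m.length}\n")


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
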