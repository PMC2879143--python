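"""Readers and writers for the pipeline's tab-delimited interchange files."""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO

from .gsea import EnrichmentResult
from .quantify import CountMatrix, InputError
from .rank import RankedList


def read_counts(counts_path, design_path) -> CountMatrix:
    """Load a protein-by-sample count TSV plus its sample-design TSV.

    The count file has protein ids in the first column and sample ids in
    the header; the design file has columns sample_id, condition, stage.
    """
    values = pd.read_csv(counts_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    design = pd.read_csv(design_path, sep="\t", dtype=str)
    required = {"sample_id", "condition", "stage"}
    if not required.issubset(design.columns):
        raise InputError(
            f"design table needs columns {sorted(required)}, "
            f"got {list(design.columns)}"
        )
    design = design.set_index("sample_id")[["condition", "stage"]]
    return CountMatrix(values=values, design=design)


def write_counts(counts: CountMatrix, path) -> None:
    counts.values.to_csv(path, sep="\t")


def write_design(counts: CountMatrix, path) -> None:
    counts.design.to_csv(path, sep="\t", index_label="sample_id")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid in seqs:
            fh.write(f">{pid}\n")
            seq = seqs[pid]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_rnk(ranked: RankedList, path) -> None:
    """Two-column ranked-list file (protein id, score), descending."""
    ranked.table["score"].to_csv(path, sep="\t", header=False)


def read_rnk(path) -> RankedList:
    table = pd.read_csv(
        path, sep="\t", header=None, names=["protein_id", "score"],
        index_col=0, dtype={0: str},
    )
    table["ks_D"] = float("nan")
    table["p_value"] = float("nan")
    table["sign"] = [0 if s == 0 else (1 if s > 0 else -1) for s in table["score"]]
    table = table[["ks_D", "p_value", "sign", "score"]]
    order = sorted(
        range(len(table)),
        key=lambda i: (-table["score"].iloc[i], table.index[i]),
    )
    return RankedList(table.iloc[order])


def results_to_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "source": r.source,
                "size": r.set_size_effective,
                "ES": r.ES,
                "NES": r.NES,
                "p_nominal": r.p_nominal,
                "fdr_q": r.fdr_q,
                "direction": r.direction,
                "leading_edge": ",".join(sorted(r.leading_edge)),
            }
            for r in results
        ],
        columns=["set_name", "source", "size", "ES", "NES", "p_nominal",
                 "fdr_q", "direction", "leading_edge"],
    )


def write_results(results: list[EnrichmentResult], path) -> None:
    results_to_table(results).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path) -> list[EnrichmentResult]:
    df = pd.read_csv(path, sep="\t", dtype={"set_name": str})
    out = []
    for _, row in df.iterrows():
        le = row.get("leading_edge", "")
        members = frozenset(str(le).split(",")) if pd.notna(le) and le else frozenset()
        out.append(
            EnrichmentResult(
                set_name=str(row["set_name"]),
                set_size_effective=int(row["size"]),
                ES=float(row["ES"]),
                NES=float(row["NES"]),
                p_nominal=float(row["p_nominal"]),
                fdr_q=float(row["fdr_q"]),
                direction=str(row["direction"]),
                leading_edge=members,
                source=str(row.get("source", "")),
            )
        )
    return out
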