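"""Table and sequence I/O.

All tables are tab-separated text with a header row.  Missing values are
written as empty cells and floats are written with six significant
digits, so a written table is the canonical form of its data:
``read(write(x))`` reproduces ``x`` exactly for values already in
canonical form, including the missingness pattern.  Sequences use FASTA.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import SAMPLES

__all__ = [
    "write_table",
    "read_table",
    "write_fasta",
    "read_fasta",
    "read_expression",
    "read_mirna_counts",
    "read_gene_list",
    "write_dataset",
]

FLOAT_FORMAT = "%.6g"


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="", float_format=FLOAT_FORMAT)


def read_table(path, dtype: dict | None = None, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=dtype, index_col=index_col)


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_expression(path) -> pd.DataFrame:
    """Expression matrix: gene_id, length, then the six sample columns."""
    df = read_table(path, index_col="gene_id")
    missing = [c for c in ("length", *SAMPLES) if c not in df.columns]
    if missing:
        raise ValueError(f"expression table is missing column {missing[0]!r}")
    return df


def read_mirna_counts(path) -> pd.DataFrame:
    df = read_table(path, index_col="mirna_id")
    missing = [c for c in SAMPLES if c not in df.columns]
    if missing:
        raise ValueError(f"miRNA count table is missing column {missing[0]!r}")
    return df


def read_gene_list(path) -> set:
    """One identifier per line (comments with '#' allowed)."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line.split("\t")[0])
    return out


def write_dataset(dataset, outdir) -> dict[str, str]:
    """Write every table of a synthetic dataset; returns name -> path."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _w(name, fn):
        paths[name] = str(outdir / name)
        fn(outdir / name)

    _w("expression.tsv", lambda p: write_table(dataset.expression, p, index=True))
    _w("proteins.tsv", lambda p: write_table(dataset.proteins, p))
    _w("mirna_counts.tsv", lambda p: write_table(dataset.mirna_counts, p, index=True))
    _w("mirna.fasta", lambda p: write_fasta(dataset.mirna_seqs, p))
    _w("cds.fasta", lambda p: write_fasta(dataset.cds_seqs, p))
    _w("as_events.tsv", lambda p: write_table(dataset.as_events, p))
    _w("ortholog_map.tsv", lambda p: write_table(dataset.ortholog_map, p))
    _w("ppi_edges.tsv", lambda p: write_table(dataset.ppi_edges, p))
    _w("truth_genes.tsv", lambda p: write_table(dataset.truth.gene_effects, p, index=True))
    _w("truth_proteins.tsv", lambda p: write_table(dataset.truth.protein_truth, p))
    if dataset.truth.mirna_truth is not None:
        _w("truth_mirnas.tsv", lambda p: write_table(dataset.truth.mirna_truth, p))
    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(dataset.config.asdict(), fh, sort_keys=False)
    paths["sim_config.yaml"] = str(outdir / "sim_config.yaml")
    return paths
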