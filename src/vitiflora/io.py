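"""Readers/writers for the pipeline's on-disk formats.

Everything is plain text: FASTA gene models (Biopython), 2-column probe
TSVs (or configurable GEO platform exports), probe/gene expression TSVs
with a header sample row, CSV peak and standards tables, and TSV renderings
of maps and classifications.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .probemap import ProbeClassification, ProbeGeneMap, ProbeHit

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_probe_tsv",
    "write_probe_tsv",
    "read_expression_tsv",
    "write_expression_tsv",
    "write_probe_gene_map",
    "read_probe_gene_map",
    "write_classification",
]


def read_fasta(path: Path | str) -> dict[str, str]:
    """FASTA records as an id -> sequence mapping (order preserved)."""
    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: dict[str, str], path: Path | str) -> Path:
    path = Path(path)
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")
    return path


def read_probe_tsv(
    path: Path | str,
    id_column: str = "probe_id",
    seq_column: str = "sequence",
) -> dict[str, str]:
    """Probe table as id -> sequence; column names configurable for GEO
    platform exports."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in (id_column, seq_column):
        if col not in df.columns:
            raise ValueError(f"probe table missing column {col!r}")
    return dict(zip(df[id_column].astype(str), df[seq_column].astype(str)))


def write_probe_tsv(probes: dict[str, str], path: Path | str) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"probe_id": list(probes), "sequence": list(probes.values())}
    ).to_csv(path, sep="\t", index=False)
    return path


def read_expression_tsv(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(df: pd.DataFrame, path: Path | str) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t")
    return path


def write_probe_gene_map(pg_map: ProbeGeneMap, path: Path | str) -> Path:
    path = Path(path)
    rows = [
        {
            "probe_id": h.probe_id,
            "gene_id": h.gene_id,
            "mismatches": h.mismatches,
            "offset": h.offset,
            "orientation": h.orientation,
        }
        for h in pg_map.hits
    ]
    pd.DataFrame(
        rows, columns=["probe_id", "gene_id", "mismatches", "offset",
                       "orientation"]
    ).to_csv(path, sep="\t", index=False)
    return path


def read_probe_gene_map(
    path: Path | str,
    probe_ids: list[str] | None = None,
    gene_ids: list[str] | None = None,
    max_mm: int = 2,
) -> ProbeGeneMap:
    df = pd.read_csv(path, sep="\t")
    hits = [
        ProbeHit(
            str(r.probe_id), str(r.gene_id), int(r.offset),
            str(r.orientation), int(r.mismatches),
        )
        for r in df.itertuples()
    ]
    return ProbeGeneMap(
        hits=hits,
        probe_ids=probe_ids or sorted({h.probe_id for h in hits}),
        gene_ids=gene_ids or sorted({h.gene_id for h in hits}),
        max_mm=max_mm,
    )


def write_classification(
    classification: ProbeClassification, path: Path | str
) -> Path:
    path = Path(path)
    rows = []
    for p in sorted(classification.unique):
        rows.append({"probe_id": p, "status": "unique", "n_genes": 1,
                     "ambiguity_ratio": "1:1"})
    for p in sorted(classification.ambiguous):
        n = classification.ambiguous[p]
        rows.append({"probe_id": p, "status": "ambiguous", "n_genes": n,
                     "ambiguity_ratio": f"1:{n}"})
    for p in sorted(classification.unmapped):
        rows.append({"probe_id": p, "status": "unmapped", "n_genes": 0,
                     "ambiguity_ratio": ""})
    pd.DataFrame(
        rows, columns=["probe_id", "status", "n_genes", "ambiguity_ratio"]
    ).to_csv(path, sep="\t", index=False)
    return path
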