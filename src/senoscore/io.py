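"""Readers and writers for the small text formats the pipeline exchanges.

GMT gene-set collections, BED6 intervals, JASPAR-style position frequency
matrices and plain FASTA. Everything is line-oriented text so that fixtures
stay human-inspectable.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file into ``{set_name: [genes...]}`` (description column dropped)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        name, _desc, *genes = fields
        if name in sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        sets[name] = [g for g in genes if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "senoscore") -> None:
    lines = ["\t".join([name, description, *genes]) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed(path) -> pd.DataFrame:
    """Read BED (3-6 columns) into a DataFrame with canonical column names."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    """Write intervals sorted by (chrom, start); missing BED6 columns are filled."""
    out = df.copy()
    for col, fill in [("name", "."), ("score", 0), ("strand", ".")]:
        if col not in out.columns:
            out[col] = fill
    out = out[BED_COLUMNS].sort_values(["chrom", "start", "end"], kind="mergesort")
    out.to_csv(path, sep="\t", header=False, index=False)


def read_jaspar_pfm(path) -> tuple[str, "pd.DataFrame"]:
    """Parse a JASPAR-format PFM via Bio.motifs.

    Returns the motif name and a 4 x width count DataFrame indexed by base.
    """
    from Bio import motifs

    with open(path) as fh:
        motif = motifs.read(fh, "jaspar")
    pfm = pd.DataFrame({b: list(motif.counts[b]) for b in "ACGT"}).T.loc[list("ACGT")]
    return motif.matrix_id or motif.name or "motif", pfm


def write_jaspar_pfm(name: str, pfm: pd.DataFrame, path) -> None:
    lines = [f">{name}\t{name}"]
    for base in "ACGT":
        counts = "  ".join(f"{v:g}" for v in pfm.loc[base])
        lines.append(f"{base}  [ {counts} ]")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
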