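"""Validated readers and writers for every on-disk artifact of the pipeline.

Formats (exact columns in docs/schema.md):

* counts — TSV, ``gene_id`` row key, one integer column per library
* sample sheet — CSV: library_id, subject_id, group, assay, replicate
* gene models — TSV: gene_id, length_bp, utr3_len_bp, intron_count, strand
  (optional chrom/start/end, 0-based half-open)
* gene sets — GMT (set, description, members...)
* 3'UTRs — FASTA keyed by the gene_id token before the first whitespace;
  T and U are equivalent on read
* protein — TSV: gene_id, group, replicate, abundance
* config — YAML

All readers are total over valid files and raise :class:`FormatError` with
file/line context otherwise; write-then-read is the identity on content and
gene order is preserved.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gene_models",
    "write_gene_models",
    "read_gmt",
    "write_gmt",
    "read_fasta",
    "write_fasta",
    "read_protein_table",
    "write_protein_table",
    "read_table",
    "write_table",
    "read_yaml",
    "write_yaml",
]

VALID_ASSAYS = {"pulse", "chase"}


class FormatError(ValueError):
    """A file failed structural validation; message carries file context."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_counts(path) -> pd.DataFrame:
    """Read a gene x library count matrix (TSV, gene_id index)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "gene_id":
        raise FormatError(f"{path}: first column must be 'gene_id'")
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicated gene_id {dup[0]!r}")
    for lib in df.columns:
        col = df[lib]
        if not pd.api.types.is_integer_dtype(col):
            raise FormatError(f"{path}: non-integer counts in library {lib!r}")
        if (col < 0).any():
            gene = col.index[col < 0][0]
            raise FormatError(
                f"{path}: negative count for gene {gene!r} in library {lib!r}"
            )
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    df = df.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the library metadata sheet (CSV)."""
    df = pd.read_csv(path)
    _require_columns(
        df, ["library_id", "subject_id", "group", "assay", "replicate"], path
    )
    bad = set(df["assay"]) - VALID_ASSAYS
    if bad:
        raise FormatError(f"{path}: unknown assay value(s) {sorted(bad)}")
    if df["library_id"].duplicated().any():
        lib = df.loc[df["library_id"].duplicated(), "library_id"].iloc[0]
        raise FormatError(f"{path}: duplicated library_id {lib!r}")
    key = df[["subject_id", "replicate", "assay"]].apply(tuple, axis=1)
    if key.duplicated().any():
        raise FormatError(
            f"{path}: duplicated (subject_id, replicate, assay) {key[key.duplicated()].iloc[0]}"
        )
    if (df["replicate"] < 1).any():
        raise FormatError(f"{path}: replicate numbers must be >= 1")
    return df


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_gene_models(path) -> pd.DataFrame:
    """Read the gene-model table (TSV, gene_id index)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "gene_id":
        raise FormatError(f"{path}: first column must be 'gene_id'")
    _require_columns(df, ["length_bp", "utr3_len_bp", "intron_count"], path)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicated gene_id {dup!r}")
    if (df["length_bp"] < 1).any():
        gene = df.index[df["length_bp"] < 1][0]
        raise FormatError(f"{path}: gene {gene!r} has length_bp < 1")
    if (df["intron_count"] < 0).any():
        gene = df.index[df["intron_count"] < 0][0]
        raise FormatError(f"{path}: gene {gene!r} has negative intron_count")
    if (df["utr3_len_bp"] > df["length_bp"]).any():
        gene = df.index[(df["utr3_len_bp"] > df["length_bp"])][0]
        raise FormatError(f"{path}: gene {gene!r} has 3'UTR longer than transcript")
    return df


def write_gene_models(df: pd.DataFrame, path) -> None:
    df = df.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection; members are deduplicated, order kept."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s), need >= 3"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicated set name {name!r}")
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} is empty")
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path, descriptions=None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read sequences keyed by the first token of each header; U -> T."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicated record id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper().replace("U", "T")
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=g, description="") for g, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_protein_table(path) -> pd.DataFrame:
    """Read the long-format protein abundance table (TSV)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene_id", "group", "abundance"], path)
    present = df["abundance"].notna()
    if (df.loc[present, "abundance"] <= 0).any():
        gene = df.loc[present & (df["abundance"] <= 0), "gene_id"].iloc[0]
        raise FormatError(f"{path}: non-positive abundance for gene {gene!r}")
    return df


def write_protein_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


_IUPAC_SYMBOLS = set("ACGTURYSWKMBDHVN")


def read_motif_table(path) -> pd.DataFrame:
    """Read a motif table (TSV: motif_name, pattern, optional rbp)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["motif_name", "pattern"], path)
    for rec in df.itertuples():
        pat = str(rec.pattern).upper()
        if not pat:
            raise FormatError(f"{path}: empty pattern for motif {rec.motif_name!r}")
        bad = set(pat) - _IUPAC_SYMBOLS
        if bad:
            raise FormatError(
                f"{path}: motif {rec.motif_name!r} has non-IUPAC symbol(s) {sorted(bad)}"
            )
    if df["motif_name"].duplicated().any():
        name = df.loc[df["motif_name"].duplicated(), "motif_name"].iloc[0]
        raise FormatError(f"{path}: duplicated motif_name {name!r}")
    return df


def write_motif_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path, index_col=None) -> pd.DataFrame:
    """Generic TSV reader for pipeline intermediates (truth, results)."""
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
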