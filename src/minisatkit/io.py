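"""File-format plumbing: FASTA motifs/reads, TSV catalogs, arm models, assays.

Conventions: all coordinates are 1-based inclusive in files and 0-based
half-open in memory; TSV outputs begin with a provenance comment header.
The catalog reader accepts the supplementary-table dialect (header line,
1-based coordinates) and a BED-like alternative (0-based half-open).
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .fluctuation import FluctuationExperiment
from .genome_dist import ChromosomeArmModel, MinisatelliteRecord
from .motifs import NucleotideMotif

__all__ = [
    "read_fasta_motifs",
    "write_fasta",
    "read_fluctuation_tsv",
    "read_arms_tsv",
    "read_catalog_tsv",
    "write_catalog_tsv",
    "write_tsv",
]

CATALOG_COLUMNS = [
    "chrom", "start", "end", "motif_size", "copy_number",
    "gc_bias", "array_length", "gc_content",
]
G4_COLUMNS = ["G4le30", "G4le40", "G4le50", "G4le100", "G4strand"]


def provenance_header(seed=None, **params) -> str:
    items = [f"minisatkit v{__version__}"]
    if seed is not None:
        items.append(f"seed={seed}")
    items += [f"{k}={v}" for k, v in params.items()]
    return "# " + " ".join(items)


def read_fasta_motifs(path) -> list[NucleotideMotif]:
    """One motif (or array sequence) per FASTA record."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [NucleotideMotif(r.id, str(r.seq)) for r in records]


def write_fasta(path, named_sequences) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in named_sequences
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fluctuation_tsv(path) -> list[FluctuationExperiment]:
    """One row per culture: label, r, Nt [, plating_fraction]; grouped by label."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"label", "r", "Nt"}
    if not required.issubset(df.columns):
        raise ValueError(f"fluctuation TSV needs columns {sorted(required)}")
    out = []
    for label, grp in df.groupby("label", sort=False):
        pf = float(grp["plating_fraction"].iloc[0]) if "plating_fraction" in grp else 1.0
        nt = grp["Nt"].astype(float)
        nt_val = float(nt.iloc[0]) if nt.nunique() == 1 else list(nt)
        out.append(
            FluctuationExperiment(
                r=[int(v) for v in grp["r"]], Nt=nt_val, label=str(label),
                plating_fraction=pf,
            )
        )
    return out


def read_arms_tsv(path) -> list[ChromosomeArmModel]:
    """Arm models from rows: chrom, p_start, p_end, centromere, q_end.

    The p arm spans p_start..centromere-1 (telomere at p_start), the q arm
    centromere..q_end (telomere at q_end).  Missing/NaN p columns mark
    acrocentric chromosomes whose p arm is skipped.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    arms = []
    for _, row in df.iterrows():
        chrom = str(row["chrom"])
        cen = int(row["centromere"])
        if not (pd.isna(row.get("p_start")) or pd.isna(row.get("p_end"))):
            arms.append(
                ChromosomeArmModel(chrom, "p", int(row["p_start"]), cen - 1, "end")
            )
        arms.append(ChromosomeArmModel(chrom, "q", cen, int(row["q_end"]), "start"))
    return arms


def read_catalog_tsv(path, dialect: str = "supp") -> list[MinisatelliteRecord]:
    """Minisatellite catalog: supplementary-table ('supp', 1-based inclusive)
    or BED-like ('bed', 0-based half-open) coordinates."""
    if dialect not in ("supp", "bed"):
        raise ValueError("dialect must be 'supp' or 'bed'")
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"catalog TSV missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        start, end = int(row["start"]), int(row["end"])
        if dialect == "bed":
            start, end = start + 1, end  # to 1-based inclusive
        g4 = {}
        for col, w in zip(G4_COLUMNS[:4], (30, 40, 50, 100)):
            if col in df.columns and not pd.isna(row[col]):
                g4[w] = int(row[col])
        strand = row.get("G4strand")
        records.append(
            MinisatelliteRecord(
                chrom=str(row["chrom"]),
                start=start,
                end=end,
                motif_size=int(row["motif_size"]),
                copy_number=float(row["copy_number"]),
                array_length=int(row["array_length"]),
                gc_content=float(row["gc_content"]),
                gc_bias=float(row["gc_bias"]) if not pd.isna(row["gc_bias"]) else math.nan,
                g4_counts=g4,
                g4_strand=None if pd.isna(strand) else str(strand),
            )
        )
    return records


def write_catalog_tsv(path, records, seed=None) -> None:
    rows = []
    for r in records:
        row = {
            "chrom": r.chrom, "start": r.start, "end": r.end,
            "motif_size": r.motif_size, "copy_number": r.copy_number,
            "gc_bias": r.gc_bias, "array_length": r.array_length,
            "gc_content": r.gc_content,
        }
        for col, w in zip(G4_COLUMNS[:4], (30, 40, 50, 100)):
            if w in r.g4_counts:
                row[col] = r.g4_counts[w]
        row["G4strand"] = r.g4_strand
        rows.append(row)
    write_tsv(path, pd.DataFrame(rows), seed=seed)


def write_tsv(path, df: pd.DataFrame, seed=None, **params) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(provenance_header(seed=seed, **params) + "\n")
        df.to_csv(fh, sep="\t", index=False)
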