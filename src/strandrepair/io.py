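"""Readers and writers for the plain-text formats the package exchanges.

Lesion tracks are stored as strand-split bedGraph (two files per track with
suffixes ``.plus.bedgraph`` / ``.minus.bedgraph``, 0-based half-open, one row
per lesion position).  Genes travel as BED6 plus an optional covariate TSV
keyed by gene id.  Genomes are FASTA.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .core import GeneModel, LesionTrack

FASTA_WIDTH = 70


def write_fasta(path: os.PathLike | str, genome: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), FASTA_WIDTH):
                fh.write(seq[i:i + FASTA_WIDTH] + "\n")


def read_fasta(path: os.PathLike | str) -> dict[str, str]:
    genome: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        genome[name] = "".join(chunks)
    return genome


# -- strand-split bedGraph lesion tracks ---------------------------------

def _strand_paths(prefix: os.PathLike | str) -> tuple[Path, Path]:
    prefix = Path(prefix)
    return (prefix.with_name(prefix.name + ".plus.bedgraph"),
            prefix.with_name(prefix.name + ".minus.bedgraph"))


def write_track(prefix: os.PathLike | str, track: LesionTrack) -> tuple[Path, Path]:
    """Write one lesion track as two single-base-resolution bedGraph files."""
    paths = _strand_paths(prefix)
    for strand, path in zip("+-", paths):
        with open(path, "w") as fh:
            for chrom in track.chroms():
                pos, cnt = track.get(chrom, strand)
                for p, c in zip(pos.tolist(), cnt.tolist()):
                    fh.write(f"{chrom}\t{p}\t{p + 1}\t{c}\n")
    return paths


def read_track(prefix: os.PathLike | str, sample_id: str = "",
               timepoint: float = 0.0) -> LesionTrack:
    track = LesionTrack(sample_id=sample_id, timepoint=timepoint,
                        provenance=f"loaded:{prefix}")
    for strand, path in zip("+-", _strand_paths(prefix)):
        if not Path(path).exists():
            raise FileNotFoundError(path)
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "count"],
                         dtype={"chrom": str})
        if len(df) == 0:
            continue
        for chrom, sub in df.groupby("chrom", sort=False):
            # expand any multi-base intervals to single positions
            width = (sub["end"] - sub["start"]).to_numpy()
            if np.all(width == 1):
                pos = sub["start"].to_numpy(np.int64)
                cnt = sub["count"].to_numpy(np.int64)
            else:
                pos = np.concatenate([np.arange(s, e)
                                      for s, e in zip(sub["start"], sub["end"])])
                cnt = np.repeat(sub["count"].to_numpy(np.int64), width)
            track.set_counts(str(chrom), strand, pos, cnt)
    return track


def write_bedgraph(path: os.PathLike | str,
                   values: Mapping[str, np.ndarray]) -> None:
    """Write per-position values (dense arrays keyed by chrom) as bedGraph,
    run-length collapsing equal adjacent values and skipping zeros."""
    with open(path, "w") as fh:
        for chrom in values:
            arr = np.asarray(values[chrom])
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts.tolist(), ends.tolist()):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph_dense(path: os.PathLike | str,
                        chrom_lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    out = {c: np.zeros(n, dtype=float) for c, n in chrom_lengths.items()}
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"], dtype={"chrom": str})
    for row in df.itertuples(index=False):
        if row.chrom in out:
            out[row.chrom][row.start:row.end] = row.value
    return out


# -- gene annotation ------------------------------------------------------

def write_genes(bed_path: os.PathLike | str, genes: list[GeneModel],
                covariates_path: Optional[os.PathLike | str] = None) -> None:
    """BED6 rows cover the gene body; the name column carries the gene id.

    TSS/TES are recoverable from the interval and strand (plus-strand:
    tss=start, tes=end; minus-strand: tss=end-1, tes=start-1).
    """
    with open(bed_path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.body_start}\t{g.body_end}\t{g.gene_id}\t0\t{g.strand}\n")
    if covariates_path is not None:
        rows = [{"gene_id": g.gene_id,
                 "transcription_rate": g.transcription_rate,
                 "expr_log2fc": g.expr_log2fc,
                 "srat_class": g.srat_class} for g in genes]
        pd.DataFrame(rows).to_csv(covariates_path, sep="\t", index=False)


def read_genes(bed_path: os.PathLike | str,
               covariates_path: Optional[os.PathLike | str] = None,
               one_based: bool = False) -> list[GeneModel]:
    df = pd.read_csv(bed_path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"],
                     dtype={"chrom": str, "name": str})
    if one_based:
        df["start"] = df["start"] - 1
    cov = None
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path, sep="\t", dtype={"gene_id": str})
        cov = cov.set_index("gene_id")
    genes = []
    for row in df.itertuples(index=False):
        if row.strand == "+":
            tss, tes = int(row.start), int(row.end)
        else:
            tss, tes = int(row.end) - 1, int(row.start) - 1
        kwargs = {}
        if cov is not None and row.name in cov.index:
            rec = cov.loc[row.name]
            for f in ("transcription_rate", "expr_log2fc"):
                if f in rec and pd.notna(rec[f]):
                    kwargs[f] = float(rec[f])
            if "srat_class" in rec and pd.notna(rec["srat_class"]):
                kwargs["srat_class"] = str(rec["srat_class"])
        genes.append(GeneModel(gene_id=str(row.name), chrom=str(row.chrom),
                               strand=str(row.strand), tss=tss, tes=tes, **kwargs))
    return genes
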