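"""Readers and writers for the package's plain-text interchange formats.

Tables are tab-separated with optional ``#``-prefixed metadata header
lines; regions travel as BED (0-based half-open); sequences as FASTA and
FASTQ through Biopython.  Floats are written with a fixed format so
repeated runs with the same seed produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .amplicon import AmpliconDesign
from .arraydm import BetaMatrix, ProbeManifest
from .enrichment import GenomicWindowSet

__all__ = [
    "read_tsv",
    "write_tsv",
    "read_manifest",
    "write_manifest",
    "read_groups",
    "write_groups",
    "write_beta",
    "read_bed",
    "write_bed",
    "read_design",
    "write_design",
    "write_fastq",
    "read_gene_set",
    "write_gene_set",
]

FLOAT_FORMAT = "%.6g"


def _meta_lines(meta: Mapping[str, object] | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k} = {v}\n" for k, v in meta.items())


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    meta: Mapping[str, object] | None = None,
    index: bool = True,
) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        df.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT, index=index)


def read_tsv(path: str | Path, index_col: int | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_manifest(
    manifest: ProbeManifest, path: str | Path, meta: Mapping[str, object] | None = None
) -> None:
    out = manifest.table.copy()
    out["genes"] = [";".join(g) for g in out["genes"]]
    write_tsv(out, path, meta=meta)


def read_manifest(path: str | Path) -> ProbeManifest:
    t = read_tsv(path, index_col=0)
    genes = [
        tuple(g.split(";")) if isinstance(g, str) and g else () for g in t["genes"]
    ]
    return ProbeManifest(t.assign(genes=genes))


def write_groups(groups: Mapping[str, str], path: str | Path) -> None:
    df = pd.DataFrame(
        {"sample": list(groups), "group": [groups[s] for s in groups]}
    )
    write_tsv(df, path, index=False)


def read_groups(path: str | Path) -> dict[str, str]:
    df = read_tsv(path)
    if not {"sample", "group"} <= set(df.columns):
        raise ValueError("groups file needs columns 'sample' and 'group'")
    return dict(zip(df["sample"].astype(str), df["group"].astype(str)))


def write_beta(
    bm: BetaMatrix, path: str | Path, meta: Mapping[str, object] | None = None
) -> None:
    write_tsv(bm.values, path, meta=meta)


def write_bed(windows: GenomicWindowSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        if windows.provenance:
            fh.write(f"# {windows.name}: {windows.provenance}\n")
        for row in windows.windows.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")


def read_bed(path: str | Path, name: str | None = None) -> GenomicWindowSet:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, *_ = line.split("\t")
            rows.append({"chrom": chrom, "start": int(start), "end": int(end)})
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return GenomicWindowSet(name or Path(path).stem, windows, provenance=str(path))


def write_design(design: AmpliconDesign, fasta_path: str | Path, tsv_path: str | Path) -> None:
    """Write the reference as FASTA and the coordinates as a design table."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{design.name}\n{design.reference}\n")
    rows = [
        {"feature": "primer_fwd", "start": design.primer_fwd_span[0], "end": design.primer_fwd_span[1]},
        {"feature": "primer_rev", "start": design.primer_rev_span[0], "end": design.primer_rev_span[1]},
    ]
    rows += [{"feature": "cpg", "start": p, "end": p + 2} for p in design.cpg_positions]
    write_tsv(
        pd.DataFrame(rows),
        tsv_path,
        meta={"name": design.name, "strand": design.strand, "coordinates": "0-based half-open"},
        index=False,
    )


def read_design(fasta_path: str | Path, tsv_path: str | Path) -> AmpliconDesign:
    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    t = read_tsv(tsv_path)
    fwd = t[t["feature"] == "primer_fwd"].iloc[0]
    rev = t[t["feature"] == "primer_rev"].iloc[0]
    cpgs = tuple(int(p) for p in t.loc[t["feature"] == "cpg", "start"])
    return AmpliconDesign(
        name=record.id,
        reference=str(record.seq),
        primer_fwd_span=(int(fwd["start"]), int(fwd["end"])),
        primer_rev_span=(int(rev["start"]), int(rev["end"])),
        cpg_positions=cpgs,
    )


def write_fastq(records: Iterable, path: str | Path) -> None:
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(set(genes)):
            fh.write(f"{g}\n")


def read_gene_set(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}
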