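"""Per-read methylation analysis of bisulfite amplicon sequencing.

The workflow mirrors the standard semi-automated amplicon pipeline: reads
are aligned to the amplicon reference in three-letter space (both read and
reference C->T converted, so methylation state cannot bias the alignment),
methylation is called back from the original read bases at each CpG
reference column, reads failing bisulfite-conversion / identity / coverage
QC are dropped, and the retained read x CpG call matrix feeds summaries,
pattern maps and per-read classification.

Calls are encoded ``M`` (methylated, C retained at a CpG), ``U``
(unmethylated, C read as T) and ``.`` (missing: gap or unexpected base).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

log = logging.getLogger(__name__)

__all__ = [
    "AmpliconDesign",
    "ReadAlignment",
    "ReadCall",
    "ReadCallMatrix",
    "MethylationSummary",
    "ReadClassProfile",
    "UnalignableReadError",
    "convert_reference",
    "align_read",
    "call_read",
    "filter_reads",
    "call_fastq",
    "summarize",
    "pattern_map",
    "classify_reads",
    "plot_pattern_map",
]

MIN_READ_LENGTH = 30

M, U, MISSING = "M", "U", "."


class UnalignableReadError(ValueError):
    """Raised when a read cannot be placed on the amplicon reference."""


@dataclass(frozen=True)
class AmpliconDesign:
    """Reference sequence, primer spans and CpG coordinates of one amplicon.

    ``cpg_positions`` are 0-based offsets of the C of each CG dinucleotide
    lying strictly between the primer annealing regions; spans are 0-based
    half-open intervals on ``reference``.
    """

    name: str
    reference: str
    primer_fwd_span: tuple[int, int]
    primer_rev_span: tuple[int, int]
    cpg_positions: tuple[int, ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        ref = self.reference.upper()
        object.__setattr__(self, "reference", ref)
        if set(ref) - set("ACGT"):
            raise ValueError("reference must contain only A/C/G/T")
        fs, fe = self.primer_fwd_span
        rs, re_ = self.primer_rev_span
        if not (0 <= fs < fe <= rs < re_ <= len(ref)):
            raise ValueError("primer spans must be ordered and inside the reference")
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")
        pos = tuple(int(p) for p in self.cpg_positions)
        object.__setattr__(self, "cpg_positions", pos)
        if any(q <= p for p, q in zip(pos, pos[1:])):
            raise ValueError("cpg_positions must be strictly increasing")
        for p in pos:
            if not (fe <= p and p + 1 < rs):
                raise ValueError(f"CpG at {p} not between the primer spans")
            if ref[p : p + 2] != "CG":
                raise ValueError(f"position {p} is not the C of a CG dinucleotide")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    @property
    def inter_primer_span(self) -> tuple[int, int]:
        return (self.primer_fwd_span[1], self.primer_rev_span[0])


def convert_reference(design: AmpliconDesign) -> str:
    """Bisulfite-convert the reference in silico: every C becomes T.

    The CpG columns are recorded on the design itself
    (``design.cpg_positions``), so calls can be read back from original
    bases after aligning in the converted space.
    """
    return design.reference.replace("C", "T")


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # semi-global: overhangs on either sequence are free
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    return aligner


_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class ReadAlignment:
    """Placement of one read on the amplicon reference.

    ``read`` is the original (unconverted) read in the orientation that
    aligned; ``ref_to_read`` maps reference columns to read columns over
    the aligned blocks.
    """

    read: str
    ref_to_read: Mapping[int, int]
    score: float
    strand: str


def _align_oriented(read: str, converted_ref: str) -> tuple[float, dict[int, int]]:
    converted_read = read.replace("C", "T")
    alignments = _ALIGNER.align(converted_ref, converted_read)
    best = alignments[0]
    mapping: dict[int, int] = {}
    tgt_blocks, qry_blocks = best.aligned
    for (ts, te), (qs, _qe) in zip(tgt_blocks, qry_blocks):
        for off in range(te - ts):
            mapping[ts + off] = qs + off
    return float(best.score), mapping


def align_read(
    read: str, design: AmpliconDesign, min_score_frac: float = 0.5
) -> ReadAlignment:
    """Semi-global three-letter alignment of one read to the amplicon.

    Scoring is match +1 / mismatch -1 / gap -2 with free end gaps.  If the
    forward C->T pass scores below ``min_score_frac`` per read base, the
    reverse complement of the read is tried (reads sequenced from the
    opposite orientation); the better pass wins.  A read whose best pass
    stays below the floor is unalignable.
    """
    read = read.upper()
    if len(read) < MIN_READ_LENGTH:
        raise UnalignableReadError(
            f"read shorter than {MIN_READ_LENGTH} bases ({len(read)})"
        )
    converted_ref = convert_reference(design)
    floor = min_score_frac * len(read)
    score_fwd, map_fwd = _align_oriented(read, converted_ref)
    if score_fwd >= floor:
        return ReadAlignment(read, map_fwd, score_fwd, "+")
    rc = reverse_complement(read)
    score_rev, map_rev = _align_oriented(rc, converted_ref)
    if score_rev >= floor and score_rev > score_fwd:
        return ReadAlignment(rc, map_rev, score_rev, "-")
    raise UnalignableReadError(
        f"best alignment score {max(score_fwd, score_rev):.1f} below floor {floor:.1f}"
    )


@dataclass(frozen=True)
class ReadCall:
    """One row of a ReadCallMatrix: ordered CpG calls plus QC metrics."""

    calls: tuple[str, ...]
    conversion_rate: float
    identity: float
    cpg_coverage: float


def call_read(alignment: ReadAlignment, design: AmpliconDesign) -> ReadCall:
    """Call methylation at each design CpG from the original read bases.

    At a CpG reference column: C -> M, T -> U, anything else (or an
    alignment gap) -> missing.  The conversion rate is estimated from
    non-CpG reference-C columns (T means converted, C means unconverted,
    other bases are ignored); identity is the match fraction over aligned
    columns whose reference base is not C.
    """
    ref = design.reference
    read = alignment.read
    mapping = alignment.ref_to_read
    cpg_set = set(design.cpg_positions)

    calls = []
    for p in design.cpg_positions:
        j = mapping.get(p)
        base = read[j] if j is not None else None
        if base == "C":
            calls.append(M)
        elif base == "T":
            calls.append(U)
        else:
            calls.append(MISSING)

    converted = unconverted = 0
    matches = total = 0
    for rp, qp in mapping.items():
        ref_base = ref[rp]
        base = read[qp]
        if ref_base == "C":
            if rp not in cpg_set:
                if base == "T":
                    converted += 1
                elif base == "C":
                    unconverted += 1
        else:
            total += 1
            if base == ref_base:
                matches += 1

    n_conv = converted + unconverted
    conversion_rate = converted / n_conv if n_conv else 1.0
    identity = matches / total if total else 0.0
    coverage = sum(c != MISSING for c in calls) / len(calls) if calls else 0.0
    return ReadCall(tuple(calls), conversion_rate, identity, coverage)


@dataclass
class ReadCallMatrix:
    """Retained reads x design CpGs call matrix with per-read QC.

    ``calls`` holds ``M``/``U``/``.`` strings indexed by read id with one
    column per design CpG position; ``qc`` carries conversion_rate,
    identity and cpg_coverage per read.
    """

    calls: pd.DataFrame
    qc: pd.DataFrame

    @classmethod
    def from_calls(
        cls, read_ids: Sequence[str], rows: Sequence[ReadCall], design: AmpliconDesign
    ) -> "ReadCallMatrix":
        calls = pd.DataFrame(
            [list(r.calls) for r in rows],
            index=pd.Index(read_ids, name="read_id"),
            columns=list(design.cpg_positions),
        )
        qc = pd.DataFrame(
            {
                "conversion_rate": [r.conversion_rate for r in rows],
                "identity": [r.identity for r in rows],
                "cpg_coverage": [r.cpg_coverage for r in rows],
            },
            index=calls.index,
        )
        return cls(calls, qc)

    @property
    def n_reads(self) -> int:
        return len(self.calls)

    def methylated_fraction(self) -> pd.Series:
        """Per-read methylated fraction over non-missing calls (NaN if none)."""
        m = (self.calls == M).sum(axis=1)
        u = (self.calls == U).sum(axis=1)
        return m / (m + u)


def filter_reads(
    matrix: ReadCallMatrix,
    min_conversion: float = 0.95,
    min_identity: float = 0.9,
    min_cpg_coverage: float = 0.8,
) -> tuple[ReadCallMatrix, dict[str, int]]:
    """Drop reads failing any QC threshold.

    Returns the retained matrix and a per-reason rejection report (a read
    failing several criteria is counted under each).  Retained + the
    number of distinct rejected reads equals the input read count.
    """
    qc = matrix.qc
    fail_conv = qc["conversion_rate"] < min_conversion
    fail_ident = qc["identity"] < min_identity
    fail_cov = qc["cpg_coverage"] < min_cpg_coverage
    keep = ~(fail_conv | fail_ident | fail_cov)
    report = {
        "retained": int(keep.sum()),
        "incomplete_conversion": int(fail_conv.sum()),
        "low_identity": int(fail_ident.sum()),
        "low_cpg_coverage": int(fail_cov.sum()),
        "rejected": int((~keep).sum()),
    }
    for reason in ("incomplete_conversion", "low_identity", "low_cpg_coverage"):
        if report[reason]:
            log.info("filter_reads: %d reads rejected (%s)", report[reason], reason)
    if report["retained"] == 0:
        log.warning("filter_reads: all %d reads rejected", len(qc))
    return ReadCallMatrix(matrix.calls[keep], matrix.qc[keep]), report


def call_fastq(
    fastq: str | Path | Iterable,
    design: AmpliconDesign,
    min_score_frac: float = 0.5,
    min_conversion: float = 0.95,
    min_identity: float = 0.9,
    min_cpg_coverage: float = 0.8,
) -> tuple[ReadCallMatrix, dict[str, int]]:
    """Full FASTQ -> filtered ReadCallMatrix pipeline.

    ``fastq`` may be a path (``.gz`` accepted) or an iterable of Biopython
    SeqRecords.  The report covers alignment drops and QC rejections;
    retained + all rejection categories account for every input read.
    """
    if isinstance(fastq, (str, Path)):
        path = Path(fastq)
        if path.suffix == ".gz":
            import gzip

            with gzip.open(path, "rt") as fh:
                records = list(SeqIO.parse(fh, "fastq"))
        else:
            records = list(SeqIO.parse(str(path), "fastq"))
    else:
        records = list(fastq)

    ids, rows = [], []
    unalignable = 0
    for rec in records:
        try:
            aln = align_read(str(rec.seq), design, min_score_frac=min_score_frac)
        except UnalignableReadError as exc:
            unalignable += 1
            log.debug("read %s dropped: %s", rec.id, exc)
            continue
        ids.append(rec.id)
        rows.append(call_read(aln, design))

    matrix = ReadCallMatrix.from_calls(ids, rows, design)
    filtered, report = filter_reads(
        matrix,
        min_conversion=min_conversion,
        min_identity=min_identity,
        min_cpg_coverage=min_cpg_coverage,
    )
    report["input_reads"] = len(records)
    report["unalignable"] = unalignable
    return filtered, report


@dataclass(frozen=True)
class MethylationSummary:
    """Mean methylation per CpG and overall, in percent."""

    per_cpg: tuple[float, ...]
    overall: float
    n_reads: int


def summarize(matrix: ReadCallMatrix) -> MethylationSummary:
    """Mean methylation per CpG column and over all calls, in percent.

    Missing calls are excluded; a column with no informative call is
    reported as NaN (not available).
    """
    if matrix.n_reads == 0:
        raise ValueError("cannot summarize an empty read matrix")
    m = (matrix.calls == M).sum(axis=0).to_numpy(dtype=float)
    u = (matrix.calls == U).sum(axis=0).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_cpg = np.where(m + u > 0, 100.0 * m / (m + u), np.nan)
    total_m, total_u = m.sum(), u.sum()
    overall = 100.0 * total_m / (total_m + total_u) if total_m + total_u else np.nan
    return MethylationSummary(tuple(per_cpg), float(overall), matrix.n_reads)


def pattern_map(matrix: ReadCallMatrix, order: str = "mean_desc") -> pd.DataFrame:
    """Reorder reads for a pattern map; content is only permuted.

    ``order`` is ``"mean_desc"`` (per-read mean methylation descending,
    ties broken by the call pattern lexicographically) or ``"input"``.
    """
    if matrix.n_reads == 0:
        raise ValueError("cannot build a pattern map from an empty matrix")
    if order == "input":
        return matrix.calls.copy()
    if order != "mean_desc":
        raise ValueError(f"unknown order {order!r}")
    frac = matrix.methylated_fraction().fillna(-1.0)
    patterns = matrix.calls.apply("".join, axis=1)
    key = pd.DataFrame({"frac": -frac, "pattern": patterns})
    idx = key.sort_values(["frac", "pattern"], kind="mergesort").index
    return matrix.calls.loc[idx]


def plot_pattern_map(matrix: ReadCallMatrix, path: str | Path, order: str = "mean_desc"):
    """Render the pattern map as an image (methylated dark, missing grey)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    table = pattern_map(matrix, order=order)
    coded = table.replace({M: 2, U: 1, MISSING: 0}).to_numpy(dtype=float)
    fig, ax = plt.subplots(
        figsize=(max(2, 0.3 * table.shape[1]), max(2, 0.02 * table.shape[0]))
    )
    cmap = ListedColormap(["#bbbbbb", "#f3f3f3", "#1a1a55"])
    ax.imshow(coded, aspect="auto", interpolation="nearest", cmap=cmap, vmin=0, vmax=2)
    ax.set_xlabel("CpG")
    ax.set_ylabel("read")
    ax.set_xticks(range(table.shape[1]))
    ax.set_xticklabels([str(c) for c in table.columns], rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass(frozen=True)
class ReadClassProfile:
    """Fractions of reads that are fully demethylated / methylated / mixed."""

    fully_demethylated: float
    fully_methylated: float
    heterogeneous: float
    lo: float
    hi: float
    n_reads: int


def classify_reads(
    matrix: ReadCallMatrix, lo: float = 0.1, hi: float = 0.9
) -> ReadClassProfile:
    """Classify each read by its methylated fraction over non-missing calls.

    A fraction <= ``lo`` is fully demethylated, >= ``hi`` fully
    methylated, anything between is heterogeneous.  Reads with no
    informative call are excluded from the denominators.
    """
    if matrix.n_reads == 0:
        raise ValueError("cannot classify an empty read matrix")
    frac = matrix.methylated_fraction().dropna()
    n = len(frac)
    if n == 0:
        raise ValueError("no read carries an informative CpG call")
    demeth = float((frac <= lo).sum()) / n
    meth = float((frac >= hi).sum()) / n
    return ReadClassProfile(
        fully_demethylated=demeth,
        fully_methylated=meth,
        heterogeneous=1.0 - demeth - meth,
        lo=lo,
        hi=hi,
        n_reads=n,
    )
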