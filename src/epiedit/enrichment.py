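"""Enrichment procedures for CpG subsets and PCA-loading genes.

Two bespoke analyses around Fisher's exact test:

* region-set enrichment — genomic windows (transcription-factor binding
  sites, predicted sgRNA off-target regions) are flank-extended, the array
  probes falling inside them form a CpG subset, and the overlap of that
  subset with a focal set (e.g. the hypomethylated CpGs of a treatment)
  is tested against the probe background;
* gene enrichment of component loadings — the top-k probes by absolute
  loading on a principal component are annotated to genes, and each gene
  is tested for over-representation relative to its total probe count on
  the array, with Benjamini-Hochberg FDR across the tested genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .arraydm import PCAResult, ProbeManifest
from .stats import ContingencyTable, bh_fdr, fisher_exact_two_sided

log = logging.getLogger(__name__)

__all__ = [
    "GenomicWindowSet",
    "EnrichmentResult",
    "extend_windows",
    "select_top_offtargets",
    "probes_in_windows",
    "subset_enrichment",
    "topk_loadings",
    "gene_enrichment",
]


@dataclass
class GenomicWindowSet:
    """Named set of 0-based half-open genomic intervals.

    ``windows`` has columns ``chrom``, ``start``, ``end``; rows are kept
    sorted by (chrom, start, end).  Overlapping windows are allowed — probe
    membership is a set property, not a count.
    """

    name: str
    windows: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        w = self.windows
        required = {"chrom", "start", "end"}
        if missing := required - set(w.columns):
            raise ValueError(f"window table missing columns: {sorted(missing)}")
        if len(w):
            if (w["start"] < 0).any():
                raise ValueError("window starts must be >= 0")
            if (w["start"] >= w["end"]).any():
                raise ValueError("windows must satisfy start < end")
        self.windows = (
            w.sort_values(["chrom", "start", "end"], kind="mergesort")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.windows)


def extend_windows(regions: GenomicWindowSet, flank: int = 1000) -> GenomicWindowSet:
    """Extend every window by ``flank`` bases on both sides, clipped at 0.

    The window count is preserved; overlapping extensions are not merged.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    w = regions.windows.copy()
    w["start"] = (w["start"] - flank).clip(lower=0)
    w["end"] = w["end"] + flank
    return GenomicWindowSet(
        name=regions.name,
        windows=w,
        provenance=f"{regions.provenance} +/-{flank} bp".strip(),
    )


def select_top_offtargets(
    predictions: pd.DataFrame, top_n: int = 50
) -> GenomicWindowSet:
    """Keep the ``top_n`` highest-scoring predicted regions per sgRNA.

    ``predictions`` needs columns ``sgrna_id``, ``chrom``, ``start``,
    ``end``, ``score``.  Score ties at the cut are all kept (logged), so a
    guide may contribute slightly more than ``top_n`` windows; a guide
    with fewer predictions contributes all of them with a warning.
    """
    required = {"sgrna_id", "chrom", "start", "end", "score"}
    if missing := required - set(predictions.columns):
        raise ValueError(f"prediction table missing columns: {sorted(missing)}")
    kept = []
    for sgrna, grp in predictions.groupby("sgrna_id", sort=True):
        if len(grp) < top_n:
            log.warning(
                "select_top_offtargets: sgRNA %s has only %d predictions (< %d)",
                sgrna,
                len(grp),
                top_n,
            )
            kept.append(grp)
            continue
        cutoff = grp["score"].nlargest(top_n).iloc[-1]
        sel = grp[grp["score"] >= cutoff]
        if len(sel) > top_n:
            log.info(
                "select_top_offtargets: sgRNA %s keeps %d regions (score ties at %g)",
                sgrna,
                len(sel),
                cutoff,
            )
        kept.append(sel)
    windows = (
        pd.concat(kept, ignore_index=True)[["chrom", "start", "end"]]
        if kept
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    return GenomicWindowSet(
        name="offtargets",
        windows=windows,
        provenance=f"top {top_n} predicted off-target regions per sgRNA",
    )


def probes_in_windows(
    manifest: ProbeManifest, windows: GenomicWindowSet
) -> set[str]:
    """Probes whose position lies in any window (half-open test).

    A probe at position p is inside (chrom, start, end) iff
    ``start <= p < end``; overlapping windows count a probe once.
    """
    t = manifest.table
    hit: set[str] = set()
    manifest_chroms = set(t["chrom"].unique())
    for chrom, grp in windows.windows.groupby("chrom", sort=False):
        if chrom not in manifest_chroms:
            log.warning("probes_in_windows: chromosome %s absent from manifest", chrom)
            continue
        sub = t[t["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        sorted_pos = pos[order]
        ids = sub.index.to_numpy()[order]
        for start, end in grp[["start", "end"]].itertuples(index=False):
            i = np.searchsorted(sorted_pos, start, side="left")
            j = np.searchsorted(sorted_pos, end, side="left")
            hit.update(ids[i:j])
    return hit


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 counts plus Fisher test outcome for one subset-vs-focal test."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_two_sided: float
    direction: str
    q_fdr: float | None = None

    @property
    def table(self) -> ContingencyTable:
        return ContingencyTable(self.a, self.b, self.c, self.d)


def subset_enrichment(
    subset: Iterable[str], focal: Iterable[str], background: Iterable[str]
) -> EnrichmentResult:
    """Fisher test of a CpG subset against a focal CpG set.

    The table is a = |subset & focal|, b = |subset - focal|,
    c = |focal - subset|, d = the rest of the background.  Both sets must
    be contained in the background.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background must be non-empty")
    sub = set(subset)
    foc = set(focal)
    if not sub <= bg:
        raise ValueError("subset must be contained in the background")
    if not foc <= bg:
        raise ValueError("focal set must be contained in the background")
    a = len(sub & foc)
    b = len(sub) - a
    c = len(foc) - a
    d = len(bg) - a - b - c
    res = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
    return EnrichmentResult(
        a=a,
        b=b,
        c=c,
        d=d,
        odds_ratio=res.odds_ratio,
        p_two_sided=res.p_two_sided,
        direction=res.direction,
    )


def topk_loadings(
    pca: PCAResult, component: str, k: int = 5000, mode: str = "abs"
) -> list[str]:
    """Top-``k`` probes by loading magnitude on one component.

    ``mode`` selects the ranking key: ``"abs"`` (default, absolute
    loading), ``"positive"`` or ``"negative"`` (signed).  Ties are broken
    by probe id for determinism; ``k`` above the probe count returns all
    probes with a warning.
    """
    if component not in pca.loadings.columns:
        raise ValueError(f"unknown component {component!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    lo = pca.loadings[component]
    if mode == "abs":
        key = -lo.abs()
    elif mode == "positive":
        key = -lo
    elif mode == "negative":
        key = lo
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if k > len(lo):
        log.warning("topk_loadings: k=%d exceeds %d probes; returning all", k, len(lo))
        k = len(lo)
    ranked = pd.DataFrame({"key": key, "probe": lo.index}).sort_values(
        ["key", "probe"], kind="mergesort"
    )
    return ranked["probe"].head(k).tolist()


def gene_enrichment(
    cpgs: Sequence[str], manifest: ProbeManifest
) -> pd.DataFrame:
    """Per-gene Fisher enrichment of a CpG list, FDR-corrected.

    For each gene with at least one hit among ``cpgs``: a = hits of the
    gene in the list, b = rest of the list, c = remaining probes of the
    gene on the array, d = everything else, correcting each gene for its
    total probe count on the array.  Returns a table with columns gene,
    hits, gene_total, odds_ratio, p_two_sided, q_fdr ranked by q, then p,
    then gene label.  Unannotated probes stay in the background but never
    form a tested gene.
    """
    cpg_list = list(dict.fromkeys(cpgs))  # dedupe, keep order
    unknown = [c for c in cpg_list if c not in manifest.probe_ids]
    if unknown:
        raise ValueError(f"CpGs absent from the manifest: {unknown[:5]}")
    n_total = len(manifest)
    n_focal = len(cpg_list)
    columns = ["gene", "hits", "gene_total", "odds_ratio", "p_two_sided", "q_fdr"]
    if n_focal == 0:
        return pd.DataFrame(columns=columns)

    totals = manifest.gene_totals()
    hits_series = (
        manifest.table.loc[cpg_list, "genes"].explode().dropna().value_counts()
    )
    rows = []
    for gene, hits in hits_series.sort_index().items():
        gene_total = int(totals[gene])
        if gene_total < hits:
            raise ValueError(
                f"annotation inconsistency: gene {gene!r} has {hits} hits but "
                f"{gene_total} probes in the manifest"
            )
        a = int(hits)
        b = n_focal - a
        c = gene_total - a
        d = n_total - a - b - c
        res = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
        rows.append(
            {
                "gene": gene,
                "hits": a,
                "gene_total": gene_total,
                "odds_ratio": res.odds_ratio,
                "p_two_sided": res.p_two_sided,
            }
        )
    out = pd.DataFrame(rows)
    out["q_fdr"] = bh_fdr(out["p_two_sided"].to_numpy())
    out = out.sort_values(
        ["q_fdr", "p_two_sided", "gene"], kind="mergesort"
    ).reset_index(drop=True)
    return out[columns]
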