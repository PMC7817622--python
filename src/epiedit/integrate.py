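"""Intersection of hypomethylation-associated genes with expression changes.

The final pipeline step asks which genes flagged by the methylation
analyses (e.g. genes carrying treatment-hypomethylated CpGs) are also
differentially expressed.  Differential-expression gene sets may come
from any external engine as plain gene lists; a simple Welch-test
substitute over log-scale values is provided for synthetic data and quick
looks, not as a replacement for a count-based model on real data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .arraydm import ProbeManifest
from .stats import bh_fdr

log = logging.getLogger(__name__)

__all__ = ["GeneSet", "simple_de", "annotate_and_intersect"]


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene labels with free-text provenance."""

    name: str
    genes: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if any(not g for g in self.genes):
            raise ValueError("gene labels must be non-empty")
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


def simple_de(
    expr: pd.DataFrame,
    groups: Mapping[str, str],
    g1: str,
    g2: str,
    lfc_min: float = 1.0,
    q_max: float = 0.05,
) -> GeneSet:
    """Welch-test differential expression on log-scale values.

    Per gene: two-sample Welch t-test between the groups plus BH-FDR; a
    gene is selected iff q <= ``q_max`` and |mean log2 difference| >=
    ``lfc_min``.  Genes constant across all samples are excluded
    (logged).  Expression values are assumed already on log2 scale.
    """
    cols1 = [s for s in expr.columns if groups.get(s) == g1]
    cols2 = [s for s in expr.columns if groups.get(s) == g2]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("both groups need at least 2 replicates")
    x1 = expr[cols1].to_numpy(dtype=float)
    x2 = expr[cols2].to_numpy(dtype=float)
    constant = np.concatenate([x1, x2], axis=1).std(axis=1) == 0
    if constant.any():
        log.info("simple_de: %d constant genes excluded", int(constant.sum()))
    keep = ~constant
    tstat, pvals = sps.ttest_ind(x1[keep], x2[keep], axis=1, equal_var=False)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    q = bh_fdr(pvals)
    lfc = x2[keep].mean(axis=1) - x1[keep].mean(axis=1)
    genes = expr.index[keep]
    selected = genes[(q <= q_max) & (np.abs(lfc) >= lfc_min)]
    return GeneSet(
        name=f"{g2}_vs_{g1}",
        genes=frozenset(selected),
        provenance=f"welch t-test, q<={q_max}, |log2fc|>={lfc_min}",
    )


def annotate_and_intersect(
    hypo_cpgs: Sequence[str],
    manifest: ProbeManifest,
    de_sets: Sequence[GeneSet],
    normalize_case: bool = False,
) -> pd.DataFrame:
    """Genes of a CpG set, sequentially intersected with DE gene sets.

    The CpG set is annotated to genes through the manifest, then
    intersected with each DE set in turn.  Returns one row per step
    (``step`` 0 is the annotation itself) with the set name, the running
    intersection size and the sorted member list.  Matching is
    case-sensitive exact unless ``normalize_case`` upper-cases all labels.
    """
    current = manifest.genes_of(hypo_cpgs)
    norm = (lambda s: s.upper()) if normalize_case else (lambda s: s)
    current = {norm(g) for g in current}
    rows = [
        {
            "step": 0,
            "set_name": "hypo_cpg_genes",
            "size": len(current),
            "genes": ";".join(sorted(current)),
        }
    ]
    for i, gs in enumerate(de_sets, start=1):
        current = current & {norm(g) for g in gs.genes}
        rows.append(
            {
                "step": i,
                "set_name": gs.name,
                "size": len(current),
                "genes": ";".join(sorted(current)),
            }
        )
    return pd.DataFrame(rows, columns=["step", "set_name", "size", "genes"])
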