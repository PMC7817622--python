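"""Beta-value matrix analytics for EPIC-like methylation arrays.

Consumes a normalized beta matrix (probes x samples, values in [0, 1])
with a probe manifest (genomic position and gene annotation per probe)
and a sample-to-group design.  Provides group-mean differential
methylation with a |delta| threshold (the hypo/hyper CpG sets), locus-level
hierarchical clustering of samples, and a centered, unscaled PCA whose
loadings feed the gene-enrichment stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist

log = logging.getLogger(__name__)

__all__ = [
    "ProbeManifest",
    "BetaMatrix",
    "DiffMethResult",
    "PCAResult",
    "load_beta",
    "compare_groups",
    "locus_cluster",
    "pca",
]


@dataclass
class ProbeManifest:
    """Array probe annotation: probe id, genomic position, gene labels.

    ``table`` has index ``probe_id`` and columns ``chrom`` (str),
    ``pos`` (0-based int) and ``genes`` (tuple of gene labels, possibly
    empty).  Probe ids are unique; positions are non-negative.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"chrom", "pos", "genes"}
        if missing := required - set(t.columns):
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if not t.index.is_unique:
            dupes = t.index[t.index.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate probe ids in manifest: {dupes}")
        if (t["pos"] < 0).any():
            raise ValueError("manifest positions must be non-negative")
        self.table = t.assign(genes=[tuple(g) for g in t["genes"]])

    def __len__(self) -> int:
        return len(self.table)

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def gene_totals(self) -> pd.Series:
        """Number of manifest probes annotated to each gene."""
        exploded = self.table["genes"].explode().dropna()
        return exploded.value_counts().sort_index()

    def genes_of(self, probes: Sequence[str]) -> set[str]:
        """Union of gene labels annotated to the given probes."""
        out: set[str] = set()
        for g in self.table.loc[list(probes), "genes"]:
            out.update(g)
        return out


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions with a group design.

    ``values`` holds beta values in [0, 1] (NaN marks missing entries);
    ``groups`` maps every sample (column) to exactly one group label.
    """

    values: pd.DataFrame
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        v = self.values
        bad = (v < 0) | (v > 1)
        if bad.any().any():
            probe = v.index[bad.any(axis=1)][0]
            sample = v.columns[bad.any(axis=0)][0]
            raise ValueError(
                f"beta value outside [0, 1] (e.g. probe {probe!r}, sample {sample!r})"
            )
        unassigned = [s for s in v.columns if s not in self.groups]
        if unassigned:
            raise ValueError(f"samples without a group assignment: {unassigned}")
        self.groups = dict(self.groups)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, group: str) -> list[str]:
        out = [s for s in self.samples if self.groups[s] == group]
        if not out:
            raise ValueError(f"unknown or empty group {group!r}")
        return out


def load_beta(
    beta_path: str | Path,
    manifest_path: str | Path,
    groups_path: str | Path,
) -> tuple[BetaMatrix, ProbeManifest]:
    """Read beta matrix, manifest and group design from tab-separated files.

    Probes absent from the manifest are rejected with a report; values
    outside [0, 1], duplicate probe ids and unassigned samples raise.
    Lines starting with ``#`` are metadata and skipped.
    """
    from . import io as eio

    beta = eio.read_tsv(beta_path, index_col=0)
    manifest = eio.read_manifest(manifest_path)
    groups = eio.read_groups(groups_path)
    if not beta.index.is_unique:
        dupes = beta.index[beta.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate probe ids in beta matrix: {dupes}")
    known = beta.index.isin(manifest.probe_ids)
    if (~known).any():
        log.warning(
            "load_beta: %d probes absent from the manifest were dropped",
            int((~known).sum()),
        )
    bm = BetaMatrix(beta[known].astype(float), groups)
    return bm, manifest


@dataclass(frozen=True)
class DiffMethResult:
    """Group-mean differential methylation at a |delta| threshold.

    ``delta = mean(reference) - mean(treatment)`` per probe, so probes
    hypomethylated in the treatment group have delta >= +threshold
    (``hypo``) and hypermethylated ones delta <= -threshold (``hyper``).
    """

    table: pd.DataFrame  # columns: mean_ref, mean_treat, delta
    hypo: pd.Index
    hyper: pd.Index
    pearson_r: float
    threshold: float
    reference: str
    treatment: str
    n_dropped: int


def compare_groups(
    bm: BetaMatrix, reference: str, treatment: str, threshold: float = 0.2
) -> DiffMethResult:
    """Delta-threshold differential methylation between two groups.

    Probes with any missing value in either group are excluded (logged).
    Returns per-probe group means, the hypo/hyper probe sets at the
    threshold, and the Pearson correlation of the two mean vectors.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    ref_cols = bm.samples_of(reference)
    trt_cols = bm.samples_of(treatment)
    sub = bm.values[ref_cols + trt_cols]
    complete = sub.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("compare_groups: %d probes dropped for missing values", n_dropped)
    sub = sub[complete]
    mean_ref = sub[ref_cols].mean(axis=1)
    mean_treat = sub[trt_cols].mean(axis=1)
    delta = mean_ref - mean_treat
    table = pd.DataFrame(
        {"mean_ref": mean_ref, "mean_treat": mean_treat, "delta": delta}
    )
    hypo = table.index[delta >= threshold]
    hyper = table.index[delta <= -threshold]
    if len(table) >= 2 and mean_ref.std() > 0 and mean_treat.std() > 0:
        r = float(np.corrcoef(mean_ref, mean_treat)[0, 1])
    else:
        r = np.nan
    return DiffMethResult(
        table=table,
        hypo=hypo,
        hyper=hyper,
        pearson_r=r,
        threshold=threshold,
        reference=reference,
        treatment=treatment,
        n_dropped=n_dropped,
    )


def locus_cluster(
    bm: BetaMatrix,
    manifest: ProbeManifest,
    chrom: str,
    start: int,
    end: int,
    method: str = "average",
) -> tuple[np.ndarray, list[str]]:
    """Hierarchical clustering of samples on one locus.

    Samples are clustered on Euclidean distances between their beta
    vectors over the complete-case probes inside [start, end) on
    ``chrom``.  Returns the scipy linkage matrix and the sample order of
    its leaves.
    """
    t = manifest.table
    in_region = (t["chrom"] == chrom) & (t["pos"] >= start) & (t["pos"] < end)
    probes = t.index[in_region]
    probes = probes[probes.isin(bm.values.index)]
    if len(probes) == 0:
        raise ValueError(f"no probes in {chrom}:{start}-{end}")
    if len(bm.samples) < 2:
        raise ValueError("clustering needs at least 2 samples")
    block = bm.values.loc[probes].dropna(axis=0)
    if block.empty:
        raise ValueError("no complete-case probes in the region")
    x = block.T.to_numpy(dtype=float)  # samples x probes
    z = scipy_linkage(pdist(x, metric="euclidean"), method=method)
    from scipy.cluster.hierarchy import leaves_list

    order = [bm.samples[i] for i in leaves_list(z)]
    return z, order


@dataclass(frozen=True)
class PCAResult:
    """Centered, unscaled PCA of samples over probe features.

    ``scores`` is samples x components, ``loadings`` probes x components
    (unit-norm columns), ``variance_ratio`` sums to 1 over all components.
    The sign of each component is fixed by making its largest-magnitude
    loading positive.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_ratio: np.ndarray
    n_dropped: int

    @property
    def components(self) -> list[str]:
        return list(self.scores.columns)


def pca(bm: BetaMatrix) -> PCAResult:
    """Principal component analysis of the beta matrix.

    Samples are observations, probes features; features are centered but
    not scaled and the decomposition runs through SVD.  Probes with any
    missing value are dropped (logged).
    """
    if len(bm.samples) < 2:
        raise ValueError("PCA needs at least 2 samples")
    complete = bm.values.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("pca: %d probes dropped for missing values", n_dropped)
    v = bm.values[complete]
    if len(v) < 2:
        raise ValueError("PCA needs at least 2 complete-case probes")
    x = v.T.to_numpy(dtype=float)  # samples x probes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # drop null components (centering makes the last singular value ~0;
    # its loading vector is arbitrary null-space noise)
    if s[0] > 0:
        keep = s > s[0] * 1e-9
        u, s, vt = u[:, keep], s[keep], vt[keep]
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    names = [f"PC{k + 1}" for k in range(len(s))]
    scores = pd.DataFrame(u * s, index=v.columns, columns=names)
    loadings = pd.DataFrame(vt.T, index=v.index, columns=names)
    total = (s**2).sum()
    ratio = s**2 / total if total > 0 else np.zeros_like(s)
    return PCAResult(
        scores=scores, loadings=loadings, variance_ratio=ratio, n_dropped=n_dropped
    )
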