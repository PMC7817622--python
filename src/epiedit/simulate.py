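"""Synthetic data generators with planted ground truth.

Every input the analysis stages consume can be generated here with a
known truth table and a mandatory seed: bisulfite amplicon reads drawn
from a mixture of per-molecule methylation patterns, an EPIC-like probe
manifest with gene annotation, replicate beta matrices with planted
hypo-/hyper-methylated probe sets, genomic region sets with a controlled
overlap odds, and log-scale expression tables with planted differential
genes.  Identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .amplicon import AmpliconDesign
from .arraydm import BetaMatrix, ProbeManifest
from .enrichment import GenomicWindowSet

__all__ = [
    "ReadSimConfig",
    "PlantedSet",
    "ArraySimConfig",
    "RegionSimResult",
    "make_tsdr_fixture",
    "simulate_bisulfite_reads",
    "simulate_probe_manifest",
    "simulate_beta_matrix",
    "simulate_region_sets",
    "simulate_expression",
    "EPIC_PROBE_COUNT",
]

#: probe count of the full-scale EPIC-like manifest profile
EPIC_PROBE_COUNT = 865_859

# Bisulfite-PCR primer pair of the human TSDR amplicon; both annealing
# sites are cytosine-free, so they read identically before and after
# conversion.
TSDR_PRIMER_FWD = "TTGTTTGGGGGTAGAGGATTTAG"
TSDR_PRIMER_REV = "CCTAATATTATACTATTTAAAAACCCC"

#: repeated inter-primer unit: one non-CpG C (conversion control) and one CpG
_TSDR_BLOCK = "TTACATTACG"
_TSDR_N_CPGS = 15


def make_tsdr_fixture() -> AmpliconDesign:
    """Synthetic TSDR-like amplicon: 15 CpGs between the bundled primers.

    The reference is an engineered stand-in for the genomic TSDR, not the
    hg19 sequence: the primer annealing sites are bisulfite-compatible
    with the standard human TSDR bisulfite primer pair and the
    inter-primer region
    carries exactly 15 CG dinucleotides plus one non-CpG cytosine per CpG
    for conversion-rate QC.
    """
    rev_site = str(Seq(TSDR_PRIMER_REV).reverse_complement())
    reference = TSDR_PRIMER_FWD + _TSDR_BLOCK * _TSDR_N_CPGS + rev_site
    fwd_len = len(TSDR_PRIMER_FWD)
    cpg_positions = tuple(
        fwd_len + i * len(_TSDR_BLOCK) + _TSDR_BLOCK.index("CG")
        for i in range(_TSDR_N_CPGS)
    )
    return AmpliconDesign(
        name="TSDR_synthetic",
        reference=reference,
        primer_fwd_span=(0, fwd_len),
        primer_rev_span=(len(reference) - len(rev_site), len(reference)),
        cpg_positions=cpg_positions,
    )


@dataclass(kw_only=True)
class ReadSimConfig:
    """Mixture model for bisulfite amplicon reads.

    ``components`` is a list of (weight, per-CpG methylation
    probabilities); a scalar probability is broadcast over all CpGs.
    ``conversion_failure_rate`` is the probability that an unmethylated C
    survives conversion and is read as C; ``sequencing_error_rate`` is the
    per-base uniform substitution probability.
    """

    n_reads: int
    components: Sequence[tuple[float, float | Sequence[float]]]
    conversion_failure_rate: float = 0.0
    sequencing_error_rate: float = 0.0
    seed: int

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        weights = [w for w, _ in self.components]
        if not weights or abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if any(w < 0 for w in weights):
            raise ValueError("component weights must be >= 0")
        for rate in (self.conversion_failure_rate, self.sequencing_error_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _component_probs(cfg: ReadSimConfig, n_cpgs: int) -> np.ndarray:
    probs = []
    for _, p in cfg.components:
        row = np.full(n_cpgs, float(p)) if np.isscalar(p) else np.asarray(p, float)
        if row.shape != (n_cpgs,):
            raise ValueError(f"per-CpG probabilities must have length {n_cpgs}")
        if ((row < 0) | (row > 1)).any():
            raise ValueError("methylation probabilities must lie in [0, 1]")
        probs.append(row)
    return np.array(probs)


def simulate_bisulfite_reads(
    design: AmpliconDesign, cfg: ReadSimConfig
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Draw reads from the mixture and bisulfite-convert them in silico.

    Per read: a component is drawn by weight, per-CpG methylation states
    are Bernoulli draws, unmethylated Cs (CpG and non-CpG alike) convert
    to T except with probability ``conversion_failure_rate``, methylated
    CpG-Cs stay C, then uniform substitution errors are applied.  Returns
    Phred+33 FASTQ records (quality 'I') and a truth table with each
    read's component and latent methylation states.
    """
    rng = np.random.default_rng(cfg.seed)
    ref = np.frombuffer(design.reference.encode(), dtype="S1")
    n = cfg.n_reads
    n_cpgs = design.n_cpgs
    cpg_idx = np.array(design.cpg_positions, dtype=int)
    non_cpg_c = np.array(
        [i for i, b in enumerate(design.reference) if b == "C" and i not in set(design.cpg_positions)],
        dtype=int,
    )
    probs = _component_probs(cfg, n_cpgs)
    weights = np.array([w for w, _ in cfg.components], dtype=float)

    components = rng.choice(len(weights), size=n, p=weights)
    meth = rng.random((n, n_cpgs)) < probs[components]

    reads = np.tile(ref, (n, 1))
    # unmethylated CpG cytosines convert unless conversion fails
    fail_cpg = rng.random((n, n_cpgs)) < cfg.conversion_failure_rate
    to_t = ~meth & ~fail_cpg
    for j, pos in enumerate(cpg_idx):
        reads[to_t[:, j], pos] = b"T"
    # non-CpG cytosines are unmethylated by construction
    if len(non_cpg_c):
        fail = rng.random((n, len(non_cpg_c))) < cfg.conversion_failure_rate
        for j, pos in enumerate(non_cpg_c):
            reads[~fail[:, j], pos] = b"T"
    # uniform substitution errors
    if cfg.sequencing_error_rate > 0:
        err = rng.random(reads.shape) < cfg.sequencing_error_rate
        n_err = int(err.sum())
        if n_err:
            shift = rng.integers(1, 4, size=n_err)
            codes = np.searchsorted(_BASES, reads[err])
            reads[err] = _BASES[(codes + shift) % 4]

    qual = [40] * len(ref)
    records = []
    ids = [f"read_{i:06d}" for i in range(n)]
    for i in range(n):
        rec = SeqRecord(
            Seq(reads[i].tobytes().decode()),
            id=ids[i],
            description=f"component={components[i]}",
        )
        rec.letter_annotations["phred_quality"] = qual
        records.append(rec)
    truth = pd.DataFrame(
        {
            "read_id": ids,
            "component": components,
            "meth_states": ["".join("1" if s else "0" for s in row) for row in meth],
        }
    )
    return records, truth


@dataclass(frozen=True)
class PlantedSet:
    """A probe set carrying a signed beta shift in one group."""

    probes: tuple[int, ...]  # integer indices into the manifest
    delta: float
    group: str


@dataclass(kw_only=True)
class ArraySimConfig:
    """Configuration of the EPIC-like manifest and beta-matrix simulators.

    The default ``n_probes`` matches the probe count of the full-scale
    array profile.  ``baseline_mixture`` is (weight_low, a_low, b_low,
    a_high, b_high) for the bimodal Beta mixture of per-probe baseline
    methylation; ``planted_sets`` add a signed delta to the designated
    group's mean; replicate noise is additive Gaussian clamped to [0, 1].
    """

    n_probes: int = EPIC_PROBE_COUNT
    n_chromosomes: int = 22
    group_design: Mapping[str, int] = field(
        default_factory=lambda: {"mCherry_neg": 3, "TET1": 3}
    )
    baseline_mixture: tuple[float, float, float, float, float] = (
        0.5,
        2.0,
        10.0,
        10.0,
        2.0,
    )
    planted_sets: tuple[PlantedSet, ...] = ()
    replicate_noise_sd: float = 0.03
    missing_rate: float = 0.0
    mean_probes_per_gene: float = 20.0
    annotated_fraction: float = 0.85
    multi_gene_rate: float = 0.01
    seed: int

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if any(r < 1 for r in self.group_design.values()):
            raise ValueError("replicate counts must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.replicate_noise_sd < 0:
            raise ValueError("replicate_noise_sd must be >= 0")


def _run_lengths(rng, total: int, mean_gene: float, mean_gap: float):
    """Alternating annotated/unannotated run lengths covering ``total`` probes."""
    runs = []
    covered = 0
    annotated = True
    while covered < total:
        if annotated:
            size = 1 + int(rng.poisson(max(mean_gene - 1, 0)))
        else:
            size = int(rng.poisson(mean_gap))
        size = min(size, total - covered)
        if size > 0:
            runs.append((annotated, size))
            covered += size
        annotated = not annotated
    return runs


def simulate_probe_manifest(cfg: ArraySimConfig) -> ProbeManifest:
    """Probe ids, sorted unique positions and gene runs on synthetic chromosomes.

    Probes are spread over ``n_chromosomes`` chromosomes with random
    spacing; genes occupy consecutive probe runs (sizes ~ 1 + Poisson)
    separated by unannotated runs sized to hit ``annotated_fraction``;
    a small fraction of annotated probes additionally carries the
    neighbouring gene's label.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_probes // cfg.n_chromosomes)
    per_chrom[: cfg.n_probes % cfg.n_chromosomes] += 1
    af = cfg.annotated_fraction
    mean_gap = cfg.mean_probes_per_gene * (1 / af - 1) if af > 0 else np.inf

    chroms, positions, genes = [], [], []
    gene_counter = 0
    for ci, n_c in enumerate(per_chrom):
        if n_c == 0:
            continue
        chrom = f"chr{ci + 1}"
        gaps = rng.integers(20, 2000, size=n_c)
        pos = np.cumsum(gaps)
        chroms.extend([chrom] * int(n_c))
        positions.extend(pos.tolist())
        if af <= 0:
            genes.extend([()] * int(n_c))
            continue
        prev_gene = None
        for annotated, size in _run_lengths(
            rng, int(n_c), cfg.mean_probes_per_gene, mean_gap
        ):
            if annotated:
                gene_counter += 1
                label = f"G{gene_counter:06d}"
                for _ in range(size):
                    if (
                        prev_gene is not None
                        and cfg.multi_gene_rate > 0
                        and rng.random() < cfg.multi_gene_rate
                    ):
                        genes.append((label, prev_gene))
                    else:
                        genes.append((label,))
                prev_gene = label
            else:
                genes.extend([()] * size)
    ids = [f"cg{i:08d}" for i in range(cfg.n_probes)]
    table = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "genes": genes},
        index=pd.Index(ids, name="probe_id"),
    )
    return ProbeManifest(table)


def simulate_beta_matrix(
    manifest: ProbeManifest, cfg: ArraySimConfig
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Replicate beta values per group with planted shifts.

    Per probe the baseline mean is drawn once from the bimodal Beta
    mixture; a planted set adds its delta to the designated group's mean;
    replicates add Gaussian noise clamped to [0, 1]; missing entries are
    injected at ``missing_rate``.  Baselines of planted probes are pulled
    into the range where the full shift is expressible (a demethylation
    target must be methylated to begin with), so the planted delta is
    never silently truncated.  The truth table lists every planted
    (probe, group, delta).
    """
    rng = np.random.default_rng([cfg.seed, 1])
    n = len(manifest)
    for ps in cfg.planted_sets:
        bad = [i for i in ps.probes if not 0 <= i < n]
        if bad:
            raise ValueError(f"planted probe indices out of range: {bad[:5]}")
        if abs(ps.delta) > 0.96:
            raise ValueError("planted |delta| must be <= 0.96 to stay clampable")

    w_low, a_low, b_low, a_high, b_high = cfg.baseline_mixture
    low = rng.random(n) < w_low
    baseline = np.where(
        low, rng.beta(a_low, b_low, size=n), rng.beta(a_high, b_high, size=n)
    )
    margin = 0.02
    for ps in cfg.planted_sets:
        idx = np.array(ps.probes, dtype=int)
        lo = max(margin, margin - ps.delta)
        hi = min(1 - margin, 1 - margin - ps.delta)
        baseline[idx] = np.clip(baseline[idx], lo, hi)

    group_means = {g: baseline.copy() for g in cfg.group_design}
    truth_rows = []
    probe_ids = manifest.probe_ids
    for ps in cfg.planted_sets:
        if ps.group not in group_means:
            raise ValueError(f"planted set targets unknown group {ps.group!r}")
        idx = np.array(ps.probes, dtype=int)
        group_means[ps.group][idx] = np.clip(
            group_means[ps.group][idx] + ps.delta, 0.0, 1.0
        )
        truth_rows.extend(
            {"probe_id": probe_ids[i], "group": ps.group, "delta": ps.delta}
            for i in idx
        )

    columns = {}
    for group, n_rep in cfg.group_design.items():
        mean = group_means[group]
        for r in range(n_rep):
            vals = mean + rng.normal(0.0, cfg.replicate_noise_sd, size=n)
            vals = np.clip(vals, 0.0, 1.0)
            if cfg.missing_rate > 0:
                vals = np.where(rng.random(n) < cfg.missing_rate, np.nan, vals)
            columns[f"{group}_{r + 1}"] = vals
    values = pd.DataFrame(columns, index=probe_ids)
    groups = {
        f"{group}_{r + 1}": group
        for group, n_rep in cfg.group_design.items()
        for r in range(n_rep)
    }
    truth = pd.DataFrame(truth_rows, columns=["probe_id", "group", "delta"])
    return BetaMatrix(values, groups), truth


@dataclass(frozen=True)
class RegionSimResult:
    """Simulated region set, its scored off-target-style listing and truth."""

    windows: GenomicWindowSet
    scored: pd.DataFrame  # sgrna_id, chrom, start, end, score
    anchor_probes: tuple[str, ...]


def simulate_region_sets(
    manifest: ProbeManifest,
    enriched_in: Sequence[str],
    odds: float,
    n_regions: int,
    seed: int,
    window_size: int = 200,
    n_sgrnas: int = 12,
) -> RegionSimResult:
    """Windows anchored on probes with a controlled membership odds.

    Each region is centred on a probe drawn without replacement with
    weight ``odds`` for probes in ``enriched_in`` and 1 otherwise, so the
    odds of a window covering an enriched probe versus any other equals
    ``odds`` in expectation.  A scored listing (random guide ids and
    scores) accompanies the windows for top-N selection tests.
    """
    if odds <= 0:
        raise ValueError("odds must be > 0")
    if n_regions < 0:
        raise ValueError("n_regions must be >= 0")
    rng = np.random.default_rng(seed)
    t = manifest.table
    empty_cols = ["sgrna_id", "chrom", "start", "end", "score"]
    if n_regions == 0:
        windows = GenomicWindowSet(
            "simulated_regions",
            pd.DataFrame(columns=["chrom", "start", "end"]),
            provenance="simulated (empty)",
        )
        return RegionSimResult(windows, pd.DataFrame(columns=empty_cols), ())
    if n_regions > len(t):
        raise ValueError("n_regions exceeds the number of probes")
    enriched = t.index.isin(set(enriched_in))
    weights = np.where(enriched, float(odds), 1.0)
    weights = weights / weights.sum()
    anchors = rng.choice(len(t), size=n_regions, replace=False, p=weights)
    pos = t["pos"].to_numpy()[anchors]
    chrom = t["chrom"].to_numpy()[anchors]
    half = window_size // 2
    start = np.maximum(0, pos - half)
    end = pos + half + 1
    scored = pd.DataFrame(
        {
            "sgrna_id": [f"sgRNA{(i % n_sgrnas) + 1}" for i in range(n_regions)],
            "chrom": chrom,
            "start": start,
            "end": end,
            "score": np.round(rng.uniform(50, 100, size=n_regions), 3),
        }
    )
    windows = GenomicWindowSet(
        "simulated_regions",
        scored[["chrom", "start", "end"]].copy(),
        provenance=f"simulated, odds={odds}, seed={seed}",
    )
    anchor_ids = tuple(t.index[anchors])
    return RegionSimResult(windows, scored, anchor_ids)


def simulate_expression(
    genes: Sequence[str],
    de_genes: Sequence[str],
    effect_log2fc: float,
    n_per_group: int,
    seed: int,
    noise_sd: float = 0.5,
    baseline_mean: float = 5.0,
    baseline_sd: float = 2.0,
    group_names: tuple[str, str] = ("control", "treatment"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log2-scale expression with an additive group effect on ``de_genes``.

    Returns a genes x samples table (columns ``<group>_<i>``) and a truth
    table of the planted genes with their log2 fold change.
    """
    genes = list(genes)
    de = set(de_genes)
    if not de <= set(genes):
        raise ValueError("de_genes must be a subset of genes")
    rng = np.random.default_rng(seed)
    baseline = rng.normal(baseline_mean, baseline_sd, size=len(genes))
    effect = np.array([effect_log2fc if g in de else 0.0 for g in genes])
    g1, g2 = group_names
    cols = {}
    for i in range(n_per_group):
        cols[f"{g1}_{i + 1}"] = baseline + rng.normal(0, noise_sd, len(genes))
    for i in range(n_per_group):
        cols[f"{g2}_{i + 1}"] = baseline + effect + rng.normal(0, noise_sd, len(genes))
    expr = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    truth = pd.DataFrame(
        {"gene": sorted(de), "log2fc": effect_log2fc}, columns=["gene", "log2fc"]
    )
    return expr, truth
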