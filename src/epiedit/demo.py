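"""One-shot end-to-end run of every analysis stage on synthetic data.

Emulates the structure of a targeted-demethylation experiment: a treated
group (``TET1``) whose methylome partially shifts towards a positive
control (``Treg``) at the probes of a small set of signature genes, plus
untreated controls.  All stages run on generated data with known planted
truth, so the summary can report recovery of the planted hypomethylated
set and of the signature genes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .amplicon import call_fastq, classify_reads, pattern_map, summarize
from .arraydm import compare_groups, locus_cluster, pca
from .enrichment import (
    extend_windows,
    gene_enrichment,
    probes_in_windows,
    select_top_offtargets,
    subset_enrichment,
    topk_loadings,
)
from .integrate import annotate_and_intersect, simple_de
from .simulate import (
    ArraySimConfig,
    PlantedSet,
    ReadSimConfig,
    make_tsdr_fixture,
    simulate_beta_matrix,
    simulate_bisulfite_reads,
    simulate_expression,
    simulate_probe_manifest,
    simulate_region_sets,
)

__all__ = ["run_demo", "DEMO_DEFAULTS"]

DEMO_DEFAULTS: dict[str, object] = {
    "n_reads": 2000,
    "read_unmeth_weight": 0.7,
    "conversion_failure_rate": 0.005,
    "sequencing_error_rate": 0.002,
    "n_probes": 20000,
    "n_signature_genes": 10,
    "planted_delta": 0.5,
    "tet1_edit_fraction": 0.6,
    "delta_threshold": 0.2,
    "flank": 1000,
    "top_k_loadings": 200,
    "top_n_offtargets": 50,
    "n_offtarget_predictions": 600,
    "min_conversion": 0.95,
    "min_identity": 0.9,
    "min_cpg_coverage": 0.8,
    "de_effect_log2fc": 4.0,
    "de_noise_sd": 0.3,
    "n_expr_per_group": 5,
}


def _signature_probe_indices(
    manifest, n_genes: int, rng: np.random.Generator
) -> tuple[list[str], np.ndarray]:
    """Pick signature genes with >= 5 probes and return their probe indices."""
    totals = manifest.gene_totals()
    eligible = totals[totals >= 5].index.to_numpy()
    genes = sorted(rng.choice(eligible, size=n_genes, replace=False).tolist())
    mask = manifest.table["genes"].map(lambda gs: any(g in genes for g in gs))
    idx = np.flatnonzero(mask.to_numpy())
    return genes, idx


def run_demo(seed: int, outdir: str | Path, **overrides) -> dict[str, object]:
    """Generate inputs, run every stage and write all result tables.

    Deterministic for a fixed seed.  Returns the summary dictionary that
    is also written to ``summary.tsv``; the resolved configuration lands
    in ``config.yaml`` next to the outputs.
    """
    params = dict(DEMO_DEFAULTS)
    unknown = set(overrides) - set(params)
    if unknown:
        raise ValueError(f"unknown demo parameters: {sorted(unknown)}")
    params.update(overrides)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    params["seed"] = int(seed)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)

    summary: dict[str, object] = {"seed": int(seed)}

    # --- amplicon stage -------------------------------------------------
    design = make_tsdr_fixture()
    eio.write_design(design, out / "tsdr.fasta", out / "tsdr.design.tsv")
    read_cfg = ReadSimConfig(
        n_reads=int(params["n_reads"]),
        components=[
            (float(params["read_unmeth_weight"]), 0.0),
            (1.0 - float(params["read_unmeth_weight"]), 1.0),
        ],
        conversion_failure_rate=float(params["conversion_failure_rate"]),
        sequencing_error_rate=float(params["sequencing_error_rate"]),
        seed=seed,
    )
    records, read_truth = simulate_bisulfite_reads(design, read_cfg)
    eio.write_fastq(records, out / "reads.fastq")
    eio.write_tsv(read_truth, out / "reads.truth.tsv", index=False)
    matrix, report = call_fastq(
        out / "reads.fastq",
        design,
        min_conversion=float(params["min_conversion"]),
        min_identity=float(params["min_identity"]),
        min_cpg_coverage=float(params["min_cpg_coverage"]),
    )
    eio.write_tsv(matrix.calls, out / "read_calls.tsv", meta=report)
    meth = summarize(matrix)
    eio.write_tsv(
        pd.DataFrame(
            {"cpg_position": design.cpg_positions, "methylation_pct": meth.per_cpg}
        ),
        out / "amplicon_summary.tsv",
        meta={"overall_methylation_pct": f"{meth.overall:.3f}", "n_reads": meth.n_reads},
        index=False,
    )
    eio.write_tsv(pattern_map(matrix), out / "pattern_map.tsv")
    profile = classify_reads(matrix)
    summary["amplicon_overall_methylation_pct"] = round(meth.overall, 3)
    summary["amplicon_reads_retained"] = report["retained"]
    summary["amplicon_fully_methylated_fraction"] = round(profile.fully_methylated, 4)
    summary["amplicon_fully_demethylated_fraction"] = round(
        profile.fully_demethylated, 4
    )

    # --- array stage ----------------------------------------------------
    rng = np.random.default_rng([seed, 100])
    base_cfg = ArraySimConfig(
        n_probes=int(params["n_probes"]),
        group_design={"Tnaive": 3, "mCherry_neg": 3, "TET1": 3, "Treg": 3},
        seed=seed,
    )
    manifest = simulate_probe_manifest(base_cfg)
    genes, sig_idx = _signature_probe_indices(
        manifest, int(params["n_signature_genes"]), rng
    )
    delta = float(params["planted_delta"])
    n_edit = int(round(len(sig_idx) * float(params["tet1_edit_fraction"])))
    tet1_idx = np.sort(rng.choice(sig_idx, size=n_edit, replace=False))
    cfg = ArraySimConfig(
        n_probes=base_cfg.n_probes,
        group_design=base_cfg.group_design,
        planted_sets=(
            PlantedSet(tuple(int(i) for i in sig_idx), -delta, "Treg"),
            PlantedSet(tuple(int(i) for i in tet1_idx), -delta, "TET1"),
        ),
        seed=seed,
    )
    bm, beta_truth = simulate_beta_matrix(manifest, cfg)
    eio.write_manifest(manifest, out / "manifest.tsv", meta={"seed": seed})
    eio.write_beta(bm, out / "beta.tsv", meta={"seed": seed})
    eio.write_groups(bm.groups, out / "groups.tsv")
    eio.write_tsv(beta_truth, out / "beta.truth.tsv", index=False)

    diff = compare_groups(
        bm, "mCherry_neg", "TET1", threshold=float(params["delta_threshold"])
    )
    eio.write_tsv(
        diff.table,
        out / "diffmeth.tsv",
        meta={
            "reference": diff.reference,
            "treatment": diff.treatment,
            "threshold": diff.threshold,
            "n_hypo": len(diff.hypo),
            "n_hyper": len(diff.hyper),
            "pearson_r": f"{diff.pearson_r:.6f}",
        },
    )
    planted_tet1 = set(manifest.probe_ids[tet1_idx])
    recovered = len(planted_tet1 & set(diff.hypo))
    summary["diffmeth_n_hypo"] = len(diff.hypo)
    summary["diffmeth_n_hyper"] = len(diff.hyper)
    summary["diffmeth_planted_recovered"] = recovered
    summary["diffmeth_planted_total"] = len(planted_tet1)
    summary["diffmeth_sensitivity"] = round(recovered / len(planted_tet1), 4)

    # locus clustering on the chromosome carrying the first signature gene
    first_chrom = manifest.table.iloc[int(sig_idx[0])]["chrom"]
    chrom_pos = manifest.table.loc[manifest.table["chrom"] == first_chrom, "pos"]
    z, order = locus_cluster(
        bm, manifest, first_chrom, int(chrom_pos.min()), int(chrom_pos.max()) + 1
    )
    eio.write_tsv(
        pd.DataFrame(z, columns=["node_i", "node_j", "height", "n_leaves"]),
        out / "locus_linkage.tsv",
        meta={"chrom": first_chrom, "leaf_order": ",".join(order)},
        index=False,
    )

    # --- enrichment stage -----------------------------------------------
    treg_diff = compare_groups(
        bm, "Tnaive", "Treg", threshold=float(params["delta_threshold"])
    )
    background = diff.table.index
    res_treg = subset_enrichment(treg_diff.hypo, diff.hypo, background)
    summary["treg_hypo_enrichment_p"] = res_treg.p_two_sided
    summary["treg_hypo_enrichment_odds"] = (
        round(res_treg.odds_ratio, 3)
        if np.isfinite(res_treg.odds_ratio)
        else res_treg.odds_ratio
    )
    summary["treg_hypo_enrichment_direction"] = res_treg.direction

    offtargets = simulate_region_sets(
        manifest,
        enriched_in=[],
        odds=1.0,
        n_regions=int(params["n_offtarget_predictions"]),
        seed=seed + 1,
    )
    eio.write_tsv(offtargets.scored, out / "offtarget_predictions.tsv", index=False)
    selected = select_top_offtargets(
        offtargets.scored, top_n=int(params["top_n_offtargets"])
    )
    extended = extend_windows(selected, flank=int(params["flank"]))
    eio.write_bed(extended, out / "offtarget_windows.bed")
    ot_probes = probes_in_windows(manifest, extended) & set(background)
    res_ot = subset_enrichment(ot_probes, diff.hypo, background)
    summary["offtarget_enrichment_p"] = res_ot.p_two_sided
    summary["offtarget_enrichment_direction"] = res_ot.direction

    pc = pca(bm)
    eio.write_tsv(pc.scores, out / "pca_scores.tsv")
    eio.write_tsv(
        pd.DataFrame(
            {"component": pc.components, "variance_ratio": pc.variance_ratio}
        ),
        out / "pca_variance.tsv",
        index=False,
    )
    top = topk_loadings(pc, "PC1", k=int(params["top_k_loadings"]))
    gene_table = gene_enrichment(top, manifest)
    eio.write_tsv(gene_table, out / "pc1_gene_enrichment.tsv", index=False)
    top_ranked = set(gene_table.head(len(genes))["gene"])
    summary["pc1_signature_genes_in_top"] = len(top_ranked & set(genes))
    summary["pc1_signature_genes_total"] = len(genes)

    # --- integration stage ----------------------------------------------
    all_genes = sorted(manifest.gene_totals().index)
    de_truth_genes = genes[: max(1, len(genes) // 2)]
    expr, expr_truth = simulate_expression(
        all_genes,
        de_truth_genes,
        effect_log2fc=float(params["de_effect_log2fc"]),
        n_per_group=int(params["n_expr_per_group"]),
        seed=seed + 2,
        noise_sd=float(params["de_noise_sd"]),
        group_names=("mCherry_neg", "TET1"),
    )
    eio.write_tsv(expr, out / "expression.tsv", meta={"scale": "log2"})
    expr_groups = {c: c.rsplit("_", 1)[0] for c in expr.columns}
    de = simple_de(expr, expr_groups, "mCherry_neg", "TET1")
    eio.write_gene_set(de.genes, out / "de_genes.txt")
    report_df = annotate_and_intersect(list(diff.hypo), manifest, [de])
    eio.write_tsv(report_df, out / "intersection_report.tsv", index=False)
    summary["de_genes_found"] = len(de)
    summary["hypo_gene_de_intersection"] = int(report_df["size"].iloc[-1])
    summary["de_planted_recovered"] = len(de.genes & set(de_truth_genes))
    summary["de_planted_total"] = len(de_truth_genes)

    eio.write_tsv(
        pd.DataFrame(
            {"metric": list(summary), "value": [summary[k] for k in summary]}
        ),
        out / "summary.tsv",
        index=False,
    )
    return summary
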