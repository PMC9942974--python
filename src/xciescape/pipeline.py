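"""End-to-end orchestration: QC -> skew -> model -> calls -> variability
-> twins, with every result written as a tab-separated table."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import allelic, escmodel, skew, twins, variability
from .config import PipelineConfig
from .io import write_table

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def run_pipeline(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    annotation: Optional[pd.DataFrame],
    config: Optional[PipelineConfig],
    outdir: Union[str, Path],
) -> dict[str, pd.DataFrame]:
    """Run the full escape analysis and write all output tables.

    Stages: allelic QC; per-sample skew calls; pooled aFC ~ DS model and
    EscScores; gene-tissue escape calls; threshold benchmark and
    hypergeometric overlap against the annotation (when given);
    intra-donor and inter-individual variability; twin-pair statistics
    per tissue with a zygosity comparison.

    Returns the result tables keyed by name; each is also written to
    ``outdir`` as ``<name>.tsv`` (the fitted model as ``model.txt``).
    Aborts with :class:`InsufficientSkewedSamplesError` when fewer than
    ``config.min_skewed_samples`` samples are skewed.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, pd.DataFrame] = {}

    observations = allelic.apply_qc(counts, sheet, config)
    results["observations"] = observations

    skew_calls = skew.call_sample_skew(observations, sheet, config)
    results["skew_calls"] = skew_calls
    n_skewed = int((skew_calls["status"] == "skewed").sum())
    logger.info(
        "skew: %d skewed / %d random / %d unavailable of %d samples",
        n_skewed,
        int((skew_calls["status"] == "random").sum()),
        int((skew_calls["status"] == "unavailable").sum()),
        len(skew_calls),
    )

    model, records = escmodel.fit_escape_model(observations, skew_calls, config)
    model.to_file(outdir / "model.txt")
    results["escscores"] = records

    calls = escmodel.call_gene_tissue(records, sheet, config)
    results["gene_tissue_calls"] = calls
    called = calls[calls["status"] != "no_call"]
    for tissue, grp in called.groupby("tissue"):
        incidence = float((grp["status"] == "escapee").mean())
        logger.info(
            "calls[%s]: %d genes called, escape incidence %.1f%%",
            tissue, len(grp), 100 * incidence,
        )

    if annotation is not None:
        cutoffs = np.round(np.arange(0.20, 0.61, 0.04), 2)
        results["threshold_benchmark"] = escmodel.benchmark_thresholds(
            records, sheet, annotation, cutoffs, config
        )
        universe = set(called["gene_id"]) & set(annotation["gene_id"])
        called_esc = {
            g for g in called[called["status"] == "escapee"]["gene_id"]
        } & universe
        ref_esc = set(
            annotation[annotation["prior_status"] == "escape"]["gene_id"]
        ) & universe
        if universe:
            n_overlap, p = escmodel.overlap_test(called_esc, ref_esc, universe)
            results["overlap_test"] = pd.DataFrame(
                [{
                    "n_called": len(called_esc),
                    "n_reference": len(ref_esc),
                    "n_universe": len(universe),
                    "n_overlap": n_overlap,
                    "p_value": p,
                }]
            )

    donor_summary, donor_detail = variability.intra_donor_summary(
        records, sheet, config
    )
    results["donor_profiles"] = donor_summary
    results["donor_profile_detail"] = donor_detail
    results["consistency_calls"] = variability.consistency_call(
        records, sheet, calls, config
    )

    # between-tissue comparison of per-gene median scores
    groups = {
        tissue: grp["median_escscore"].to_numpy()
        for tissue, grp in called.groupby("tissue")
        if len(grp) >= 2
    }
    if len(groups) >= 2:
        h, p = variability.group_difference_test(groups)
        results["tissue_comparison"] = pd.DataFrame(
            [{"n_groups": len(groups), "kruskal_h": h, "p_value": p}]
        )

    pair_frames = []
    zyg_rows = []
    analysed_tissues = [
        t for t in sheet["tissue"].unique() if t not in config.excluded_tissues
    ]
    for tissue in sorted(analysed_tissues):
        stats_t = twins.twin_pair_stats(records, sheet, tissue, config)
        if stats_t.empty:
            continue
        stats_t.insert(1, "tissue", tissue)
        pair_frames.append(stats_t)
        if stats_t["valid"].sum() >= 2:
            comp = twins.zygosity_compare(stats_t, fisher_z=config.fisher_z)
            comp["tissue"] = tissue
            zyg_rows.append(comp)
    if pair_frames:
        results["twin_pair_stats"] = pd.concat(pair_frames, ignore_index=True)
    if zyg_rows:
        results["zygosity_comparison"] = pd.DataFrame(zyg_rows)

    for name, table in results.items():
        write_table(table, outdir / f"{name}.tsv")
    return results
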