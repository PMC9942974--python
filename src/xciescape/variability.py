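"""Variability of escape across tissues within donors, across
individuals within tissues, and across immune cell types.

Three views of the same score table:

* intra-donor — for donors with a skewed sample in every analysed
  tissue, count genes escaping in exactly 0, 1, ..., T tissues;
* inter-individual — within a tissue, a gene's score is "consistent"
  when at least 80% of individuals lie within one standard deviation
  of the gene's mean score (at least 10 scored individuals required);
* cell type — per purified cell type, the gene score is the average
  over the co-twins carrying that cell type, summarised as mean score
  and escape incidence.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .errors import XCIEscapeError

__all__ = [
    "intra_donor_summary",
    "consistency_call",
    "group_difference_test",
    "cell_type_escape_summary",
]

logger = logging.getLogger(__name__)


def _per_individual_scores(
    records: pd.DataFrame, sheet: pd.DataFrame, exclude: Sequence[str]
) -> pd.DataFrame:
    """One score per (gene, tissue, individual): the median over that
    individual's skewed samples of the tissue."""
    meta = sheet.set_index("sample_id")[["individual_id", "tissue"]]
    scored = records.join(meta, on="sample_id")
    scored = scored[~scored["tissue"].isin(exclude)]
    return (
        scored.groupby(["gene_id", "tissue", "individual_id"], sort=True)["escscore"]
        .median()
        .reset_index()
    )


def intra_donor_summary(
    records: pd.DataFrame,
    sheet: pd.DataFrame,
    config: PipelineConfig | None = None,
    tissues: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tissue-sharing of escape within donors.

    Only donors with a scored skewed sample in *every* analysed tissue
    qualify.  For each such donor, every gene scored in all T tissues
    is binned by the number of tissues in which its score reaches the
    escape cutoff.

    Returns ``(summary, detail)``: the summary has one row per donor x
    bin (individual_id, n_tissues_escaping, n_genes); the detail lists
    each gene's per-tissue score and escape flags for the qualifying
    donors.  The bin counts partition each donor's fully-scored gene
    set.
    """
    config = config or PipelineConfig()
    per_ind = _per_individual_scores(records, sheet, config.excluded_tissues)
    if tissues is None:
        tissues = sorted(
            t for t in sheet["tissue"].unique()
            if t not in config.excluded_tissues
        )
    tissues = list(tissues)
    per_ind = per_ind[per_ind["tissue"].isin(tissues)]

    donors = [
        ind
        for ind, grp in per_ind.groupby("individual_id")
        if set(grp["tissue"]) == set(tissues)
    ]
    if not donors:
        logger.warning(
            "intra_donor_summary: no donor has skewed scored samples in "
            "all of %s", tissues,
        )
        return (
            pd.DataFrame(columns=["individual_id", "n_tissues_escaping", "n_genes"]),
            pd.DataFrame(columns=["individual_id", "gene_id", "tissue",
                                  "escscore", "escaping"]),
        )

    detail = per_ind[per_ind["individual_id"].isin(donors)].copy()
    # keep only genes scored in all T tissues within each donor
    complete = (
        detail.groupby(["individual_id", "gene_id"])["tissue"]
        .transform("nunique")
        .eq(len(tissues))
    )
    detail = detail[complete].copy()
    detail["escaping"] = detail["escscore"] >= config.escape_cutoff

    n_escaping = (
        detail.groupby(["individual_id", "gene_id"])["escaping"].sum().rename(
            "n_tissues_escaping"
        )
    )
    summary = (
        n_escaping.reset_index()
        .groupby(["individual_id", "n_tissues_escaping"])
        .size()
        .rename("n_genes")
        .reset_index()
    )
    # emit explicit zero bins so counts always partition the gene set
    full_index = pd.MultiIndex.from_product(
        [sorted(donors), range(len(tissues) + 1)],
        names=["individual_id", "n_tissues_escaping"],
    )
    summary = (
        summary.set_index(["individual_id", "n_tissues_escaping"])
        .reindex(full_index, fill_value=0)
        .reset_index()
    )
    detail = detail.rename(columns={"escscore": "escscore"})[
        ["individual_id", "gene_id", "tissue", "escscore", "escaping"]
    ].reset_index(drop=True)
    return summary, detail


def consistency_call(
    records: pd.DataFrame,
    sheet: pd.DataFrame,
    gene_tissue_calls: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Inter-individual consistency of escape scores within tissues.

    Restricted to genes called escapee in at least one tissue.  Per
    gene x tissue, each individual contributes one score (median over
    their skewed samples); with at least ``min_individuals_consistency``
    individuals the gene is ``consistent`` when the fraction of
    individuals within +/- 1 standard deviation of the mean reaches the
    band fraction (0.8), otherwise ``variable``; fewer individuals give
    ``no_call``.  A zero standard deviation puts every individual in
    the band (degenerate but well-defined: perfectly consistent).

    Returns columns: gene_id, tissue, n_individuals, mean_escscore,
    sd_escscore, frac_within_band, label.
    """
    config = config or PipelineConfig()
    escapees = set(
        gene_tissue_calls[gene_tissue_calls["status"] == "escapee"]["gene_id"]
    )
    per_ind = _per_individual_scores(records, sheet, config.excluded_tissues)
    per_ind = per_ind[per_ind["gene_id"].isin(escapees)]

    ddof = 1 if config.sample_sd_consistency else 0
    rows = []
    for (gene, tissue), grp in per_ind.groupby(["gene_id", "tissue"], sort=True):
        scores = grp["escscore"].to_numpy(dtype=float)
        n = len(scores)
        mean = float(scores.mean())
        sd = float(scores.std(ddof=ddof)) if n > ddof else 0.0
        within = float(np.mean(np.abs(scores - mean) <= sd))
        if n < config.min_individuals_consistency:
            label = "no_call"
        elif within >= config.consistency_band_fraction:
            label = "consistent"
        else:
            label = "variable"
        rows.append(
            {
                "gene_id": gene,
                "tissue": tissue,
                "n_individuals": n,
                "mean_escscore": mean,
                "sd_escscore": sd,
                "frac_within_band": within,
                "label": label,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "tissue", "n_individuals", "mean_escscore",
            "sd_escscore", "frac_within_band", "label",
        ],
    )


def group_difference_test(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis rank test across groups of scores.

    Groups with fewer than two values are excluded with a warning; at
    least two usable groups are required.  Tied values are mid-ranked
    with the standard tie correction.

    Returns (H statistic, p-value).
    """
    usable = {}
    for label, values in groups.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            logger.warning(
                "group_difference_test: excluding group %r with %d value(s)",
                label, arr.size,
            )
            continue
        usable[label] = arr
    if len(usable) < 2:
        raise XCIEscapeError(
            "group_difference_test needs at least two groups with >= 2 values"
        )
    h, p = stats.kruskal(*usable.values())
    return float(h), float(p)


def cell_type_escape_summary(
    records: pd.DataFrame,
    sheet: pd.DataFrame,
    config: PipelineConfig | None = None,
    cell_types: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Escape summary per purified immune cell type.

    The sheet's tissue labels name the cell types here.  Per cell type
    and gene, each individual contributes their median score; when both
    co-twins carry the cell type the gene score is the mean of the two,
    otherwise the single co-twin's score is used directly.

    Returns ``(summary, gene_scores)``: the summary has one row per
    cell type with the mean gene score, escape incidence and gene
    count, plus the same quantities restricted to genes with data in
    every cell type; gene_scores is the gene x cell-type score table.
    """
    config = config or PipelineConfig()
    meta = sheet.set_index("sample_id")[["individual_id", "tissue"]]
    scored = records.join(meta, on="sample_id")
    if cell_types is not None:
        scored = scored[scored["tissue"].isin(cell_types)]
    per_ind = (
        scored.groupby(["gene_id", "tissue", "individual_id"], sort=True)["escscore"]
        .median()
        .reset_index()
    )
    gene_scores = (
        per_ind.groupby(["gene_id", "tissue"], sort=True)["escscore"]
        .mean()
        .reset_index()
        .rename(columns={"tissue": "cell_type"})
    )
    n_types = gene_scores["cell_type"].nunique()
    in_all = (
        gene_scores.groupby("gene_id")["cell_type"].transform("nunique").eq(n_types)
    )

    def _summarise(frame: pd.DataFrame, subset: str) -> pd.DataFrame:
        out = (
            frame.groupby("cell_type")["escscore"]
            .agg(
                n_genes="size",
                mean_escscore="mean",
                incidence=lambda s: float((s >= config.escape_cutoff).mean()),
            )
            .reset_index()
        )
        out["subset"] = subset
        return out

    summary = pd.concat(
        [_summarise(gene_scores, "all"),
         _summarise(gene_scores[in_all], "complete")],
        ignore_index=True,
    )
    return summary, gene_scores
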