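"""Co-twin concordance of escape.

A "complete pair" has both co-twins with skewed, scored samples in the
same tissue.  Per pair, the co-twin score vectors (one score per gene
per co-twin, median over that co-twin's skewed samples) are correlated
over the shared genes — Spearman by default, matching the rank-based
summaries used elsewhere in the analysis — and the discordance rate is
the fraction of jointly-called genes escaping in exactly one co-twin.
A pair needs at least 5 shared genes to yield a valid correlation.

Monozygotic twins share their whole genome, dizygotic twins half on
average, so a genetic component of escape shows up as higher MZ than
DZ concordance; the contrast is a Welch two-sample t-test on per-pair
correlation coefficients (Fisher-z transform optional).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig

__all__ = [
    "pair_correlation",
    "discordance_rate",
    "twin_pair_stats",
    "zygosity_compare",
]

logger = logging.getLogger(__name__)


def pair_correlation(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    min_genes: int = 5,
    method: str = "spearman",
) -> tuple[float, bool]:
    """Correlation between aligned co-twin score vectors.

    Returns ``(rho, valid)``; with fewer than ``min_genes`` shared
    genes the pair is invalid and rho is NaN (not an exception — short
    vectors are expected and simply ineligible).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("co-twin score vectors must be aligned on shared genes")
    if a.size < min_genes:
        return float("nan"), False
    if method == "spearman":
        rho = stats.spearmanr(a, b).statistic
    elif method == "pearson":
        rho = stats.pearsonr(a, b).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(rho), True


def discordance_rate(calls_a: Sequence[str], calls_b: Sequence[str]) -> float:
    """Fraction of jointly-called genes escaping in exactly one co-twin.

    Inputs are aligned per-gene status vectors ('escapee'/'silenced').
    NaN when no gene is jointly called.
    """
    a = np.asarray(calls_a, dtype=object)
    b = np.asarray(calls_b, dtype=object)
    if a.shape != b.shape:
        raise ValueError("co-twin call vectors must be aligned on shared genes")
    if a.size == 0:
        logger.warning("discordance_rate: zero jointly-called genes")
        return float("nan")
    discordant = (a == "escapee") ^ (b == "escapee")
    return float(discordant.mean())


def twin_pair_stats(
    records: pd.DataFrame,
    sheet: pd.DataFrame,
    tissue: str,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-pair concordance statistics in one tissue.

    Only complete pairs (both co-twins with scored skewed samples of
    the tissue) appear in the output.  Per co-twin and gene the score
    is the median across that co-twin's skewed samples; genes are
    called escapee at the configured cutoff for the discordance rate.

    Returns columns: pair_id, zygosity, n_genes, rho, discordance_rate,
    valid.
    """
    config = config or PipelineConfig()
    meta = sheet.set_index("sample_id")[["individual_id", "tissue"]]
    scored = records.join(meta, on="sample_id")
    scored = scored[scored["tissue"] == tissue]
    per_ind = (
        scored.groupby(["gene_id", "individual_id"], sort=True)["escscore"]
        .median()
        .reset_index()
    )

    pairs = (
        sheet[sheet["twin_pair_id"].notna()]
        .groupby("twin_pair_id")
        .agg(
            zygosity=("zygosity", "first"),
            individuals=("individual_id", lambda s: sorted(set(s))),
        )
    )
    rows = []
    for pair_id, row in pairs.iterrows():
        ind_a, ind_b = row["individuals"]
        a = per_ind[per_ind["individual_id"] == ind_a].set_index("gene_id")["escscore"]
        b = per_ind[per_ind["individual_id"] == ind_b].set_index("gene_id")["escscore"]
        if a.empty or b.empty:
            continue  # not a complete pair in this tissue
        shared = a.index.intersection(b.index)
        rho, valid = pair_correlation(
            a.loc[shared], b.loc[shared],
            min_genes=config.min_shared_genes_twins,
            method=config.twin_correlation,
        )
        call_a = np.where(a.loc[shared] >= config.escape_cutoff, "escapee", "silenced")
        call_b = np.where(b.loc[shared] >= config.escape_cutoff, "escapee", "silenced")
        disc = discordance_rate(call_a, call_b) if len(shared) else float("nan")
        rows.append(
            {
                "pair_id": pair_id,
                "zygosity": row["zygosity"],
                "n_genes": int(len(shared)),
                "rho": rho,
                "discordance_rate": disc,
                "valid": valid,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["pair_id", "zygosity", "n_genes", "rho",
                 "discordance_rate", "valid"],
    )


def zygosity_compare(
    pair_stats: pd.DataFrame, fisher_z: bool = False
) -> dict[str, float]:
    """Compare MZ and DZ per-pair correlations.

    Computed over valid pairs only.  Returns group means of rho and of
    the discordance rate, group sizes, and a Welch t-test on the
    per-pair correlation coefficients (optionally Fisher-z transformed
    first).  With fewer than two valid pairs in either group the test
    is unavailable (NaN statistic and p) but means are still reported.
    """
    valid = pair_stats[pair_stats["valid"]]
    mz = valid[valid["zygosity"] == "MZ"]
    dz = valid[valid["zygosity"] == "DZ"]

    def _mean(series: pd.Series) -> float:
        return float(series.mean()) if len(series) else float("nan")

    out = {
        "n_mz": int(len(mz)),
        "n_dz": int(len(dz)),
        "mean_rho_mz": _mean(mz["rho"]),
        "mean_rho_dz": _mean(dz["rho"]),
        "mean_disc_mz": _mean(mz["discordance_rate"]),
        "mean_disc_dz": _mean(dz["discordance_rate"]),
        "t_statistic": float("nan"),
        "p_value": float("nan"),
    }
    if len(mz) >= 2 and len(dz) >= 2:
        x, y = mz["rho"].to_numpy(), dz["rho"].to_numpy()
        if fisher_z:
            x, y = np.arctanh(np.clip(x, -1 + 1e-12, 1 - 1e-12)), \
                   np.arctanh(np.clip(y, -1 + 1e-12, 1 - 1e-12))
        t = stats.ttest_ind(x, y, equal_var=False)
        out["t_statistic"] = float(t.statistic)
        out["p_value"] = float(t.pvalue)
    else:
        logger.warning(
            "zygosity_compare: fewer than 2 valid pairs in a group; "
            "t-test unavailable"
        )
    return out
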