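"""Per gene-sample allele-specific expression, allelic fold change and QC.

For a biallelic gene g in sample s with haplotype read counts
AC and BC (total TC = AC + BC):

    ASE  = AC / TC                  in [0, 1]; 0 or 1 = monoallelic
    aFC  = min(AC, BC) / max(AC, BC) in [0, 1]; 0 = full silencing,
                                               1 = balanced (full escape)

In a sample with skewed X-inactivation the lower-count haplotype is
taken to sit on the inactive X, so aFC estimates the Xi/Xa expression
ratio of the gene.

Quality control keeps observations with total allelic depth >= 8 reads
and requires that both haplotypes of the gene were seen at least once
in the RNA-seq data — evidence that the genotype really is
heterozygous.  The heterozygosity check is pooled across all samples of
an individual by default, so a gene that is monoallelic in one sample
(a genuine silencing signal) is not discarded when another sample of
the same individual shows the other allele; a strict per-sample mode is
available.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import UndefinedObservationError

__all__ = ["compute_ase", "compute_afc", "apply_qc"]

logger = logging.getLogger(__name__)


def compute_ase(ac, bc):
    """Allele-specific expression AC / (AC + BC).

    Accepts scalars or arrays; raises for zero total depth.
    """
    ac = np.asarray(ac, dtype=float)
    bc = np.asarray(bc, dtype=float)
    tc = ac + bc
    if np.any(tc == 0):
        raise UndefinedObservationError("ASE undefined for zero total depth")
    out = ac / tc
    return float(out) if out.ndim == 0 else out


def compute_afc(ac, bc):
    """Allelic fold change min(AC, BC) / max(AC, BC).

    Symmetric in the haplotype labels; 0 for monoallelic expression,
    1 for perfectly balanced expression.
    """
    ac = np.asarray(ac, dtype=float)
    bc = np.asarray(bc, dtype=float)
    if np.any(ac + bc == 0):
        raise UndefinedObservationError("aFC undefined for zero total depth")
    out = np.minimum(ac, bc) / np.maximum(ac, bc)
    return float(out) if out.ndim == 0 else out


def apply_qc(
    counts: pd.DataFrame,
    sheet: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Compute ASE/aFC for every count record and apply the QC filters.

    Parameters
    ----------
    counts
        Validated count table (gene_id, sample_id, hapA_count, hapB_count).
    sheet
        Sample sheet; required for the default per-individual
        both-haplotype scope (maps samples to individuals).
    config
        Thresholds; defaults to :class:`PipelineConfig()`.

    Returns
    -------
    DataFrame with one row per input record (zero-depth records are
    dropped with a logged count): gene_id, sample_id, ac, bc, tc, ase,
    afc, qc_depth, qc_both_haps, retained.
    """
    config = config or PipelineConfig()
    obs = counts.rename(columns={"hapA_count": "ac", "hapB_count": "bc"}).copy()
    obs["tc"] = obs["ac"] + obs["bc"]

    n_in = len(obs)
    zero_depth = obs["tc"] == 0
    if zero_depth.any():
        logger.info("QC: dropping %d zero-depth record(s)", int(zero_depth.sum()))
    obs = obs[~zero_depth].copy()

    obs["ase"] = obs["ac"] / obs["tc"]
    obs["afc"] = np.minimum(obs["ac"], obs["bc"]) / np.maximum(obs["ac"], obs["bc"])
    obs["qc_depth"] = obs["tc"] >= config.depth_threshold

    if config.both_haps_scope == "sample":
        obs["qc_both_haps"] = (obs["ac"] > 0) & (obs["bc"] > 0)
    else:
        if sheet is None:
            raise ValueError(
                "apply_qc needs a sample sheet for the per-individual "
                "both-haplotype scope"
            )
        ind = sheet.set_index("sample_id")["individual_id"]
        obs["_individual"] = obs["sample_id"].map(ind)
        pooled = obs.groupby(["gene_id", "_individual"])[["ac", "bc"]].transform("sum")
        obs["qc_both_haps"] = (pooled["ac"] > 0) & (pooled["bc"] > 0)
        obs = obs.drop(columns="_individual")

    obs["retained"] = obs["qc_depth"] & obs["qc_both_haps"]

    n_depth = int((~obs["qc_depth"]).sum())
    n_haps = int((obs["qc_depth"] & ~obs["qc_both_haps"]).sum())
    n_kept = int(obs["retained"].sum())
    # attrition accounting: in = kept + zero-depth + failed-depth + failed-haps
    logger.info(
        "QC attrition: %d in = %d retained + %d zero-depth + "
        "%d below depth %d + %d single-haplotype",
        n_in, n_kept, int(zero_depth.sum()), n_depth,
        config.depth_threshold, n_haps,
    )
    return obs.reset_index(drop=True)
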