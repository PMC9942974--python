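"""Per-sample X-inactivation skew from XIST allele-specific expression.

XIST is transcribed exclusively from the inactive X, so the allelic
ratio of XIST reads in a bulk sample reports which fraction of its
cells inactivated each parental X.  The degree of skewing is

    DS = |0.5 - XIST_ASE|            in [0, 0.5]

with 0 meaning random X-inactivation (a 50:50 cell mosaic) and 0.5 a
completely skewed sample.  Samples with DS >= 0.3 (equivalently
XIST_ASE <= 0.2 or >= 0.8) are classified as skewed; only those carry
information about gene-level escape, because in a random-XCI mosaic
both alleles of every gene are expressed at the tissue level
regardless of escape.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import DomainError

__all__ = ["compute_ds", "classify_skew", "call_sample_skew"]


def compute_ds(xist_ase):
    """Degree of skewing |0.5 - XIST_ASE|; input must lie in [0, 1]."""
    x = np.asarray(xist_ase, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise DomainError("XIST_ASE must lie in [0, 1]")
    out = np.abs(0.5 - x)
    return float(out) if out.ndim == 0 else out


def classify_skew(ds, threshold: float = 0.3):
    """'skewed' iff DS >= threshold (boundary inclusive), else 'random'."""
    ds_arr = np.asarray(ds, dtype=float)
    out = np.where(ds_arr >= threshold, "skewed", "random")
    return str(out[()]) if out.ndim == 0 else out


def call_sample_skew(
    observations: pd.DataFrame,
    sheet: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Produce one skew call per sample in the sheet.

    The XIST observation must have passed the same QC as any other gene
    (depth, heterozygosity); samples without a retained XIST record get
    status ``unavailable`` with missing xist_ase/ds.

    Returns columns: sample_id, xist_ase, ds, status.
    """
    config = config or PipelineConfig()
    xist = observations[
        (observations["gene_id"] == config.xist_gene_id) & observations["retained"]
    ]
    calls = sheet[["sample_id"]].copy()
    ase_by_sample = xist.set_index("sample_id")["ase"]
    calls["xist_ase"] = calls["sample_id"].map(ase_by_sample)
    calls["ds"] = np.abs(0.5 - calls["xist_ase"])
    calls["status"] = np.where(
        calls["xist_ase"].isna(),
        "unavailable",
        np.where(calls["ds"] >= config.skew_threshold, "skewed", "random"),
    )
    return calls
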