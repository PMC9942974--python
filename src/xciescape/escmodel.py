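"""The escape score: skew-adjusted residual allelic fold change.

Raw aFC confounds escape with the sample's degree of X-inactivation
skew: under partial skew even a fully silenced gene shows residual
expression of the minor haplotype ((1-p)/p for active-X fraction p),
so aFC correlates negatively with DS across samples.  The correction
is a single ordinary-least-squares regression of aFC on DS pooled over
every retained gene x skewed-sample observation of the whole cohort
(whole-blood samples included in the fit even when excluded from
downstream escape calls).  The residual of each observation — observed
minus predicted aFC — is the raw escape score; min-max rescaling over
the fitting set maps it to [0, 1]:

    EscScore' = (EscScore - min) / (max - min)

By construction the rescaled score is uncorrelated with DS on the
fitting set (OLS residual orthogonality survives a positive affine
map).  0 means complete silencing, 1 complete biallelic escape.

Gene-tissue calls take the median EscScore across >= 3 skewed samples
of the tissue and classify escapee at median >= 0.36, a cutoff
benchmarked against reference XCI-status annotation (a sweep utility
is provided).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .errors import (
    DegenerateDesignError,
    DegenerateRescaleError,
    DomainError,
    InsufficientSkewedSamplesError,
)

__all__ = [
    "EscapeModel",
    "fit_escape_model",
    "rescale_minmax",
    "score_new_samples",
    "call_gene_tissue",
    "benchmark_thresholds",
    "overlap_test",
]

logger = logging.getLogger(__name__)


@dataclass
class EscapeModel:
    """Fitted aFC-on-DS line plus the residual extremes of its fitting
    set, persisted so samples outside the cohort can be scored on the
    same scale."""

    intercept: float
    slope: float
    n_obs: int
    resid_min: float
    resid_max: float

    def predict(self, ds) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(ds, dtype=float)

    def rescale(self, residuals) -> np.ndarray:
        span = self.resid_max - self.resid_min
        return (np.asarray(residuals, dtype=float) - self.resid_min) / span

    def to_file(self, path: Union[str, Path]) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(
            "\n".join(
                [
                    f"intercept = {self.intercept!r}",
                    f"slope = {self.slope!r}",
                    f"n_obs = {self.n_obs}",
                    f"resid_min = {self.resid_min!r}",
                    f"resid_max = {self.resid_max!r}",
                ]
            )
            + "\n"
        )

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "EscapeModel":
        values: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            key, _, raw = line.partition("=")
            values[key.strip()] = raw.strip()
        return cls(
            intercept=float(values["intercept"]),
            slope=float(values["slope"]),
            n_obs=int(values["n_obs"]),
            resid_min=float(values["resid_min"]),
            resid_max=float(values["resid_max"]),
        )


def rescale_minmax(residuals) -> np.ndarray:
    """Affine map sending the minimum residual to 0 and the maximum to 1.

    Order-preserving; raises :class:`DegenerateRescaleError` when all
    residuals coincide.
    """
    resid = np.asarray(residuals, dtype=float)
    lo, hi = float(resid.min()), float(resid.max())
    if hi == lo:
        raise DegenerateRescaleError("all residuals identical; min-max undefined")
    return (resid - lo) / (hi - lo)


def _join_skewed(observations: pd.DataFrame, skew_calls: pd.DataFrame) -> pd.DataFrame:
    skewed = skew_calls[skew_calls["status"] == "skewed"][["sample_id", "ds"]]
    joined = observations[observations["retained"]].merge(skewed, on="sample_id")
    return joined


def fit_escape_model(
    observations: pd.DataFrame,
    skew_calls: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> tuple[EscapeModel, pd.DataFrame]:
    """Fit the pooled aFC ~ DS regression and score the fitting set.

    Only retained observations from skewed samples enter the fit; all
    tissues of the cohort are pooled (the model needs the full span of
    DS values, and whole blood contributes to the fit even though it is
    excluded from escape calls downstream).

    Returns the fitted :class:`EscapeModel` and a score table with one
    row per fitted observation: gene_id, sample_id, afc, ds, residual,
    escscore, clamped (always False on the fitting set).
    """
    config = config or PipelineConfig()
    fit_set = _join_skewed(observations, skew_calls)
    n_samples = fit_set["sample_id"].nunique()
    if n_samples < config.min_skewed_samples:
        raise InsufficientSkewedSamplesError(
            f"insufficient skewed samples for model fitting: "
            f"{n_samples} < {config.min_skewed_samples}"
        )
    ds = fit_set["ds"].to_numpy(dtype=float)
    afc = fit_set["afc"].to_numpy(dtype=float)
    if np.unique(ds).size < 2:
        raise DegenerateDesignError(
            "all degree-of-skew values identical; aFC ~ DS fit is degenerate"
        )
    fit = stats.linregress(ds, afc)
    residual = afc - (fit.intercept + fit.slope * ds)

    if config.quantile_rescale:
        lo, hi = np.quantile(residual, [0.005, 0.995])
    else:
        lo, hi = float(residual.min()), float(residual.max())
    # tolerance absorbs rounding of an exactly-linear fitting set
    if hi - lo <= 1e-10 * max(1.0, abs(hi), abs(lo)):
        raise DegenerateRescaleError("all residuals identical; min-max undefined")
    model = EscapeModel(
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        n_obs=len(fit_set),
        resid_min=float(lo),
        resid_max=float(hi),
    )
    records = fit_set[["gene_id", "sample_id", "afc", "ds"]].copy()
    records["residual"] = residual
    escscore = model.rescale(residual)
    clamped = (escscore < 0) | (escscore > 1)  # only under quantile rescale
    records["escscore"] = np.clip(escscore, 0.0, 1.0)
    records["clamped"] = clamped
    logger.info(
        "escape model: n_obs=%d over %d skewed samples, slope=%.4f, "
        "intercept=%.4f", model.n_obs, n_samples, model.slope, model.intercept,
    )
    return model, records.reset_index(drop=True)


def score_new_samples(
    model: EscapeModel,
    observations: pd.DataFrame,
    skew_calls: pd.DataFrame,
) -> pd.DataFrame:
    """Score observations outside the fitting cohort (e.g. purified
    immune-cell samples) against a persisted model.

    Residuals are taken against the stored line and rescaled with the
    stored extremes; scores falling outside [0, 1] are clipped and
    flagged ``clamped``.  Samples without a skew call, or not skewed,
    are skipped with a log message.
    """
    usable = _join_skewed(observations, skew_calls)
    skipped = observations["retained"].sum() - len(usable)
    if skipped:
        logger.info(
            "score_new_samples: skipped %d observation(s) from non-skewed "
            "or uncalled samples", int(skipped),
        )
    records = usable[["gene_id", "sample_id", "afc", "ds"]].copy()
    residual = records["afc"].to_numpy() - model.predict(records["ds"].to_numpy())
    raw = model.rescale(residual)
    records["residual"] = residual
    records["escscore"] = np.clip(raw, 0.0, 1.0)
    records["clamped"] = (raw < 0) | (raw > 1)
    return records.reset_index(drop=True)


def call_gene_tissue(
    records: pd.DataFrame,
    sheet: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per gene x tissue escape calls from EscScore records.

    The median EscScore across the tissue's skewed samples (multiple
    samples per individual, and both co-twins, all count) is compared
    with the escape cutoff; tissues on the exclusion list (whole blood
    by default) are removed before calling.

    Returns columns: gene_id, tissue, n_samples, median_escscore,
    status (escapee / silenced / no_call).
    """
    config = config or PipelineConfig()
    tissue = sheet.set_index("sample_id")["tissue"]
    scored = records.copy()
    scored["tissue"] = scored["sample_id"].map(tissue)
    scored = scored[~scored["tissue"].isin(config.excluded_tissues)]
    grouped = (
        scored.groupby(["gene_id", "tissue"], sort=True)["escscore"]
        .agg(n_samples="size", median_escscore="median")
        .reset_index()
    )
    grouped["status"] = np.where(
        grouped["n_samples"] < config.min_samples_per_call,
        "no_call",
        np.where(
            grouped["median_escscore"] >= config.escape_cutoff, "escapee", "silenced"
        ),
    )
    return grouped


def benchmark_thresholds(
    records: pd.DataFrame,
    sheet: pd.DataFrame,
    annotation: pd.DataFrame,
    cutoffs: Iterable[float],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Sweep escape cutoffs and tabulate concordance with a reference
    XCI-status annotation.

    A gene's call at a cutoff is 'escapee' if it is called escapee in
    at least one (non-excluded) tissue, 'silenced' if it is called in
    at least one tissue and never escapee.  Reference genes annotated
    variable or discordant_unknown are excluded from the concordance
    tally (no binary expectation exists for them).

    Returns columns: cutoff, n_concordant, n_discordant, concordance.
    """
    config = config or PipelineConfig()
    prior = annotation.set_index("gene_id")["prior_status"]
    binary_prior = prior[prior.isin(["silenced", "escape"])]
    rows = []
    for cutoff in cutoffs:
        cfg = PipelineConfig(
            **{
                **{f: getattr(config, f) for f in config.__dataclass_fields__},
                "escape_cutoff": float(cutoff),
            }
        )
        calls = call_gene_tissue(records, sheet, cfg)
        called = calls[calls["status"] != "no_call"]
        gene_call = (
            called.groupby("gene_id")["status"]
            .agg(lambda s: "escapee" if (s == "escapee").any() else "silenced")
        )
        overlap = gene_call.index.intersection(binary_prior.index)
        expected = binary_prior.loc[overlap].map(
            {"silenced": "silenced", "escape": "escapee"}
        )
        n_conc = int((gene_call.loc[overlap] == expected).sum())
        n_disc = len(overlap) - n_conc
        rows.append(
            {
                "cutoff": float(cutoff),
                "n_concordant": n_conc,
                "n_discordant": n_disc,
                "concordance": n_conc / len(overlap) if len(overlap) else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    if table["n_concordant"].add(table["n_discordant"]).eq(0).all():
        logger.warning(
            "benchmark_thresholds: no overlap between called genes and "
            "annotation with binary prior status"
        )
    return table


def overlap_test(
    called: set[str], reference: set[str], universe: set[str]
) -> tuple[int, float]:
    """Hypergeometric upper-tail test of the overlap between an escape
    call set and a reference escape set within a gene universe.

    Returns (overlap size, P[overlap >= observed] under random draws of
    |called| genes from the universe containing |reference| successes).
    """
    if not universe:
        raise DomainError("overlap_test: empty universe")
    if not (called <= universe and reference <= universe):
        raise DomainError("overlap_test: sets must be subsets of the universe")
    k = len(called & reference)
    M, n, N = len(universe), len(reference), len(called)
    p = float(stats.hypergeom.sf(k - 1, M, n, N))
    return k, min(p, 1.0)
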