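"""Pipeline configuration.

All analysis thresholds are exposed as configuration keys. The defaults
are the values used throughout the escape-calling literature this
package implements: allelic depth >= 8, skew classification at
DS >= 0.3, escape classification at median EscScore >= 0.36 across >= 3
skewed samples, the 10-individual / 80%-band consistency rule, and the
5-shared-gene gate for twin-pair correlations.

Configuration files are plain text, one ``key = value`` per line.
Lines starting with ``#`` and blank lines are ignored.  List-valued
keys use comma-separated items.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from .errors import ConfigError

__all__ = ["PipelineConfig", "read_config", "write_config"]


@dataclass
class PipelineConfig:
    """Thresholds and structural options for the escape pipeline.

    Attributes
    ----------
    xist_gene_id
        Identifier of the XIST record in the count table; the whole
        skew analysis is keyed on this single gene.
    depth_threshold
        Minimum total allelic read depth for an observation to pass QC.
    both_haps_scope
        Scope of the both-haplotypes-detected heterozygosity filter:
        ``"individual"`` pools all samples of an individual (default),
        ``"sample"`` requires both haplotypes within each sample.
    skew_threshold
        Minimum degree of skewing (DS) for a sample to count as skewed.
    escape_cutoff
        EscScore at or above which a gene-tissue median is called escapee.
    min_samples_per_call
        Minimum number of skewed samples behind a gene-tissue call.
    min_individuals_consistency
        Minimum individuals with a score for the consistency analysis.
    consistency_band_fraction
        Fraction of individuals that must lie within one standard
        deviation of the mean for a gene to be labelled consistent.
    min_shared_genes_twins
        Minimum genes scored in both co-twins for a valid pair correlation.
    min_skewed_samples
        Minimum skewed samples required to fit the escape model at all.
    excluded_tissues
        Tissues kept in the model fit but excluded from escape calls
        (whole blood by default: too few skewed samples overlap the
        solid-tissue donors).
    solid_tissues
        Labels treated as solid tissue in summaries.
    per_tissue_fit
        Fit one model per tissue instead of one pooled model.
    quantile_rescale
        Use the 0.5%/99.5% residual quantiles instead of min/max when
        rescaling (robust variant; off by default).
    sample_sd_consistency
        Use the n-1 sample standard deviation in the consistency band
        instead of the population standard deviation.
    twin_correlation
        ``"spearman"`` (default) or ``"pearson"`` per-pair correlation.
    fisher_z
        Apply the Fisher z-transform before the zygosity t-test.
    """

    xist_gene_id: str = "XIST"
    depth_threshold: int = 8
    both_haps_scope: str = "individual"
    skew_threshold: float = 0.3
    escape_cutoff: float = 0.36
    min_samples_per_call: int = 3
    min_individuals_consistency: int = 10
    consistency_band_fraction: float = 0.8
    min_shared_genes_twins: int = 5
    min_skewed_samples: int = 10
    excluded_tissues: list[str] = field(default_factory=lambda: ["whole-blood"])
    solid_tissues: list[str] = field(default_factory=lambda: ["adipose", "skin"])
    per_tissue_fit: bool = False
    quantile_rescale: bool = False
    sample_sd_consistency: bool = False
    twin_correlation: str = "spearman"
    fisher_z: bool = False

    def __post_init__(self) -> None:
        if self.both_haps_scope not in ("individual", "sample"):
            raise ConfigError(
                f"both_haps_scope must be 'individual' or 'sample', "
                f"got {self.both_haps_scope!r}"
            )
        if self.twin_correlation not in ("spearman", "pearson"):
            raise ConfigError(
                f"twin_correlation must be 'spearman' or 'pearson', "
                f"got {self.twin_correlation!r}"
            )
        if not 0 <= self.skew_threshold <= 0.5:
            raise ConfigError("skew_threshold must lie in [0, 0.5]")
        if not 0 <= self.escape_cutoff <= 1:
            raise ConfigError("escape_cutoff must lie in [0, 1]")
        if self.depth_threshold < 1:
            raise ConfigError("depth_threshold must be >= 1")
        if not 0 < self.consistency_band_fraction <= 1:
            raise ConfigError("consistency_band_fraction must lie in (0, 1]")


def _parse_value(raw: str, target_type: type, key: str):
    raw = raw.strip()
    if target_type is bool:
        low = raw.lower()
        if low in ("true", "1", "yes"):
            return True
        if low in ("false", "0", "no"):
            return False
        raise ConfigError(f"cannot parse boolean for key {key!r}: {raw!r}")
    if target_type is int:
        try:
            return int(raw)
        except ValueError as exc:
            raise ConfigError(f"cannot parse integer for key {key!r}: {raw!r}") from exc
    if target_type is float:
        try:
            return float(raw)
        except ValueError as exc:
            raise ConfigError(f"cannot parse float for key {key!r}: {raw!r}") from exc
    if target_type is list or target_type == list[str]:
        if not raw:
            return []
        return [item.strip() for item in raw.split(",") if item.strip()]
    return raw


def read_config(path: Union[str, Path]) -> PipelineConfig:
    """Read a :class:`PipelineConfig` from a plain-text key-value file."""
    fields = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    # resolve the concrete type behind the annotation string
    type_map = {
        "str": str, "int": int, "float": float, "bool": bool, "list[str]": list,
    }
    values: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, raw = stripped.partition("=")
        key = key.strip()
        if key not in fields:
            raise ConfigError(f"{path}:{lineno}: unknown configuration key {key!r}")
        target = type_map.get(str(fields[key].type), str)
        values[key] = _parse_value(raw, target, key)
    return PipelineConfig(**values)


def write_config(config: PipelineConfig, path: Union[str, Path]) -> None:
    """Write a configuration as a plain-text key-value file (round-trips
    with :func:`read_config`)."""
    lines = []
    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        if isinstance(value, list):
            value = ",".join(value)
        lines.append(f"{f.name} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")
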