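"""Synthetic allelic-count data with the structure the analysis assumes.

A bulk sample is a mosaic of cells, a fraction ``p`` of which keep
haplotype A active (and B inactive) while the rest keep B active.  A
gene with Xi/Xa escape ratio ``e`` (0 = fully silenced on the inactive
X, approaching 1 = full escape) then shows expected haplotype-A read
fraction

    pi_A = (p + (1 - p) * e) / (1 + e)

because A-active cells contribute 1 unit from A plus e from B, and
B-active cells the mirror image.  XIST is transcribed from the
inactive X only, so its expected haplotype-A fraction is ``1 - p``.
Total allelic depth per gene-sample is negative-binomial; haplotype-A
reads are binomial (beta-binomial under allelic overdispersion).

Per-gene escape propensity varies across tissues and individuals on
the logit scale (keeping ``e`` inside (0, 1) without truncation).  The
individual component splits into a genetic part — shared exactly by
monozygotic co-twins, correlated 0.5 between dizygotic co-twins — and
an independent environmental part, mixed by ``heritability_weight``.

Everything is drawn from a single seeded generator, so a config plus
seed reproduces the dataset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = ["SimulationConfig", "GroundTruth", "simulate_dataset",
           "expected_afc", "twin_study_config"]


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic cohort.

    Gene classes: ``frac_silenced`` genes draw their baseline escape
    ratio from Beta(silenced_e_beta) (concentrated near 0),
    ``frac_escape`` from 0.3 + 0.5 * Beta(escape_e_beta) (constitutive
    escape stays below ~0.8, as observed Xi/Xa ratios do), and the
    remaining variable-escape genes from a broad mid-range
    distribution.

    Skew: the active-A cell fraction ``p`` is symmetric around 0.5.
    The default Beta(1.5, 1.5) makes roughly a quarter of samples
    skewed (|p - 0.5| >= 0.3), matching cohort skew rates of 14-32%
    per tissue.  ``skew_distribution="skewed_cohort"`` instead draws
    |p - 0.5| uniformly from ``skewed_ds_range``, emulating a cohort
    pre-selected for skewed X-inactivation (as twin concordance
    analyses are).

    Depth: negative-binomial with mean 50 and dispersion (size) 5 per
    gene-sample, a typical allelic depth profile for bulk RNA-seq of
    heterozygous X-linked genes.
    """

    n_genes: int = 200
    frac_silenced: float = 0.60
    frac_escape: float = 0.25
    frac_variable: float = 0.15
    silenced_e_beta: tuple[float, float] = (1.0, 19.0)
    escape_e_beta: tuple[float, float] = (2.0, 2.0)
    variable_e_beta: tuple[float, float] = (1.2, 1.2)

    n_mz_pairs: int = 17
    n_dz_pairs: int = 10
    n_singletons: int = 20
    tissues: list[str] = field(
        default_factory=lambda: ["LCL", "adipose", "skin", "whole-blood"]
    )
    tissue_availability: list[float] = field(
        default_factory=lambda: [1.0, 0.85, 0.85, 0.35]
    )

    heritability_weight: float = 0.6
    tissue_effect_sd: float = 0.5
    environment_sd: float = 1.5
    correlate_skew_within_individual: bool = False

    skew_distribution: str = "beta"
    skew_beta: float = 1.5
    skewed_ds_range: tuple[float, float] = (0.32, 0.45)

    depth_mean: float = 50.0
    depth_dispersion: float = 5.0
    allelic_overdispersion: float = 0.0

    xist_gene_id: str = "XIST"
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.frac_silenced, self.frac_escape, self.frac_variable)
        if any(not 0 <= f <= 1 for f in fracs):
            raise ConfigError("gene class fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigError("gene class fractions must sum to 1")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ConfigError("depth mean and dispersion must be positive")
        if not 0 <= self.heritability_weight <= 1:
            raise ConfigError("heritability_weight must lie in [0, 1]")
        if not 0 <= self.allelic_overdispersion < 1:
            raise ConfigError("allelic_overdispersion must lie in [0, 1)")
        if len(self.tissues) != len(self.tissue_availability):
            raise ConfigError("one availability per tissue required")
        if self.skew_distribution not in ("beta", "skewed_cohort"):
            raise ConfigError(
                "skew_distribution must be 'beta' or 'skewed_cohort'"
            )
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")


@dataclass
class GroundTruth:
    """True generative state behind a simulated dataset.

    ``genes``: gene_id, class_label, base_e;
    ``escape``: true escape ratio e per (gene_id, tissue, individual_id);
    ``samples``: true active-A cell fraction p per sample_id.
    """

    genes: pd.DataFrame
    escape: pd.DataFrame
    samples: pd.DataFrame


def expected_afc(p: float, e: float) -> float:
    """Noise-free allelic fold change of a gene with escape ratio ``e``
    in a sample with active-A fraction ``p``.

    The two haplotype expression masses are m_A = p + (1-p) e and
    m_B = (1-p) + p e; aFC is their min/max ratio.  At p = 1 this is
    exactly ``e`` (the skewed-sample reading of aFC as Xi/Xa ratio);
    at p = 0.5 it is 1 regardless of ``e`` — random X-inactivation
    hides escape.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if not 0 <= e <= 1:
        raise ValueError("e must lie in [0, 1]")
    m_a = p + (1 - p) * e
    m_b = (1 - p) + p * e
    if m_a == 0 and m_b == 0:  # unreachable for valid p, e but keep total
        return 1.0
    return min(m_a, m_b) / max(m_a, m_b)


def _logit(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 1e-9, 1 - 1e-9)
    return np.log(x / (1 - x))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _draw_base_e(config: SimulationConfig, rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray]:
    n = config.n_genes
    n_sil = int(round(n * config.frac_silenced))
    n_esc = int(round(n * config.frac_escape))
    n_var = n - n_sil - n_esc
    classes = np.array(
        ["silenced"] * n_sil + ["escape"] * n_esc + ["variable"] * n_var
    )
    base = np.empty(n)
    a, b = config.silenced_e_beta
    base[:n_sil] = rng.beta(a, b, size=n_sil)
    a, b = config.escape_e_beta
    base[n_sil:n_sil + n_esc] = 0.3 + 0.5 * rng.beta(a, b, size=n_esc)
    a, b = config.variable_e_beta
    base[n_sil + n_esc:] = 0.05 + 0.65 * rng.beta(a, b, size=n_var)
    return classes, base


def _draw_skew(config: SimulationConfig, size: int,
               rng: np.random.Generator) -> np.ndarray:
    if config.skew_distribution == "beta":
        return rng.beta(config.skew_beta, config.skew_beta, size=size)
    lo, hi = config.skewed_ds_range
    ds = rng.uniform(lo, hi, size=size)
    side = rng.integers(0, 2, size=size)  # which parental X dominates
    return np.where(side == 1, 0.5 + ds, 0.5 - ds)


def simulate_dataset(
    config: Optional[SimulationConfig] = None,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth, pd.DataFrame]:
    """Generate (count table, sample sheet, ground truth, annotation).

    ``seed`` overrides ``config.seed`` when given.  The reference
    annotation is derived from the true gene classes (silenced /
    escape / variable), with the pseudoautosomal flag all False — the
    generator models no positional structure.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    # --- individuals and twin structure -------------------------------
    individuals: list[str] = []
    pair_of: dict[str, str] = {}
    zygosity_of: dict[str, str] = {}
    counter = 0

    def _new_individual() -> str:
        nonlocal counter
        counter += 1
        return f"I{counter:04d}"

    pair_counter = 0
    for zygo, n_pairs in (("MZ", config.n_mz_pairs), ("DZ", config.n_dz_pairs)):
        for _ in range(n_pairs):
            pair_counter += 1
            pid = f"P{pair_counter:03d}"
            for _ in range(2):
                ind = _new_individual()
                individuals.append(ind)
                pair_of[ind] = pid
                zygosity_of[ind] = zygo
    for _ in range(config.n_singletons):
        individuals.append(_new_individual())
    n_ind = len(individuals)
    ind_index = {ind: i for i, ind in enumerate(individuals)}

    # --- gene truth ---------------------------------------------------
    classes, base_e = _draw_base_e(config, rng)
    gene_ids = np.array([f"G{i + 1:04d}" for i in range(config.n_genes)])
    n_genes = config.n_genes
    n_tissues = len(config.tissues)

    # logit-scale perturbations: tissue (shared across individuals),
    # genetic (MZ identical, DZ correlated 0.5) and environmental
    tissue_eff = rng.normal(0.0, config.tissue_effect_sd, size=(n_genes, n_tissues))

    genetic = np.empty((n_genes, n_ind))
    drawn: set[str] = set()
    for ind in individuals:
        i = ind_index[ind]
        if ind in drawn:
            continue
        pid = pair_of.get(ind)
        if pid is None:
            genetic[:, i] = rng.normal(0.0, 1.0, size=n_genes)
            drawn.add(ind)
            continue
        co = [x for x, p in pair_of.items() if p == pid]
        a_idx, b_idx = ind_index[co[0]], ind_index[co[1]]
        if zygosity_of[ind] == "MZ":
            g = rng.normal(0.0, 1.0, size=n_genes)
            genetic[:, a_idx] = g
            genetic[:, b_idx] = g
        else:
            shared = rng.normal(0.0, 1.0, size=n_genes)
            for idx in (a_idx, b_idx):
                own = rng.normal(0.0, 1.0, size=n_genes)
                genetic[:, idx] = np.sqrt(0.5) * shared + np.sqrt(0.5) * own
        drawn.update(co)

    environment = rng.normal(0.0, 1.0, size=(n_genes, n_ind))
    w = config.heritability_weight
    individual_eff = config.environment_sd * (
        np.sqrt(w) * genetic + np.sqrt(1.0 - w) * environment
    )

    # e[g, t, i] on the logit scale, mapped back into (0, 1)
    logit_e = (
        _logit(base_e)[:, None, None]
        + tissue_eff[:, :, None]
        + individual_eff[:, None, :]
    )
    true_e = _sigmoid(logit_e)

    # --- samples ------------------------------------------------------
    sheet_rows = []
    sample_ind_idx: list[int] = []
    sample_tis_idx: list[int] = []
    s_counter = 0
    for ind in individuals:
        for t, (tissue, avail) in enumerate(
            zip(config.tissues, config.tissue_availability)
        ):
            if rng.random() >= avail:
                continue
            s_counter += 1
            sid = f"S{s_counter:04d}"
            sheet_rows.append(
                {
                    "sample_id": sid,
                    "individual_id": ind,
                    "tissue": tissue,
                    "twin_pair_id": pair_of.get(ind, pd.NA),
                    "zygosity": zygosity_of.get(ind, pd.NA),
                }
            )
            sample_ind_idx.append(ind_index[ind])
            sample_tis_idx.append(t)
    sheet = pd.DataFrame(sheet_rows)
    n_samples = len(sheet)
    sample_ind = np.array(sample_ind_idx)
    sample_tis = np.array(sample_tis_idx)

    if config.correlate_skew_within_individual:
        p_ind = _draw_skew(config, n_ind, rng)
        p = p_ind[sample_ind]
    else:
        p = _draw_skew(config, n_samples, rng)

    # --- counts -------------------------------------------------------
    # e per (gene, sample) picked out of the (gene, tissue, individual) cube
    e_gs = true_e[:, sample_tis, sample_ind]  # (n_genes, n_samples)
    pi_a = (p[None, :] + (1.0 - p[None, :]) * e_gs) / (1.0 + e_gs)

    all_gene_ids = np.concatenate([gene_ids, [config.xist_gene_id]])
    pi_full = np.vstack([pi_a, (1.0 - p)[None, :]])  # XIST from the inactive X

    nb_n = config.depth_dispersion
    nb_p = nb_n / (nb_n + config.depth_mean)
    depth = rng.negative_binomial(nb_n, nb_p, size=pi_full.shape)

    rho = config.allelic_overdispersion
    if rho > 0:
        scale = (1.0 - rho) / rho
        alpha = np.clip(pi_full, 1e-9, 1 - 1e-9) * scale
        beta = np.clip(1.0 - pi_full, 1e-9, 1 - 1e-9) * scale
        per_draw_pi = rng.beta(alpha, beta)
        hap_a = rng.binomial(depth, per_draw_pi)
    else:
        hap_a = rng.binomial(depth, pi_full)
    hap_b = depth - hap_a

    n_rows = pi_full.shape[0] * n_samples
    counts = pd.DataFrame(
        {
            "gene_id": np.repeat(all_gene_ids, n_samples),
            "sample_id": np.tile(sheet["sample_id"].to_numpy(), pi_full.shape[0]),
            "hapA_count": hap_a.reshape(n_rows),
            "hapB_count": hap_b.reshape(n_rows),
        }
    )

    # --- truth + annotation -------------------------------------------
    genes_df = pd.DataFrame(
        {"gene_id": gene_ids, "class_label": classes, "base_e": base_e}
    )
    escape_df = pd.DataFrame(
        {
            "gene_id": np.repeat(gene_ids, n_tissues * n_ind),
            "tissue": np.tile(np.repeat(config.tissues, n_ind), n_genes),
            "individual_id": np.tile(individuals, n_genes * n_tissues),
            "e": true_e.reshape(-1),
        }
    )
    samples_df = pd.DataFrame({"sample_id": sheet["sample_id"], "p": p})
    truth = GroundTruth(genes=genes_df, escape=escape_df, samples=samples_df)

    annotation = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "prior_status": pd.Series(classes).map(
                {"silenced": "silenced", "escape": "escape", "variable": "variable"}
            ),
            "par_flag": False,
        }
    )
    return counts, sheet, truth, annotation


def twin_study_config(
    heritability_weight: float = 0.6,
    n_genes: int = 120,
    seed: int = 0,
) -> SimulationConfig:
    """Config emulating a twin concordance study: 17 MZ and 10 DZ
    complete pairs, one cell-line tissue, cohort pre-selected for
    skewed X-inactivation (so pairs are complete by construction up to
    XIST QC dropout)."""
    return SimulationConfig(
        n_genes=n_genes,
        n_mz_pairs=17,
        n_dz_pairs=10,
        n_singletons=0,
        tissues=["LCL"],
        tissue_availability=[1.0],
        heritability_weight=heritability_weight,
        skew_distribution="skewed_cohort",
        seed=seed,
    )
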