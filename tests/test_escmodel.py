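import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xciescape import (
    EscapeModel,
    PipelineConfig,
    benchmark_thresholds,
    call_gene_tissue,
    fit_escape_model,
    overlap_test,
    rescale_minmax,
    score_new_samples,
)
from xciescape.errors import (
    DegenerateDesignError,
    DegenerateRescaleError,
    DomainError,
    InsufficientSkewedSamplesError,
)

from conftest import make_sheet


def _obs(rows):
    """rows: (gene_id, sample_id, afc); all retained."""
    df = pd.DataFrame(rows, columns=["gene_id", "sample_id", "afc"])
    df["retained"] = True
    return df


def _skew(pairs):
    """pairs: (sample_id, ds); all skewed."""
    df = pd.DataFrame(pairs, columns=["sample_id", "ds"])
    df["status"] = "skewed"
    return df


class TestRescale:
    def test_affine_example(self):
        out = rescale_minmax([-0.2, 0.0, 0.2])
        assert out == pytest.approx([0.0, 0.5, 1.0])

    def test_endpoints_and_rank_order(self):
        rng = np.random.default_rng(3)
        resid = rng.normal(size=50)
        out = rescale_minmax(resid)
        assert out.min() == 0.0 and out.max() == 1.0
        assert (np.argsort(out) == np.argsort(resid)).all()

    def test_degenerate(self):
        with pytest.raises(DegenerateRescaleError):
            rescale_minmax([0.3, 0.3, 0.3])


class TestFit:
    def test_perfect_linear_fit_is_degenerate(self, tiny_config):
        ds_values = [0.30, 0.35, 0.40, 0.45]
        obs = _obs(
            [(f"G{g}", f"S{i}", 0.9 - ds) for g in range(3)
             for i, ds in enumerate(ds_values)]
        )
        skew = _skew([(f"S{i}", ds) for i, ds in enumerate(ds_values)])
        with pytest.raises(DegenerateRescaleError):
            fit_escape_model(obs, skew, tiny_config)

    def test_identical_ds_is_degenerate_design(self, tiny_config):
        obs = _obs([("G1", "S1", 0.2), ("G1", "S2", 0.8)])
        skew = _skew([("S1", 0.4), ("S2", 0.4)])
        with pytest.raises(DegenerateDesignError):
            fit_escape_model(obs, skew, tiny_config)

    def test_too_few_skewed_samples_aborts(self):
        obs = _obs([("G1", "S1", 0.2), ("G1", "S2", 0.8)])
        skew = _skew([("S1", 0.3), ("S2", 0.4)])
        with pytest.raises(InsufficientSkewedSamplesError, match="insufficient"):
            fit_escape_model(obs, skew, PipelineConfig(min_skewed_samples=10))

    def test_escscore_orthogonal_to_ds(self, default_scored):
        records = default_scored["records"]
        rho = stats.pearsonr(records["escscore"], records["ds"]).statistic
        assert abs(rho) < 1e-10

    def test_slope_negative_and_matches_independent_ols(self, default_scored):
        """Raw aFC falls with DS (residual expression of a silenced gene
        shrinks as skew grows); check our fit against an independent
        least-squares route."""
        model = default_scored["model"]
        records = default_scored["records"]
        assert model.slope < 0
        slope_ref, intercept_ref = np.polyfit(records["ds"], records["afc"], 1)
        assert model.slope == pytest.approx(slope_ref, rel=1e-9)
        assert model.intercept == pytest.approx(intercept_ref, rel=1e-9)
        raw_rho = stats.pearsonr(records["afc"], records["ds"]).statistic
        assert raw_rho < 0

    def test_model_round_trips_through_file(self, default_scored, tmp_path):
        model = default_scored["model"]
        model.to_file(tmp_path / "model.txt")
        back = EscapeModel.from_file(tmp_path / "model.txt")
        assert back == model


class TestScoreNewSamples:
    def test_fitting_set_scores_reproduced(self, default_scored):
        rescored = score_new_samples(
            default_scored["model"],
            default_scored["observations"],
            default_scored["skew_calls"],
        )
        merged = rescored.merge(
            default_scored["records"], on=["gene_id", "sample_id"],
            suffixes=("_new", "_fit"),
        )
        assert len(merged) == len(default_scored["records"])
        assert np.allclose(merged["escscore_new"], merged["escscore_fit"])

    def test_out_of_range_residual_clamped(self, tiny_config):
        model = EscapeModel(intercept=0.5, slope=-1.0, n_obs=10,
                            resid_min=-0.05, resid_max=0.05)
        obs = _obs([("G1", "S1", 1.0), ("G2", "S1", 0.0)])
        skew = _skew([("S1", 0.4)])
        out = score_new_samples(model, obs, skew).set_index("gene_id")
        # residuals 0.9 and -0.1 both fall outside [-0.05, 0.05]
        assert out.loc["G1", "escscore"] == 1.0 and out.loc["G1", "clamped"]
        assert out.loc["G2", "escscore"] == 0.0 and out.loc["G2", "clamped"]

    def test_empty_observations_give_empty_output(self, default_scored):
        empty = _obs([]).astype({"afc": float})
        out = score_new_samples(default_scored["model"], empty, _skew([]))
        assert out.empty


class TestGeneTissueCalls:
    sheet = make_sheet(
        [("S1", "I1", "LCL"), ("S2", "I2", "LCL"), ("S3", "I3", "LCL"),
         ("S4", "I4", "whole-blood")]
    )

    def _records(self, scores, gene="G1"):
        return pd.DataFrame(
            {
                "gene_id": gene,
                "sample_id": [f"S{i+1}" for i in range(len(scores))],
                "escscore": scores,
            }
        )

    def test_escapee_at_cutoff_boundary(self):
        calls = call_gene_tissue(self._records([0.30, 0.36, 0.50]), self.sheet)
        assert calls["median_escscore"].iloc[0] == pytest.approx(0.36)
        assert calls["status"].iloc[0] == "escapee"

    def test_silenced_just_below_cutoff(self):
        calls = call_gene_tissue(self._records([0.3599, 0.3599, 0.3599]), self.sheet)
        assert calls["status"].iloc[0] == "silenced"

    def test_no_call_below_min_samples(self):
        calls = call_gene_tissue(self._records([0.10, 0.20]), self.sheet)
        assert calls["status"].iloc[0] == "no_call"

    def test_silenced_median(self):
        calls = call_gene_tissue(self._records([0.1, 0.2, 0.3]), self.sheet)
        assert calls["median_escscore"].iloc[0] == pytest.approx(0.2)
        assert calls["status"].iloc[0] == "silenced"

    def test_excluded_tissue_removed_from_calls(self):
        records = pd.DataFrame(
            {"gene_id": "G1", "sample_id": ["S1", "S2", "S3", "S4"],
             "escscore": [0.5, 0.5, 0.5, 0.9]}
        )
        calls = call_gene_tissue(records, self.sheet)
        assert set(calls["tissue"]) == {"LCL"}  # whole-blood dropped
        assert calls["n_samples"].iloc[0] == 3


class TestBenchmark:
    def test_self_agreement_is_perfect(self, default_sim, default_scored):
        """Using the gene calls themselves as the annotation gives
        concordance 1 at the calling cutoff."""
        records = default_scored["records"]
        sheet = default_sim["sheet"]
        calls = call_gene_tissue(records, sheet)
        called = calls[calls["status"] != "no_call"]
        gene_status = (
            called.groupby("gene_id")["status"]
            .agg(lambda s: "escape" if (s == "escapee").any() else "silenced")
        )
        annotation = pd.DataFrame(
            {"gene_id": gene_status.index, "prior_status": gene_status.values,
             "par_flag": False}
        )
        table = benchmark_thresholds(records, sheet, annotation, [0.36])
        assert table["concordance"].iloc[0] == 1.0

    def test_cutoff_zero_calls_everything_escapee(self, default_sim, default_scored):
        records = default_scored["records"]
        sheet = default_sim["sheet"]
        annotation = default_sim["annotation"]
        table = benchmark_thresholds(records, sheet, annotation, [0.0])
        row = table.iloc[0]
        # every called gene is an escapee, so concordance equals the
        # fraction of overlapping binary-prior genes annotated escape
        calls = call_gene_tissue(records, sheet,
                                 PipelineConfig(escape_cutoff=0.0))
        called_genes = set(calls[calls["status"] != "no_call"]["gene_id"])
        prior = annotation.set_index("gene_id")["prior_status"]
        binary = prior[prior.isin(["silenced", "escape"])]
        overlap = [g for g in binary.index if g in called_genes]
        frac_escape = (binary.loc[overlap] == "escape").mean()
        assert row["concordance"] == pytest.approx(frac_escape)

    def test_truth_annotation_maximized_near_class_separation(
        self, default_sim, default_scored
    ):
        """Against the simulation's own class labels, concordance peaks
        at a cutoff between the silenced and escape score clusters."""
        grid = np.round(np.arange(0.04, 0.97, 0.04), 2)
        table = benchmark_thresholds(
            default_scored["records"], default_sim["sheet"],
            default_sim["annotation"], grid,
        )
        best = table.loc[table["concordance"].idxmax(), "cutoff"]
        assert 0.2 <= best <= 0.6
        assert table["concordance"].max() >= 0.9
        # partition invariant: concordant + discordant = overlap size
        assert (
            table["n_concordant"] + table["n_discordant"]
        ).nunique() == 1


def _hypergeom_tail_bruteforce(k, M, n, N):
    """P[overlap >= k] by exhaustive summation of the hypergeometric
    probability mass function."""
    total = 0.0
    for j in range(k, min(n, N) + 1):
        total += math.comb(n, j) * math.comb(M - n, N - j) / math.comb(M, N)
    return total


class TestOverlap:
    def test_disjoint_sets_p_is_one(self):
        universe = {f"G{i}" for i in range(20)}
        k, p = overlap_test({"G1", "G2"}, {"G5", "G6"}, universe)
        assert k == 0 and p == pytest.approx(1.0)

    def test_reference_equal_to_universe_forces_overlap(self):
        universe = {f"G{i}" for i in range(10)}
        called = {"G1", "G2", "G3"}
        k, p = overlap_test(called, universe, universe)
        assert k == len(called)
        assert p == pytest.approx(1.0)

    def test_matches_bruteforce_tail_sum(self):
        universe = {f"G{i}" for i in range(100)}
        called = {f"G{i}" for i in range(20)}          # |A| = 20
        reference = {f"G{i}" for i in range(10, 40)}   # |B| = 30, overlap 10
        k, p = overlap_test(called, reference, universe)
        assert k == 10
        assert p == pytest.approx(
            _hypergeom_tail_bruteforce(10, 100, 30, 20), rel=1e-9
        )

    def test_empty_universe_rejected(self):
        with pytest.raises(DomainError):
            overlap_test(set(), set(), set())
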