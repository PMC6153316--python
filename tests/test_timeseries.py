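"""Temporal selection: design construction, global F, BH, backward stepwise."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import toxtempo as tt
from toxtempo.errors import DesignError
from toxtempo.timeseries import _ols, build_time_design, global_fits

from conftest import small_config


def _samples(times=(2.0, 8.0, 24.0), doses=("control", "low", "middle", "high"),
             reps=2):
    rows = []
    for t in times:
        for d in doses:
            for r in range(reps):
                rows.append(dict(sample_id=f"{d}_{t}_{r}", compound="C1",
                                 dose_level=d, time_h=t, replicate=r + 1,
                                 batch=f"C1_{t}", is_negative_control=False))
    return pd.DataFrame(rows)


class TestTimeDesign:
    def test_column_count_and_order(self):
        design = build_time_design(_samples(), degree=2)
        assert list(design.matrix.columns) == [
            "intercept", "t", "t2",
            "dose_low", "dose_middle", "dose_high",
            "dose_low:t", "dose_middle:t", "dose_high:t",
            "dose_low:t2", "dose_middle:t2", "dose_high:t2",
        ]
        assert design.matrix.shape[1] == 12
        assert np.linalg.matrix_rank(design.matrix.to_numpy()) == 12

    def test_degree_bounded_by_timepoints(self):
        design = build_time_design(_samples(times=(2.0, 8.0)), degree=1)
        assert "t2" not in design.matrix.columns
        with pytest.raises(DesignError, match="degree"):
            build_time_design(_samples(times=(2.0, 8.0)), degree=2)

    def test_control_reference_coding(self):
        design = build_time_design(_samples(doses=("control",)), degree=2)
        dose_cols = [c for c in design.matrix.columns if c.startswith("dose_")]
        assert dose_cols == []


class TestGlobalFit:
    def test_constant_y_gives_p_one(self):
        design = build_time_design(_samples(), degree=2)
        assert tt.global_fit(np.full(24, 3.0), design) == 1.0

    def test_exact_fit_gives_p_zero(self):
        design = build_time_design(_samples(), degree=2)
        y = design.matrix["t"].to_numpy() * 2.0 + 1.0
        assert tt.global_fit(y, design) < 1e-12

    def test_null_p_values_uniform(self, rng):
        """Under Gaussian noise the F-test p is uniform (simulation oracle)."""
        design = build_time_design(_samples(), degree=2)
        X = design.matrix.to_numpy()
        Y = rng.normal(size=(2000, X.shape[0]))
        p, _ = global_fits(Y, X)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_single_fit_matches_vectorised(self, rng):
        design = build_time_design(_samples(), degree=2)
        X = design.matrix.to_numpy()
        Y = rng.normal(size=(5, X.shape[0]))
        p_vec, _ = global_fits(Y, X)
        for i in range(5):
            assert tt.global_fit(Y[i], design) == pytest.approx(p_vec[i], rel=1e-9)


class TestFdrBh:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(tt.fdr_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_degenerate_cases(self):
        np.testing.assert_allclose(tt.fdr_bh([1.0, 1.0]), [1.0, 1.0])
        np.testing.assert_allclose(tt.fdr_bh([0.2]), [0.2])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        q = tt.fdr_bh(pvals)
        q_perm = tt.fdr_bh([pvals[i] for i in perm])
        np.testing.assert_allclose([q[i] for i in perm], q_perm, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            tt.fdr_bh([-0.1])


class TestBackwardStepwise:
    def test_noise_free_time_trend_selected(self):
        design = build_time_design(_samples(), degree=2)
        y = 1.0 + 3.0 * design.matrix["t"].to_numpy()
        terms, coef, r2 = tt.backward_stepwise(y, design)
        assert terms == ["t"]
        assert r2 == pytest.approx(1.0)
        assert coef["t"] == pytest.approx(3.0)

    def test_pure_noise_usually_reduces_to_intercept(self, rng):
        """Each of the k terms survives the backward pass with probability
        ~alpha, so an intercept-only outcome is the norm."""
        design = build_time_design(_samples(), degree=2)
        empty = 0
        n_sim = 200
        for _ in range(n_sim):
            y = rng.normal(size=design.matrix.shape[0])
            terms, _, _ = tt.backward_stepwise(y, design)
            empty += not terms
        assert empty / n_sim > 0.5

    def test_matches_greedy_elimination_oracle(self, rng):
        """Independent re-implementation of the same stopping rule on
        6-column designs."""
        samples = _samples(doses=("control", "high"), reps=3)
        design = build_time_design(samples, degree=2)  # 6 columns
        assert design.matrix.shape[1] == 6

        def oracle(y):
            cols = list(design.matrix.columns)
            keep = [c for c in cols if c != "intercept"]
            while keep:
                X = design.matrix[["intercept"] + keep].to_numpy()
                n, k = X.shape
                beta, lower = np.linalg.lstsq(X, y, rcond=None)[:2]
                resid = y - X @ beta
                sigma2 = float(resid @ resid) / (n - k)
                cov = np.linalg.inv(X.T @ X) * sigma2
                pv = 2 * stats.t.sf(np.abs(beta / np.sqrt(np.diag(cov))), n - k)
                cand = [(pv[i + 1], design.term_order[c], cols.index(c), c)
                        for i, c in enumerate(keep) if pv[i + 1] > 0.05]
                if not cand:
                    break
                keep.remove(max(cand)[3])
            return keep

        for _ in range(25):
            y = rng.normal(size=design.matrix.shape[0]) + rng.choice([0, 2]) * design.matrix["t"].to_numpy()
            terms, _, _ = tt.backward_stepwise(y, design)
            assert terms == oracle(y)

    def test_selected_r2_never_exceeds_full_model_r2(self, rng):
        design = build_time_design(_samples(), degree=2)
        X = design.matrix.to_numpy()
        for _ in range(10):
            y = rng.normal(size=X.shape[0]) + rng.normal() * X[:, 1]
            _, _, r2_sel = tt.backward_stepwise(y, design)
            _, r2_full = global_fits(y[None, :], X)
            assert r2_sel <= r2_full[0] + 1e-12


class TestSelection:
    @pytest.mark.parametrize(
        "q, r2, expected",
        [(0.01, 0.59, False), (0.01, 0.95, True), (0.2, 0.99, False)],
    )
    def test_both_gates_required(self, q, r2, expected):
        fits = pd.DataFrame(
            {"gene": ["g1"], "compound": ["C1"], "p_global": [q], "q_bh": [q],
             "selected_terms": ["t"], "r_squared": [r2], "passes": [None]}
        )
        out = tt.select_time_genes(fits)
        assert (("g1" in out["C1"]) is expected)

    def test_exclusion_list_is_set_difference(self):
        assert tt.exclude_genes({"A", "B"}, {"B", "C"}) == {"A"}
        assert tt.exclude_genes({"A"}, set()) == {"A"}
        assert tt.exclude_genes({"A"}, {"A"}) == set()

    def test_single_timepoint_compound_skipped_not_errored(self):
        cfg = small_config(seed=31)
        study, _, _ = tt.generate_study(cfg)
        # first compound keeps only its 2 h samples
        keep = (study.samples["compound"] != study.compounds[0]) | (study.samples["time_h"] == 2.0)
        truncated = study.subset_samples(keep)
        fits, skipped = tt.run_timeseries(truncated, compounds=truncated.steatotic_compounds)
        assert [c for c, _ in skipped] == [study.compounds[0]]
        assert study.compounds[0] not in set(fits["compound"])

    def test_planted_genes_recovered_single_seed(self):
        """Smoke-scale recovery; the multi-seed version lives in acceptance."""
        cfg = small_config(seed=37, n_genes=400)
        study, truth, _ = tt.generate_study(cfg)
        fits, _ = tt.run_timeseries(tt.quantile_normalize(study))
        sel = tt.select_time_genes(fits)
        planted = set(truth.response_genes) | set(truth.confounder_genes)
        compound = study.steatotic_compounds[0]
        sens = len(sel[compound] & planted) / len(planted)
        spec = 1 - len(sel[compound] - planted) / (len(study.gene_ids) - len(planted))
        assert sens > 0.8 and spec > 0.9
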