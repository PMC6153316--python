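"""PAGE statistics, GFE scores and pathway trajectories."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import toxtempo as tt
from toxtempo.errors import GmtParseError
from toxtempo.genesets import GeneSetCollection

from conftest import small_config


def _series(values, prefix="g"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))], dtype=float)


class TestGmtIO:
    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection()
        coll.add("alpha", ["g1", "g2"], "first")
        coll.add("beta", ["g3"], "second")
        path = tt.write_gmt(coll, tmp_path / "sets.gmt")
        back = tt.read_gmt(path)
        assert back.sets == coll.sets and back.descriptions == coll.descriptions

    def test_parse_error_names_line(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("ok\tdesc\tg1\tg2\nbroken_line\n")
        with pytest.raises(GmtParseError, match="line 2"):
            tt.read_gmt(path)

    def test_restrict_to_measured_genes(self):
        coll = GeneSetCollection()
        coll.add("alpha", ["g1", "gX"])
        coll.add("ghost", ["gY"])
        restricted = coll.restrict_to(["g1", "g2"])
        assert restricted.sets == {"alpha": ["g1"]}


class TestPageScore:
    def test_worked_example(self):
        """Background 1..5, set {4,5}: mu=3, sigma=sqrt(2.5), Sm=4.5,
        z = 1.5*sqrt(2)/sqrt(2.5)."""
        r = tt.page_score(_series([1, 2, 3, 4, 5]), ["g3", "g4"])
        assert r.z_score == pytest.approx(1.5 * np.sqrt(2) / np.sqrt(2.5), abs=1e-9)
        assert r.m == 2 and r.mu == 3.0 and r.s_m == 4.5

    def test_whole_background_set_is_null(self, rng):
        fc = _series(rng.normal(size=40))
        r = tt.page_score(fc, list(fc.index))
        assert r.z_score == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_null_calibration_over_random_sets(self, rng):
        """z over random same-size sets is ~standard normal (permutation oracle)."""
        fc = _series(rng.normal(size=5000))
        zs = np.array([
            tt.page_score(fc, rng.choice(fc.index, size=20, replace=False)).z_score
            for _ in range(2000)
        ])
        assert -0.1 < zs.mean() < 0.1
        assert 0.9 < zs.std() < 1.1

    def test_location_equivariance(self, rng):
        fc = _series(rng.normal(size=60))
        members = list(fc.index[:10])
        z0 = tt.page_score(fc, members).z_score
        z1 = tt.page_score(fc + 7.5, members).z_score
        assert z1 == pytest.approx(z0, abs=1e-9)

    def test_degenerate_inputs(self):
        assert tt.page_score(_series([1, 2, 3]), ["nope"]).absent
        with pytest.raises(ValueError, match="sigma"):
            tt.page_score(_series([2.0, 2.0, 2.0]), ["g0"])

    def test_permutation_p_tracks_parametric_p(self, rng):
        fc = _series(rng.normal(size=500))
        members = list(fc.index[:25])
        r = tt.page_score(fc, members)
        p_perm = tt.pathway.page_permutation_p(fc, members, n_perm=2000, rng=1)
        assert abs(p_perm - r.p_value) < 0.08


class TestGfeScore:
    def test_zero_when_nothing_deregulated(self, rng):
        fc = _series(rng.normal(size=10) + 3)
        flags = pd.Series(False, index=fc.index)
        r = tt.gfe_score(fc, flags, list(fc.index))
        assert r.gfe == 0.0 and r.k_dereg == 0

    def test_fraction_times_mean(self):
        fc = _series([1.2] * 10)
        flags = pd.Series([True] * 2 + [False] * 8, index=fc.index)
        r = tt.gfe_score(fc, flags, list(fc.index))
        assert r.gfe == pytest.approx(0.24)
        assert (r.k_dereg, r.k_total) == (2, 10)

    def test_sign_carries_direction(self):
        fc = _series([-0.5] * 6)
        flags = pd.Series(True, index=fc.index)
        r = tt.gfe_score(fc, flags, list(fc.index))
        assert r.gfe == pytest.approx(-0.5)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(1, 30), st.integers(0, 2 ** 31 - 1))
    def test_identity_property(self, k_total, seed):
        rng = np.random.default_rng(seed)
        fc = _series(rng.normal(size=k_total))
        flags = pd.Series(rng.random(k_total) < 0.4, index=fc.index)
        r = tt.gfe_score(fc, flags, list(fc.index))
        assert r.gfe == (r.k_dereg / r.k_total) * r.stat_mean


@pytest.fixture(scope="module")
def run():
    cfg = small_config(seed=41, n_genes=400)
    study, truth, collection = tt.generate_study(cfg)
    norm = tt.quantile_normalize(study)
    fc = tt.compute_fold_changes(tt.average_replicates(norm))
    deg = tt.run_deg(norm)
    ste_fc = fc[fc["compound"].isin(set(study.steatotic_compounds))]
    traj = tt.gfe_trajectories(deg.table, ste_fc, collection,
                               dose_levels=study.dose_levels)
    return study, truth, collection, deg, ste_fc, traj


class TestTrajectories:

    def test_identity_holds_at_every_point(self, run):
        *_, traj = run
        lhs = traj["gfe"].to_numpy()
        rhs = (traj["k_dereg"] / traj["k_total"] * traj["stat_mean"]).to_numpy()
        np.testing.assert_array_equal(lhs, rhs)

    def test_single_compound_reduces_to_pointwise_gfe(self, run):
        study, _, collection, deg, ste_fc, traj = run
        compound = study.steatotic_compounds[0]
        point = traj[(traj["group"] == compound) & (traj["dose_level"] == "high")
                     & (traj["time_h"] == 24.0)].set_index("set")
        cond = ste_fc[(ste_fc["compound"] == compound)
                      & (ste_fc["dose_level"] == "high") & (ste_fc["time_h"] == 24.0)]
        fc_series = cond.set_index("gene")["log2fc"]
        flags = deg.table[
            (deg.table["compound"] == compound)
            & (deg.table["dose_level"] == "high") & (deg.table["time_h"] == 24.0)
        ].set_index("gene")["is_deregulated"].reindex(fc_series.index).fillna(False)
        restricted = collection.restrict_to(fc_series.index)
        for name in restricted:
            r = tt.gfe_score(fc_series, flags, restricted[name])
            assert point.loc[name, "gfe"] == pytest.approx(r.gfe, abs=1e-12)

    def test_cluster_pooling_averages_member_gfe(self, run):
        study, truth, collection, deg, ste_fc, traj = run
        labels = {c: truth.compound_clusters[c] for c in study.steatotic_compounds}
        pooled = tt.gfe_trajectories(deg.table, ste_fc, collection,
                                     grouping="cluster", cluster_labels=labels,
                                     dose_levels=study.dose_levels)
        some = pooled.iloc[0]
        members = [c for c, k in labels.items() if f"cluster{k}" == some["group"]]
        per_comp = traj[(traj["set"] == some["set"]) & traj["group"].isin(members)
                        & (traj["dose_level"] == some["dose_level"])
                        & (traj["time_h"] == some["time_h"])]
        assert some["gfe"] == pytest.approx(per_comp["gfe"].mean(), abs=1e-12)

    def test_times_ordered_ascending(self, run):
        *_, traj = run
        for _, grp in traj.groupby(["set", "group", "dose_level"], sort=False):
            assert list(grp["time_h"]) == sorted(grp["time_h"])


class TestRankPathways:
    def _results(self, z, p, names=None):
        names = names or [f"S{i}" for i in range(len(z))]
        return pd.DataFrame({"set": names, "z_score": z, "p_value": p})

    def test_filters_and_orders_by_abs_z(self):
        out = tt.rank_pathways(self._results([1.0, -3.0, 2.0], [0.01, 0.001, 0.2]))
        assert list(out["set"]) == ["S1", "S0"]

    def test_all_insignificant_gives_empty(self):
        assert tt.rank_pathways(self._results([5.0], [0.5])).empty

    def test_order_invariant_to_permutation_with_name_tiebreak(self, rng):
        z = [2.0, 2.0, -2.0, 1.5]
        p = [0.01] * 4
        base = tt.rank_pathways(self._results(z, p, ["b", "a", "c", "d"]))
        perm = rng.permutation(4)
        shuffled = self._results([z[i] for i in perm], [p[i] for i in perm],
                                 [["b", "a", "c", "d"][i] for i in perm])
        again = tt.rank_pathways(shuffled)
        assert list(base["set"]) == list(again["set"]) == ["a", "b", "c", "d"]

    def test_matches_brute_force_sort(self, rng):
        z = rng.normal(size=15)
        p = rng.random(15)
        res = self._results(z, p)
        out = tt.rank_pathways(res, p_threshold=0.3)
        brute = sorted(
            (row for _, row in res.iterrows() if row["p_value"] < 0.3),
            key=lambda r: (-abs(r["z_score"]), r["set"]),
        )
        assert list(out["set"]) == [r["set"] for r in brute]
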