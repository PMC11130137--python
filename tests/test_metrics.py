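"""Evenness, Bray-Curtis, PERMANOVA/PERMDISP and beta regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio.stats.distance import permanova as skbio_permanova

from nestwebs.metrics import (
    beta_regression,
    bray_curtis,
    evenness_table,
    permanova,
    permanova_exhaustive_f,
    permdisp,
    pielou_evenness,
    rank_abundance,
)


class TestPielou:
    def test_perfect_evenness(self):
        assert pielou_evenness([5, 5, 5, 5]).J == pytest.approx(1.0)

    def test_two_group_hand_value(self):
        # H = -(0.75 ln 0.75 + 0.25 ln 0.25) = 0.56234, ln 2 = 0.69315
        rec = pielou_evenness([75, 25])
        assert rec.H == pytest.approx(0.562335, abs=1e-6)
        assert rec.J == pytest.approx(0.811278, abs=1e-6)

    def test_single_group_flagged_undefined(self):
        rec = pielou_evenness([10])
        assert rec.S == 1
        assert rec.J is None
        assert not rec.defined

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="all counts are zero"):
            pielou_evenness([0, 0, 0])

    @given(
        counts=st.lists(st.integers(min_value=1, max_value=500), min_size=2, max_size=16),
        scale=st.integers(min_value=2, max_value=50),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_rescaling(self, counts, scale):
        a = pielou_evenness(counts)
        b = pielou_evenness([c * scale for c in counts])
        assert a.J == pytest.approx(b.J, abs=1e-12)


class TestBrayCurtis:
    def test_identical_rows_distance_zero(self):
        t = pd.DataFrame([[3, 1, 2]] * 2, index=["a", "b"])
        assert bray_curtis(t)["a", "b"] == pytest.approx(0.0)

    def test_disjoint_rows_distance_one(self):
        t = pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"])
        assert bray_curtis(t)["a", "b"] == pytest.approx(1.0)

    def test_hand_value(self):
        t = pd.DataFrame([[3, 1], [1, 3]], index=["a", "b"])
        assert bray_curtis(t)["a", "b"] == pytest.approx(0.5)

    def test_all_zero_nest_named_in_error(self):
        t = pd.DataFrame([[1, 2], [0, 0]], index=["a", "bad"])
        with pytest.raises(ValueError, match="bad"):
            bray_curtis(t)


def _toy_distances(seed=0, n=6):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    pts[: n // 2] += 1.5
    t = pd.DataFrame(np.abs(pts) + 0.1, index=[f"s{i}" for i in range(n)])
    return bray_curtis(t)


class TestPermanova:
    def test_matches_exhaustive_enumeration_on_six_samples(self):
        """Observed pseudo-F and the exact permutation p from full enumeration
        of all 6! label orderings must match the Monte-Carlo machinery."""
        d = _toy_distances(seed=1)
        labels = pd.Series(["x", "x", "x", "y", "y", "y"], index=list(d.ids))
        f_obs, p_exact = permanova_exhaustive_f(d, labels)
        res = permanova(
            d, pd.DataFrame({"g": labels}), terms=("g",), n_perm=4999, seed=0
        )
        assert res.term("g", "F") == pytest.approx(f_obs, rel=1e-10)
        assert res.term("g", "p") == pytest.approx(p_exact, abs=0.02)

    def test_single_factor_statistic_matches_skbio(self):
        d = _toy_distances(seed=2, n=10)
        labels = ["x"] * 5 + ["y"] * 5
        mine = permanova(
            d,
            pd.DataFrame({"g": labels}, index=list(d.ids)),
            terms=("g",),
            n_perm=9,
            seed=0,
        )
        theirs = skbio_permanova(d, labels, permutations=9)
        assert mine.term("g", "F") == pytest.approx(theirs["test statistic"], rel=1e-6)

    def test_r2_terms_plus_residual_sum_to_one(self, preset_dataset):
        d = bray_curtis(preset_dataset.abundance_table())
        design = preset_dataset.metadata_table()
        res = permanova(d, design, n_perm=49, seed=1)
        total = sum(v["R2"] for v in res.terms.values()) + res.residual["R2"]
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_p_never_zero(self):
        d = _toy_distances(seed=3)
        labels = pd.Series(["x", "x", "x", "y", "y", "y"], index=list(d.ids))
        res = permanova(d, pd.DataFrame({"g": labels}), terms=("g",), n_perm=99, seed=0)
        assert res.term("g", "p") > 0

    def test_no_signal_gives_small_r2_large_p(self):
        rng = np.random.default_rng(5)
        t = pd.DataFrame(rng.poisson(20, size=(20, 6)), index=[f"s{i}" for i in range(20)])
        d = bray_curtis(t)
        labels = pd.Series(["x", "y"] * 10, index=t.index)
        res = permanova(d, pd.DataFrame({"g": labels}), terms=("g",), n_perm=199, seed=0)
        assert res.term("g", "R2") < 0.15
        assert res.term("g", "p") > 0.1

    def test_default_999_permutations(self):
        d = _toy_distances(seed=1)
        labels = pd.Series(["x", "x", "x", "y", "y", "y"], index=list(d.ids))
        res = permanova(d, pd.DataFrame({"g": labels}), terms=("g",), seed=0)
        assert res.n_permutations == 999

    def test_constant_predictor_rejected(self):
        d = _toy_distances(seed=1)
        design = pd.DataFrame({"g": ["x"] * 6}, index=list(d.ids))
        with pytest.raises(ValueError, match="constant predictor"):
            permanova(d, design, terms=("g",), n_perm=9, seed=0)

    def test_mismatched_ids_rejected(self):
        d = _toy_distances(seed=1)
        design = pd.DataFrame({"g": ["x", "y"] * 3}, index=[f"z{i}" for i in range(6)])
        with pytest.raises(ValueError, match="do not match"):
            permanova(d, design, terms=("g",), n_perm=9, seed=0)


class TestPermdisp:
    def test_identical_point_clouds_equal_dispersion(self):
        # two groups with the same multiset of profiles: dispersions equal
        rng = np.random.default_rng(0)
        a = np.abs(rng.normal(size=(12, 3))) + 0.5
        t = pd.DataFrame(np.vstack([a, a]), index=[f"s{i}" for i in range(24)])
        d = bray_curtis(t)
        groups = pd.Series(["x"] * 12 + ["y"] * 12, index=t.index)
        out = permdisp(d, groups, n_perm=199, seed=0)
        assert out["F"] == pytest.approx(0.0, abs=1e-9)
        assert out["p"] > 0.5

    def test_inflated_group_detected(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(15, 3)) * 0.1
        wide = rng.normal(size=(15, 3)) * 1.5
        t = pd.DataFrame(np.abs(np.vstack([base + 5, wide + 5])) + 0.1,
                         index=[f"s{i}" for i in range(30)])
        d = bray_curtis(t)
        groups = pd.Series(["tight"] * 15 + ["wide"] * 15, index=t.index)
        out = permdisp(d, groups, n_perm=999, seed=0)
        assert out["p"] < 0.05

    def test_zero_permutations_rejected(self):
        d = _toy_distances()
        groups = pd.Series(["x", "x", "x", "y", "y", "y"], index=list(d.ids))
        with pytest.raises(ValueError, match="n_perm"):
            permdisp(d, groups, n_perm=0)

    def test_singleton_group_rejected(self):
        d = _toy_distances()
        groups = pd.Series(["x", "x", "x", "x", "x", "y"], index=list(d.ids))
        with pytest.raises(ValueError, match="singleton"):
            permdisp(d, groups, n_perm=9)


def _simulate_beta(n, beta_age, seed, phi=40.0):
    rng = np.random.default_rng(seed)
    age = rng.integers(0, 2, size=n)
    conn = rng.poisson(1.5, size=n)
    eta = -0.3 + beta_age * age + 0.0 * conn
    mu = 1 / (1 + np.exp(-eta))
    y = rng.beta(mu * phi, (1 - mu) * phi)
    design = pd.DataFrame({"age_class": np.where(age == 1, "old", "new"),
                           "connectivity": conn})
    return pd.Series(y, index=design.index), design


class TestBetaRegression:
    def test_recovers_generating_age_coefficient(self):
        y, design = _simulate_beta(n=200, beta_age=0.8, seed=0)
        fit = beta_regression(y, design)
        est = fit.coef("age_class[T.old]")
        assert est == pytest.approx(0.8, abs=0.15)

    def test_null_rejection_rate_near_alpha(self):
        hits = 0
        n_sim = 100
        for s in range(n_sim):
            y, design = _simulate_beta(n=60, beta_age=0.0, seed=1000 + s)
            fit = beta_regression(y, design, formula_terms=("age_class",))
            hits += fit.wald_p["age_class[T.old]"] < 0.05
        assert 0 <= hits / n_sim <= 0.12

    def test_boundary_response_shrunk_and_flagged(self):
        y, design = _simulate_beta(n=50, beta_age=0.5, seed=3)
        y.iloc[0] = 1.0
        fit = beta_regression(y, design)
        assert fit.shrunk
        assert fit.converged

    def test_out_of_range_response_rejected(self):
        y, design = _simulate_beta(n=30, beta_age=0.0, seed=4)
        y.iloc[0] = 1.2
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            beta_regression(y, design)


class TestRankAbundance:
    def _ds(self, rows, ages):
        import dataclasses

        import nestwebs as nw

        base = nw.generate_dataset(nw.preset_studylike(seed=0))
        gids = base.group_ids[: len(rows[0])]
        nests = tuple(
            dataclasses.replace(
                base.nests[i],
                nest_id=f"n{i}",
                age_class=ages[i],
                abundance={g: c for g, c in zip(gids, row)},
            )
            for i, row in enumerate(rows)
        )
        return dataclasses.replace(base, catalog=base.catalog[: len(gids)], nests=nests)

    def test_single_nest_equal_counts_se_undefined(self):
        ds = self._ds([[2, 2]], ["new"])
        out = rank_abundance(ds, by_age=False)
        assert set(out["mean_rel_abundance"]) == {0.5}
        assert out["se"].isna().all()

    def test_two_nest_hand_values(self):
        ds = self._ds([[1, 3], [3, 1]], ["new", "new"])
        out = rank_abundance(ds, by_age=False)
        assert set(out["mean_rel_abundance"].round(12)) == {0.5}
        assert set(out["se"].round(12)) == {0.25}

    def test_ties_broken_by_group_id(self):
        ds = self._ds([[2, 2, 2]], ["new"])
        out = rank_abundance(ds, by_age=False)
        assert list(out.sort_values("rank")["group"]) == sorted(out["group"])

    def test_empty_age_class_rejected(self):
        ds = self._ds([[1, 2], [2, 1]], ["new", "new"])
        with pytest.raises(ValueError, match="empty age class"):
            rank_abundance(ds, by_age=True)

    def test_study_pattern_obligates_climb_ranks_in_old_nests(self, preset_dataset):
        out = rank_abundance(preset_dataset, by_age=True)
        obligate = {g.id for g in preset_dataset.catalog if g.association.value == "obligate"}
        mean_by = out.assign(obl=out["group"].isin(obligate)).groupby(
            ["age_class", "obl"]
        )["mean_rel_abundance"].sum()
        assert mean_by["old", True] > mean_by["new", True]
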