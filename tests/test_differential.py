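"""F-gated Student/Welch differential statistic, BH-FDR, candidate ranking
and activity-profile grouping, checked against formula-level oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hepatoregulon as hr
from hepatoregulon.differential import (
    bh_fdr,
    differential_regulons,
    group_regulons,
    log2_activity_fc,
    overlap_and_rank,
    two_sample_test,
    variance_gate,
)
from tests.conftest import truth_regulons


def oracle_stats(x, y, alpha_var=0.05):
    """Independent recomputation of the F gate and both t branches from the
    textbook formulas (only distribution CDFs come from scipy)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx = ((x - x.mean()) ** 2).sum() / (nx - 1)
    vy = ((y - y.mean()) ** 2).sum() / (ny - 1)
    f = vx / vy
    cdf = stats.f.cdf(f, nx - 1, ny - 1)
    f_p = min(1.0, 2 * min(cdf, 1 - cdf))
    if f_p > alpha_var:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
        df = nx + ny - 2
    else:
        se2 = vx / nx + vy / ny
        t = (x.mean() - y.mean()) / np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return f, f_p, t, p


class TestVarianceGate:
    def test_identical_groups(self):
        f, p, eq = variance_gate([1, 2, 3], [1, 2, 3])
        assert (f, p, eq) == (1.0, 1.0, True)

    def test_worked_variance_ratio(self):
        f, p, eq = variance_gate([0, 0, 1, 1], [0, 4, 8])
        assert f == pytest.approx(1 / 48)
        dist = stats.f(3, 2)
        assert p == pytest.approx(min(1, 2 * min(dist.cdf(1 / 48), dist.sf(1 / 48))))
        assert eq is False

    def test_swap_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.normal(size=4), rng.normal(size=5) * 2
            f1, p1, _ = variance_gate(x, y)
            f2, p2, _ = variance_gate(y, x)
            assert f2 == pytest.approx(1 / f1)
            assert p2 == pytest.approx(p1)

    def test_zero_variance_branches(self):
        assert variance_gate([1, 1, 1], [2, 2, 2]) == (1.0, 1.0, True)
        _, p, eq = variance_gate([1, 1, 1], [0, 4, 8])
        assert (p, eq) == (0.0, False)


class TestTwoSampleTest:
    def test_pooled_worked_example(self):
        t, p = two_sample_test([1, 2, 3], [3, 4, 5], equal_var=True)
        assert t == pytest.approx(-2.449489742783178, abs=1e-9)
        assert p == pytest.approx(0.07048, abs=1e-4)

    def test_identical_groups(self):
        assert two_sample_test([1, 2, 3], [1, 2, 3], True) == (pytest.approx(0.0), pytest.approx(1.0))
        assert two_sample_test([2, 2, 2], [2, 2, 2], True) == (0.0, 1.0)

    def test_welch_satterthwaite_oracle(self):
        x, y = [0, 0, 0.1], [5, 9, 13]
        t, p = two_sample_test(x, y, equal_var=False)
        _, _, t_o, p_o = oracle_stats(x, y, alpha_var=1.1)  # force Welch branch
        assert t == pytest.approx(t_o, rel=1e-12)
        assert p == pytest.approx(p_o, rel=1e-12)

    def test_statistic_oracle_on_500_random_instances(self):
        rng = np.random.default_rng(123)
        checked = 0
        for _ in range(500):
            nx, ny = rng.integers(2, 8), rng.integers(2, 8)
            x = rng.normal(0, rng.uniform(0.5, 3), nx)
            y = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 3), ny)
            f_o, fp_o, t_o, p_o = oracle_stats(x, y)
            f, fp, eq = variance_gate(x, y)
            t, p = two_sample_test(x, y, eq)
            assert f == pytest.approx(f_o, rel=1e-10)
            assert fp == pytest.approx(fp_o, rel=1e-10)
            assert t == pytest.approx(t_o, rel=1e-10)
            assert p == pytest.approx(p_o, rel=1e-10)
            checked += 1
        assert checked == 500


class TestFoldChangeAndFDR:
    @pytest.mark.parametrize(
        "x, y, expected",
        [([2, 2], [4, 4], 1.0), ([3, 3], [3, 3], 0.0), ([0.2, 0.2], [0.05, 0.05], -2.0)],
    )
    def test_log2_fold_change(self, x, y, expected):
        assert log2_activity_fc(x, y) == pytest.approx(expected, abs=1e-12)

    def test_both_means_zero_flagged_as_zero(self):
        assert log2_activity_fc([0, 0], [0, 0]) == 0.0

    def test_bh_worked_examples(self):
        assert bh_fdr([0.5]) == pytest.approx([0.5])
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])
        assert bh_fdr([0.04, 0.01]) == pytest.approx([0.04, 0.02])

    def test_bh_permutation_invariance_and_floor(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=25)
        adj = bh_fdr(p)
        perm = rng.permutation(25)
        assert bh_fdr(p[perm]) == pytest.approx(adj[perm])
        assert adj.min() >= p.min() - 1e-15
        assert np.all((adj >= 0) & (adj <= 1))


def _activity_from(values: pd.DataFrame, stage_order) -> hr.ActivityMatrix:
    stage_of = pd.Series({s: s.split("_")[0] for s in values.columns})
    return hr.ActivityMatrix(values=values, stage_of=stage_of, stage_order=stage_order, top_fraction=0.5)


class TestDifferentialRegulons:
    def test_constant_activity_row_is_ns_with_zero_fc(self):
        samples = [f"{st}_r{i}" for st in ("A", "B") for i in (1, 2, 3)]
        values = pd.DataFrame(
            {"R1": [0.5] * 6, "R2": [0.1, 0.2, 0.15, 0.8, 0.9, 0.85]}, index=samples
        ).T
        table = differential_regulons(_activity_from(values, ["A", "B"]), "A", "B")
        assert table.loc["R1", "direction"] == "ns"
        assert table.loc["R1", "log2_fc"] == 0.0
        assert table.loc["R2", "direction"] == "up_in_b"

    def test_planted_direction_flips_between_transitions(self, zero_noise_dataset):
        ds = zero_noise_dataset
        act = hr.score_activity(ds.expression, truth_regulons(ds.truth), 0.5, seed=0)
        s1, s2, s3 = ds.expression.stage_order
        d1 = differential_regulons(act, s1, s2)
        d2 = differential_regulons(act, s2, s3)
        for tf in ds.truth.differential_tfs_up:
            assert d1.loc[tf, "direction"] == "up_in_b"
            assert d2.loc[tf, "direction"] == "down_in_b"
        for tf in ds.truth.differential_tfs_down:
            assert d1.loc[tf, "direction"] == "down_in_b"
            assert d2.loc[tf, "direction"] == "up_in_b"

    def test_missing_stage_rejected(self):
        samples = [f"{st}_r{i}" for st in ("A", "B") for i in (1, 2)]
        values = pd.DataFrame({"R1": [0.1, 0.2, 0.3, 0.4]}, index=samples).T
        with pytest.raises(ValueError, match="absent"):
            differential_regulons(_activity_from(values, ["A", "B"]), "A", "C")


def _diff_table(rows: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index")


class TestOverlapAndRank:
    def make(self, t1, t2, alpha=0.05):
        def direction(fc, fdr):
            if fdr <= alpha and fc != 0:
                return "up_in_b" if fc > 0 else "down_in_b"
            return "ns"

        d1 = _diff_table({r: {"log2_fc": f, "fdr": q, "direction": direction(f, q)} for r, (f, q) in t1.items()})
        d2 = _diff_table({r: {"log2_fc": f, "fdr": q, "direction": direction(f, q)} for r, (f, q) in t2.items()})
        return d1, d2

    def test_empty_overlap_gives_empty_rankings(self):
        d1, d2 = self.make({"R1": (1.0, 0.5)}, {"R1": (-1.0, 0.5)})
        prog, mat = overlap_and_rank(d1, d2)
        assert prog.top == [] and mat.top == []

    def test_same_sign_regulons_excluded(self):
        d1, d2 = self.make({"R1": (1.0, 0.01)}, {"R1": (1.0, 0.01)})
        prog, mat = overlap_and_rank(d1, d2)
        assert len(prog.table) == 0 and len(mat.table) == 0

    def test_combined_score_orders_candidates(self):
        d1, d2 = self.make(
            {"R1": (2.0, 1e-4), "R2": (1.0, 0.04), "R3": (-1.5, 1e-3)},
            {"R1": (-2.0, 1e-4), "R2": (-1.0, 0.04), "R3": (1.5, 1e-3)},
        )
        prog, mat = overlap_and_rank(d1, d2, top_k=1)
        assert list(prog.table.index) == ["R1", "R2"]
        assert prog.top == ["R1"]
        assert mat.top == ["R3"]
        expected = 2 * (-np.log10(1e-4) * 2.0)
        assert prog.table.loc["R1", "combined_score"] == pytest.approx(expected)

    def test_rank_product_scorer_available(self):
        d1, d2 = self.make(
            {"R1": (2.0, 1e-4), "R2": (1.0, 0.04)}, {"R1": (-2.0, 1e-4), "R2": (-1.0, 0.04)}
        )
        prog, _ = overlap_and_rank(d1, d2, scorer="rank_product")
        assert list(prog.table.index) == ["R1", "R2"]
        with pytest.raises(ValueError, match="scorer"):
            overlap_and_rank(d1, d2, scorer="bogus")


class TestGrouping:
    def archetype_activity(self, reps=5, eps=0.0):
        # four stage-profiles: mature-flanked, flat-ish, late, progenitor-peaked
        archetypes = {
            "mat": [0.9, 0.1, 0.9],
            "flat": [0.5, 0.52, 0.48],
            "late": [0.1, 0.2, 0.9],
            "prog": [0.1, 0.9, 0.1],
        }
        samples = [f"{st}_r{i}" for st in ("S1", "S2", "S3") for i in (1, 2)]
        rows = {}
        rng = np.random.default_rng(0)
        for name, prof in archetypes.items():
            for j in range(reps):
                noise = rng.normal(0, eps, 6) if eps else 0
                rows[f"{name}{j}"] = np.clip(np.repeat(prof, 2) + noise, 0, 1)
        values = pd.DataFrame(rows, index=samples).T
        return _activity_from(values, ["S1", "S2", "S3"])

    def test_four_archetypes_form_pure_ordered_clusters(self):
        act = self.archetype_activity()
        groups = group_regulons(act, k=4, seed=0)
        by_arch = {name: {groups[f"{name}{j}"] for j in range(5)} for name in ("mat", "flat", "late", "prog")}
        assert all(len(g) == 1 for g in by_arch.values())
        assert by_arch["mat"] == {"G1"}  # lowest progenitor-stage centroid
        assert by_arch["prog"] == {"G4"}  # highest progenitor-stage centroid

    def test_duplicated_rows_share_a_group(self):
        act = self.archetype_activity(eps=0.02)
        dup = act.values.copy()
        dup.loc["prog0_copy"] = dup.loc["prog0"]
        act2 = _activity_from(dup, ["S1", "S2", "S3"])
        groups = group_regulons(act2, k=4, seed=1)
        assert groups["prog0"] == groups["prog0_copy"]

    def test_affine_rescaling_of_a_row_does_not_change_groups(self):
        act = self.archetype_activity(eps=0.02)
        scaled = act.values.copy()
        scaled.loc["mat0"] = scaled.loc["mat0"] * 0.5 + 0.2  # z-scores unchanged
        groups_a = group_regulons(act, k=4, seed=2)
        groups_b = group_regulons(_activity_from(scaled, ["S1", "S2", "S3"]), k=4, seed=2)
        assert (groups_a == groups_b).all()

    def test_too_few_distinct_profiles_suggests_smaller_k(self):
        samples = [f"{st}_r{i}" for st in ("S1", "S2", "S3") for i in (1, 2)]
        values = pd.DataFrame({f"R{i}": np.tile([0.1, 0.9, 0.1], 2)[[0, 3, 1, 4, 2, 5]] for i in range(6)}, index=samples).T
        with pytest.raises(ValueError, match="smaller k"):
            group_regulons(_activity_from(values, ["S1", "S2", "S3"]), k=4, seed=0)
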