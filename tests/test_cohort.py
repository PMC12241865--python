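import itertools
import math

import numpy as np
import pandas as pd
import pytest

from hervwha.cohort import (
    CohortError,
    PresenceMatrix,
    anova_tukey,
    compare_groups,
    compare_host_genes,
    compare_windows_ttest,
    pangenome_filter,
    set_summary,
    shared_loci,
)


# ---------------------------------------------------------------------------
# helpers / oracles
# ---------------------------------------------------------------------------

def random_matrix(rng, n_samples=10, n_regions=20, p_positive=0.3, cohorts=None):
    samples = [f"S{i}" for i in range(n_samples)]
    regions = [f"R{j}" for j in range(n_regions)]
    status = pd.DataFrame(
        rng.random((n_samples, n_regions)) < p_positive,
        index=samples, columns=regions,
    )
    windows = pd.DataFrame(
        rng.integers(0, 30, (n_samples, n_regions)), index=samples, columns=regions
    )
    depth = pd.DataFrame(
        rng.random((n_samples, n_regions)) * 10, index=samples, columns=regions
    )
    if cohorts is None:
        cohorts = ["a"] * (n_samples // 2) + ["b"] * (n_samples - n_samples // 2)
    return PresenceMatrix(
        status=status, windows=windows, depth=depth,
        cohorts=pd.Series(cohorts, index=samples),
    )


def brute_pangenome(matrix, controls, patients):
    out = []
    for region in matrix.region_ids:
        ok = all(not matrix.status.loc[s, region] for s in controls)
        ok = ok and any(matrix.status.loc[s, region] for s in patients)
        if ok:
            out.append(region)
    return out


def brute_set_summary(matrix, a_ids, b_ids):
    pos = lambda ids: {
        r for r in matrix.region_ids
        if any(matrix.status.loc[s, r] for s in ids)
    }
    pa, pb = pos(a_ids), pos(b_ids)
    return sorted(pa - pb), sorted(pb - pa), sorted(pa & pb)


def welch_closed_form(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    from scipy.stats import t as tdist
    return t, 2 * tdist.sf(abs(t), df)


def anova_f_closed_form(groups):
    all_values = np.concatenate([np.asarray(g, float) for g in groups])
    grand = all_values.mean()
    k = len(groups)
    n = len(all_values)
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    f = (ssb / (k - 1)) / (ssw / (n - k))
    from scipy.stats import f as fdist
    return f, fdist.sf(f, k - 1, n - k)


# ---------------------------------------------------------------------------
# presence-matrix set operations
# ---------------------------------------------------------------------------

class TestPangenomeFilter:
    def test_single_positive_control_excludes_region(self, rng):
        m = random_matrix(rng, 6, 3, p_positive=0.0)
        m.status.loc["S0", "R1"] = True   # one positive control
        m.status.loc["S5", "R1"] = True
        m.status.loc["S5", "R2"] = True
        retained = pangenome_filter(m, ["S0", "S1", "S2"], ["S3", "S4", "S5"])
        assert retained == ["R2"]

    def test_one_positive_patient_suffices(self, rng):
        m = random_matrix(rng, 4, 2, p_positive=0.0)
        m.status.loc["S3", "R0"] = True
        assert pangenome_filter(m, ["S0", "S1"], ["S2", "S3"]) == ["R0"]

    def test_matches_brute_force_on_fuzzed_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(120):
            n_s = int(rng.integers(4, 20))
            m = random_matrix(rng, n_s, int(rng.integers(2, 50)), 0.3)
            cut = int(rng.integers(1, n_s))
            controls = m.sample_ids[:cut]
            patients = m.sample_ids[cut:]
            assert pangenome_filter(m, controls, patients) == brute_pangenome(
                m, controls, patients
            )

    def test_validates_group_ids(self, rng):
        m = random_matrix(rng, 4, 3)
        with pytest.raises(CohortError, match="both groups"):
            pangenome_filter(m, ["S0", "S1"], ["S1", "S2"])
        with pytest.raises(CohortError, match="unknown"):
            pangenome_filter(m, ["S0"], ["NOPE"])
        with pytest.raises(CohortError, match="non-empty"):
            pangenome_filter(m, [], ["S0"])


class TestSharedLoci:
    def test_single_sample_group_returns_its_positive_set(self, rng):
        m = random_matrix(rng, 5, 10)
        expected = [r for r in m.region_ids if m.status.loc["S2", r]]
        assert shared_loci(m, ["S2"]) == expected

    def test_disjoint_positives_intersect_to_nothing(self, rng):
        m = random_matrix(rng, 2, 4, p_positive=0.0)
        m.status.loc["S0", "R0"] = True
        m.status.loc["S1", "R1"] = True
        assert shared_loci(m, ["S0", "S1"]) == []

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            m = random_matrix(rng, int(rng.integers(2, 15)), int(rng.integers(2, 40)), 0.5)
            group = m.sample_ids[: int(rng.integers(1, len(m.sample_ids) + 1))]
            brute = [
                r for r in m.region_ids
                if all(m.status.loc[s, r] for s in group)
            ]
            assert shared_loci(m, group) == brute


class TestSetSummary:
    def test_identical_positive_sets(self, rng):
        m = random_matrix(rng, 2, 6, p_positive=0.0)
        for r in ["R0", "R3"]:
            m.status.loc["S0", r] = True
            m.status.loc["S1", r] = True
        out = set_summary(m, ["S0"], ["S1"])
        assert (out["n_unique_a"], out["n_unique_b"], out["n_shared"]) == (0, 0, 2)

    def test_fully_disjoint_sets_share_nothing(self, rng):
        m = random_matrix(rng, 2, 4, p_positive=0.0)
        m.status.loc["S0", "R0"] = True
        m.status.loc["S1", "R1"] = True
        out = set_summary(m, ["S0"], ["S1"])
        assert out["n_shared"] == 0
        assert out["unique_a"] == ["R0"] and out["unique_b"] == ["R1"]

    def test_matches_brute_force_and_conserves_counts(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n_s = int(rng.integers(4, 16))
            m = random_matrix(rng, n_s, int(rng.integers(2, 50)), 0.4)
            cut = int(rng.integers(1, n_s))
            a_ids, b_ids = m.sample_ids[:cut], m.sample_ids[cut:]
            out = set_summary(m, a_ids, b_ids)
            ua, ub, sh = brute_set_summary(m, a_ids, b_ids)
            assert sorted(out["unique_a"]) == ua
            assert sorted(out["unique_b"]) == ub
            assert sorted(out["shared"]) == sh
            n_pos_a = int(m.status.loc[a_ids].any(axis=0).sum())
            assert out["n_unique_a"] + out["n_shared"] == n_pos_a

    def test_rejects_overlapping_groups(self, rng):
        m = random_matrix(rng, 4, 3)
        with pytest.raises(CohortError, match="disjoint"):
            set_summary(m, ["S0", "S1"], ["S1", "S2"])


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

class TestWelch:
    def test_identical_samples_give_t0_p1(self):
        out = compare_windows_ttest([1, 2, 3], [1, 2, 3])
        assert out.statistic == pytest.approx(0.0)
        assert out.p_value == pytest.approx(1.0)
        assert not out.significant

    def test_matches_closed_form_example(self):
        out = compare_windows_ttest([10, 11, 12], [1, 2, 3])
        t, p = welch_closed_form([10, 11, 12], [1, 2, 3])
        assert out.statistic == pytest.approx(t, abs=1e-10)
        assert out.p_value == pytest.approx(p, abs=1e-10)
        assert out.significant

    def test_matches_closed_form_on_fuzzed_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), int(rng.integers(2, 30)))
            b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), int(rng.integers(2, 30)))
            out = compare_windows_ttest(list(a), list(b))
            t, p = welch_closed_form(a, b)
            assert out.statistic == pytest.approx(t, abs=1e-8)
            assert out.p_value == pytest.approx(p, abs=1e-8)

    def test_zero_variance_contracts(self):
        out = compare_windows_ttest([5, 5, 5], [5, 5])
        assert (out.statistic, out.p_value) == (0.0, 1.0)
        out = compare_windows_ttest([5, 5, 5], [7, 7])
        assert out.p_value == 0.0 and out.statistic == -np.inf

    def test_small_group_is_an_error_naming_the_group(self):
        with pytest.raises(CohortError, match="'b'"):
            compare_windows_ttest([1, 2, 3], [1], group_b="b")


class TestAnovaTukey:
    def test_constant_groups_report_no_effect(self):
        out = anova_tukey({"g1": [2, 2], "g2": [2, 2], "g3": [2, 2]})
        assert (out.statistic, out.p_value) == (0.0, 1.0)
        assert all(p == 1.0 and not sig for _, _, p, sig in out.pairwise)

    def test_f_matches_closed_form_textbook_case(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0], "c": [6.0, 7.0, 8.0]}
        out = anova_tukey(groups)
        f, p = anova_f_closed_form(list(groups.values()))
        assert out.statistic == pytest.approx(f, abs=1e-10)
        assert out.p_value == pytest.approx(p, abs=1e-10)

    def test_f_matches_closed_form_on_fuzzed_inputs(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            k = int(rng.integers(2, 6))
            groups = {
                f"g{i}": list(rng.normal(rng.uniform(-3, 3), 1.0, int(rng.integers(2, 15))))
                for i in range(k)
            }
            out = anova_tukey(groups)
            f, p = anova_f_closed_form(list(groups.values()))
            assert out.statistic == pytest.approx(f, abs=1e-8)
            assert out.p_value == pytest.approx(p, abs=1e-8)

    def test_tukey_pairs_invariant_to_relabeling(self):
        groups = {"x": [1.0, 2.0, 2.5], "y": [4.0, 5.0, 4.5], "z": [9.0, 8.0, 8.5]}
        out1 = anova_tukey(groups)
        relabeled = {"z": groups["z"], "y": groups["y"], "x": groups["x"]}
        out2 = anova_tukey(relabeled)
        p1 = {frozenset((g1, g2)): p for g1, g2, p, _ in out1.pairwise}
        p2 = {frozenset((g1, g2)): p for g1, g2, p, _ in out2.pairwise}
        assert p1.keys() == p2.keys()
        for key in p1:
            assert p1[key] == pytest.approx(p2[key], abs=1e-10)

    def test_requires_two_values_per_group(self):
        with pytest.raises(CohortError, match="'b'"):
            anova_tukey({"a": [1, 2], "b": [3]})


class TestCompareGroups:
    def test_positive_only_excludes_negative_samples(self, rng):
        m = random_matrix(rng, 6, 1, p_positive=0.0,
                          cohorts=["a"] * 3 + ["b"] * 3)
        m.windows.loc[:, "R0"] = [10, 11, 0, 20, 21, 0]
        m.status.loc[:, "R0"] = [True, True, False, True, True, False]
        frame = compare_groups(m, ["S0", "S1", "S2"], ["S3", "S4", "S5"])
        assert frame.loc[0, "n_a"] == 2 and frame.loc[0, "n_b"] == 2
        assert frame.loc[0, "mean_a"] == pytest.approx(10.5)

    def test_bh_correction_adds_adjusted_column(self, rng):
        m = random_matrix(rng, 10, 8, p_positive=1.0)
        frame = compare_groups(
            m, m.sample_ids[:5], m.sample_ids[5:], correction="bh"
        )
        assert "p_adjusted" in frame.columns
        assert (frame["p_adjusted"] >= frame["p_value"] - 1e-12).all()

    def test_skips_regions_without_enough_positive_samples(self, rng):
        m = random_matrix(rng, 6, 2, p_positive=0.0)
        frame = compare_groups(m, m.sample_ids[:3], m.sample_ids[3:])
        assert frame.empty


class TestCompareHostGenes:
    def test_amplified_gene_flagged_against_control(self, rng):
        m = random_matrix(rng, 12, 1, p_positive=1.0,
                          cohorts=["control"] * 4 + ["acute"] * 4 + ["PASC"] * 4)
        m.windows.loc[:, "R0"] = [15, 16, 15, 14, 15, 16, 14, 15, 25, 26, 25, 24]
        frame = compare_host_genes(
            m, ["R0"],
            {"control": m.sample_ids[:4], "acute": m.sample_ids[4:8],
             "PASC": m.sample_ids[8:]},
        )
        by_pair = {
            frozenset((r["group1"], r["group2"])): r["significant"]
            for _, r in frame.iterrows()
        }
        assert by_pair[frozenset(("control", "PASC"))]
        assert not by_pair[frozenset(("control", "acute"))]
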