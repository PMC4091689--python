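import itertools

import numpy as np
import pandas as pd
import pytest

from medusa.corepan import (
    PresenceMatrix,
    abundance_by_region,
    call_presence_abundance,
    call_presence_reads,
    core_sensitivity,
    core_size,
    dedupe_subjects,
    gene_richness,
    pan_core_curve,
    pan_size,
    venn_partition,
)
from medusa.model import AbundanceTable, CountTable, SampleMap
from medusa.tables import relative_abundance


def presence_from(arr, subjects=None):
    arr = np.asarray(arr, bool)
    subjects = subjects or [f"u{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=[f"f{i}" for i in range(arr.shape[0])], columns=subjects)
    return PresenceMatrix(df, rule="test")


class TestDedupeSubjects:
    def test_single_visit_subjects_identity(self):
        t = CountTable.from_arrays(["f"], ["b1"], np.array([[1]]))
        sm = SampleMap(sample_to_subject={"b1": "B"}, sample_to_visit={"b1": 1})
        out, dropped = dedupe_subjects(t, sm)
        assert out.sample_ids == ["b1"] and dropped == []

    def test_repeat_visits_removed(self, visit_map):
        t = CountTable.from_arrays(
            ["f"], ["a1", "a2", "a3", "b1"], np.array([[1, 2, 3, 4]])
        )
        out, dropped = dedupe_subjects(t, visit_map)
        assert out.sample_ids == ["a1", "b1"]
        assert sorted(dropped) == ["a2", "a3"]

    def test_no_visit1_keeps_lowest_with_warning(self, visit_map):
        t = CountTable.from_arrays(["f"], ["c2", "c3"], np.array([[1, 2]]))
        with pytest.warns(UserWarning, match="visit 2"):
            out, dropped = dedupe_subjects(t, visit_map)
        assert out.sample_ids == ["c2"] and dropped == ["c3"]

    def test_782_to_719_style_reduction(self):
        # 719 subjects, 63 of which have one extra visit
        samples, sm = [], SampleMap()
        for i in range(719):
            s = f"v1_{i}"
            samples.append(s)
            sm.sample_to_subject[s] = f"subj{i}"
            sm.sample_to_visit[s] = 1
        for i in range(63):
            s = f"v2_{i}"
            samples.append(s)
            sm.sample_to_subject[s] = f"subj{i}"
            sm.sample_to_visit[s] = 2
        t = CountTable.from_arrays(["f"], samples, np.ones((1, 782), dtype=int))
        out, dropped = dedupe_subjects(t, sm)
        assert len(out.sample_ids) == 719 and len(dropped) == 63


class TestPresence:
    def test_read_rule_boundary(self):
        t = CountTable.from_arrays(["g1", "g2"], ["s"], np.array([[1], [2]]))
        p = call_presence_reads(t, 2)
        assert not p.data.loc["g1", "s"] and p.data.loc["g2", "s"]

    def test_min_reads_zero_all_present(self):
        t = CountTable.from_arrays(["g"], ["s1", "s2"], np.array([[0, 5]]))
        assert call_presence_reads(t, 0).data.all().all()

    def test_presence_equals_elementwise_oracle(self, random_counts):
        t = random_counts(seed=2)
        p = call_presence_reads(t, 3)
        assert (p.data.to_numpy() == (t.counts >= 3)).all()

    def test_abundance_rule_is_strict(self):
        df = pd.DataFrame({"s": [1e-4, 2e-4, 1 - 3e-4]}, index=["x", "y", "z"])
        ab = AbundanceTable(df)
        p = call_presence_abundance(ab, 1e-4)
        assert not p.data.loc["x", "s"] and p.data.loc["y", "s"]
        p2 = call_presence_abundance(ab, 1e-4, strict=False)
        assert p2.data.loc["x", "s"]


class TestCoreSize:
    def test_ubiquitous_feature_always_in_core(self):
        p = presence_from(np.ones((1, 10)))
        for f in (0.1, 0.5, 0.9, 1.0):
            assert core_size(p, f) == 1

    def test_half_prevalence_boundary(self):
        rows = [[1] * 5 + [0] * 5, [1] * 4 + [0] * 6]
        p = presence_from(rows)
        assert core_size(p, 0.5) == 1  # 5/10 >= ceil(0.5*10)=5; 4 is not

    def test_fraction_one_is_intersection(self, rng):
        arr = rng.random((20, 6)) < 0.6
        p = presence_from(arr)
        assert core_size(p, 1.0) == int(arr.all(axis=1).sum())

    def test_monotone_in_fraction(self, rng):
        p = presence_from(rng.random((30, 9)) < 0.5)
        sizes = [core_size(p, f) for f in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)]
        assert sizes == sorted(sizes, reverse=True)


class TestPanCoreCurve:
    def test_n1_equals_mean_per_subject_presence(self, rng):
        arr = rng.random((25, 5)) < 0.4
        p = presence_from(arr)
        curve = pan_core_curve(p, (0.5,), n_orderings=400, seed=0)
        assert curve.pan[0] == pytest.approx(arr.sum(axis=0).mean(), abs=0.5)
        assert curve.core[0.5][0] == curve.pan[0]  # at n=1 core == pan

    def test_full_n_matches_core_size_for_every_ordering(self, rng):
        arr = rng.random((25, 6)) < 0.4
        p = presence_from(arr)
        curve = pan_core_curve(p, (0.5, 0.9), n_orderings=13, seed=1)
        assert curve.pan[-1] == pan_size(p)
        assert curve.core[0.5][-1] == core_size(p, 0.5)
        assert curve.core[0.9][-1] == core_size(p, 0.9)

    def test_matches_exhaustive_ordering_average(self, rng):
        from medusa.model import ceil_fraction

        arr = rng.random((10, 5)) < 0.5
        p = presence_from(arr)
        N = 5
        pan_exp = np.zeros(N)
        core_exp = np.zeros(N)
        perms = list(itertools.permutations(range(N)))
        for perm in perms:
            cum = arr[:, list(perm)].cumsum(axis=1)
            pan_exp += (cum > 0).sum(axis=0)
            need = np.array([ceil_fraction(0.5, n) for n in range(1, N + 1)])
            core_exp += (cum >= need[None, :]).sum(axis=0)
        pan_exp /= len(perms)
        core_exp /= len(perms)
        curve = pan_core_curve(p, (0.5,), n_orderings=3000, seed=2)
        np.testing.assert_allclose(curve.pan, pan_exp, atol=0.35)
        np.testing.assert_allclose(curve.core[0.5], core_exp, atol=0.35)

    def test_pan_nondecreasing_core_strict_nonincreasing_any_seed(self, rng):
        arr = rng.random((40, 8)) < 0.3
        p = presence_from(arr)
        for seed in range(5):
            curve = pan_core_curve(p, (1.0,), n_orderings=1, seed=seed)
            assert (np.diff(curve.pan) >= 0).all()
            assert (np.diff(curve.core[1.0]) <= 0).all()


class TestCoreSensitivity:
    def test_monotone_in_cutoff_and_edges(self, rng):
        df = pd.DataFrame(
            rng.dirichlet(np.ones(15), size=8).T,
            index=[f"sp{i}" for i in range(15)],
            columns=[f"u{j}" for j in range(8)],
        )
        ab = AbundanceTable(df)
        res = core_sensitivity(ab, [0.0, 1e-4, 1e-3, 1e-2, 0.1, 1.0], 0.5)
        assert (np.diff(res["core_size"]) <= 0).all()
        assert (np.diff(res["pan_size"]) <= 0).all()
        assert res["pan_size"].iloc[0] == int((df.to_numpy() > 0).any(axis=1).sum())
        assert res["core_size"].iloc[-1] == 0  # nothing is above abundance 1


class TestVennPartition:
    def test_all_clusters_everywhere_single_region(self):
        v = venn_partition({f"c{i}": {"A", "B", "C", "D"} for i in range(7)})
        assert v.sizes() == {frozenset("ABCD"): 7}

    def test_hand_counted_regions(self):
        members = {
            "c1": {"A"}, "c2": {"A"}, "c3": {"A", "B"},
            "c4": {"B", "C"}, "c5": {"A", "B", "C"},
        }
        v = venn_partition(members)
        assert v.sizes() == {
            frozenset("A"): 2, frozenset("AB"): 1,
            frozenset("BC"): 1, frozenset("ABC"): 1,
        }

    def test_disjoint_studies_only_singleton_regions(self):
        members = {f"{st}{i}": {st} for st in "ABCD" for i in range(3)}
        v = venn_partition(members)
        assert set(v.regions) == {frozenset(st) for st in "ABCD"}

    def test_regions_are_a_partition(self, rng):
        studies = ["A", "B", "C", "D"]
        members = {}
        for i in range(60):
            k = rng.integers(1, 5)
            members[f"c{i}"] = set(rng.choice(studies, size=k, replace=False))
        v = venn_partition(members)
        all_ids = [c for region in v.regions.values() for c in region]
        assert len(all_ids) == len(set(all_ids)) == 60

    def test_empty_study_set_rejected(self):
        with pytest.raises(ValueError):
            venn_partition({"c": set()})


class TestAbundanceByRegion:
    def test_single_region_fraction_one(self):
        t = CountTable.from_arrays(["c1", "c2"], ["s"], np.array([[10], [30]]))
        v = venn_partition({"c1": {"A"}, "c2": {"A"}})
        frac = abundance_by_region(t, v)
        assert frac.loc["A", "s"] == 1.0

    def test_two_study_toy_hand_computed(self):
        t = CountTable.from_arrays(
            ["u1", "u2", "sh"], ["s"], np.array([[20], [20], [60]])
        )
        v = venn_partition({"u1": {"A"}, "u2": {"B"}, "sh": {"A", "B"}})
        frac = abundance_by_region(t, v)
        assert frac.loc["A", "s"] == pytest.approx(0.2)
        assert frac.loc["A+B", "s"] == pytest.approx(0.6)
        # per-gene normalisation: all regions have one gene, unchanged
        norm = abundance_by_region(t, v, normalize_by_region_size=True)
        assert norm.loc["A+B", "s"] == pytest.approx(0.6)

    def test_region_size_normalisation_shifts_mass(self):
        # region A holds 2 genes with 60 reads total, region B one gene, 40 reads
        t = CountTable.from_arrays(
            ["a1", "a2", "b1"], ["s"], np.array([[30], [30], [40]])
        )
        v = venn_partition({"a1": {"A"}, "a2": {"A"}, "b1": {"B"}})
        plain = abundance_by_region(t, v)
        norm = abundance_by_region(t, v, normalize_by_region_size=True)
        assert plain.loc["A", "s"] == pytest.approx(0.6)
        # per gene: A 30 vs B 40 -> 30/70
        assert norm.loc["A", "s"] == pytest.approx(30 / 70)

    def test_all_zero_sample_stays_zero(self):
        t = CountTable.from_arrays(["c"], ["s0"], np.array([[0]]))
        v = venn_partition({"c": {"A"}})
        assert abundance_by_region(t, v)["s0"].sum() == 0


class TestGeneRichness:
    def test_all_zero_sample_zero(self):
        t = CountTable.from_arrays(["g"], ["s"], np.array([[0]]))
        assert gene_richness(t, 2).loc["s"] == 0

    def test_equals_presence_column_sums(self, random_counts):
        t = random_counts(seed=4)
        rich = gene_richness(t, 2)
        pres = call_presence_reads(t, 2)
        assert rich.equals(pres.data.sum(axis=0))

    def test_planted_richness_recovered(self):
        counts = np.zeros((10, 2), int)
        counts[:7, 0] = 5  # sample 0 carries 7 genes
        counts[:3, 1] = 2  # sample 1 carries 3
        counts[3, 1] = 1  # a 1-read gene does not count
        t = CountTable.from_arrays([f"g{i}" for i in range(10)], ["sA", "sB"], counts)
        assert gene_richness(t, 2).to_dict() == {"sA": 7, "sB": 3}
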