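import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multimorbnet.io_formats import (
    CatalogueEntry,
    DiseaseCatalogue,
    DiseaseProteinSet,
)
from multimorbnet.overlap_stats import (
    NullDistribution,
    catalogue_null,
    empirical_test,
    jaccard_pair,
    jaccard_triad,
    proteome_null,
    z_test,
)
from multimorbnet.synthetic_data import paper_tables_fixture


def dset(name, members):
    return DiseaseProteinSet(name, frozenset(members))


class TestJaccard:
    def test_identity_and_disjoint(self):
        a = dset("a", {"P1", "P2"})
        assert jaccard_pair(a, a).jaccard == 1.0
        assert jaccard_pair(a, dset("b", {"P3"})).jaccard == 0.0
        assert jaccard_triad(a, a, a).jaccard == 1.0
        assert jaccard_triad(a, dset("b", {"P3"}), dset("c", {"P4"})).jaccard == 0.0

    def test_symmetry(self):
        a, b = dset("a", {"P1", "P2", "P3"}), dset("b", {"P2", "P4"})
        assert jaccard_pair(a, b).jaccard == jaccard_pair(b, a).jaccard

    def test_printed_disease_table_values(self):
        """The encoded allergic-disease sets give 16/229 and 5/234."""
        asthma, eczema, rhinitis = paper_tables_fixture()
        pair = jaccard_pair(asthma, eczema)
        assert (pair.intersection_size, pair.union_size) == (16, 229)
        assert pair.jaccard == pytest.approx(16 / 229)
        triad = jaccard_triad(asthma, eczema, rhinitis)
        assert (triad.intersection_size, triad.union_size) == (5, 234)
        assert triad.jaccard == pytest.approx(5 / 234)

    def test_triad_via_inclusion_exclusion_oracle(self):
        rng = np.random.default_rng(0)
        universe = [f"P{i}" for i in range(60)]
        sets = [dset(n, rng.choice(universe, size=20, replace=False))
                for n in "abc"]
        res = jaccard_triad(*sets)
        # oracle: inclusion-exclusion on pairwise and triple counts
        pa, pb, pc = (set(s.proteins) for s in sets)
        inter = len(pa & pb & pc)
        union = (len(pa) + len(pb) + len(pc)
                 - len(pa & pb) - len(pa & pc) - len(pb & pc) + inter)
        assert res.intersection_size == inter
        assert res.union_size == union

    @given(st.lists(st.sets(st.integers(0, 30), min_size=1), min_size=3, max_size=3))
    @settings(max_examples=60, deadline=None)
    def test_triad_never_exceeds_pairwise(self, members):
        sets = [dset(str(i), {f"P{x}" for x in m}) for i, m in enumerate(members)]
        triad = jaccard_triad(*sets).jaccard
        for i in range(3):
            for j in range(i + 1, 3):
                assert triad <= jaccard_pair(sets[i], sets[j]).jaccard + 1e-12

    def test_empty_set_handling(self, caplog):
        a = dset("a", {"P1"})
        empty = DiseaseProteinSet("e", frozenset())
        with caplog.at_level("WARNING"):
            assert jaccard_pair(a, empty).jaccard == 0.0
        assert "empty" in caplog.text
        with pytest.raises(ValueError):
            jaccard_pair(empty, empty)


class TestProteomeNull:
    def test_forced_full_overlap(self):
        null = proteome_null([4, 10], proteome_size=10, R=50, seed=0)
        assert np.all(null.samples == 4 / 10)

    def test_single_protein_match_probability(self):
        null = proteome_null([1, 1], proteome_size=10, R=1000, seed=1)
        se = np.sqrt(0.1 * 0.9 / 1000)
        assert abs(null.samples.mean() - 0.1) < 3 * se

    def test_hypergeometric_intersection_mean(self):
        null = proteome_null([196, 49], R=1000, seed=2, statistic="intersection")
        expected = 196 * 49 / 14_754
        se = null.samples.std(ddof=1) / np.sqrt(1000)
        assert abs(null.samples.mean() - expected) < 4 * se

    def test_reproducible_under_seed(self):
        a = proteome_null([20, 30], R=50, seed=9)
        b = proteome_null([20, 30], R=50, seed=9)
        assert np.array_equal(a.samples, b.samples)

    def test_size_exceeding_proteome_rejected(self):
        with pytest.raises(ValueError):
            proteome_null([11, 2], proteome_size=10, R=10, seed=0)


class TestCatalogueNull:
    def make_catalogue(self):
        return DiseaseCatalogue([
            CatalogueEntry(dset("X", {"P1", "P2"})),
            CatalogueEntry(dset("Xchild", {"P1"}), parents=frozenset({"X"})),
            CatalogueEntry(dset("Y", {"P3", "P4"})),
        ])

    def test_descendant_pairs_never_drawn(self):
        drawn = []

        def spy(sets):
            drawn.append(frozenset(s.name for s in sets))
            return 0.0

        catalogue_null(self.make_catalogue(), k=2, R=200, seed=3, statistic=spy)
        assert frozenset({"X", "Xchild"}) not in drawn
        assert all(len(names) == 2 for names in drawn)

    def test_two_unrelated_diseases_constant(self):
        cat = DiseaseCatalogue([
            CatalogueEntry(dset("A", {"P1", "P2"})),
            CatalogueEntry(dset("B", {"P2", "P3"})),
        ])
        null = catalogue_null(cat, k=2, R=100, seed=4)
        assert np.all(null.samples == 1 / 3)

    def test_disjoint_catalogue_gives_minimal_p(self):
        cat = DiseaseCatalogue([
            CatalogueEntry(dset(f"D{i}", {f"P{i}"})) for i in range(6)
        ])
        null = catalogue_null(cat, k=2, R=999, seed=5)
        assert np.all(null.samples == 0.0)
        assert empirical_test(0.5, null).p == pytest.approx(1 / 1000)

    def test_no_valid_subset_is_an_error(self):
        cat = DiseaseCatalogue([
            CatalogueEntry(dset("X", {"P1"})),
            CatalogueEntry(dset("Xchild", {"P1"}), parents=frozenset({"X"})),
        ])
        with pytest.raises(ValueError, match="no valid"):
            catalogue_null(cat, k=2, R=10, seed=6, max_consecutive_rejects=500)


class TestTests:
    def test_z_at_null_mean_is_half(self):
        null = NullDistribution("s", np.array([0.0, 1.0, 2.0, 3.0]), "m")
        res = z_test(1.5, null)
        assert res.z == pytest.approx(0.0)
        assert res.p == pytest.approx(0.5)

    def test_empirical_add_one_rule(self):
        null = NullDistribution("s", np.linspace(0, 1, 999), "m")
        assert empirical_test(2.0, null).p == pytest.approx(1 / 1000)
        zeros = NullDistribution("s", np.zeros(1000), "m")
        assert empirical_test(0.0, zeros).p == 1.0

    def test_degenerate_null_directs_to_empirical(self):
        null = NullDistribution("s", np.zeros(100), "m")
        with pytest.raises(ValueError, match="empirical"):
            z_test(0.5, null)

    def test_calibration_empirical_p_uniform(self):
        """Resubmitted null draws give approximately uniform empirical p."""
        from scipy import stats

        null = proteome_null([300, 300], proteome_size=2000, R=1000, seed=7)
        obs = proteome_null([300, 300], proteome_size=2000, R=300, seed=8)
        ps = [empirical_test(o, null).p for o in obs.samples]
        assert stats.kstest(ps, "uniform").pvalue > 0.01
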