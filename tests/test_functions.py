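import numpy as np
import pandas as pd
import pytest

from virotyper import functions
from virotyper.synthetic import CommunitySpec, emit_scaffold_fixtures, simulate_community

from test_reads import make_hits


class TestAnnotation:
    def test_conjunctive_thresholds(self):
        assert functions.annotate_proteins(
            make_hits([("p1", "K00001", 40.0, 1e-6, 60.0)])) == {"p1": "K00001"}
        assert functions.annotate_proteins(
            make_hits([("p1", "K00001", 34.0, 1e-6, 60.0)])) == {}
        assert functions.annotate_proteins(make_hits([])) == {}


class TestCategoryProfile:
    def test_single_category_normalizes_to_protein_count(self):
        annotations = {"p1": "K1", "p2": "K2", "p3": "K3"}
        counts = pd.DataFrame({"s": [10, 20, 30]}, index=["p1", "p2", "p3"])
        mapping = {"K1": "C", "K2": "C", "K3": "C"}
        profile = functions.category_profile(annotations, counts, mapping)
        # all proteins in one category: normalized count == number of proteins
        assert profile.loc["C", "s"] == pytest.approx(3.0)

    def test_depth_rescaling_invariance(self, rng):
        proteins = [f"p{i}" for i in range(8)]
        annotations = {p: f"K{i % 3}" for i, p in enumerate(proteins)}
        mapping = {"K0": "A", "K1": "B", "K2": "C"}
        counts = pd.DataFrame({"s": rng.integers(1, 100, 8)}, index=proteins)
        p1 = functions.category_profile(annotations, counts, mapping)
        p2 = functions.category_profile(annotations, counts * 2, mapping)
        pd.testing.assert_frame_equal(p1, p2)

    def test_unmapped_identifier_goes_unclassified(self):
        profile = functions.category_profile(
            {"p1": "K_unknown"}, pd.DataFrame({"s": [5]}, index=["p1"]), {})
        assert profile.index.tolist() == ["unclassified"]

    def test_no_annotated_proteins_warns_empty(self):
        counts = pd.DataFrame({"s": [5]}, index=["p1"])
        with pytest.warns(UserWarning, match="no annotated"):
            profile = functions.category_profile({}, counts, {})
        assert profile.empty


class TestAMGProfile:
    def test_single_amg_carries_its_count(self):
        calls = pd.DataFrame({"protein_id": ["p1"], "ko": ["K00001"]})
        counts = pd.DataFrame({"s": [40]}, index=["p1"])
        profile = functions.amg_profile(calls, counts, {"K00001": "Carbohydrate metabolism"})
        assert profile.index.tolist() == ["Carbohydrate metabolism"]
        assert profile.loc["Carbohydrate metabolism", "s"] == pytest.approx(1.0)

    def test_planted_amg_categories_recovered_exactly(self):
        # noise-free: every AMG protein has count 1, mapping is exact
        calls = pd.DataFrame({"protein_id": [f"p{i}" for i in range(6)],
                              "ko": ["K1", "K1", "K1", "K2", "K2", "K3"]})
        counts = pd.DataFrame({"s": np.ones(6, dtype=int)},
                              index=[f"p{i}" for i in range(6)])
        mapping = {"K1": "A", "K2": "B", "K3": "C"}
        profile = functions.amg_profile(calls, counts, mapping)
        shares = profile["s"] / profile["s"].sum()
        assert shares.loc["A"] == pytest.approx(0.5)
        assert shares.loc["B"] == pytest.approx(2 / 6)
        assert shares.loc["C"] == pytest.approx(1 / 6)


class TestHostProfile:
    def test_single_phylum_dominates(self):
        virotypes = {"s1": "V1", "s2": "V1"}
        counts = pd.DataFrame({"a": [10, 20]}, index=["s1", "s2"])
        profile = functions.host_profile(
            virotypes, counts, virus_host={"V1": "Bacteria;Cyanobacteria"})
        assert profile.loc["Cyanobacteria", "a"] == pytest.approx(1.0)

    def test_unassigned_scaffolds_count_as_unknown(self):
        virotypes = {"s1": "V1", "s2": None}
        counts = pd.DataFrame({"a": [10, 30]}, index=["s1", "s2"])
        profile = functions.host_profile(
            virotypes, counts, virus_host={"V1": "Bacteria;Proteobacteria"})
        assert profile.loc["unknown", "a"] == pytest.approx(0.75)
        assert profile["a"].sum() == pytest.approx(1.0)

    def test_exactly_one_source_required(self):
        with pytest.raises(ValueError, match="exactly one"):
            functions.host_profile({}, pd.DataFrame({"a": [1]}, index=["s"]))

    def test_predictor_route(self):
        counts = pd.DataFrame({"a": [10, 10]}, index=["s1", "s2"])
        profile = functions.host_profile(
            {}, counts, scaffold_host={"s1": "Bacteria;Firmicutes"})
        assert profile.loc["Firmicutes", "a"] == pytest.approx(0.5)
        assert profile.loc["unknown", "a"] == pytest.approx(0.5)

    def test_planted_host_mixture_recovered(self):
        """60/30/10 phylum mixture over ~1000 scaffolds, multinomial error."""
        pool = (("Bacteria;Cyanobacteria", 0.6), ("Bacteria;Proteobacteria", 0.3),
                ("Bacteria;Bacteroidetes", 0.1))
        spec = CommunitySpec(n_virotypes=300, n_samples=2, reads_per_sample=100,
                             sdlog=0.3, sample_sdlog=0.1,
                             n_scaffolds=1000, proteins_per_scaffold=3.0,
                             majority_rate=1.0, host_pool=pool, seed=17)
        truth, _ = simulate_community(spec)
        fx = emit_scaffold_fixtures(truth, spec)
        virotypes = dict(zip(fx.scaffolds["scaffold_id"], fx.scaffolds["true_virotype"]))
        ones = pd.DataFrame({"all": np.ones(len(fx.scaffolds), dtype=int)},
                            index=fx.scaffolds["scaffold_id"])
        profile = functions.host_profile(virotypes, ones, virus_host=fx.virus_host)
        for phylum, p in [("Cyanobacteria", 0.6), ("Proteobacteria", 0.3),
                          ("Bacteroidetes", 0.1)]:
            se = np.sqrt(p * (1 - p) / len(fx.scaffolds))
            assert profile.loc[phylum, "all"] == pytest.approx(p, abs=5 * se + 0.02)
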