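"""OBO parsing, true-path propagation, hypergeometric enrichment, GO masking."""

import itertools

import numpy as np
import pytest

from lightmask import go_enrichment as goe
from lightmask import synthetic_data as sd
from lightmask.expression_qc import ValidationError


def write_obo(tmp_path, stanzas, name="test.obo"):
    lines = ["format-version: 1.2", "ontology: test"]
    for term_id, term_name, parents in stanzas:
        lines += ["", "[Term]", f"id: {term_id}", f"name: {term_name}"]
        lines += [f"is_a: {p}" for p in parents]
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\n")
    return p


class TestOboParsing:
    def test_two_term_chain(self, tmp_path):
        dag = goe.parse_obo_lite(write_obo(tmp_path, [("T:1", "root", []), ("T:2", "leaf", ["T:1"])]))
        assert len(dag) == 2
        assert dag.n_edges == 1
        assert dag.parents("T:2") == {"T:1"}

    def test_missing_parent_rejected(self, tmp_path):
        p = write_obo(tmp_path, [("T:1", "a", ["T:404"])])
        with pytest.raises(goe.DagError, match="T:404"):
            goe.parse_obo_lite(p)

    def test_diamond(self, tmp_path):
        p = write_obo(
            tmp_path,
            [("T:a", "a", []), ("T:b", "b", ["T:a"]), ("T:c", "c", ["T:a"]), ("T:d", "d", ["T:b", "T:c"])],
        )
        dag = goe.parse_obo_lite(p)
        assert len(dag) == 4 and dag.n_edges == 4
        assert dag.ancestors("T:d") == {"T:a", "T:b", "T:c"}

    def test_cycle_rejected(self, tmp_path):
        p = write_obo(tmp_path, [("T:1", "a", ["T:2"]), ("T:2", "b", ["T:1"])])
        with pytest.raises(goe.DagError, match="cycle"):
            goe.parse_obo_lite(p)

    def test_obsolete_terms_skipped(self, tmp_path):
        p = tmp_path / "obs.obo"
        p.write_text(
            "format-version: 1.2\nontology: t\n\n[Term]\nid: T:1\nname: root\n\n"
            "[Term]\nid: T:9\nname: gone\nis_obsolete: true\n"
        )
        dag = goe.parse_obo_lite(p)
        assert "T:9" not in dag and "T:1" in dag


@pytest.fixture
def chain_dag():
    return goe.GODag.from_dict(
        {
            "a": {"name": "root", "parents": []},
            "b": {"name": "mid", "parents": ["a"]},
            "c": {"name": "leaf", "parents": ["b"]},
        }
    )


class TestPropagation:
    def test_leaf_closes_over_chain(self, chain_dag):
        assert goe.propagate_annotations({"g": {"c"}}, chain_dag) == {"g": {"a", "b", "c"}}

    def test_root_annotation_unchanged(self, chain_dag):
        assert goe.propagate_annotations({"g": {"a"}}, chain_dag) == {"g": {"a"}}

    def test_diamond_root_counted_once(self):
        dag = goe.GODag.from_dict(
            {
                "a": {"name": "a", "parents": []},
                "b": {"name": "b", "parents": ["a"]},
                "c": {"name": "c", "parents": ["a"]},
                "d": {"name": "d", "parents": ["b", "c"]},
            }
        )
        out = goe.propagate_annotations({"g": {"d"}}, dag)
        assert out["g"] == {"a", "b", "c", "d"}

    def test_unknown_term_rejected(self, chain_dag):
        with pytest.raises(ValidationError):
            goe.propagate_annotations({"g": {"zz"}}, chain_dag)

    def test_parent_counts_dominate_children(self, small_study):
        _, _, truth = small_study
        gene2go, dag_dict = sd.generate_go(truth, seed=7)
        dag = goe.GODag.from_dict(dag_dict)
        ann = goe.propagate_annotations(gene2go, dag)
        counts = {}
        for terms in ann.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        for term in dag_dict:
            for child in dag.children(term):
                assert counts.get(term, 0) >= counts.get(child, 0)


def hypergeom_enumeration(N, K, n, k):
    """P(X >= k) by exhaustive enumeration of all C(N, n) study draws."""
    universe = list(range(N))
    annotated = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(annotated.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestEnrich:
    def _enrich_single(self, N, K, n, k):
        universe = {f"g{i}" for i in range(N)}
        study = {f"g{i}" for i in range(k)} | {f"g{i}" for i in range(K, K + n - k)}
        ann = {f"g{i}": {"t"} for i in range(K)}
        res = goe.enrich(study, universe, ann, min_term_size=1)
        assert res["k"].iloc[0] == k and res["K"].iloc[0] == K
        return res["p_value"].iloc[0]

    def test_worked_example(self):
        # N=20, K=5, n=5, k=4: (C(5,4)C(15,1) + C(5,5)) / C(20,5) = 76/15504
        assert self._enrich_single(20, 5, 5, 4) == pytest.approx(76 / 15504)

    def test_term_annotating_everything_is_null(self):
        assert self._enrich_single(10, 10, 4, 4) == pytest.approx(1.0)

    def test_zero_overlap_upper_tail_is_one(self):
        assert self._enrich_single(10, 4, 3, 0) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            N = int(rng.integers(4, 13))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(max(0, n - (N - K)), min(K, n) + 1))
            assert self._enrich_single(N, K, n, k) == pytest.approx(
                hypergeom_enumeration(N, K, n, k)
            )

    def test_study_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            goe.enrich({"zz"}, {"a"}, {"a": {"t"}})

    def test_small_terms_not_tested(self):
        universe = {f"g{i}" for i in range(10)}
        ann = {"g0": {"rare"}, "g1": {"rare"}}
        res = goe.enrich({"g0"}, universe, ann, min_term_size=3)
        assert len(res) == 0

    def test_tiers(self):
        universe = {f"g{i}" for i in range(60)}
        ann = {f"g{i}": {"t"} for i in range(10)}
        study = {f"g{i}" for i in range(10)}
        res = goe.enrich(study, universe, ann, min_term_size=3)
        assert res["tier"].iloc[0] == "**"


class TestMaskGo:
    def test_hand_example(self):
        assert goe.mask_go({"t1", "t2", "t3"}, {"t2", "t3", "t9"}, {"t2", "t3", "t8"}) == {"t1"}

    def test_empty_between_sets_identity(self):
        assert goe.mask_go({"t1", "t2"}, set(), set()) == {"t1", "t2"}

    def test_fully_masked(self):
        assert goe.mask_go({"t1"}, {"t1"}, {"t1", "t2"}) == set()


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", range(1, 6))
    def test_light_terms_enriched_and_dev_terms_masked(self, seed):
        """On the default study the planted light GO terms stay significant in
        the sensitive genotype's retained set while the planted development
        terms are development-masked."""
        from lightmask import contrast_masking as cm
        from lightmask import diffexpr as de

        params = sd.SimulationParams(seed=seed)
        design = sd.generate_design(3, seed=seed)
        matrix, truth = sd.generate_counts(design, params)
        gene2go, dag_dict = sd.generate_go(truth, seed)
        dag = goe.GODag.from_dict(dag_dict)
        ann = goe.propagate_annotations(gene2go, dag)

        def grp(geno, cond):
            rows = design[(design.genotype == geno) & (design.condition == cond)]
            return list(rows.sample_id)

        within = de.call_de(
            de.add_qvalues(de.de_test(matrix, grp("G_sensitive", "M"), grp("G_sensitive", "F"))),
            0.01, label="G_sensitive",
        )
        between = {
            o: de.call_de(
                de.add_qvalues(de.de_test(matrix, grp("G_insensitive", "M"), grp(o, "M"))),
                0.01, condition="M",
            )
            for o in ("G_intermediate", "G_sensitive")
        }
        dev = cm.development_set(between["G_intermediate"], between["G_sensitive"])
        retained, _ = cm.mask_development(within, dev)
        universe = set(matrix.gene_ids)
        between_terms = {
            o: goe.significant_terms(goe.enrich(s.genes(), universe, ann, dag), 0.05)
            for o, s in between.items()
        }
        within_terms = goe.significant_terms(goe.enrich(within.genes(), universe, ann, dag), 0.05)
        retained_terms = goe.significant_terms(
            goe.enrich(retained.genes(), universe, ann, dag), 0.05
        )
        kept = goe.mask_go(
            within_terms, between_terms["G_intermediate"], between_terms["G_sensitive"]
        )
        planted_light = (
            truth.planted_go_terms[sd.CLASS_LIGHT_SHARED]
            | truth.planted_go_terms[f"{sd.CLASS_LIGHT_SPECIFIC}:G_sensitive"]
        )
        planted_dev = truth.planted_go_terms[sd.CLASS_DEVELOPMENT]
        assert planted_light <= retained_terms
        assert planted_dev <= within_terms  # the confound is visible...
        assert planted_dev & kept == set()  # ...and the masking removes it
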