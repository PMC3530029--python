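"""Synteny: neighborhood windows, shared-family scoring, paralogon
detection versus a brute-force graph oracle, classification, and post-WGD
duplicate detection."""

import pytest

import kissevo as kv
from kissevo.errors import ConfigurationError, UnknownAnchorError
from kissevo.synteny import _regions_from_annotation

from .oracles import brute_force_paralogon_components


def random_annotation(rng, n_genes=12, n_seqs=3, n_families=5, species="sp"):
    records = []
    for i in range(n_genes):
        seq = f"chr{rng.randrange(n_seqs)}"
        start = rng.randrange(1, 10_000) * 100
        fam = rng.choice([None] + [f"F{j}" for j in range(n_families)])
        records.append(
            kv.GeneRecord(
                f"g{i}", species, seq, start, start + 50, rng.choice("+-"), fam
            )
        )
    return kv.AnnotationTable(species, records)


class TestBuildNeighborhood:
    def test_equals_sort_and_slice(self, rng):
        for _ in range(20):
            ann = random_annotation(rng)
            anchor = rng.choice(list(ann)).gene_id
            k = 3
            got = kv.build_neighborhood(ann, anchor, k)
            genes = sorted(
                (g for g in ann if g.seq_id == ann[anchor].seq_id),
                key=lambda g: (g.start, g.end, g.gene_id),
            )
            idx = [g.gene_id for g in genes].index(anchor)
            expected = genes[max(0, idx - k) : idx + k + 1]
            assert list(got.genes) == expected

    def test_k_zero_is_anchor_alone(self, kiss_tables):
        hood = kv.build_neighborhood(kiss_tables["human"], "human:KISS1", 0)
        assert hood.gene_ids == ("human:KISS1",)
        assert hood.anchor_family == "KISS"

    def test_unknown_anchor(self, kiss_tables):
        with pytest.raises(UnknownAnchorError):
            kv.build_neighborhood(kiss_tables["human"], "human:NOPE", 3)

    def test_positional_anchor(self, kiss_tables):
        by_gene = kv.build_neighborhood(kiss_tables["human"], "human:KISS1", 2)
        rec = kiss_tables["human"]["human:KISS1"]
        by_pos = kv.build_neighborhood(
            kiss_tables["human"], (rec.seq_id, (rec.start + rec.end) // 2), 2
        )
        assert by_pos.gene_ids == by_gene.gene_ids

    def test_kiss1_neighborhood_carries_reported_families(self, kiss_tables):
        hood = kv.build_neighborhood(kiss_tables["human"], "human:KISS1", 15)
        assert {"TEAD", "NAV", "PPFIA"} <= hood.families


class TestSharedFamilyCount:
    def test_set_intersection_oracle(self, rng):
        for _ in range(20):
            a = kv.build_neighborhood(*self._random_pick(rng))
            b = kv.build_neighborhood(*self._random_pick(rng))
            got = kv.shared_family_count(a, b)
            assert got == len(a.families & b.families)
            assert got == kv.shared_family_count(b, a)
            assert got <= min(len(a.families), len(b.families))

    @staticmethod
    def _random_pick(rng):
        ann = random_annotation(rng, species=f"sp{rng.randrange(3)}")
        return ann, rng.choice(list(ann)).gene_id, rng.randrange(0, 4)

    def test_disjoint_sets(self, kiss_tables):
        a = kv.build_neighborhood(kiss_tables["xenopus"], "xenopus:kiss1b", 5)
        b = kv.build_neighborhood(kiss_tables["stickleback"], "stickleback:kiss2", 5)
        assert kv.shared_family_count(a, b, exclude={"KISS"}) == 0

    def test_coelacanth_kiss3_vs_xenopus_kiss1b(self, kiss_tables):
        """The two Kiss3-type regions share exactly the three reported
        neighbor families (TEAD2, PIH1D1, ALDH16A1) besides Kiss itself."""
        coel = kv.build_neighborhood(kiss_tables["coelacanth"], "coelacanth:Kiss3", 15)
        xen = kv.build_neighborhood(kiss_tables["xenopus"], "xenopus:kiss1b", 15)
        assert kv.shared_family_count(coel, xen, exclude={"KISS"}) == 3
        assert coel.families & xen.families - {"KISS"} == {
            "TEAD", "PIH1D1", "ALDH16A1",
        }


class TestDetectParalogons:
    def test_single_member_families_give_nothing(self):
        ann = kv.AnnotationTable(
            "sp",
            [
                kv.GeneRecord("a", "sp", "c1", 100, 200, "+", "F1"),
                kv.GeneRecord("b", "sp", "c2", 100, 200, "+", "F2"),
            ],
        )
        assert kv.detect_paralogons(ann) == []

    def test_empty_annotation(self):
        assert kv.detect_paralogons(kv.AnnotationTable("sp", [])) == []

    def test_matches_brute_force_on_random_instances(self, rng):
        for trial in range(40):
            ann = random_annotation(
                rng, n_genes=rng.randrange(4, 13), n_seqs=4, n_families=4
            )
            tau = rng.choice([1, 2])
            k = rng.choice([2, 15])
            got = kv.detect_paralogons(ann, tau=tau, k=k)
            regions = _regions_from_annotation(ann, k)
            expected = brute_force_paralogon_components(
                [r.families for r in regions], tau
            )
            got_sets = {
                frozenset(regions.index(r) for r in p.regions) for p in got
            }
            assert got_sets == expected

    def test_invariant_under_renaming_translation_and_flips(self, kissr_tables):
        base = kv.detect_paralogons(kissr_tables["human"])
        shift, flip = 13_577, {"+": "-", "-": "+"}
        transformed = kv.AnnotationTable(
            "human",
            [
                kv.GeneRecord(
                    r.gene_id, r.species, f"scaf_{r.seq_id}", r.start + shift,
                    r.end + shift, flip[r.strand], r.family_id, r.symbol,
                )
                for r in kissr_tables["human"]
            ],
        )
        moved = kv.detect_paralogons(transformed)
        assert len(moved) == len(base) == 1
        assert moved[0].supporting_families == base[0].supporting_families
        assert [sorted(g.gene_id for g in r.genes) for r in moved[0].regions] == [
            sorted(g.gene_id for g in r.genes) for r in base[0].regions
        ]

    def test_simulated_wgd_regions_recovered(self, species_tree):
        """With no losses, n WGDs on the root path give one paralogon of 2^n
        regions in every leaf genome."""
        fams = [f"fam{i:02d}" for i in range(12)]
        history = kv.simulate_wgd_history(species_tree, fams, 0.0, seed=4)
        annotations = history.annotations()
        for species, n_wgd in [("human", 2), ("zebrafish", 3)]:
            paralogons = kv.detect_paralogons(annotations[species])
            assert len(paralogons) == 1
            assert len(paralogons[0]) == 2 ** n_wgd


class TestClassifyGene:
    def _refs(self, kiss_tables, k=15):
        coel = kiss_tables["coelacanth"]
        return [
            (rec.symbol, kv.build_neighborhood(coel, rec.gene_id, k))
            for rec in coel
            if rec.family_id == "KISS"
        ]

    def test_identical_query_returns_reference_label(self, kiss_tables):
        refs = self._refs(kiss_tables)
        assert kv.classify_gene(refs[0][1], refs) == refs[0][0]

    def test_stickleback_kiss_is_kiss2(self, kiss_tables):
        query = kv.build_neighborhood(
            kiss_tables["stickleback"], "stickleback:kiss2", 15
        )
        assert kv.classify_gene(query, self._refs(kiss_tables)) == "Kiss2"

    def test_tie_is_unclassified(self):
        mk = lambda sp, fams: kv.AnnotationTable(
            sp,
            [
                kv.GeneRecord(f"{sp}{i}", sp, "c1", 100 * (i + 1), 100 * (i + 1) + 50,
                              "+", f)
                for i, f in enumerate(fams)
            ],
        )
        q = kv.build_neighborhood(mk("q", ["F1", "F2", "F3"]), "q0", 5)
        r1 = kv.build_neighborhood(mk("r1", ["F1", "F2"]), "r10", 5)
        r2 = kv.build_neighborhood(mk("r2", ["F1", "F2"]), "r20", 5)
        assert kv.classify_gene(q, [("L1", r1), ("L2", r2)], tau=2) is None

    def test_isolated_scaffold_gene_unclassified(self, kiss_tables):
        """A gene alone on a mini-scaffold (the eel Kiss1 situation) scores
        zero everywhere and is unclassified, not an error."""
        lone = kv.AnnotationTable(
            "eel", [kv.GeneRecord("eel:Kiss1", "eel", "sc901", 10, 500, "+", "KISS")]
        )
        query = kv.build_neighborhood(lone, "eel:Kiss1", 15)
        assert kv.classify_gene(query, self._refs(kiss_tables)) is None

    def test_empty_reference_set_is_an_error(self, kiss_tables):
        query = kv.build_neighborhood(kiss_tables["human"], "human:KISS1", 5)
        with pytest.raises(ConfigurationError):
            kv.classify_gene(query, [])


class TestDetectPostWgdDuplicates:
    def test_zebrafish_vs_gar_finds_four_pairs_missing_kissr(self, kissr_tables):
        pairs = kv.detect_post_wgd_duplicates(
            kissr_tables["zebrafish"], kissr_tables["spotted_gar"]
        )
        assert len(pairs) == 4
        assert {p.outgroup_region.seq_id for p in pairs} == {
            "LG2", "LG5", "LG9", "LG13",
        }
        for p in pairs:
            assert "KISSR" in p.missing_families

    def test_self_comparison_reports_nothing(self, kissr_tables):
        gar = kissr_tables["spotted_gar"]
        assert kv.detect_post_wgd_duplicates(gar, gar) == []

    def test_single_wgd_simulation_maps_each_region_twice(self):
        # the WGD sits on the ingroup branch; the outgroup lacks it
        tree = kv.SpeciesTree.from_newick("(ingroup[&wgd=1R],outgroup)root;")
        fams = [f"fam{i}" for i in range(10)]
        history = kv.simulate_wgd_history(tree, fams, 0.0, seed=2)
        ann = history.annotations()
        pairs = kv.detect_post_wgd_duplicates(ann["ingroup"], ann["outgroup"])
        assert len(pairs) == 1
        assert {pairs[0].derived_a.seq_id, pairs[0].derived_b.seq_id} == {
            "R0-1Ra", "R0-1Rb",
        }
        assert pairs[0].missing_families == frozenset()
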