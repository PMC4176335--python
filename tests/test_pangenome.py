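"""Positional orthology, core/pan-genomes and integration regions."""

import copy
import itertools

import pytest

from rmscape.core_model import Gene, Genome, Replicon
from rmscape.pangenome import (PanFamily, classify_rm_families,
                               compare_region_sizes, core_genome,
                               integration_regions, pan_families,
                               positional_orthologs, rm_family_fractions)
from rmscape.synthetic_data import (CladeSimConfig, random_protein,
                                    simulate_clade, _rng)


def _genome(gid, proteins, circular=True):
    genes = [Gene(f"{gid}_g{i:03d}", f"{gid}_c", i, 40 * i + 1, 40 * i + 30,
                  "+", p) for i, p in enumerate(proteins)]
    rep = Replicon(f"{gid}_c", "chromosome", 40 * len(proteins) + 40,
                   circular, genes)
    return Genome(gid, "x", [rep])


@pytest.fixture(scope="module")
def clade_fams(clade_full):
    return pan_families(clade_full.genomes, identity_min=0.8)


@pytest.fixture(scope="module")
def twin_genomes():
    rng = _rng(31)
    proteins = [random_protein(60, rng) for _ in range(30)]
    return _genome("a", proteins), _genome("b", proteins)


class TestPositionalOrthologs:
    def test_identical_genomes_pair_every_gene(self, twin_genomes):
        a, b = twin_genomes
        pairs = positional_orthologs(a, b)
        assert len(pairs) == 30
        assert all(p.synteny_support >= 4 for p in pairs)

    def test_support_threshold_four_vs_three(self):
        rng = _rng(13)
        proteins = [random_protein(60, rng) for _ in range(30)]
        # strain b keeps only 4 of gene 15's 10 window mates recognisable
        mutated = list(proteins)
        for r in (10, 11, 12, 14, 16, 18):
            mutated[r] = random_protein(60, rng)
        a = _genome("a", proteins, circular=False)
        b = _genome("b", mutated, circular=False)
        pairs4 = {p.gene_a for p in positional_orthologs(a, b, min_support=4)}
        pairs5 = {p.gene_a for p in positional_orthologs(a, b, min_support=5)}
        assert "a_g015" in pairs4      # exactly 4 supporting pairs: retained
        assert "a_g015" not in pairs5  # one fewer would drop it

    def test_invariant_under_gene_id_relabeling(self, twin_genomes):
        a, b = twin_genomes
        b2 = copy.deepcopy(b)
        mapping = {}
        for g in b2.genes():
            new = g.gene_id.replace("b_", "zz_")
            mapping[new] = g.gene_id
            g.gene_id = new
        got = {(p.gene_a, mapping[p.gene_b])
               for p in positional_orthologs(a, b2)}
        want = {(p.gene_a, p.gene_b) for p in positional_orthologs(a, b)}
        assert got == want

    def test_inversion_interior_pairs_retained(self):
        rng = _rng(77)
        proteins = [random_protein(60, rng) for _ in range(40)]
        a = _genome("a", proteins)
        inverted = proteins[:10] + proteins[10:22][::-1] + proteins[22:]
        b = _genome("b", inverted)
        pairs = positional_orthologs(a, b)
        # interior genes of the inverted block keep full neighbourhoods
        interior = {f"a_g{i:03d}" for i in range(13, 19)}
        assert interior <= {p.gene_a for p in pairs}


class TestCoreGenome:
    def test_seven_identical_strains_core_is_whole_proteome(self):
        rng = _rng(5)
        proteins = [random_protein(60, rng) for _ in range(25)]
        genomes = [_genome(f"s{i}", proteins) for i in range(7)]
        core = core_genome(genomes)
        assert len(core) == 25

    def test_gene_missing_in_one_strain_leaves_core(self):
        rng = _rng(5)
        proteins = [random_protein(60, rng) for _ in range(25)]
        genomes = [_genome(f"s{i}", proteins) for i in range(6)]
        genomes.append(_genome("s6", proteins[:12] + proteins[13:]))
        core = core_genome(genomes)
        assert len(core) == 24

    def test_planted_clade_core_recovered_exactly(self, clade_full):
        core = core_genome(clade_full.genomes)
        pivot = sorted(g.genome_id for g in clade_full.genomes)[0]
        truth = {v[pivot] for v in clade_full.core_map.values()}
        got = {v[pivot] for v in core.values()}
        assert got == truth

    def test_missing_pivot_is_error(self, clade_full):
        with pytest.raises(ValueError):
            core_genome(clade_full.genomes, pivot="nope")


class TestPanFamilies:
    def test_partition_and_core_family_presence(self, clade_full, clade_fams):
        fams = clade_fams
        seen = [g for f in fams for _gen, g in f.members]
        assert len(seen) == len(set(seen))
        assert len(seen) == sum(1 for g in clade_full.genomes
                                for _ in g.genes())

    def test_stringent_refines_relaxed_and_matches_union_find(self,
                                                              clade_full):
        from rmscape.homology import all_vs_all
        proteome = {g.gene_id: g.protein_seq for gen in clade_full.genomes
                    for g in gen.genes()}
        hits = all_vs_all(proteome, evalue_max=1e-4)
        tight = pan_families(clade_full.genomes, 0.8, hits=hits)
        loose = pan_families(clade_full.genomes, 0.4, hits=hits)
        loose_of = {g: f.family_id for f in loose for _gen, g in f.members}
        for fam in tight:
            assert len({loose_of[g] for _gen, g in fam.members}) == 1
        # independent union-find over thresholded edges
        parent = {g: g for g in proteome}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for h in hits:
            if h.identity >= 0.8 and h.coverage_smallest >= 0.8:
                parent[find(h.query_id)] = find(h.subject_id)
        tight_of = {g: f.family_id for f in tight for _gen, g in f.members}
        for a, b in itertools.combinations(sorted(proteome), 2):
            assert (find(a) == find(b)) == (tight_of[a] == tight_of[b])

    def test_persistence_thresholds(self):
        fam = PanFamily("F0", [("s0", "g0"), ("s1", "g1")], 2 / 7)
        assert not fam.persistent
        assert PanFamily("F1", [], 3 / 7).persistent


class TestRMFamilyClassification:
    def test_planted_solitary_lineage_never_mixes(self, clade_full, clade_fams):
        """Solitary genes planted as an independent lineage form
        solitary_only families, never mixed with complete-system genes."""
        fams = clade_fams
        roles = clade_full.truth.roles
        sys_genes = [g for g, r in roles.items() if _has_partner(g, roles)]
        sol_genes = [g for g, r in roles.items()
                     if r["role"] == "MTase" and not _has_partner(g, roles)]

        class _Sys:
            complete = True

            def __init__(self, gs):
                self.components = [(g, "x") for g in gs]

        class _Sol:
            def __init__(self, g):
                self.gene_id = g

        df = classify_rm_families(fams, [_Sys(sys_genes)],
                                  [_Sol(g) for g in sol_genes])
        by_content = df.groupby("rm_content").size().to_dict()
        assert by_content.get("mixed", 0) == 0
        assert by_content.get("complete_only", 0) >= 1
        assert by_content.get("solitary_only", 0) >= 1
        fr = rm_family_fractions(fams)
        assert fr["mixed_fraction_of_complete"] == 0.0


def _has_partner(gene_id, roles):
    feat = roles[gene_id]["feature"]
    return any(r["feature"] == feat and r["role"] == "REase"
               for g, r in roles.items() if g != gene_id)


class TestIntegrationRegions:
    def test_planted_lengths_and_breakpoints(self):
        cfg = CladeSimConfig(clade_id="cl", sequences=False)
        sim = simulate_clade(cfg, 99)
        els = [dict(e, element_class=e["content"]) for e in sim.elements]
        regions = integration_regions(els, sim.core_map, sim.genomes)
        for el, reg in zip(els, regions):
            if el["breakpoint"]:
                assert reg.breakpoint
            else:
                assert not reg.breakpoint and not reg.excluded
                assert reg.length == el["length"]

    def test_element_overlapping_core_gene_excluded(self):
        cfg = CladeSimConfig(clade_id="cl", sequences=False)
        sim = simulate_clade(cfg, 99)
        el = dict(sim.elements[0])
        el["ranks"] = [0, 1]  # ancestral core genes
        el["element_class"] = "system"
        reg = integration_regions([el], sim.core_map, sim.genomes)[0]
        assert reg.excluded == "overlaps_core_gene"


class TestCompareRegionSizes:
    class _R:
        breakpoint = False
        excluded = ""

        def __init__(self, cls, length):
            self.element_class = cls
            self.length = length

    def test_ten_of_ten_closed_form(self):
        by_sp = {f"sp{i}": [self._R("system", 2), self._R("solitary", 8)]
                 for i in range(10)}
        res = compare_region_sizes(by_sp)
        assert res["n_smaller"] == 10
        assert res["p_value"] == pytest.approx(0.5 ** 10)

    def test_five_of_ten_is_no_signal(self):
        by_sp = {f"sp{i}": [self._R("system", 2 if i < 5 else 9),
                            self._R("solitary", 5)] for i in range(10)}
        res = compare_region_sizes(by_sp)
        assert res["n_smaller"] == 5
        assert res["p_value"] > 0.5

    def test_no_qualifying_species_warns_empty(self):
        with pytest.warns(UserWarning):
            res = compare_region_sizes({"sp0": [self._R("system", 2)]})
        assert res["n_species"] == 0
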