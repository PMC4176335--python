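"""Positional-orthology core genomes, pan-genome families and
integration-region analysis.

Core genomes are built per species (clade) from bidirectional best hits
(end-gap-free global alignment, >= 80% similarity, <= 20% length
difference) refined by conserved gene neighbourhood: a BBH pair is a
*positional ortholog* when at least four other BBH pairs lie within a
10-gene window (five upstream, five downstream) around both members —
few enough that orthologs at rearrangement-breakpoint edges survive.
The core genome is the intersection of the pivot's positional-ortholog
lists against every other strain.

Pan-genome families are single-linkage clusters of all-against-all hits
at >= 80% identity (stringent) or >= 40% (relaxed) covering > 80% of the
smallest protein.  Families present in less than a third of the strains
are non-persistent, the signature of recent horizontal acquisition.

An integration region is the stretch between the two consecutive core
genes flanking an acquired element; its gene count L proxies the size of
the acquired segment.  Regions whose flanks are not consecutive core
genes in some other strain sit on rearrangement breakpoints and are
excluded from size statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .core_model import Gene, Genome, neighborhood_ranks
from .homology import (ClusterConfig, ProteinAligner, all_vs_all, bbh_pairs,
                       cluster_families, default_aligner)
from . import stats as rmstats

MIN_CLADE_GENOMES = 7


@dataclass
class OrthologPair:
    gene_a: str
    gene_b: str
    similarity: float
    length_diff: float
    synteny_support: int


@dataclass
class PanFamily:
    family_id: str
    members: list[tuple[str, str]]          # (genome_id, gene_id)
    strain_presence: float
    rm_content: str = "none"

    @property
    def persistent(self) -> bool:
        return self.strain_presence >= 1 / 3


@dataclass
class IntegrationRegion:
    element_id: str
    genome_id: str
    replicon_id: str
    element_class: str
    flank_a: str
    flank_b: str
    length: int
    breakpoint: bool = False
    excluded: str = ""                      # non-empty reason -> not usable


def _proteome(genome: Genome) -> dict[str, str]:
    return {g.gene_id: g.protein_seq for g in genome.genes()}


def _rank_lookup(genome: Genome) -> dict[str, Gene]:
    return genome.gene_index()


def positional_orthologs(genome_a: Genome, genome_b: Genome,
                         min_similarity: float = 0.8,
                         max_length_diff: float = 0.2,
                         window: int = 5, min_support: int = 4,
                         aligner: ProteinAligner | None = None,
                         prefilter: bool = True) -> list[OrthologPair]:
    """BBH pairs supported by conserved neighbourhood around both members."""
    aligner = aligner or default_aligner()
    hits = bbh_pairs(_proteome(genome_a), _proteome(genome_b),
                     min_similarity, max_length_diff, aligner, prefilter)
    idx_a, idx_b = _rank_lookup(genome_a), _rank_lookup(genome_b)
    rep_a = {r.replicon_id: r for r in genome_a.replicons}
    rep_b = {r.replicon_id: r for r in genome_b.replicons}
    # partner rank of each BBH by (replicon, rank) on each side
    pair_by_pos_a: dict[tuple[str, int], tuple[str, int]] = {}
    for h in hits:
        ga, gb = idx_a[h.query_id], idx_b[h.subject_id]
        pair_by_pos_a[(ga.replicon_id, ga.rank)] = (gb.replicon_id, gb.rank)
    out = []
    for h in hits:
        ga, gb = idx_a[h.query_id], idx_b[h.subject_id]
        ra, rb = rep_a[ga.replicon_id], rep_b[gb.replicon_id]
        win_a = neighborhood_ranks(ga.rank, window, ra.n_genes, ra.circular)
        win_b = set(neighborhood_ranks(gb.rank, window, rb.n_genes,
                                       rb.circular))
        support = 0
        for r in win_a:
            partner = pair_by_pos_a.get((ga.replicon_id, r))
            if partner and partner[0] == gb.replicon_id and partner[1] in win_b:
                support += 1
        if support >= min_support:
            out.append(OrthologPair(h.query_id, h.subject_id, h.similarity,
                                    h.length_diff, support))
    return out


def core_genome(genomes: list[Genome], pivot: str | None = None,
                aligner: ProteinAligner | None = None,
                prefilter: bool = True,
                **ortholog_kwargs) -> dict[str, dict[str, tuple[str, int]]]:
    """Core map from the intersection of pairwise positional orthologs.

    Returns core_id -> {genome_id: (replicon_id, rank)}; core ids follow
    the pivot's gene order.  Below 7 genomes a warning is raised (the
    species-level analysis expects at least seven strains).
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    if len(genomes) < MIN_CLADE_GENOMES:
        warnings.warn(f"only {len(genomes)} genomes; core genomes are "
                      f"intended for >= {MIN_CLADE_GENOMES}", stacklevel=2)
    by_id = {g.genome_id: g for g in genomes}
    pivot = pivot or min(by_id)
    if pivot not in by_id:
        raise ValueError(f"pivot {pivot!r} not among genomes")
    pivot_genome = by_id[pivot]
    others = [g for g in genomes if g.genome_id != pivot]
    maps: list[dict[str, str]] = []
    for other in others:
        pairs = positional_orthologs(pivot_genome, other, aligner=aligner,
                                     prefilter=prefilter, **ortholog_kwargs)
        maps.append({p.gene_a: p.gene_b for p in pairs})
    core_gene_ids = [g.gene_id for g in pivot_genome.genes()
                     if all(g.gene_id in m for m in maps)]
    idxs = [_rank_lookup(g) for g in others]
    pivot_idx = _rank_lookup(pivot_genome)
    core_map: dict[str, dict[str, tuple[str, int]]] = {}
    ordered = sorted(core_gene_ids,
                     key=lambda gid: (pivot_idx[gid].replicon_id,
                                      pivot_idx[gid].rank))
    for k, gid in enumerate(ordered):
        cid = f"C{k:04d}"
        entry = {pivot: (pivot_idx[gid].replicon_id, pivot_idx[gid].rank)}
        for other, m, idx in zip(others, maps, idxs):
            og = idx[m[gid]]
            entry[other.genome_id] = (og.replicon_id, og.rank)
        core_map[cid] = entry
    return core_map


def pan_families(genomes: list[Genome], identity_min: float = 0.8,
                 coverage_min: float = 0.8, evalue_max: float = 1e-4,
                 aligner: ProteinAligner | None = None,
                 prefilter: bool = True,
                 hits=None) -> list[PanFamily]:
    """Single-linkage pan-genome families at an identity/coverage threshold.

    ``hits`` may carry precomputed all-against-all AlignmentStats (e.g.
    ingested BLAST tabular); otherwise the built-in aligner produces them.
    """
    gene_to_genome = {g.gene_id: genome.genome_id
                      for genome in genomes for g in genome.genes()}
    if hits is None:
        proteome = {g.gene_id: g.protein_seq
                    for genome in genomes for g in genome.genes()}
        hits = all_vs_all(proteome, evalue_max, aligner, prefilter)
    cfg = ClusterConfig(method="single_linkage", identity_min=identity_min,
                        coverage_min=coverage_min)
    partition = cluster_families(hits, cfg, all_ids=gene_to_genome)
    members_by_family: dict[str, list[tuple[str, str]]] = {}
    for gid, fid in partition.items():
        members_by_family.setdefault(fid, []).append((gene_to_genome[gid], gid))
    n_strains = len(genomes)
    out = []
    for fid in sorted(members_by_family):
        members = sorted(members_by_family[fid])
        presence = len({g for g, _ in members}) / n_strains
        out.append(PanFamily(fid, members, presence))
    return out


def classify_rm_families(families: list[PanFamily], systems,
                         solitaries) -> pd.DataFrame:
    """Label each family by its R-M content and summarise the overlap
    between complete-system proteins and solitary proteins."""
    complete_genes = {g for s in systems if s.complete
                      for g, _r in s.components}
    solitary_genes = {s.gene_id for s in solitaries}
    rows = []
    for fam in families:
        gene_ids = {g for _gen, g in fam.members}
        has_c = bool(gene_ids & complete_genes)
        has_s = bool(gene_ids & solitary_genes)
        fam.rm_content = ("mixed" if has_c and has_s else
                          "complete_only" if has_c else
                          "solitary_only" if has_s else "none")
        rows.append({"family_id": fam.family_id, "n_members": len(fam.members),
                     "strain_presence": fam.strain_presence,
                     "persistent": fam.persistent,
                     "rm_content": fam.rm_content})
    return pd.DataFrame(rows, columns=["family_id", "n_members",
                                       "strain_presence", "persistent",
                                       "rm_content"])


def rm_family_fractions(families: list[PanFamily]) -> dict[str, float]:
    """Fraction of complete-system families also holding solitary proteins
    (and the symmetric fraction), after classify_rm_families."""
    n_complete = sum(1 for f in families
                     if f.rm_content in ("complete_only", "mixed"))
    n_solitary = sum(1 for f in families
                     if f.rm_content in ("solitary_only", "mixed"))
    n_mixed = sum(1 for f in families if f.rm_content == "mixed")
    return {
        "families_with_complete": n_complete,
        "families_with_solitary": n_solitary,
        "mixed_fraction_of_complete": n_mixed / n_complete if n_complete else 0.0,
        "mixed_fraction_of_solitary": n_mixed / n_solitary if n_solitary else 0.0,
    }


# ---------------------------------------------------------------------------
# integration regions


def _core_order(core_map: dict[str, dict[str, tuple[str, int]]],
                genome_id: str, replicon_id: str) -> list[tuple[int, str]]:
    out = [(pos[1], cid) for cid, entry in core_map.items()
           for gid, pos in entry.items()
           if gid == genome_id and pos[0] == replicon_id]
    return sorted(out)


def _adjacent_in(order: list[tuple[int, str]], ca: str, cb: str,
                 circular: bool) -> bool:
    ids = [cid for _r, cid in order]
    if ca not in ids or cb not in ids:
        return False
    ia, ib = ids.index(ca), ids.index(cb)
    d = abs(ia - ib)
    if circular:
        d = min(d, len(ids) - d)
    return d == 1


def integration_regions(elements: list[dict],
                        core_map: dict[str, dict[str, tuple[str, int]]],
                        genomes: list[Genome]) -> list[IntegrationRegion]:
    """Locate each element between its flanking consecutive core genes.

    ``elements`` carry element_id, genome_id, replicon_id, ranks (the
    element's gene ranks in the focal genome) and element_class.  Regions
    whose flanks are non-consecutive core genes in at least one other
    strain are marked ``breakpoint``; elements overlapping a core gene,
    on replicons with fewer than two core genes, or at linear-replicon
    termini are excluded with a reason.
    """
    by_id = {g.genome_id: g for g in genomes}
    genome_ids = sorted({gid for entry in core_map.values() for gid in entry})
    orders: dict[tuple[str, str], list[tuple[int, str]]] = {}
    for gid in genome_ids:
        for rep in by_id[gid].replicons:
            orders[(gid, rep.replicon_id)] = _core_order(core_map, gid,
                                                         rep.replicon_id)
    out = []
    for el in elements:
        gid, rid = el["genome_id"], el["replicon_id"]
        rep = by_id[gid].replicon(rid)
        order = orders.get((gid, rid), [])
        region = IntegrationRegion(el["element_id"], gid, rid,
                                   el.get("element_class", el.get("content", "")),
                                   "", "", -1)
        if len(order) < 2:
            region.excluded = "fewer_than_two_core_genes"
            out.append(region)
            continue
        lo, hi = min(el["ranks"]), max(el["ranks"])
        core_ranks = [r for r, _c in order]
        if any(lo <= r <= hi for r in core_ranks):
            region.excluded = "overlaps_core_gene"
            out.append(region)
            continue
        below = [i for i, (r, _c) in enumerate(order) if r < lo]
        above = [i for i, (r, _c) in enumerate(order) if r > hi]
        if below and above:
            ia, ib = below[-1], above[0]
            if ib != ia + 1:
                region.excluded = "core_gene_between_flanks"
                out.append(region)
                continue
            length = order[ib][0] - order[ia][0] - 1
        elif rep.circular:
            # element sits across the origin gap between last and first core
            ia, ib = len(order) - 1, 0
            length = (rep.n_genes - order[ia][0] - 1) + order[ib][0]
        else:
            region.excluded = "terminal_element"
            out.append(region)
            continue
        region.flank_a, region.flank_b = order[ia][1], order[ib][1]
        region.length = length
        for other in genome_ids:
            if other == gid:
                continue
            adjacent = any(
                _adjacent_in(orders[(other, rep2.replicon_id)],
                             region.flank_a, region.flank_b, rep2.circular)
                for rep2 in by_id[other].replicons)
            if not adjacent:
                region.breakpoint = True
                break
        out.append(region)
    return out


def regions_table(regions: list[IntegrationRegion]) -> pd.DataFrame:
    rows = [{"element_id": r.element_id, "genome_id": r.genome_id,
             "replicon_id": r.replicon_id, "element_class": r.element_class,
             "flank_a": r.flank_a, "flank_b": r.flank_b, "length": r.length,
             "breakpoint": r.breakpoint, "excluded": r.excluded}
            for r in sorted(regions, key=lambda r: r.element_id)]
    return pd.DataFrame(rows, columns=["element_id", "genome_id",
                                       "replicon_id", "element_class",
                                       "flank_a", "flank_b", "length",
                                       "breakpoint", "excluded"])


def compare_region_sizes(regions_by_species: dict[str, list[IntegrationRegion]],
                         class_a: str = "system", class_b: str = "solitary"
                         ) -> dict:
    """Per-species median region size per element class plus the one-sided
    binomial test that class_a regions tend smaller than class_b regions."""
    medians = {}
    for sp in sorted(regions_by_species):
        usable = [r for r in regions_by_species[sp]
                  if not r.breakpoint and not r.excluded]
        la = sorted(r.length for r in usable if r.element_class == class_a)
        lb = sorted(r.length for r in usable if r.element_class == class_b)
        if la and lb:
            medians[sp] = (la[len(la) // 2] if len(la) % 2 else
                           (la[len(la) // 2 - 1] + la[len(la) // 2]) / 2,
                           lb[len(lb) // 2] if len(lb) % 2 else
                           (lb[len(lb) // 2 - 1] + lb[len(lb) // 2]) / 2)
    if not medians:
        warnings.warn("no species with both element classes", stacklevel=2)
        return {"n_species": 0, "n_smaller": 0, "p_value": float("nan"),
                "medians": {}}
    n = len(medians)
    k = sum(1 for ma, mb in medians.values() if ma < mb)
    res = rmstats.binomial_test(k, n, 0.5, sidedness="greater")
    return {"n_species": n, "n_smaller": k, "p_value": res.p_value,
            "medians": medians}
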