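"""End-to-end analysis over a (synthetic or loaded) annotated dataset.

Glues the stages together in the order the analysis runs on real data:
role assignment against the reference library, R-M system assembly and
solitary/ambiguous calling, co-localization and census summaries, plasmid
mobility typing, integron/competence detection, spacer matching, MGE
enrichment, within-family dN/dS, and the stratified co-occurrence tests.
Every result lands in a named DataFrame; ``run_pipeline`` writes them as
deterministic TSVs plus a manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import evolution, mobilome, rm_inference
from . import stats as rmstats
from .core_model import Genome, export_report
from .homology import (ClusterConfig, RoleCall, all_vs_all, assign_roles,
                       cluster_families, default_aligner)
from .synthetic_data import Dataset, standard_dataset


@dataclass
class AnalysisResult:
    roles: dict[str, RoleCall]
    systems: list
    solitaries: list
    ambiguous: list
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    scalars: dict[str, float] = field(default_factory=dict)


def _all_proteins(genomes: list[Genome]) -> dict[str, str]:
    return {g.gene_id: g.protein_seq for genome in genomes
            for g in genome.genes()}


def _replicon_lookup(genomes: list[Genome]):
    return {rep.replicon_id: rep for g in genomes for rep in g.replicons}


def analyze_dataset(dataset: Dataset, max_gap: int = 4,
                    solitary_gap: int = 10, run_dnds: bool = True
                    ) -> AnalysisResult:
    genomes = dataset.genomes
    roles = assign_roles(_all_proteins(genomes), dataset.library)
    systems, solitaries, ambiguous = [], [], []
    for genome in genomes:
        sys_g, sol_g, amb_g = rm_inference.detect_genome(
            genome, roles, max_gap, solitary_gap)
        systems.extend(sys_g)
        solitaries.extend(sol_g)
        ambiguous.extend(amb_g)
    res = AnalysisResult(roles, systems, solitaries, ambiguous)
    tables = res.tables
    tables["systems"] = rm_inference.systems_table(systems)
    tables["solitary"] = rm_inference.solitary_table(solitaries, ambiguous)
    census = rm_inference.rm_census(genomes, systems, solitaries)
    tables["census_per_genome"] = census["per_genome"]
    tables["census_per_clade"] = census["per_clade"]
    tables["census_types"] = census["type_counts"]
    reps = _replicon_lookup(genomes)
    tables["colocalization"] = rm_inference.colocalization_summary(systems, reps)

    # mobilome
    mob_rows, integron_rows, competence_rows = [], [], []
    competent, has_cas, has_argo, has_mge = {}, {}, {}, {}
    for genome in genomes:
        competent[genome.genome_id] = mobilome.genome_is_competent(genome, roles)
        labels = {roles[g.gene_id].role for g in genome.genes()
                  if g.gene_id in roles}
        has_cas[genome.genome_id] = "cas" in labels
        has_argo[genome.genome_id] = "argo" in labels
        has_mge[genome.genome_id] = any(
            m.replicon_id in {r.replicon_id for r in genome.replicons}
            for m in dataset.mges)
        for rep in genome.replicons:
            if rep.kind == "plasmid":
                mob_rows.append({"replicon_id": rep.replicon_id,
                                 "genome_id": genome.genome_id,
                                 "mob": mobilome.classify_plasmid_mob(rep,
                                                                      roles)})
            integron_rows.extend(mobilome.detect_integrons(rep, roles))
            for locus in mobilome.detect_competence_loci(rep, roles):
                competence_rows.append({
                    "replicon_id": locus["replicon_id"],
                    "start_rank": locus["start_rank"],
                    "end_rank": locus["end_rank"],
                    "n_genes": len(locus["gene_ids"]),
                    "complete": locus["complete"]})
    tables["plasmid_mob"] = pd.DataFrame(
        mob_rows, columns=["replicon_id", "genome_id", "mob"])
    tables["integrons"] = pd.DataFrame(
        integron_rows, columns=["replicon_id", "gene_id", "rank"])
    tables["competence_loci"] = pd.DataFrame(
        competence_rows, columns=["replicon_id", "start_rank", "end_rank",
                                  "n_genes", "complete"])

    # spacers vs R-M genes, per genome
    match_rows = []
    gene_dna = {g.gene_id: g.dna_seq for genome in genomes
                for g in genome.genes() if g.dna_seq}
    rm_gene_ids = ({g for s in systems for g, _r in s.components}
                   | {s.gene_id for s in solitaries})
    for genome in genomes:
        recs = dataset.spacers.get(genome.genome_id, [])
        if not recs:
            continue
        targets = {gid: gene_dna[gid] for g in genome.genes()
                   if (gid := g.gene_id) in rm_gene_ids and gid in gene_dna}
        matches = mobilome.match_spacers({r.spacer_id: r.seq for r in recs},
                                         targets)
        for m in matches:
            match_rows.append({"spacer_id": m.spacer_id, "gene_id": m.gene_id,
                               "identity": m.identity,
                               "length_diff": m.length_diff,
                               "strand": m.strand, "exact": m.exact})
    tables["spacer_matches"] = pd.DataFrame(
        match_rows, columns=["spacer_id", "gene_id", "identity",
                             "length_diff", "strand", "exact"])

    tables["mge_enrichment"] = mobilome.mge_enrichment(systems, genomes,
                                                       dataset.mges)
    tables["element_densities"] = mobilome.element_densities(
        systems, solitaries, genomes, dataset.mges)

    # IIC fusion scan
    iic = [s for s in systems if s.rm_type == "IIC"]
    split_ii = [s for s in systems if s.rm_type == "II" and s.n_genes == 2]
    proteins = _all_proteins(genomes)
    frac, flagged = rm_inference.iic_fusion_scan(iic, split_ii, proteins)
    tables["iic_fusion"] = pd.DataFrame(
        [{"n_iic": len(iic), "n_flagged": len(flagged),
          "fraction_fused": frac,
          "flagged_ids": ";".join(flagged)}])
    res.scalars["iic_fusion_fraction"] = frac

    # stratified co-occurrence tests
    counts = {g.genome_id: sum(1 for s in systems
                               if s.genome_id == g.genome_id)
              for g in genomes}
    sizes = {g.genome_id: g.size_mb for g in genomes}
    cooc = []
    for flag_name, flag in (("competence", competent), ("cas", has_cas),
                            ("argo", has_argo), ("mge", has_mge)):
        df = rmstats.co_occurrence_test(counts, flag, sizes)
        df.insert(0, "feature", flag_name)
        cooc.append(df)
    tables["co_occurrence"] = pd.concat(cooc, ignore_index=True)

    # genome size vs system count correlation
    ids = sorted(counts)
    corr = rmstats.rank_correlation([sizes[i] for i in ids],
                                    [counts[i] for i in ids])
    tables["size_correlation"] = pd.DataFrame(
        [{"rho": corr.statistic, "p_value": corr.p_value,
          "method": corr.method, "n": len(ids)}])

    if run_dnds:
        tables["dnds_estimates"], tables["dnds_summary"], \
            tables["dnds_comparisons"] = rm_gene_dnds(
                genomes, roles, systems, solitaries)
    return res


def rm_gene_dnds(genomes: list[Genome], roles: dict[str, RoleCall],
                 systems, solitaries,
                 max_pairs_per_family: int = 15):
    """Within-family pairwise dN/dS over all R-M genes.

    Families are single-linkage clusters at 80% identity (singletons
    dropped); within each family every pair (capped per family for
    runtime) is aligned end-gap-free, back-threaded to DNA and estimated
    with the kappa-aware counting method.
    """
    member_role = {}
    for s in systems:
        for gid, role in s.components:
            member_role[gid] = f"{role}:{s.rm_type}"
    for s in solitaries:
        member_role[s.gene_id] = f"solitary_{s.role}:{s.rm_type_hint}"
    prot = {}
    dna = {}
    for genome in genomes:
        for g in genome.genes():
            if g.gene_id in member_role and g.dna_seq:
                prot[g.gene_id] = g.protein_seq
                dna[g.gene_id] = g.dna_seq
    hits = all_vs_all(prot, evalue_max=1e-3)
    fam = cluster_families(hits, ClusterConfig(method="single_linkage",
                                               identity_min=0.8,
                                               coverage_min=0.8),
                           all_ids=prot)
    members_by_fam: dict[str, list[str]] = {}
    for gid, fid in fam.items():
        members_by_fam.setdefault(fid, []).append(gid)
    grouped, rows = [], []
    for fid in sorted(members_by_fam):
        members = sorted(members_by_fam[fid])
        if len(members) < 2:
            continue  # singletons eliminated
        pairs = [(a, b) for i, a in enumerate(members)
                 for b in members[i + 1:]][:max_pairs_per_family]
        for a, b in pairs:
            al = default_aligner()
            alignment = al._aligners["global_endgapfree"].align(prot[a],
                                                                prot[b])[0]
            a_aln, b_aln = str(alignment[0]), str(alignment[1])
            codon_aln = evolution.backtranslate_alignment((a_aln, b_aln),
                                                          dna[a], dna[b])
            est = evolution.estimate_dnds(codon_aln, "yn00", a, b)
            label = member_role[a]
            grouped.append((label, est))
            rows.append({"family_id": fid, "id_a": a, "id_b": b,
                         "group": label, "dN": est.dN, "dS": est.dS,
                         "omega": est.omega, "kappa": est.kappa,
                         "saturated": est.saturated})
    estimates = pd.DataFrame(rows, columns=["family_id", "id_a", "id_b",
                                            "group", "dN", "dS", "omega",
                                            "kappa", "saturated"])
    summary, comparisons = evolution.summarize_selection(grouped)
    return estimates, summary, comparisons


def run_pipeline(out_dir: str | Path, seed: int, n_genomes: int = 20,
                 run_dnds: bool = True) -> dict:
    """Simulate the standard dataset, analyse it and export all tables."""
    dataset = standard_dataset(seed, n_genomes)
    result = analyze_dataset(dataset, run_dnds=run_dnds)
    config = {"seed": seed, "n_genomes": n_genomes, "max_gap": 4,
              "solitary_gap": 10, "run_dnds": run_dnds}
    return export_report(result.tables, out_dir, config)
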