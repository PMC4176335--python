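"""Assembly of R-M systems from role-called genes.

Systems of Types I, II and III are genes encoding cognate REase/MTase
(plus specificity S subunits for Type I) lying less than ``max_gap`` genes
apart (rank offset < 4 by default); overlapping candidate clusters of the
same type merge into a single system, and extra same-role genes become
additional components rather than new systems.  A Type IIC gene (REase
and MTase functions fused in one polypeptide) is a complete system by
itself; a Type IV REase forms a "restriction system" entry with no MTase.
A system is *complete* when it has both an REase and an MTase (or is IIC).

An unassigned MTase/REase whose nearest cognate-role gene lies at least
``solitary_gap`` (10) genes away is *solitary*; one whose nearest cognate
falls in the [max_gap, solitary_gap) band is *ambiguous* — reported,
never silently dropped.  Every REase/MTase/S gene therefore lands in
exactly one of {system member, solitary, ambiguous}.

An REase whose role call is compatible with both Type II and Type IV is
resolved by genomic context: a compatible MTase in assembly range makes
it Type II, otherwise it is Type IV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core_model import Genome, Replicon, rank_distance
from .homology import RoleCall, pairwise_align

DEFAULT_MAX_GAP = 4
DEFAULT_SOLITARY_GAP = 10

#: roles that can satisfy the "cognate" requirement for each role
COGNATE_ROLES = {
    "MTase": ("REase", "IIC", "TypeIV_REase"),
    "REase": ("MTase", "IIC"),
}


@dataclass
class RMSystem:
    system_id: str
    rm_type: str                     # I | II | IIC | III | IV | mixed
    genome_id: str
    replicon_id: str
    components: list[tuple[str, str]]   # (gene_id, role)
    component_ranks: list[int]
    complete: bool
    flags: set = field(default_factory=set)

    @property
    def span(self) -> tuple[int, int]:
        return (min(self.component_ranks), max(self.component_ranks))

    @property
    def n_genes(self) -> int:
        return len(self.components)

    def roles(self) -> set[str]:
        return {r for _g, r in self.components}


@dataclass
class SolitaryComponent:
    gene_id: str
    role: str              # MTase | REase
    rm_type_hint: str
    genome_id: str
    replicon_id: str
    rank: int


@dataclass
class AmbiguousComponent:
    gene_id: str
    role: str
    genome_id: str
    replicon_id: str
    rank: int
    nearest_cognate_distance: int


def _candidate_role(call: RoleCall, replicon_context: dict[int, str],
                    rank: int, n_genes: int, circular: bool,
                    max_gap: int) -> tuple[str, str] | None:
    """(role, rm_type) of one gene for assembly purposes.

    Resolves the Type II / Type IV REase ambiguity by context: an REase
    carrying both labels becomes Type II when a compatible MTase lies
    within assembly range, Type IV otherwise.
    """
    if call.role == "IIC":
        return ("IIC", "IIC")
    if call.role == "TypeIV_REase":
        if call.has_flag("REase", "II"):
            for other_rank, other_role in replicon_context.items():
                if (other_role == "MTase:II"
                        and rank_distance(rank, other_rank, n_genes,
                                          circular) < max_gap):
                    return ("REase", "II")
        return ("TypeIV", "IV")
    if call.role == "REase" and call.has_flag("REase", "IV"):
        for other_rank, other_role in replicon_context.items():
            if (other_role == f"MTase:{call.rm_type}"
                    and rank_distance(rank, other_rank, n_genes,
                                      circular) < max_gap):
                return ("REase", call.rm_type)
        return ("TypeIV", "IV")
    if call.role in ("REase", "MTase", "S") and call.rm_type in ("I", "II", "III"):
        return (call.role, call.rm_type)
    return None


def assemble_rm_systems(replicon: Replicon, roles: dict[str, RoleCall],
                        genome_id: str, max_gap: int = DEFAULT_MAX_GAP
                        ) -> tuple[list[RMSystem], list[tuple[str, str, str, int]]]:
    """Greedy left-to-right agglomeration of R-M systems on one replicon.

    Returns (systems, unassigned) where unassigned lists
    (gene_id, role, rm_type, rank) of REase/MTase/S genes claimed by no
    system.
    """
    n, circ = replicon.n_genes, replicon.circular
    context = {}
    cands: list[tuple[int, str, str, str]] = []  # (rank, gene_id, role, type)
    for g in replicon.genes:
        call = roles.get(g.gene_id)
        if call is None:
            continue
        if call.role == "MTase" and call.rm_type in ("I", "II", "III"):
            context[g.rank] = f"MTase:{call.rm_type}"
    for g in replicon.genes:
        call = roles.get(g.gene_id)
        if call is None:
            continue
        resolved = _candidate_role(call, context, g.rank, n, circ, max_gap)
        if resolved is not None:
            cands.append((g.rank, g.gene_id, resolved[0], resolved[1]))

    systems: list[RMSystem] = []
    claimed: set[str] = set()
    counter = 0

    def emit(cluster: list[tuple[int, str, str, str]], rm_type: str) -> bool:
        """Emit one system if the cluster qualifies; claim its genes."""
        nonlocal counter
        roles_present = {r for _rk, _g, r, _t in cluster}
        if rm_type == "IIC":
            complete = True
        elif rm_type == "IV":
            complete = False
        else:
            # a cluster of a single role (or S only) is not a system: its
            # genes fall back to the solitary/ambiguous classification
            if len(roles_present - {"S"}) == 0 or len(roles_present) < 2:
                return False
            complete = {"REase", "MTase"} <= roles_present
        sys = RMSystem(
            system_id=f"{genome_id}_{replicon.replicon_id}_RM{counter:03d}",
            rm_type=rm_type, genome_id=genome_id,
            replicon_id=replicon.replicon_id,
            components=[(g, r) for _rk, g, r, _t in cluster],
            component_ranks=[rk for rk, _g, _r, _t in cluster],
            complete=complete)
        counter += 1
        systems.append(sys)
        claimed.update(g for _rk, g, _r, _t in cluster)
        return True

    # single-gene complete IIC systems
    for rk, gid, role, rm_type in cands:
        if rm_type == "IIC":
            emit([(rk, gid, "IIC", "IIC")], "IIC")
    # per-type proximity chains (Type IV REases chain into multi-REase entries)
    for rm_type in ("I", "II", "III", "IV"):
        members = sorted(c for c in cands if c[3] == rm_type)
        clusters: list[list] = []
        for cand in members:
            if clusters and rank_distance(clusters[-1][-1][0], cand[0], n,
                                          circ) < max_gap:
                clusters[-1].append(cand)
            else:
                clusters.append([cand])
        if (circ and len(clusters) > 1
                and rank_distance(clusters[-1][-1][0], clusters[0][0][0], n,
                                  circ) < max_gap):
            clusters[0] = clusters.pop() + clusters[0]
        for cluster in clusters:
            emit(cluster, rm_type)

    unassigned = [(g, r, t, rk) for rk, g, r, t in cands
                  if g not in claimed and t != "IIC"]
    return systems, unassigned


def call_solitary(replicon: Replicon, roles: dict[str, RoleCall],
                  systems: list[RMSystem], genome_id: str,
                  unassigned: list[tuple[str, str, str, int]],
                  max_gap: int = DEFAULT_MAX_GAP,
                  solitary_gap: int = DEFAULT_SOLITARY_GAP
                  ) -> tuple[list[SolitaryComponent], list[AmbiguousComponent]]:
    """Classify unassigned REase/MTase genes as solitary or ambiguous.

    Solitary: nearest cognate-role gene at distance >= ``solitary_gap``
    (or no cognate at all).  Ambiguous: nearest cognate closer than the
    solitary threshold but not assembled into a system (including
    unassigned S subunits).
    """
    n, circ = replicon.n_genes, replicon.circular
    cognate_ranks: dict[str, list[int]] = {"REase": [], "MTase": [],
                                           "IIC": [], "TypeIV_REase": []}
    gene_rank = {g.gene_id: g.rank for g in replicon.genes}
    for g in replicon.genes:
        call = roles.get(g.gene_id)
        if call is None:
            continue
        if call.role in cognate_ranks:
            cognate_ranks[call.role].append(g.rank)
    solitaries, ambiguous = [], []
    for gid, role, rm_type, rank in sorted(unassigned, key=lambda u: u[3]):
        if role == "S":
            ambiguous.append(AmbiguousComponent(gid, role, genome_id,
                                                replicon.replicon_id, rank, -1))
            continue
        dists = [rank_distance(rank, r, n, circ)
                 for cr in COGNATE_ROLES[role]
                 for r in cognate_ranks.get(cr, [])
                 if r != rank]
        nearest = min(dists) if dists else None
        if nearest is None or nearest >= solitary_gap:
            solitaries.append(SolitaryComponent(gid, role, rm_type, genome_id,
                                                replicon.replicon_id, rank))
        else:
            ambiguous.append(AmbiguousComponent(gid, role, genome_id,
                                                replicon.replicon_id, rank,
                                                nearest))
    return solitaries, ambiguous


def detect_genome(genome: Genome, roles: dict[str, RoleCall],
                  max_gap: int = DEFAULT_MAX_GAP,
                  solitary_gap: int = DEFAULT_SOLITARY_GAP):
    """Run assembly + solitary calling over every replicon of a genome."""
    systems, solitaries, ambiguous = [], [], []
    for rep in genome.replicons:
        sys_r, unassigned = assemble_rm_systems(rep, roles, genome.genome_id,
                                                max_gap)
        sol_r, amb_r = call_solitary(rep, roles, sys_r, genome.genome_id,
                                     unassigned, max_gap, solitary_gap)
        systems.extend(sys_r)
        solitaries.extend(sol_r)
        ambiguous.extend(amb_r)
    return systems, solitaries, ambiguous


# ---------------------------------------------------------------------------
# co-localization


def colocalization_pairs(systems: list[RMSystem], replicons: dict[str, Replicon],
                         neighborhood: int = 10) -> tuple[list[tuple], float]:
    """Pairs of distinct systems with nearest components < neighborhood
    apart, plus the fraction of systems appearing in at least one pair."""
    pairs = []
    in_pair: set[str] = set()
    by_rep: dict[str, list[RMSystem]] = {}
    for s in systems:
        by_rep.setdefault(s.replicon_id, []).append(s)
    for rep_id, group in sorted(by_rep.items()):
        rep = replicons[rep_id]
        group = sorted(group, key=lambda s: s.system_id)
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                d = min(rank_distance(ra, rb, rep.n_genes, rep.circular)
                        for ra in a.component_ranks
                        for rb in b.component_ranks)
                if d < neighborhood:
                    pairs.append((a.system_id, b.system_id, d))
                    in_pair.update((a.system_id, b.system_id))
    frac = len(in_pair) / len(systems) if systems else 0.0
    return pairs, frac


def colocalization_summary(systems: list[RMSystem],
                           replicons: dict[str, Replicon],
                           neighborhoods: tuple[int, ...] = (10, 50)
                           ) -> pd.DataFrame:
    """Co-localized fractions at each neighborhood, overall and restricted
    to genomes with at least two systems."""
    by_genome: dict[str, int] = {}
    for s in systems:
        by_genome[s.genome_id] = by_genome.get(s.genome_id, 0) + 1
    multi = {g for g, k in by_genome.items() if k >= 2}
    rows = []
    for nb in neighborhoods:
        _pairs, frac = colocalization_pairs(systems, replicons, nb)
        sub = [s for s in systems if s.genome_id in multi]
        _p2, frac_multi = colocalization_pairs(sub, replicons, nb)
        rows.append({"neighborhood": nb, "fraction_colocalized": frac,
                     "fraction_colocalized_multi": frac_multi,
                     "n_systems": len(systems), "n_systems_multi": len(sub)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# census


def rm_census(genomes: list[Genome], systems: list[RMSystem],
              solitaries: list[SolitaryComponent],
              min_clade_species: int = 10) -> dict[str, pd.DataFrame]:
    """Per-genome counts/densities by type, clade means (clades with at
    least ``min_clade_species`` species only) and solitary tallies."""
    types = sorted({s.rm_type for s in systems}) or ["II"]
    per_genome = []
    for g in genomes:
        row = {"genome_id": g.genome_id, "clade": g.clade,
               "size_mb": g.size_mb}
        gsys = [s for s in systems if s.genome_id == g.genome_id]
        row["n_systems"] = len(gsys)
        row["density_per_mb"] = len(gsys) / g.size_mb
        for t in types:
            n = sum(1 for s in gsys if s.rm_type == t)
            row[f"n_{t}"] = n
            row[f"density_{t}"] = n / g.size_mb
        row["n_solitary_MTase"] = sum(1 for s in solitaries
                                      if s.genome_id == g.genome_id
                                      and s.role == "MTase")
        row["n_solitary_REase"] = sum(1 for s in solitaries
                                      if s.genome_id == g.genome_id
                                      and s.role == "REase")
        per_genome.append(row)
    df = pd.DataFrame(per_genome).sort_values("genome_id").reset_index(drop=True)
    clade_sizes = df.groupby("clade")["genome_id"].nunique()
    keep = clade_sizes[clade_sizes >= min_clade_species].index
    clade_df = (df[df["clade"].isin(keep)]
                .groupby("clade")
                .agg(n_species=("genome_id", "nunique"),
                     mean_density=("density_per_mb", "mean"),
                     mean_count=("n_systems", "mean"))
                .reset_index())
    type_counts = pd.DataFrame([
        {"rm_type": t,
         "count": sum(1 for s in systems if s.rm_type == t),
         "fraction": (sum(1 for s in systems if s.rm_type == t)
                      / len(systems)) if systems else 0.0}
        for t in types])
    return {"per_genome": df, "per_clade": clade_df, "type_counts": type_counts}


# ---------------------------------------------------------------------------
# Type IIC fusion scan


def iic_fusion_scan(iic_systems: list[RMSystem],
                    split_type_ii: list[RMSystem],
                    proteins: dict[str, str],
                    threshold: float = 0.5) -> tuple[float, list[str]]:
    """Fraction of IIC systems resembling a fused two-gene Type II system.

    An IIC system is flagged when its (single) protein aligns to the
    concatenated REase+MTase proteins — or either individual protein — of
    any two-gene Type II system with similarity above ``threshold`` while
    covering more than half of the IIC protein.
    """
    flagged = []
    for iic in sorted(iic_systems, key=lambda s: s.system_id):
        gid = iic.components[0][0]
        prot = proteins[gid]
        hit = False
        for sys2 in split_type_ii:
            if sys2.n_genes != 2:
                continue
            parts = [proteins[g] for g, _r in sys2.components]
            for cand in parts + ["".join(parts), "".join(parts[::-1])]:
                st = pairwise_align(prot, cand, "local")
                if st.similarity > threshold and st.query_coverage > 0.5:
                    hit = True
                    break
            if hit:
                break
        if hit:
            flagged.append(iic.system_id)
    frac = len(flagged) / len(iic_systems) if iic_systems else 0.0
    return frac, flagged


# ---------------------------------------------------------------------------
# tables


def systems_table(systems: list[RMSystem]) -> pd.DataFrame:
    rows = [{
        "system_id": s.system_id, "rm_type": s.rm_type,
        "genome_id": s.genome_id, "replicon_id": s.replicon_id,
        "n_components": s.n_genes,
        "gene_ids": ";".join(g for g, _r in s.components),
        "roles": ";".join(r for _g, r in s.components),
        "span_lo": s.span[0], "span_hi": s.span[1],
        "complete": s.complete, "flags": ";".join(sorted(s.flags)),
    } for s in sorted(systems, key=lambda s: s.system_id)]
    return pd.DataFrame(rows, columns=["system_id", "rm_type", "genome_id",
                                       "replicon_id", "n_components",
                                       "gene_ids", "roles", "span_lo",
                                       "span_hi", "complete", "flags"])


def solitary_table(solitaries: list[SolitaryComponent],
                   ambiguous: list[AmbiguousComponent]) -> pd.DataFrame:
    rows = [{"gene_id": s.gene_id, "status": "solitary", "role": s.role,
             "rm_type_hint": s.rm_type_hint, "genome_id": s.genome_id,
             "replicon_id": s.replicon_id, "rank": s.rank,
             "nearest_cognate": -1}
            for s in solitaries]
    rows += [{"gene_id": a.gene_id, "status": "ambiguous", "role": a.role,
              "rm_type_hint": "", "genome_id": a.genome_id,
              "replicon_id": a.replicon_id, "rank": a.rank,
              "nearest_cognate": a.nearest_cognate_distance}
             for a in ambiguous]
    rows.sort(key=lambda r: r["gene_id"])
    return pd.DataFrame(rows, columns=["gene_id", "status", "role",
                                       "rm_type_hint", "genome_id",
                                       "replicon_id", "rank",
                                       "nearest_cognate"])
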