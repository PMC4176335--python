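"""Synthetic annotated genomes with machine-readable planted truth.

This module generates every input the pipeline consumes: a labelled
reference protein library (emulating a curated set of R-M reference
proteins plus mobility/defense/competence references), single genomes with
planted R-M systems, solitary genes, decoys, MGE spans, integron and
competence loci and CRISPR spacers, clades of strains derived from a
common ancestor by gene insertion/deletion/inversion, and codon sequences
diverged under a known kappa/omega substitution process.

Design principles:

* every planted feature is recorded in a truth table that can be checked
  against the emitted files without access to generator internals;
* planted features never violate the thresholds they exercise (system
  component offsets stay below the assembly gap, solitary genes sit at
  least the solitary threshold away from any cognate gene, and the
  generator re-validates this after assembly);
* background genes are random-codon sequences rejection-sampled to share
  no k-mer signal with the reference library, so spurious role calls on
  background are structurally impossible;
* all randomness flows through a counter-based generator (numpy Philox),
  so one seed reproduces every dataset byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .codons import (AA_TO_CODONS as _AA_TO_CODONS, CODON_TO_AA,
                     NUCLEOTIDES as _NTS, STOP_CODONS,
                     TRANSITION as _TRANSITION)
from .core_model import Gene, Genome, Replicon, TruthTable, write_genbank
from .homology import ReferenceEntry, ReferenceLibrary, kmer_set, shares_kmers
from .mobilome import MGEAnnotation

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.Generator(np.random.Philox(int(seed_or_rng)))


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def mutate_protein(seq: str, fraction: float, rng: np.random.Generator) -> str:
    """Substitute ``fraction`` of positions with a different residue."""
    n = int(round(fraction * len(seq)))
    pos = rng.choice(len(seq), size=n, replace=False)
    out = list(seq)
    for p in pos:
        alt = [a for a in AA_ALPHABET if a != out[p]]
        out[p] = alt[rng.integers(len(alt))]
    return "".join(out)


def reverse_translate(protein: str, rng: np.random.Generator,
                      stop: bool = True) -> str:
    codons = [_AA_TO_CODONS[a][rng.integers(len(_AA_TO_CODONS[a]))]
              for a in protein]
    if stop:
        codons.append(STOP_CODONS[rng.integers(len(STOP_CODONS))])
    return "".join(codons)


def translate(dna: str) -> str:
    return str(Seq(dna).translate()).rstrip("*")


def _codon_exit(codon: str, kappa: float, omega: float,
                _cache: dict = {}) -> tuple[list[str], np.ndarray, float]:
    """Single-nucleotide neighbour codons, their relative rates, and the
    total exit rate (stop codons forbidden; transitions x kappa,
    nonsynonymous changes x omega)."""
    key = (codon, kappa, omega)
    hit = _cache.get(key)
    if hit is not None:
        return hit
    cands, weights = [], []
    aa = CODON_TO_AA[codon]
    for pos in range(3):
        for nt in _NTS:
            if nt == codon[pos]:
                continue
            new = codon[:pos] + nt + codon[pos + 1:]
            if new in STOP_CODONS:
                continue
            w = kappa if _TRANSITION[codon[pos]] == nt else 1.0
            if CODON_TO_AA[new] != aa:
                w *= omega
            if w > 0:
                cands.append(new)
                weights.append(w)
    weights = np.asarray(weights, dtype=float)
    out = (cands, weights, float(weights.sum()))
    _cache[key] = out
    return out


def evolve_codon_sequence(dna: str, t: float, kappa: float, omega: float,
                          seed) -> str:
    """Diverge a coding sequence under a kappa/omega codon process.

    A continuous-time Markov codon process with synonymous rate
    proportional to 1, nonsynonymous to ``omega`` and transitions to
    ``kappa``; stop codons are forbidden.  Rates are normalised so the
    expected substitution count per codon, averaged over the input
    sequence, is ``t`` (each codon draws a Poisson count proportional to
    its own total exit rate, so low-opportunity codons such as Met/Trp
    evolve more slowly).  ``omega = 0`` freezes the protein; ``t = 0``
    returns the input unchanged.
    """
    if len(dna) % 3:
        raise ValueError("length not divisible by 3")
    rng = _rng(seed)
    codons = [dna[i:i + 3] for i in range(0, len(dna), 3)]
    for idx, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon at {idx}")
    rates = np.array([_codon_exit(c, kappa, omega)[2] for c in codons])
    mean_rate = rates.mean()
    if t == 0 or mean_rate == 0:
        return dna
    counts = rng.poisson(t * rates / mean_rate)
    for idx in np.nonzero(counts)[0]:
        codon = codons[idx]
        for _ in range(counts[idx]):
            cands, weights, total = _codon_exit(codon, kappa, omega)
            if not cands:
                break
            codon = cands[rng.choice(len(cands), p=weights / total)]
        codons[idx] = codon
    return "".join(codons)


def simulate_divergent_pair(n_codons: int, t: float, kappa: float,
                            omega: float, seed) -> tuple[str, str]:
    """An ancestral coding sequence and a copy diverged by ``t``."""
    rng = _rng(seed)
    anc = reverse_translate(random_protein(n_codons, rng), rng, stop=False)
    der = evolve_codon_sequence(anc, t, kappa, omega, rng)
    return anc, der


# ---------------------------------------------------------------------------
# reference library

COMPETENCE_COMPONENTS = ("ComEA", "ComEC", "ComFA", "ComGA", "ComGB",
                         "ComGC", "ComC", "DprA")
COMPETENCE_FACULTATIVE = ("ComC",)

#: (founder name, role label, rm_type label, protein length)
FOUNDER_PLAN: list[tuple[str, str, str, int]] = (
    [(f"{role}_{t}", role, t, ln)
     for t in ("I", "II", "III")
     for role, ln in (("REase", 150), ("MTase", 140))]
    + [("S_I", "S", "I", 120),
       ("REase_IV", "REase", "IV", 145),
       ("IIC_R", "REase", "IIC", 125),
       ("IIC_M", "MTase", "IIC", 130),
       ("relaxase", "relaxase", "", 140),
       ("conj_virb4", "conjugation", "", 150),
       ("conj_t4cp", "conjugation", "", 135),
       ("conj_mpf", "conjugation", "", 125),
       ("int_tyr", "integrase_tyr", "", 130),
       ("int_sig", "integron_signature", "", 70),
       ("argo", "argo", "", 150),
       ("cas", "cas", "", 140)]
    + [(f"com_{c}", f"competence:{c}", "", 120) for c in COMPETENCE_COMPONENTS]
    # independent lineages for solitary genes: same role labels, distinct
    # founders, so solitary and complete-system proteins never share a family
    + [("MTase_solo", "MTase", "II", 140), ("REase_solo", "REase", "II", 150)]
)

LIBRARY_TIERS = (1.00, 0.95, 0.70, 0.40)


def build_reference_library(seed) -> tuple[ReferenceLibrary, dict]:
    """Labelled reference FASTA content plus founder truth.

    Per role x rm_type founder, the library carries the founder itself and
    divergent copies at controlled identity tiers.  Distinct roles share no
    founder, so cross-role identity stays far below any role-call
    threshold.
    """
    rng = _rng(seed)
    entries, founders = [], {}
    for name, role, rm_type, length in FOUNDER_PLAN:
        founder = random_protein(length, rng)
        founders[name] = {"role": role, "rm_type": rm_type, "seq": founder,
                          "dna": reverse_translate(founder, rng, stop=False)}
        for tier in LIBRARY_TIERS:
            seq = founder if tier == 1.0 else mutate_protein(founder, 1 - tier, rng)
            entries.append(ReferenceEntry(f"{name}_t{int(tier * 100)}",
                                          role, rm_type, seq))
    return ReferenceLibrary(entries), founders


# ---------------------------------------------------------------------------
# single-genome simulation

SYSTEM_COMPONENTS = {
    "I": ("MTase", "S", "REase"),
    "I2S": ("MTase", "S", "REase", "S"),  # Type I with two specificity genes
    "II": ("REase", "MTase"),
    "III": ("REase", "MTase"),
    "IIC": ("IIC",),
    "IV": ("TypeIV",),
}

#: role label -> founder name per rm_type
_COMPONENT_FOUNDER = {
    ("MTase", "I"): "MTase_I", ("S", "I"): "S_I", ("REase", "I"): "REase_I",
    ("REase", "II"): "REase_II", ("MTase", "II"): "MTase_II",
    ("REase", "III"): "REase_III", ("MTase", "III"): "MTase_III",
}

REASE_LIKE = ("REase", "IIC", "TypeIV")
MTASE_LIKE = ("MTase", "IIC")

FILLER = 11          # background genes between planted feature blocks
# planted genes are founder coding sequences diverged under the codon
# process below: enough drift for realistic within-family variation while
# staying far above every role-call threshold and below dS saturation
PLANT_T = 0.25
PLANT_KAPPA = 2.0
PLANT_OMEGA = 0.15


@dataclass
class SpacerRecord:
    spacer_id: str
    seq: str
    source_gene: str
    n_mut: int
    tail: int
    revcomp: bool
    expect_retained: bool
    expect_exact: bool


@dataclass
class GenomeSimConfig:
    genome_id: str
    clade: str = "cladeA"
    systems: tuple = (("II", (1,)),)      # (type, offsets between components)
    solitary: tuple = ("MTase",)          # roles planted as solitary genes
    ambiguous_pairs: tuple = ()           # cognate-pair offsets in [4, 10)
    prophage_over_system: int | None = None   # index into systems
    ice_span: bool = False
    integron: bool = False
    competence: bool = False
    argo: bool = False
    cas: bool = False
    iic_fusion: bool = False              # IIC gene fusing a split II system
    plasmid_genes: int = 8
    plasmid_mob: str = "MOB-"             # MOB+ | MOB- | conj (machinery only)
    plasmid_system: str | None = None     # rm_type planted on the plasmid
    spacers: tuple = ()                   # (n_mut, tail, revcomp) triples
    min_fill: int = FILLER


@dataclass
class _Spec:
    protein: str
    role: str = ""         # truth role label ('' = background)
    rm_type: str = ""
    feature: str = ""      # truth feature tag
    dna: str | None = None


class _Background:
    """Background-protein factory with reference-library rejection sampling."""

    def __init__(self, library: ReferenceLibrary, rng: np.random.Generator):
        self._ref_kmers = [e.kmers or kmer_set(e.seq) for e in library.entries]
        self._rng = rng

    def protein(self, length: int | None = None) -> str:
        length = length or int(self._rng.integers(100, 140))
        for _ in range(50):
            cand = random_protein(length, self._rng)
            ck = kmer_set(cand)
            if not any(shares_kmers(ck, rk) for rk in self._ref_kmers):
                return cand
        raise RuntimeError("background rejection sampling failed")


def _plant_coding(founders: dict, name: str,
                  rng: np.random.Generator) -> str:
    """Founder coding DNA diverged under the planting codon process."""
    return evolve_codon_sequence(founders[name]["dna"], PLANT_T, PLANT_KAPPA,
                                 PLANT_OMEGA, rng)


def _plant_spec(founders: dict, names, role: str, rm_type: str, feature: str,
                rng: np.random.Generator) -> _Spec:
    """Planted gene from one founder (or a fusion of several)."""
    if isinstance(names, str):
        names = (names,)
    coding = "".join(_plant_coding(founders, n, rng) for n in names)
    return _Spec(translate(coding), role, rm_type, feature, coding + "TAA")


def _system_specs(rm_type: str, offsets: tuple, founders: dict,
                  bg: _Background, rng: np.random.Generator,
                  feature: str) -> list[_Spec]:
    comps = SYSTEM_COMPONENTS[rm_type]
    truth_type = "I" if rm_type == "I2S" else rm_type
    if len(offsets) != len(comps) - 1:
        raise ValueError("offsets must have one entry per component gap")
    specs: list[_Spec] = []
    for k, comp in enumerate(comps):
        if k:
            gap = offsets[k - 1]
            if not 1 <= gap < 4:
                raise ValueError("system component offsets must be in [1, 4)")
            specs.extend(_Spec(bg.protein()) for _ in range(gap - 1))
        if comp == "IIC":
            specs.append(_plant_spec(founders, ("IIC_R", "IIC_M"), "IIC",
                                     "IIC", feature, rng))
        elif comp == "TypeIV":
            specs.append(_plant_spec(founders, "REase_IV", "TypeIV", "IV",
                                     feature, rng))
        else:
            founder = _COMPONENT_FOUNDER[(comp, truth_type)]
            specs.append(_plant_spec(founders, founder, comp, truth_type,
                                     feature, rng))
    return specs


def _make_spacer(dna: str, n_mut: int, tail: int, revcomp: bool,
                 rng: np.random.Generator, length: int = 32) -> str:
    start = int(rng.integers(0, len(dna) - length - 1))
    frag = list(dna[start:start + length])
    # mutations kept >= 3 positions from either end so the ungapped local
    # alignment never trims them away
    pos = rng.choice(np.arange(3, length - 3), size=n_mut, replace=False)
    for p in pos:
        alt = [n for n in _NTS if n != frag[p]]
        frag[p] = alt[rng.integers(3)]
    seq = "".join(frag)
    if tail:
        # every tail base mismatches the gene's continuation, so the local
        # alignment can never extend into the tail and the length-difference
        # rule is exercised cleanly
        ext = []
        for i in range(tail):
            nxt = dna[start + length + i] if start + length + i < len(dna) else ""
            ext.append(rng.choice([n for n in _NTS if n != nxt]))
        seq = seq + "".join(ext)
    if revcomp:
        seq = str(Seq(seq).reverse_complement())
    return seq


def _build_replicon(replicon_id: str, kind: str, specs: list[_Spec],
                    rng: np.random.Generator, circular: bool = True
                    ) -> tuple[Replicon, str]:
    """Lay specs onto coordinates and return the replicon + its sequence."""
    genes, chunks, pos = [], [], 0
    for rank, spec in enumerate(specs):
        gap = int(rng.integers(15, 40))
        chunks.append("".join(rng.choice(list(_NTS), size=gap)))
        pos += gap
        dna = spec.dna or reverse_translate(spec.protein, rng)
        spec.dna = dna
        start = pos + 1
        end = pos + len(dna)
        strand = "+" if rng.random() > 0.25 else "-"
        chunks.append(dna if strand == "+"
                      else str(Seq(dna).reverse_complement()))
        pos = end
        genes.append(Gene(f"{replicon_id}_g{rank:04d}", replicon_id, rank,
                          start, end, strand, spec.protein, dna))
    tail = int(rng.integers(30, 80))
    chunks.append("".join(rng.choice(list(_NTS), size=tail)))
    pos += tail
    rep = Replicon(replicon_id, kind, pos, circular, genes)
    return rep, "".join(chunks)


@dataclass
class GenomeSim:
    genome: Genome
    truth: TruthTable
    mges: list[MGEAnnotation]
    spacers: list[SpacerRecord]
    replicon_seqs: dict[str, str]


def simulate_genome(config: GenomeSimConfig, seed, library: ReferenceLibrary,
                    founders: dict) -> GenomeSim:
    """One genome with planted features; see module docstring for contracts."""
    rng = _rng(seed)
    bg = _Background(library, rng)
    gid = config.genome_id
    chrom_id = f"{gid}_c0"
    specs: list[_Spec] = []
    blocks: dict[str, tuple[int, int]] = {}  # feature -> (first, last rank)

    def fill(n: int) -> None:
        specs.extend(_Spec(bg.protein()) for _ in range(n))

    def add_block(name: str, block: list[_Spec]) -> None:
        fill(config.min_fill)
        start = len(specs)
        specs.extend(block)
        blocks[name] = (start, len(specs) - 1)

    truth = TruthTable()
    # --- R-M systems ------------------------------------------------------
    for si, (rm_type, offsets) in enumerate(config.systems):
        feature = f"{gid}_sys{si}"
        add_block(feature, _system_specs(rm_type, offsets, founders, bg, rng,
                                         feature))
    # --- solitary genes and ambiguous decoys ------------------------------
    for si, role in enumerate(config.solitary):
        feature = f"{gid}_sol{si}"
        founder = "MTase_solo" if role == "MTase" else "REase_solo"
        add_block(feature, [_plant_spec(founders, founder, role, "II",
                                        feature, rng)])
    for ai, gap in enumerate(config.ambiguous_pairs):
        if not 4 <= gap < 10:
            raise ValueError("ambiguous-pair offsets must be in [4, 10)")
        feature = f"{gid}_amb{ai}"
        block = [_plant_spec(founders, "MTase_II", "MTase", "II", feature, rng)]
        block.extend(_Spec(bg.protein()) for _ in range(gap - 1))
        block.append(_plant_spec(founders, "REase_II", "REase", "II", feature,
                                 rng))
        add_block(feature, block)
    # --- IIC fusion of a freshly planted split Type II system -------------
    if config.iic_fusion:
        rease = _plant_spec(founders, "REase_II", "REase", "II",
                            f"{gid}_fsplit", rng)
        mtase = _plant_spec(founders, "MTase_II", "MTase", "II",
                            f"{gid}_fsplit", rng)
        add_block(f"{gid}_fsplit", [rease, _Spec(bg.protein()), mtase])
        fusion = _Spec(rease.protein + mtase.protein, "IIC", "IIC",
                       f"{gid}_fusion",
                       rease.dna[:-3] + mtase.dna[:-3] + "TAA")
        add_block(f"{gid}_fusion", [fusion])
        truth.extra.setdefault("iic_fusions", []).append(f"{gid}_fusion")
    # --- mobility / defense features --------------------------------------
    if config.integron:
        add_block(f"{gid}_integron",
                  [_plant_spec(founders, ("int_tyr", "int_sig"), "integron",
                               "", f"{gid}_integron", rng)])
    if config.competence:
        block = []
        for k, comp in enumerate(COMPETENCE_COMPONENTS):
            if k:
                for _ in range(int(rng.integers(0, 3))):
                    block.append(_Spec(bg.protein()))
            block.append(_plant_spec(founders, f"com_{comp}",
                                     f"competence:{comp}", "",
                                     f"{gid}_competence", rng))
        add_block(f"{gid}_competence", block)
    if config.argo:
        add_block(f"{gid}_argo", [_plant_spec(founders, "argo", "argo", "",
                                              f"{gid}_argo", rng)])
    if config.cas:
        add_block(f"{gid}_cas", [_plant_spec(founders, "cas", "cas", "",
                                             f"{gid}_cas", rng)])
    fill(config.min_fill)

    chrom, chrom_seq = _build_replicon(chrom_id, "chromosome", specs, rng)

    # --- truth bookkeeping on final ranks ---------------------------------
    def block_genes(name: str) -> list[Gene]:
        s, e = blocks[name]
        return [g for g in chrom.genes[s:e + 1]]

    for rank, spec in enumerate(specs):
        if spec.role:
            g = chrom.genes[rank]
            truth.roles[g.gene_id] = {"role": spec.role, "rm_type": spec.rm_type,
                                      "feature": spec.feature}
    for si, (rm_type, _off) in enumerate(config.systems):
        feature = f"{gid}_sys{si}"
        members = [g.gene_id for g in block_genes(feature)
                   if truth.roles.get(g.gene_id, {}).get("feature") == feature]
        tt = "I" if rm_type == "I2S" else rm_type
        truth.systems.append({"system_id": feature, "rm_type": tt,
                              "gene_ids": members,
                              "complete": tt in ("I", "II", "III", "IIC")})
    if config.iic_fusion:
        for name, tt in ((f"{gid}_fsplit", "II"), (f"{gid}_fusion", "IIC")):
            members = [g.gene_id for g in block_genes(name)
                       if truth.roles.get(g.gene_id, {}).get("feature") == name]
            truth.systems.append({"system_id": name, "rm_type": tt,
                                  "gene_ids": members, "complete": True})
    for si, _role in enumerate(config.solitary):
        truth.solitary.extend(g.gene_id for g in block_genes(f"{gid}_sol{si}")
                              if g.gene_id in truth.roles)
    for ai in range(len(config.ambiguous_pairs)):
        truth.ambiguous.extend(g.gene_id
                               for g in block_genes(f"{gid}_amb{ai}")
                               if g.gene_id in truth.roles)

    # --- MGE spans ---------------------------------------------------------
    mges: list[MGEAnnotation] = []
    if config.prophage_over_system is not None:
        s, e = blocks[f"{gid}_sys{config.prophage_over_system}"]
        mge = MGEAnnotation(f"{gid}_prophage0", "prophage", chrom_id,
                            max(0, s - 2), min(chrom.n_genes - 1, e + 2))
        mges.append(mge)
        for g in chrom.genes[mge.start_rank:mge.end_rank + 1]:
            truth.mge_members[g.gene_id] = mge.mge_id
    if config.ice_span:
        # an ICE over background only: occupy the final filler stretch
        e = chrom.n_genes - 2
        mge = MGEAnnotation(f"{gid}_ice0", "ICE", chrom_id, e - 5, e)
        mges.append(mge)
        for g in chrom.genes[mge.start_rank:mge.end_rank + 1]:
            truth.mge_members[g.gene_id] = mge.mge_id

    # --- plasmid -----------------------------------------------------------
    replicons = [chrom]
    seqs = {chrom_id: chrom_seq}
    if config.plasmid_genes:
        pid = f"{gid}_p0"
        pspecs: list[_Spec] = []
        if config.plasmid_mob == "MOB+":
            pspecs.append(_plant_spec(founders, "relaxase", "relaxase", "",
                                      f"{gid}_mob", rng))
        elif config.plasmid_mob == "conj":
            for fd in ("conj_virb4", "conj_t4cp", "conj_mpf"):
                pspecs.append(_plant_spec(founders, fd, "conjugation", "",
                                          f"{gid}_conj", rng))
        if config.plasmid_system:
            pspecs.extend(_Spec(bg.protein()) for _ in range(2))
            pspecs.extend(_system_specs(config.plasmid_system, (1,), founders,
                                        bg, rng, f"{gid}_psys"))
        while len(pspecs) < config.plasmid_genes:
            pspecs.append(_Spec(bg.protein()))
        plasmid, pseq = _build_replicon(pid, "plasmid", pspecs, rng)
        replicons.append(plasmid)
        seqs[pid] = pseq
        for rank, spec in enumerate(pspecs):
            if spec.role:
                g = plasmid.genes[rank]
                truth.roles[g.gene_id] = {"role": spec.role,
                                          "rm_type": spec.rm_type,
                                          "feature": spec.feature}
        if config.plasmid_system:
            members = [g.gene_id for g in plasmid.genes
                       if truth.roles.get(g.gene_id, {}).get("feature")
                       == f"{gid}_psys"]
            truth.systems.append({"system_id": f"{gid}_psys",
                                  "rm_type": config.plasmid_system,
                                  "gene_ids": members, "complete": True})
        truth.extra.setdefault("mob_labels", {})[pid] = (
            "MOB+" if config.plasmid_mob in ("MOB+", "conj") else "MOB-")

    genome = Genome(gid, config.clade, replicons)

    # --- CRISPR spacers ----------------------------------------------------
    spacers: list[SpacerRecord] = []
    rm_genes = [g for g in chrom.genes
                if truth.roles.get(g.gene_id, {}).get("role")
                in ("REase", "MTase", "S", "IIC", "TypeIV")]
    for k, (n_mut, tail, revcomp) in enumerate(config.spacers):
        src = rm_genes[k % len(rm_genes)]
        seq = _make_spacer(src.dna_seq, n_mut, tail, bool(revcomp), rng)
        retained = n_mut <= 3 and tail == 0
        spacers.append(SpacerRecord(f"{gid}_spacer{k}", seq, src.gene_id,
                                    n_mut, tail, bool(revcomp), retained,
                                    n_mut == 0 and tail == 0))
    truth.extra["spacers"] = [vars(s) for s in spacers]
    truth.extra.setdefault("features", {})[gid] = {
        k: list(v) for k, v in blocks.items()}

    sim = GenomeSim(genome, truth, mges, spacers, seqs)
    _validate_genome_sim(sim)
    return sim


def _validate_genome_sim(sim: GenomeSim) -> None:
    """Planted features must respect the thresholds they exercise."""
    truth = sim.truth
    for rep in sim.genome.replicons:
        rep.validate()
        role_of = {g.gene_id: truth.roles.get(g.gene_id, {}).get("role")
                   for g in rep.genes}
        for g in rep.genes:
            if g.gene_id not in truth.solitary:
                continue
            role = role_of[g.gene_id]
            cognate = REASE_LIKE if role == "MTase" else MTASE_LIKE
            for h in rep.genes:
                if h.gene_id != g.gene_id and role_of[h.gene_id] in cognate:
                    d = abs(g.rank - h.rank)
                    d = min(d, rep.n_genes - d) if rep.circular else d
                    if d < 10:
                        raise AssertionError(
                            f"solitary {g.gene_id} has cognate at {d}")
    for sys in truth.systems:
        ranks = sorted(sim.genome.gene_index()[m].rank for m in sys["gene_ids"])
        for a, b in zip(ranks, ranks[1:]):
            if b - a >= 4:
                raise AssertionError(f"{sys['system_id']}: component gap {b-a}")


# ---------------------------------------------------------------------------
# the standard 20-genome dataset


@dataclass
class Dataset:
    library: ReferenceLibrary
    founders: dict
    genomes: list[Genome]
    truth: TruthTable
    mges: list[MGEAnnotation]
    spacers: dict[str, list[SpacerRecord]]
    replicon_seqs: dict[str, str]


def _merge_truth(dest: TruthTable, src: TruthTable) -> None:
    dest.roles.update(src.roles)
    dest.systems.extend(src.systems)
    dest.solitary.extend(src.solitary)
    dest.ambiguous.extend(src.ambiguous)
    dest.mge_members.update(src.mge_members)
    for key, val in src.extra.items():
        if isinstance(val, list):
            dest.extra.setdefault(key, []).extend(val)
        elif isinstance(val, dict):
            dest.extra.setdefault(key, {}).update(val)


def standard_genome_config(i: int) -> GenomeSimConfig:
    """Deterministic per-genome feature plan for the standard dataset."""
    gid = f"G{i:02d}"
    clade = "cladeA" if i < 10 else "cladeB"
    systems: list[tuple] = []
    if i % 2 == 0:
        systems.append(("II", (1,) if i % 4 == 0 else (3,)))
    if i % 3 == 0:
        systems.append(("I2S" if i % 6 == 0 else "I", (1, 1, 1)
                        if i % 6 == 0 else (1, 2)))
    if i % 4 == 1:
        systems.append(("III", (2,)))
    if i % 2 == 1:
        systems.append(("IIC", ()))
    if i % 5 == 2:
        systems.append(("IV", ()))
    solitary = ["MTase"]
    if i % 3 == 1:
        solitary.append("REase")
    return GenomeSimConfig(
        genome_id=gid, clade=clade, systems=tuple(systems),
        solitary=tuple(solitary),
        ambiguous_pairs=(4 + (i % 6),) if i % 4 == 2 else (),
        prophage_over_system=0 if (i % 3 == 0 and systems) else None,
        ice_span=(i % 4 == 0),
        integron=(i % 5 == 0), competence=(i % 2 == 0),
        argo=(i % 6 == 0), cas=(i % 3 == 2),
        iic_fusion=(i == 1),
        plasmid_genes=8 + i % 4,
        plasmid_mob=("conj" if i % 6 == 4 else
                     "MOB+" if i % 2 == 0 else "MOB-"),
        plasmid_system="II" if i % 5 == 3 else None,
        spacers=((0, 0, 1), (3, 0, 0), (4, 0, 0)) + (((0, 8, 0),)
                                                     if i % 4 == 0 else ())
        if i % 2 == 0 else (),
    )


def standard_dataset(seed: int, n_genomes: int = 20) -> Dataset:
    """The study dataset: 2 clades x 10 genomes with every feature planted."""
    library, founders = build_reference_library(seed)
    truth = TruthTable()
    genomes, mges, spacers, seqs = [], [], {}, {}
    for i in range(n_genomes):
        sim = simulate_genome(standard_genome_config(i), seed * 1000 + i + 1,
                              library, founders)
        genomes.append(sim.genome)
        _merge_truth(truth, sim.truth)
        mges.extend(sim.mges)
        spacers[sim.genome.genome_id] = sim.spacers
        seqs.update(sim.replicon_seqs)
    return Dataset(library, founders, genomes, truth, mges, spacers, seqs)


def dataset_to_dir(dataset: Dataset, out_dir: str | Path) -> None:
    """Emit a dataset as GenBank + reference FASTA + MGE TSV + spacer FASTA
    + truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.library.to_fasta(out / "reference_library.faa")
    for genome in dataset.genomes:
        write_genbank(genome, out / f"{genome.genome_id}.gbk",
                      dataset.replicon_seqs)
    with open(out / "mge_spans.tsv", "w") as fh:
        fh.write("mge_id\tkind\treplicon_id\tstart_rank\tend_rank\n")
        for m in dataset.mges:
            fh.write(f"{m.mge_id}\t{m.kind}\t{m.replicon_id}"
                     f"\t{m.start_rank}\t{m.end_rank}\n")
    with open(out / "spacers.fna", "w") as fh:
        for recs in dataset.spacers.values():
            for s in recs:
                fh.write(f">{s.spacer_id}\n{s.seq}\n")
    dataset.truth.to_json(out / "truth.json")


# ---------------------------------------------------------------------------
# clade simulation


#: ancestor genes kept between any two planned events; wider than the
#: 5-gene synteny half-window so one event never erodes the neighbourhood
#: support of genes flanking another
EVENT_BUFFER = 7


@dataclass
class InsertionPlan:
    """One per-strain insertion between two consecutive ancestral genes."""
    strain: int
    anchor: int            # inserted after ancestral gene index `anchor`
    content: str           # background | system | solitary
    length: int            # total genes inserted
    breakpoint: bool = False   # planted at another strain's inversion edge


@dataclass
class CladeSimConfig:
    clade_id: str = "clade0"
    n_strains: int = 7
    n_core: int = 320
    insertions_per_strain: int = 2
    deletions_per_strain: int = 1
    inversions_per_strain: int = 1
    inversion_len: int = 8
    system_insert_len: tuple = (2, 5)    # complete systems live in short inserts
    solitary_insert_len: tuple = (6, 12)  # solitary genes in long inserts
    divergence_t: float = 0.02
    kappa: float = 2.0
    omega: float = 0.2
    protein_len: int = 110
    breakpoint_decoy: bool = True
    sequences: bool = True   # False: gene-order bookkeeping only (fast)
    # separation between planted events; the default protects the 5-gene
    # synteny half-window used by alignment-based core construction, and
    # can be narrowed for gene-order-only (sequences=False) studies
    event_buffer: int = EVENT_BUFFER


@dataclass
class CladeSim:
    config: CladeSimConfig
    genomes: list[Genome]
    truth: TruthTable
    core_map: dict[str, dict[str, tuple[str, int]]]
    elements: list[dict]


def _allocate_slots(cfg: CladeSimConfig, rng: np.random.Generator):
    """Disjoint, buffered ancestor intervals for every planned event."""
    cursor = 2
    inversions, deletions, insertions = [], [], []
    order = []
    for s in range(cfg.n_strains):
        for _ in range(cfg.inversions_per_strain):
            order.append(("inv", s, cfg.inversion_len))
        for _ in range(cfg.deletions_per_strain):
            order.append(("del", s, 1))
        for k in range(cfg.insertions_per_strain):
            order.append(("ins", s, 0, k))
    for ev in order:
        kind, s = ev[0], ev[1]
        size = ev[2]
        need = max(size, 1) + cfg.event_buffer
        if cursor + need >= cfg.n_core - 2:
            raise ValueError("clade plan exceeds ancestor gene budget")
        if kind == "inv":
            inversions.append((s, cursor, cursor + size - 1))
        elif kind == "del":
            deletions.append((s, cursor))
        else:
            insertions.append((s, cursor, ev[3]))
        cursor += need + int(rng.integers(0, 3))
    return inversions, deletions, insertions


def simulate_clade(config: CladeSimConfig, seed,
                   library: ReferenceLibrary | None = None,
                   founders: dict | None = None) -> CladeSim:
    """Strains derived from one ancestor by insertions, deletions and
    inversions, with exact core-set and region-length truth.

    In ``sequences`` mode every retained gene is diverged per strain under
    the configured kappa/omega process; in fast mode genes carry empty
    sequences and only the gene-order truth (used by region statistics) is
    produced.
    """
    cfg = config
    rng = _rng(seed)
    inversions, deletions, insertions = _allocate_slots(cfg, rng)
    deleted_by_strain: dict[int, set[int]] = {}
    for s, pos in deletions:
        deleted_by_strain.setdefault(s, set()).add(pos)
    inv_by_strain = {s: [(a, b) for ss, a, b in inversions if ss == s]
                     for s in range(cfg.n_strains)}
    ins_by_strain: dict[int, list[InsertionPlan]] = {s: []
                                                     for s in range(cfg.n_strains)}
    plans: list[InsertionPlan] = []
    for idx, (s, anchor, k) in enumerate(insertions):
        if k == 0:
            content = "system"
            length = int(rng.integers(*cfg.system_insert_len))
            length = max(length, 2)
        else:
            content = "solitary"
            length = int(rng.integers(*cfg.solitary_insert_len))
        plan = InsertionPlan(s, anchor, content, length)
        plans.append(plan)
        ins_by_strain[s].append(plan)
    if cfg.breakpoint_decoy and inversions:
        inv_strain, a, _b = inversions[0]
        decoy_strain = (inv_strain + 1) % cfg.n_strains
        plan = InsertionPlan(decoy_strain, a - 1, "solitary", 4,
                             breakpoint=True)
        plans.append(plan)
        ins_by_strain[decoy_strain].append(plan)

    deleted_any = {pos for _s, pos in deletions}
    core_idx = [i for i in range(cfg.n_core) if i not in deleted_any]

    # ancestor sequences
    if cfg.sequences:
        if library is None or founders is None:
            library, founders = build_reference_library(seed)
        bg = _Background(library, rng)
        anc_prot = [bg.protein(cfg.protein_len) for _ in range(cfg.n_core)]
        anc_dna = [reverse_translate(p, rng, stop=False) for p in anc_prot]
    else:
        bg = None
        anc_prot = anc_dna = None

    genomes, elements = [], []
    truth = TruthTable()
    core_map: dict[str, dict[str, tuple[str, int]]] = {
        f"C{i:04d}": {} for i in core_idx}
    plan_ranks: dict[int, list[int]] = {}
    for s in range(cfg.n_strains):
        sid = f"{cfg.clade_id}_s{s}"
        order = [i for i in range(cfg.n_core)
                 if i not in deleted_by_strain.get(s, ())]
        for a, b in inv_by_strain[s]:
            ia = order.index(a)
            ib = order.index(b)
            order[ia:ib + 1] = order[ia:ib + 1][::-1]
        # insertions: items ('ins', plan, slot_index_in_insert)
        items: list[tuple] = [("anc", i) for i in order]
        for plan in sorted(ins_by_strain[s], key=lambda p: p.anchor,
                           reverse=True):
            at = order.index(plan.anchor) + 1
            ins_items = [("ins", plan, j) for j in range(plan.length)]
            items[at:at] = ins_items
        rep_id = f"{sid}_c0"
        specs: list[_Spec] = []
        strain_rng = _rng(int(seed) * 100 + s + 7)
        for item in items:
            if item[0] == "anc":
                i = item[1]
                if cfg.sequences:
                    dna = evolve_codon_sequence(anc_dna[i], cfg.divergence_t,
                                                cfg.kappa, cfg.omega,
                                                strain_rng)
                    specs.append(_Spec(translate(dna), feature=f"anc{i}",
                                       dna=dna + "TAA"))
                else:
                    specs.append(_Spec("", feature=f"anc{i}"))
            else:
                _tag, plan, j = item
                role = ""
                if plan.content == "system" and j < 2:
                    role = ("REase", "MTase")[j]
                elif plan.content == "solitary" and j == plan.length // 2:
                    role = "MTase"
                if cfg.sequences:
                    feature = f"ins_s{plan.strain}_a{plan.anchor}"
                    if role:
                        founder = (_COMPONENT_FOUNDER[(role, "II")]
                                   if plan.content == "system"
                                   else "MTase_solo")
                        specs.append(_plant_spec(founders, founder, role,
                                                 "II", feature, strain_rng))
                    else:
                        specs.append(_Spec(bg.protein(cfg.protein_len),
                                           feature=feature))
                else:
                    specs.append(_Spec("", role, "II" if role else "",
                                       feature=f"ins_s{plan.strain}_a{plan.anchor}"))
        if cfg.sequences:
            rep, seq = _build_replicon(rep_id, "chromosome", specs, strain_rng)
            truth.extra.setdefault("replicon_seqs", {})[rep_id] = seq
        else:
            genes = [Gene(f"{rep_id}_g{r:04d}", rep_id, r, 3 * r + 1, 3 * r + 3,
                          "+", spec.protein) for r, spec in enumerate(specs)]
            rep = Replicon(rep_id, "chromosome", 3 * len(genes) + 3, True, genes)
        genome = Genome(sid, cfg.clade_id, [rep])
        genomes.append(genome)
        for rank, item in enumerate(items):
            if item[0] == "anc":
                fid = f"C{item[1]:04d}"
                truth.families[rep.genes[rank].gene_id] = fid
                if fid in core_map:
                    core_map[fid][sid] = (rep_id, rank)
            else:
                _tag, plan, _j = item
                plan_ranks.setdefault(id(plan), []).append(rank)
                spec = specs[rank]
                if spec.role:
                    truth.roles[rep.genes[rank].gene_id] = {
                        "role": spec.role, "rm_type": spec.rm_type,
                        "feature": spec.feature}

    # element truth, with the planted ranks in the focal strain
    for plan in plans:
        sid = f"{cfg.clade_id}_s{plan.strain}"
        rep = genomes[plan.strain].replicons[0]
        ranks = sorted(plan_ranks.get(id(plan), []))
        gene_ids = [rep.genes[r].gene_id for r in ranks]
        elements.append({
            "element_id": f"{sid}_ins_a{plan.anchor}",
            "genome_id": sid, "replicon_id": rep.replicon_id,
            "content": plan.content, "length": plan.length,
            "anchor": plan.anchor, "breakpoint": plan.breakpoint,
            "ranks": ranks, "gene_ids": gene_ids,
        })
    truth.core_genes = sorted(core_map)
    return CladeSim(cfg, genomes, truth, core_map, elements)
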