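"""Plasmid mobility, integrons, competence loci, CRISPR spacer matching
and R-M enrichment in mobile genetic elements.

Prophage/ICE/IME spans are *inputs* (a BED-like TSV of gene-rank spans);
their detection is out of scope.  A plasmid is MOB+ when it encodes at
least a relaxase (mobilizable in trans) or the complete conjugation
machinery, MOB- otherwise.  Integron loci are genes carrying both a
tyrosine-recombinase signal and the integron-integrase-specific signal
simultaneously.  Competence loci are runs of competence-machinery genes
with bounded gaps; PilU and ComC count as facultative components.

Spacer-protospacer matching uses optimal ungapped local alignment
(match +2 / mismatch -3, both strands); matches with >= 90% identity over
the aligned span and < 10% length difference between spacer and span are
retained, with the exact (100% identity) tier reported separately.

Enrichment of R-M systems in MGE categories follows an observed/expected
scheme: the expected count of a type in a category is the type's total
multiplied by the fraction of all systems located in that category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .core_model import Genome, Replicon
from .homology import RoleCall
from . import stats as rmstats

MGE_KINDS = ("prophage", "ICE", "IME")


@dataclass
class MGEAnnotation:
    mge_id: str
    kind: str
    replicon_id: str
    start_rank: int
    end_rank: int

    def __post_init__(self) -> None:
        if self.kind not in MGE_KINDS:
            raise ValueError(f"unknown MGE kind {self.kind!r}")
        if self.end_rank < self.start_rank:
            raise ValueError("end_rank < start_rank")

    @property
    def span(self) -> int:
        return self.end_rank - self.start_rank + 1

    def contains(self, rank: int) -> bool:
        return self.start_rank <= rank <= self.end_rank


def read_mge_tsv(path: str | Path) -> list[MGEAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return [MGEAnnotation(r.mge_id, r.kind, r.replicon_id,
                          int(r.start_rank), int(r.end_rank))
            for r in df.itertuples()]


@dataclass
class SpacerMatch:
    spacer_id: str
    gene_id: str
    identity: float
    length_diff: float
    strand: str
    span: int

    @property
    def exact(self) -> bool:
        return self.identity == 1.0


# ---------------------------------------------------------------------------
# plasmid mobility


DEFAULT_CONJUGATION_SET = 3  # distinct conjugation-machinery genes required


def classify_plasmid_mob(plasmid: Replicon, roles: dict[str, RoleCall],
                         conjugation_set: int = DEFAULT_CONJUGATION_SET) -> str:
    """MOB+ iff the plasmid encodes a relaxase or the full conjugation
    machinery; MOB- otherwise.  Non-plasmid replicons are a domain error."""
    if plasmid.kind != "plasmid":
        raise ValueError(f"{plasmid.replicon_id}: not a plasmid")
    n_conj = 0
    for g in plasmid.genes:
        call = roles.get(g.gene_id)
        if call is None:
            continue
        if call.role == "relaxase":
            return "MOB+"
        if call.role == "conjugation":
            n_conj += 1
    return "MOB+" if n_conj >= conjugation_set else "MOB-"


# ---------------------------------------------------------------------------
# integrons


def detect_integrons(replicon: Replicon, roles: dict[str, RoleCall]
                     ) -> list[dict]:
    """Loci at genes carrying the tyrosine-recombinase and the
    integron-integrase signature simultaneously."""
    loci = []
    for g in replicon.genes:
        call = roles.get(g.gene_id)
        if call is None:
            continue
        labels = {r for r, _t in call.flags} | {call.role}
        if "integrase_tyr" in labels and "integron_signature" in labels:
            loci.append({"replicon_id": replicon.replicon_id,
                         "gene_id": g.gene_id, "rank": g.rank})
    return loci


# ---------------------------------------------------------------------------
# competence loci

GRAM_POSITIVE_COMPONENTS = ("ComEA", "ComEC", "ComFA", "ComGA", "ComGB",
                            "ComGC", "ComC", "DprA")
GRAM_NEGATIVE_COMPONENTS = ("PilA", "PilC", "PilD", "PilM", "PilN", "PilO",
                            "PilP", "PilQ", "PilT", "PilU", "ComEA", "ComEC")
FACULTATIVE_COMPONENTS = ("PilU", "ComC")


def detect_competence_loci(replicon: Replicon, roles: dict[str, RoleCall],
                           gram: str = "positive", max_gap: int = 5,
                           min_genes: int = 6) -> list[dict]:
    """Maximal runs of competence-machinery genes.

    Consecutive competence genes in a run are at most ``max_gap`` ranks
    apart and a locus needs at least ``min_genes`` members.  A locus is
    flagged ``complete`` when the mandatory components (everything but
    PilU/ComC) are all present in it.
    """
    if gram == "positive":
        components = GRAM_POSITIVE_COMPONENTS
    elif gram == "negative":
        components = GRAM_NEGATIVE_COMPONENTS
    else:
        raise ValueError(f"unknown gram label {gram!r}")
    mandatory = {c for c in components if c not in FACULTATIVE_COMPONENTS}
    hits = []
    for g in replicon.genes:
        call = roles.get(g.gene_id)
        if call and call.role.startswith("competence:"):
            comp = call.role.split(":", 1)[1]
            if comp in components:
                hits.append((g.rank, g.gene_id, comp))
    loci, run = [], []
    for h in sorted(hits):
        if run and h[0] - run[-1][0] > max_gap:
            loci.append(run)
            run = []
        run.append(h)
    if run:
        loci.append(run)
    out = []
    for run in loci:
        if len(run) < min_genes:
            continue
        present = {c for _r, _g, c in run}
        out.append({"replicon_id": replicon.replicon_id,
                    "start_rank": run[0][0], "end_rank": run[-1][0],
                    "gene_ids": [g for _r, g, _c in run],
                    "components": sorted(present),
                    "complete": mandatory <= present})
    return out


def genome_is_competent(genome: Genome, roles: dict[str, RoleCall],
                        gram: str = "positive") -> bool:
    """All mandatory components present across this genome's loci."""
    if gram == "positive":
        components = GRAM_POSITIVE_COMPONENTS
    else:
        components = GRAM_NEGATIVE_COMPONENTS
    mandatory = {c for c in components if c not in FACULTATIVE_COMPONENTS}
    found: set[str] = set()
    for rep in genome.replicons:
        for locus in detect_competence_loci(rep, roles, gram):
            found.update(locus["components"])
    return mandatory <= found


# ---------------------------------------------------------------------------
# CRISPR spacer matching


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def _best_ungapped(spacer: np.ndarray, target: np.ndarray,
                   match: int = 2, mismatch: int = -3
                   ) -> tuple[int, int, int]:
    """Best-scoring ungapped diagonal segment (score, span, matches)."""
    n, m = len(spacer), len(target)
    best = (-1, 0, 0)
    for off in range(-(n - 1), m):
        lo = max(0, -off)
        hi = min(n, m - off)
        if hi - lo < 4:
            continue
        eq = spacer[lo:hi] == target[lo + off:hi + off]
        contrib = np.where(eq, match, mismatch)
        csum = np.concatenate(([0], np.cumsum(contrib)))
        running_min = np.minimum.accumulate(csum[:-1])
        gains = csum[1:] - running_min
        j = int(np.argmax(gains))
        score = int(gains[j])
        if score <= best[0]:
            continue
        # recover segment [i, j] for match/span bookkeeping
        i = int(np.argmin(csum[:j + 1]))
        seg = eq[i:j + 1]
        best = (score, len(seg), int(seg.sum()))
    return best


def match_spacers(spacers: dict[str, str], targets: dict[str, str],
                  min_identity: float = 0.9, max_length_diff: float = 0.1
                  ) -> list[SpacerMatch]:
    """Ungapped local alignment of every spacer against every target gene,
    on both strands; retain per the identity and length thresholds."""
    out = []
    for sp_id in sorted(spacers):
        sp = spacers[sp_id]
        arrs = {"+": _encode(sp),
                "-": _encode(str(Seq(sp).reverse_complement()))}
        for t_id in sorted(targets):
            tg = _encode(targets[t_id])
            best = None
            for strand, arr in arrs.items():
                score, span, matches = _best_ungapped(arr, tg)
                if span and (best is None or score > best[0]):
                    best = (score, span, matches, strand)
            if best is None:
                continue
            _score, span, matches, strand = best
            identity = matches / span
            length_diff = (len(sp) - span) / len(sp)
            if identity >= min_identity and length_diff < max_length_diff:
                out.append(SpacerMatch(sp_id, t_id, identity, length_diff,
                                       strand, span))
    return out


# ---------------------------------------------------------------------------
# enrichment of R-M systems in MGEs


@dataclass
class EnrichmentRow:
    rm_type: str
    category: str
    observed: int
    expected: float
    oe_ratio: float


def locate_system(system, genomes_by_id: dict[str, Genome],
                  mges: list[MGEAnnotation]) -> str:
    """MGE category of one assembled system.

    ``plasmid`` when the system's replicon is a plasmid; a prophage/ICE/IME
    id's kind when *all* component ranks fall inside one span (straddling
    systems stay chromosomal, flagged); else ``chromosome``.  Overlapping
    spans resolve to the smallest enclosing one with a warning.
    """
    genome = genomes_by_id[system.genome_id]
    rep = genome.replicon(system.replicon_id)
    if rep.kind == "plasmid":
        return "plasmid"
    ranks = system.component_ranks
    enclosing = [m for m in mges if m.replicon_id == rep.replicon_id
                 and all(m.contains(r) for r in ranks)]
    partial = [m for m in mges if m.replicon_id == rep.replicon_id
               and any(m.contains(r) for r in ranks)]
    if not enclosing:
        if partial:
            system.flags.add("mge_straddle")
        return "chromosome"
    if len(enclosing) > 1:
        warnings.warn(f"{system.system_id}: overlapping MGE spans; "
                      "smallest wins", stacklevel=2)
        enclosing.sort(key=lambda m: (m.span, m.mge_id))
    return enclosing[0].kind


def mge_enrichment(systems, genomes: list[Genome],
                   mges: list[MGEAnnotation]) -> pd.DataFrame:
    """Observed/expected table of R-M types across MGE categories.

    Expected(type, category) = total(type) x fraction of all systems in
    the category, so expected counts per type sum to the type's total and
    O/E is 1 under uniform placement.  A chi-square goodness-of-fit p-value
    is attached per category (observed type distribution vs expected).
    """
    genomes_by_id = {g.genome_id: g for g in genomes}
    cats = ("chromosome", "plasmid") + MGE_KINDS
    types = sorted({s.rm_type for s in systems})
    obs = {(t, c): 0 for t in types for c in cats}
    for s in systems:
        cat = locate_system(s, genomes_by_id, mges)
        obs[(s.rm_type, cat)] += 1
    total = len(systems)
    rows = []
    for c in cats:
        cat_total = sum(obs[(t, c)] for t in types)
        frac = cat_total / total if total else 0.0
        observed = [obs[(t, c)] for t in types]
        expected = [sum(obs[(t, cc)] for cc in cats) * frac for t in types]
        if total and cat_total and all(e > 0 for e in expected):
            chi = rmstats.chi_square(observed, expected)
            chi_p = chi.p_value
        else:
            chi_p = float("nan")
        for t, o, e in zip(types, observed, expected):
            rows.append({"rm_type": t, "category": c, "observed": o,
                         "expected": e,
                         "oe_ratio": (o / e) if e else float("nan"),
                         "chi2_p_category": chi_p})
    return pd.DataFrame(rows, columns=["rm_type", "category", "observed",
                                       "expected", "oe_ratio",
                                       "chi2_p_category"])


def element_densities(systems, solitaries, genomes: list[Genome],
                      mges: list[MGEAnnotation]) -> pd.DataFrame:
    """Counts and per-Mb densities of systems and solitary genes per
    element class.  Chromosome tallies exclude prophage-resident elements."""
    genomes_by_id = {g.genome_id: g for g in genomes}
    mges_by_rep: dict[str, list[MGEAnnotation]] = {}
    for m in mges:
        mges_by_rep.setdefault(m.replicon_id, []).append(m)

    def element_class(genome_id: str, replicon_id: str, ranks) -> str:
        rep = genomes_by_id[genome_id].replicon(replicon_id)
        if rep.kind != "chromosome":
            return rep.kind
        for m in mges_by_rep.get(replicon_id, []):
            if all(m.contains(r) for r in ranks):
                return m.kind
        return "chromosome"

    size_bp: dict[str, float] = {"chromosome": 0.0, "plasmid": 0.0,
                                 "phage": 0.0}
    for g in genomes:
        for rep in g.replicons:
            size_bp[rep.kind] = size_bp.get(rep.kind, 0.0) + rep.length_bp
    for m in mges:
        rep = next(r for g in genomes for r in g.replicons
                   if r.replicon_id == m.replicon_id)
        lo = rep.genes[m.start_rank].start
        hi = rep.genes[m.end_rank].end
        size_bp[m.kind] = size_bp.get(m.kind, 0.0) + (hi - lo + 1)
        if rep.kind == "chromosome":
            size_bp["chromosome"] -= (hi - lo + 1)

    counts: dict[tuple[str, str], int] = {}
    for s in systems:
        cls = element_class(s.genome_id, s.replicon_id, s.component_ranks)
        counts[("system", cls)] = counts.get(("system", cls), 0) + 1
    for s in solitaries:
        cls = element_class(s.genome_id, s.replicon_id, (s.rank,))
        key = (f"solitary_{s.role}", cls)
        counts[key] = counts.get(key, 0) + 1
    rows = []
    for (what, cls), n in sorted(counts.items()):
        mb = size_bp.get(cls, 0.0) / 1e6
        rows.append({"element_class": cls, "feature": what, "count": n,
                     "per_mb": n / mb if mb else float("nan")})
    return pd.DataFrame(rows, columns=["element_class", "feature", "count",
                                       "per_mb"])
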