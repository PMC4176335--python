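"""Pairwise protein comparison, role assignment and family clustering.

The similarity engine is a substitution-matrix dynamic-programming aligner
(BLOSUM62, affine gaps) with two modes: Smith-Waterman local alignment and
end-gap-free global alignment.  A Karlin-Altschul-style transform of the
raw score serves as a significance surrogate (``evalue_proxy``); it is only
ever compared against a fixed threshold, so any monotone surrogate would
do.  "Similarity" of an aligned pair is the fraction of aligned columns
with a positive substitution score.

Role assignment scans every gene against a labelled reference library
(FASTA headers carrying ``role=`` / ``rm_type=`` key-value pairs) and keeps
the best passing hit per label.  Precomputed hits in BLAST tabular
(outfmt-6) dialect can be ingested in place of the built-in aligner.

Two clustering algorithms build protein families: Markov clustering (MCL)
over the similarity graph, and single linkage at identity/coverage
thresholds (connected components).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

# Karlin-Altschul parameters for gapped BLOSUM62 (open 11 / extend 1).
KA_LAMBDA = 0.267
KA_K = 0.041

RM_ROLES = ("REase", "MTase", "S")
RM_TYPES = ("I", "II", "III")


@dataclass
class AlignmentStats:
    query_id: str
    subject_id: str
    identity: float
    similarity: float
    query_coverage: float
    subject_coverage: float
    score: float
    evalue_proxy: float
    length_diff: float

    @property
    def coverage_smallest(self) -> float:
        """Fraction of the smaller sequence covered by the alignment."""
        return max(self.query_coverage, self.subject_coverage)


@dataclass
class RoleCall:
    """Functional label of one gene plus every reference label it passed."""

    gene_id: str
    role: str
    rm_type: str  # 'I' | 'II' | 'III' | 'none'
    best_hit: AlignmentStats | None = None
    flags: frozenset = frozenset()  # {(role, rm_type_label), ...}

    def has_flag(self, role: str, rm_type: str = "") -> bool:
        return (role, rm_type) in self.flags


@dataclass
class ClusterConfig:
    method: str = "single_linkage"  # or "mcl"
    inflation: float = 1.4
    identity_min: float = 0.8
    coverage_min: float = 0.8

    def __post_init__(self) -> None:
        if self.method == "mcl" and self.inflation < 1:
            raise ValueError("MCL inflation must be >= 1")


# ---------------------------------------------------------------------------
# aligner


def _make_aligner(mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    if mode == "local":
        al.mode = "local"
    elif mode == "global_endgapfree":
        al.mode = "global"
        al.end_insertion_score = 0.0
        al.end_deletion_score = 0.0
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")
    return al


class ProteinAligner:
    """Shared pairwise protein aligner with score-only fast path."""

    def __init__(self) -> None:
        self._aligners = {m: _make_aligner(m) for m in ("local", "global_endgapfree")}
        self._matrix = substitution_matrices.load("BLOSUM62")
        self._alphabet = set(self._matrix.alphabet)

    def _clean(self, seq: str) -> str:
        seq = seq.upper()
        if not seq:
            raise ValueError("empty sequence")
        bad = set(seq) - self._alphabet
        if bad:
            warnings.warn(f"unknown residues {sorted(bad)} treated as wildcard X",
                          stacklevel=3)
            seq = "".join(c if c in self._alphabet else "X" for c in seq)
        return seq

    def score(self, a: str, b: str, mode: str = "local") -> float:
        return float(self._aligners[mode].score(self._clean(a), self._clean(b)))

    def evalue_proxy(self, score: float, len_a: int, len_b: int) -> float:
        return KA_K * len_a * len_b * math.exp(-KA_LAMBDA * score)

    def stats(self, a: str, b: str, mode: str = "local",
              query_id: str = "query", subject_id: str = "subject") -> AlignmentStats:
        a, b = self._clean(a), self._clean(b)
        aln = self._aligners[mode].align(a, b)[0]
        blocks_a, blocks_b = aln.aligned
        ident = pos = cols = 0
        for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
            for x, y in zip(a[as_:ae], b[bs:be]):
                cols += 1
                if x == y:
                    ident += 1
                if self._matrix[x, y] > 0:
                    pos += 1
        cols = max(cols, 1)
        score = float(aln.score)
        return AlignmentStats(
            query_id=query_id, subject_id=subject_id,
            identity=ident / cols, similarity=pos / cols,
            query_coverage=sum(e - s for s, e in blocks_a) / len(a),
            subject_coverage=sum(e - s for s, e in blocks_b) / len(b),
            score=score, evalue_proxy=self.evalue_proxy(score, len(a), len(b)),
            length_diff=abs(len(a) - len(b)) / max(len(a), len(b)))


_DEFAULT_ALIGNER: ProteinAligner | None = None


def default_aligner() -> ProteinAligner:
    global _DEFAULT_ALIGNER
    if _DEFAULT_ALIGNER is None:
        _DEFAULT_ALIGNER = ProteinAligner()
    return _DEFAULT_ALIGNER


def pairwise_align(a: str, b: str, mode: str = "local",
                   query_id: str = "query",
                   subject_id: str = "subject") -> AlignmentStats:
    """Optimal pairwise alignment statistics for the declared mode."""
    return default_aligner().stats(a, b, mode, query_id, subject_id)


# ---------------------------------------------------------------------------
# shared-k-mer prefilter


def kmer_set(seq: str, k: int = 4) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def shares_kmers(ka: set[str], kb: set[str], min_shared: int = 3) -> bool:
    if len(ka) > len(kb):
        ka, kb = kb, ka
    n = 0
    for kmer in ka:
        if kmer in kb:
            n += 1
            if n >= min_shared:
                return True
    return False


# ---------------------------------------------------------------------------
# reference library


@dataclass
class ReferenceEntry:
    ref_id: str
    role: str
    rm_type: str  # 'I','II','IIC','III','IV' or '' for non-R-M roles
    seq: str
    kmers: set[str] = field(default_factory=set)

    @property
    def label(self) -> tuple[str, str]:
        return (self.role, self.rm_type)


class ReferenceLibrary:
    """Labelled reference protein library (role= / rm_type= FASTA headers)."""

    def __init__(self, entries: Sequence[ReferenceEntry]):
        if not entries:
            raise ValueError("empty reference library")
        self.entries = list(entries)
        for e in self.entries:
            if not e.kmers:
                e.kmers = kmer_set(e.seq)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceLibrary":
        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            kv = dict(tok.split("=", 1) for tok in rec.description.split()
                      if "=" in tok)
            entries.append(ReferenceEntry(rec.id, kv.get("role", "other"),
                                          kv.get("rm_type", ""), str(rec.seq)))
        return cls(entries)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                tag = f" rm_type={e.rm_type}" if e.rm_type else ""
                fh.write(f">{e.ref_id} role={e.role}{tag}\n{e.seq}\n")


@dataclass
class RoleThresholds:
    """Hit-retention thresholds for role assignment.

    ``coverage_roles`` lists labels additionally requiring a minimum
    subject-coverage (the BLAST-searched Type II / Type IV REase roles).
    """

    evalue_max: float = 1e-3
    subject_coverage_min: float = 0.5
    coverage_roles: frozenset = frozenset({("REase", "II"), ("REase", "IV")})


def _call_from_flags(gene_id: str, passing: dict[tuple[str, str], AlignmentStats]
                     ) -> RoleCall:
    flags = frozenset(passing)
    # one polypeptide passing both an REase and an MTase reference encodes
    # both functions: a Type IIC fusion protein
    rease_labels = [lb for lb in flags if lb[0] == "REase"]
    mtase_labels = [lb for lb in flags if lb[0] == "MTase"]
    if rease_labels and mtase_labels:
        best = max((passing[lb] for lb in rease_labels + mtase_labels),
                   key=lambda h: (h.score, h.subject_id))
        return RoleCall(gene_id, "IIC", "none", best, flags)
    if not flags:
        return RoleCall(gene_id, "other", "none", None, flags)
    label = max(flags, key=lambda lb: (passing[lb].score, lb))
    role, rmt = label
    hit = passing[label]
    if role == "REase" and rmt == "IV":
        return RoleCall(gene_id, "TypeIV_REase", "none", hit, flags)
    if role in RM_ROLES and rmt in RM_TYPES:
        return RoleCall(gene_id, role, rmt, hit, flags)
    return RoleCall(gene_id, role, "none", hit, flags)


def assign_roles(genes: dict[str, str], reference: ReferenceLibrary,
                 thresholds: RoleThresholds | None = None,
                 aligner: ProteinAligner | None = None,
                 prefilter: bool = True) -> dict[str, RoleCall]:
    """Assign each gene the role of its best passing reference hit.

    ``genes`` maps gene_id to protein sequence.  A gene passing both the
    Type IIC REase and Type IIC MTase references (a single polypeptide with
    both functions) is called ``IIC``.  Genes with no passing hit are
    ``other``.  ``prefilter=False`` disables the shared-k-mer screen and
    aligns every gene against every reference.
    """
    thresholds = thresholds or RoleThresholds()
    aligner = aligner or default_aligner()
    calls: dict[str, RoleCall] = {}
    for gid in sorted(genes):
        seq = genes[gid]
        gk = kmer_set(seq) if prefilter else None
        passing: dict[tuple[str, str], AlignmentStats] = {}
        for entry in reference.entries:
            if prefilter and not shares_kmers(gk, entry.kmers):
                continue
            score = aligner.score(seq, entry.seq, "local")
            if aligner.evalue_proxy(score, len(seq), len(entry.seq)) >= thresholds.evalue_max:
                continue
            hit = aligner.stats(seq, entry.seq, "local", gid, entry.ref_id)
            if (entry.label in thresholds.coverage_roles
                    and hit.subject_coverage < thresholds.subject_coverage_min):
                continue
            prev = passing.get(entry.label)
            if (prev is None or hit.score > prev.score
                    or (hit.score == prev.score and hit.subject_id < prev.subject_id)):
                passing[entry.label] = hit
        calls[gid] = _call_from_flags(gid, passing)
    return calls


def read_blast_tab(path: str | Path, seq_lengths: dict[str, int] | None = None
                   ) -> list[AlignmentStats]:
    """Ingest BLAST tabular (outfmt 6) hits as AlignmentStats.

    Coverage fields require ``seq_lengths``; without it they are reported
    as the aligned length over the span seen in the table (upper bound 1).
    Similarity is approximated by identity (tabular output carries no
    positives column), which is conservative for the 80% similarity filter.
    """
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        (qid, sid, pident, length, _mm, _go, qstart, qend, sstart, send,
         evalue, bitscore) = line.split("\t")[:12]
        length = int(length)
        if seq_lengths:
            qlen, slen = seq_lengths[qid], seq_lengths[sid]
            qcov, scov = length / qlen, length / slen
            ldiff = abs(qlen - slen) / max(qlen, slen)
        else:
            qcov = scov = 1.0
            ldiff = 0.0
        ident = float(pident) / 100.0
        out.append(AlignmentStats(qid, sid, ident, ident, min(qcov, 1.0),
                                  min(scov, 1.0), float(bitscore),
                                  float(evalue), ldiff))
    return out


# ---------------------------------------------------------------------------
# bidirectional best hits


def bbh_pairs(proteome_a: dict[str, str], proteome_b: dict[str, str],
              min_similarity: float = 0.8, max_length_diff: float = 0.2,
              aligner: ProteinAligner | None = None, prefilter: bool = True
              ) -> list[AlignmentStats]:
    """Reciprocal best hits between two proteomes (end-gap-free global).

    Hits below ``min_similarity`` (fraction of aligned columns with a
    positive substitution score) or above ``max_length_diff`` relative
    length difference are discarded.  Score ties are broken toward the
    lexicographically smallest partner id and flagged with a warning.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    aligner = aligner or default_aligner()
    ids_a, ids_b = sorted(proteome_a), sorted(proteome_b)
    kb = {j: kmer_set(proteome_b[j]) for j in ids_b} if prefilter else None
    scores: dict[str, list[tuple[float, str]]] = {i: [] for i in ids_a}
    back: dict[str, list[tuple[float, str]]] = {j: [] for j in ids_b}
    for i in ids_a:
        ka = kmer_set(proteome_a[i]) if prefilter else None
        for j in ids_b:
            if prefilter and not shares_kmers(ka, kb[j]):
                continue
            s = aligner.score(proteome_a[i], proteome_b[j], "global_endgapfree")
            scores[i].append((s, j))
            back[j].append((s, i))

    def _best(cands: list[tuple[float, str]]) -> str | None:
        if not cands:
            return None
        top = max(s for s, _ in cands)
        ids = sorted(j for s, j in cands if s == top)
        if len(ids) > 1:
            warnings.warn(f"best-hit tie broken toward {ids[0]}", stacklevel=2)
        return ids[0]

    pairs = []
    for i in ids_a:
        j = _best(scores[i])
        if j is None or _best(back[j]) != i:
            continue
        hit = aligner.stats(proteome_a[i], proteome_b[j], "global_endgapfree", i, j)
        if hit.similarity >= min_similarity and hit.length_diff <= max_length_diff:
            pairs.append(hit)
    return pairs


def all_vs_all(proteome: dict[str, str], evalue_max: float = 1e-4,
               aligner: ProteinAligner | None = None, prefilter: bool = True
               ) -> list[AlignmentStats]:
    """All-against-all local-alignment hits within one protein set."""
    aligner = aligner or default_aligner()
    ids = sorted(proteome)
    km = {i: kmer_set(proteome[i]) for i in ids} if prefilter else None
    hits = []
    for x, i in enumerate(ids):
        for j in ids[x + 1:]:
            if prefilter and not shares_kmers(km[i], km[j]):
                continue
            s = aligner.score(proteome[i], proteome[j], "local")
            if aligner.evalue_proxy(s, len(proteome[i]), len(proteome[j])) >= evalue_max:
                continue
            hits.append(aligner.stats(proteome[i], proteome[j], "local", i, j))
    return hits


# ---------------------------------------------------------------------------
# clustering


def _mcl_partition(ids: list[str], weights: dict[tuple[str, str], float],
                   inflation: float, tol: float = 1e-6,
                   max_iter: int = 200) -> list[set[str]]:
    n = len(ids)
    idx = {v: k for k, v in enumerate(ids)}
    m = np.zeros((n, n))
    for (a, b), w in weights.items():
        i, j = idx[a], idx[b]
        m[i, j] = max(m[i, j], w)
        m[j, i] = max(m[j, i], w)
    # self-loops at the weight of the heaviest incident edge
    diag = m.max(axis=0)
    diag[diag == 0] = 1.0
    np.fill_diagonal(m, diag)
    m = m / m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = m @ m
        inflated = np.power(expanded, inflation)
        inflated[inflated < 1e-12] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        new = inflated / colsum
        change = float(np.abs(new - m).max())
        m = new
        if change < tol:
            break
    else:
        raise RuntimeError(f"MCL did not converge (residual {change:.2e})")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    rows, cols = np.nonzero(m > 1e-6)
    g.add_edges_from(zip(rows.tolist(), cols.tolist()))
    return [{ids[i] for i in comp} for comp in nx.connected_components(g)]


def cluster_families(hits: Iterable[AlignmentStats], config: ClusterConfig,
                     all_ids: Iterable[str] = ()) -> dict[str, str]:
    """Partition sequences into families; returns member_id -> family_id.

    ``mcl`` mode runs Markov clustering on the (symmetrised, max-score)
    similarity graph; ``single_linkage`` takes connected components of the
    graph whose edges pass ``identity_min`` and coverage-of-the-smallest
    ``coverage_min``.  Ids in ``all_ids`` with no qualifying edge become
    singleton families.  Family ids are ``F000000``-style, assigned in
    order of the lexicographically smallest member.
    """
    hits = list(hits)
    nodes = set(all_ids)
    for h in hits:
        nodes.update((h.query_id, h.subject_id))
    ids = sorted(nodes)
    if config.method == "mcl":
        weights: dict[tuple[str, str], float] = {}
        for h in hits:
            if h.query_id == h.subject_id:
                continue
            key = tuple(sorted((h.query_id, h.subject_id)))
            weights[key] = max(weights.get(key, 0.0), h.score)
        comps = _mcl_partition(ids, weights, config.inflation)
    elif config.method == "single_linkage":
        g = nx.Graph()
        g.add_nodes_from(ids)
        for h in hits:
            if (h.query_id != h.subject_id
                    and h.identity >= config.identity_min
                    and h.coverage_smallest >= config.coverage_min):
                g.add_edge(h.query_id, h.subject_id)
        comps = [set(c) for c in nx.connected_components(g)]
    else:
        raise ValueError(f"unknown clustering method {config.method!r}")
    comps.sort(key=lambda c: min(c))
    out = {}
    for k, comp in enumerate(comps):
        fid = f"F{k:06d}"
        for member in comp:
            out[member] = fid
    return out
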