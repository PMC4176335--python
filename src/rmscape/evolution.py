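"""Pairwise dN/dS estimation by codon counting.

Two counting estimators are provided.  ``ng86`` follows the classic
Nei-Gojobori scheme: synonymous/nonsynonymous site opportunities counted
per codon with equal weight on every legal single-nucleotide change,
differences counted by enumerating every substitution pathway between a
codon pair (pathways through stop codons are discarded; each remaining
pathway weighs equally), and a Jukes-Cantor multiple-hit correction.
``yn00`` implements a Yang-Nielsen (2000)-style refinement: a
transition/transversion ratio kappa estimated from fourfold-degenerate
third positions (K80 formulae), site opportunities weighted by kappa and
F3x4 codon-position nucleotide frequencies, transition/transversion
difference classes tracked separately, and a K80-style correction applied
to the synonymous and nonsynonymous classes independently.

Conventions shared by both estimators (documented here because counting
variants differ across programs): changes to stop codons are excluded
from site opportunity; each codon carries three sites split
proportionally to its (weighted) synonymous fraction, so S + N = 3L;
gap-bearing codon columns are removed pairwise before estimation; omega
is undefined (NaN) when dS = 0; estimates with dS > 1 are flagged
saturated and must be discarded from selection summaries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import log

import numpy as np
import pandas as pd

from .codons import CODON_TO_AA, STOP_CODONS, TRANSITION as _TRANSITION
from . import stats as rmstats

_NTS = "ACGT"
FOURFOLD_PREFIXES = {p for p in
                     {c[:2] for c in CODON_TO_AA}
                     if all(p + nt in CODON_TO_AA
                            and CODON_TO_AA[p + nt] == CODON_TO_AA[p + "A"]
                            for nt in _NTS)}


@dataclass
class SubstitutionEstimate:
    id_a: str
    id_b: str
    dN: float
    dS: float
    omega: float
    kappa: float
    S: float
    N: float
    pS: float
    pN: float
    n_codons: int
    flags: set = field(default_factory=set)

    @property
    def saturated(self) -> bool:
        return self.dS > 1 or "saturated_overflow" in self.flags


# ---------------------------------------------------------------------------
# codon alignment back-threading


def backtranslate_alignment(prot_aln: tuple[str, str], dna_a: str, dna_b: str
                            ) -> tuple[str, str]:
    """Thread DNA onto an aligned protein pair (every protein gap becomes
    a triplet gap).  Trailing stop codons are stripped; a translation
    mismatch or internal stop raises with the offending position."""
    out = []
    for aln, dna, tag in ((prot_aln[0], dna_a, "a"), (prot_aln[1], dna_b, "b")):
        ungapped = aln.replace("-", "")
        if len(dna) == 3 * (len(ungapped) + 1) and dna[-3:] in STOP_CODONS:
            dna = dna[:-3]
        if len(dna) != 3 * len(ungapped):
            raise ValueError(f"sequence {tag}: DNA length {len(dna)} does not "
                             f"match {len(ungapped)} residues")
        codons = [dna[i:i + 3] for i in range(0, len(dna), 3)]
        for i, (codon, aa) in enumerate(zip(codons, ungapped)):
            if codon in STOP_CODONS:
                raise ValueError(f"sequence {tag}: internal stop at codon {i}")
            if CODON_TO_AA.get(codon) != aa:
                raise ValueError(f"sequence {tag}: codon {codon} at {i} does "
                                 f"not encode {aa}")
        it = iter(codons)
        out.append("".join("---" if c == "-" else next(it) for c in aln))
    return out[0], out[1]


def _degap(codon_aln: tuple[str, str]) -> list[tuple[str, str]]:
    a, b = codon_aln
    if len(a) != len(b) or len(a) % 3:
        raise ValueError("codon alignment strings must have equal 3n length")
    pairs = []
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if "-" in ca or "-" in cb:
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"stop codon in alignment at column {i // 3}")
        pairs.append((ca, cb))
    if not pairs:
        raise ValueError("no alignable codons")
    return pairs


# ---------------------------------------------------------------------------
# site and difference counting


def _codon_site_split(codon: str, kappa: float = 1.0,
                      pi: np.ndarray | None = None) -> tuple[float, float]:
    """(synonymous, nonsynonymous) share of this codon's three sites."""
    aa = CODON_TO_AA[codon]
    w_syn = w_tot = 0.0
    for pos in range(3):
        for nt in _NTS:
            if nt == codon[pos]:
                continue
            new = codon[:pos] + nt + codon[pos + 1:]
            if new in STOP_CODONS:
                continue
            w = kappa if _TRANSITION[codon[pos]] == nt else 1.0
            if pi is not None:
                w *= pi[pos, _NTS.index(nt)]
            w_tot += w
            if CODON_TO_AA[new] == aa:
                w_syn += w
    if w_tot == 0:
        return 0.0, 3.0
    s = 3.0 * w_syn / w_tot
    return s, 3.0 - s


def _pathway_table(ca: str, cb: str) -> list[list[tuple[bool, bool]]]:
    """Step classifications of every substitution pathway from ca to cb.

    Each pathway is a list of (is_synonymous, is_transition) steps in
    order.  Pathways through stop codons are excluded; if every ordering
    passes through a stop, all orderings are kept instead (counting the
    stop-crossing steps as they fall).
    """
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return []

    def walk(order, forbid_stops: bool):
        cur = ca
        steps = []
        for pos in order:
            new = cur[:pos] + cb[pos] + cur[pos + 1:]
            if forbid_stops and new in STOP_CODONS:
                return None
            steps.append((CODON_TO_AA.get(new) == CODON_TO_AA.get(cur),
                          _TRANSITION[cur[pos]] == cb[pos]))
            cur = new
        return steps

    valid = [s for order in itertools.permutations(diff)
             if (s := walk(order, True)) is not None]
    if not valid:
        valid = [walk(order, False) for order in itertools.permutations(diff)]
    return valid


def _pathway_steps(ca: str, cb: str, kappa: float = 1.0, omega: float = 1.0
                   ) -> tuple[float, float, float, float]:
    """Pathway-averaged (syn, nonsyn, syn_ts, nonsyn_ts) difference counts.

    Orderings are weighted by their relative probability under the
    substitution model: each step contributes ``kappa`` if a transition
    and ``omega`` if nonsynonymous.  Equal weights (kappa = omega = 1)
    reproduce the classic equal-pathway average.
    """
    table = _pathway_table(ca, cb)
    if not table:
        return 0.0, 0.0, 0.0, 0.0
    totals = np.zeros(4)
    weights = 0.0
    for steps in table:
        w = 1.0
        counts = np.zeros(4)
        for syn, ts in steps:
            w *= (kappa if ts else 1.0) * (1.0 if syn else omega)
            if syn:
                counts[0] += 1
                counts[2] += ts
            else:
                counts[1] += 1
                counts[3] += ts
        totals += w * counts
        weights += w
    if weights == 0:
        weights = len(table)
        totals = np.sum([[sum(s for s, _t in p), sum(1 for s, _t in p if not s),
                          sum(t for s, t in p if s),
                          sum(t for s, t in p if not s)]
                         for p in table], axis=0, dtype=float)
    return tuple(totals / weights)


def _estimate_kappa(pairs: list[tuple[str, str]]) -> float:
    """K80 kappa from fourfold-degenerate third positions."""
    n = ts = tv = 0
    for ca, cb in pairs:
        if ca[:2] == cb[:2] and ca[:2] in FOURFOLD_PREFIXES:
            n += 1
            if ca[2] != cb[2]:
                if _TRANSITION[ca[2]] == cb[2]:
                    ts += 1
                else:
                    tv += 1
    if n < 10:
        return 1.0
    P, Q = ts / n, tv / n
    if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
        return 1.0
    A = -0.5 * log(1 - 2 * P - Q) + 0.25 * log(1 - 2 * Q)
    B = -0.5 * log(1 - 2 * Q)
    if B <= 0:
        return 1.0
    kappa = 2 * A / B
    return max(kappa, 0.1)


def _f3x4(pairs: list[tuple[str, str]]) -> np.ndarray:
    pi = np.zeros((3, 4))
    for ca, cb in pairs:
        for codon in (ca, cb):
            for pos in range(3):
                pi[pos, _NTS.index(codon[pos])] += 1
    return pi / pi.sum(axis=1, keepdims=True)


def _jc_correct(p: float) -> tuple[float, bool]:
    if p <= 0:
        return 0.0, False
    if p >= 0.75:
        return float("inf"), True
    return -0.75 * log(1 - 4 * p / 3), False


def _k80_correct(P: float, Q: float) -> tuple[float, bool]:
    if P == 0 and Q == 0:
        return 0.0, False
    if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
        return float("inf"), True
    return -0.5 * log(1 - 2 * P - Q) - 0.25 * log(1 - 2 * Q), False


def estimate_dnds(codon_aln: tuple[str, str], method: str = "yn00",
                  id_a: str = "a", id_b: str = "b",
                  kappa: float | None = None) -> SubstitutionEstimate:
    """Pairwise dN/dS for one gap-stripped codon alignment.

    ``ng86``: equal-weight sites, Jukes-Cantor correction.  ``yn00``:
    kappa/F3x4-weighted sites and class-wise K80 correction; ``kappa``
    overrides the built-in fourfold-site estimate.  The two estimators
    are symmetric in sequence order.
    """
    pairs = _degap(codon_aln)
    L = len(pairs)
    flags: set = set()
    if method == "ng86":
        k_used = 1.0
        pi = None
    elif method == "yn00":
        k_used = kappa if kappa is not None else _estimate_kappa(pairs)
        pi = _f3x4(pairs)
    else:
        raise ValueError(f"unknown method {method!r}")
    S = N = 0.0
    for ca, cb in pairs:
        sa, na = _codon_site_split(ca, k_used, pi)
        sb, nb = _codon_site_split(cb, k_used, pi)
        S += (sa + sb) / 2
        N += (na + nb) / 2

    def count_and_correct(kappa_w: float, omega_w: float):
        Sd = Nd = Sd_ts = Nd_ts = 0.0
        for ca, cb in pairs:
            syn, non, syn_ts, non_ts = _pathway_steps(ca, cb, kappa_w, omega_w)
            Sd += syn
            Nd += non
            Sd_ts += syn_ts
            Nd_ts += non_ts
        pS = Sd / S if S else 0.0
        pN = Nd / N if N else 0.0
        if method == "ng86":
            dS, sat_s = _jc_correct(pS)
            dN, sat_n = _jc_correct(pN)
        else:
            dS, sat_s = _k80_correct(Sd_ts / S if S else 0.0,
                                     (Sd - Sd_ts) / S if S else 0.0)
            dN, sat_n = _k80_correct(Nd_ts / N if N else 0.0,
                                     (Nd - Nd_ts) / N if N else 0.0)
        return dN, dS, pN, pS, sat_s or sat_n

    if method == "ng86":
        dN, dS, pN, pS, sat = count_and_correct(1.0, 1.0)
    else:
        # iterate omega in the pathway weights until self-consistent
        omega_w = 1.0
        dN, dS, pN, pS, sat = count_and_correct(k_used, omega_w)
        for _ in range(30):
            if not (dS > 0 and np.isfinite(dS) and np.isfinite(dN)):
                break
            new_w = max(dN / dS, 1e-4)
            if abs(new_w - omega_w) < 1e-4:
                break
            omega_w = new_w
            dN, dS, pN, pS, sat = count_and_correct(k_used, omega_w)
    if sat:
        flags.add("saturated_overflow")
    omega = dN / dS if dS > 0 and np.isfinite(dS) and np.isfinite(dN) \
        else float("nan")
    return SubstitutionEstimate(id_a, id_b, dN, dS, omega, k_used, S, N,
                                pS, pN, L, flags)


# ---------------------------------------------------------------------------
# selection summaries


def summarize_selection(grouped: list[tuple[str, SubstitutionEstimate]]
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group omega summaries plus pairwise Mann-Whitney comparisons.

    ``grouped`` pairs a group label (e.g. "MTase:II") with an estimate.
    Saturated estimates (dS > 1 or overflow) and undefined omegas are
    removed before summarising; groups left with fewer than two usable
    estimates are reported without tests.
    """
    usable: dict[str, list[float]] = {}
    removed = 0
    for label, est in grouped:
        if est.saturated or not np.isfinite(est.omega):
            removed += 1
            continue
        usable.setdefault(label, []).append(est.omega)
    rows = []
    for label in sorted(usable):
        vals = np.array(usable[label])
        rows.append({"group": label, "n": len(vals),
                     "mean_omega": float(vals.mean()),
                     "sd_omega": float(vals.std(ddof=1)) if len(vals) > 1
                     else float("nan")})
    summary = pd.DataFrame(rows, columns=["group", "n", "mean_omega",
                                          "sd_omega"])
    summary.attrs["n_removed_saturated_or_undefined"] = removed
    comps = []
    labels = sorted(usable)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            if len(usable[la]) < 2 or len(usable[lb]) < 2:
                comps.append({"group_a": la, "group_b": lb,
                              "statistic": float("nan"),
                              "p_value": float("nan"), "method": "none"})
                continue
            res = rmstats.mann_whitney_u(usable[la], usable[lb])
            comps.append({"group_a": la, "group_b": lb,
                          "statistic": res.statistic, "p_value": res.p_value,
                          "method": res.method})
    comparisons = pd.DataFrame(comps, columns=["group_a", "group_b",
                                               "statistic", "p_value",
                                               "method"])
    return summary, comparisons
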