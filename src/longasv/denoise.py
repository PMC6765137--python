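"""ASV inference by divisive partitioning under the error model.

Dereplicated reads start in a single partition centered on the most
abundant sequence.  For every unique sequence the model gives the
probability (lambda) that a read of its partition center would be misread
as that exact sequence; comparing the observed abundance against the
expected number of such error reads (Poisson) yields an abundance p-value.
The most significant unique is split off as a new partition center, all
uniques are reassigned to the center most likely to have produced them,
and the cycle repeats until nothing is significant.  Partition centers are
the inferred amplicon sequence variants (ASVs).

Pairwise comparisons use a kmer prefilter (skip pairs that are too
distant; use the positional ungapped alignment when the ordered kmer
overlap proves it optimal) and otherwise a banded Needleman-Wunsch
alignment.  Inference is fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammainc, gammaln

from . import _align
from .errormodel import ErrorModel
from .seqio import QualRead

__all__ = [
    "UniqueSequence",
    "Partition",
    "DadaResult",
    "dereplicate",
    "kmer_screen",
    "align_banded",
    "compute_lambda",
    "abundance_pvalue",
    "run_dada",
    "make_asv_table",
]

_LN10 = math.log(10.0)

DEFAULT_K = 8
DEFAULT_KDIST_CUTOFF = 0.42
DEFAULT_BAND = 32
DEFAULT_OMEGA_A = 1e-40
MATCH, MISMATCH, GAP = 5.0, -4.0, -8.0


@dataclass
class UniqueSequence:
    """A dereplicated sequence: distinct string, multiplicity, mean quality."""

    sequence: str
    abundance: int
    quality_profile: np.ndarray  # per-position mean quality (float)

    def __post_init__(self):
        if self.abundance < 1:
            raise ValueError("abundance must be >= 1")
        self.quality_profile = np.asarray(self.quality_profile, dtype=float)
        if len(self.quality_profile) != len(self.sequence):
            raise ValueError("quality profile length != sequence length")
        self.encoded = _align.encode(self.sequence)
        self.rounded_quality = np.clip(
            np.rint(self.quality_profile), 0, 93).astype(np.int64)


def dereplicate(reads: Iterable[QualRead]) -> list[UniqueSequence]:
    """Collapse identical read sequences into unique sequences.

    Output is sorted by descending abundance, ties broken lexicographically
    by sequence.  Quality profiles are position-wise arithmetic means over
    the collapsed reads.
    """
    acc: dict[str, list] = {}
    for read in reads:
        entry = acc.get(read.nucleotides)
        if entry is None:
            acc[read.nucleotides] = [1, read.qualities.astype(np.float64).copy()]
        else:
            entry[0] += 1
            entry[1] += read.qualities
    uniques = [UniqueSequence(seq, n, qsum / n)
               for seq, (n, qsum) in acc.items()]
    uniques.sort(key=lambda u: (-u.abundance, u.sequence))
    return uniques


def kmer_screen(a, b, k: int = DEFAULT_K) -> dict:
    """Kmer distance and ungapped-optimality check for a sequence pair.

    kdist = 1 - (multiset kmer overlap) / (smaller kmer count).  When the
    in-sequence-order kmer overlap equals the multiset overlap, no shift
    improves the matching and the positional (ungapped) alignment is taken
    as optimal downstream.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    ea = a if isinstance(a, np.ndarray) else _align.encode(a)
    eb = b if isinstance(b, np.ndarray) else _align.encode(b)
    if len(ea) < k or len(eb) < k:
        raise ValueError("sequences must be at least k long")
    ka = _align.kmer_indices(ea, k)
    kb = _align.kmer_indices(eb, k)
    unordered = _align.multiset_overlap(np.sort(ka), np.sort(kb))
    ordered = _align.ordered_overlap(ka, kb)
    nmin = min(len(ka), len(kb))
    return {"kdist": 1.0 - unordered / nmin,
            "ungapped_is_optimal": ordered == unordered}


def align_banded(a, b, band: int = DEFAULT_BAND,
                 scoring: tuple[float, float, float] = (MATCH, MISMATCH, GAP)):
    """Banded global alignment of two sequences.

    Returns (score, gapped_a, gapped_b, (a_idx, b_idx)) or None when the
    length difference reaches the band (the pair is treated as unrelated).
    a_idx/b_idx give, per alignment column, the position in each input
    sequence or -1 at a gap.  Ties prefer diagonal, then up, then left.
    """
    sa = a.sequence if isinstance(a, UniqueSequence) else a
    sb = b.sequence if isinstance(b, UniqueSequence) else b
    ea = sa if isinstance(sa, np.ndarray) else _align.encode(sa)
    eb = sb if isinstance(sb, np.ndarray) else _align.encode(sb)
    res = _align.banded_nw(ea, eb, band, *scoring)
    if res is None:
        return None
    score, ai, bi = res
    ga = "".join(sa[i] if i >= 0 else "-" for i in ai) \
        if isinstance(sa, str) else None
    gb = "".join(sb[j] if j >= 0 else "-" for j in bi) \
        if isinstance(sb, str) else None
    return score, ga, gb, (ai, bi)


def _log10_lambda(member_enc: np.ndarray, member_q: np.ndarray,
                  center_enc: np.ndarray, aln, model: ErrorModel) -> float:
    """Sum of log10 per-column transition rates for member given center.

    ``aln`` is (member_idx, center_idx) with -1 at gaps, or None for the
    positional alignment of equal-length sequences.  Indel columns each
    contribute the model's quality-independent indel rate.
    """
    lr = model.log10_rates
    if aln is None:
        return float(lr[center_enc, member_enc, member_q].sum())
    mi, ci = aln
    both = (mi >= 0) & (ci >= 0)
    n_indel = int(len(mi) - both.sum())
    mij, cij = mi[both], ci[both]
    s = float(lr[center_enc[cij], member_enc[mij], member_q[mij]].sum())
    return s + n_indel * math.log10(model.indel_rate)


def compute_lambda(member: UniqueSequence, center, alignment,
                   model: ErrorModel) -> float:
    """Probability that a read of the center is sequenced as the member.

    Product over alignment columns of rate(true = center base, observed =
    member base, q = member's rounded mean quality); indel columns use the
    model's indel rate.  The member's quality profile must lie in [0, 93].
    """
    if member.rounded_quality.min() < 0 or member.rounded_quality.max() > 93:
        raise ValueError("quality outside 0-93")
    cenc = center.encoded if isinstance(center, UniqueSequence) \
        else (_align.encode(center) if isinstance(center, str) else center)
    aln = alignment[3] if isinstance(alignment, tuple) and len(alignment) == 4 \
        else alignment
    return 10.0 ** _log10_lambda(member.encoded, member.rounded_quality,
                                 cenc, aln, model)


def _log10_pA(log10_mu: float, a: int) -> float:
    """log10 P(X >= a | X >= 1) for X ~ Poisson(mu), stable for tiny mu."""
    if a == 1:
        return 0.0
    if log10_mu == -math.inf:
        return -math.inf
    if log10_mu > -8.0:
        mu = 10.0 ** log10_mu
        num = float(gammainc(a, mu))  # P(X >= a)
        den = -math.expm1(-mu)
        if num > 0.0:
            return math.log10(num / den)
    # small-mu regime: P ~ mu^(a-1) / a!
    ln_mu = log10_mu * _LN10
    return ((a - 1) * ln_mu - float(gammaln(a + 1))) / _LN10


def abundance_pvalue(lam: float, n_center: int, a: int) -> float:
    """P(X >= a | X >= 1) with X ~ Poisson(n_center * lam).

    The probability that a sequence produced as an error of its partition
    center (per-read probability lam, n_center partition reads) is seen at
    least ``a`` times, conditioned on being seen at all.  Values below the
    smallest positive double underflow to 0.0.
    """
    if not (0.0 < lam <= 1.0):
        raise ValueError("lambda must be in (0, 1]")
    if a < 1:
        raise ValueError("abundance must be >= 1")
    if n_center < a:
        raise ValueError("n_center must be >= a")
    log10_mu = math.log10(n_center) + math.log10(lam)
    return 10.0 ** _log10_pA(log10_mu, a)


@dataclass
class Partition:
    """A denoising cluster: center unique plus its assigned members."""

    center: UniqueSequence
    members: list[UniqueSequence] = field(default_factory=list)
    lambdas: list[float] = field(default_factory=list)  # log10 lambda
    p_A: float = 1.0  # most significant member p-value

    @property
    def abundance(self) -> int:
        return sum(m.abundance for m in self.members)


@dataclass
class DadaResult:
    """Output of run_dada: partitions, ASVs, per-unique assignment."""

    partitions: list[Partition]
    asvs: list[tuple[str, int]]  # (sequence, abundance), partition order
    assignment: np.ndarray  # unique index -> partition index
    centers: list[int]  # partition index -> unique index of center
    alignments: list  # unique index -> (m_idx, c_idx) vs its center, or None
    log_lambdas: np.ndarray  # unique index -> log10 lambda vs its center
    unaligned: set = field(default_factory=set)  # uniques with no alignment

    def asv_abundance(self) -> dict[str, int]:
        return dict(self.asvs)


def _lambda_column(uniques, kord, ksort, center_idx: int, model: ErrorModel,
                   kdist_cutoff: float, band: int, want_aln: bool = False):
    """log10 lambda of every unique against one center (-inf = skipped)."""
    n = len(uniques)
    col = np.full(n, -np.inf)
    alns: list = [None] * n
    c = uniques[center_idx]
    nk_c = len(kord[center_idx])
    for i in range(n):
        u = uniques[i]
        if i == center_idx:
            col[i] = _log10_lambda(u.encoded, u.rounded_quality, c.encoded,
                                   None, model)
            continue
        unordered = _align.multiset_overlap(ksort[i], ksort[center_idx])
        nmin = min(len(kord[i]), nk_c)
        if 1.0 - unordered / nmin > kdist_cutoff:
            continue
        ordered = _align.ordered_overlap(kord[i], kord[center_idx])
        if ordered == unordered and len(u.encoded) == len(c.encoded):
            aln = None
        else:
            res = _align.banded_nw(u.encoded, c.encoded, band,
                                   MATCH, MISMATCH, GAP)
            if res is None:
                continue
            aln = (res[1], res[2])
        col[i] = _log10_lambda(u.encoded, u.rounded_quality, c.encoded,
                               aln, model)
        if want_aln:
            alns[i] = aln
    return (col, alns) if want_aln else col


def run_dada(uniques: Sequence[UniqueSequence], model: ErrorModel,
             omega_a: float = DEFAULT_OMEGA_A,
             kdist_cutoff: float = DEFAULT_KDIST_CUTOFF,
             band: int = DEFAULT_BAND, k: int = DEFAULT_K,
             max_partitions: Optional[int] = None) -> DadaResult:
    """Infer ASVs from dereplicated reads by divisive partitioning.

    Greedy loop: promote the member with the smallest abundance p-value to
    a new partition center whenever p_A times the number of uniques
    (Bonferroni) falls below omega_a; after each promotion reassign every
    unique to the center giving it the largest lambda (pairs beyond the
    kmer cutoff or the band contribute lambda = 0).  Singletons are never
    promoted (their p-value is 1 by construction).  Deterministic.
    """
    uniques = list(uniques)
    n = len(uniques)
    if n == 0:
        raise ValueError("no unique sequences to denoise")
    k = max(1, min(k, min(len(u.sequence) for u in uniques)))
    ab = np.array([u.abundance for u in uniques], dtype=np.int64)
    kord = [_align.kmer_indices(u.encoded, k) for u in uniques]
    ksort = [np.sort(x) for x in kord]

    log_omega = math.log10(omega_a) - math.log10(n) if omega_a > 0 else -math.inf
    centers = [0]
    is_center = np.zeros(n, dtype=bool)
    is_center[0] = True
    lam_cols = [_lambda_column(uniques, kord, ksort, 0, model,
                               kdist_cutoff, band)]
    lam = np.column_stack(lam_cols)
    assign = np.zeros(n, dtype=np.int64)

    while True:
        part_tot = np.bincount(assign, weights=ab, minlength=len(centers)
                               ).astype(np.int64)
        best_i, best_logp = -1, math.inf
        logp_arr = np.full(n, np.inf)
        for i in range(n):
            if is_center[i] or ab[i] < 2:
                continue
            p = assign[i]
            ll = lam[i, p]
            log10_mu = (math.log10(part_tot[p]) + ll) if ll > -np.inf \
                else -math.inf
            lp = _log10_pA(log10_mu, int(ab[i]))
            logp_arr[i] = lp
            # ties: higher abundance, then input (lexical) order
            if lp < best_logp or (lp == best_logp and best_i >= 0
                                  and ab[i] > ab[best_i]):
                best_i, best_logp = i, lp
        if omega_a <= 0 or best_i < 0 or best_logp >= log_omega:
            break
        if max_partitions is not None and len(centers) >= max_partitions:
            break
        centers.append(best_i)
        is_center[best_i] = True
        lam_cols.append(_lambda_column(uniques, kord, ksort, best_i, model,
                                       kdist_cutoff, band))
        lam = np.column_stack(lam_cols)
        assign = np.argmax(lam, axis=1)
        # uniques unreachable from every center stay with the first center
        assign[np.all(np.isinf(lam) & (lam < 0), axis=1)] = 0
        for p, ci in enumerate(centers):
            assign[ci] = p

    # final per-unique alignment against the assigned center
    alignments: list = [None] * n
    unaligned: set[int] = set()
    final_lam = np.full(n, -np.inf)
    for p, ci in enumerate(centers):
        idx = np.flatnonzero(assign == p)
        cenc = uniques[ci].encoded
        for i in idx:
            u = uniques[i]
            if i == ci or len(u.encoded) == len(cenc):
                screen = None if i == ci else kmer_screen(u.encoded, cenc, k)
                if i == ci or screen["ungapped_is_optimal"]:
                    alignments[i] = None
                    final_lam[i] = _log10_lambda(
                        u.encoded, u.rounded_quality, cenc, None, model)
                    continue
            res = _align.banded_nw(u.encoded, cenc, band, MATCH, MISMATCH, GAP)
            if res is None:  # band refused: member carries no usable alignment
                unaligned.add(int(i))
                continue
            alignments[i] = (res[1], res[2])
            final_lam[i] = _log10_lambda(u.encoded, u.rounded_quality, cenc,
                                         alignments[i], model)

    partitions = []
    part_tot = np.bincount(assign, weights=ab, minlength=len(centers)
                           ).astype(np.int64)
    for p, ci in enumerate(centers):
        idx = np.flatnonzero(assign == p)
        part = Partition(center=uniques[ci],
                         members=[uniques[i] for i in idx],
                         lambdas=[float(final_lam[i]) for i in idx])
        min_lp = math.inf
        for i in idx:
            if i == ci or ab[i] < 2:
                continue
            ll = final_lam[i]
            log10_mu = (math.log10(part_tot[p]) + ll) if np.isfinite(ll) \
                else -math.inf
            min_lp = min(min_lp, _log10_pA(log10_mu, int(ab[i])))
        part.p_A = 10.0 ** min_lp if np.isfinite(min_lp) else 1.0
        partitions.append(part)

    asvs = [(uniques[ci].sequence, int(part_tot[p]))
            for p, ci in enumerate(centers)]
    return DadaResult(partitions=partitions, asvs=asvs, assignment=assign,
                      centers=centers, alignments=alignments,
                      log_lambdas=final_lam, unaligned=unaligned)


def make_asv_table(results: dict[str, "DadaResult | dict[str, int]"]
                   ) -> pd.DataFrame:
    """Merge per-sample denoising results into a samples x ASVs table.

    Columns are the union of ASV sequences, ordered by total abundance
    descending then lexicographically; cells are integer read counts (0
    where an ASV is absent from a sample).
    """
    samples = list(results)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample names")
    per_sample: dict[str, dict[str, int]] = {}
    for name, res in results.items():
        per_sample[name] = res.asv_abundance() if isinstance(res, DadaResult) \
            else dict(res)
    table = pd.DataFrame.from_dict(per_sample, orient="index").fillna(0)
    table = table.astype(np.int64)
    if table.shape[1]:
        order = sorted(table.columns,
                       key=lambda s: (-int(table[s].sum()), s))
        table = table[order]
    return table
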