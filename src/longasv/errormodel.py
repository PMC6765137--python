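"""Quality-conditioned sequencing error model.

The denoiser needs, for every (true base, observed base) transition and
every quality score q in 0..93, the probability that the sequencer reports
the observed base given the true base and q.  Rates are estimated from
reads aligned to their inferred true sequences.  CCS quality scores run to
93 and the maximum score carries most bases, so the q = 93 rate is
estimated on its own directly from the q = 93 observations, while rates
over q = 0..92 come from a smoothed (tricube-weighted local linear) fit of
log10 rate against q followed by an isotonic non-increasing correction.
The model assumes the quality/error relationship is the same at every base
position in a read.

Error-model learning alternates denoising and re-estimation: starting from
a deliberately pessimistic quality-independent model, reads are denoised,
reassigned to the inferred sequences, and the rates re-estimated, until the
rates stop changing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "TransitionCounts",
    "ErrorModel",
    "count_transitions",
    "estimate_rates",
    "learn_errors",
]

N_QUAL = 94  # quality scores 0..93
MAX_Q = 93
RATE_FLOOR = 1e-7
RATE_CEIL = 0.25


@dataclass
class TransitionCounts:
    """Substitution-matrix tallies by (true nt, observed nt, quality).

    ``counts[t, o, q]`` counts aligned columns where the true base was t,
    the read base o, and the read quality q.  Indel columns are excluded
    from the matrix but tallied separately (they set the indel rate used in
    read-to-center likelihoods).  Counts are additive under merging.
    """

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((4, 4, N_QUAL), dtype=np.int64))
    indels: int = 0
    aligned_columns: int = 0

    def __add__(self, other: "TransitionCounts") -> "TransitionCounts":
        return TransitionCounts(self.counts + other.counts,
                                self.indels + other.indels,
                                self.aligned_columns + other.aligned_columns)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def total_errors(self) -> int:
        off = self.counts.sum() - np.einsum("iiq->", self.counts)
        return int(off)


def count_transitions(assigned_reads) -> TransitionCounts:
    """Tally (true nt, observed nt, quality) triples from aligned reads.

    ``assigned_reads`` yields (read, true_seq, alignment) where the read is
    a QualRead, true_seq the assigned true sequence (str or encoded array),
    and alignment a pair of column index arrays (read_idx, true_idx) with
    -1 marking gaps, as produced by the banded aligner.  An equal-length
    positional alignment may be given as None.
    """
    from . import _align

    tc = TransitionCounts()
    flat = np.zeros(16 * N_QUAL, dtype=np.int64)
    for read, true_seq, aln in assigned_reads:
        robs = _align.encode(read.nucleotides) \
            if isinstance(read.nucleotides, str) else read.nucleotides
        tobs = _align.encode(true_seq) if isinstance(true_seq, str) else true_seq
        if aln is None:
            if len(robs) != len(tobs):
                raise ValueError(
                    f"read {read.id!r}: positional alignment requires equal "
                    "lengths")
            ri = ti = np.arange(len(robs))
        else:
            ri, ti = aln
            n_cols = len(ri)
            if len(ti) != n_cols:
                raise ValueError("alignment column count mismatch")
            both = (ri >= 0) & (ti >= 0)
            tc.indels += int(n_cols - both.sum())
            tc.aligned_columns += int(n_cols)
            ri, ti = ri[both], ti[both]
        t = tobs[ti].astype(np.int64)
        o = robs[ri].astype(np.int64)
        q = np.asarray(read.qualities, dtype=np.int64)[ri]
        ok = (t < 4) & (o < 4)
        np.add.at(flat, (t[ok] * 4 + o[ok]) * N_QUAL + q[ok], 1)
        if aln is None:
            tc.aligned_columns += len(robs)
    tc.counts += flat.reshape(4, 4, N_QUAL)
    return tc


@dataclass
class ErrorModel:
    """Transition-rate matrix p(observed nt | true nt, quality).

    ``rates[t, o, q]`` sums to 1 over o for every (t, q); each of the 12
    error transitions is non-increasing in q over 0..92, with the q = 93
    entry estimated independently.  ``indel_rate`` is the per-column
    probability used for gap columns in read likelihoods.
    """

    rates: np.ndarray  # (4, 4, 94)
    indel_rate: float = 1e-3
    _log10: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (4, 4, N_QUAL):
            raise ValueError("rates must have shape (4, 4, 94)")

    @property
    def log10_rates(self) -> np.ndarray:
        if self._log10 is None:
            self._log10 = np.log10(self.rates)
        return self._log10

    @classmethod
    def pessimistic(cls, error_rate: float = 0.01,
                    indel_rate: float = 0.005) -> "ErrorModel":
        """Quality-independent starting model for error learning.

        Every wrong base is given error_rate / 3 at every quality, so no
        quality score is trusted until the data says otherwise.
        """
        rates = np.full((4, 4, N_QUAL), error_rate / 3.0)
        for t in range(4):
            rates[t, t, :] = 1.0 - error_rate
        return cls(rates, indel_rate=indel_rate)

    def to_json(self, path) -> None:
        obj = {"indel_rate": self.indel_rate,
               "rates": {f"{a}>{b}": self.rates["ACGT".index(a),
                                                "ACGT".index(b)].tolist()
                         for a in "ACGT" for b in "ACGT"}}
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "ErrorModel":
        with open(path) as fh:
            obj = json.load(fh)
        rates = np.zeros((4, 4, N_QUAL))
        for key, vals in obj["rates"].items():
            a, b = key.split(">")
            rates["ACGT".index(a), "ACGT".index(b)] = vals
        return cls(rates, indel_rate=obj["indel_rate"])


def _tricube_local_fit(q_obs: np.ndarray, y: np.ndarray, w: np.ndarray,
                       q_eval: np.ndarray, span: float) -> np.ndarray:
    """Tricube-weighted local linear regression of y on q.

    ``span`` is the half-width (in quality units) of the tricube window;
    weights combine the kernel with per-point observation weights w.
    """
    out = np.empty(len(q_eval))
    for i, q0 in enumerate(q_eval):
        d = np.abs(q_obs - q0) / span
        kw = np.where(d < 1, (1 - d ** 3) ** 3, 0.0) * w
        if kw.sum() <= 0:
            # outside the window of every observation: nearest point
            j = int(np.argmin(np.abs(q_obs - q0)))
            out[i] = y[j]
            continue
        wz = kw / kw.sum()
        qm = np.sum(wz * q_obs)
        ym = np.sum(wz * y)
        var = np.sum(wz * (q_obs - qm) ** 2)
        slope = np.sum(wz * (q_obs - qm) * (y - ym)) / var if var > 1e-12 else 0.0
        out[i] = ym + slope * (q0 - qm)
    return out


def _pava_nonincreasing(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted pool-adjacent-violators fit, non-increasing."""
    # fit non-decreasing to the negated series
    vals = list(-y)
    wts = list(w)
    # blocks of (value, weight, count)
    blocks: list[list[float]] = []
    for v, wt in zip(vals, wts):
        blocks.append([v, wt, 1])
        while len(blocks) > 1 and blocks[-2][0] > blocks[-1][0]:
            v2, w2, c2 = blocks.pop()
            v1, w1, c1 = blocks.pop()
            wsum = w1 + w2
            blocks.append([(v1 * w1 + v2 * w2) / wsum, wsum, c1 + c2])
    out = np.empty(len(y))
    i = 0
    for v, _, c in blocks:
        out[i:i + c] = -v
        i += c
    return out


def estimate_rates(counts: TransitionCounts, pseudocount: float = 1.0,
                   span: Optional[float] = None, floor: float = RATE_FLOOR
                   ) -> ErrorModel:
    """Estimate the quality-conditioned error-rate matrix from tallies.

    For q <= 92 each of the 12 error transitions is fit by a local linear
    regression of log10((errors + pseudocount) / total) on q, weighted by
    observation counts, then corrected to be non-increasing in q and
    floored.  The q = 93 rate is computed separately from the q = 93
    observations alone as (errors + pc) / (total + 2 pc).  Rows are
    normalized to sum to 1 over the observed base.
    """
    c = counts.counts
    if c.sum() == 0:
        raise ValueError("cannot estimate error rates from empty counts")
    totals = c.sum(axis=1)  # (true, q)
    rates = np.zeros((4, 4, N_QUAL))
    qs = np.arange(N_QUAL - 1, dtype=float)  # 0..92

    for t in range(4):
        tot = totals[t, :MAX_Q].astype(float)
        obs_mask = tot > 0
        for o in range(4):
            if o == t:
                continue
            if not obs_mask.any():
                rates[t, o, :MAX_Q] = floor
            else:
                q_obs = qs[obs_mask]
                err = c[t, o, :MAX_Q][obs_mask].astype(float)
                raw = (err + pseudocount) / (tot[obs_mask] + pseudocount)
                y = np.log10(raw)
                sp = span
                if sp is None:
                    sp = max((q_obs.max() - q_obs.min()) / 2.0, 2.0)
                fit = _tricube_local_fit(q_obs, y, tot[obs_mask], qs, sp)
                # non-increasing in q; weight by totals (1 where unobserved)
                w = np.where(obs_mask, tot, 1.0)
                fit = _pava_nonincreasing(fit, w)
                rates[t, o, :MAX_Q] = np.clip(10.0 ** fit, floor, RATE_CEIL)
            # q = 93 handled independently of the smooth fit
            tot93 = float(totals[t, MAX_Q])
            err93 = float(c[t, o, MAX_Q])
            r93 = (err93 + pseudocount) / (tot93 + 2.0 * pseudocount)
            rates[t, o, MAX_Q] = min(max(r93, floor), RATE_CEIL)
        # self-transition takes the remainder; each error rate is capped at
        # RATE_CEIL so the remainder is >= 1 - 3*RATE_CEIL = 0.25 and rows
        # sum to exactly 1 without a monotonicity-breaking renormalization
        err_sum = rates[t].sum(axis=0) - rates[t, t]
        rates[t, t] = 1.0 - err_sum

    indel_rate = max((counts.indels + pseudocount) /
                     (counts.aligned_columns + pseudocount), floor)
    return ErrorModel(rates, indel_rate=min(indel_rate, RATE_CEIL))


def learn_errors(reads, max_rounds: int = 10, tol: float = 0.05,
                 n_learn: Optional[int] = None, omega_a: float = 1e-40,
                 kdist_cutoff: float = 0.42, band: int = 32,
                 verbose: bool = False):
    """Learn the error model by alternating denoising and re-estimation.

    Starting from a pessimistic quality-independent model, the reads are
    denoised, every read is reassigned to its inferred true sequence, and
    the rate matrix is re-estimated from the implied transitions.  The loop
    stops when the largest absolute change in log10 rate drops below
    ``tol`` or after ``max_rounds``.  ``n_learn`` caps the number of reads
    used (the first n_learn reads, deterministically).

    Returns (ErrorModel, diagnostics) where diagnostics is one dict per
    round (number of inferred sequences, max log10 rate change, aggregate
    substitution / indel rates).
    """
    from .denoise import dereplicate, run_dada

    reads = list(reads)
    if not reads:
        raise ValueError("no reads supplied to learn_errors")
    if n_learn is not None:
        reads = reads[:n_learn]
    uniques = dereplicate(reads)
    uindex = {u.sequence: i for i, u in enumerate(uniques)}

    model = ErrorModel.pessimistic()
    diagnostics: list[dict] = []
    for rnd in range(max_rounds):
        result = run_dada(uniques, model, omega_a=omega_a,
                          kdist_cutoff=kdist_cutoff, band=band)
        centers = result.centers  # unique idx of each partition center
        assigned = []
        for read in reads:
            ui = uindex[read.nucleotides]
            if ui in result.unaligned:
                continue
            part = result.assignment[ui]
            center_seq = uniques[centers[part]].sequence
            assigned.append((read, center_seq, result.alignments[ui]))
        counts = count_transitions(assigned)
        new_model = estimate_rates(counts)
        delta = float(np.max(np.abs(new_model.log10_rates - model.log10_rates)))
        n_bases = max(counts.aligned_columns, 1)
        diagnostics.append({
            "round": rnd + 1,
            "n_sequences": len(centers),
            "max_log10_change": delta,
            "substitution_rate": counts.total_errors / max(counts.total, 1),
            "indel_rate": counts.indels / n_bases,
        })
        model = new_model
        if verbose:
            print(f"learn_errors round {rnd + 1}: {len(centers)} sequences, "
                  f"max |dlog10| = {delta:.3f}")
        if delta < tol:
            break
    return model, diagnostics
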