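"""Mock-community evaluation analytics.

In a community of known composition, every inferred ASV can be checked
against ground truth.  Because the 16S rRNA gene is multi-copy, the read
abundance of a genuine allele is (copy number) x (genomic abundance of its
strain): dividing ASV abundances by the strain's genomic abundance must
therefore give near-integer ratios.  This module implements that integral
-ratio accounting, the exact-match / integral-ratio accuracy calls, raw
-read error profiling by type, position and quality, rarefaction, and
replicate concordance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import _align
from .denoise import DEFAULT_BAND, MATCH, MISMATCH, GAP, kmer_screen
from .seqio import QualRead

__all__ = [
    "StrainReference",
    "ErrorProfile",
    "genomic_abundance",
    "normalized_ratios",
    "integral_ratio_check",
    "assess_accuracy",
    "profile_errors",
    "rarefy",
    "replicate_concordance",
]


@dataclass(frozen=True)
class StrainReference:
    """The true 16S allele complement of one strain."""

    name: str
    alleles: tuple[tuple[str, int], ...]  # (sequence, copy number)
    copy_number: int  # total 16S copies in the genome

    def __post_init__(self):
        s = sum(c for _, c in self.alleles)
        if s != self.copy_number:
            raise ValueError(
                f"{self.name}: allele copies sum to {s}, "
                f"not the stated copy number {self.copy_number}")

    @property
    def sequences(self) -> list[str]:
        return [seq for seq, _ in self.alleles]


def genomic_abundance(asv_abundances: Sequence[float], copy_number: int
                      ) -> float:
    """Strain genomic abundance: summed ASV abundances / 16S copy number."""
    if copy_number < 1:
        raise ValueError("copy_number must be >= 1")
    if len(asv_abundances) == 0:
        raise ValueError("at least one ASV abundance required")
    return float(sum(asv_abundances)) / copy_number


def normalized_ratios(asv_abundances: Sequence[float],
                      genome_abundance: float) -> np.ndarray:
    """Per-ASV copies-per-genome ratios: abundance / genomic abundance."""
    if genome_abundance <= 0:
        raise ValueError("genome abundance must be positive")
    return np.asarray(asv_abundances, dtype=float) / genome_abundance


def integral_ratio_check(ratio: float, tol: float = 0.2) -> dict:
    """Is the ratio within tol of a positive integer?"""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    nearest = int(round(ratio))
    deviation = abs(ratio - nearest)
    # the bound is inclusive; guard against float representation of tol
    return {"nearest": nearest, "deviation": deviation,
            "pass": deviation <= tol + 1e-9 and nearest >= 1}


def assess_accuracy(asvs: dict[str, int], assignments: dict[str, str],
                    references: dict[str, StrainReference],
                    tol: float = 0.2) -> pd.DataFrame:
    """Classify each ASV as exact / integral-ratio-supported / unsupported.

    ``asvs`` maps ASV sequence to abundance; ``assignments`` maps ASV
    sequence to strain name.  An ASV is 'exact' when it string-matches a
    reference allele of its strain; otherwise 'supported' when its
    copies-per-genome ratio is within tol of an integer >= 1 and the
    strain bin holds multiple ASVs; otherwise 'unsupported'.
    """
    rows = []
    by_strain: dict[str, list[str]] = {}
    for seq, strain in assignments.items():
        by_strain.setdefault(strain, []).append(seq)
    for seq, ab in asvs.items():
        strain = assignments.get(seq)
        if strain is None or strain not in references:
            rows.append((seq, ab, None, np.nan, "unsupported", "unassigned"))
            continue
        ref = references[strain]
        members = by_strain[strain]
        g = genomic_abundance([asvs[s] for s in members], ref.copy_number)
        ratio = ab / g if g > 0 else np.nan
        if seq in ref.sequences:
            rows.append((seq, ab, strain, ratio, "exact", ""))
        else:
            chk = integral_ratio_check(ratio, tol) if ratio > 0 else \
                {"pass": False}
            if chk["pass"] and len(members) >= 2:
                rows.append((seq, ab, strain, ratio, "supported", ""))
            else:
                rows.append((seq, ab, strain, ratio, "unsupported",
                             "non-integral ratio or single-allele bin"))
    return pd.DataFrame(
        rows, columns=["sequence", "abundance", "strain", "ratio",
                       "verdict", "reason"])


@dataclass
class ErrorProfile:
    """Error tallies by type, 1-based read position and quality.

    Substitutions and insertions carry the read base's quality; deletions
    have none (the base is absent from the read).  ``totals`` counts
    aligned reference bases; positional totals count read bases.
    """

    substitutions: dict[tuple[int, int], int] = field(default_factory=dict)
    insertions: dict[tuple[int, int], int] = field(default_factory=dict)
    deletions: dict[int, int] = field(default_factory=dict)  # position only
    total_ref_bases: int = 0
    total_read_bases: int = 0
    n_reads: int = 0
    n_excluded: int = 0

    def aggregate_rates(self) -> dict[str, float]:
        denom = max(self.total_ref_bases, 1)
        return {
            "substitution": sum(self.substitutions.values()) / denom,
            "insertion": sum(self.insertions.values()) / denom,
            "deletion": sum(self.deletions.values()) / denom,
            "total": (sum(self.substitutions.values())
                      + sum(self.insertions.values())
                      + sum(self.deletions.values())) / denom,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (pos, q), n in sorted(self.substitutions.items()):
            rows.append(("substitution", pos, q, n))
        for (pos, q), n in sorted(self.insertions.items()):
            rows.append(("insertion", pos, q, n))
        for pos, n in sorted(self.deletions.items()):
            rows.append(("deletion", pos, None, n))
        return pd.DataFrame(rows, columns=["type", "position", "quality",
                                           "count"])


def profile_errors(reads: Iterable[QualRead], truth: Sequence[str],
                   band: int = DEFAULT_BAND, exclude=None) -> ErrorProfile:
    """Align reads to their best-matching truth and tally the differences.

    Each read is aligned (banded) to the best-scoring true sequence
    (kmer-nearest candidates first; ties go to the earlier truth in input
    order).  Differences are recorded by type with 1-based positions along
    the read; insertions take the inserted base's quality, deletions have
    no quality.  Reads matching no truth within the band, or whose ids are
    in ``exclude``, are skipped and counted.
    """
    truth = list(truth)
    if not truth:
        raise ValueError("truth set is empty")
    exclude = set(exclude) if exclude else set()
    tenc = [_align.encode(t) for t in truth]
    prof = ErrorProfile()
    for read in reads:
        if read.id in exclude:
            prof.n_excluded += 1
            continue
        renc = _align.encode(read.nucleotides)
        # rank truths by kmer distance, align to the closest few
        kd = []
        for j, te in enumerate(tenc):
            s = kmer_screen(renc, te)
            kd.append((s["kdist"], j))
        kd.sort()
        best = None
        for _, j in kd[:4]:
            res = _align.banded_nw(renc, tenc[j], band, MATCH, MISMATCH, GAP)
            if res is None:
                continue
            if best is None or res[0] > best[0]:
                best = (res[0], j, res[1], res[2])
        if best is None:
            prof.n_excluded += 1
            continue
        _, j, ri, ti = best
        te = tenc[j]
        q = np.asarray(read.qualities)
        # 1-based read position per column: position of the read base, or
        # of the next read base for deletion columns
        read_pos = np.maximum.accumulate(np.where(ri >= 0, ri, -1))
        read_pos = read_pos + 2  # next read base, 1-based
        both = (ri >= 0) & (ti >= 0)
        sub_cols = np.flatnonzero(both)
        sub_cols = sub_cols[renc[ri[sub_cols]] != te[ti[sub_cols]]]
        ins_cols = np.flatnonzero((ri >= 0) & (ti < 0))
        del_cols = np.flatnonzero(ri < 0)
        for c in sub_cols:
            key = (int(ri[c]) + 1, int(q[ri[c]]))
            prof.substitutions[key] = prof.substitutions.get(key, 0) + 1
        for c in ins_cols:
            key = (int(ri[c]) + 1, int(q[ri[c]]))
            prof.insertions[key] = prof.insertions.get(key, 0) + 1
        for c in del_cols:
            pos = int(read_pos[c])
            prof.deletions[pos] = prof.deletions.get(pos, 0) + 1
        prof.total_ref_bases += len(te)
        prof.total_read_bases += len(renc)
        prof.n_reads += 1
    return prof


def rarefy(counts: Sequence[int], depth: int, seed: int) -> np.ndarray:
    """Subsample a count vector to a fixed total, without replacement."""
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds total count {total}")
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth).astype(np.int64)


def replicate_concordance(table_a: pd.DataFrame, table_b: pd.DataFrame
                          ) -> dict:
    """Compare two samples x ASVs tables from technical replicates.

    An observation is a (sample, ASV) pair with positive abundance.
    Reports counts of shared / A-only / B-only observations and the
    Pearson correlation of per-sample abundances over the union of
    observations (absences as 0).
    """
    shared_samples = table_a.index.intersection(table_b.index)
    if len(shared_samples) == 0:
        raise ValueError("replicate tables share no sample identifiers")
    a = table_a.loc[shared_samples]
    b = table_b.loc[shared_samples]
    cols = a.columns.union(b.columns)
    a = a.reindex(columns=cols, fill_value=0)
    b = b.reindex(columns=cols, fill_value=0)
    pa = a.values > 0
    pb = b.values > 0
    union = pa | pb
    x = a.values[union].astype(float)
    y = b.values[union].astype(float)
    if len(x) >= 2 and np.std(x) > 0 and np.std(y) > 0:
        r = float(np.corrcoef(x, y)[0, 1])
    else:
        r = 1.0 if np.allclose(x, y) else float("nan")
    return {
        "shared": int((pa & pb).sum()),
        "a_only": int((pa & ~pb).sum()),
        "b_only": int((~pa & pb).sum()),
        "pearson_r": r,
    }
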