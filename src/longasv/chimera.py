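"""De novo bimera (two-parent chimera) detection and removal.

A PCR chimera formed by one template switch is an exact one-crossover
mosaic of two more-abundant sequences.  A candidate ASV is flagged when
some ordered parent pair reconstructs it perfectly -- a left segment
matching parent A and the remainder matching parent B under banded
alignment -- while neither parent alone matches it.

Multi-copy marker genes complicate this: a genuine low-copy allele can
look like a mosaic of two higher-copy alleles from the same genome.  The
``min_fold`` parent-overabundance requirement (default 3.5) guards against
flagging such intragenomic variants, since same-genome alleles appear at
small integral abundance ratios (e.g. 3:1) that stay below the fold
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _align

__all__ = ["BimeraVerdict", "is_bimera", "remove_bimeras",
           "DEFAULT_MIN_FOLD"]

DEFAULT_MIN_FOLD = 3.5
DEFAULT_MAX_SHIFT = 16


@dataclass
class BimeraVerdict:
    candidate: str
    is_bimera: bool
    best_parents: Optional[tuple[str, str]] = None  # (left, right)
    crossover: Optional[int] = None  # candidate position where right begins

    def __post_init__(self):
        if self.is_bimera and self.best_parents is None:
            raise ValueError("a bimera verdict requires parents")


def _match_runs(cand_enc: np.ndarray, parent_enc: np.ndarray,
                max_shift: int) -> tuple[int, int, bool]:
    """(prefix, suffix, exact): perfect-match run lengths in candidate
    coordinates from each end of the candidate/parent alignment."""
    band = max(max_shift, abs(len(cand_enc) - len(parent_enc)) + 1)
    if abs(len(cand_enc) - len(parent_enc)) > max_shift:
        return 0, 0, False
    res = _align.banded_nw(cand_enc, parent_enc, band)
    if res is None:
        return 0, 0, False
    _, ci, pi = res
    ncol = len(ci)
    match = (ci >= 0) & (pi >= 0)
    match[match] = cand_enc[ci[match]] == parent_enc[pi[match]]
    if match.all():
        return len(cand_enc), len(cand_enc), True
    first_bad = int(np.argmax(~match))
    last_bad = ncol - 1 - int(np.argmax(~match[::-1]))
    # candidate bases covered by the clean prefix / suffix of the alignment
    prefix = int((ci[:first_bad] >= 0).sum())
    suffix = int((ci[last_bad + 1:] >= 0).sum())
    return prefix, suffix, False


def is_bimera(candidate: str, abundance: int,
              pool: Sequence[tuple[str, int]],
              min_fold: float = DEFAULT_MIN_FOLD,
              max_shift: int = DEFAULT_MAX_SHIFT) -> BimeraVerdict:
    """Judge one candidate sequence against a pool of potential parents.

    Parents are pool members at least ``min_fold`` times more abundant than
    the candidate.  The candidate is a bimera iff some ordered pair of
    parents reconstructs it exactly as a one-crossover mosaic while
    neither parent alone matches it exactly.
    """
    if min_fold <= 0:
        raise ValueError("min_fold must be positive")
    cand_enc = _align.encode(candidate)
    L = len(cand_enc)
    prefixes: list[tuple[int, str]] = []
    suffixes: list[tuple[int, str]] = []
    for seq, ab in pool:
        if seq == candidate:
            return BimeraVerdict(candidate, False)
        if ab < min_fold * abundance:
            continue
        pre, suf, exact = _match_runs(cand_enc, _align.encode(seq), max_shift)
        if exact:
            # an exact parent match means the candidate is not chimeric
            return BimeraVerdict(candidate, False)
        if pre > 0:
            prefixes.append((pre, seq))
        if suf > 0:
            suffixes.append((suf, seq))
    best = None
    for pre, pa in prefixes:
        for suf, pb in suffixes:
            if pa is pb or pa == pb:
                continue
            if pre + suf >= L:
                cross = L - suf
                if best is None or (pre + suf) > best[0]:
                    best = (pre + suf, pa, pb, cross)
    if best is None:
        return BimeraVerdict(candidate, False)
    return BimeraVerdict(candidate, True, best_parents=(best[1], best[2]),
                         crossover=best[3])


def remove_bimeras(table: pd.DataFrame, min_fold: float = DEFAULT_MIN_FOLD,
                   max_shift: int = DEFAULT_MAX_SHIFT
                   ) -> tuple[pd.DataFrame, list[BimeraVerdict]]:
    """Flag and drop bimeric ASV columns from a samples x ASVs table.

    Each ASV is judged per sample against that sample's more abundant
    ASVs; an ASV is removed table-wide iff it is flagged in a strict
    majority of the samples in which it occurs (consensus rule).
    Returns (cleaned table, verdicts for the removed columns).
    """
    flagged: list[BimeraVerdict] = []
    drop: list[str] = []
    for seq in table.columns:
        n_present = 0
        n_flagged = 0
        verdict = None
        for sample in table.index:
            ab = int(table.at[sample, seq])
            if ab <= 0:
                continue
            n_present += 1
            pool = [(s, int(table.at[sample, s])) for s in table.columns
                    if s != seq and table.at[sample, s] > 0]
            v = is_bimera(seq, ab, pool, min_fold=min_fold,
                          max_shift=max_shift)
            if v.is_bimera:
                n_flagged += 1
                verdict = v
        if n_present and n_flagged * 2 > n_present:
            drop.append(seq)
            flagged.append(verdict)
    return table.drop(columns=drop), flagged
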