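"""Sequence I/O, primer detection/orientation and quality filtering.

PacBio CCS amplicon reads arrive in a mixture of forward and
reverse-complement orientations with the PCR primers still attached.  This
module reads Sanger-encoded FASTQ (offset 33, qualities up to 93), locates
the degenerate primer pair near the read ends in either orientation, trims
primers and everything outside them, orients every kept read forward, and
applies length / ambiguity / expected-error filters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "QualRead",
    "PrimerSpec",
    "FilterParams",
    "IUPAC",
    "read_fastq",
    "write_fastq",
    "write_fasta",
    "reverse_complement",
    "match_iupac",
    "remove_primers",
    "filter_reads",
    "expected_errors",
]

#: IUPAC nucleotide codes mapped to the set of bases each one matches.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class QualRead:
    """One amplicon read with per-base Phred qualities (0-93)."""

    id: str
    nucleotides: str
    qualities: np.ndarray  # int array, one per base
    orientation: str = "unknown"  # forward | reverse-complemented | unknown

    def __post_init__(self):
        q = np.asarray(self.qualities, dtype=np.int16)
        object.__setattr__(self, "qualities", q)
        if len(self.nucleotides) != len(q):
            raise ValueError(
                f"read {self.id!r}: {len(self.nucleotides)} bases but "
                f"{len(q)} quality scores")
        if len(q) and (q.min() < 0 or q.max() > 93):
            raise ValueError(f"read {self.id!r}: quality outside [0, 93]")

    def __len__(self) -> int:
        return len(self.nucleotides)

    def reverse_complement(self) -> "QualRead":
        orient = {"forward": "reverse-complemented",
                  "reverse-complemented": "forward"}.get(
                      self.orientation, "unknown")
        return QualRead(self.id, reverse_complement(self.nucleotides),
                        self.qualities[::-1].copy(), orient)


@dataclass(frozen=True)
class PrimerSpec:
    """A degenerate PCR primer pair with matching tolerances.

    ``forward``/``reverse`` are IUPAC strings written 5'->3' on their own
    strands (the reverse primer binds the amplicon's reverse complement, so
    its reverse complement is what appears at the 3' end of an oriented
    read).  ``search_window`` limits how far from each read end a primer is
    looked for.
    """

    forward: str
    reverse: str
    max_mismatch: int = 2
    search_window: Optional[int] = None  # default: primer length + 10

    def __post_init__(self):
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not p:
                raise ValueError(f"{name} primer is empty")
            bad = set(p.upper()) - set(IUPAC)
            if bad:
                raise ValueError(
                    f"{name} primer contains non-IUPAC characters {sorted(bad)}")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")

    def window(self, primer: str) -> int:
        return self.search_window if self.search_window is not None \
            else len(primer) + 10


#: The full-length 16S rRNA gene universal primer pair (27F / 1492R).
DEFAULT_PRIMERS = PrimerSpec(forward="AGRGTTYGATYMTGGCTCAG",
                             reverse="RGYTACCTTGTTACGACTT")


@dataclass(frozen=True)
class FilterParams:
    """Length / ambiguity / expected-error read filter thresholds."""

    min_len: int = 1000
    max_len: int = 1600
    max_expected_errors: float = 2.0
    max_n: int = 0

    def __post_init__(self):
        if self.min_len <= 0 or self.max_len <= 0:
            raise ValueError("lengths must be positive")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.max_expected_errors <= 0:
            raise ValueError("max_expected_errors must be positive")
        if self.max_n < 0:
            raise ValueError("max_n must be >= 0")


def read_fastq(path) -> list[QualRead]:
    """Read a Sanger-encoded FASTQ file (offset 33; supports Q93, i.e. '~').

    Raises a parse error naming the offending record when sequence and
    quality lengths disagree or a record is malformed.
    """
    reads: list[QualRead] = []
    with open(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                rid = title.split()[0] if title else ""
                q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8)
                q = q.astype(np.int16) - 33
                reads.append(QualRead(rid, seq.upper(), q))
        except ValueError as exc:
            n = len(reads)
            raise ValueError(
                f"malformed FASTQ record #{n + 1} in {path}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[QualRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = (r.qualities.astype(np.uint8) + 33).tobytes().decode("ascii")
            fh.write(f"@{r.id}\n{r.nucleotides}\n+\n{qual}\n")


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def expected_errors(qualities: np.ndarray) -> float:
    """Expected number of errors, sum of 10^(-q/10) over the read."""
    q = np.asarray(qualities, dtype=float)
    return float(np.sum(10.0 ** (-q / 10.0)))


def _primer_sets(primer: str) -> list[frozenset[str]]:
    try:
        return [IUPAC[c] for c in primer.upper()]
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC character {exc.args[0]!r} "
                         f"in primer {primer!r}") from exc


def match_iupac(primer: str, sequence: str, max_mismatch: int = 0
                ) -> Optional[dict]:
    """Best ungapped match of a degenerate primer within a sequence.

    A position matches when the primer code's IUPAC set contains the read
    base; indels are not allowed.  Among offsets with <= max_mismatch
    violations the fewest-mismatch one is returned (ties: smallest offset),
    as ``{"offset": int, "mismatches": int}``; None if no offset qualifies.
    """
    sets = _primer_sets(primer)
    lp = len(sets)
    if lp > len(sequence):
        return None
    best = None
    for off in range(len(sequence) - lp + 1):
        mm = 0
        for ps, base in zip(sets, sequence[off:off + lp]):
            if base not in ps:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            if best is None or mm < best["mismatches"]:
                best = {"offset": off, "mismatches": mm}
                if mm == 0:
                    break
    return best


def _find_primers(seq: str, primers: PrimerSpec):
    """Locate fwd primer near 5' and revcomp(rev primer) near 3'.

    Returns (insert_start, insert_end, total_mismatches) or None.
    """
    fwd = primers.forward.upper()
    rc_rev = reverse_complement(primers.reverse.upper())
    wf = min(primers.window(fwd), len(seq))
    wr = min(primers.window(rc_rev), len(seq))

    mf = match_iupac(fwd, seq[:wf], primers.max_mismatch)
    if mf is None:
        return None
    tail_start = max(0, len(seq) - wr)
    mr = match_iupac(rc_rev, seq[tail_start:], primers.max_mismatch)
    if mr is None:
        return None
    start = mf["offset"] + len(fwd)
    end = tail_start + mr["offset"]
    if end <= start:
        return None
    return start, end, mf["mismatches"] + mr["mismatches"]


def remove_primers(reads: Iterable[QualRead], primers: PrimerSpec = DEFAULT_PRIMERS
                   ) -> tuple[list[QualRead], dict[str, int]]:
    """Detect and remove primers; orient kept reads forward.

    Each read is searched as-is first, then as its reverse complement
    (qualities reversed in step).  Kept reads are trimmed to the insert
    between the primers.  When both orientations match, the one with fewer
    total primer mismatches wins; an exact tie is ambiguous and dropped.
    Returns (kept reads, tally); tally counts sum to the input size.
    """
    kept: list[QualRead] = []
    tally = {"kept_forward": 0, "kept_reverse_complemented": 0,
             "no_primer": 0, "ambiguous_orientation": 0}
    for read in reads:
        hit_f = _find_primers(read.nucleotides, primers)
        rc = read.reverse_complement()
        hit_r = _find_primers(rc.nucleotides, primers)
        if hit_f is not None and hit_r is not None:
            if hit_f[2] < hit_r[2]:
                hit_r = None
            elif hit_r[2] < hit_f[2]:
                hit_f = None
            else:
                tally["ambiguous_orientation"] += 1
                continue
        if hit_f is not None:
            src, (start, end, _) = read, hit_f
            orient = "forward"
        elif hit_r is not None:
            src, (start, end, _) = rc, hit_r
            orient = "reverse-complemented"
        else:
            tally["no_primer"] += 1
            continue
        kept.append(QualRead(src.id, src.nucleotides[start:end],
                             src.qualities[start:end].copy(), orient))
        tally["kept_" + orient.replace("-", "_")] += 1
    return kept, tally


def filter_reads(reads: Iterable[QualRead], params: FilterParams = FilterParams()
                 ) -> tuple[list[QualRead], dict[str, int]]:
    """Keep reads passing length, ambiguous-base and expected-error limits."""
    kept: list[QualRead] = []
    tally = {"kept": 0, "too_short": 0, "too_long": 0,
             "too_many_n": 0, "expected_errors": 0}
    for read in reads:
        n = len(read)
        if n < params.min_len:
            tally["too_short"] += 1
        elif n > params.max_len:
            tally["too_long"] += 1
        elif read.nucleotides.count("N") > params.max_n:
            tally["too_many_n"] += 1
        elif expected_errors(read.qualities) > params.max_expected_errors:
            tally["expected_errors"] += 1
        else:
            kept.append(read)
            tally["kept"] += 1
    return kept, tally


def write_tally(tally: dict, path) -> None:
    Path(path).write_text(json.dumps(tally, indent=2) + "\n")
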