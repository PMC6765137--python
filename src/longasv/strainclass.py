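"""Strain-level binning and full-complement consensus classification.

Same-genome 16S alleles appear at integral abundance ratios set by their
copy numbers, so the ASVs of one taxonomic group can be partitioned into
strain bins by finding a per-strain 'genome unit' (reads per genome) under
which every member abundance is close to an integer multiple, with the
integers summing to the genome's total 16S copy number when known.

Classification then uses the full complement of a bin's alleles jointly:
the accessions reaching the best database hit score are recorded per ASV,
the accessions hitting the largest number of the bin's ASVs are taken, and
a metadata field (e.g. serotype) is read across them -- a unanimous value
classifies the strain, disagreement is ambiguous, and accessions missing
the field are ignored.  Sub-region extraction (e.g. V3V4, V4V5) allows the
same procedure to be compared on short-read-sized fragments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .seqio import match_iupac, reverse_complement

__all__ = [
    "StrainBin",
    "HitTable",
    "bin_strains",
    "consensus_classify",
    "extract_subregion",
    "V3V4_PRIMERS",
    "V4V5_PRIMERS",
]

#: Illumina-recommended V3V4 primer pair (341F / 805R).
V3V4_PRIMERS = ("CCTACGGGNGGCWGCAG", "GACTACHVGGGTATCTAATCC")
#: JGI-recommended V4V5 primer pair (515F / 926R).
V4V5_PRIMERS = ("GTGYCAGCMGCCGCGGTAA", "CCGYCAATTYMTTTRAGTTT")

RATIO_TOL = 0.2


@dataclass
class StrainBin:
    """A group of ASVs attributed to one genome.

    ``members`` maps ASV id to (abundance, estimated integer copies);
    ``genome_unit`` is the estimated reads-per-genome scale.
    """

    label: str
    members: dict[str, tuple[float, int]]
    genome_unit: float
    total_copies: int

    @property
    def copies(self) -> list[int]:
        return sorted((c for _, c in self.members.values()), reverse=True)


def _bin_candidates(items: list[tuple[str, float]], max_copies: int,
                    copy_number: Optional[int], tol: float):
    """Enumerate candidate genome units for the bin seeded on items[0].

    Candidate units are every observed abundance divided by 1..max_copies.
    Yields (n_members, total_deviation, genome_unit, members) where
    members maps asv id -> (abundance, copies); members always include the
    seed (the most abundant remaining ASV) and are filled greedily in
    descending abundance under the copy-number budget.
    """
    seed_id = items[0][0]
    units = sorted({ab / c for _, ab in items
                    for c in range(1, max_copies + 1)})
    for g in units:
        members: dict[str, tuple[float, int]] = {}
        total = 0
        dev = 0.0
        for aid, ab in items:
            ratio = ab / g
            k = int(round(ratio))
            if k >= 1 and abs(ratio - k) <= tol:
                if copy_number is not None and total + k > copy_number:
                    continue
                members[aid] = (ab, k)
                total += k
                dev += abs(ratio - k)
        if not members or seed_id not in members:
            continue
        if copy_number is not None and total != copy_number:
            continue
        yield (len(members), dev, g, members)


def bin_strains(asv_abundances: dict[str, float],
                copy_number: Optional[int] = None,
                tol: float = RATIO_TOL,
                label_prefix: str = "bin") -> tuple[list[StrainBin], list[str]]:
    """Partition ASV abundances into strain bins of integral copy ratios.

    Candidate genome units g are enumerated by dividing observed
    abundances by 1..copy_number; a bin accepts the ASVs whose
    abundance/g is within ``tol`` of an integer >= 1, with copies summing
    to ``copy_number`` when given.  Bins are grown greedily from the most
    abundant unassigned ASV, preferring more members then smaller total
    deviation (fewer, larger bins win ties).  Returns (bins, unbinned ids).
    """
    if not asv_abundances:
        raise ValueError("at least one ASV required")
    items = sorted(asv_abundances.items(), key=lambda kv: (-kv[1], kv[0]))
    max_copies = copy_number if copy_number is not None else 12
    bins: list[StrainBin] = []
    unbinned: list[str] = []
    remaining = items
    while remaining:
        best = None
        for cand in _bin_candidates(remaining, max_copies, copy_number, tol):
            n, dev, g, members = cand
            if best is None or (n, -dev) > (best[0], -best[1]):
                best = (n, dev, g, members)
        if best is None:
            # seed fits nothing, not even alone under the sum constraint
            unbinned.append(remaining[0][0])
            remaining = remaining[1:]
            continue
        _, _, g, members = best
        total = sum(c for _, c in members.values())
        bins.append(StrainBin(label=f"{label_prefix}{len(bins) + 1}",
                              members=members, genome_unit=g,
                              total_copies=total))
        remaining = [(aid, ab) for aid, ab in remaining if aid not in members]
    return bins, unbinned


@dataclass
class HitTable:
    """Best database hits per ASV plus per-accession metadata.

    ``hits`` maps ASV id to the set of accessions reaching that ASV's best
    hit score; ``metadata`` maps accession to a field->value mapping
    (missing fields simply absent).
    """

    hits: dict[str, set[str]]
    metadata: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        for aid, accs in self.hits.items():
            if not accs:
                raise ValueError(f"ASV {aid!r} has an empty accession set")

    @classmethod
    def from_tsv(cls, path) -> "HitTable":
        """Read a long-format TSV: asv_id, accession, then metadata columns."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"asv_id", "accession"} <= set(df.columns):
            raise ValueError("hit table needs asv_id and accession columns")
        hits: dict[str, set[str]] = {}
        metadata: dict[str, dict[str, str]] = {}
        meta_cols = [c for c in df.columns if c not in ("asv_id", "accession")]
        for _, row in df.iterrows():
            hits.setdefault(row["asv_id"], set()).add(row["accession"])
            md = metadata.setdefault(row["accession"], {})
            for c in meta_cols:
                v = row[c]
                if isinstance(v, str) and v != "":
                    md[c] = v
        return cls(hits=hits, metadata=metadata)


def consensus_classify(hits: HitTable, metadata_field: str) -> dict:
    """Classify a strain bin by consensus over its ASVs' best hits.

    Accession occurrences are tabulated across the per-ASV best-hit sets;
    the accessions with the maximal count are inspected for
    ``metadata_field``, ignoring accessions where it is absent.  A
    unanimous value is returned as the classification; conflicting values
    give 'ambiguous'; all-missing gives 'unclassified'.
    """
    if not hits.hits:
        raise ValueError("empty hit table")
    occurrences: dict[str, int] = {}
    considered = 0
    for accs in hits.hits.values():
        considered += len(accs)
        for acc in accs:
            occurrences[acc] = occurrences.get(acc, 0) + 1
    top = max(occurrences.values())
    top_accs = sorted(a for a, n in occurrences.items() if n == top)
    values = {hits.metadata.get(a, {}).get(metadata_field)
              for a in top_accs}
    values.discard(None)
    if not values:
        classification = "unclassified"
    elif len(values) == 1:
        classification = values.pop()
    else:
        classification = "ambiguous"
    return {"classification": classification,
            "supporting_accessions": len(top_accs),
            "max_occurrence": top,
            "hits_considered": considered}


def extract_subregion(sequence: str, fwd_primer: str, rev_primer: str,
                      max_mismatch: int = 0) -> Optional[str]:
    """Extract the region between a primer pair from a full-length gene.

    Returns the subsequence strictly between the forward primer match and
    the reverse-complemented reverse primer match, or None when either is
    absent.  If the forward primer matches more than once, the first match
    is used (a warning reports it).
    """
    mf = match_iupac(fwd_primer, sequence, max_mismatch)
    if mf is None:
        return None
    # count additional forward matches for reporting
    rest = match_iupac(fwd_primer, sequence[mf["offset"] + 1:], max_mismatch)
    if rest is not None:
        warnings.warn("multiple forward primer matches; using the first",
                      stacklevel=2)
    start = mf["offset"] + len(fwd_primer)
    rc_rev = reverse_complement(rev_primer)
    mr = match_iupac(rc_rev, sequence[start:], max_mismatch)
    if mr is None:
        return None
    return sequence[start:start + mr["offset"]]
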