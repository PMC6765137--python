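"""Synthetic CCS-like mock-community read generator with known truth.

Produces amplicon reads that emulate the error structure of PacBio
circular-consensus full-length 16S sequencing: multi-strain communities
whose strains carry multiple 16S alleles at integral within-genome copy
numbers, per-base substitutions conditioned on quality scores (most bases
at the maximum quality of 93, a low-quality tail enriched for errors),
quality-independent insertions and deletions, one-crossover chimeric
amplicons, random read orientation, and attached degenerate primers.
Default per-type error rates are substitutions 1.1e-4, insertions 2.2e-4
and deletions 1.0e-4 per base, matching rates measured for CCS amplicon
reads at 99.9% predicted accuracy.

Two bundled community designs ship with the package: ``zymo_like`` (8
strains, equimolar genomes, 29 alleles) and ``hmp_like`` (20 strains with
genome proportions spanning three orders of magnitude).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .mockeval import StrainReference
from .seqio import IUPAC, PrimerSpec, QualRead, DEFAULT_PRIMERS, \
    reverse_complement

__all__ = [
    "QualityModel",
    "CommunitySpec",
    "make_alleles",
    "simulate_reads",
    "load_spec",
    "DEFAULT_RATES",
]

#: Measured per-type CCS amplicon error rates (per nucleotide).
DEFAULT_RATES = {"substitution": 1.1e-4, "insertion": 2.2e-4,
                 "deletion": 1.0e-4}

AMPLICON_LENGTH = 1450
_BASES = np.arange(4, dtype=np.uint8)
_BASE_STR = "ACGT"


@dataclass(frozen=True)
class QualityModel:
    """Distribution of per-base quality scores.

    A point mass ``p_max`` at the maximum score (93) and the remainder
    uniform over [low_min, low_max], reflecting that CCS bases are
    predominantly maximum-quality with a low-quality tail.
    """

    p_max: float = 0.9
    q_max: int = 93
    low_min: int = 30
    low_max: int = 92

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        q = rng.integers(self.low_min, self.low_max + 1, size=n)
        q[rng.random(n) < self.p_max] = self.q_max
        return q.astype(np.int16)

    def mean_error_weight(self, half_decade: float = 20.0) -> float:
        """E[10^(-q/half_decade)] under this distribution."""
        low = np.arange(self.low_min, self.low_max + 1)
        return (self.p_max * 10.0 ** (-self.q_max / half_decade)
                + (1 - self.p_max)
                * float(np.mean(10.0 ** (-low / half_decade))))


@dataclass
class CommunitySpec:
    """Ground-truth description of a simulated mock community."""

    strains: list[StrainReference]
    proportions: list[float]  # genome proportion per strain
    rates: dict = field(default_factory=lambda: dict(DEFAULT_RATES))
    quality: QualityModel = field(default_factory=QualityModel)
    chimera_fraction: float = 0.02
    rc_fraction: float = 0.5
    primers: PrimerSpec = field(default_factory=lambda: DEFAULT_PRIMERS)
    seed: int = 0
    name: str = "community"

    def __post_init__(self):
        if len(self.strains) != len(self.proportions):
            raise ValueError("one proportion per strain required")
        tot = float(sum(self.proportions))
        if tot <= 0:
            raise ValueError("proportions must be positive")
        self.proportions = [p / tot for p in self.proportions]
        for key, r in self.rates.items():
            if not 0.0 <= r <= 0.01:
                raise ValueError(f"{key} rate {r} outside [0, 0.01]")
        if not 0.0 <= self.chimera_fraction < 1.0:
            raise ValueError("chimera_fraction must be in [0, 1)")
        for s in self.strains:
            if any(c < 1 for _, c in s.alleles):
                raise ValueError("allele copy numbers must be >= 1")


def make_alleles(n_strains: int, copies_per_strain: Sequence[Sequence[int]],
                 divergence: int = 4, seed: int = 0,
                 length: int = AMPLICON_LENGTH,
                 names: Optional[Sequence[str]] = None
                 ) -> list[StrainReference]:
    """Generate random strain references with multi-copy 16S-like alleles.

    Each strain gets a backbone derived from a shared ancestor with 5% of
    positions substituted (so inter-strain identity < 95%); within a
    strain, allele i carries ``divergence`` substitutions at positions
    private to that allele, so distinct alleles differ by at least
    ``divergence`` substitutions.  Deterministic under ``seed``.
    """
    if divergence < 1:
        raise ValueError("divergence between distinct alleles must be >= 1")
    if n_strains != len(copies_per_strain):
        raise ValueError("copies_per_strain must list one entry per strain")
    max_alleles = max(len(c) for c in copies_per_strain)
    if (max_alleles - 1) * divergence > length // 2:
        raise ValueError("divergence infeasible for the amplicon length")
    rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, 4, size=length, dtype=np.uint8)
    refs = []
    for si, copies in enumerate(copies_per_strain):
        backbone = ancestor.copy()
        n_mut = max(int(round(0.05 * length)), 1)
        pos = rng.choice(length, size=n_mut, replace=False)
        backbone[pos] = (backbone[pos] + rng.integers(1, 4, size=n_mut)) % 4
        # private substitution positions per non-backbone allele
        priv = rng.choice(length, size=(len(copies) - 1) * divergence,
                          replace=False) if len(copies) > 1 else np.array([], int)
        name = names[si] if names is not None else f"strain{si + 1}"
        alleles = []
        for ai, c in enumerate(copies):
            seq = backbone.copy()
            if ai > 0:
                p = priv[(ai - 1) * divergence: ai * divergence]
                seq[p] = (seq[p] + rng.integers(1, 4, size=len(p))) % 4
            alleles.append(("".join(_BASE_STR[b] for b in seq), int(c)))
        refs.append(StrainReference(name=name, alleles=tuple(alleles),
                                    copy_number=int(sum(copies))))
    return refs


def _realize_primer(primer: str, rng: np.random.Generator) -> str:
    return "".join(b if len(IUPAC[b]) == 1 else
                   sorted(IUPAC[b])[rng.integers(len(IUPAC[b]))]
                   for b in primer.upper())


def _mutate(template: np.ndarray, rng: np.random.Generator,
            quality: QualityModel, c_sub: float, ins_rate: float,
            del_rate: float):
    """Apply quality-conditioned substitutions and uniform indels.

    Returns (bases, quals, n_sub, n_ins, n_del).
    """
    L = len(template)
    q = quality.sample(rng, L)
    p_sub = np.minimum(c_sub * 10.0 ** (-q / 20.0), 0.25)
    sub_mask = rng.random(L) < p_sub
    bases = template.copy()
    if sub_mask.any():
        shift = rng.integers(1, 4, size=int(sub_mask.sum())).astype(np.uint8)
        bases[sub_mask] = (bases[sub_mask] + shift) % 4
    del_mask = rng.random(L) < del_rate
    keep = ~del_mask
    bases = bases[keep]
    q = q[keep]
    ins_mask = rng.random(L) < ins_rate
    n_ins = int(ins_mask.sum())
    if n_ins:
        # insert before randomly chosen retained positions
        ipos = rng.integers(0, len(bases) + 1, size=n_ins)
        ibase = rng.integers(0, 4, size=n_ins).astype(np.uint8)
        iq = quality.sample(rng, n_ins)
        order = np.argsort(ipos, kind="stable")
        bases = np.insert(bases, ipos[order], ibase[order])
        q = np.insert(q, ipos[order], iq[order])
    return bases, q, int(sub_mask.sum()), n_ins, int(del_mask.sum())


def simulate_reads(spec: CommunitySpec, n_reads: int,
                   seed: Optional[int] = None
                   ) -> tuple[list[QualRead], pd.DataFrame]:
    """Simulate CCS-like amplicon reads from a community specification.

    Alleles are sampled with probability proportional to (genome
    proportion x allele copy number).  Substitutions are drawn per base
    with probability scaled by the base's quality so that the marginal
    rate equals the configured substitution rate; insertions and
    deletions are placed uniformly at their configured rates.  A
    ``chimera_fraction`` of reads are one-crossover mosaics of two
    sampled templates.  Primers are attached (degenerate positions
    realized at random) and a ``rc_fraction`` of reads are emitted
    reverse-complemented.  Returns (reads, truth table); deterministic
    under the seed (``spec.seed`` unless overridden).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    allele_seqs: list[np.ndarray] = []
    allele_ids: list[str] = []
    allele_strain: list[str] = []
    probs: list[float] = []
    for ref, prop in zip(spec.strains, spec.proportions):
        for ai, (seq, copies) in enumerate(ref.alleles):
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            lut = np.zeros(256, dtype=np.uint8)
            for i, b in enumerate(_BASE_STR):
                lut[ord(b)] = i
            allele_seqs.append(lut[arr])
            allele_ids.append(f"{ref.name}|allele{ai + 1}")
            allele_strain.append(ref.name)
            probs.append(prop * copies)
    probs = np.asarray(probs)
    probs = probs / probs.sum()

    c_sub = spec.rates["substitution"] / spec.quality.mean_error_weight()
    ins_rate = spec.rates["insertion"]
    del_rate = spec.rates["deletion"]

    choices = rng.choice(len(allele_seqs), size=n_reads, p=probs)
    chim = rng.random(n_reads) < spec.chimera_fraction
    partners = rng.choice(len(allele_seqs), size=n_reads, p=probs)
    rc = rng.random(n_reads) < spec.rc_fraction

    fwd = spec.primers.forward
    rev = spec.primers.reverse
    reads: list[QualRead] = []
    rows = []
    for i in range(n_reads):
        a = int(choices[i])
        b = int(partners[i])
        if chim[i] and b != a:
            ta, tb = allele_seqs[a], allele_seqs[b]
            L = min(len(ta), len(tb))
            x = int(rng.integers(L // 4, 3 * L // 4))
            template = np.concatenate([ta[:x], tb[x:]])
            allele_b = allele_ids[b]
        else:  # a degenerate same-template 'chimera' is just a normal read
            template = allele_seqs[a]
            allele_b = ""
            x = -1
        bases, quals, n_sub, n_ins, n_del = _mutate(
            template, rng, spec.quality, c_sub, ins_rate, del_rate)
        insert = "".join(_BASE_STR[v] for v in bases)
        p5 = _realize_primer(fwd, rng)
        p3 = reverse_complement(_realize_primer(rev, rng))
        seq = p5 + insert + p3
        qp5 = spec.quality.sample(rng, len(p5))
        qp3 = spec.quality.sample(rng, len(p3))
        q = np.concatenate([qp5, quals, qp3])
        if rc[i]:
            seq = reverse_complement(seq)
            q = q[::-1].copy()
        rid = f"read{i}"
        reads.append(QualRead(rid, seq, q))
        rows.append((rid, allele_strain[a], allele_ids[a], allele_b,
                     bool(allele_b), int(x), n_sub, n_ins, n_del,
                     bool(rc[i])))
    truth = pd.DataFrame(rows, columns=[
        "read_id", "strain", "allele", "allele_b", "is_chimera", "crossover",
        "n_sub", "n_ins", "n_del", "reverse_complemented"])
    return reads, truth


def load_spec(name_or_path, seed: Optional[int] = None) -> CommunitySpec:
    """Load a community specification from JSON.

    ``name_or_path`` is either a bundled design name ('zymo_like',
    'hmp_like') or a path to a JSON file with the same schema.  Allele
    sequences are generated deterministically from the spec's seed (or
    the ``seed`` override).
    """
    name = str(name_or_path)
    if name in ("zymo_like", "hmp_like"):
        text = resources.files("longasv.data").joinpath(
            f"{name}.json").read_text()
    else:
        with open(name_or_path) as fh:
            text = fh.read()
    obj = json.loads(text)
    if seed is None:
        seed = int(obj.get("seed", 0))
    copies = [s["copies"] for s in obj["strains"]]
    names = [s["name"] for s in obj["strains"]]
    refs = make_alleles(len(copies), copies,
                        divergence=int(obj.get("divergence", 4)),
                        seed=seed, names=names,
                        length=int(obj.get("length", AMPLICON_LENGTH)))
    props = [float(s["proportion"]) for s in obj["strains"]]
    return CommunitySpec(
        strains=refs, proportions=props,
        rates=obj.get("rates", dict(DEFAULT_RATES)),
        quality=QualityModel(**obj.get("quality", {})),
        chimera_fraction=float(obj.get("chimera_fraction", 0.02)),
        rc_fraction=float(obj.get("rc_fraction", 0.5)),
        seed=seed, name=obj.get("name", name))
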