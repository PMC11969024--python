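"""Combinatorial peptide library enumeration and reverse translation.

A library is built from class-specific pools of improving point mutations:
all subsets of size >= 2 with pairwise-distinct positions are enumerated per
pool, pooled, deduplicated, and extended with the single mutants, the parent
and a scrambled parent control. Peptides are reverse-translated into
oligonucleotides with cloning arms using an E. coli codon-usage model.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .selection import Mutation, validate_mutation

# Cloning arms flanking the 48-nt insert in the synthesised oligo pool.
DEFAULT_ARM_5 = "GCAGCCTCTTCATCTGGC"
DEFAULT_ARM_3 = "GGTGGAGGATCCGGA"

#: Synthetic 16-mer parent used by the simulator and examples. Two positions
#: (8 and 14, here G) are placeholders; this is a synthetic stand-in for an
#: evasin-derived hexadecapeptide, not a published sequence.
SYNTHETIC_PARENT = "EEDDYTAGAPLTCGFT"

# E. coli K-12 codon usage, relative frequency within each amino acid.
ECOLI_USAGE: dict[str, dict[str, float]] = {
    "A": {"GCG": 0.36, "GCC": 0.27, "GCA": 0.21, "GCT": 0.16},
    "R": {"CGC": 0.40, "CGT": 0.38, "CGG": 0.10, "CGA": 0.06, "AGA": 0.04, "AGG": 0.02},
    "N": {"AAC": 0.55, "AAT": 0.45},
    "D": {"GAT": 0.63, "GAC": 0.37},
    "C": {"TGC": 0.55, "TGT": 0.45},
    "Q": {"CAG": 0.65, "CAA": 0.35},
    "E": {"GAA": 0.68, "GAG": 0.32},
    "G": {"GGC": 0.40, "GGT": 0.34, "GGG": 0.15, "GGA": 0.11},
    "H": {"CAT": 0.57, "CAC": 0.43},
    "I": {"ATT": 0.51, "ATC": 0.42, "ATA": 0.07},
    "L": {"CTG": 0.50, "TTA": 0.13, "TTG": 0.13, "CTT": 0.10, "CTC": 0.10, "CTA": 0.04},
    "K": {"AAA": 0.74, "AAG": 0.26},
    "M": {"ATG": 1.0},
    "F": {"TTT": 0.57, "TTC": 0.43},
    "P": {"CCG": 0.52, "CCA": 0.19, "CCT": 0.16, "CCC": 0.13},
    "S": {"AGC": 0.28, "TCT": 0.15, "TCC": 0.15, "AGT": 0.15, "TCG": 0.15, "TCA": 0.12},
    "T": {"ACC": 0.44, "ACG": 0.27, "ACT": 0.17, "ACA": 0.13},
    "W": {"TGG": 1.0},
    "Y": {"TAT": 0.57, "TAC": 0.43},
    "V": {"GTG": 0.37, "GTT": 0.26, "GTC": 0.22, "GTA": 0.15},
}


@dataclass(frozen=True)
class MutationPool:
    label: str  # "CC" or "CXnC"
    mutations: tuple[Mutation, ...]

    def __post_init__(self) -> None:
        if len(set(self.mutations)) != len(self.mutations):
            raise ValueError(f"pool {self.label}: duplicate mutations")


@dataclass(frozen=True)
class PeptideVariant:
    sequence: str
    mutations: frozenset[Mutation]
    provenance: str  # parent / scrambled / single / combo
    pool_origin: frozenset[str] = frozenset()


def apply_mutations(parent: str, muts: frozenset[Mutation] | set[Mutation]) -> str:
    """Apply substitutions to the parent; positions must be pairwise distinct."""
    positions = [m.position for m in muts]
    if len(set(positions)) != len(positions):
        clash = sorted(p for p in set(positions) if positions.count(p) > 1)
        raise ValueError(f"conflicting mutations at position(s) {clash}")
    seq = list(parent)
    for m in muts:
        validate_mutation(m, parent)
        seq[m.position - 1] = m.to_aa
    return "".join(seq)


def enumerate_combinations(
    pools: list[MutationPool],
    parent: str,
    scrambled: str,
    min_size: int = 2,
    exclude_same_position: bool = True,
) -> list[PeptideVariant]:
    """All valid mutation combinations per pool, plus singles, parent, scrambled.

    Per pool, every subset of size >= ``min_size`` whose positions are
    pairwise distinct is applied to the parent. Pool outputs are united and
    deduplicated on sequence (first provenance kept, pool origins united).
    With ``exclude_same_position`` off, same-position subsets are generated
    and collapse at the sequence-dedup stage instead (sensitivity mode).
    """
    if scrambled == parent:
        raise ValueError("scrambled control equals the parent sequence")
    if not pools:
        raise ValueError("at least one mutation pool required")
    by_seq: dict[str, PeptideVariant] = {}

    def add(seq: str, muts: frozenset[Mutation], provenance: str, origin: frozenset[str]):
        if seq in by_seq:
            prev = by_seq[seq]
            by_seq[seq] = PeptideVariant(
                seq, prev.mutations, prev.provenance, prev.pool_origin | origin
            )
        else:
            by_seq[seq] = PeptideVariant(seq, muts, provenance, origin)

    for pool in pools:
        muts = pool.mutations
        for k in range(min_size, len(muts) + 1):
            for subset in itertools.combinations(muts, k):
                positions = {m.position for m in subset}
                if exclude_same_position and len(positions) != len(subset):
                    continue
                try:
                    seq = apply_mutations(parent, frozenset(subset))
                except ValueError:
                    continue  # same-position subset in sensitivity mode
                add(seq, frozenset(subset), "combo", frozenset({pool.label}))
    # singles from the union of all pools
    for pool in pools:
        for m in pool.mutations:
            seq = apply_mutations(parent, frozenset({m}))
            add(seq, frozenset({m}), "single", frozenset({pool.label}))
    add(parent, frozenset(), "parent", frozenset())
    by_seq.setdefault(
        scrambled, PeptideVariant(scrambled, frozenset(), "scrambled", frozenset())
    )
    return list(by_seq.values())


def build_nnk_library(parent: str) -> list[PeptideVariant]:
    """Site-saturation singles: every position to each of the 20 amino acids.

    Substitution to the parental residue collapses to the parent, giving
    L x 19 unique singles plus the parent.
    """
    from .selection import AA20

    variants = [PeptideVariant(parent, frozenset(), "parent")]
    for i, from_aa in enumerate(parent, start=1):
        for to_aa in AA20:
            if to_aa == from_aa:
                continue
            mut = Mutation(i, from_aa, to_aa)
            variants.append(
                PeptideVariant(apply_mutations(parent, {mut}), frozenset({mut}), "single")
            )
    return variants


def scramble(parent: str, seed: int = 0) -> str:
    """Seeded random permutation of the parent, guaranteed distinct from it."""
    if len(parent) < 2 or len(set(parent)) < 2:
        raise ValueError("parent has no distinct permutation to scramble to")
    rng = random.Random(seed)
    letters = list(parent)
    while True:
        rng.shuffle(letters)
        candidate = "".join(letters)
        if candidate != parent:
            return candidate


@dataclass(frozen=True)
class CodonModel:
    """Codon choice model over a per-amino-acid usage table.

    ``most_frequent`` always picks the top codon; ``weighted_sample`` draws
    proportionally to usage (seeded). With ``gc_biased`` the choice is
    restricted to the two highest-GC codons of each residue.
    """

    usage: dict[str, dict[str, float]] = field(
        default_factory=lambda: {aa: dict(v) for aa, v in ECOLI_USAGE.items()}
    )
    mode: str = "most_frequent"
    gc_biased: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("most_frequent", "weighted_sample"):
            raise ValueError("mode must be most_frequent or weighted_sample")
        for aa, codons in self.usage.items():
            if not codons or all(w <= 0 for w in codons.values()):
                raise ValueError(f"no positively weighted codon for {aa}")

    def _candidates(self, aa: str) -> dict[str, float]:
        try:
            codons = self.usage[aa]
        except KeyError:
            raise ValueError(f"residue {aa!r} absent from codon table") from None
        if not self.gc_biased:
            return codons
        ranked = sorted(
            codons, key=lambda c: (c.count("G") + c.count("C"), codons[c]), reverse=True
        )
        return {c: codons[c] for c in ranked[:2]}


@dataclass(frozen=True)
class OligoDesign:
    variant: PeptideVariant
    insert_nt: str
    full_oligo: str


def reverse_translate(
    variant: PeptideVariant,
    model: CodonModel | None = None,
    arm5: str = DEFAULT_ARM_5,
    arm3: str = DEFAULT_ARM_3,
    rng: random.Random | None = None,
) -> OligoDesign:
    """Encode a peptide as DNA under the codon model; arms flank the insert."""
    model = model or CodonModel()
    if rng is None:
        rng = random.Random(model.seed)
    codons = []
    for aa in variant.sequence:
        cands = model._candidates(aa)
        if model.mode == "most_frequent":
            codons.append(max(cands, key=lambda c: (cands[c], c)))
        else:
            names = sorted(cands)
            weights = [cands[c] for c in names]
            codons.append(rng.choices(names, weights=weights, k=1)[0])
    insert = "".join(codons)
    assert str(Seq(insert).translate()) == variant.sequence
    return OligoDesign(variant, insert, arm5 + insert + arm3)
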