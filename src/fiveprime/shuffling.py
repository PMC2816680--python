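"""Permutation-null sequence generation per gene.

The default null randomly reshuffles synonymous codons among sites encoding
the same amino acid, which conditions on the protein sequence, the per-gene
codon usage, and hence the gene-wide base composition.  A dinucleotide-
preserving variant (dicodon shuffle) additionally constrains the whole-
sequence dinucleotide count vector, including codon-junction dinucleotides.

Reproducibility contract: each gene gets its own RNG stream derived from
(master seed, gene_id), so results are independent of gene processing order.
"""

from __future__ import annotations

import itertools
import math
import zlib
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

from .genome_io import CodingSequence

_BASES = "ACGT"


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> amino-acid mapping with derived synonymous families.

    Stops map to ``*``.  Families partition the 61 sense codons of the
    standard code; single-codon families (Met, Trp) have no synonymous
    freedom.
    """

    codon_to_aa: dict[str, str]
    families: dict[str, tuple[str, ...]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError("genetic code must map exactly 64 codons")
        fams: dict[str, list[str]] = {}
        for codon, aa in sorted(self.codon_to_aa.items()):
            if aa != "*":
                fams.setdefault(aa, []).append(codon)
        object.__setattr__(
            self, "families", {aa: tuple(cs) for aa, cs in fams.items()}
        )

    def translate(self, seq: str) -> str:
        return "".join(
            self.codon_to_aa[seq[i : i + 3]] for i in range(0, len(seq), 3)
        )


@lru_cache(maxsize=1)
def standard_code() -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return GeneticCode(codon_to_aa=mapping)


@dataclass(frozen=True)
class ShuffleConfig:
    n_permutations: int = 1000
    method: str = "codon_shuffle"  # or "dicodon_shuffle"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.method not in ("codon_shuffle", "dicodon_shuffle"):
            raise ValueError(f"unknown shuffle method {self.method!r}")


def gene_rng(master_seed: int, gene_id: str) -> np.random.Generator:
    """Independent, order-insensitive RNG stream for one gene."""
    ss = np.random.SeedSequence(
        entropy=master_seed, spawn_key=(zlib.crc32(gene_id.encode()),)
    )
    return np.random.default_rng(ss)


def _shuffleable_groups(
    codons: list[str], code: GeneticCode
) -> dict[str, list[int]]:
    """Positions grouped by amino acid, excluding stops (no amino acid).

    The terminal stop codon — and any internal stop, which carries a warning
    at IO time — stays fixed in place.
    """
    groups: dict[str, list[int]] = {}
    for i, codon in enumerate(codons):
        aa = code.codon_to_aa[codon]
        if aa == "*":
            continue
        groups.setdefault(aa, []).append(i)
    return groups


def codon_shuffle(
    gene: CodingSequence, code: GeneticCode, rng: np.random.Generator
) -> CodingSequence:
    """Uniformly random synonymous-codon permutation of one gene.

    Within each amino acid's positions the codon arrangement is a uniform
    random permutation; the translation and the per-amino-acid codon multiset
    (hence gene GC) are preserved exactly.
    """
    codons = gene.codons()
    out = list(codons)
    for positions in _shuffleable_groups(codons, code).values():
        if len(positions) < 2:
            continue
        perm = rng.permutation(len(positions))
        for dst, src in zip(positions, perm):
            out[dst] = codons[positions[src]]
    return CodingSequence(gene.gene_id, gene.species_id, "".join(out))


def dinucleotide_counts(seq: str) -> np.ndarray:
    """16-entry count vector of overlapping dinucleotides (AA..TT order)."""
    idx = {b: i for i, b in enumerate(_BASES)}
    counts = np.zeros(16, dtype=np.int64)
    for a, b in zip(seq, seq[1:]):
        counts[idx[a] * 4 + idx[b]] += 1
    return counts


def _multiset_permutation_count(items: list[str]) -> int:
    n = math.factorial(len(items))
    for mult in Counter(items).values():
        n //= math.factorial(mult)
    return n


def _distinct_permutations(items: list[str]):
    """All distinct orderings of a multiset, without iterating n! tuples."""
    counts = Counter(items)
    keys = sorted(counts)
    out: list[str] = []

    def rec():
        if len(out) == len(items):
            yield tuple(out)
            return
        for k in keys:
            if counts[k]:
                counts[k] -= 1
                out.append(k)
                yield from rec()
                out.pop()
                counts[k] += 1

    yield from rec()


def _enumerate_synonymous(
    codons: list[str], code: GeneticCode, limit: int
):
    """All distinct synonymous arrangements, or None when > limit.

    The multiset-permutation count per family is computed arithmetically
    first, so oversized spaces are detected without enumerating anything.
    """
    groups = _shuffleable_groups(codons, code)
    total = 1
    for positions in groups.values():
        total *= _multiset_permutation_count([codons[i] for i in positions])
        if total > limit:
            return None
    per_family: list[tuple[list[int], list[tuple[str, ...]]]] = []
    for positions in groups.values():
        fam_codons = [codons[i] for i in positions]
        per_family.append((positions, list(_distinct_permutations(fam_codons))))
    results = []
    for combo in itertools.product(*(arrs for _, arrs in per_family)):
        out = list(codons)
        for (positions, _), arr in zip(per_family, combo):
            for pos, c in zip(positions, arr):
                out[pos] = c
        results.append(tuple(out))
    return results


def enumerate_dicodon_arrangements(
    gene: CodingSequence,
    code: GeneticCode,
    limit: int = 200_000,
) -> list[str] | None:
    """All synonymous arrangements preserving the dinucleotide count vector.

    Brute-force filter over the full synonymous space; None when the space
    exceeds ``limit``.  Used both as the exact sampler for small genes and as
    the enumeration oracle in tests.
    """
    codons = gene.codons()
    space = _enumerate_synonymous(codons, code, limit)
    if space is None:
        return None
    target = dinucleotide_counts(gene.seq)
    valid = []
    for arrangement in space:
        seq = "".join(arrangement)
        if np.array_equal(dinucleotide_counts(seq), target):
            valid.append(seq)
    return valid


# enumeration threshold for exact dicodon sampling; above it, rejection
# sampling against the count constraint is used
_DICODON_ENUM_LIMIT = 5000


def dicodon_shuffle(
    gene: CodingSequence,
    code: GeneticCode,
    rng: np.random.Generator,
    max_attempts: int = 200,
) -> CodingSequence:
    """Synonymous shuffle preserving the 16-dinucleotide count vector.

    For small genes the valid arrangement set is enumerated and sampled
    uniformly.  Larger genes use rejection sampling (draw a codon shuffle,
    accept iff dinucleotide counts match) capped at ``max_attempts``; on
    budget exhaustion the input is returned (a self-permutation, always
    valid).
    """
    valid = enumerate_dicodon_arrangements(gene, code, limit=_DICODON_ENUM_LIMIT)
    if valid is not None:
        seq = valid[rng.integers(len(valid))]
        return CodingSequence(gene.gene_id, gene.species_id, seq)
    target = dinucleotide_counts(gene.seq)
    for _ in range(max_attempts):
        candidate = codon_shuffle(gene, code, rng)
        if np.array_equal(dinucleotide_counts(candidate.seq), target):
            return candidate
    return CodingSequence(gene.gene_id, gene.species_id, gene.seq)


def generate_null_set(
    gene: CodingSequence,
    config: ShuffleConfig,
    code: GeneticCode | None = None,
) -> list[CodingSequence]:
    """Exactly ``n_permutations`` permuted sequences for one gene.

    Reproducible given (seed, gene_id); different genes get independent
    streams, so parallel or reordered execution cannot change results.
    """
    if code is None:
        code = standard_code()
    rng = gene_rng(config.seed, gene.gene_id)
    shuffle = codon_shuffle if config.method == "codon_shuffle" else dicodon_shuffle
    return [shuffle(gene, code, rng) for _ in range(config.n_permutations)]
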