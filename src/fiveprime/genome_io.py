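"""Reading, validating and filtering coding sequences and metadata tables.

Coding sequences (CDS) are stored as DNA over {A,C,G,T}; transcription to the
RNA alphabet happens only at the folding boundary.  The default length filter
keeps genes *strictly longer* than 50 codons (>=51 codons, >=153 nt), which
guarantees that every accepted gene covers the full default 13-window scan
(the last window ends at nucleotide 150).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_MIN_CODONS = 50

TAXON_GROUPS = frozenset(
    {"bacteria", "archaea", "fungi", "plants", "insects", "fishes", "birds",
     "mammals", "other"}
)

#: groups treated as prokaryotes in temperature analyses
PROKARYOTE_GROUPS = frozenset({"bacteria", "archaea"})

_VALID_BASES = frozenset("ACGT")
_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class CodingSequence:
    """One CDS; the unit of permutation testing.

    ``seq`` is normalized DNA (uppercase, U mapped to T), validated to be a
    positive multiple of 3 over {A,C,G,T}.
    """

    gene_id: str
    species_id: str
    seq: str

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3

    def codons(self) -> list[str]:
        return [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]

    @property
    def gc(self) -> float:
        """Whole-CDS G+C fraction."""
        s = self.seq
        return (s.count("G") + s.count("C")) / len(s)


@dataclass(frozen=True)
class SpeciesMetadata:
    species_id: str
    taxon_group: str
    optimal_growth_temperature: float | None = None
    genomic_gc: float | None = None

    def __post_init__(self) -> None:
        if self.taxon_group not in TAXON_GROUPS:
            raise ValueError(
                f"unknown taxon_group {self.taxon_group!r} for {self.species_id}"
            )
        t = self.optimal_growth_temperature
        if t is not None and not math.isfinite(t):
            raise ValueError(f"non-finite temperature for {self.species_id}")
        g = self.genomic_gc
        if g is not None and not 0.0 <= g <= 1.0:
            raise ValueError(f"genomic_gc outside [0,1] for {self.species_id}")


@dataclass
class RejectionReport:
    """Per-gene rejections (with reason) plus non-fatal warnings."""

    rejected: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def counts(self) -> Counter:
        return Counter(reason for _, reason in self.rejected)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rejected, columns=["gene_id", "reason"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def normalize_sequence(raw: str) -> str:
    """Uppercase and map U->T.  Does not validate."""
    return raw.upper().replace("U", "T")


def validate_cds(gene_id: str, seq: str, min_codons: int) -> tuple[str | None, list[str]]:
    """Classify one normalized sequence.

    Returns ``(rejection_reason | None, warnings)``.  Reasons: ``ambiguous``
    (non-ACGT characters, including IUPAC ambiguity codes), ``frame`` (length
    not a positive multiple of 3), ``too_short`` (not strictly more than
    ``min_codons`` codons).  Internal stop codons only warn.
    """
    warnings: list[str] = []
    if not set(seq) <= _VALID_BASES:
        return "ambiguous", warnings
    if len(seq) == 0 or len(seq) % 3 != 0:
        return "frame", warnings
    if len(seq) // 3 <= min_codons:
        return "too_short", warnings
    internal = [seq[i : i + 3] for i in range(0, len(seq) - 3, 3)]
    if any(c in _STOP_CODONS for c in internal):
        warnings.append("internal_stop")
    if not seq.startswith("ATG"):
        warnings.append("non_atg_start")
    return None, warnings


def read_cds_fasta(
    path: str | Path,
    min_codons: int = DEFAULT_MIN_CODONS,
    species_id: str | None = None,
) -> tuple[list[CodingSequence], RejectionReport]:
    """Read a CDS FASTA, keeping only validated genes.

    Individual malformed records are rejected (never fatal); an unreadable
    file raises.  ``species_id`` defaults to the file stem.
    """
    path = Path(path)
    if species_id is None:
        species_id = path.stem
    accepted: list[CodingSequence] = []
    report = RejectionReport()
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        if gene_id in seen:
            report.rejected.append((gene_id, "duplicate_id"))
            continue
        seen.add(gene_id)
        seq = normalize_sequence(str(rec.seq))
        reason, warns = validate_cds(gene_id, seq, min_codons)
        if reason is not None:
            report.rejected.append((gene_id, reason))
            continue
        for w in warns:
            report.warnings.append((gene_id, w))
        accepted.append(CodingSequence(gene_id=gene_id, species_id=species_id, seq=seq))
    return accepted, report


def write_cds_fasta(genes: Iterable[CodingSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(g.seq), id=g.gene_id, description="") for g in genes
    ]
    SeqIO.write(records, str(path), "fasta")


def compute_genomic_gc(genes: Iterable[CodingSequence]) -> float:
    """Pooled (total G+C)/(total length) over all genes.

    Pooling over nucleotides, not averaging per-gene fractions, so the value
    is invariant under any partition or ordering of the gene collection.
    """
    gc = 0
    total = 0
    for g in genes:
        gc += g.seq.count("G") + g.seq.count("C")
        total += len(g.seq)
    if total == 0:
        raise ValueError("no genes")
    return gc / total


def read_metadata(path: str | Path) -> list[SpeciesMetadata]:
    """Read a species metadata TSV (species_id, taxon_group,
    optimal_growth_temperature[, genomic_gc]); missing temperatures stay absent."""
    df = pd.read_csv(path, sep="\t")
    dup = df["species_id"][df["species_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate species_id: {dup.iloc[0]!r}")
    out = []
    for row in df.itertuples(index=False):
        temp = getattr(row, "optimal_growth_temperature", None)
        if temp is not None and pd.isna(temp):
            temp = None
        gc = getattr(row, "genomic_gc", None)
        if gc is not None and pd.isna(gc):
            gc = None
        out.append(
            SpeciesMetadata(
                species_id=str(row.species_id),
                taxon_group=str(row.taxon_group),
                optimal_growth_temperature=None if temp is None else float(temp),
                genomic_gc=None if gc is None else float(gc),
            )
        )
    return out


def write_metadata(meta: Iterable[SpeciesMetadata], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "species_id": m.species_id,
                "taxon_group": m.taxon_group,
                "optimal_growth_temperature": m.optimal_growth_temperature,
                "genomic_gc": m.genomic_gc,
            }
            for m in meta
        ]
    ).to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> dict[str, float]:
    """Read an expression TSV (gene_id, expression) into a mapping.

    Zero is a valid expression level; negative values and duplicate gene ids
    are errors.  Multi-tissue inputs are expected to be pre-reduced to a
    geometric mean by the caller.
    """
    df = pd.read_csv(path, sep="\t")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate gene_id: {dup.iloc[0]!r}")
    table: dict[str, float] = {}
    for row in df.itertuples(index=False):
        val = float(row.expression)
        if val < 0:
            raise ValueError(f"negative expression for {row.gene_id!r}")
        table[str(row.gene_id)] = val
    return table


def write_expression(table: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": list(table.keys()), "expression": list(table.values())}
    ).to_csv(path, sep="\t", index=False)
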