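"""Synthetic multi-gene CDS generation with controllable 5' destabilization.

Genes are built codon-wise: amino acids are drawn i.i.d. from a configurable
composition (uniform over the 20 standard amino acids by default; the
permutation statistic conditions on the amino-acid sequence, so composition
realism is not required for its validity).  Synonymous codons within each
family are sampled from per-genome weights

    w_c ∝ exp(bias_c + beta * n_GC(c) [- delta_gene * n_GC(c) in the 5' span])

where ``bias_c`` are fixed per-genome perturbations whose scale is the codon
usage bias strength, and beta is solved numerically so the expected pooled GC
matches the target.  The 5' destabilization delta acts purely on synonymous
choice (an excess AT preference within the first ``delta5_span_nt``
nucleotides), mimicking a depletion of GC — and hence of stable mRNA
structure — right after the start codon, without touching the amino-acid
sequence.

Every generated gene starts with ATG, ends with a stop codon, has no internal
stops, and passes the default IO filter with zero rejections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import CodingSequence, SpeciesMetadata
from .shuffling import GeneticCode, standard_code

_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class SyntheticGenomeConfig:
    species_id: str = "synthetic"
    n_genes: int = 300
    length_codons: tuple[int, int] = (60, 200)  # inclusive range, min > 50
    target_gc: float = 0.5
    codon_bias_strength: float = 0.5
    delta5: float = 0.0
    delta5_span_nt: int = 30
    expression_coupling: float = 0.0
    seed: int = 0
    aa_composition: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.length_codons[0] <= 50:
            raise ValueError("minimum gene length must exceed 50 codons")
        if not 0.0 < self.target_gc < 1.0:
            raise ValueError("target_gc must be in (0,1)")
        if self.codon_bias_strength < 0:
            raise ValueError("codon_bias_strength must be >= 0")


def _codon_gc(codon: str) -> int:
    return sum(b in "GC" for b in codon)


def _family_weights(
    code: GeneticCode, bias: dict[str, np.ndarray], beta: float
) -> dict[str, np.ndarray]:
    weights = {}
    for aa, codons in code.families.items():
        logw = bias[aa] + beta * np.array([_codon_gc(c) for c in codons])
        w = np.exp(logw - logw.max())
        weights[aa] = w / w.sum()
    return weights


def _expected_gc(
    code: GeneticCode,
    bias: dict[str, np.ndarray],
    beta: float,
    aa_freq: dict[str, float],
) -> float:
    w = _family_weights(code, bias, beta)
    num = 0.0
    for aa, freq in aa_freq.items():
        gcs = np.array([_codon_gc(c) for c in code.families[aa]])
        num += freq * float(w[aa] @ gcs)
    return num / 3.0


def _solve_beta(
    code: GeneticCode,
    bias: dict[str, np.ndarray],
    target_gc: float,
    aa_freq: dict[str, float],
) -> tuple[float, float]:
    """Bisection for the GC tilt; returns (beta, achievable_gc)."""
    lo, hi = -15.0, 15.0
    glo = _expected_gc(code, bias, lo, aa_freq)
    ghi = _expected_gc(code, bias, hi, aa_freq)
    if not glo <= target_gc <= ghi:
        import warnings

        achieved = glo if target_gc < glo else ghi
        warnings.warn(
            f"target GC {target_gc:.3f} unattainable; closest {achieved:.3f}"
        )
        return (lo if target_gc < glo else hi), achieved
    for _ in range(60):
        mid = (lo + hi) / 2
        if _expected_gc(code, bias, mid, aa_freq) < target_gc:
            lo = mid
        else:
            hi = mid
    beta = (lo + hi) / 2
    return beta, _expected_gc(code, bias, beta, aa_freq)


def generate_genome(
    config: SyntheticGenomeConfig,
    code: GeneticCode | None = None,
) -> tuple[list[CodingSequence], pd.DataFrame]:
    """Generate one species' gene set plus a per-gene truth table.

    The truth table records each gene's realized GC, the destabilization
    delta actually applied, and a simulated expression level whose log-scale
    correlation with the per-gene delta latent equals ``expression_coupling``.
    """
    if code is None:
        code = standard_code()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    aas = sorted(code.families)
    if config.aa_composition is None:
        aa_freq = {aa: 1.0 / len(aas) for aa in aas}
    else:
        total = sum(config.aa_composition.values())
        aa_freq = {aa: v / total for aa, v in config.aa_composition.items()}

    bias = {
        aa: config.codon_bias_strength * rng.standard_normal(len(code.families[aa]))
        for aa in aas
    }
    beta, _ = _solve_beta(code, bias, config.target_gc, aa_freq)
    body_weights = _family_weights(code, bias, beta)

    aa_names = list(aa_freq)
    aa_probs = np.array([aa_freq[a] for a in aa_names])
    span_codons = config.delta5_span_nt // 3

    genes: list[CodingSequence] = []
    truth_rows = []
    ec = config.expression_coupling
    for i in range(config.n_genes):
        gene_id = f"{config.species_id}_g{i:05d}"
        length = int(rng.integers(config.length_codons[0], config.length_codons[1] + 1))
        u = float(rng.standard_normal())  # latent behind delta and expression
        delta = config.delta5 * float(np.exp(0.3 * u)) if config.delta5 > 0 else 0.0
        e_latent = ec * u + np.sqrt(max(0.0, 1 - ec * ec)) * rng.standard_normal()
        expression = float(100.0 * np.exp(e_latent))

        five_weights = None
        if delta > 0:
            five_weights = _family_weights(
                code,
                {aa: bias[aa] - delta * np.array([_codon_gc(c) for c in code.families[aa]])
                 for aa in aas},
                beta,
            )

        codons = ["ATG"]
        aa_idx = rng.choice(len(aa_names), size=length - 2, p=aa_probs)
        for pos, ai in enumerate(aa_idx, start=1):
            aa = aa_names[ai]
            fam = code.families[aa]
            w = (
                five_weights[aa]
                if five_weights is not None and pos < span_codons
                else body_weights[aa]
            )
            codons.append(fam[rng.choice(len(fam), p=w)])
        codons.append(_STOPS[rng.integers(len(_STOPS))])
        seq = "".join(codons)
        gene = CodingSequence(gene_id, config.species_id, seq)
        genes.append(gene)
        truth_rows.append(
            {
                "gene_id": gene_id,
                "n_codons": length,
                "gc": gene.gc,
                "delta_applied": delta,
                "expression": expression,
            }
        )
    return genes, pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class PanelResult:
    genomes: dict[str, list[CodingSequence]]
    truth: dict[str, pd.DataFrame]
    metadata: list[SpeciesMetadata] = field(default_factory=list)


def generate_species_panel(
    n_species: int,
    gc_range: tuple[float, float] = (0.32, 0.62),
    delta_vs_gc_slope: float = 0.0,
    temperature_model: dict | None = None,
    seed: int = 0,
    n_genes: int = 100,
    base_delta: float = 1.0,
    taxon_group: str = "bacteria",
    **genome_kwargs,
) -> PanelResult:
    """A panel of synthetic species spanning a GC range.

    Species GC values are evenly spread over ``gc_range``; each species'
    destabilization strength is ``base_delta + slope * (gc - gc_mid)``
    (clipped at 0), coupling delta positively to GC when the slope is
    positive.  ``temperature_model`` (dict with keys ``t0``, ``delta_coeff``,
    ``noise_sd``) optionally assigns growth temperatures coupled to delta —
    a negative ``delta_coeff`` yields hotter species with weaker 5'
    destabilization.
    """
    if n_species < 3:
        raise ValueError("need at least 3 species")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EC1E5]))
    gcs = np.linspace(gc_range[0], gc_range[1], n_species)
    gc_mid = float(np.mean(gc_range))
    genomes: dict[str, list[CodingSequence]] = {}
    truth: dict[str, pd.DataFrame] = {}
    metadata = []
    for s, gc in enumerate(gcs):
        sp = f"sp{s:03d}"
        delta = max(0.0, base_delta + delta_vs_gc_slope * (float(gc) - gc_mid))
        cfg = SyntheticGenomeConfig(
            species_id=sp,
            n_genes=n_genes,
            target_gc=float(gc),
            delta5=delta,
            seed=int(rng.integers(2**31)),
            **genome_kwargs,
        )
        genes, tr = generate_genome(cfg)
        genomes[sp] = genes
        truth[sp] = tr
        temp = None
        if temperature_model is not None and taxon_group in ("bacteria", "archaea"):
            temp = float(
                temperature_model.get("t0", 50.0)
                + temperature_model.get("delta_coeff", -20.0) * delta
                + temperature_model.get("noise_sd", 2.0) * rng.standard_normal()
            )
        metadata.append(
            SpeciesMetadata(
                species_id=sp,
                taxon_group=taxon_group,
                optimal_growth_temperature=temp,
                genomic_gc=None,  # filled downstream from the sequences
            )
        )
    return PanelResult(genomes=genomes, truth=truth, metadata=metadata)
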