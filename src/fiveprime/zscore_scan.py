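"""Sliding-window folding-energy and GC Z-scores, and genome aggregation.

For each gene, local folding free energy ΔG is computed in sliding windows
(default 30 nt wide, step 10 nt, 13 windows) starting at the first nucleotide
of the start codon.  The same windows are folded for N synonymously permuted
copies of the gene (one fixed permutation set serves all windows — the null
is per-sequence, not per-window), giving a per-window Z-score

    Z_dG = (dG_wt - mean(dG_perm)) / sd(dG_perm)

with the sample (N-1) standard deviation.  Positive Z_dG means the wild-type
window is *less stable* (less negative ΔG) than expected given its amino-acid
sequence and codon usage.  Z_GC is the analogous score for the window's G+C
fraction.  A degenerate null (sd = 0) makes the score undefined (NaN); such
windows are excluded, with counts, from genome-level means.

Genome aggregation: per window, the mean Z over genes, its standard error,
and a two-sided one-sample t-test of the mean against 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .folding import fold_batch, to_rna
from .genome_io import CodingSequence
from .shuffling import GeneticCode, ShuffleConfig, generate_null_set, standard_code

UNDEFINED = float("nan")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry, 1-based inclusive coordinates.

    Window i spans nucleotides [(i-1)*step + 1, (i-1)*step + width] relative
    to the first nucleotide of the start codon.  ``n_windows=None`` means
    "as many as fit".
    """

    width: int = 30
    step: int = 10
    n_windows: int | None = 13

    def __post_init__(self) -> None:
        if self.width < 1 or self.step < 1:
            raise ValueError("width and step must be >= 1")


@dataclass(frozen=True)
class WindowProfile:
    gene_id: str
    window_index: int  # 1-based
    start: int
    end: int
    dg_wt: float
    dg_perm_mean: float
    dg_perm_sd: float
    z_dg: float  # NaN when the null is degenerate
    gc_wt: float
    gc_perm_mean: float
    gc_perm_sd: float
    z_gc: float
    n_perm: int


@dataclass(frozen=True)
class GenomeSummary:
    species_id: str
    window_index: int
    mean_z_dg: float
    se_z_dg: float
    n_genes: int
    n_excluded: int
    t_stat: float
    p_value: float
    mean_dg: float
    mean_z_gc: float


def enumerate_windows(seq_length: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """(start, end) 1-based inclusive for every window fitting the sequence."""
    if seq_length < spec.width:
        return []
    n_fit = (seq_length - spec.width) // spec.step + 1
    n = n_fit if spec.n_windows is None else min(spec.n_windows, n_fit)
    return [
        ((i - 1) * spec.step + 1, (i - 1) * spec.step + spec.width)
        for i in range(1, n + 1)
    ]


def zscore(wt_value: float, perm_values) -> float:
    """(wt - mean(perm)) / sample sd(perm); NaN when sd = 0.

    Positive values mean the wild type exceeds the null mean — for ΔG, a
    less negative (less stable) window.
    """
    perm = np.asarray(perm_values, dtype=float)
    if perm.size < 2:
        raise ValueError("need at least 2 permutation values")
    # identical null values, not a float-noise sd, define degeneracy
    if np.all(perm == perm[0]):
        return UNDEFINED
    return float((wt_value - perm.mean()) / perm.std(ddof=1))


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def scan_gene(
    gene: CodingSequence,
    spec: WindowSpec,
    shuffle_config: ShuffleConfig,
    backend,
    code: GeneticCode | None = None,
) -> list[WindowProfile]:
    """Window profiles for one gene: fold wild type and all permutations.

    The permutation set is generated once per gene and reused across windows;
    a fold cache shared across the gene avoids re-folding identical windows.
    """
    if code is None:
        code = standard_code()
    windows = enumerate_windows(len(gene.seq), spec)
    if not windows:
        return []
    perms = generate_null_set(gene, shuffle_config, code)
    n_perm = len(perms)

    cache: dict = {}
    wt_rna = to_rna(gene.seq)
    wt_windows = [wt_rna[s - 1 : e] for s, e in windows]
    wt_results = fold_batch(wt_windows, backend, cache)

    # perm_dg[w, k], perm_gc[w, k]
    perm_dg = np.empty((len(windows), n_perm))
    perm_gc = np.empty((len(windows), n_perm))
    for k, perm in enumerate(perms):
        rna = to_rna(perm.seq)
        seqs = [rna[s - 1 : e] for s, e in windows]
        results = fold_batch(seqs, backend, cache)
        for w in range(len(windows)):
            perm_dg[w, k] = results[w].delta_g
            perm_gc[w, k] = _gc_fraction(seqs[w])

    profiles = []
    for w, (start, end) in enumerate(windows):
        dg_wt = wt_results[w].delta_g
        gc_wt = _gc_fraction(wt_windows[w])
        dg_mean = float(perm_dg[w].mean())
        gc_mean = float(perm_gc[w].mean())
        dg_degenerate = n_perm < 2 or bool(np.all(perm_dg[w] == perm_dg[w, 0]))
        gc_degenerate = n_perm < 2 or bool(np.all(perm_gc[w] == perm_gc[w, 0]))
        dg_sd = 0.0 if dg_degenerate else float(perm_dg[w].std(ddof=1))
        gc_sd = 0.0 if gc_degenerate else float(perm_gc[w].std(ddof=1))
        z_dg = UNDEFINED if dg_degenerate else (dg_wt - dg_mean) / dg_sd
        z_gc = UNDEFINED if gc_degenerate else (gc_wt - gc_mean) / gc_sd
        profiles.append(
            WindowProfile(
                gene_id=gene.gene_id,
                window_index=w + 1,
                start=start,
                end=end,
                dg_wt=dg_wt,
                dg_perm_mean=dg_mean,
                dg_perm_sd=dg_sd,
                z_dg=z_dg,
                gc_wt=gc_wt,
                gc_perm_mean=gc_mean,
                gc_perm_sd=gc_sd,
                z_gc=z_gc,
                n_perm=n_perm,
            )
        )
    return profiles


def scan_genes(
    genes,
    spec: WindowSpec,
    shuffle_config: ShuffleConfig,
    backend,
    code: GeneticCode | None = None,
) -> list[WindowProfile]:
    """Scan a gene collection; backend failure skips the gene, never aborts."""
    profiles: list[WindowProfile] = []
    for gene in genes:
        try:
            profiles.extend(scan_gene(gene, spec, shuffle_config, backend, code))
        except ValueError:
            continue
    return profiles


def summarize_genome(
    profiles: list[WindowProfile], species_id: str
) -> list[GenomeSummary]:
    """Per-window genome means of Z_dG with SE and one-sample t-test vs 0."""
    by_window: dict[int, list[WindowProfile]] = {}
    for p in profiles:
        by_window.setdefault(p.window_index, []).append(p)
    out = []
    for w in sorted(by_window):
        rows = by_window[w]
        z = np.array([p.z_dg for p in rows])
        ok = np.isfinite(z)
        z_ok = z[ok]
        n = int(ok.sum())
        n_excl = len(rows) - n
        mean_dg = float(np.mean([p.dg_wt for p in rows]))
        z_gc = np.array([p.z_gc for p in rows])
        mean_z_gc = float(np.nanmean(z_gc)) if np.isfinite(z_gc).any() else UNDEFINED
        if n < 2:
            out.append(
                GenomeSummary(species_id, w, float(z_ok.mean()) if n else UNDEFINED,
                              UNDEFINED, n, n_excl, UNDEFINED, UNDEFINED,
                              mean_dg, mean_z_gc)
            )
            continue
        mean = float(z_ok.mean())
        sd = float(z_ok.std(ddof=1))
        se = sd / math.sqrt(n)
        if sd == 0.0:
            t_stat, p_value = UNDEFINED, UNDEFINED
        else:
            t_stat, p_value = stats.ttest_1samp(z_ok, 0.0)
            t_stat, p_value = float(t_stat), float(p_value)
        out.append(
            GenomeSummary(species_id, w, mean, se, n, n_excl, t_stat, p_value,
                          mean_dg, mean_z_gc)
        )
    return out


def profiles_to_frame(profiles: list[WindowProfile]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in profiles])


def summaries_to_frame(summaries: list[GenomeSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])
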