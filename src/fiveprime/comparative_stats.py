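"""Determinants of 5' folding-energy Z-scores, across and within genomes.

Cross-species: Spearman correlations of the genome-mean window-1 Z_dG with
genomic GC content (optionally excluding taxa whose isochore structure breaks
the genome-level signal: plants, birds, mammals), a per-window correlation
profile, prokaryote growth-temperature correlations, and raw-ΔG analogues.

Within-genome: effective number of codons (ENC, Wright's statistic) as the
codon-bias measure; stratified top/bottom 5% comparisons of window-1 Z_dG by
GC, ENC and expression; and a principal-component regression apportioning the
explained variance of Z5 among the three (standardized) predictors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import (
    PROKARYOTE_GROUPS,
    CodingSequence,
    SpeciesMetadata,
)
from .shuffling import GeneticCode, standard_code
from .zscore_scan import UNDEFINED, GenomeSummary, WindowProfile

DEFAULT_TAXON_EXCLUSIONS = frozenset({"plants", "birds", "mammals"})


# ---------------------------------------------------------------------------
# effective number of codons (Wright)
# ---------------------------------------------------------------------------

def _degeneracy_classes(code: GeneticCode) -> dict[int, list[str]]:
    """Amino acids grouped by family size; the classic treatment keeps the
    6-fold amino acids (Leu, Ser, Arg) as single 6-fold families."""
    classes: dict[int, list[str]] = {}
    for aa, codons in code.families.items():
        classes.setdefault(len(codons), []).append(aa)
    return classes


# number of amino acids per degeneracy class in the standard code;
# ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6
_CLASS_WEIGHTS = {2: 9, 3: 1, 4: 5, 6: 3}


def enc(
    gene: CodingSequence,
    code: GeneticCode | None = None,
    missing_class: str = "interpolate",
) -> float:
    """Wright's effective number of codons, in [20, 61].

    F for one amino acid with n observed codons and usage fractions p_i is
    (n*sum(p_i^2) - 1)/(n - 1); the class mean F̄_k averages over amino acids
    of degeneracy k observed with n >= 2.  ENC = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 +
    3/F̄6, capped into [20, 61].  Stop codons are excluded.

    A degeneracy class with no usable amino acid leaves its F̄ undefined;
    ``missing_class='interpolate'`` estimates it from the neighboring classes
    (F̄3 ≈ (F̄2+F̄4)/2, in general the mean of nearest available classes),
    ``'drop'`` removes the class's term and rescales the remaining
    super-singleton contribution to the full 59-codon weight.
    """
    if code is None:
        code = standard_code()
    if missing_class not in ("interpolate", "drop"):
        raise ValueError("missing_class must be 'interpolate' or 'drop'")
    counts: dict[str, dict[str, int]] = {}
    for codon in gene.codons():
        aa = code.codon_to_aa[codon]
        if aa == "*":
            continue
        counts.setdefault(aa, {})
        counts[aa][codon] = counts[aa].get(codon, 0) + 1

    class_f: dict[int, float] = {}
    for k, aas in _degeneracy_classes(code).items():
        if k == 1:
            continue
        fs = []
        for aa in aas:
            usage = counts.get(aa)
            if not usage:
                continue
            n = sum(usage.values())
            if n < 2:
                continue
            p2 = sum((c / n) ** 2 for c in usage.values())
            fs.append((n * p2 - 1) / (n - 1))
        if fs:
            fbar = float(np.mean(fs))
            if fbar > 0:
                class_f[k] = fbar
    if not class_f:
        return UNDEFINED

    weights = dict(_CLASS_WEIGHTS)
    if missing_class == "interpolate":
        for k in list(weights):
            if k not in class_f:
                neighbors = sorted(class_f, key=lambda m: abs(m - k))[:2]
                class_f[k] = float(np.mean([class_f[m] for m in neighbors]))
        total = 2 + sum(weights[k] / class_f[k] for k in weights)
    else:
        avail = {k: w for k, w in weights.items() if k in class_f}
        scale = sum(weights.values()) / sum(avail.values())
        total = 2 + scale * sum(w / class_f[k] for k, w in avail.items())
    return float(min(61.0, max(20.0, total)))


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), two-sided p.

    Pairs with a missing value in either variable are dropped; fewer than 3
    complete pairs -> (NaN, NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return UNDEFINED, UNDEFINED
    rho, p = stats.spearmanr(x[ok], y[ok])
    return float(rho), float(p)


@dataclass(frozen=True)
class SpeciesPoint:
    """One species' inputs to the cross-species correlations."""

    species_id: str
    taxon_group: str
    genomic_gc: float
    z5: float  # genome-mean window-1 Z_dG
    dg1: float  # genome-mean window-1 raw ΔG
    dg10: float | None = None
    temperature: float | None = None
    per_window_z: Mapping[int, float] | None = None


def species_points(
    summaries: Mapping[str, list[GenomeSummary]],
    metadata: Iterable[SpeciesMetadata],
) -> list[SpeciesPoint]:
    """Join per-species window summaries with metadata into analysis points."""
    meta = {m.species_id: m for m in metadata}
    points = []
    for sp, rows in summaries.items():
        m = meta.get(sp)
        if m is None or m.genomic_gc is None:
            continue
        by_w = {r.window_index: r for r in rows}
        if 1 not in by_w:
            continue
        points.append(
            SpeciesPoint(
                species_id=sp,
                taxon_group=m.taxon_group,
                genomic_gc=m.genomic_gc,
                z5=by_w[1].mean_z_dg,
                dg1=by_w[1].mean_dg,
                dg10=by_w[10].mean_dg if 10 in by_w else None,
                temperature=m.optimal_growth_temperature,
                per_window_z={w: r.mean_z_dg for w, r in by_w.items()},
            )
        )
    return points


def cross_species_analysis(
    points: Sequence[SpeciesPoint],
    exclude_taxa: Iterable[str] = DEFAULT_TAXON_EXCLUSIONS,
) -> pd.DataFrame:
    """Cross-species Spearman correlation table.

    Rows: ``gc_vs_z5`` (taxa in ``exclude_taxa`` removed), per-window
    ``gc_vs_z_w<i>`` profile, prokaryote ``temperature_vs_z5`` and
    ``temperature_vs_gc``, and raw-energy analogues ``gc_vs_dg1`` and
    ``gc_vs_dg1_minus_dg10``.  Insufficient species leave NaN rows.
    """
    exclude = set(exclude_taxa)
    rows = []

    kept = [p for p in points if p.taxon_group not in exclude]
    rho, p = spearman([q.genomic_gc for q in kept], [q.z5 for q in kept])
    rows.append(("gc_vs_z5", rho, p, len(kept)))

    all_windows = sorted({w for q in kept if q.per_window_z for w in q.per_window_z})
    for w in all_windows:
        xs = [q.genomic_gc for q in kept if q.per_window_z and w in q.per_window_z]
        ys = [q.per_window_z[w] for q in kept if q.per_window_z and w in q.per_window_z]
        rho, p = spearman(xs, ys)
        rows.append((f"gc_vs_z_w{w}", rho, p, len(xs)))

    prok = [
        q for q in points
        if q.taxon_group in PROKARYOTE_GROUPS and q.temperature is not None
    ]
    rho, p = spearman([q.temperature for q in prok], [q.z5 for q in prok])
    rows.append(("temperature_vs_z5", rho, p, len(prok)))
    rho, p = spearman([q.temperature for q in prok], [q.genomic_gc for q in prok])
    rows.append(("temperature_vs_gc", rho, p, len(prok)))

    rho, p = spearman([q.genomic_gc for q in kept], [q.dg1 for q in kept])
    rows.append(("gc_vs_dg1", rho, p, len(kept)))
    diff_pts = [q for q in kept if q.dg10 is not None]
    rho, p = spearman(
        [q.genomic_gc for q in diff_pts],
        [q.dg1 - q.dg10 for q in diff_pts],
    )
    rows.append(("gc_vs_dg1_minus_dg10", rho, p, len(diff_pts)))

    return pd.DataFrame(rows, columns=["analysis", "rho", "p", "n"])


# ---------------------------------------------------------------------------
# within-genome stratification and PC regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotations:
    gene_id: str
    gc: float
    enc: float
    z5: float
    expression: float | None = None


def annotate_genes(
    genes: Iterable[CodingSequence],
    profiles: Iterable[WindowProfile],
    code: GeneticCode | None = None,
    expression: Mapping[str, float] | None = None,
) -> list[GeneAnnotations]:
    """Per-gene GC, ENC, window-1 Z_dG, and optional expression."""
    if code is None:
        code = standard_code()
    z5 = {p.gene_id: p.z_dg for p in profiles if p.window_index == 1}
    out = []
    for g in genes:
        if g.gene_id not in z5:
            continue
        expr = expression.get(g.gene_id) if expression else None
        out.append(
            GeneAnnotations(
                gene_id=g.gene_id,
                gc=g.gc,
                enc=enc(g, code),
                z5=z5[g.gene_id],
                expression=expr,
            )
        )
    return out


@dataclass(frozen=True)
class StratifiedComparison:
    criterion: str
    top_mean_z5: float
    bottom_mean_z5: float
    n_per_group: int
    difference: float
    test_p: float


def stratify(
    genes: Sequence[GeneAnnotations],
    criterion: str,
    fraction: float = 0.05,
) -> StratifiedComparison:
    """Compare mean Z5 between the top and bottom ``fraction`` of genes.

    ``criterion`` is one of gc / enc / expression.  The "top" group is the
    one expected to show elevated Z5: highest GC, *lowest* ENC (strongest
    codon bias), or highest expression.  Ties at the cut are resolved by
    stable gene_id order; the comparison is a two-sided Welch t-test.
    """
    if criterion not in ("gc", "enc", "expression"):
        raise ValueError(f"unknown criterion {criterion!r}")

    def value(g: GeneAnnotations) -> float | None:
        v = getattr(g, criterion)
        if v is None or not math.isfinite(v):
            return None
        return v

    usable = [
        g for g in sorted(genes, key=lambda g: g.gene_id)
        if value(g) is not None and math.isfinite(g.z5)
    ]
    if len(usable) < 40:
        raise ValueError("too few genes for 5% stratification")
    k = max(1, int(len(usable) * fraction))
    # ascending sort, stable in gene_id
    ranked = sorted(usable, key=value)
    low, high = ranked[:k], ranked[-k:]
    # for ENC, strongest bias (lowest ENC) is the "top" group
    top, bottom = (low, high) if criterion == "enc" else (high, low)
    top_z = np.array([g.z5 for g in top])
    bot_z = np.array([g.z5 for g in bottom])
    if k >= 2 and (top_z.std() > 0 or bot_z.std() > 0):
        _, p = stats.ttest_ind(top_z, bot_z, equal_var=False)
        p = float(p)
    else:
        p = UNDEFINED
    return StratifiedComparison(
        criterion=criterion,
        top_mean_z5=float(top_z.mean()),
        bottom_mean_z5=float(bot_z.mean()),
        n_per_group=k,
        difference=float(top_z.mean() - bot_z.mean()),
        test_p=p,
    )


def pc_regression(genes: Sequence[GeneAnnotations]) -> pd.DataFrame:
    """Principal-component regression of Z5 on GC, ENC and log expression.

    Predictors are standardized (expression is log-transformed after adding
    the smallest positive observed value as pseudo-count).  Z5 is regressed
    on all principal components of the predictor matrix; the fitted PC
    coefficients are mapped back to the original predictors and each
    predictor's contribution is its coefficient times its covariance with Z5
    (so contributions sum exactly to the regression R²; for uncorrelated
    predictors each equals that predictor's squared correlation with Z5).
    This is one defensible allocation convention among several; under strong
    predictor collinearity individual contributions can be negative.
    """
    rows = [
        g for g in genes
        if g.expression is not None
        and all(math.isfinite(v) for v in (g.gc, g.enc, g.z5))
        and math.isfinite(g.expression)
    ]
    if len(rows) < 50:
        raise ValueError("need at least 50 genes with all three predictors")
    expr = np.array([g.expression for g in rows])
    positive = expr[expr > 0]
    if positive.size == 0:
        raise ValueError("all expression values are zero")
    log_expr = np.log(expr + positive.min())
    raw = {
        "gc": np.array([g.gc for g in rows]),
        "enc": np.array([g.enc for g in rows]),
        "expression": log_expr,
    }
    names, cols = [], []
    for name, col in raw.items():
        if col.std(ddof=0) == 0:
            warnings.warn(f"constant predictor {name!r} dropped")
            continue
        names.append(name)
        cols.append((col - col.mean()) / col.std(ddof=0))
    X = np.column_stack(cols)
    y = np.array([g.z5 for g in rows])
    y_c = y - y.mean()

    # PCA of the standardized predictor matrix via SVD
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    scores = u * s  # n x m, orthogonal columns
    loadings = vt.T  # m x m, orthonormal columns

    total_ss = float(y_c @ y_c)
    beta_pc = np.zeros(len(names))
    for kk in range(len(names)):
        t = scores[:, kk]
        denom = float(t @ t)
        if denom > 0:
            beta_pc[kk] = float(y_c @ t) / denom
    # back-transform to the original (standardized) predictors
    b = loadings @ beta_pc
    contrib = b * (X.T @ y_c) / total_ss if total_ss > 0 else np.zeros(len(names))
    total_r2 = float(contrib.sum())

    return pd.DataFrame(
        {
            "predictor": names,
            "contribution_r2": contrib,
            "share_of_explained": contrib / total_r2 if total_r2 > 0 else np.nan,
        }
    )
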