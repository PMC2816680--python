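"""ENC, Spearman wrappers, cross-species correlations, stratification and
principal-component regression."""

import math

import numpy as np
import pytest

from fiveprime.comparative_stats import (
    GeneAnnotations,
    SpeciesPoint,
    cross_species_analysis,
    enc,
    pc_regression,
    spearman,
    stratify,
)
from fiveprime.genome_io import CodingSequence
from fiveprime.shuffling import ShuffleConfig, generate_null_set, standard_code

CODE = standard_code()


# ---------------------------------------------------------------------------
# ENC
# ---------------------------------------------------------------------------

def test_enc_extreme_bias_is_20():
    """One codon per amino acid in every degeneracy class forces ENC = 20."""
    picks = {}
    for aa, codons in CODE.families.items():
        picks[aa] = codons[0]
    body = "".join(picks[aa] * 10 for aa in sorted(picks))
    gene = CodingSequence("g", "s", "ATG" + body + "TAA")
    assert enc(gene) == pytest.approx(20.0)


def test_enc_uniform_usage_approaches_61():
    """Uniform synonymous usage within every family gives F = 1/k, ENC = 61."""
    body = "".join(
        "".join(codons) * 6 for codons in CODE.families.values()
    )  # every codon equally often
    gene = CodingSequence("g", "s", "ATG" + body + "TAA")
    assert enc(gene) == pytest.approx(61.0)


def _wright_oracle(gene):
    """Independent straight-line Wright formula (standard code, 6-fold kept
    whole), written without reference to the implementation."""
    aa_of = CODE.codon_to_aa
    fam_size = {aa: len(c) for aa, c in CODE.families.items()}
    counts = {}
    for i in range(0, len(gene.seq), 3):
        codon = gene.seq[i : i + 3]
        aa = aa_of[codon]
        if aa == "*":
            continue
        counts.setdefault(aa, {}).setdefault(codon, 0)
        counts[aa][codon] += 1
    f_by_class = {}
    for aa, usage in counts.items():
        n = sum(usage.values())
        if n < 2:
            continue
        f = (n * sum((c / n) ** 2 for c in usage.values()) - 1) / (n - 1)
        f_by_class.setdefault(fam_size[aa], []).append(f)
    fbar = {k: sum(v) / len(v) for k, v in f_by_class.items()}
    total = 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6]
    return min(61.0, max(20.0, total))


def test_enc_matches_independent_wright_formula(rng):
    sense = sorted(set(CODE.codon_to_aa) - {"TAA", "TAG", "TGA"})
    for _ in range(5):
        body = "".join(rng.choice(sense, 300))
        gene = CodingSequence("g", "s", "ATG" + body + "TAA")
        assert enc(gene) == pytest.approx(_wright_oracle(gene), abs=1e-12)


def test_enc_invariant_under_synonymous_shuffle(rng):
    sense = sorted(set(CODE.codon_to_aa) - {"TAA", "TAG", "TGA"})
    gene = CodingSequence("g", "s", "ATG" + "".join(rng.choice(sense, 200)) + "TAA")
    base = enc(gene)
    for p in generate_null_set(gene, ShuffleConfig(n_permutations=10, seed=8)):
        assert enc(p) == pytest.approx(base, abs=1e-12)


def test_enc_too_short_is_undefined():
    assert math.isnan(enc(CodingSequence("g", "s", "ATGTGG")))


def test_enc_missing_class_interpolation():
    """A gene with no 3-fold (Ile) amino acid still gets a finite ENC."""
    body = ("AAA" + "AAG") * 20 + ("GGT" + "GGC") * 20 \
        + ("CTT" + "CTG" + "CTA") * 10  # Lys (2f), Gly (4f), Leu (6f)
    gene = CodingSequence("g", "s", "ATG" + body + "TAA")
    val = enc(gene, missing_class="interpolate")
    assert 20.0 <= val <= 61.0 and math.isfinite(val)
    val_drop = enc(gene, missing_class="drop")
    assert 20.0 <= val_drop <= 61.0


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def test_spearman_monotone_extremes():
    x = [1.0, 2, 3, 4, 5]
    assert spearman(x, [2.0, 4, 6, 8, 10])[0] == pytest.approx(1.0)
    assert spearman(x, [-v for v in x])[0] == pytest.approx(-1.0)


def test_spearman_ties_match_manual_ranks():
    x = [1, 2, 2, 3, 4, 5, 5, 5, 6, 7]
    y = [3, 1, 4, 4, 5, 8, 7, 7, 9, 10]
    # manual average-rank computation, then Pearson on ranks
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = np.array(ranks(x)), np.array(ranks(y))
    oracle = float(
        ((rx - rx.mean()) @ (ry - ry.mean()))
        / np.sqrt(((rx - rx.mean()) ** 2).sum() * ((ry - ry.mean()) ** 2).sum())
    )
    assert spearman(x, y)[0] == pytest.approx(oracle, abs=1e-12)


def test_spearman_invariance_and_incomplete_pairs(rng):
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    rho, _ = spearman(x, y)
    assert spearman(np.exp(x), y)[0] == pytest.approx(rho)  # monotone transform
    assert math.isnan(spearman([1, 2], [3, 4])[0])
    x2 = x.copy()
    x2[:28] = np.nan  # only 2 complete pairs
    assert math.isnan(spearman(x2, y)[0])


# ---------------------------------------------------------------------------
# cross-species table
# ---------------------------------------------------------------------------

def _point(i, gc, z5, group="bacteria", temp=None, dg1=-5.0, dg10=-7.0):
    return SpeciesPoint(f"sp{i}", group, gc, z5, dg1, dg10, temp,
                        per_window_z={1: z5, 10: z5 - 1})


def test_cross_species_monotone_relation_gives_rho_one():
    points = [_point(i, 0.3 + 0.1 * i, 0.1 * i) for i in range(5)]
    df = cross_species_analysis(points).set_index("analysis")
    assert df.loc["gc_vs_z5", "rho"] == pytest.approx(1.0)
    assert df.loc["gc_vs_z5", "n"] == 5


def test_cross_species_taxon_exclusion_and_missing_temperature():
    points = [_point(i, 0.3 + 0.05 * i, 0.1 * i) for i in range(5)]
    points += [_point(9, 0.9, -5.0, group="mammals")]  # would break monotonicity
    df = cross_species_analysis(points).set_index("analysis")
    assert df.loc["gc_vs_z5", "n"] == 5  # mammal excluded by default
    assert df.loc["gc_vs_z5", "rho"] == pytest.approx(1.0)
    assert math.isnan(df.loc["temperature_vs_z5", "rho"])  # no temperatures


def test_cross_species_temperature_rows():
    points = [
        _point(i, 0.4, z5=1.0 - 0.1 * i, temp=20.0 + 5 * i) for i in range(6)
    ]
    df = cross_species_analysis(points).set_index("analysis")
    assert df.loc["temperature_vs_z5", "rho"] == pytest.approx(-1.0)


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def _annots(rng, n=100, couple=0.0):
    gcs = rng.uniform(0.3, 0.7, n)
    z5 = couple * (gcs - 0.5) + rng.normal(0, 0.3, n)
    return [
        GeneAnnotations(f"g{i:03d}", float(gcs[i]), 45.0, float(z5[i]), None)
        for i in range(n)
    ]


def test_stratify_group_size_and_reorder_invariance(rng):
    annots = _annots(rng)
    comp = stratify(annots, "gc")
    assert comp.n_per_group == 5  # floor(0.05 * 100)
    shuffled = list(annots)
    rng.shuffle(shuffled)
    comp2 = stratify(shuffled, "gc")
    assert comp2.top_mean_z5 == pytest.approx(comp.top_mean_z5)
    assert comp2.bottom_mean_z5 == pytest.approx(comp.bottom_mean_z5)


def test_stratify_null_within_3se(rng):
    annots = _annots(rng, n=400, couple=0.0)
    comp = stratify(annots, "gc")
    se = 0.3 * math.sqrt(2 / comp.n_per_group)
    assert abs(comp.difference) < 3 * se


def test_stratify_detects_coupling(rng):
    annots = _annots(rng, n=400, couple=3.0)
    comp = stratify(annots, "gc")
    assert comp.difference > 0 and comp.test_p < 0.05


def test_stratify_enc_direction(rng):
    # strong bias (low ENC) genes constructed with high z5
    annots = [
        GeneAnnotations(f"g{i:03d}", 0.5, 20.0 + 41.0 * i / 99, 1.0 - i / 99, None)
        for i in range(100)
    ]
    comp = stratify(annots, "enc")
    assert comp.top_mean_z5 > comp.bottom_mean_z5  # lowest ENC is the top group


def test_stratify_too_few_genes(rng):
    with pytest.raises(ValueError, match="too few"):
        stratify(_annots(rng, n=30), "gc")


# ---------------------------------------------------------------------------
# principal component regression
# ---------------------------------------------------------------------------

def _pcr_genes(rng, n, w_gc, w_enc, w_expr, noise):
    gc = rng.normal(0.5, 0.1, n)
    enc_v = rng.normal(45, 5, n)
    log_expr = rng.normal(3, 1, n)
    z_gc = (gc - gc.mean()) / gc.std()
    z_enc = (enc_v - enc_v.mean()) / enc_v.std()
    z_ex = (log_expr - log_expr.mean()) / log_expr.std()
    z5 = w_gc * z_gc + w_enc * z_enc + w_expr * z_ex + noise * rng.normal(size=n)
    return [
        GeneAnnotations(f"g{i:04d}", float(gc[i]), float(enc_v[i]),
                        float(z5[i]), float(np.exp(log_expr[i])))
        for i in range(n)
    ]


def test_pcr_pure_gc_signal(rng):
    genes = _pcr_genes(rng, 500, w_gc=1.0, w_enc=0.0, w_expr=0.0, noise=1e-6)
    df = pc_regression(genes).set_index("predictor")
    assert df.loc["gc", "share_of_explained"] > 0.95
    assert df["contribution_r2"].sum() == pytest.approx(1.0, abs=0.01)


def test_pcr_pure_noise(rng):
    genes = _pcr_genes(rng, 500, 0.0, 0.0, 0.0, noise=1.0)
    df = pc_regression(genes)
    assert df["contribution_r2"].sum() < 0.05


def test_pcr_equal_contributions(rng):
    """Equal independent effects of all three predictors split the explained
    variance roughly in thirds (mean over 20 replicates)."""
    shares = np.zeros(3)
    for _ in range(20):
        genes = _pcr_genes(rng, 300, 0.5, 0.5, 0.5, noise=0.5)
        df = pc_regression(genes).set_index("predictor")
        shares += df["share_of_explained"].to_numpy()
    shares /= 20
    assert np.all(np.abs(shares - 1 / 3) < 0.10)


def test_pcr_contributions_sum_to_r2(rng):
    genes = _pcr_genes(rng, 200, 0.8, 0.2, 0.1, noise=0.7)
    df = pc_regression(genes)
    # independent total-R2 oracle via ordinary least squares on the predictors
    expr = np.array([g.expression for g in genes])
    X = np.column_stack([
        [g.gc for g in genes], [g.enc for g in genes],
        np.log(expr + expr[expr > 0].min()),  # same pseudo-count convention
    ])
    X = (X - X.mean(0)) / X.std(0)
    y = np.array([g.z5 for g in genes])
    beta, *_ = np.linalg.lstsq(np.column_stack([np.ones(len(y)), X]), y, rcond=None)
    resid = y - np.column_stack([np.ones(len(y)), X]) @ beta
    r2 = 1 - resid.var() / y.var()
    assert df["contribution_r2"].sum() == pytest.approx(r2, abs=1e-6)


def test_pcr_too_few_genes(rng):
    with pytest.raises(ValueError):
        pc_regression(_pcr_genes(rng, 30, 1, 0, 0, 0.1))
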