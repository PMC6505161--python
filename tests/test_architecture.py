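"""Trait architectures: QTL selection, effect sampling, true genetic values."""

import itertools
import math

import numpy as np
import pytest

from bulkblup import architecture as qa
from bulkblup import founders as qf
from bulkblup import theory as qt

SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


def _map_n(n_loci, length=100.0, n_chrom=1):
    per = n_loci // n_chrom
    chrom = np.repeat(np.arange(1, n_chrom + 1), per)
    pos = np.tile(np.linspace(0.0, length, per), n_chrom)
    ids = np.array([f"M{i:03d}" for i in range(per * n_chrom)], dtype=object)
    return qf.GeneticMap(marker_id=ids, chromosome=chrom, position_cM=pos)


def _panel(geno, gmap, group="male"):
    geno = np.asarray(geno)
    lines = np.array([f"{group[0]}{i}" for i in range(geno.shape[0])], dtype=object)
    return qf.GenotypePanel(group=group, lines=lines, genotypes=geno, map=gmap)


def _panel_with_freqs(freqs, n_lines, gmap, group="male"):
    """Deterministic panel whose allele frequencies match ``freqs`` exactly."""
    geno = np.zeros((n_lines, len(freqs)), dtype=int)
    for v, p in enumerate(freqs):
        k = int(round(p * n_lines))
        geno[:k, v] = 2
    return _panel(geno, gmap, group)


# ---------------------------------------------------------------------------
# QTL selection
# ---------------------------------------------------------------------------


def _scenario_panels():
    # loci 0-39: identical frequencies (convergent-eligible)
    # loci 40-79: strongly diverged (divergent-eligible)
    # loci 80-99: fixed in the male group (always excluded by MAF)
    gmap = _map_n(100)
    freq_m = np.r_[np.full(40, 0.5), np.full(40, 0.9), np.full(20, 1.0)]
    freq_f = np.r_[np.full(40, 0.5), np.full(40, 0.1), np.full(20, 0.5)]
    pm = _panel_with_freqs(freq_m, 20, gmap, "male")
    pf = _panel_with_freqs(freq_f, 20, gmap, "female")
    return pm, pf


def test_qtl_selection_respects_scenario_constraints(rng):
    pm, pf = _scenario_panels()
    conv = qa.select_qtl(pm, pf, "convergent", n_qtl=30, rng=rng)
    assert np.all(conv < 40)
    div = qa.select_qtl(pm, pf, "divergent", n_qtl=30, rng=rng)
    assert np.all((div >= 40) & (div < 80))


def test_qtl_selection_excludes_low_maf_loci(rng):
    gmap = _map_n(10)
    pm = _panel_with_freqs(np.full(10, 1.0), 20, gmap, "male")  # fixed everywhere
    pf = _panel_with_freqs(np.full(10, 1.0), 20, gmap, "female")
    with pytest.raises(ValueError, match="satisfy"):
        qa.select_qtl(pm, pf, "convergent", n_qtl=2, rng=rng)


def test_qtl_selection_fails_loudly_when_infeasible(rng):
    pm, pf = _scenario_panels()
    with pytest.raises(ValueError, match="only .* loci satisfy"):
        qa.select_qtl(pm, pf, "divergent", n_qtl=60, rng=rng)
    with pytest.raises(ValueError, match="scenario"):
        qa.select_qtl(pm, pf, "intermediate", n_qtl=10, rng=rng)


# ---------------------------------------------------------------------------
# gene action assignment and effect sampling
# ---------------------------------------------------------------------------


def test_gene_action_proportions(rng):
    n = 100_000
    labels = qa.assign_gene_action(n, rng)
    counts = {lab: (labels == lab).mean() for lab in qa.GENE_ACTION_PROBS}
    for lab, p in qa.GENE_ACTION_PROBS.items():
        se = math.sqrt(p * (1 - p) / n)
        assert abs(counts[lab] - p) < 3 * se, lab


def test_gene_action_probabilities_must_sum_to_one(rng):
    with pytest.raises(ValueError, match="sum to 1"):
        qa.assign_gene_action(10, rng, probs={"additive": 0.5, "duplicate": 0.4})


def test_homozygous_effect_scale(rng):
    # sampler dispersion chosen so that E|a| = 0.25
    a = qa.sample_homozygous_effects(200_000, rng)
    se = np.abs(a).std() / math.sqrt(len(a))
    assert abs(np.abs(a).mean() - 0.25) < 3 * se
    assert abs(a.mean()) < 3 * a.std() / math.sqrt(len(a))


def test_dominance_effects_mostly_positive_with_unit_mean_degree(rng):
    a, d = qa.sample_dominance_effects(100_000, rng)
    share_pos = (d > 0).mean()
    se = math.sqrt(0.9 * 0.1 / len(d))
    assert abs(share_pos - 0.90) < 3 * se
    degree = d / np.abs(a)
    se_deg = degree.std() / math.sqrt(len(degree))
    assert abs(degree.mean() - 1.0) < 3 * se_deg


def test_epistatic_scale_magnitudes(rng):
    z_dup = qa.sample_epistatic_scales(200_000, rng, "duplicate")
    z_axa = qa.sample_epistatic_scales(200_000, rng, "additive_x_additive")
    assert abs(np.abs(z_dup).mean() - 1.0) < 0.01
    assert abs(np.abs(z_axa).mean() - 0.25) < 0.005
    with pytest.raises(ValueError, match="epistatic scale"):
        qa.sample_epistatic_scales(5, rng, "dominance")


def test_sampled_matrices_have_their_models_pattern_plus_noise(rng):
    for label in ("additive", "dominance", "additive_x_additive", "duplicate", "complementary"):
        U = qa.sample_effects(label, rng)
        assert U.model_label == label
        base = U.entries - U.noise_entries
        rebuilt = qt.make_gene_action_matrix(label, **U.params)
        np.testing.assert_allclose(base, rebuilt.entries, atol=1e-12)


def test_genetic_noise_scales_with_matrix_magnitude(rng):
    # per matrix, E|noise entry| = 0.1 x mean |pattern entry|
    ratios = []
    for _ in range(2000):
        U = qa.sample_effects("duplicate", rng)
        base = U.entries - U.noise_entries
        mean_abs = np.abs(base).mean()
        if mean_abs > 1e-6:
            ratios.append(np.abs(U.noise_entries).mean() / mean_abs)
    mean_ratio = float(np.mean(ratios))
    assert abs(mean_ratio - 0.10) < 0.002  # 2% of the target


def test_zero_noise_factor_gives_pure_patterns(rng):
    params = qa.EffectSamplerParams(noise_factor=0.0)
    U = qa.sample_effects("complementary", rng, params)
    np.testing.assert_array_equal(U.noise_entries, np.zeros((3, 3)))


# ---------------------------------------------------------------------------
# linkage
# ---------------------------------------------------------------------------


def test_haldane_recombination_fraction():
    gmap = _map_n(10, length=90.0)
    # adjacent loci are 10 cM apart
    assert qa.haldane_r(gmap, 0, 1) == pytest.approx((1 - math.exp(-0.2)) / 2)
    assert qa.haldane_r(gmap, 0, 9) == pytest.approx((1 - math.exp(-1.8)) / 2)
    assert qa.haldane_r(gmap, 3, 3) == 0.0
    gmap2 = _map_n(10, n_chrom=2)
    assert qa.haldane_r(gmap2, 0, 9) == 0.5  # different chromosomes


# ---------------------------------------------------------------------------
# architectures and true values
# ---------------------------------------------------------------------------


def _single_pair_arch(U, gmap, r=0.5, loci=(0, 1)):
    return qa.TraitArchitecture(
        scenario="convergent",
        qtl_loci=np.array(loci),
        pairs=np.array([loci]),
        matrices=[U],
        recomb_fractions=np.array([r]),
    )


def test_architecture_validates_pair_coverage():
    U = qt.make_gene_action_matrix("duplicate", z=1.0)
    with pytest.raises(ValueError, match="exactly one pair"):
        qa.TraitArchitecture(
            scenario="convergent",
            qtl_loci=np.array([0, 1]),
            pairs=np.array([[0, 0]]),
            matrices=[U],
            recomb_fractions=np.array([0.5]),
        )
    with pytest.raises(ValueError, match="cover"):
        qa.TraitArchitecture(
            scenario="convergent",
            qtl_loci=np.array([0, 1]),
            pairs=np.array([[0, 2]]),
            matrices=[U],
            recomb_fractions=np.array([0.5]),
        )


def test_build_architecture_pairs_all_qtl_once(rng):
    pm, pf = _scenario_panels()
    arch = qa.build_architecture(pm, pf, "convergent", rng, n_qtl=30)
    assert arch.n_pairs == 15
    assert sorted(arch.pairs.ravel().tolist()) == sorted(arch.qtl_loci.tolist())
    for (b, c), r in zip(arch.pairs, arch.recomb_fractions):
        assert r == pytest.approx(qa.haldane_r(pm.map, b, c))


def test_build_architecture_rejects_odd_qtl_counts(rng):
    pm, pf = _scenario_panels()
    with pytest.raises(ValueError, match="even"):
        qa.build_architecture(pm, pf, "convergent", rng, qtl_loci=np.arange(3))


def test_f1_value_from_reference_and_alternate_parents():
    gmap = _map_n(2)
    U = qt.make_gene_action_matrix("duplicate", z=1.0)
    arch = _single_pair_arch(U, gmap)
    ref = np.array([2, 2])  # homozygous reference = origin allele 1
    alt = np.array([0, 0])
    assert qa.f1_genetic_value(arch, ref, ref) == 1.0  # u11
    assert qa.f1_genetic_value(arch, alt, alt) == 0.0  # u33
    assert qa.f1_genetic_value(arch, ref, alt) == 1.0  # double het, u22


def test_f1_values_add_over_pairs(rng):
    gmap = _map_n(4)
    U1 = qa.sample_effects("dominance", rng)
    U2 = qa.sample_effects("complementary", rng)
    both = qa.TraitArchitecture(
        scenario="convergent",
        qtl_loci=np.arange(4),
        pairs=np.array([[0, 1], [2, 3]]),
        matrices=[U1, U2],
        recomb_fractions=np.array([0.5, 0.5]),
    )
    only1 = _single_pair_arch(U1, gmap, loci=(0, 1))
    only2 = _single_pair_arch(U2, gmap, loci=(2, 3))
    m = np.array([2, 0, 2, 0])
    f = np.array([0, 0, 2, 2])
    assert qa.f1_genetic_value(both, m, f) == pytest.approx(
        qa.f1_genetic_value(only1, m, f) + qa.f1_genetic_value(only2, m, f)
    )


def test_factorial_matches_single_hybrid_values(rng):
    gmap = _map_n(6)
    geno_m = 2 * rng.integers(0, 2, size=(5, 6))
    geno_f = 2 * rng.integers(0, 2, size=(4, 6))
    pm, pf = _panel(geno_m, gmap, "male"), _panel(geno_f, gmap, "female")
    arch = qa.build_architecture(
        pm, pf, "convergent", rng, qtl_loci=np.arange(6),
        gene_action_probs={"duplicate": 0.5, "dominance": 0.5},
    )
    F = qa.f1_factorial(arch, pm, pf)
    assert F.shape == (5, 4)
    for i, j in itertools.product(range(5), range(4)):
        assert F[i, j] == pytest.approx(
            qa.f1_genetic_value(arch, geno_m[i], geno_f[j])
        )


def test_heterozygous_parents_rejected(rng):
    gmap = _map_n(2)
    arch = _single_pair_arch(qt.make_gene_action_matrix("duplicate", z=1.0), gmap)
    with pytest.raises(ValueError, match="heterozygous"):
        qa.f1_genetic_value(arch, np.array([1, 2]), np.array([0, 0]))


# ---------------------------------------------------------------------------
# F1:2 bulk values
# ---------------------------------------------------------------------------


def test_exact_bulk_matches_two_locus_theory_for_all_classes(rng):
    gmap = _map_n(2, length=25.0)
    U = qa.sample_effects("dominance", rng)
    r = qa.haldane_r(gmap, 0, 1)
    arch = _single_pair_arch(U, gmap, r=r)
    code = {1: 2, 2: 0}  # origin allele -> genotype code
    for i, j, k, l in itertools.product((1, 2), repeat=4):
        pm = _panel(np.array([[code[i], code[k]]]), gmap, "male")
        pf = _panel(np.array([[code[j], code[l]]]), gmap, "female")
        got = qa.f12_bulk_genetic_value(arch, pm, pf, 0, 0, mode="exact")
        assert got == pytest.approx(qt.f12_bulk_value(U, i, j, k, l, r=r))


def test_unlinked_duplicate_double_het_bulk_is_15_16():
    gmap = _map_n(2, n_chrom=2)  # loci on different chromosomes
    U = qt.make_gene_action_matrix("duplicate", z=1.0)
    arch = _single_pair_arch(U, gmap, r=0.5)
    pm = _panel(np.array([[2, 2]]), gmap, "male")
    pf = _panel(np.array([[0, 0]]), gmap, "female")
    assert qa.f12_bulk_genetic_value(arch, pm, pf, 0, 0, mode="exact") == pytest.approx(
        15.0 / 16.0
    )


def test_additive_x_additive_bulks_equal_f1_values(rng):
    # additive-by-additive gene action survives selfing unchanged
    gmap = _map_n(2)
    U = qt.make_gene_action_matrix("additive_x_additive", z=0.7)
    arch = _single_pair_arch(U, gmap, r=qa.haldane_r(gmap, 0, 1))
    geno = 2 * rng.integers(0, 2, size=(8, 2))
    pm, pf = _panel(geno, gmap, "male"), _panel(geno, gmap, "female")
    idx = np.arange(8)
    f1 = np.array([qa.f1_genetic_value(arch, geno[i], geno[i]) for i in idx])
    bulk = qa.f12_bulk_values(arch, pm, pf, idx, idx, mode="exact")
    np.testing.assert_allclose(bulk, f1, atol=1e-12)


def _simulation_se(arch, pm, pf, mi, fi, n_f2):
    """Exact per-F2 value standard deviation for independent pairs."""
    var = 0.0
    for p, U in enumerate(arch.matrices):
        i = int(2 - pm.genotypes[mi, arch.pairs[p, 0]] // 2)
        k = int(2 - pm.genotypes[mi, arch.pairs[p, 1]] // 2)
        j = int(2 - pf.genotypes[fi, arch.pairs[p, 0]] // 2)
        l = int(2 - pf.genotypes[fi, arch.pairs[p, 1]] // 2)
        r = arch.recomb_fractions[p]
        gam = ((i, k, (1 - r) / 2), (j, l, (1 - r) / 2), (i, l, r / 2), (j, k, r / 2))
        m1 = m2 = 0.0
        for b1, c1, p1 in gam:
            for b2, c2, p2 in gam:
                v = U.entries[b1 + b2 - 2, c1 + c2 - 2]
                m1 += p1 * p2 * v
                m2 += p1 * p2 * v * v
        var += m2 - m1 * m1
    return math.sqrt(var / n_f2)


def test_simulated_bulks_converge_to_exact_expectation(rng):
    # three linked pairs, each on its own chromosome (independent segregation)
    gmap = _map_n(6, length=40.0, n_chrom=3)
    matrices = [
        qa.sample_effects("duplicate", rng),
        qa.sample_effects("dominance", rng),
        qa.sample_effects("complementary", rng),
    ]
    pairs = np.array([[0, 1], [2, 3], [4, 5]])
    rfrac = np.array([qa.haldane_r(gmap, b, c) for b, c in pairs])
    arch = qa.TraitArchitecture(
        scenario="convergent", qtl_loci=np.arange(6), pairs=pairs,
        matrices=matrices, recomb_fractions=rfrac,
    )
    geno_m = np.array([[2, 2, 2, 0, 2, 2]])
    geno_f = np.array([[0, 0, 2, 2, 0, 2]])
    pm, pf = _panel(geno_m, gmap, "male"), _panel(geno_f, gmap, "female")
    exact = qa.f12_bulk_genetic_value(arch, pm, pf, 0, 0, mode="exact")
    n_f2 = 100_000
    sim = qa.f12_bulk_genetic_value(
        arch, pm, pf, 0, 0, mode="simulate", n_f2=n_f2, rng=rng
    )
    se = _simulation_se(arch, pm, pf, 0, 0, n_f2)
    assert abs(sim - exact) < 3 * se


def test_simulate_mode_requires_rng(rng):
    gmap = _map_n(2)
    arch = _single_pair_arch(qt.make_gene_action_matrix("duplicate", z=1.0), gmap)
    pm = _panel(np.array([[2, 2]]), gmap, "male")
    pf = _panel(np.array([[0, 0]]), gmap, "female")
    with pytest.raises(ValueError, match="rng"):
        qa.f12_bulk_genetic_value(arch, pm, pf, 0, 0, mode="simulate")
    with pytest.raises(ValueError, match="mode"):
        qa.f12_bulk_genetic_value(arch, pm, pf, 0, 0, mode="enumerate")


def test_duplicate_epistasis_releases_bulk_variance_at_extreme_divergence(rng):
    # nearly fixed, strongly diverged groups: F1s are almost uniformly double
    # heterozygotes (constant value), while selfing segregates the masked
    # allele, so the bulks vary more than the F1s.
    gmap = _map_n(2, n_chrom=2)
    U = qt.make_gene_action_matrix("duplicate", z=1.0)
    arch = _single_pair_arch(U, gmap, r=0.5)
    n = 400
    geno_m = 2 * (rng.random((n, 2)) < 0.97).astype(int)
    geno_f = 2 * (rng.random((n, 2)) < 0.03).astype(int)
    pm, pf = _panel(geno_m, gmap, "male"), _panel(geno_f, gmap, "female")
    F = qa.f1_factorial(arch, pm, pf)
    mi = np.repeat(np.arange(n), n)
    fi = np.tile(np.arange(n), n)
    bulks = qa.f12_bulk_values(arch, pm, pf, mi, fi, mode="exact")
    assert np.var(F) < np.var(bulks)


# ---------------------------------------------------------------------------
# truth tables
# ---------------------------------------------------------------------------


def test_truth_decomposition_is_exact(rng):
    gmap = _map_n(10)
    geno_m = 2 * rng.integers(0, 2, size=(15, 10))
    geno_f = 2 * rng.integers(0, 2, size=(12, 10))
    pm, pf = _panel(geno_m, gmap, "male"), _panel(geno_f, gmap, "female")
    arch = qa.build_architecture(pm, pf, "convergent", rng, qtl_loci=np.arange(10))
    truth = qa.build_truth(arch, pm, pf)
    assert truth.gca_male.sum() == pytest.approx(0.0, abs=1e-9)
    assert truth.gca_female.sum() == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(truth.sca.sum(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(truth.sca.sum(axis=1), 0.0, atol=1e-9)
    rebuilt = (
        truth.grand_mean
        + truth.gca_male[:, None]
        + truth.gca_female[None, :]
        + truth.sca
    )
    np.testing.assert_allclose(rebuilt, truth.f1_values, atol=1e-9)
    total = np.var(truth.f1_values)
    parts = (
        np.var(truth.gca_male) + np.var(truth.gca_female) + np.var(truth.sca)
    )
    assert parts == pytest.approx(total, rel=1e-9)


def test_purely_additive_truth_has_no_sca(rng):
    gmap = _map_n(10)
    geno_m = 2 * rng.integers(0, 2, size=(15, 10))
    geno_f = 2 * rng.integers(0, 2, size=(12, 10))
    pm, pf = _panel(geno_m, gmap, "male"), _panel(geno_f, gmap, "female")
    arch = qa.build_architecture(
        pm, pf, "convergent", rng, qtl_loci=np.arange(10),
        gene_action_probs={"additive": 1.0},
        params=qa.EffectSamplerParams(noise_factor=0.0),
    )
    truth = qa.build_truth(arch, pm, pf)
    np.testing.assert_allclose(truth.sca, 0.0, atol=1e-9)


def test_architecture_serialization_roundtrip(tmp_path, rng):
    pm, pf = _scenario_panels()
    arch = qa.build_architecture(pm, pf, "divergent", rng, n_qtl=20)
    path = tmp_path / "arch.json"
    arch.to_file(path)
    back = qa.TraitArchitecture.from_file(path)
    np.testing.assert_array_equal(back.qtl_loci, arch.qtl_loci)
    np.testing.assert_array_equal(back.pairs, arch.pairs)
    np.testing.assert_allclose(back.recomb_fractions, arch.recomb_fractions)
    for a, b in zip(back.matrices, arch.matrices):
        assert a.model_label == b.model_label
        np.testing.assert_allclose(a.entries, b.entries)
        np.testing.assert_allclose(a.noise_entries, b.noise_entries)
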