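"""Trait architecture: QTL selection, gene-action assignment, true values.

A complex trait is controlled by 200 QTL arranged in 100 two-locus
pairs, each pair carrying one of the classical gene-action models
(additive, additive-by-additive, dominance, duplicate-factor or
complementary epistasis) plus a small amount of "genetic noise" so
that no pair follows its model exactly.  QTL are selected from the
marker panel under one of two population-structure scenarios:

* convergent — QTL allele frequencies nearly equal in the two heterotic
  groups (|p_m - p_f| < 0.05), as in a newly formed hybrid program;
* divergent — strongly differentiated frequencies (|p_m - p_f| > 0.60),
  as after many cycles of reciprocal recurrent selection.

True genetic values of F1 hybrids are sums of the pair matrices' entries
over all 100 pairs; F1:2 bulk values are the expectation (or a finite-F2
simulation) of the same sum over Mendelian segregation, with linkage
between the pair's loci respected through the Haldane recombination
fraction.  The full male x female factorial of F1 values defines true
GCA (centred row/column means) and SCA (double-centred residuals).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .founders import GeneticMap, GenotypePanel
from .meiosis import recombine_gametes
from .theory import GeneActionMatrix, make_gene_action_matrix

__all__ = [
    "EffectSamplerParams",
    "TraitArchitecture",
    "TruthTable",
    "GENE_ACTION_PROBS",
    "select_qtl",
    "assign_gene_action",
    "sample_homozygous_effects",
    "sample_dominance_effects",
    "sample_epistatic_scales",
    "sample_effects",
    "build_architecture",
    "haldane_r",
    "f1_genetic_value",
    "f1_factorial",
    "f12_bulk_genetic_value",
    "f12_bulk_values",
    "build_truth",
]

# Root-mean-square-to-mean-absolute conversion for a zero-mean Normal:
# E|N(0, s)| = s * sqrt(2/pi), so s = target_mean_abs * sqrt(pi/2).
_SQRT_HALF_PI = math.sqrt(math.pi / 2.0)

#: Per-pair gene-action assignment probabilities.
GENE_ACTION_PROBS = {
    "additive": 0.05,
    "additive_x_additive": 0.05,
    "dominance": 0.10,
    "duplicate": 0.40,
    "complementary": 0.40,
}


@dataclass(frozen=True)
class EffectSamplerParams:
    """Dispersion settings of the QTL effect sampler.

    ``sd_a`` makes E|a| = 0.25 for homozygous effects;
    ``dominance_sd_factor`` (0.78) makes 90% of heterozygosity effects
    positive given d ~ N(|a|, 0.78|a|), for an average degree of
    dominance of one; the two ``sd_z`` values make E|z| = 0.25
    (additive-by-additive) and 1.00 (duplicate/complementary), so gene
    action effects have the same magnitude across models; the genetic
    noise added to every matrix entry has mean absolute value equal to
    one tenth of the matrix's mean absolute entry.
    """

    sd_a: float = 0.25 * _SQRT_HALF_PI
    dominance_sd_factor: float = 0.78
    sd_z_addxadd: float = 0.25 * _SQRT_HALF_PI
    sd_z_dupcomp: float = 1.00 * _SQRT_HALF_PI
    noise_factor: float = _SQRT_HALF_PI / 90.0  # times sum |u_xy|


def select_qtl(
    panel_m: GenotypePanel,
    panel_f: GenotypePanel,
    scenario: str,
    n_qtl: int = 200,
    rng: np.random.Generator | None = None,
    maf_min: float = 0.025,
    convergent_max: float = 0.05,
    divergent_min: float = 0.60,
) -> np.ndarray:
    """Sample QTL positions satisfying the scenario's frequency constraints.

    Eligibility is computed from the allele frequencies of the two
    panels passed in: a locus qualifies if its minor allele frequency is
    at least ``maf_min`` in both groups (so it contributes variation)
    and its between-group frequency difference is below
    ``convergent_max`` (convergent scenario) or above ``divergent_min``
    (divergent).  ``n_qtl`` eligible loci are then drawn uniformly.
    """
    rng = np.random.default_rng() if rng is None else rng
    if len(panel_m.map) != len(panel_f.map):
        raise ValueError("panels must share a map")
    p_m = panel_m.allele_frequencies()
    p_f = panel_f.allele_frequencies()
    maf_ok = (np.minimum(p_m, 1 - p_m) >= maf_min) & (
        np.minimum(p_f, 1 - p_f) >= maf_min
    )
    delta = np.abs(p_m - p_f)
    if scenario == "convergent":
        eligible = maf_ok & (delta < convergent_max)
    elif scenario == "divergent":
        eligible = maf_ok & (delta > divergent_min)
    else:
        raise ValueError(f"unknown population-structure scenario: {scenario!r}")
    idx = np.flatnonzero(eligible)
    if len(idx) < n_qtl:
        raise ValueError(
            f"only {len(idx)} loci satisfy the {scenario} scenario "
            f"constraints; {n_qtl} required"
        )
    return np.sort(rng.choice(idx, size=n_qtl, replace=False))


def assign_gene_action(
    n_pairs: int,
    rng: np.random.Generator,
    probs: dict[str, float] | None = None,
) -> np.ndarray:
    """Independent per-pair gene-action labels at the stated proportions."""
    probs = GENE_ACTION_PROBS if probs is None else probs
    labels = np.array(list(probs), dtype=object)
    p = np.array(list(probs.values()))
    if not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("gene-action probabilities must sum to 1")
    return rng.choice(labels, size=n_pairs, p=p)


def sample_homozygous_effects(
    n: int, rng: np.random.Generator, params: EffectSamplerParams | None = None
) -> np.ndarray:
    """``n`` homozygous effects a ~ N(0, sd_a); E|a| = 0.25."""
    params = EffectSamplerParams() if params is None else params
    return rng.normal(0.0, params.sd_a, size=n)


def sample_dominance_effects(
    n: int, rng: np.random.Generator, params: EffectSamplerParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """``n`` (a, d) pairs: d ~ N(|a|, 0.78 |a|), so 90% of d are positive."""
    params = EffectSamplerParams() if params is None else params
    a = sample_homozygous_effects(n, rng, params)
    d = rng.normal(np.abs(a), params.dominance_sd_factor * np.abs(a))
    return a, d


def sample_epistatic_scales(
    n: int,
    rng: np.random.Generator,
    label: str,
    params: EffectSamplerParams | None = None,
) -> np.ndarray:
    """``n`` scale parameters z for an epistatic gene-action model."""
    params = EffectSamplerParams() if params is None else params
    if label == "additive_x_additive":
        sd = params.sd_z_addxadd
    elif label in ("duplicate", "complementary"):
        sd = params.sd_z_dupcomp
    else:
        raise ValueError(f"no epistatic scale for model {label!r}")
    return rng.normal(0.0, sd, size=n)


def sample_effects(
    label: str,
    rng: np.random.Generator,
    params: EffectSamplerParams | None = None,
) -> GeneActionMatrix:
    """Draw one gene-action matrix with sampled effects and genetic noise."""
    params = EffectSamplerParams() if params is None else params
    kwargs: dict = {}
    if label in ("additive", "dominance"):
        aB = float(sample_homozygous_effects(1, rng, params)[0])
        aC = float(sample_homozygous_effects(1, rng, params)[0])
        kwargs.update(aB=aB, aC=aC)
        if label == "dominance":
            kwargs.update(
                dB=rng.normal(abs(aB), params.dominance_sd_factor * abs(aB)),
                dC=rng.normal(abs(aC), params.dominance_sd_factor * abs(aC)),
            )
    elif label in ("additive_x_additive", "duplicate", "complementary"):
        kwargs.update(z=float(sample_epistatic_scales(1, rng, label, params)[0]))
    else:
        raise ValueError(f"unknown gene-action model: {label!r}")
    base = make_gene_action_matrix(label, **kwargs)
    sigma_n = params.noise_factor * np.abs(base.entries).sum()
    noise = rng.normal(0.0, sigma_n, size=(3, 3)) if sigma_n > 0 else np.zeros((3, 3))
    return make_gene_action_matrix(label, **kwargs, noise_entries=noise)


def haldane_r(gmap: GeneticMap, locus_a: int, locus_b: int) -> float:
    """Recombination fraction between two mapped loci (0.5 across chromosomes)."""
    if gmap.chromosome[locus_a] != gmap.chromosome[locus_b]:
        return 0.5
    d = abs(gmap.position_cM[locus_a] - gmap.position_cM[locus_b]) / 100.0
    return (1.0 - math.exp(-2.0 * d)) / 2.0


@dataclass(frozen=True)
class TraitArchitecture:
    """100 QTL pairs with their gene-action matrices and linkage.

    ``pairs`` holds map indices (ordered: first locus = B, second = C);
    ``recomb_fractions`` the Haldane recombination fraction within each
    pair.  Every QTL belongs to exactly one pair.
    """

    scenario: str
    qtl_loci: np.ndarray
    pairs: np.ndarray
    matrices: list[GeneActionMatrix]
    recomb_fractions: np.ndarray
    sampler_params: EffectSamplerParams = field(default_factory=EffectSamplerParams)

    def __post_init__(self):
        pairs = np.asarray(self.pairs, dtype=int)
        flat = pairs.ravel()
        if len(set(flat.tolist())) != len(flat):
            raise ValueError("each QTL must appear in exactly one pair")
        if set(flat.tolist()) != set(np.asarray(self.qtl_loci).tolist()):
            raise ValueError("pairs must cover exactly the QTL loci")
        if len(self.matrices) != len(pairs):
            raise ValueError("need one gene-action matrix per pair")
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "qtl_loci", np.asarray(self.qtl_loci, dtype=int))
        object.__setattr__(
            self, "recomb_fractions", np.asarray(self.recomb_fractions, dtype=float)
        )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_file(self, path: str | Path) -> None:
        """Serialize loci, pairs and matrices to a JSON text file."""
        data = {
            "scenario": self.scenario,
            "qtl_loci": self.qtl_loci.tolist(),
            "pairs": self.pairs.tolist(),
            "recomb_fractions": self.recomb_fractions.tolist(),
            "matrices": [
                {
                    "model_label": m.model_label,
                    "params": m.params,
                    "entries": m.entries.tolist(),
                    "noise_entries": m.noise_entries.tolist(),
                }
                for m in self.matrices
            ],
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_file(cls, path: str | Path) -> "TraitArchitecture":
        data = json.loads(Path(path).read_text())
        matrices = [
            GeneActionMatrix(
                entries=np.array(m["entries"]),
                model_label=m["model_label"],
                params=m["params"],
                noise_entries=np.array(m["noise_entries"]),
            )
            for m in data["matrices"]
        ]
        return cls(
            scenario=data["scenario"],
            qtl_loci=np.array(data["qtl_loci"]),
            pairs=np.array(data["pairs"]),
            matrices=matrices,
            recomb_fractions=np.array(data["recomb_fractions"]),
        )


def build_architecture(
    panel_m: GenotypePanel,
    panel_f: GenotypePanel,
    scenario: str,
    rng: np.random.Generator,
    n_qtl: int = 200,
    params: EffectSamplerParams | None = None,
    qtl_loci: np.ndarray | None = None,
    gene_action_probs: dict[str, float] | None = None,
) -> TraitArchitecture:
    """Select QTL, pair them at random and sample per-pair gene action.

    Pairing is uniform over the selected QTL regardless of chromosome,
    so pairs may be linked; within-pair recombination fractions are
    taken from the map via the Haldane function.
    """
    params = EffectSamplerParams() if params is None else params
    if qtl_loci is None:
        qtl_loci = select_qtl(panel_m, panel_f, scenario, n_qtl=n_qtl, rng=rng)
    qtl_loci = np.asarray(qtl_loci, dtype=int)
    if len(qtl_loci) % 2:
        raise ValueError("number of QTL must be even")
    perm = rng.permutation(len(qtl_loci))
    pairs = qtl_loci[perm].reshape(-1, 2)
    labels = assign_gene_action(len(pairs), rng, probs=gene_action_probs)
    matrices = [sample_effects(lab, rng, params) for lab in labels]
    gmap = panel_m.map
    rfrac = np.array([haldane_r(gmap, b, c) for b, c in pairs])
    return TraitArchitecture(
        scenario=scenario,
        qtl_loci=np.sort(qtl_loci),
        pairs=pairs,
        matrices=matrices,
        recomb_fractions=rfrac,
        sampler_params=params,
    )


def _allele_index(genotypes: np.ndarray, loci: np.ndarray) -> np.ndarray:
    """Origin-allele index (1 = reference homozygote, 2 = alternate) per locus."""
    codes = genotypes[:, loci]
    if not np.isin(codes, (0, 2)).all():
        raise ValueError("parent heterozygous at a QTL; parents must be DH lines")
    return (2 - codes // 2).astype(np.int64)


def f1_genetic_value(
    arch: TraitArchitecture, male_dh: np.ndarray, female_dh: np.ndarray
) -> float:
    """True genetic value of one F1 hybrid: sum over the 100 QTL pairs."""
    im = _allele_index(male_dh[None, :], arch.pairs[:, 0])[0]
    jf = _allele_index(female_dh[None, :], arch.pairs[:, 0])[0]
    km = _allele_index(male_dh[None, :], arch.pairs[:, 1])[0]
    lf = _allele_index(female_dh[None, :], arch.pairs[:, 1])[0]
    total = 0.0
    for p, U in enumerate(arch.matrices):
        total += U.entries[im[p] + jf[p] - 2, km[p] + lf[p] - 2]
    return float(total)


def f1_factorial(
    arch: TraitArchitecture, panel_m: GenotypePanel, panel_f: GenotypePanel
) -> np.ndarray:
    """True F1 values of the full male x female factorial (n_m, n_f)."""
    im = _allele_index(panel_m.genotypes, arch.pairs[:, 0])  # (n_m, P)
    km = _allele_index(panel_m.genotypes, arch.pairs[:, 1])
    jf = _allele_index(panel_f.genotypes, arch.pairs[:, 0])  # (n_f, P)
    lf = _allele_index(panel_f.genotypes, arch.pairs[:, 1])
    out = np.zeros((panel_m.n_lines, panel_f.n_lines))
    for p, U in enumerate(arch.matrices):
        x = im[:, p][:, None] + jf[:, p][None, :] - 2
        y = km[:, p][:, None] + lf[:, p][None, :] - 2
        out += U.entries[x, y]
    return out


def _exact_pair_bulk(
    U: GeneActionMatrix,
    i: np.ndarray,
    j: np.ndarray,
    k: np.ndarray,
    l: np.ndarray,
    r: float,
) -> np.ndarray:
    """Vectorized expected F2 value of one pair for many hybrids.

    Enumerates the 4 x 4 gamete combinations of the F1 (haplotypes
    (B_i, C_k) and (B_j, C_l)) with Haldane recombination fraction r.
    """
    gametes = ((i, k, (1 - r) / 2), (j, l, (1 - r) / 2), (i, l, r / 2), (j, k, r / 2))
    out = np.zeros(i.shape)
    for b1, c1, p1 in gametes:
        for b2, c2, p2 in gametes:
            out += p1 * p2 * U.entries[b1 + b2 - 2, c1 + c2 - 2]
    return out


def f12_bulk_values(
    arch: TraitArchitecture,
    panel_m: GenotypePanel,
    panel_f: GenotypePanel,
    male_idx: np.ndarray,
    female_idx: np.ndarray,
    mode: str = "simulate",
    n_f2: int = 100,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """True F1:2 bulk values for the hybrids (male_idx[i], female_idx[i]).

    ``exact`` mode returns the expectation over the two-locus F2
    distribution of every pair (respecting within-pair linkage);
    ``simulate`` mode selfs each F1 in silico — every F2 is the union
    of two independent recombinant gametes over the QTL map — and
    averages the true values of ``n_f2`` F2 individuals, which includes
    the finite-bulk sampling noise of a real experiment.
    """
    male_idx = np.asarray(male_idx)
    female_idx = np.asarray(female_idx)
    if mode == "exact":
        im = _allele_index(panel_m.genotypes[male_idx], arch.pairs[:, 0])
        km = _allele_index(panel_m.genotypes[male_idx], arch.pairs[:, 1])
        jf = _allele_index(panel_f.genotypes[female_idx], arch.pairs[:, 0])
        lf = _allele_index(panel_f.genotypes[female_idx], arch.pairs[:, 1])
        out = np.zeros(len(male_idx))
        for p, U in enumerate(arch.matrices):
            out += _exact_pair_bulk(
                U, im[:, p], jf[:, p], km[:, p], lf[:, p], arch.recomb_fractions[p]
            )
        return out
    if mode != "simulate":
        raise ValueError(f"mode must be 'simulate' or 'exact', got {mode!r}")
    if rng is None:
        raise ValueError("simulate mode requires an rng")

    # meiosis is simulated on the QTL sub-map; pair loci positions are
    # re-indexed into it
    order = np.argsort(arch.qtl_loci, kind="stable")
    qtl_sorted = arch.qtl_loci[order]
    qmap = panel_m.map.subset(qtl_sorted)
    pos_in_qtl = np.searchsorted(qtl_sorted, arch.pairs)
    hap_m = (panel_m.genotypes[:, qtl_sorted] // 2).astype(np.int8)
    hap_f = (panel_f.genotypes[:, qtl_sorted] // 2).astype(np.int8)

    out = np.empty(len(male_idx))
    for t, (mi, fi) in enumerate(zip(male_idx, female_idx)):
        gam1 = recombine_gametes(hap_m[mi], hap_f[fi], qmap, n_f2, rng)
        gam2 = recombine_gametes(hap_m[mi], hap_f[fi], qmap, n_f2, rng)
        cls = 3 - gam1.astype(np.int64) - gam2  # genotype class 1..3 per locus
        vals = np.zeros(n_f2)
        for p, U in enumerate(arch.matrices):
            vals += U.entries[
                cls[:, pos_in_qtl[p, 0]] - 1, cls[:, pos_in_qtl[p, 1]] - 1
            ]
        out[t] = vals.mean()
    return out


def f12_bulk_genetic_value(
    arch: TraitArchitecture,
    panel_m: GenotypePanel,
    panel_f: GenotypePanel,
    male_index: int,
    female_index: int,
    mode: str = "simulate",
    n_f2: int = 100,
    rng: np.random.Generator | None = None,
) -> float:
    """F1:2 bulk value of a single hybrid (see :func:`f12_bulk_values`)."""
    return float(
        f12_bulk_values(
            arch,
            panel_m,
            panel_f,
            np.array([male_index]),
            np.array([female_index]),
            mode=mode,
            n_f2=n_f2,
            rng=rng,
        )[0]
    )


@dataclass(frozen=True)
class TruthTable:
    """Full-factorial truth: F1 values, GCA and SCA effects.

    GCA effects are the centred row/column means of the factorial and
    SCA the double-centred residuals, so the classical decomposition
    var(F1) = var(GCA_m) + var(GCA_f) + var(SCA) holds exactly over
    the table.
    """

    f1_values: np.ndarray
    grand_mean: float
    gca_male: np.ndarray
    gca_female: np.ndarray
    sca: np.ndarray
    f12_values: dict | None = None  # optional bulk truth for designated hybrids


def build_truth(
    arch: TraitArchitecture, dh_panel_m: GenotypePanel, dh_panel_f: GenotypePanel
) -> TruthTable:
    """Reference population of hybrids: factorial, GCA and SCA truth."""
    if dh_panel_m.n_lines == 0 or dh_panel_f.n_lines == 0:
        raise ValueError("panels must be nonempty")
    F = f1_factorial(arch, dh_panel_m, dh_panel_f)
    mu = float(F.mean())
    gca_m = F.mean(axis=1) - mu
    gca_f = F.mean(axis=0) - mu
    sca = F - mu - gca_m[:, None] - gca_f[None, :]
    return TruthTable(
        f1_values=F, grand_mean=mu, gca_male=gca_m, gca_female=gca_f, sca=sca
    )
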