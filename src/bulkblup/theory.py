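"""Exact two-locus theory of F1 hybrids versus F1:2 bulks.

This module implements a closed-form calculator for the quantitative
genetics of an interpopulation hybrid population formed by randomly
intermating two panels of fully homozygous inbred lines (two "heterotic
groups", labelled male and female).  Two biallelic loci B and C are
considered, with alleles labelled by their population of origin, so that
an F1 genotype is indexed by the four allele origins ``(i, j, k, l)``
(male/female B allele, male/female C allele, each in {1, 2}).  Random
intermating makes the population "gene orthogonal": male- and
female-origin effects are statistically independent, genotype
frequencies are products of the four allele frequencies, and the total
genetic variance decomposes exactly into male GCA, female GCA and SCA
components.

Gene action at the locus pair is encoded by a 3x3 matrix of genotypic
values ``u[x, y]`` with ``x = i + j - 1`` indexing the B-locus genotype
class (1 = B1B1, 2 = heterozygous, 3 = B2B2) and ``y = k + l - 1`` the
C-locus class.  Selfing an F1 and bulking the F2 seed gives the "F1:2
bulk", whose genetic value is the expectation of ``u`` over Mendelian
segregation of whichever loci were heterozygous in the F1.

The module computes population means, variances, the GCA/SCA
decomposition, the correlation between F1 and F1:2 genetic values
(``cor_hybrids``) and between F1- and F1:2-based GCA effects
(``cor_gca``), for the classical gene-action models (additive,
dominance, additive-by-additive, duplicate-factor and complementary
epistasis), and scans them over grids of between-group allele-frequency
divergence.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneActionMatrix",
    "TwoLocusFrequencies",
    "TheorySummary",
    "MODEL_LABELS",
    "make_gene_action_matrix",
    "f1_value",
    "f12_bulk_value",
    "f2_origin_genotype_frequencies",
    "population_summary",
    "grid_scan",
    "default_divergence_grid",
    "default_dominance_grid",
    "frequencies_from_divergence",
]

#: Gene-action models with a hard-coded genotypic-value pattern.
MODEL_LABELS = (
    "additive",
    "dominance",
    "additive_x_additive",
    "duplicate",
    "complementary",
    "custom",
)

# Variances below this (relative) floor are treated as exactly zero when
# deciding whether a correlation or an SCA proportion is defined.
_ZERO_VAR_TOL = 1e-14


@dataclass(frozen=True)
class GeneActionMatrix:
    """Genotypic values of the nine two-locus genotype classes.

    ``entries[x-1, y-1]`` is the genotypic value of the genotype with
    B-locus class ``x`` and C-locus class ``y`` (1 = homozygous for
    allele 1, 2 = heterozygous, 3 = homozygous for allele 2), including
    any genetic noise.  ``noise_entries`` records the noise that was
    added to the pure model pattern (all zero by default).
    """

    entries: np.ndarray
    model_label: str = "custom"
    params: dict = field(default_factory=dict)
    noise_entries: np.ndarray = field(
        default_factory=lambda: np.zeros((3, 3))
    )

    def __post_init__(self):
        entries = np.asarray(self.entries, dtype=float)
        noise = np.asarray(self.noise_entries, dtype=float)
        if entries.shape != (3, 3) or noise.shape != (3, 3):
            raise ValueError("gene-action matrices must be 3x3")
        if not np.all(np.isfinite(entries)):
            raise ValueError("gene-action matrix entries must be finite")
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "noise_entries", noise)


def _dominance_entries(aB: float, aC: float, dB: float, dC: float) -> np.ndarray:
    """Genotypic values under additive + dominant gene action."""
    row_b = np.array([aB, dB, -aB])  # B-locus class effects
    row_c = np.array([aC, dC, -aC])
    return row_b[:, None] + row_c[None, :]


def make_gene_action_matrix(
    model_label: str,
    *,
    aB: float = 0.0,
    aC: float = 0.0,
    dB: float = 0.0,
    dC: float = 0.0,
    z: float = 0.0,
    entries: np.ndarray | None = None,
    noise_entries: np.ndarray | None = None,
) -> GeneActionMatrix:
    """Build the genotypic-value matrix for one of the classical models.

    Parameters
    ----------
    model_label
        One of ``additive``, ``dominance``, ``additive_x_additive``,
        ``duplicate``, ``complementary`` or ``custom``.  The additive
        and dominance models use homozygous effects ``aB``, ``aC`` and
        (dominance only) heterozygous effects ``dB``, ``dC``; the three
        epistatic models use the scale parameter ``z``.
    entries
        Required for ``custom``: the full 3x3 matrix.
    noise_entries
        Optional 3x3 "genetic noise" added to the pattern.
    """
    params = dict(aB=aB, aC=aC, dB=dB, dC=dC, z=z)
    for name, value in params.items():
        if not math.isfinite(value):
            raise ValueError(f"parameter {name} must be finite, got {value}")

    if model_label == "additive":
        base = _dominance_entries(aB, aC, 0.0, 0.0)
    elif model_label == "dominance":
        base = _dominance_entries(aB, aC, dB, dC)
    elif model_label == "additive_x_additive":
        base = z * np.array([[2.0, 1.0, 0.0], [1.0, 1.0, 1.0], [0.0, 1.0, 2.0]])
    elif model_label == "duplicate":
        base = np.full((3, 3), z)
        base[2, 2] = 0.0
    elif model_label == "complementary":
        base = np.zeros((3, 3))
        base[:2, :2] = z
    elif model_label == "custom":
        if entries is None:
            raise ValueError("custom model requires explicit entries")
        base = np.asarray(entries, dtype=float)
    else:
        raise ValueError(f"unknown gene-action model: {model_label!r}")

    noise = np.zeros((3, 3)) if noise_entries is None else np.asarray(noise_entries, float)
    return GeneActionMatrix(
        entries=base + noise,
        model_label=model_label,
        params=params,
        noise_entries=noise,
    )


def _check_origin_indices(i: int, j: int, k: int, l: int) -> None:
    for name, idx in (("i", i), ("j", j), ("k", k), ("l", l)):
        if idx not in (1, 2):
            raise ValueError(f"allele origin index {name} must be 1 or 2, got {idx}")


def f1_value(U: GeneActionMatrix, i: int, j: int, k: int, l: int) -> float:
    """Genotypic value of the F1 with allele origins ``(i, j, k, l)``.

    The F1 carries B alleles ``i`` (male origin) and ``j`` (female
    origin), hence B-class ``x = i + j - 1``, and similarly for C.
    """
    _check_origin_indices(i, j, k, l)
    return float(U.entries[i + j - 2, k + l - 2])


def _f1_gametes(i: int, j: int, k: int, l: int, r: float):
    """Gamete types and frequencies produced by the F1 ``(i, j, k, l)``.

    The F1's two haplotypes are (B_i, C_k) and (B_j, C_l).  With
    recombination fraction ``r`` between the loci the parental gamete
    types each have frequency (1-r)/2 and the recombinant types r/2.
    Homozygous loci collapse automatically (duplicate gamete types).
    """
    return (
        ((i, k), (1.0 - r) / 2.0),
        ((j, l), (1.0 - r) / 2.0),
        ((i, l), r / 2.0),
        ((j, k), r / 2.0),
    )


def f12_bulk_value(
    U: GeneActionMatrix, i: int, j: int, k: int, l: int, r: float = 0.5
) -> float:
    """Mean genotypic value of the F1:2 bulk from F1 ``(i, j, k, l)``.

    Selfing the F1 and bulking all F2 seed gives, at each locus that was
    heterozygous in the F1, the Mendelian 1/4 : 1/2 : 1/4 genotype
    distribution; homozygous loci remain fixed, so the bulk value equals
    the F1 value when both loci are homozygous.  ``r`` is the
    recombination fraction between the two loci (0.5 = unlinked, the
    independent-loci case of the analytical theory); linkage only
    matters when the F1 is heterozygous at both loci.
    """
    _check_origin_indices(i, j, k, l)
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5], got {r}")
    gametes = _f1_gametes(i, j, k, l, r)
    value = 0.0
    for (b1, c1), p1 in gametes:
        for (b2, c2), p2 in gametes:
            value += p1 * p2 * U.entries[b1 + b2 - 2, c1 + c2 - 2]
    return value


def f2_origin_genotype_frequencies(
    i: int, j: int, k: int, l: int, r: float = 0.5
) -> dict[tuple[tuple[int, int], tuple[int, int]], float]:
    """Origin-labelled F2 genotype distribution within one F1:2 bulk.

    Keys are ``((b1, b2), (c1, c2))``: the ordered pair of B-allele
    origins and of C-allele origins carried by the F2 individual.  With
    unlinked loci all 16 ordered classes have frequency 1/16 regardless
    of the F1 genotype (allele origins segregate independently).
    """
    _check_origin_indices(i, j, k, l)
    gametes = _f1_gametes(i, j, k, l, r)
    freqs: dict[tuple[tuple[int, int], tuple[int, int]], float] = {}
    for (b1, c1), p1 in gametes:
        for (b2, c2), p2 in gametes:
            key = ((b1, b2), (c1, c2))
            freqs[key] = freqs.get(key, 0.0) + p1 * p2
    return freqs


@dataclass(frozen=True)
class TwoLocusFrequencies:
    """Allele-1 frequencies of loci B and C in the two groups."""

    pB1m: float
    pC1m: float
    pB1f: float
    pC1f: float

    def __post_init__(self):
        for name in ("pB1m", "pC1m", "pB1f", "pC1f"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")

    def genotype_frequencies(self) -> np.ndarray:
        """P[i-1, j-1, k-1, l-1]: frequency of F1 genotype (i, j, k, l).

        Under random intermating these are products of the four allele
        frequencies; they sum to one over the 16 classes.
        """
        pBm = np.array([self.pB1m, 1.0 - self.pB1m])
        pBf = np.array([self.pB1f, 1.0 - self.pB1f])
        pCm = np.array([self.pC1m, 1.0 - self.pC1m])
        pCf = np.array([self.pC1f, 1.0 - self.pC1f])
        return np.einsum("i,j,k,l->ijkl", pBm, pBf, pCm, pCf)


def frequencies_from_divergence(div_B: float, div_C: float) -> TwoLocusFrequencies:
    """Frequencies with given male-minus-female divergence around 0.5.

    "Allele divergence" d places the group frequencies at 0.5 +/- d/2,
    e.g. a divergence of 0.20 gives 0.6 in the male and 0.4 in the
    female group.
    """
    return TwoLocusFrequencies(
        pB1m=0.5 + div_B / 2.0,
        pC1m=0.5 + div_C / 2.0,
        pB1f=0.5 - div_B / 2.0,
        pC1f=0.5 - div_C / 2.0,
    )


@dataclass(frozen=True)
class TheorySummary:
    """Closed-form population summary for one gene-action/frequency setting.

    Undefined quantities (zero-variance denominators) are reported as
    ``nan``, never silently as 0 or 1.
    """

    muF1: float
    muF12: float
    var_F1: float
    var_F12: float
    varGCA_m_F1: float
    varGCA_f_F1: float
    varSCA_F1: float
    varGCA_m_F12: float
    varGCA_f_F12: float
    varSCA_F12: float
    cor_hybrids: float
    cor_gca_m: float
    cor_gca_f: float
    cor_gca_avg: float
    psca_F1: float
    psca_F12: float


def _wcorr(values1: np.ndarray, values2: np.ndarray, weights: np.ndarray) -> float:
    """Frequency-weighted Pearson correlation; nan if either variance is zero."""
    w = weights / weights.sum()
    m1 = float(np.sum(w * values1))
    m2 = float(np.sum(w * values2))
    v1 = float(np.sum(w * (values1 - m1) ** 2))
    v2 = float(np.sum(w * (values2 - m2) ** 2))
    scale = max(
        float(np.sum(w * values1**2)), float(np.sum(w * values2**2)), 1.0
    )
    if v1 <= _ZERO_VAR_TOL * scale or v2 <= _ZERO_VAR_TOL * scale:
        return float("nan")
    cov = float(np.sum(w * (values1 - m1) * (values2 - m2)))
    return cov / math.sqrt(v1 * v2)


def population_summary(
    U: GeneActionMatrix, freqs: TwoLocusFrequencies
) -> TheorySummary:
    """Exact means, variances, GCA/SCA decomposition and correlations.

    Enumerates the 16 origin-labelled F1 genotype classes of the
    gene-orthogonal population, their F1 and F1:2-bulk genotypic values
    (unlinked loci), and derives:

    * population means and total genetic variances of F1s and bulks;
    * GCA variances per group (variance of the conditional means of the
      four parental two-locus genotype classes) and the SCA variance as
      the remainder ``var - varGCA_m - varGCA_f``;
    * ``cor_hybrids``: the frequency-weighted correlation between F1
      and bulk values over the 16 classes;
    * ``cor_gca_m``/``cor_gca_f``: the frequency-weighted correlation
      between F1- and bulk-based GCA effects over the parental classes,
      and their plain average ``cor_gca_avg``;
    * the SCA proportions ``psca = varSCA / var``.
    """
    P = freqs.genotype_frequencies()
    G1 = np.empty((2, 2, 2, 2))
    G2 = np.empty((2, 2, 2, 2))
    for i, j, k, l in itertools.product((1, 2), repeat=4):
        G1[i - 1, j - 1, k - 1, l - 1] = f1_value(U, i, j, k, l)
        G2[i - 1, j - 1, k - 1, l - 1] = f12_bulk_value(U, i, j, k, l)

    def moments(G):
        mu = float(np.sum(P * G))
        var = float(np.sum(P * G**2) - mu**2)
        return mu, var

    mu1, var1 = moments(G1)
    mu2, var2 = moments(G2)

    # cor_hybrids over the 16 classes
    cor_hyb = _wcorr(G1.ravel(), G2.ravel(), P.ravel())

    # GCA: conditional expectation of G over the opposite group's gametes,
    # per parental two-locus genotype class, centred at the population mean.
    pBm = np.array([freqs.pB1m, 1.0 - freqs.pB1m])
    pBf = np.array([freqs.pB1f, 1.0 - freqs.pB1f])
    pCm = np.array([freqs.pC1m, 1.0 - freqs.pC1m])
    pCf = np.array([freqs.pC1f, 1.0 - freqs.pC1f])

    def gca(G, mu, male: bool):
        if male:
            cond = np.einsum("ijkl,j,l->ik", G, pBf, pCf) - mu
            w = np.einsum("i,k->ik", pBm, pCm)
        else:
            cond = np.einsum("ijkl,i,k->jl", G, pBm, pCm) - mu
            w = np.einsum("j,l->jl", pBf, pCf)
        var = float(np.sum(w * cond**2))
        return cond.ravel(), w.ravel(), var

    g1m, wm, varGCAm1 = gca(G1, mu1, male=True)
    g1f, wf, varGCAf1 = gca(G1, mu1, male=False)
    g2m, _, varGCAm2 = gca(G2, mu2, male=True)
    g2f, _, varGCAf2 = gca(G2, mu2, male=False)

    varSCA1 = var1 - varGCAm1 - varGCAf1
    varSCA2 = var2 - varGCAm2 - varGCAf2

    cor_m = _wcorr(g1m, g2m, wm)
    cor_f = _wcorr(g1f, g2f, wf)
    cor_avg = (cor_m + cor_f) / 2.0

    scale1 = max(abs(mu1) ** 2, var1, 1.0)
    scale2 = max(abs(mu2) ** 2, var2, 1.0)
    psca1 = varSCA1 / var1 if var1 > _ZERO_VAR_TOL * scale1 else float("nan")
    psca2 = varSCA2 / var2 if var2 > _ZERO_VAR_TOL * scale2 else float("nan")

    return TheorySummary(
        muF1=mu1,
        muF12=mu2,
        var_F1=var1,
        var_F12=var2,
        varGCA_m_F1=varGCAm1,
        varGCA_f_F1=varGCAf1,
        varSCA_F1=varSCA1,
        varGCA_m_F12=varGCAm2,
        varGCA_f_F12=varGCAf2,
        varSCA_F12=varSCA2,
        cor_hybrids=cor_hyb,
        cor_gca_m=cor_m,
        cor_gca_f=cor_f,
        cor_gca_avg=cor_avg,
        psca_F1=psca1,
        psca_F12=psca2,
    )


def default_divergence_grid(step: float = 0.02, stop: float = 0.98) -> np.ndarray:
    """Allele-divergence grid 0 .. ``stop`` (inclusive) in steps of ``step``."""
    n = int(round(stop / step))
    return np.linspace(0.0, n * step, n + 1)


def default_dominance_grid(step: float = 0.05, stop: float = 3.0) -> np.ndarray:
    """Degree-of-dominance grid 0 .. ``stop`` (inclusive) in steps of ``step``."""
    n = int(round(stop / step))
    return np.linspace(0.0, n * step, n + 1)


def grid_scan(
    model_label: str,
    params: dict | None = None,
    divergence_grid_B: Sequence[float] | None = None,
    divergence_grid_C_or_dominance_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Scan a gene-action model over divergence (and dominance) grids.

    For the dominance model only the B locus varies (``aC = dC = 0``,
    ``aB`` fixed at 1): the first axis is B-locus allele divergence and
    the second the degree of dominance ``dB / aB``.  For the epistatic
    models (``z`` from ``params``, default 1) both axes are allele
    divergences, applied to loci B and C respectively.

    Returns one row per grid point with the full ``TheorySummary``
    fields; undefined quantities appear as ``nan``.
    """
    params = dict(params or {})
    grid_b = (
        default_divergence_grid()
        if divergence_grid_B is None
        else np.asarray(divergence_grid_B, dtype=float)
    )
    if grid_b.size == 0:
        raise ValueError("empty divergence grid")

    rows = []
    if model_label == "dominance":
        aB = params.get("aB", 1.0)
        grid_deg = (
            default_dominance_grid()
            if divergence_grid_C_or_dominance_grid is None
            else np.asarray(divergence_grid_C_or_dominance_grid, dtype=float)
        )
        if grid_deg.size == 0:
            raise ValueError("empty dominance grid")
        for div in grid_b:
            freqs = frequencies_from_divergence(div, 0.0)
            for deg in grid_deg:
                U = make_gene_action_matrix("dominance", aB=aB, dB=aB * deg)
                s = population_summary(U, freqs)
                rows.append({"model": model_label, "div_B": div, "degree": deg, **vars(s)})
    else:
        if model_label not in ("additive", "additive_x_additive", "duplicate", "complementary"):
            raise ValueError(f"unknown gene-action model: {model_label!r}")
        z = params.get("z", 1.0)
        if model_label == "additive":
            make = lambda: make_gene_action_matrix(
                "additive", aB=params.get("aB", 1.0), aC=params.get("aC", 1.0)
            )
        else:
            make = lambda: make_gene_action_matrix(model_label, z=z)
        grid_c = (
            grid_b
            if divergence_grid_C_or_dominance_grid is None
            else np.asarray(divergence_grid_C_or_dominance_grid, dtype=float)
        )
        if grid_c.size == 0:
            raise ValueError("empty divergence grid")
        U = make()
        for div_b in grid_b:
            for div_c in grid_c:
                freqs = frequencies_from_divergence(div_b, div_c)
                s = population_summary(U, freqs)
                rows.append({"model": model_label, "div_B": div_b, "div_C": div_c, **vars(s)})

    return pd.DataFrame(rows)
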