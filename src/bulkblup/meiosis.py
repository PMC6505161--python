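"""Meiosis under the Haldane model, DH production and biparental families.

Crossovers are simulated without interference: per chromosome the
crossover count is Poisson with mean equal to the chromosome's genetic
length in Morgans and crossover positions are uniform, which is exactly
the process underlying the Haldane mapping function
``r = (1 - exp(-2d)) / 2``.  A doubled-haploid (DH) line is one
recombined gamete of the (virtual) F1 between two homozygous parents,
doubled to homozygosity.

Each heterotic group's breeding population is represented by biparental
DH families whose parents are drawn with importance weights, mirroring
the unbalanced use of a few highly successful inbreds in applied
programs: a small "high importance" class (weight 0.1 each), a
"medium" class (0.0125 each) and the remainder sharing the leftover
probability mass equally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .founders import GeneticMap, GenotypePanel

__all__ = [
    "FamilySet",
    "recombine_gamete",
    "recombine_gametes",
    "make_dh",
    "make_dh_lines",
    "assign_importance_weights",
    "sample_families",
    "build_dh_panel",
]


def recombine_gametes(
    hap1: np.ndarray,
    hap2: np.ndarray,
    gmap: GeneticMap,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate ``n`` independent gametes from the haplotype pair.

    Per chromosome: a random starting strand, a Poisson number of
    crossovers (mean = mapped length in Morgans) at uniform positions,
    and a strand switch at every crossover.  Chromosomes assort
    independently.  Returns an ``(n, n_loci)`` mosaic of the inputs.
    """
    hap1 = np.asarray(hap1)
    hap2 = np.asarray(hap2)
    if hap1.shape != (len(gmap),) or hap2.shape != (len(gmap),):
        raise ValueError("haplotype length does not match map")
    out = np.empty((n, len(gmap)), dtype=hap1.dtype)
    for c in gmap.chromosomes:
        idx = gmap.chromosome_indices(c)
        pos = gmap.position_cM[idx]
        length_m = (pos[-1] - pos[0]) / 100.0  # mapped extent in Morgans
        start = rng.integers(0, 2, size=n)
        if length_m > 0:
            counts = rng.poisson(length_m, size=n)
            kmax = int(counts.max())
        else:
            counts = np.zeros(n, dtype=int)
            kmax = 0
        if kmax > 0:
            xpos = rng.uniform(pos[0], pos[-1], size=(n, kmax))
            # deactivate draws beyond each gamete's crossover count
            xpos[np.arange(kmax)[None, :] >= counts[:, None]] = np.inf
            below = (xpos[:, :, None] < pos[None, None, :]).sum(axis=1)
            strand = (start[:, None] + below) % 2
        else:
            strand = np.broadcast_to(start[:, None], (n, len(idx)))
        out[:, idx] = np.where(strand == 0, hap1[idx][None, :], hap2[idx][None, :])
    return out


def recombine_gamete(
    hap1: np.ndarray, hap2: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """Single recombined gamete (see :func:`recombine_gametes`)."""
    return recombine_gametes(hap1, hap2, gmap, 1, rng)[0]


def _haplotype(genotype: np.ndarray) -> np.ndarray:
    geno = np.asarray(genotype)
    if not np.isin(geno, (0, 2)).all():
        raise ValueError("parent must be fully homozygous (codes 0/2)")
    return (geno // 2).astype(np.int8)


def make_dh_lines(
    parent1_genotype: np.ndarray,
    parent2_genotype: np.ndarray,
    gmap: GeneticMap,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """``n`` DH genotypes from a biparental cross of homozygous parents.

    Each DH is a single recombined gamete of the virtual F1 (whose two
    haplotypes are the parents' haplotypes), chromosome-doubled back to
    codes 0/2.
    """
    h1 = _haplotype(parent1_genotype)
    h2 = _haplotype(parent2_genotype)
    return 2 * recombine_gametes(h1, h2, gmap, n, rng)


def make_dh(
    parent1_genotype: np.ndarray,
    parent2_genotype: np.ndarray,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """Single DH genotype (see :func:`make_dh_lines`)."""
    return make_dh_lines(parent1_genotype, parent2_genotype, gmap, 1, rng)[0]


def assign_importance_weights(
    line_ids: Sequence,
    n_high: int = 5,
    n_medium: int = 20,
    rng: np.random.Generator | None = None,
    w_high: float = 0.1,
    w_medium: float = 0.0125,
) -> np.ndarray:
    """Random importance weights summing exactly to one.

    ``n_high`` lines get weight ``w_high``, ``n_medium`` get
    ``w_medium`` and the remaining lines share the leftover mass
    equally; class membership is assigned at random.  With the default
    classes and 123 lines the low weight is 0.25/98 ~ 0.00255.
    """
    rng = np.random.default_rng() if rng is None else rng
    n = len(line_ids)
    n_low = n - n_high - n_medium
    if n_low <= 0:
        raise ValueError(
            f"need more than {n_high + n_medium} lines for a low-importance class"
        )
    w_low = (1.0 - n_high * w_high - n_medium * w_medium) / n_low
    if w_low <= 0:
        raise ValueError("low-importance weight must be positive")
    weights = np.full(n, w_low)
    order = rng.permutation(n)
    weights[order[:n_high]] = w_high
    weights[order[n_high : n_high + n_medium]] = w_medium
    return weights / weights.sum()


def sample_families(
    line_ids: Sequence,
    weights: np.ndarray,
    n_families: int,
    rng: np.random.Generator,
) -> list[tuple[object, object, float]]:
    """Draw distinct biparental families proportional to weight products.

    All unordered parent pairs (selfs excluded) get weight
    ``w_i * w_j``; ``n_families`` distinct pairs are sampled without
    replacement with probability proportional to those weights.
    Returns ``(parent1_id, parent2_id, weight_product)`` triples.
    """
    line_ids = np.asarray(line_ids, dtype=object)
    weights = np.asarray(weights, dtype=float)
    n = len(line_ids)
    ii, jj = np.triu_indices(n, k=1)
    pair_w = weights[ii] * weights[jj]
    if n_families > len(ii):
        raise ValueError(
            f"requested {n_families} families but only {len(ii)} distinct pairs exist"
        )
    chosen = rng.choice(len(ii), size=n_families, replace=False, p=pair_w / pair_w.sum())
    return [
        (line_ids[ii[c]], line_ids[jj[c]], float(pair_w[c])) for c in chosen
    ]


@dataclass(frozen=True)
class FamilySet:
    """Biparental DH families of one heterotic group.

    ``dh_lines`` carries per-line family labels; at the full scale of
    the simulated program this is 40 families x 25 DH = 1,000 lines.
    """

    group: str
    families: list[tuple[object, object, float]]
    dh_lines: GenotypePanel

    def __post_init__(self):
        if any(w <= 0 for _, _, w in self.families):
            raise ValueError("family weights must be positive")


def build_dh_panel(
    founder_panel: GenotypePanel,
    n_families: int = 40,
    n_dh_per_family: int = 25,
    rng: np.random.Generator | None = None,
    n_high: int = 5,
    n_medium: int = 20,
) -> FamilySet:
    """Importance-weighted families and their in-silico DH progeny."""
    rng = np.random.default_rng() if rng is None else rng
    weights = assign_importance_weights(
        founder_panel.lines, n_high=n_high, n_medium=n_medium, rng=rng
    )
    families = sample_families(founder_panel.lines, weights, n_families, rng)
    line_index = {lid: i for i, lid in enumerate(founder_panel.lines)}
    geno = np.empty(
        (n_families * n_dh_per_family, len(founder_panel.map)), dtype=np.int8
    )
    ids = []
    fam_labels = []
    prefix = founder_panel.group[0].upper()
    for f, (p1, p2, _) in enumerate(families):
        g = make_dh_lines(
            founder_panel.genotypes[line_index[p1]],
            founder_panel.genotypes[line_index[p2]],
            founder_panel.map,
            n_dh_per_family,
            rng,
        )
        geno[f * n_dh_per_family : (f + 1) * n_dh_per_family] = g
        fam = f"{prefix}F{f + 1:02d}"
        fam_labels.extend([fam] * n_dh_per_family)
        ids.extend(f"{fam}-{d + 1:02d}" for d in range(n_dh_per_family))
    panel = GenotypePanel(
        group=founder_panel.group,
        lines=np.array(ids, dtype=object),
        genotypes=geno,
        map=founder_panel.map,
        family=np.array(fam_labels, dtype=object),
    )
    return FamilySet(group=founder_panel.group, families=families, dh_lines=panel)
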