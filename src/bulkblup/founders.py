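"""Synthetic founder panels for two heterotic groups, plus panel I/O.

The breeding-program simulation starts from two panels of fully
homozygous inbred lines (a "male" and a "female" heterotic group, e.g.
maize Dent and Flint) genotyped at a multi-chromosome SNP panel with a
genetic map in centiMorgans.  This module generates such panels
synthetically with a controllable spectrum of per-locus allele-frequency
divergence between the groups — the quantity that drives every
F1-versus-F1:2 contrast in the theory — and reads/writes external
panels in a plain TSV dialect.

Genotypes are coded 0/2, counting copies of the reference allele;
founders are fully homozygous inbreds, so heterozygous codes are
rejected.  Synthetic founder loci are drawn in linkage equilibrium
within groups; linkage disequilibrium then arises downstream from the
biparental family structure of the derived DH panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneticMap",
    "GenotypePanel",
    "make_genetic_map",
    "rescale_physical_to_genetic",
    "default_divergence_profile",
    "sample_founder_panels",
    "read_panel",
    "write_panel",
]


@dataclass(frozen=True)
class GeneticMap:
    """Marker positions on a multi-chromosome genetic map.

    Markers are stored sorted by (chromosome, position_cM); positions
    must be nondecreasing within a chromosome and marker ids unique.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position_cM: np.ndarray
    position_bp: np.ndarray | None = None

    def __post_init__(self):
        mid = np.asarray(self.marker_id, dtype=object)
        chrom = np.asarray(self.chromosome, dtype=int)
        pos = np.asarray(self.position_cM, dtype=float)
        if not (len(mid) == len(chrom) == len(pos)):
            raise ValueError("map columns must have equal length")
        if len(set(mid)) != len(mid):
            raise ValueError("marker ids must be unique")
        if np.any(pos < 0):
            raise ValueError("cM positions must be nonnegative")
        if np.any(chrom < 1):
            raise ValueError("chromosome numbers must be >= 1")
        for c in np.unique(chrom):
            pc = pos[chrom == c]
            if np.any(np.diff(pc) < 0):
                raise ValueError(
                    f"cM positions must be nondecreasing within chromosome {c}"
                )
        object.__setattr__(self, "marker_id", mid)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position_cM", pos)
        if self.position_bp is not None:
            bp = np.asarray(self.position_bp, dtype=np.int64)
            if len(bp) != len(mid):
                raise ValueError("position_bp length mismatch")
            if np.any(bp < 0):
                raise ValueError("bp positions must be nonnegative")
            object.__setattr__(self, "position_bp", bp)

    def __len__(self) -> int:
        return len(self.marker_id)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chromosome)

    def chromosome_indices(self, chrom: int) -> np.ndarray:
        """Indices of the markers on one chromosome, in map order."""
        return np.flatnonzero(self.chromosome == chrom)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "marker": self.marker_id,
                "chrom": self.chromosome,
                "pos_cM": self.position_cM,
            }
        )
        if self.position_bp is not None:
            df.insert(2, "pos_bp", self.position_bp)
        return df

    def subset(self, indices: np.ndarray) -> "GeneticMap":
        """Map restricted to ``indices`` (kept in map order)."""
        idx = np.sort(np.asarray(indices))
        return GeneticMap(
            marker_id=self.marker_id[idx],
            chromosome=self.chromosome[idx],
            position_cM=self.position_cM[idx],
            position_bp=None if self.position_bp is None else self.position_bp[idx],
        )


@dataclass(frozen=True)
class GenotypePanel:
    """Fully homozygous inbred lines of one heterotic group.

    ``genotypes`` is lines x loci with codes in {0, 2} counting the
    reference allele; columns follow the map order.
    """

    group: str
    lines: np.ndarray
    genotypes: np.ndarray
    map: GeneticMap
    family: np.ndarray | None = None  # optional biparental-family labels

    def __post_init__(self):
        lines = np.asarray(self.lines, dtype=object)
        geno = np.asarray(self.genotypes)
        if geno.ndim != 2 or geno.shape != (len(lines), len(self.map)):
            raise ValueError(
                f"genotype matrix shape {geno.shape} does not match "
                f"{len(lines)} lines x {len(self.map)} mapped markers"
            )
        if not np.isin(geno, (0, 2)).all():
            raise ValueError(
                "heterozygous founder: genotype codes must be 0 or 2 "
                "(fully homozygous inbred lines)"
            )
        if len(set(lines)) != len(lines):
            raise ValueError("line ids must be unique")
        object.__setattr__(self, "lines", lines)
        object.__setattr__(self, "genotypes", geno.astype(np.int8))
        if self.family is not None:
            fam = np.asarray(self.family, dtype=object)
            if len(fam) != len(lines):
                raise ValueError("family labels length mismatch")
            object.__setattr__(self, "family", fam)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def allele_frequencies(self) -> np.ndarray:
        """Reference-allele frequency per locus in this panel."""
        return self.genotypes.mean(axis=0) / 2.0


def make_genetic_map(
    n_chrom: int,
    chrom_lengths_cM: Sequence[float],
    n_loci: int,
    rng: np.random.Generator,
) -> GeneticMap:
    """Random marker map: loci uniform along the genome, sorted per chromosome.

    Each locus falls on a chromosome with probability proportional to
    its length and at a uniform cM position.  The default paper-scale
    configuration uses 10 chromosomes emulating a maize genetic map.
    """
    lengths = np.asarray(chrom_lengths_cM, dtype=float)
    if len(lengths) != n_chrom:
        raise ValueError("need one chromosome length per chromosome")
    if np.any(lengths <= 0):
        raise ValueError("chromosome lengths must be positive")
    if n_loci < n_chrom:
        raise ValueError("need at least one locus per chromosome")
    chrom = rng.choice(n_chrom, size=n_loci, p=lengths / lengths.sum()) + 1
    pos = rng.uniform(0.0, lengths[chrom - 1])
    order = np.lexsort((pos, chrom))
    width = len(str(n_loci))
    ids = np.array([f"M{i + 1:0{width}d}" for i in range(n_loci)], dtype=object)
    return GeneticMap(marker_id=ids, chromosome=chrom[order], position_cM=pos[order])


def rescale_physical_to_genetic(
    map_with_bp: GeneticMap, target_lengths_cM: dict[int, float]
) -> GeneticMap:
    """Linearly rescale bp positions to given per-chromosome cM lengths.

    ``pos_cM = pos_bp / max(pos_bp on chromosome) * target_length``;
    marker order is preserved (the transform is monotone).
    """
    if map_with_bp.position_bp is None:
        raise ValueError("map has no physical (bp) positions")
    pos_cm = np.empty(len(map_with_bp), dtype=float)
    for c in map_with_bp.chromosomes:
        if c not in target_lengths_cM:
            raise ValueError(f"no target cM length for chromosome {c}")
        idx = map_with_bp.chromosome_indices(c)
        bp = map_with_bp.position_bp[idx].astype(float)
        max_bp = bp.max()
        if max_bp <= 0:
            raise ValueError(f"chromosome {c} has no positive bp position")
        pos_cm[idx] = bp / max_bp * target_lengths_cM[c]
    return GeneticMap(
        marker_id=map_with_bp.marker_id,
        chromosome=map_with_bp.chromosome,
        position_cM=pos_cm,
        position_bp=map_with_bp.position_bp,
    )


def default_divergence_profile(
    n_loci: int,
    rng: np.random.Generator,
    frac_divergent: float = 0.35,
    frac_convergent: float = 0.35,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus target allele frequencies (p_male, p_female).

    A three-class mixture emulating a panel that contains both strongly
    diverged and near-identical loci, so that QTL selection is
    satisfiable under both the divergent (|p_m - p_f| > 0.60) and the
    convergent (|p_m - p_f| < 0.05) population-structure scenario:

    * ``frac_divergent`` of loci: divergence drawn U(0.70, 0.90) around
      a 0.5 midpoint, direction random — the footprint of many cycles
      of reciprocal recurrent selection;
    * ``frac_convergent`` of loci: a common frequency U(0.10, 0.90)
      with a group offset U(-0.045, 0.045) — undifferentiated loci;
    * the remainder: independent frequencies U(0.05, 0.95) per group.
    """
    if frac_divergent + frac_convergent > 1.0:
        raise ValueError("class fractions must sum to at most 1")
    u = rng.random(n_loci)
    p_m = np.empty(n_loci)
    p_f = np.empty(n_loci)

    div = u < frac_divergent
    n_div = int(div.sum())
    d = rng.uniform(0.70, 0.90, n_div)
    sign = rng.choice((-1.0, 1.0), n_div)
    p_m[div] = 0.5 + sign * d / 2.0
    p_f[div] = 0.5 - sign * d / 2.0

    conv = (u >= frac_divergent) & (u < frac_divergent + frac_convergent)
    n_conv = int(conv.sum())
    base = rng.uniform(0.10, 0.90, n_conv)
    p_m[conv] = base
    p_f[conv] = np.clip(base + rng.uniform(-0.045, 0.045, n_conv), 0.03, 0.97)

    rest = ~(div | conv)
    n_rest = int(rest.sum())
    p_m[rest] = rng.uniform(0.05, 0.95, n_rest)
    p_f[rest] = rng.uniform(0.05, 0.95, n_rest)
    return p_m, p_f


def sample_founder_panels(
    gmap: GeneticMap,
    n_male: int,
    n_female: int,
    divergence_profile: tuple[np.ndarray, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypePanel, GenotypePanel]:
    """Draw two homozygous founder panels at the profile's frequencies.

    ``divergence_profile`` is a pair of per-locus target frequencies
    ``(p_male, p_female)``; by default :func:`default_divergence_profile`
    is used.  Line genotypes are drawn independently per locus as
    homozygous 0/2 with P(code 2) equal to the group frequency, so
    realized panel frequencies match the targets up to binomial
    sampling error.
    """
    rng = np.random.default_rng() if rng is None else rng
    if divergence_profile is None:
        divergence_profile = default_divergence_profile(len(gmap), rng)
    p_m, p_f = (np.asarray(p, dtype=float) for p in divergence_profile)
    if len(p_m) != len(gmap) or len(p_f) != len(gmap):
        raise ValueError("divergence profile length does not match map")
    for p in (p_m, p_f):
        if np.any((p < 0) | (p > 1)):
            raise ValueError("profile frequencies must be in [0, 1]")

    def draw(group: str, n: int, p: np.ndarray) -> GenotypePanel:
        geno = 2 * (rng.random((n, len(gmap))) < p).astype(np.int8)
        width = len(str(n))
        lines = np.array(
            [f"{group[0].upper()}{i + 1:0{width}d}" for i in range(n)], dtype=object
        )
        return GenotypePanel(group=group, lines=lines, genotypes=geno, map=gmap)

    return draw("male", n_male, p_m), draw("female", n_female, p_f)


def write_panel(
    panel: GenotypePanel, genotype_file: str | Path, map_file: str | Path
) -> None:
    """Write a panel to TSV (rows = lines, header = marker ids) plus map TSV."""
    df = pd.DataFrame(
        panel.genotypes, index=pd.Index(panel.lines, name="line"),
        columns=panel.map.marker_id,
    )
    df.to_csv(genotype_file, sep="\t")
    panel.map.to_frame().to_csv(map_file, sep="\t", index=False)


def read_panel(
    genotype_file: str | Path, map_file: str | Path, group: str = "male"
) -> GenotypePanel:
    """Read a panel from the TSV dialect written by :func:`write_panel`.

    The map file needs columns ``marker``, ``chrom`` and ``pos_cM``
    (and optionally ``pos_bp``); every genotype column must appear in
    the map.  Heterozygous codes are rejected — founders must be
    fully homozygous inbred lines.
    """
    mdf = pd.read_csv(map_file, sep="\t")
    required = {"marker", "chrom"}
    if not required.issubset(mdf.columns):
        raise ValueError(f"map file must have columns {sorted(required)}")
    if "pos_cM" not in mdf.columns:
        raise ValueError("map file has no pos_cM column (rescale bp first)")
    gdf = pd.read_csv(genotype_file, sep="\t", index_col=0)
    unknown = [m for m in gdf.columns if m not in set(mdf["marker"])]
    if unknown:
        raise ValueError(f"markers missing from map: {unknown[:5]}")
    mdf = mdf.set_index("marker").loc[list(gdf.columns)].reset_index()
    order = np.lexsort((mdf["pos_cM"].to_numpy(), mdf["chrom"].to_numpy()))
    mdf = mdf.iloc[order]
    gmap = GeneticMap(
        marker_id=mdf["marker"].to_numpy(dtype=object),
        chromosome=mdf["chrom"].to_numpy(),
        position_cM=mdf["pos_cM"].to_numpy(),
        position_bp=mdf["pos_bp"].to_numpy() if "pos_bp" in mdf.columns else None,
    )
    geno = gdf.to_numpy()[:, order]
    bad = ~np.isin(geno, (0, 2))
    if bad.any():
        raise ValueError(
            "heterozygous founder: file contains genotype codes other than 0/2"
        )
    return GenotypePanel(
        group=group,
        lines=gdf.index.to_numpy(dtype=object),
        genotypes=geno,
        map=gmap,
    )
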