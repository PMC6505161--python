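"""Reciprocal training-set construction and phenotype simulation.

The training set pairs every tested DH line of one heterotic group with
exactly one tested DH line of the other (a random bijection over the
DH of a random subset of families per group) — a reciprocal design in
which each parent appears in a single hybrid combination.  Phenotypes
are the true genetic values plus Gaussian noise calibrated to a broad
sense heritability of 0.5 for the F1 generation; for F1:2 bulks the
residual either stays at the F1 level ("constant residual variation",
so the bulks' lower genetic variance depresses their heritability) or
is recalibrated to keep heritability at 0.5 ("constant heritability").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .architecture import TraitArchitecture, f12_bulk_values
from .founders import GenotypePanel

__all__ = ["TrainingSet", "build_training_pairs", "generate_phenotypes", "make_training_set"]


@dataclass(frozen=True)
class TrainingSet:
    """Tested hybrid combinations with truth and phenotypes.

    ``male_idx[i]``/``female_idx[i]`` index the panels' lines; the
    pairing is a bijection, so every tested DH appears in exactly one
    hybrid.  Phenotype vectors are truth plus Gaussian noise with the
    recorded residual standard deviations.
    """

    male_idx: np.ndarray
    female_idx: np.ndarray
    tested_male_families: np.ndarray
    tested_female_families: np.ndarray
    f1_truth: np.ndarray
    f12_truth: np.ndarray
    phenotypes_f1: np.ndarray
    phenotypes_f12_constant_residual: np.ndarray
    phenotypes_f12_constant_h2: np.ndarray
    sigma_e_f1: float
    sigma_e_f12_h2: float

    def __post_init__(self):
        if len(self.male_idx) != len(self.female_idx):
            raise ValueError("pairing must be a bijection")
        for idx in (self.male_idx, self.female_idx):
            if len(set(idx.tolist())) != len(idx):
                raise ValueError("a tested DH appears in more than one pair")

    @property
    def n_pairs(self) -> int:
        return len(self.male_idx)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "male_idx": self.male_idx,
                "female_idx": self.female_idx,
                "f1_truth": self.f1_truth,
                "f12_truth": self.f12_truth,
                "pheno_f1": self.phenotypes_f1,
                "pheno_f12_const_resid": self.phenotypes_f12_constant_residual,
                "pheno_f12_const_h2": self.phenotypes_f12_constant_h2,
            }
        )


def build_training_pairs(
    dh_panel_m: GenotypePanel,
    dh_panel_f: GenotypePanel,
    n_families: int = 20,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Random family subsets and a random male-female DH bijection.

    ``n_families`` families per group are chosen uniformly; all their
    DH lines become "tested" and are paired one-to-one at random with
    the opposite group's tested DH.  Returns
    ``(male_idx, female_idx, male_families, female_families)``.
    """
    rng = np.random.default_rng() if rng is None else rng
    picks = []
    for panel in (dh_panel_m, dh_panel_f):
        if panel.family is None:
            raise ValueError("panels need family labels (see build_dh_panel)")
        fams = np.unique(panel.family)
        if len(fams) < n_families:
            raise ValueError(
                f"{panel.group} group has {len(fams)} families, {n_families} needed"
            )
        chosen = rng.choice(fams, size=n_families, replace=False)
        idx = np.flatnonzero(np.isin(panel.family, chosen))
        picks.append((np.sort(chosen), idx))
    (fam_m, idx_m), (fam_f, idx_f) = picks
    if len(idx_m) != len(idx_f):
        raise ValueError(
            f"tested DH counts differ between groups ({len(idx_m)} vs {len(idx_f)}); "
            "a reciprocal bijection needs equal counts"
        )
    male_idx = rng.permutation(idx_m)
    female_idx = rng.permutation(idx_f)
    return male_idx, female_idx, fam_m, fam_f


def generate_phenotypes(
    truth_values: np.ndarray,
    scenario: str,
    rng: np.random.Generator,
    sigma_reference: float | None = None,
) -> tuple[np.ndarray, float]:
    """Truth plus Gaussian noise under a residual-variance scenario.

    ``calibrated``: the residual standard deviation equals the standard
    deviation of the truth values, so broad-sense heritability is 0.5
    by construction (used for the F1 training set and for the F1:2
    "constant heritability" scenario).  ``constant_residual``: reuse
    ``sigma_reference`` (the F1 residual) unchanged.
    """
    truth = np.asarray(truth_values, dtype=float)
    sd_g = float(np.std(truth))
    if scenario == "calibrated":
        if sd_g <= 0:
            raise ValueError("truth values have zero genetic variance")
        sigma = sd_g
    elif scenario == "constant_residual":
        if sigma_reference is None:
            raise ValueError("constant_residual scenario needs sigma_reference")
        sigma = float(sigma_reference)
    else:
        raise ValueError(f"unknown phenotype scenario: {scenario!r}")
    return truth + rng.normal(0.0, sigma, size=len(truth)), sigma


def make_training_set(
    arch: TraitArchitecture,
    dh_panel_m: GenotypePanel,
    dh_panel_f: GenotypePanel,
    f1_factorial_values: np.ndarray,
    n_families: int = 20,
    rng: np.random.Generator | None = None,
    bulk_mode: str = "simulate",
    n_f2: int = 100,
) -> TrainingSet:
    """Assemble the full training set with F1 and F1:2 truth and phenotypes."""
    rng = np.random.default_rng() if rng is None else rng
    male_idx, female_idx, fam_m, fam_f = build_training_pairs(
        dh_panel_m, dh_panel_f, n_families=n_families, rng=rng
    )
    f1_truth = f1_factorial_values[male_idx, female_idx]
    f12_truth = f12_bulk_values(
        arch, dh_panel_m, dh_panel_f, male_idx, female_idx,
        mode=bulk_mode, n_f2=n_f2, rng=rng,
    )
    pheno_f1, sigma_f1 = generate_phenotypes(f1_truth, "calibrated", rng)
    pheno_f12_cr, _ = generate_phenotypes(
        f12_truth, "constant_residual", rng, sigma_reference=sigma_f1
    )
    pheno_f12_h2, sigma_f12 = generate_phenotypes(f12_truth, "calibrated", rng)
    return TrainingSet(
        male_idx=male_idx,
        female_idx=female_idx,
        tested_male_families=fam_m,
        tested_female_families=fam_f,
        f1_truth=f1_truth,
        f12_truth=f12_truth,
        phenotypes_f1=pheno_f1,
        phenotypes_f12_constant_residual=pheno_f12_cr,
        phenotypes_f12_constant_h2=pheno_f12_h2,
        sigma_e_f1=sigma_f1,
        sigma_e_f12_h2=sigma_f12,
    )
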