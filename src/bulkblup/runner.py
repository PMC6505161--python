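"""Replicated end-to-end genomic prediction experiments.

One replicate runs the whole pipeline — founder panels, biparental DH
families, trait architecture under a population-structure scenario,
full-factorial truth, reciprocal training set, Gibbs variance-component
estimation and selective-component BLUP — and records quantitative
genetic parameters and prediction accuracies for the F1 training set
and the F1:2 bulk training set under both residual-variance scenarios.
Replicates are averaged into three summary tables:

* table 1 — training-set genetic variances, full-factorial %SCA and the
  F1/F1:2 truth correlation, per population structure;
* table 2 — GCA prediction accuracy (tested/untested x within/across
  families), per structure, training generation and residual scenario;
* table 3 — hybrid-performance and SCA prediction accuracy by T0-T3
  prediction set.

Every stochastic stage draws from a child seed spawned from the
replicate seed with a fixed stage counter, so a replicate is exactly
reproducible and stages can be replayed in isolation.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import architecture as qarch
from . import founders as qfound
from . import meiosis as qmei
from . import model as qmod
from . import training as qtrain
from .model import ChainConfig

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "desk_config",
    "paper_config",
    "ReplicateRecord",
    "run_replicate",
    "run_experiment",
    "summarize",
]

TRAININGS = ("f1", "f12_const_resid", "f12_const_h2")
STRUCTURES = ("convergent", "divergent")
T_CLASSES = ("T3", "T2", "T1", "T0")


@dataclass(frozen=True)
class ExperimentConfig:
    """All tunable parameters of one simulated breeding program."""

    # genome and founders
    n_chrom: int = 10
    chrom_length_cM: float = 160.0
    n_loci: int = 15_000
    n_male_founders: int = 123
    n_female_founders: int = 86
    frac_divergent: float = 0.35
    frac_convergent: float = 0.35
    # biparental DH families
    n_families: int = 40
    n_dh_per_family: int = 25
    n_high_importance: int = 5
    n_medium_importance: int = 20
    # trait architecture
    n_qtl: int = 200
    qtl_freq_source: str = "founders"  # or "dh"
    gene_action_probs: dict | None = None
    noise_factor: float | None = None  # None = sampler default
    # training set
    n_training_families: int = 20
    bulk_mode: str = "simulate"
    n_f2: int = 100
    # prediction model
    n_kernel_markers: int = 5_000
    chain: ChainConfig = field(default_factory=ChainConfig)
    prediction_block: int = 20_000

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["chain"] = dataclasses.asdict(self.chain)
        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "chain" in data:
            data["chain"] = ChainConfig(**data["chain"])
        return cls(**data)


def desk_config(**overrides) -> ExperimentConfig:
    """Small configuration that exercises the full pipeline in minutes.

    2,000 loci, 1,000 kernel markers, 200 QTL, 20 families x 10 DH per
    group of which 10 families are tested (100 training pairs), a
    200 x 200 prediction factorial and a 10,000-iteration chain.
    """
    defaults = dict(
        n_loci=2_000,
        n_kernel_markers=1_000,
        n_families=20,
        n_dh_per_family=10,
        n_training_families=10,
        chain=ChainConfig(length=10_000, burn_in=5_000, thin=10),
    )
    defaults.update(overrides)
    return ExperimentConfig(**defaults)


def paper_config(**overrides) -> ExperimentConfig:
    """Full-scale configuration (long chain, 1,000 DH lines per group)."""
    defaults = dict(chain=qmod.FULL_CHAIN)
    defaults.update(overrides)
    return ExperimentConfig(**defaults)


@dataclass
class ReplicateRecord:
    """Everything one replicate measures, with its seed."""

    seed: int
    structure: str
    var_F1: float
    var_F12: float
    psca_F1: float
    cor_hybrids: float
    h2_f12_const_resid: float
    gca_acc: dict  # training -> {within/across x tested/untested -> float}
    hybrid_acc: dict  # training -> {T-class -> float}
    sca_acc: dict  # training -> {T-class -> float}

    def flat(self) -> dict:
        row = {
            "seed": self.seed,
            "structure": self.structure,
            "var_F1": self.var_F1,
            "var_F12": self.var_F12,
            "psca_F1": self.psca_F1,
            "cor_hybrids": self.cor_hybrids,
            "h2_f12_const_resid": self.h2_f12_const_resid,
        }
        for tr in TRAININGS:
            for key, val in self.gca_acc[tr].items():
                row[f"gca_{key}_{tr}"] = val
            for cls in T_CLASSES:
                row[f"hybrid_{cls}_{tr}"] = self.hybrid_acc[tr][cls]
                row[f"sca_{cls}_{tr}"] = self.sca_acc[tr][cls]
        return row


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


def run_replicate(
    config: ExperimentConfig, seed: int, structure: str
) -> ReplicateRecord:
    """One full pipeline pass under a population-structure scenario."""
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure scenario: {structure!r}")
    t0 = time.perf_counter()

    # stage 0: genome and founder panels
    rng = _stage_rng(seed, 0)
    gmap = qfound.make_genetic_map(
        config.n_chrom, [config.chrom_length_cM] * config.n_chrom, config.n_loci, rng
    )
    profile = qfound.default_divergence_profile(
        config.n_loci, rng, config.frac_divergent, config.frac_convergent
    )
    founder_m, founder_f = qfound.sample_founder_panels(
        gmap, config.n_male_founders, config.n_female_founders, profile, rng
    )

    # stage 1: biparental DH families
    rng = _stage_rng(seed, 1)
    fams_m = qmei.build_dh_panel(
        founder_m, config.n_families, config.n_dh_per_family, rng,
        config.n_high_importance, config.n_medium_importance,
    )
    fams_f = qmei.build_dh_panel(
        founder_f, config.n_families, config.n_dh_per_family, rng,
        config.n_high_importance, config.n_medium_importance,
    )
    dh_m, dh_f = fams_m.dh_lines, fams_f.dh_lines

    # stage 2: trait architecture
    rng = _stage_rng(seed, 2)
    if config.qtl_freq_source == "founders":
        freq_m, freq_f = founder_m, founder_f
    elif config.qtl_freq_source == "dh":
        freq_m, freq_f = dh_m, dh_f
    else:
        raise ValueError(f"unknown qtl_freq_source: {config.qtl_freq_source!r}")
    params = (
        None
        if config.noise_factor is None
        else qarch.EffectSamplerParams(noise_factor=config.noise_factor)
    )
    try:
        arch = qarch.build_architecture(
            freq_m, freq_f, structure, rng,
            n_qtl=config.n_qtl, params=params,
            gene_action_probs=config.gene_action_probs,
        )
    except ValueError as err:
        raise RuntimeError(f"architecture stage failed: {err}") from err

    # stage 3: full-factorial truth
    truth = qarch.build_truth(arch, dh_m, dh_f)

    # stage 4: training set
    rng = _stage_rng(seed, 4)
    tset = qtrain.make_training_set(
        arch, dh_m, dh_f, truth.f1_values,
        n_families=config.n_training_families, rng=rng,
        bulk_mode=config.bulk_mode, n_f2=config.n_f2,
    )

    # stage 5: kernel markers (disjoint from QTL) and relationship matrices
    rng = _stage_rng(seed, 5)
    candidates = np.setdiff1d(np.arange(config.n_loci), arch.qtl_loci)
    marker_set = np.sort(
        rng.choice(candidates, size=config.n_kernel_markers, replace=False)
    )
    A_m = qmod.compute_grm(dh_m.genotypes, marker_set)
    A_f = qmod.compute_grm(dh_f.genotypes, marker_set)
    hk = qmod.HybridKernels(A_m, A_f, tset.male_idx, tset.female_idx)

    # stage 6: fit and predict, per training set
    rng = _stage_rng(seed, 6)
    n_m, n_f = dh_m.n_lines, dh_f.n_lines
    hyb_m = np.repeat(np.arange(n_m), n_f)
    hyb_f = np.tile(np.arange(n_f), n_m)
    labels = qmod.classify_T(
        hyb_m, hyb_f,
        set(tset.male_idx.tolist()), set(tset.female_idx.tolist()),
        set(zip(tset.male_idx.tolist(), tset.female_idx.tolist())),
    )
    truth_flat = truth.f1_values.ravel()
    sca_flat = truth.sca.ravel()
    tested_m = np.isin(np.arange(n_m), tset.male_idx)
    tested_f = np.isin(np.arange(n_f), tset.female_idx)

    phenos = {
        "f1": tset.phenotypes_f1,
        "f12_const_resid": tset.phenotypes_f12_constant_residual,
        "f12_const_h2": tset.phenotypes_f12_constant_h2,
    }
    gca_acc, hybrid_acc, sca_acc = {}, {}, {}
    for tr, y_raw in phenos.items():
        y = (y_raw - y_raw.mean()) / y_raw.std()
        vc = qmod.fit_variance_components(
            y, hk.kernels_TT, chain=config.chain,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        # hybrid and SCA predictions over the factorial, in row blocks
        pred_total = np.empty(n_m * n_f)
        pred_sca = np.empty(n_m * n_f)
        for lo in range(0, n_m * n_f, config.prediction_block):
            hi = min(lo + config.prediction_block, n_m * n_f)
            k_pt = hk.hybrid_cross_kernels(hyb_m[lo:hi], hyb_f[lo:hi])
            pred_total[lo:hi] = qmod.predict_blup(vc, hk.kernels_TT, k_pt, y)
            pred_sca[lo:hi] = qmod.predict_blup(
                vc, hk.kernels_TT, k_pt, y, qmod.SCA_TERMS
            )
        hybrid_acc[tr] = qmod.accuracy_by_class(pred_total, truth_flat, labels)
        sca_acc[tr] = qmod.accuracy_by_class(pred_sca, sca_flat, labels)
        # GCA per group, then male/female-averaged
        acc_by_group = []
        for group, panel, tested, true_gca, terms in (
            ("male", dh_m, tested_m, truth.gca_male, qmod.GCA_MALE_TERMS),
            ("female", dh_f, tested_f, truth.gca_female, qmod.GCA_FEMALE_TERMS),
        ):
            k_pt = hk.gca_cross_kernels(group, np.arange(panel.n_lines))
            pred_gca = qmod.predict_blup(vc, hk.kernels_TT, k_pt, y, terms)
            acc_by_group.append(
                qmod.gca_accuracy(pred_gca, true_gca, panel.family, tested)
            )
        gca_acc[tr] = {
            key: float(np.mean([a[key] for a in acc_by_group]))
            for key in acc_by_group[0]
        }

    var_f1 = float(np.var(tset.f1_truth))
    var_f12 = float(np.var(tset.f12_truth))
    record = ReplicateRecord(
        seed=seed,
        structure=structure,
        var_F1=var_f1,
        var_F12=var_f12,
        psca_F1=float(np.var(truth.sca) / np.var(truth.f1_values)),
        cor_hybrids=qmod.safe_corr(tset.f1_truth, tset.f12_truth),
        h2_f12_const_resid=var_f12 / (var_f12 + tset.sigma_e_f1**2),
        gca_acc=gca_acc,
        hybrid_acc=hybrid_acc,
        sca_acc=sca_acc,
    )
    logger.info(
        "replicate seed=%d structure=%s done in %.1fs",
        seed, structure, time.perf_counter() - t0,
    )
    return record


def replicate_seed(master_seed: int, structure_index: int, rep: int) -> int:
    """Counter-based child seed for one replicate."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(structure_index, rep))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_experiment(
    config: ExperimentConfig,
    n_reps: int,
    master_seed: int,
    structures: tuple[str, ...] = STRUCTURES,
) -> list[ReplicateRecord]:
    """Independent replicates for each population-structure scenario."""
    records = []
    for si, structure in enumerate(structures):
        for rep in range(n_reps):
            seed = replicate_seed(master_seed, si, rep)
            records.append(run_replicate(config, seed, structure))
    return records


def _mean(series: pd.Series) -> float:
    return float(series.mean())


def summarize(records: list[ReplicateRecord]) -> dict[str, pd.DataFrame]:
    """Replicate means arranged as the three summary tables."""
    if not records:
        raise ValueError("no replicate records to summarize")
    df = pd.DataFrame([r.flat() for r in records])

    # table 1: genetic parameters per structure
    rows = []
    for structure, grp in df.groupby("structure"):
        rows.append(
            {
                "structure": structure,
                "n_reps": len(grp),
                "var_F1": _mean(grp.var_F1),
                "var_F12": _mean(grp.var_F12),
                "psca_F1": _mean(grp.psca_F1),
                "cor_hybrids": _mean(grp.cor_hybrids),
            }
        )
    table1 = pd.DataFrame(rows)

    # table 2 (GCA) and table 3 (hybrid/SCA): per residual scenario the F1
    # training set is the same; the F1:2 column changes.
    scenario_map = {
        "constant_residual": {"F1": "f1", "F1:2": "f12_const_resid"},
        "constant_heritability": {"F1": "f1", "F1:2": "f12_const_h2"},
    }
    gca_cols = ["within_tested", "within_untested", "across_tested", "across_untested"]
    rows2, rows3 = [], []
    for scen, gens in scenario_map.items():
        for structure, grp in df.groupby("structure"):
            for gen, tr in gens.items():
                rows2.append(
                    {
                        "scenario": scen,
                        "structure": structure,
                        "generation": gen,
                        **{c: _mean(grp[f"gca_{c}_{tr}"]) for c in gca_cols},
                    }
                )
                rows3.append(
                    {
                        "scenario": scen,
                        "structure": structure,
                        "generation": gen,
                        **{
                            f"hybrid_{cls}": _mean(grp[f"hybrid_{cls}_{tr}"])
                            for cls in T_CLASSES
                        },
                        **{
                            f"sca_{cls}": _mean(grp[f"sca_{cls}_{tr}"])
                            for cls in T_CLASSES
                        },
                    }
                )
    return {
        "table1": table1,
        "table2": pd.DataFrame(rows2),
        "table3": pd.DataFrame(rows3),
        "replicates": df,
    }


def run_experiment_to_dir(
    config: ExperimentConfig,
    n_reps: int,
    master_seed: int,
    out_dir: str | Path,
    structures: tuple[str, ...] = STRUCTURES,
) -> dict[str, pd.DataFrame]:
    """Run, summarize and write table1/2/3.csv plus per-replicate records."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = run_experiment(config, n_reps, master_seed, structures)
    tables = summarize(records)
    for name in ("table1", "table2", "table3", "replicates"):
        tables[name].to_csv(out / f"{name}.csv", index=False)
    config.to_yaml(out / "config.yaml")
    return tables
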