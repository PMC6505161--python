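"""Multi-kernel genomic prediction of hybrid, GCA and SCA performance.

The phenotype of training-set hybrid i is modelled as

    y_i = mu + a_i^m + (aa)_i^m + a_i^f + (aa)_i^f
             + d_i + (ad)_i^m + (ad)_i^f + (dd)_i + e_i

where the male/female additive and additive-by-additive effects jointly
form the parents' GCA and the dominance and dominance-involving
epistatic effects the hybrid's SCA.  Each random effect vector is
multivariate normal with a covariance kernel built from the group-wise
additive genomic relationship matrices (VanRaden standardization) by
element-wise (Hadamard) products:

    K_alpha_m ~ A_m            K_aa_m ~ A_m o A_m
    K_delta   ~ A_m o A_f      K_ad_m ~ A_m o A_m o A_f   (etc.)

each normalized by the mean of its diagonal so variance components are
on a comparable scale.  Variance components are estimated by a Gibbs
sampler (scaled-inverse-chi-square priors, eigenbasis parametrization)
and point estimates (posterior means) plug into selective-component
BLUP, ``C_PT V_TT^{-1} (y - mu)``, restricting ``C_PT`` to the
components of interest (all eight for total hybrid performance, the
additive pair for a group's GCA, the dominance-involving four for SCA).

Prediction targets are classified by training-set representation:
T3 = the tested hybrids themselves, T2 = both parents tested (new
combination), T1 = one parent tested, T0 = neither.  Accuracy is the
Pearson correlation between predictions and true F1-level values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

logger = logging.getLogger(__name__)

__all__ = [
    "KERNEL_TERMS",
    "GCA_MALE_TERMS",
    "GCA_FEMALE_TERMS",
    "SCA_TERMS",
    "ChainConfig",
    "VarianceComponents",
    "compute_grm",
    "grm_weights",
    "build_kernels",
    "fit_variance_components",
    "predict_blup",
    "classify_T",
    "safe_corr",
    "accuracy_by_class",
    "gca_accuracy",
    "HybridKernels",
]

# (exponent on A_male, exponent on A_female) of each Hadamard kernel
KERNEL_TERMS: dict[str, tuple[int, int]] = {
    "alpha_m": (1, 0),
    "aa_m": (2, 0),
    "alpha_f": (0, 1),
    "aa_f": (0, 2),
    "delta": (1, 1),
    "ad_m": (2, 1),
    "ad_f": (1, 2),
    "dd": (2, 2),
}

GCA_MALE_TERMS = ("alpha_m", "aa_m")
GCA_FEMALE_TERMS = ("alpha_f", "aa_f")
SCA_TERMS = ("delta", "ad_m", "ad_f", "dd")


def grm_weights(genotypes: np.ndarray, freqs: np.ndarray) -> tuple[np.ndarray, int]:
    """VanRaden-standardized marker matrix W and the marker count used.

    ``w_uv = (x_uv - 2 p_v) / sqrt(4 p_v (1 - p_v))`` with ``p_v`` the
    reference-allele frequency of the designated reference population.
    Markers fixed in the reference population (p of 0 or 1) are excluded
    with a logged warning.
    """
    freqs = np.asarray(freqs, dtype=float)
    usable = (freqs > 0.0) & (freqs < 1.0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning(
            "excluding %d monomorphic markers from the relationship matrix",
            n_dropped,
        )
    p = freqs[usable]
    X = np.asarray(genotypes, dtype=float)[:, usable]
    W = (X - 2.0 * p) / np.sqrt(4.0 * p * (1.0 - p))
    return W, W.shape[1]


def compute_grm(
    genotypes: np.ndarray,
    marker_set: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
) -> np.ndarray:
    """Additive genomic relationship matrix ``A = W W' / M``.

    ``marker_set`` optionally restricts to a subset of columns; ``freqs``
    are the per-marker reference-allele frequencies of the reference
    population (defaults to the sample frequencies of ``genotypes``).
    """
    G = np.asarray(genotypes, dtype=float)
    if marker_set is not None:
        G = G[:, np.asarray(marker_set)]
        if freqs is not None:
            freqs = np.asarray(freqs)[np.asarray(marker_set)]
    if freqs is None:
        freqs = G.mean(axis=0) / 2.0
    W, M = grm_weights(G, freqs)
    if M == 0:
        raise ValueError("no polymorphic markers left for the relationship matrix")
    return W @ W.T / M


def build_kernels(
    A_m: np.ndarray, A_f: np.ndarray
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """The eight Hadamard covariance kernels and their normalizations.

    Row/column i of both inputs must correspond to training entry i's
    male and female parent respectively.  Each kernel is divided by the
    mean of its unnormalized diagonal (``c_t``), so its mean diagonal
    is one.
    """
    A_m = np.asarray(A_m, dtype=float)
    A_f = np.asarray(A_f, dtype=float)
    if A_m.shape != A_f.shape or A_m.shape[0] != A_m.shape[1]:
        raise ValueError("A_m and A_f must be square and conformable")
    kernels: dict[str, np.ndarray] = {}
    c: dict[str, float] = {}
    for term, (em, ef) in KERNEL_TERMS.items():
        K = A_m**em * A_f**ef
        c[term] = float(np.mean(np.diag(K)))
        kernels[term] = K / c[term]
    return kernels, c


@dataclass(frozen=True)
class ChainConfig:
    """Gibbs chain settings and prior hyperparameters.

    Scaled-inverse-chi-square priors with ``df_prior`` degrees of
    freedom on every variance; prior scales are set so that each
    genetic term's prior mode equals ``r2 * var(y) / n_terms`` and the
    residual's equals ``(1 - r2) * var(y)``.
    """

    length: int = 10_000
    burn_in: int = 5_000
    thin: int = 10
    df_prior: float = 5.0
    r2: float = 0.5

    def __post_init__(self):
        if self.burn_in >= self.length:
            raise ValueError("burn-in must be shorter than the chain")


#: Paper-scale chain (long runs).
FULL_CHAIN = ChainConfig(length=100_000, burn_in=50_000, thin=50)


@dataclass
class VarianceComponents:
    """Posterior-mean point estimates plus the thinned samples."""

    mu: float
    sigma2: dict[str, float]
    sigma2_e: float
    chain: ChainConfig
    seed: int
    samples: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def posterior_sd(self, term: str) -> float:
        return float(np.std(self.samples[term], ddof=1))


@njit(cache=True)
def _gibbs_core(y, Phi, d, offsets, nu, S2g, S2e, n_iter, burn_in, thin, seed):
    np.random.seed(seed)
    n = y.shape[0]
    T = offsets.shape[0] - 1
    mu = y.mean()
    sigma2 = np.full(T, S2g)
    sigma2_e = S2e
    u = np.zeros(Phi.shape[1])
    e = y - mu  # current residual with all effects at zero
    n_keep = (n_iter - burn_in + thin - 1) // thin
    out = np.zeros((n_keep, T + 2))
    kept = 0
    for it in range(n_iter):
        # intercept
        r = e + mu
        mu = r.mean() + np.random.normal() * math.sqrt(sigma2_e / n)
        e = r - mu
        # kernel blocks in the eigenbasis: Phi_t' Phi_t = diag(d_t), so
        # Phi_t' r = Phi_t' e + d_t * u_t without forming r explicitly
        for t in range(T):
            o0, o1 = offsets[t], offsets[t + 1]
            Pt = Phi[:, o0:o1]
            ut = u[o0:o1]
            dt = d[o0:o1]
            rhs = (Pt.T @ e + dt * ut) / sigma2_e
            prec = dt / sigma2_e + 1.0 / sigma2[t]
            ssq = 0.0
            delta = np.empty(o1 - o0)
            for q in range(o1 - o0):
                new = rhs[q] / prec[q] + np.random.normal() / math.sqrt(prec[q])
                delta[q] = ut[q] - new
                ut[q] = new
                ssq += new * new
            e = e + Pt @ delta
            sigma2[t] = (ssq + nu * S2g) / np.random.chisquare(nu + (o1 - o0))
        sigma2_e = (e @ e + nu * S2e) / np.random.chisquare(nu + n)
        if it >= burn_in and (it - burn_in) % thin == 0:
            out[kept, 0] = mu
            for t in range(T):
                out[kept, 1 + t] = sigma2[t]
            out[kept, T + 1] = sigma2_e
            kept += 1
    return out[:kept]


def fit_variance_components(
    y: np.ndarray,
    kernels: dict[str, np.ndarray],
    chain: ChainConfig | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> VarianceComponents:
    """Gibbs sampling of the multi-kernel Gaussian model.

    ``y = mu 1 + sum_t g_t + e`` with ``g_t ~ N(0, K_t sigma_t^2)`` and
    ``e ~ N(0, I sigma_e^2)``.  Each kernel is eigendecomposed once and
    its effect sampled in the rotated basis, where the conditional
    posterior is diagonal; variances get scaled-inverse-chi-square
    updates.  Returns posterior means over the thinned post-burn-in
    samples.
    """
    chain = ChainConfig() if chain is None else chain
    y = np.asarray(y, dtype=float)
    var_y = float(np.var(y))
    if var_y <= 0:
        raise ValueError("phenotypes have zero variance")
    terms = list(kernels)
    phis = []
    for term in terms:
        K = np.asarray(kernels[term], dtype=float)
        if K.shape != (len(y), len(y)):
            raise ValueError(f"kernel {term} does not match the data size")
        evals, evecs = np.linalg.eigh(K)
        if evals.min() < -1e-8 * max(1.0, evals.max()):
            raise ValueError(f"kernel {term} is not positive semidefinite")
        keep = evals > 1e-10 * max(1.0, evals.max())
        phis.append((evecs[:, keep] * np.sqrt(evals[keep]), evals[keep]))
    offsets = np.zeros(len(terms) + 1, dtype=np.int64)
    for t, (_, ev) in enumerate(phis):
        offsets[t + 1] = offsets[t] + len(ev)
    # Fortran order: the sampler slices columns per kernel block
    Phi = np.asfortranarray(np.concatenate([p for p, _ in phis], axis=1))
    d = np.concatenate([ev for _, ev in phis])

    nu = chain.df_prior
    # scaled-inv-chi2 mode = nu*S2/(nu+2); solve the scale from the target mode
    S2g = chain.r2 * var_y / len(terms) * (nu + 2.0) / nu
    S2e = (1.0 - chain.r2) * var_y * (nu + 2.0) / nu
    if seed is None:
        rng = np.random.default_rng() if rng is None else rng
        seed = int(rng.integers(0, 2**31 - 1))
    samples = _gibbs_core(
        y, Phi, d, offsets, nu, S2g, S2e, chain.length, chain.burn_in, chain.thin, seed
    )
    sample_dict = {"mu": samples[:, 0], "sigma2_e": samples[:, -1]}
    sigma2 = {}
    for t, term in enumerate(terms):
        sample_dict[term] = samples[:, 1 + t]
        sigma2[term] = float(samples[:, 1 + t].mean())
    return VarianceComponents(
        mu=float(samples[:, 0].mean()),
        sigma2=sigma2,
        sigma2_e=float(samples[:, -1].mean()),
        chain=chain,
        seed=seed,
        samples=sample_dict,
    )


def predict_blup(
    vc: VarianceComponents,
    kernels_TT: dict[str, np.ndarray],
    kernels_PT: dict[str, np.ndarray],
    y: np.ndarray,
    component_selection: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Selective-component BLUP ``C_PT V_TT^{-1} (y - mu)``.

    ``V_TT`` always contains all fitted components plus the residual;
    ``C_PT`` sums only the selected components' cross kernels (all of
    them by default).  A singular ``V_TT`` is regularized by 1e-8 on
    the diagonal with a logged warning.
    """
    terms = list(kernels_TT)
    selection = tuple(terms) if component_selection is None else tuple(component_selection)
    unknown = set(selection) - set(terms)
    if unknown:
        raise ValueError(f"unknown components: {sorted(unknown)}")
    n = len(y)
    V = np.zeros((n, n))
    for term in terms:
        V += vc.sigma2[term] * kernels_TT[term]
    V[np.diag_indices_from(V)] += vc.sigma2_e
    resid = np.asarray(y, dtype=float) - vc.mu
    try:
        alpha = np.linalg.solve(V, resid)
    except np.linalg.LinAlgError:
        logger.warning("singular V_TT; applying 1e-8 diagonal regularization")
        V[np.diag_indices_from(V)] += 1e-8
        alpha = np.linalg.solve(V, resid)
    C = np.zeros_like(kernels_PT[selection[0]])
    for term in selection:
        C += vc.sigma2[term] * kernels_PT[term]
    return C @ alpha


def classify_T(
    male_idx: np.ndarray,
    female_idx: np.ndarray,
    tested_male: set | np.ndarray,
    tested_female: set | np.ndarray,
    training_pairs: set,
) -> np.ndarray:
    """T0-T3 label per hybrid (male_idx[i], female_idx[i]).

    T3 = the hybrid is itself a training pair; T2 = both parents tested
    (with other partners); T1 = exactly one parent tested; T0 = none.
    """
    tested_male = set(np.asarray(list(tested_male)).tolist())
    tested_female = set(np.asarray(list(tested_female)).tolist())
    labels = np.empty(len(male_idx), dtype=object)
    for h, (m, f) in enumerate(zip(male_idx.tolist(), female_idx.tolist())):
        if (m, f) in training_pairs:
            labels[h] = "T3"
        else:
            n_tested = (m in tested_male) + (f in tested_female)
            labels[h] = ("T0", "T1", "T2")[n_tested]
    return labels


def safe_corr(a: np.ndarray, b: np.ndarray, min_n: int = 3) -> float:
    """Pearson correlation; nan for short or zero-variance inputs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < min_n or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def accuracy_by_class(
    predictions: np.ndarray, truth: np.ndarray, labels: np.ndarray
) -> dict[str, float]:
    """Pearson accuracy per T-class (nan for cells below 3 entries)."""
    out = {}
    for cls in ("T0", "T1", "T2", "T3"):
        mask = labels == cls
        out[cls] = safe_corr(predictions[mask], truth[mask])
    return out


def gca_accuracy(
    predictions: np.ndarray,
    truth: np.ndarray,
    family: np.ndarray,
    tested: np.ndarray,
) -> dict[str, float]:
    """GCA accuracy split by tested/untested and within/across families.

    Within-family correlations are computed per family and averaged
    across families (families with undefined correlations are skipped);
    across-family accuracy is the plain correlation over all lines of
    the tested (or untested) set.
    """
    out = {}
    for name, mask in (("tested", np.asarray(tested, bool)), ("untested", ~np.asarray(tested, bool))):
        out[f"across_{name}"] = safe_corr(predictions[mask], truth[mask])
        fams = np.unique(family[mask])
        vals = [
            safe_corr(predictions[mask & (family == f)], truth[mask & (family == f)])
            for f in fams
        ]
        vals = [v for v in vals if not math.isnan(v)]
        out[f"within_{name}"] = float(np.mean(vals)) if vals else float("nan")
    return out


class HybridKernels:
    """Training kernels plus cross-kernel construction for prediction.

    Wraps the full group relationship matrices (over all lines of each
    group, so training and prediction share one centring) and the
    training pairs' parent indices; builds the eight TT kernels with
    their normalization constants and produces PT cross kernels for
    arbitrary hybrid or per-line GCA targets, in row blocks if needed.
    """

    def __init__(
        self,
        A_m: np.ndarray,
        A_f: np.ndarray,
        male_parents: np.ndarray,
        female_parents: np.ndarray,
    ):
        self.A_m = np.asarray(A_m, dtype=float)
        self.A_f = np.asarray(A_f, dtype=float)
        self.male_parents = np.asarray(male_parents, dtype=int)
        self.female_parents = np.asarray(female_parents, dtype=int)
        Am_TT = self.A_m[np.ix_(self.male_parents, self.male_parents)]
        Af_TT = self.A_f[np.ix_(self.female_parents, self.female_parents)]
        self.kernels_TT, self.c = build_kernels(Am_TT, Af_TT)

    def hybrid_cross_kernels(
        self, male_rows: np.ndarray, female_rows: np.ndarray
    ) -> dict[str, np.ndarray]:
        """PT kernels for hybrids (male_rows[i], female_rows[i])."""
        Bm = self.A_m[np.asarray(male_rows)][:, self.male_parents]
        Bf = self.A_f[np.asarray(female_rows)][:, self.female_parents]
        Bm2 = Bm * Bm
        Bf2 = Bf * Bf
        raw = {
            "alpha_m": Bm, "aa_m": Bm2, "alpha_f": Bf, "aa_f": Bf2,
            "delta": Bm * Bf, "ad_m": Bm2 * Bf, "ad_f": Bm * Bf2,
            "dd": Bm2 * Bf2,
        }
        return {term: raw[term] / self.c[term] for term in KERNEL_TERMS}

    def gca_cross_kernels(self, group: str, line_rows: np.ndarray) -> dict[str, np.ndarray]:
        """PT kernels of the GCA terms of one group, for given lines."""
        if group == "male":
            B = self.A_m[np.ix_(np.asarray(line_rows), self.male_parents)]
            return {"alpha_m": B / self.c["alpha_m"], "aa_m": B**2 / self.c["aa_m"]}
        if group == "female":
            B = self.A_f[np.ix_(np.asarray(line_rows), self.female_parents)]
            return {"alpha_f": B / self.c["alpha_f"], "aa_f": B**2 / self.c["aa_f"]}
        raise ValueError(f"group must be 'male' or 'female', got {group!r}")
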