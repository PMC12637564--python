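"""Hierarchical Bayesian decomposition of phospho-PCA scores.

The model posits that the phospho-PCA score of kinase i with substrate j,
position k, mutation l is a linear sum of latent effects:

    abundance[i,j,k,l] ~ Normal(alpha[i,k,l], sigma_a)
    phospho[i,j,k,l]   ~ Normal(alpha[i,k,l] + c[i,k,l] + s[i,j,k,l], sigma_p)

Abundance (alpha, folding stability) and activity (c, shifts toward active or
inactive conformations) are shared across substrates -- the per-substrate
abundance measurements act as technical replicates of one underlying abundance
parameter -- while specificity (s) varies with all four indices. Hierarchical
zero-centered Normal priors are placed on alpha and c. Specificity effects
are roughly an order of magnitude smaller than the others and sparse, so s
carries a regularizing scale-mixture prior -- s ~ Normal(0, tau_s^2 *
lambda^2) with conjugate per-cell Inverse-Gamma local variances, i.e. a
Student-t marginal -- whose tight global scale shrinks the background to zero
while the heavy tails let genuinely specificity-determining cells escape
shrinkage. A soft sum-to-zero constraint on s across substrates within each
(i,k,l) keeps s identifiable against c.

Because every conditional of this hierarchy is conjugate, posterior draws
come from a blocked Gibbs sampler: Normal updates for alpha, c and s,
Inverse-Gamma updates for the local variances, and univariate slice sampling
for the half-Normal-prior scale parameters (tau_alpha, tau_c, tau_s, sigma_p,
sigma_a). Convergence is monitored with split R-hat and effective sample
size.

Significance of specificity effects uses a dual threshold: the posterior
probability of a directional effect must reach ``directional_prob`` (0.97,
equivalent to a 94% credible interval excluding zero), and a two-sample
Kolmogorov-Smirnov test must show the posterior has genuinely diverged from
the prior. The local false-sign rate is 1 minus the directional probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import ks_2samp


@dataclass
class ScoreTensor:
    """Phospho and abundance score tensors indexed (kinase, substrate, position, mutation)."""

    phospho: np.ndarray
    abundance: np.ndarray
    mask_phospho: np.ndarray  # True where observed
    mask_abundance: np.ndarray
    kinases: list[str]
    substrates: list[str]
    positions: list[int]
    mutations: list[str]
    se_phospho: np.ndarray | None = None    # known measurement s.e. per cell
    se_abundance: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = (len(self.kinases), len(self.substrates), len(self.positions), len(self.mutations))
        for name in ("phospho", "abundance", "mask_phospho", "mask_abundance"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        for name in ("se_phospho", "se_abundance"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if not np.isfinite(self.phospho[self.mask_phospho]).all():
            raise ValueError("non-finite phospho scores inside mask")
        if not np.isfinite(self.abundance[self.mask_abundance]).all():
            raise ValueError("non-finite abundance scores inside mask")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.phospho.shape


@dataclass
class DecompositionModelConfig:
    """Priors, sampler settings, and significance thresholds."""

    tau_alpha_scale: float = 1.0   # Half-Normal scale of the alpha prior s.d.
    tau_c_scale: float = 1.0
    tau_s_scale: float = 0.2       # tighter: specificity regularization
    tau_s_mode: str = "fixed"      # "fixed": s ~ N(0, tau_s_scale^2); "hierarchical": tau_s ~ HN
    s_df: float = np.inf           # finite: Student-t prior on s via local variances
    sigma_scale: float = 0.5       # Half-Normal scale for observation noise s.d.
    sum_zero_sd: float = 0.05      # soft sum-to-zero constraint on s across substrates
    draws: int = 500
    tune: int = 500
    chains: int = 4
    seed: int = 0
    ci_level: float = 0.94
    directional_prob: float = 0.97
    ks_alpha: float = 0.05
    rhat_max: float = 1.01

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        for name in ("tau_alpha_scale", "tau_c_scale", "tau_s_scale", "sigma_scale", "sum_zero_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PosteriorDraws:
    """MCMC draws (chains, draws, ...) for every model parameter, plus diagnostics."""

    alpha: np.ndarray          # (C, D, I, K, L)
    c: np.ndarray              # (C, D, I, K, L)
    s: np.ndarray              # (C, D, I, J, K, L)
    sigma_p: np.ndarray        # (C, D)
    sigma_a: np.ndarray
    tau_alpha: np.ndarray
    tau_c: np.ndarray
    tau_s: np.ndarray
    tensor: ScoreTensor
    config: DecompositionModelConfig
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)
    converged: bool = True

    def flat(self, name: str) -> np.ndarray:
        """Draws with chain/draw axes merged: (C*D, ...)."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])


# --------------------------------------------------------------------------
# tensor assembly
# --------------------------------------------------------------------------


def assemble_tensor(matrices: list[pd.DataFrame]) -> ScoreTensor:
    """Align variant score matrices (both assays) into masked 4-d tensors.

    Input frames carry kinase, substrate, assay, position, mut_aa,
    variant_class and score columns (the fitness-module output). The
    synonymous class score, where present, anchors zero per
    (kinase, substrate, assay). Duplicate cells raise.
    """
    df = pd.concat(matrices, ignore_index=True)
    both = set(df["assay"].unique())
    if not {"phospho", "abundance"} <= both:
        raise ValueError("need score matrices for both phospho and abundance assays")
    # zero-anchor on the synonymous class, then keep single-aa variant rows
    df = df.copy()
    for (kin, sub, assay), grp in df.groupby(["kinase", "substrate", "assay"]):
        syn = grp.loc[grp["variant_class"] == "synonymous", "score"]
        if len(syn):
            df.loc[grp.index, "score"] = grp["score"] - syn.mean()
    var = df[df["variant_class"].isin(["missense", "nonsense"])]
    kinases = sorted(var["kinase"].unique())
    substrates = sorted(var["substrate"].unique())
    positions = sorted(int(p) for p in var["position"].unique())
    mutations = sorted(var["mut_aa"].unique())
    pos_range = set(positions)
    for kin, grp in var.groupby("kinase"):
        if not set(int(p) for p in grp["position"].unique()) <= pos_range:
            raise ValueError("inconsistent position ranges across kinases")
    I, J, K, L = len(kinases), len(substrates), len(positions), len(mutations)
    ki = {k: i for i, k in enumerate(kinases)}
    si = {s: j for j, s in enumerate(substrates)}
    pi = {p: k for k, p in enumerate(positions)}
    mi = {m: l for l, m in enumerate(mutations)}
    arrays = {a: np.zeros((I, J, K, L)) for a in ("phospho", "abundance")}
    masks = {a: np.zeros((I, J, K, L), dtype=bool) for a in ("phospho", "abundance")}
    for row in var.itertuples(index=False):
        c = (ki[row.kinase], si[row.substrate], pi[int(row.position)], mi[row.mut_aa])
        if masks[row.assay][c]:
            raise ValueError(f"duplicate cell {row.kinase}/{row.substrate}/{row.assay}/{row.position}{row.mut_aa}")
        arrays[row.assay][c] = row.score
        masks[row.assay][c] = True
    return ScoreTensor(
        phospho=arrays["phospho"],
        abundance=arrays["abundance"],
        mask_phospho=masks["phospho"],
        mask_abundance=masks["abundance"],
        kinases=kinases,
        substrates=substrates,
        positions=positions,
        mutations=mutations,
    )


# --------------------------------------------------------------------------
# Gibbs sampler
# --------------------------------------------------------------------------


def _slice_sample_log_scale(logf, x0: float, rng: np.random.Generator, w: float = 1.0, max_steps: int = 30) -> float:
    """One slice-sampling update of a positive scalar, on the log scale.

    ``logf`` is the unnormalised log density in the original scale; the
    log-scale target adds the Jacobian term x = log(value).
    """
    def g(x: float) -> float:
        return logf(np.exp(x)) + x

    y = g(x0) - rng.exponential()
    u = rng.random()
    lo, hi = x0 - w * u, x0 + w * (1.0 - u)
    for _ in range(max_steps):
        if g(lo) <= y:
            break
        lo -= w
    for _ in range(max_steps):
        if g(hi) <= y:
            break
        hi += w
    for _ in range(100):
        x = rng.uniform(lo, hi)
        if g(x) > y:
            return x
        if x < x0:
            lo = x
        else:
            hi = x
    return x0


def _scale_logpost(value: float, n: int, ss: float, prior_scale: float) -> float:
    """log p(scale | data): Normal likelihood of n terms with sum of squares ss,
    Half-Normal(prior_scale) prior."""
    if value <= 0:
        return -np.inf
    return -n * np.log(value) - ss / (2.0 * value**2) - value**2 / (2.0 * prior_scale**2)


def fit_decomposition(tensor: ScoreTensor, config: DecompositionModelConfig | None = None) -> PosteriorDraws:
    """Draw from the posterior of the decomposition model by blocked Gibbs.

    Requires at least two substrates so specificity is identifiable against
    activity. Missing cells contribute no likelihood. Each chain is seeded from
    ``config.seed`` and initialised from data-driven moments with chain-specific
    jitter; ``tune`` warm-up sweeps are discarded.
    """
    config = config or DecompositionModelConfig()
    I, J, K, L = tensor.shape
    if J < 2:
        raise ValueError("need >=2 substrates for specificity identifiability")
    A = np.where(tensor.mask_abundance, tensor.abundance, 0.0)
    P = np.where(tensor.mask_phospho, tensor.phospho, 0.0)
    MA = tensor.mask_abundance.astype(float)
    MP = tensor.mask_phospho.astype(float)
    nA = MA.sum(axis=1)  # (I, K, L) observations per alpha cell from abundance
    nP = MP.sum(axis=1)
    n_obs_a = int(MA.sum())
    n_obs_p = int(MP.sum())
    n_alpha = I * K * L
    n_s = I * J * K * L
    # known per-cell measurement error (meta-analytic observation model) when
    # the tensor carries standard errors; otherwise a free global noise scale
    use_se_p = tensor.se_phospho is not None
    use_se_a = tensor.se_abundance is not None
    if use_se_p:
        fixed_wP = np.where(tensor.mask_phospho, 1.0 / np.maximum(tensor.se_phospho, 1e-12) ** 2, 0.0)
    if use_se_a:
        fixed_wA = np.where(tensor.mask_abundance, 1.0 / np.maximum(tensor.se_abundance, 1e-12) ** 2, 0.0)

    C, D, T = config.chains, config.draws, config.tune
    store = {
        "alpha": np.empty((C, D, I, K, L)),
        "c": np.empty((C, D, I, K, L)),
        "s": np.empty((C, D, I, J, K, L)),
        "sigma_p": np.empty((C, D)),
        "sigma_a": np.empty((C, D)),
        "tau_alpha": np.empty((C, D)),
        "tau_c": np.empty((C, D)),
        "tau_s": np.empty((C, D)),
    }

    seeds = np.random.SeedSequence(config.seed).spawn(C)
    for chain in range(C):
        rng = np.random.default_rng(seeds[chain])
        # data-driven initialisation with chain-specific jitter
        with np.errstate(invalid="ignore"):
            alpha = np.where(nA > 0, A.sum(axis=1) / np.maximum(nA, 1), 0.0)
            cc = np.where(nP > 0, P.sum(axis=1) / np.maximum(nP, 1) - alpha, 0.0)
        alpha = alpha + rng.normal(0, 0.05, alpha.shape)
        cc = cc + rng.normal(0, 0.05, cc.shape)
        s = np.zeros((I, J, K, L))
        lam2 = np.ones((I, J, K, L))
        # noise scales are sampled only when no measurement s.e. is supplied;
        # 0.0 marks "fixed by the data" in the stored draws
        sigma_p = 0.0 if use_se_p else 0.2 * np.exp(rng.normal(0, 0.2))
        sigma_a = 0.0 if use_se_a else 0.2 * np.exp(rng.normal(0, 0.2))
        tau_alpha = tau_c = 0.5 * np.exp(rng.normal(0, 0.2))
        if config.tau_s_mode == "fixed":
            tau_s = config.tau_s_scale
        elif config.tau_s_mode == "hierarchical":
            tau_s = 0.1 * np.exp(rng.normal(0, 0.2))
        else:
            raise ValueError("tau_s_mode must be 'fixed' or 'hierarchical'")
        inv_sz2 = 1.0 / config.sum_zero_sd**2

        for sweep in range(T + D):
            wP = fixed_wP if use_se_p else MP / sigma_p**2
            wA = fixed_wA if use_se_a else MA / sigma_a**2
            # (alpha, c, s_1..s_J) | scales -- the whole per-cell effect block
            # is jointly Gaussian, so it is drawn exactly as one batched
            # (J+2)-dimensional Normal. This removes every intra-cell coupling
            # (alpha-c anticorrelation, c-s leakage, the sum-to-zero
            # correlation among the s_j) from the Gibbs autocorrelation.
            wPt = np.moveaxis(wP, 1, -1)  # (I, K, L, J)
            bPt = np.moveaxis(P * wP, 1, -1)
            wA_sum, wP_sum = wA.sum(axis=1), wP.sum(axis=1)
            bP_sum = bPt.sum(axis=-1)
            prior_prec_t = np.moveaxis(1.0 / (tau_s**2 * lam2), 1, -1)
            dim = J + 2
            lam = np.full((I, K, L, dim, dim), inv_sz2)
            lam[..., 0, 0] = wA_sum + wP_sum + 1.0 / tau_alpha**2
            lam[..., 0, 1] = lam[..., 1, 0] = wP_sum
            lam[..., 1, 1] = wP_sum + 1.0 / tau_c**2
            for j in range(J):
                lam[..., 0, 2 + j] = lam[..., 2 + j, 0] = wPt[..., j]
                lam[..., 1, 2 + j] = lam[..., 2 + j, 1] = wPt[..., j]
                lam[..., 2 + j, 2 + j] = wPt[..., j] + prior_prec_t[..., j] + inv_sz2
            b = np.empty((I, K, L, dim))
            b[..., 0] = (A * wA).sum(axis=1) + bP_sum
            b[..., 1] = bP_sum
            b[..., 2:] = bPt
            mu = np.linalg.solve(lam, b[..., None])[..., 0]
            chol = np.linalg.cholesky(lam)
            z = rng.standard_normal((I, K, L, dim, 1))
            noise = np.linalg.solve(np.swapaxes(chol, -1, -2), z)[..., 0]
            theta = mu + noise
            alpha = theta[..., 0]
            cc = theta[..., 1]
            s = np.moveaxis(theta[..., 2:], -1, 1)
            # local variances | s, tau_s: conjugate Inverse-Gamma (Student-t
            # scale mixture; with s_df = inf the prior is Normal and lam2 == 1)
            nu = config.s_df
            if np.isfinite(nu):
                ig_rate = (nu + (s / tau_s) ** 2) / 2.0
                lam2 = ig_rate / rng.gamma((nu + 1.0) / 2.0, 1.0, size=(I, J, K, L))
            # scales | rest
            if not use_se_p:
                ss = float((((P - alpha[:, None] - cc[:, None] - s) * MP) ** 2).sum())
                sigma_p = np.exp(
                    _slice_sample_log_scale(
                        lambda v: _scale_logpost(v, n_obs_p, ss, config.sigma_scale), np.log(sigma_p), rng
                    )
                )
            if config.tau_s_mode == "hierarchical":
                ss = float((s**2 / lam2).sum())
                tau_s = np.exp(
                    _slice_sample_log_scale(
                        lambda v: _scale_logpost(v, n_s, ss, config.tau_s_scale), np.log(tau_s), rng
                    )
                )
                # interweaved (non-centered) tau_s update: with w = s / tau_s
                # held fixed, the conditional of tau_s is conjugate -- a
                # truncated Normal -- because tau_s enters the likelihood
                # linearly through s = tau_s * w. Re-scaling s afterwards moves
                # the whole s field coherently with its scale, which breaks the
                # tau_s -> 0 funnel that defeats purely centered Gibbs updates.
                w = s / tau_s
                w_sum = w.sum(axis=1)
                prec_t = (
                    float((wP * w**2).sum())
                    + float((w_sum**2).sum()) * inv_sz2
                    + 1.0 / config.tau_s_scale**2
                )
                num_t = float((wP * (P - alpha[:, None] - cc[:, None]) * w).sum())
                m_t, sd_t = num_t / prec_t, 1.0 / np.sqrt(prec_t)
                lo_u = ndtr(-m_t / sd_t)
                tau_s = m_t + sd_t * ndtri(lo_u + (1.0 - lo_u) * rng.random())
                tau_s = max(tau_s, 1e-8)
                s = tau_s * w
            if not use_se_a:
                ss = float((((A - alpha[:, None]) * MA) ** 2).sum())
                sigma_a = np.exp(
                    _slice_sample_log_scale(
                        lambda v: _scale_logpost(v, n_obs_a, ss, config.sigma_scale), np.log(sigma_a), rng
                    )
                )
            ss = float((alpha**2).sum())
            tau_alpha = np.exp(
                _slice_sample_log_scale(
                    lambda v: _scale_logpost(v, n_alpha, ss, config.tau_alpha_scale), np.log(tau_alpha), rng
                )
            )
            ss = float((cc**2).sum())
            tau_c = np.exp(
                _slice_sample_log_scale(
                    lambda v: _scale_logpost(v, n_alpha, ss, config.tau_c_scale), np.log(tau_c), rng
                )
            )
            # interweaved tau_alpha / tau_c updates (non-centered, truncated
            # Normal conditionals), as for tau_s: prevents the tau -> 0 funnel
            # when the true effects are near zero
            w = alpha / tau_alpha
            prec_t = (
                float((wA * w[:, None] ** 2).sum())
                + float((wP * w[:, None] ** 2).sum())
                + 1.0 / config.tau_alpha_scale**2
            )
            num_t = float((wA * A * w[:, None]).sum()) + float(
                (wP * (P - cc[:, None] - s) * w[:, None]).sum()
            )
            m_t, sd_t = num_t / prec_t, 1.0 / np.sqrt(prec_t)
            lo_u = ndtr(-m_t / sd_t)
            tau_alpha = max(m_t + sd_t * ndtri(lo_u + (1.0 - lo_u) * rng.random()), 1e-8)
            alpha = tau_alpha * w
            w = cc / tau_c
            prec_t = float((wP * w[:, None] ** 2).sum()) + 1.0 / config.tau_c_scale**2
            num_t = float((wP * (P - alpha[:, None] - s) * w[:, None]).sum())
            m_t, sd_t = num_t / prec_t, 1.0 / np.sqrt(prec_t)
            lo_u = ndtr(-m_t / sd_t)
            tau_c = max(m_t + sd_t * ndtri(lo_u + (1.0 - lo_u) * rng.random()), 1e-8)
            cc = tau_c * w
            if sweep >= T:
                d = sweep - T
                store["alpha"][chain, d] = alpha
                store["c"][chain, d] = cc
                store["s"][chain, d] = s
                store["sigma_p"][chain, d] = sigma_p
                store["sigma_a"][chain, d] = sigma_a
                store["tau_alpha"][chain, d] = tau_alpha
                store["tau_c"][chain, d] = tau_c
                store["tau_s"][chain, d] = tau_s

    draws = PosteriorDraws(tensor=tensor, config=config, **store)
    draws.diagnostics, draws.converged = _diagnose(draws, config)
    return draws


def _diagnose(draws: PosteriorDraws, config: DecompositionModelConfig) -> tuple[pd.DataFrame, bool]:
    """Split R-hat and bulk ESS for every parameter block (via arviz)."""
    idata = az.from_dict(
        posterior={
            "alpha": draws.alpha,
            "c": draws.c,
            "s": draws.s,
            "sigma_p": draws.sigma_p,
            "sigma_a": draws.sigma_a,
            "tau_alpha": draws.tau_alpha,
            "tau_c": draws.tau_c,
            "tau_s": draws.tau_s,
        }
    )
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = []
    for name in ("alpha", "c", "s", "sigma_p", "sigma_a", "tau_alpha", "tau_c", "tau_s"):
        draws_arr = getattr(draws, name)
        if np.ptp(draws_arr) == 0:  # held fixed, not sampled
            continue
        r = np.asarray(rhat[name]).ravel()
        e = np.asarray(ess[name]).ravel()
        rows.append(
            {"parameter": name, "max_rhat": float(np.nanmax(r)), "min_ess": float(np.nanmin(e))}
        )
    diag = pd.DataFrame(rows)
    converged = bool((diag["max_rhat"] <= config.rhat_max).all())
    return diag, converged


# --------------------------------------------------------------------------
# posterior summaries and significance
# --------------------------------------------------------------------------


def _summary_rows(flat: np.ndarray, config: DecompositionModelConfig):
    lo_q = (1.0 - config.ci_level) / 2.0
    mean = flat.mean(axis=0)
    ci_low = np.quantile(flat, lo_q, axis=0)
    ci_high = np.quantile(flat, 1.0 - lo_q, axis=0)
    p_pos = (flat > 0).mean(axis=0)
    dir_prob = np.maximum(p_pos, 1.0 - p_pos)
    return mean, ci_low, ci_high, dir_prob


def summarize_posterior(draws: PosteriorDraws, config: DecompositionModelConfig | None = None) -> pd.DataFrame:
    """Posterior mean, credible interval, directional probability and lfsr
    for every observed effect cell (alpha and c per kinase/position/mutation,
    s additionally per substrate)."""
    config = config or draws.config
    t = draws.tensor
    has_alpha = (t.mask_abundance.sum(axis=1) + t.mask_phospho.sum(axis=1)) > 0
    rows = []
    for comp in ("alpha", "c"):
        mean, lo, hi, dp = _summary_rows(draws.flat(comp), config)
        for i, k, l in zip(*np.nonzero(has_alpha)):
            rows.append(
                {
                    "component": comp, "kinase": t.kinases[i], "substrate": "",
                    "position": t.positions[k], "mutation": t.mutations[l],
                    "mean": mean[i, k, l], "ci_low": lo[i, k, l], "ci_high": hi[i, k, l],
                    "dir_prob": dp[i, k, l], "lfsr": 1.0 - dp[i, k, l],
                }
            )
    mean, lo, hi, dp = _summary_rows(draws.flat("s"), config)
    for i, j, k, l in zip(*np.nonzero(t.mask_phospho)):
        rows.append(
            {
                "component": "s", "kinase": t.kinases[i], "substrate": t.substrates[j],
                "position": t.positions[k], "mutation": t.mutations[l],
                "mean": mean[i, j, k, l], "ci_low": lo[i, j, k, l], "ci_high": hi[i, j, k, l],
                "dir_prob": dp[i, j, k, l], "lfsr": 1.0 - dp[i, j, k, l],
            }
        )
    return pd.DataFrame(rows)


def sample_specificity_prior(config: DecompositionModelConfig, n: int, seed_offset: int = 9001) -> np.ndarray:
    """Seeded draws from the marginal prior of s.

    tau_s is either fixed at ``tau_s_scale`` or drawn Half-Normal(tau_s_scale)
    (hierarchical mode); with finite ``s_df`` a per-draw Inverse-Gamma local
    variance gives a Student-t marginal: s ~ Normal(0, tau^2 lambda^2).
    """
    rng = np.random.default_rng(config.seed + seed_offset)
    if config.tau_s_mode == "hierarchical":
        tau = np.abs(rng.normal(0.0, config.tau_s_scale, size=n))
    else:
        tau = np.full(n, config.tau_s_scale)
    nu = config.s_df
    if np.isfinite(nu):
        lam2 = (nu / 2.0) / rng.gamma(nu / 2.0, 1.0, size=n)
    else:
        lam2 = np.ones(n)
    return rng.normal(0.0, tau * np.sqrt(lam2))


def flag_specificity_effects(
    draws: PosteriorDraws,
    config: DecompositionModelConfig | None = None,
    prior_draws: np.ndarray | None = None,
) -> pd.DataFrame:
    """Dual-threshold significance calls for specificity effects.

    significant <=> directional probability >= ``directional_prob`` AND a
    two-sample KS test rejects equality of the posterior with matched seeded
    prior draws at ``ks_alpha``.
    """
    config = config or draws.config
    t = draws.tensor
    flat = draws.flat("s")  # (N, I, J, K, L)
    if prior_draws is None:
        prior_draws = sample_specificity_prior(config, flat.shape[0])
    p_pos = (flat > 0).mean(axis=0)
    dir_prob = np.maximum(p_pos, 1.0 - p_pos)
    mean = flat.mean(axis=0)
    rows = []
    for i, j, k, l in zip(*np.nonzero(t.mask_phospho)):
        post = flat[:, i, j, k, l]
        ks = ks_2samp(post, prior_draws)
        dp = dir_prob[i, j, k, l]
        sig = bool(dp >= config.directional_prob and ks.pvalue < config.ks_alpha)
        rows.append(
            {
                "kinase": t.kinases[i], "substrate": t.substrates[j],
                "position": t.positions[k], "mutation": t.mutations[l],
                "mean": mean[i, j, k, l], "dir_prob": dp, "lfsr": 1.0 - dp,
                "ks_stat": ks.statistic, "ks_p": ks.pvalue, "significant": sig,
            }
        )
    return pd.DataFrame(rows)
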