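"""Bayesian binary mixed models with phylogenetic random effects.

The event model is a logistic regression on the latent scale,

    logit P(y_i = 1) = x_i' beta + a_{s(i)} + b_{s(i)} + c_{cell(i)}
                       + d_{country(i)} + e_i,

with a ~ N(0, sigma_p^2 A) for phylogenetic covariance A (expected
between-species correlation under Brownian motion: shared root-path
length over tree depth), iid species, cell and country effects, and a
residual e with variance fixed at 1 on the latent scale (binary models
leave it non-identifiable).  Variance components carry univariate
inverse-Wishart priors (V = 1, nu = 0.002), i.e. inverse-gamma with
shape nu/2 and scale nu*V/2.

Sampling uses Polya-Gamma data augmentation, which makes every
conditional conjugate: given omega_i ~ PG(1, psi_i), the likelihood is
Gaussian in the linear predictor and beta, the random-effect vectors and
the variances have closed-form updates.  PG variates are drawn by the
truncated infinite-sum-of-gammas representation with a deterministic
tail-mean correction (truncation depth configurable).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LOGIT_VARIANCE = np.pi**2 / 3  # distribution-specific variance of the logistic link


class PhyloError(ValueError):
    pass


@dataclass
class PhyloCovariance:
    species: list[str]
    matrix: np.ndarray  # symmetric, unit diagonal for ultrametric trees

    @classmethod
    def identity(cls, species: list[str]) -> "PhyloCovariance":
        return cls(species=list(species), matrix=np.eye(len(species)))


def phylo_correlation(
    tree: "dendropy.Tree | str | Path", species: list[str], tol: float = 1e-6
) -> PhyloCovariance:
    """Brownian-motion correlation matrix from a phylogeny.

    A[i, j] is the shared root-to-MRCA path length divided by tree
    depth; for an ultrametric tree the diagonal is exactly 1.  Trees
    that are not ultrametric within tolerance are depth-normalised per
    pair with a warning.  Missing tips are a hard error.
    """
    if not isinstance(tree, dendropy.Tree):
        src = str(tree)
        if "(" in src:
            tree = dendropy.Tree.get(data=src, schema="newick", preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(path=src, schema="newick", preserve_underscores=True)
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [s for s in species if s not in taxa]
    if missing:
        raise PhyloError(f"species missing from tree: {missing}")

    pdm = tree.phylogenetic_distance_matrix()
    depths = {}
    for leaf in tree.leaf_node_iter():
        depths[leaf.taxon.label] = leaf.distance_from_root()
    dvals = np.array([depths[s] for s in species])
    mean_depth = float(dvals.mean())
    if mean_depth <= 0:
        raise PhyloError("tree has zero depth")
    if np.ptp(dvals) > tol * mean_depth:
        warnings.warn("tree is not ultrametric; depth-normalising shared paths")

    n = len(species)
    A = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[species[i]], taxa[species[j]])
            shared = (dvals[i] + dvals[j] - d) / 2.0
            A[i, j] = A[j, i] = max(shared, 0.0) / np.sqrt(dvals[i] * dvals[j])
    return PhyloCovariance(species=list(species), matrix=A)


@dataclass
class MCMCConfig:
    """Chain length and priors for the Gibbs sampler.

    The full-scale default (220,000 iterations, 20,000 burn-in, thinning
    interval 200) retains 1000 draws.  ``desk()`` keeps the same
    retained-draw count at a tenth of the iterations for small synthetic
    tables, and ``quick()`` at a fiftieth for repeated simulation
    studies; both are stated problem-size choices, not approximations of
    a different model.
    """

    iterations: int = 220_000
    burn_in: int = 20_000
    thin: int = 200
    prior_v: float = 1.0
    prior_nu: float = 0.002
    residual_variance: float = 1.0
    beta_prior_variance: float = 100.0
    pg_truncation: int = 32
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_retained < 100:
            raise ValueError(
                f"only {self.n_retained} retained draws; need at least 100"
            )

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin

    @classmethod
    def desk(cls, seed: int | None = None) -> "MCMCConfig":
        return cls(iterations=22_000, burn_in=2_000, thin=20, seed=seed)

    @classmethod
    def quick(cls, seed: int | None = None) -> "MCMCConfig":
        return cls(iterations=4_400, burn_in=400, thin=4, seed=seed)


@dataclass
class PosteriorDraws:
    """Retained draws from one model run."""

    beta: pd.DataFrame  # one column per fixed effect
    variances: pd.DataFrame  # sigma2_phylo, sigma2_species, sigma2_cell, sigma2_country
    X: np.ndarray  # the fixed-effect design the model was fitted to
    config: MCMCConfig
    rhat: pd.Series = field(default=None)


def _sample_pg(c: np.ndarray, rng: np.random.Generator, K: int) -> np.ndarray:
    """Approximate PG(1, c) draws via the truncated sum-of-gammas series.

    omega = (1/2 pi^2) sum_k g_k / ((k - 1/2)^2 + c^2 / 4 pi^2) for
    g_k ~ Exp(1), truncated at K terms plus the deterministic mean of
    the dropped tail (keeps E[omega] exact).
    """
    c = np.abs(np.asarray(c, dtype=float))
    ks = (np.arange(1, K + 1) - 0.5) ** 2  # (K,)
    denom = ks[:, None] + (c**2) / (4 * np.pi**2)  # (K, n)
    g = rng.standard_exponential(size=denom.shape)
    trunc = (g / denom).sum(axis=0) / (2 * np.pi**2)
    mean_full = np.where(c < 1e-8, 0.25, np.tanh(c / 2) / (2 * np.clip(c, 1e-8, None)))
    mean_trunc = (1.0 / denom).sum(axis=0) / (2 * np.pi**2)
    return trunc + np.maximum(mean_full - mean_trunc, 0.0)


def sample_variance_component(
    rng: np.random.Generator, quad_form: float, q: int, nu: float, v: float,
    floor: float = 1e-10,
) -> float:
    """Conjugate inverse-gamma draw for one variance component.

    Prior IG(nu/2, nu*v/2) (the univariate inverse-Wishart(V, nu));
    posterior IG(nu/2 + q/2, (nu*v + u' K^-1 u)/2) given the q-vector of
    effects with prior covariance sigma^2 K.
    """
    shape = nu / 2.0 + q / 2.0
    scale = (nu * v + quad_form) / 2.0
    return max(1.0 / rng.gamma(shape, 1.0 / scale), floor)


def _group_index(values: pd.Series) -> tuple[np.ndarray, list]:
    levels = sorted(values.unique())
    lookup = {v: i for i, v in enumerate(levels)}
    return values.map(lookup).to_numpy(), levels


def _split_rhat(draws: np.ndarray) -> float:
    """Potential scale reduction from the two halves of a single chain."""
    n = len(draws) // 2
    halves = np.stack([draws[:n], draws[n : 2 * n]])
    w = halves.var(axis=1, ddof=1).mean()
    b = n * halves.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    return float(np.sqrt((w * (n - 1) / n + b / n) / w))


def design_matrix(
    rows: pd.DataFrame, fixed_effects: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + named covariates; categoricals expand to 0/1 dummies."""
    cols = [np.ones(len(rows))]
    names = ["intercept"]
    for name in fixed_effects:
        col = rows[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.dropna().unique())
            for lev in levels[1:]:
                cols.append((col == lev).to_numpy(dtype=float))
                names.append(f"{name}[{lev}]")
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
    return np.column_stack(cols), names


def fit_binary_mixed(
    rows: pd.DataFrame,
    A: PhyloCovariance,
    fixed_effects: list[str],
    config: MCMCConfig | None = None,
) -> PosteriorDraws:
    """Gibbs sampler for the binary mixed model.

    ``rows`` must contain ``response``, ``species_id``, ``cell_id``,
    ``country`` and every fixed-effect column; all species must appear
    in ``A``.  Perfect separation does not crash the sampler, it simply
    yields a prior-dominated posterior for the offending coefficient.
    """
    config = config or MCMCConfig()
    rng = np.random.default_rng(config.seed)

    y = rows["response"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("response contains a single class")
    X, names = design_matrix(rows, fixed_effects)
    n, p = X.shape

    sp_order = list(A.species)
    missing = set(rows["species_id"]) - set(sp_order)
    if missing:
        raise PhyloError(f"rows reference species absent from A: {sorted(missing)}")
    sp_lookup = {s: i for i, s in enumerate(sp_order)}
    sp_idx = rows["species_id"].map(sp_lookup).to_numpy()
    q_sp = len(sp_order)
    if q_sp < 2:
        raise ValueError("need at least two species")
    cell_idx, cell_levels = _group_index(rows["cell_id"])
    ctry_idx, ctry_levels = _group_index(rows["country"])
    q_cell, q_ctry = len(cell_levels), len(ctry_levels)

    Amat = A.matrix + 1e-8 * np.eye(q_sp)
    Ainv = np.linalg.inv(Amat)

    kappa = y - 0.5
    beta = np.zeros(p)
    u_phylo = np.zeros(q_sp)
    u_sp = np.zeros(q_sp)
    u_cell = np.zeros(q_cell)
    u_ctry = np.zeros(q_ctry)
    e = np.zeros(n)
    sig = {"phylo": 1.0, "species": 1.0, "cell": 1.0, "country": 1.0}
    sig_e = config.residual_variance

    n_keep = config.n_retained
    beta_draws = np.empty((n_keep, p))
    var_draws = np.empty((n_keep, 4))
    keep = 0

    def gsum(idx, vals, size):
        return np.bincount(idx, weights=vals, minlength=size)

    for it in range(config.iterations):
        xb = X @ beta
        psi = xb + u_phylo[sp_idx] + u_sp[sp_idx] + u_cell[cell_idx] + u_ctry[ctry_idx] + e
        omega = _sample_pg(psi, rng, config.pg_truncation)

        # beta
        offset = psi - xb
        prec = X.T @ (X * omega[:, None]) + np.eye(p) / config.beta_prior_variance
        rhs = X.T @ (kappa - omega * offset)
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, rhs)
        beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))
        xb = X @ beta

        # phylogenetic species effect (dense q x q solve)
        offset = xb + u_sp[sp_idx] + u_cell[cell_idx] + u_ctry[ctry_idx] + e
        t_sp = gsum(sp_idx, omega, q_sp)
        rhs = gsum(sp_idx, kappa - omega * offset, q_sp)
        prec = np.diag(t_sp) + Ainv / sig["phylo"]
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, rhs)
        u_phylo = mean + np.linalg.solve(L.T, rng.standard_normal(q_sp))

        # iid species effect
        offset = xb + u_phylo[sp_idx] + u_cell[cell_idx] + u_ctry[ctry_idx] + e
        prec_d = gsum(sp_idx, omega, q_sp) + 1.0 / sig["species"]
        rhs = gsum(sp_idx, kappa - omega * offset, q_sp)
        u_sp = rhs / prec_d + rng.standard_normal(q_sp) / np.sqrt(prec_d)

        # cell effect
        offset = xb + u_phylo[sp_idx] + u_sp[sp_idx] + u_ctry[ctry_idx] + e
        prec_d = gsum(cell_idx, omega, q_cell) + 1.0 / sig["cell"]
        rhs = gsum(cell_idx, kappa - omega * offset, q_cell)
        u_cell = rhs / prec_d + rng.standard_normal(q_cell) / np.sqrt(prec_d)

        # country effect
        offset = xb + u_phylo[sp_idx] + u_sp[sp_idx] + u_cell[cell_idx] + e
        prec_d = gsum(ctry_idx, omega, q_ctry) + 1.0 / sig["country"]
        rhs = gsum(ctry_idx, kappa - omega * offset, q_ctry)
        u_ctry = rhs / prec_d + rng.standard_normal(q_ctry) / np.sqrt(prec_d)

        # residual (fixed variance)
        offset = xb + u_phylo[sp_idx] + u_sp[sp_idx] + u_cell[cell_idx] + u_ctry[ctry_idx]
        prec_d = omega + 1.0 / sig_e
        e = (kappa - omega * offset) / prec_d + rng.standard_normal(n) / np.sqrt(prec_d)

        # variance components: conjugate inverse-gamma
        nu, v = config.prior_nu, config.prior_v
        sig["phylo"] = sample_variance_component(
            rng, float(u_phylo @ Ainv @ u_phylo), q_sp, nu, v
        )
        sig["species"] = sample_variance_component(rng, float(u_sp @ u_sp), q_sp, nu, v)
        sig["cell"] = sample_variance_component(rng, float(u_cell @ u_cell), q_cell, nu, v)
        sig["country"] = sample_variance_component(
            rng, float(u_ctry @ u_ctry), q_ctry, nu, v
        )

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 and keep < n_keep:
            beta_draws[keep] = beta
            var_draws[keep] = [sig["phylo"], sig["species"], sig["cell"], sig["country"]]
            keep += 1

    beta_df = pd.DataFrame(beta_draws[:keep], columns=names)
    var_df = pd.DataFrame(
        var_draws[:keep],
        columns=["sigma2_phylo", "sigma2_species", "sigma2_cell", "sigma2_country"],
    )
    rhat = pd.Series({c: _split_rhat(beta_df[c].to_numpy()) for c in beta_df.columns})
    if (rhat > 1.1).any():
        worst = rhat.idxmax()
        warnings.warn(
            f"split-chain R-hat {rhat.max():.3f} for {worst!r} exceeds 1.1; "
            "chain may not have converged"
        )
    return PosteriorDraws(beta=beta_df, variances=var_df, X=X, config=config, rhat=rhat)


# -- derived quantities -------------------------------------------------


def marginal_r2(draws: PosteriorDraws) -> np.ndarray:
    """Per-draw marginal R^2 (fixed-effect variance over total variance).

    R2m = var(X beta) / (var(X beta) + sum of random-effect variances
    + fixed residual variance + pi^2/3).
    """
    X = draws.X
    betas = draws.beta.to_numpy()
    var_f = (X @ betas.T).var(axis=0, ddof=0)
    var_r = draws.variances.to_numpy().sum(axis=1)
    denom = var_f + var_r + draws.config.residual_variance + LOGIT_VARIANCE
    return var_f / denom


def variance_shares(draws: PosteriorDraws, include_intercept: bool = False) -> pd.DataFrame:
    """Per-predictor percentage of the explained (fixed-effect) variance.

    share_k = var(x_k beta_k) / sum_j var(x_j beta_j) per draw, as a
    percentage.  Draws with zero total fixed variance are skipped (count
    logged).  The intercept has zero variance by construction and is
    excluded unless requested.
    """
    cols = list(draws.beta.columns)
    if not include_intercept and "intercept" in cols:
        cols = [c for c in cols if c != "intercept"]
    idx = [list(draws.beta.columns).index(c) for c in cols]
    x_var = draws.X[:, idx].var(axis=0, ddof=0)  # (p,)
    betas = draws.beta.to_numpy()[:, idx]  # (n_draws, p)
    per = (betas**2) * x_var[None, :]
    total = per.sum(axis=1)
    ok = total > 0
    if (~ok).any():
        logger.info("skipped %d all-zero fixed-variance draws", int((~ok).sum()))
    shares = 100.0 * per[ok] / total[ok, None]
    return pd.DataFrame(shares, columns=cols)


@dataclass
class PosteriorSummary:
    fixed_effects: pd.DataFrame  # mean, sd, q2.5, q97.5, excludes_zero per effect
    variance_components: pd.Series
    r2_per_run: np.ndarray
    r2_mean: float
    r2_sd: float
    shares: pd.DataFrame  # median, iqr_low/high, q2.5, q97.5 per predictor
    n_runs: int


def combine_runs(runs: list[PosteriorDraws]) -> PosteriorSummary:
    """Pool posterior draws across trees x absence resamples, equal weight.

    Fixed-effect and variance summaries use the concatenated draws;
    marginal R^2 is summarised per run (mean, SD across runs) and the
    per-predictor variance shares across all pooled draws.
    """
    if not runs:
        raise ValueError("no runs to combine")
    beta = pd.concat([r.beta for r in runs], ignore_index=True)
    variances = pd.concat([r.variances for r in runs], ignore_index=True)
    fixed = pd.DataFrame(
        {
            "mean": beta.mean(),
            "sd": beta.std(ddof=1),
            "q2.5": beta.quantile(0.025),
            "q97.5": beta.quantile(0.975),
        }
    )
    fixed["excludes_zero"] = (fixed["q2.5"] > 0) | (fixed["q97.5"] < 0)
    r2_runs = np.array([float(np.mean(marginal_r2(r))) for r in runs])
    shares_all = pd.concat([variance_shares(r) for r in runs], ignore_index=True)
    shares = pd.DataFrame(
        {
            "median": shares_all.median(),
            "iqr_low": shares_all.quantile(0.25),
            "iqr_high": shares_all.quantile(0.75),
            "q2.5": shares_all.quantile(0.025),
            "q97.5": shares_all.quantile(0.975),
        }
    )
    return PosteriorSummary(
        fixed_effects=fixed,
        variance_components=variances.mean(),
        r2_per_run=r2_runs,
        r2_mean=float(r2_runs.mean()),
        r2_sd=float(r2_runs.std(ddof=1)) if len(r2_runs) > 1 else 0.0,
        shares=shares,
        n_runs=len(runs),
    )
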