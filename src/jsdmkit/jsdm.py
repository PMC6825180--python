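"""Multivariate probit joint species distribution model (JSDM).

Model
-----
For site *i* with predictor vector ``x_i`` and species *j*:

    y_ij = 1[z_ij > 0],    z_i ~ Normal(alpha + B x_i, R)

where ``R`` is a species-by-species residual *correlation* matrix.  The
off-diagonals of ``R`` capture co-occurrence beyond the shared environmental
response — the quantity ecologists read as a signal of biotic association —
while the similarity of two species' environmental linear predictors across
sites (their Pearson correlation) is the *environmental* correlation.

Sampler
-------
A Gibbs sampler with the Albert–Chib latent-variable augmentation:

(a) each latent ``z_ij`` is drawn from its full conditional — a univariate
    normal given the other species' latents (mean/variance from the
    partitioned ``R``), truncated to ``(0, inf)`` if ``y_ij = 1`` and
    ``(-inf, 0]`` otherwise;
(b) the coefficients ``(alpha, B)`` are drawn jointly from their conjugate
    multivariate-normal full conditional under independent
    ``Normal(0, prior_scale^2)`` priors;
(c) an *expanded* residual covariance is drawn from its inverse-Wishart full
    conditional given the latent residuals and rescaled to correlation form,
    with the latents and coefficients rescaled accordingly (parameter
    expansion, which restores the unit-variance identification of the probit).

With a single species the correlation matrix is identically 1, step (c) is a
no-op and the sampler reduces exactly to the univariate Albert–Chib probit.

Chains use seed streams spawned from the master seed by fixed offsets; draws
are retained after burn-in at the thinning interval, chain by chain, so
posteriors are bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from .tables import SiteTable

log = logging.getLogger(__name__)

_TINY = 1e-15


class JSDMError(ValueError):
    """Raised for invalid JSDM specifications or unidentifiable data."""


@dataclass
class JSDMSpec:
    """MCMC run configuration.

    Defaults follow the full-scale protocol (5 chains of 1,000,000 iterations,
    burn-in 15,000, thinning 1,000).  ``desk_preset`` gives a configuration
    sized for interactive use and tests.  ``prior_scale`` is the sd of the
    Normal(0, scale^2) prior on intercepts and coefficients (standardized
    predictors assumed); ``wishart_df`` defaults to species-count + 1 with an
    identity scale matrix.  ``fix_identity=True`` freezes R at the identity
    (diagnostic switch: the model then factorizes into independent probits).
    """

    chains: int = 5
    iterations: int = 1_000_000
    burn_in: int = 15_000
    thin: int = 1_000
    prior_scale: float = 10.0
    wishart_df: int | None = None
    seed: int = 0
    fix_identity: bool = False

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise JSDMError("chains must be >= 1")
        if not (self.iterations > self.burn_in >= 0):
            raise JSDMError("need iterations > burn_in >= 0")
        if self.thin < 1:
            raise JSDMError("thinning factor must be >= 1")
        if self.prior_scale <= 0:
            raise JSDMError("prior_scale must be positive")

    @property
    def draws_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


def paper_preset(**kw) -> JSDMSpec:
    """The full-scale protocol: 5 chains x 1e6 iterations, burn 15k, thin 1k."""
    return JSDMSpec(**kw)


def desk_preset(**kw) -> JSDMSpec:
    """Desk-scale preset: 4 chains x 20,000 iterations, burn 5,000, thin 10."""
    defaults = dict(chains=4, iterations=20_000, burn_in=5_000, thin=10)
    defaults.update(kw)
    return JSDMSpec(**defaults)


def _truncnorm_draw(rng: np.random.Generator, mean: np.ndarray,
                    sd: float, positive: np.ndarray) -> np.ndarray:
    """Vectorized one-sided truncated-normal draws via inverse CDF.

    ``positive`` marks entries truncated to (0, inf); the rest are (-inf, 0].
    Uniforms are clipped away from {0, 1} for numerical safety in deep tails.
    """
    p0 = ndtr(-mean / sd)  # P(z <= 0)
    u = rng.random(mean.shape)
    q = np.where(positive, p0 + u * (1.0 - p0), u * p0)
    np.clip(q, _TINY, 1.0 - _TINY, out=q)
    return mean + sd * ndtri(q)


def _invwishart_draw(rng: np.random.Generator, df: int,
                     scale: np.ndarray) -> np.ndarray:
    """Inverse-Wishart(df, scale) draw via the Bartlett decomposition.

    With ``A A' ~ Wishart(df, I)`` (A lower-triangular Bartlett factor) and
    ``L L' = scale``, the matrix ``L (A A')^{-1} L'`` is IW(df, scale).
    """
    J = scale.shape[0]
    A = np.zeros((J, J))
    A[np.tril_indices(J, -1)] = rng.standard_normal(J * (J - 1) // 2)
    A[np.diag_indices(J)] = np.sqrt(rng.chisquare(df - np.arange(J)))
    L = np.linalg.cholesky(scale)
    M = solve_triangular(A, L.T, lower=True, check_finite=False)  # A^{-1} L'
    return M.T @ M


@dataclass
class JSDMPosterior:
    """Retained MCMC draws plus the site table the model was fitted to."""

    species: list[str]
    predictors: list[str]
    alpha: np.ndarray   # (D, J)
    beta: np.ndarray    # (D, J, P)
    rcorr: np.ndarray   # (D, J, J)
    chain: np.ndarray   # (D,) chain index of each draw
    sites: SiteTable
    spec: JSDMSpec

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_chains(self) -> int:
        return int(self.chain.max()) + 1 if len(self.chain) else 0

    def posterior_mean_alpha(self) -> pd.Series:
        return pd.Series(self.alpha.mean(axis=0), index=self.species)

    def posterior_mean_beta(self) -> pd.DataFrame:
        return pd.DataFrame(self.beta.mean(axis=0), index=self.species,
                            columns=self.predictors)

    def posterior_mean_rcorr(self) -> pd.DataFrame:
        return pd.DataFrame(self.rcorr.mean(axis=0), index=self.species,
                            columns=self.species)

    def site_probability(self, X: pd.DataFrame, species: str,
                         mode: str = "draws") -> np.ndarray:
        """Marginal occurrence probability Phi(alpha_j + B_j . x) per site.

        ``mode="draws"`` averages the probability over retained draws (the
        default); ``mode="plugin"`` plugs in posterior means.
        """
        j = self.species.index(species)
        Xa = X[self.predictors].to_numpy(dtype=float)
        if mode == "plugin":
            eta = self.alpha[:, j].mean() + Xa @ self.beta[:, j, :].mean(axis=0)
            return norm.cdf(eta)
        if mode != "draws":
            raise JSDMError(f"unknown prediction mode {mode!r}")
        out = np.zeros(len(Xa))
        step = max(1, 200)
        for s in range(0, self.n_draws, step):
            a = self.alpha[s:s + step, j]                    # (d,)
            b = self.beta[s:s + step, j, :]                  # (d, P)
            out += norm.cdf(a[None, :] + Xa @ b.T).sum(axis=1)
        return out / self.n_draws

    # -- I/O (flat tables with draw/chain indices) --------------------------
    def write_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        D, J, P = self.n_draws, len(self.species), len(self.predictors)
        idx = pd.MultiIndex.from_product(
            [range(D)], names=["draw"]).to_frame(index=False)
        alpha = pd.DataFrame(self.alpha, columns=self.species)
        alpha.insert(0, "chain", self.chain)
        alpha.insert(0, "draw", idx["draw"])
        alpha.to_csv(path / "alpha.csv", index=False)
        beta = pd.DataFrame(self.beta.reshape(D, J * P),
                            columns=[f"{s}:{p}" for s in self.species
                                     for p in self.predictors])
        beta.insert(0, "chain", self.chain)
        beta.insert(0, "draw", idx["draw"])
        beta.to_csv(path / "beta.csv", index=False)
        rc = pd.DataFrame(self.rcorr.reshape(D, J * J),
                          columns=[f"{a}:{b}" for a in self.species
                                   for b in self.species])
        rc.insert(0, "chain", self.chain)
        rc.insert(0, "draw", idx["draw"])
        rc.to_csv(path / "rcorr.csv", index=False)
        (path / "posterior.json").write_text(json.dumps({
            "species": self.species, "predictors": self.predictors,
            "spec": {k: getattr(self.spec, k) for k in
                     ("chains", "iterations", "burn_in", "thin",
                      "prior_scale", "seed", "fix_identity")},
        }, indent=2))
        self.sites.write(path / "sites.csv")

    @classmethod
    def read_dir(cls, path: str | Path) -> "JSDMPosterior":
        path = Path(path)
        meta = json.loads((path / "posterior.json").read_text())
        species, predictors = meta["species"], meta["predictors"]
        J, P = len(species), len(predictors)
        alpha = pd.read_csv(path / "alpha.csv")
        beta = pd.read_csv(path / "beta.csv")
        rc = pd.read_csv(path / "rcorr.csv")
        D = len(alpha)
        return cls(
            species=species, predictors=predictors,
            alpha=alpha[species].to_numpy(),
            beta=beta.drop(columns=["draw", "chain"]).to_numpy().reshape(D, J, P),
            rcorr=rc.drop(columns=["draw", "chain"]).to_numpy().reshape(D, J, J),
            chain=alpha["chain"].to_numpy(),
            sites=SiteTable.read(path / "sites.csv"),
            spec=JSDMSpec(**meta["spec"]),
        )


def _run_chain(Y: np.ndarray, W: np.ndarray, spec: JSDMSpec,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray,
                                                  np.ndarray]:
    """One chain of the Gibbs sampler.

    Returns ``(gamma draws, R draws, retained count)``.  ``W`` is the design
    with leading intercept column; ``gamma`` is the (J, K) coefficient matrix
    with K = P + 1 (intercept first).
    """
    n, J = Y.shape
    K = W.shape[1]
    nu0 = spec.wishart_df if spec.wishart_df is not None else J + 1
    WtW = W.T @ W
    prior_prec = 1.0 / spec.prior_scale ** 2
    positive = Y.astype(bool)

    gamma = np.zeros((J, K))
    R = np.eye(J)
    # initialize latents consistent with the response signs
    Z = np.where(positive, 0.5, -0.5) + 0.1 * rng.standard_normal((n, J))
    Z = np.where(positive, np.abs(Z), -np.abs(Z))

    n_keep = spec.draws_per_chain
    g_draws = np.empty((n_keep, J, K))
    r_draws = np.empty((n_keep, J, J))
    keep = 0

    eye_jk = prior_prec * np.eye(J * K)
    eye_j = np.eye(J)
    for it in range(1, spec.iterations + 1):
        Mu = W @ gamma.T  # (n, J)
        Rinv = np.linalg.inv(R) if J > 1 else np.ones((1, 1))

        # (a) latent truncated-normal sweep, species by species
        if J == 1:
            Z[:, 0] = _truncnorm_draw(rng, Mu[:, 0], 1.0, positive[:, 0])
        else:
            resid = Z - Mu
            for j in range(J):
                cond_var = 1.0 / Rinv[j, j]
                coef = -Rinv[j] * cond_var
                coef[j] = 0.0
                cmean = Mu[:, j] + resid @ coef
                Z[:, j] = _truncnorm_draw(rng, cmean, np.sqrt(cond_var),
                                          positive[:, j])
                resid[:, j] = Z[:, j] - Mu[:, j]

        # (b) conjugate (alpha, B) draw: gamma | Z, R
        Q = np.einsum("ik,jl->ijkl", WtW, Rinv).reshape(J * K, J * K) + eye_jk
        rhs = (Rinv @ (Z.T @ W)).flatten(order="F")  # vec(Rinv Z' W)
        Lfac = np.linalg.cholesky(Q)
        half = solve_triangular(Lfac, rhs, lower=True, check_finite=False)
        eta = rng.standard_normal(J * K)
        gamma_vec = solve_triangular(Lfac.T, half + eta, lower=False,
                                     check_finite=False)
        gamma = gamma_vec.reshape((J, K), order="F")

        # (c) parameter-expanded covariance draw, rescaled to correlation
        if J > 1 and not spec.fix_identity:
            E = Z - W @ gamma.T
            S = eye_j + E.T @ E
            Sigma = _invwishart_draw(rng, nu0 + n, S)
            d = np.sqrt(np.diag(Sigma))
            R = Sigma / np.outer(d, d)
            R = (R + R.T) / 2.0
            np.fill_diagonal(R, 1.0)
            np.linalg.cholesky(R)  # positive definiteness guard
            Z /= d[None, :]
            gamma /= d[:, None]

        if not np.all(np.isfinite(gamma)):
            raise JSDMError(
                f"non-finite coefficient draw at iteration {it}; state: "
                f"gamma={gamma!r}")

        if it > spec.burn_in and (it - spec.burn_in) % spec.thin == 0 \
                and keep < n_keep:
            g_draws[keep] = gamma
            r_draws[keep] = R
            keep += 1

    return g_draws[:keep], r_draws[:keep], keep


def fit_jsdm(sites: SiteTable, spec: JSDMSpec | None = None) -> JSDMPosterior:
    """Fit the multivariate probit JSDM by Gibbs sampling.

    Requires every species column of ``Y`` to contain both presences and
    absences (complete separation leaves the probit unidentifiable) and a
    design matrix without missing values.  Chain ``c`` uses the seed stream
    spawned from ``spec.seed`` at offset ``c``.
    """
    spec = spec if spec is not None else desk_preset()
    Y = sites.Y.to_numpy(dtype=float)
    X = sites.X.to_numpy(dtype=float)
    n, J = Y.shape
    for j, sp_name in enumerate(sites.species):
        if Y[:, j].min() == Y[:, j].max():
            raise JSDMError(
                f"species {sp_name!r} is all-{int(Y[0, j])} in the response; "
                "the probit intercept is unidentifiable")
    if not np.all(np.isfinite(X)):
        raise JSDMError("design matrix contains non-finite values")

    W = np.column_stack([np.ones(n), X])
    streams = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    g_all, r_all, chain_idx = [], [], []
    for c in range(spec.chains):
        rng = np.random.default_rng(streams[c])
        g, r, kept = _run_chain(Y, W, spec, rng)
        g_all.append(g)
        r_all.append(r)
        chain_idx.append(np.full(kept, c))
        log.info("chain %d/%d finished: %d retained draws", c + 1,
                 spec.chains, kept)
    g = np.concatenate(g_all)
    r = np.concatenate(r_all)
    return JSDMPosterior(
        species=list(sites.species), predictors=list(sites.predictors),
        alpha=g[:, :, 0], beta=g[:, :, 1:], rcorr=r,
        chain=np.concatenate(chain_idx), sites=sites, spec=spec)


# -- co-occurrence decomposition -------------------------------------------

def residual_correlation(post: JSDMPosterior) -> pd.DataFrame:
    """Posterior mean and sd of each pair's residual correlation R_jk.

    Returns a tidy symmetric summary with one row per ordered pair, columns
    ``species_a, species_b, mean, sd``.
    """
    rows = []
    for a, sa in enumerate(post.species):
        for b, sb in enumerate(post.species):
            draws = post.rcorr[:, a, b]
            rows.append({"species_a": sa, "species_b": sb,
                         "mean": float(draws.mean()),
                         "sd": float(draws.std(ddof=0))})
    return pd.DataFrame(rows)


def _env_linear_predictors(post: JSDMPosterior, X: np.ndarray) -> np.ndarray:
    """Per-draw environmental linear predictors, shape (D, n, J)."""
    return post.alpha[:, None, :] + np.einsum("np,djp->dnj", X, post.beta)


def environmental_correlation(post: JSDMPosterior,
                              X: pd.DataFrame | None = None) -> pd.DataFrame:
    """Between-species correlation of environmental linear predictors.

    For each retained draw, species *j*'s environmental signal is the vector
    ``alpha_j + B_j . x_i`` over sites; the environmental correlation of a
    pair is the Pearson correlation of the two site-vectors, summarized as
    mean +/- sd across draws.  Defaults to the fitted sites; pass ``X`` to
    evaluate over a prediction grid instead.
    """
    Xa = (post.sites.X if X is None else X)[post.predictors] \
        .to_numpy(dtype=float)
    if Xa.shape[0] < 3:
        raise JSDMError("environmental correlation needs at least 3 sites")
    D, J = post.n_draws, len(post.species)
    corr_draws = np.empty((D, J, J))
    lp = _env_linear_predictors(post, Xa)  # (D, n, J)
    for d in range(D):
        L = lp[d]
        sd = L.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(L, rowvar=False)
        c = np.where(np.outer(sd > 0, sd > 0), c, np.nan)
        np.fill_diagonal(c, 1.0)
        corr_draws[d] = c
    rows = []
    for a, sa in enumerate(post.species):
        for b, sb in enumerate(post.species):
            draws = corr_draws[:, a, b]
            rows.append({"species_a": sa, "species_b": sb,
                         "mean": float(np.nanmean(draws)),
                         "sd": float(np.nanstd(draws, ddof=0))})
    return pd.DataFrame(rows)


def cooccurrence_summary(post: JSDMPosterior) -> pd.DataFrame:
    """Per-pair environmental and residual correlation summary.

    One row per unordered species pair with columns ``pair, env_mean, env_sd,
    res_mean, res_sd`` — the layout of the standard environmental-vs-residual
    co-occurrence scatter.
    """
    env = environmental_correlation(post)
    res = residual_correlation(post)
    key = ["species_a", "species_b"]
    merged = env.merge(res, on=key, suffixes=("_env", "_res"))
    merged = merged[merged["species_a"] < merged["species_b"]]
    return pd.DataFrame({
        "pair": merged["species_a"] + ":" + merged["species_b"],
        "env_mean": merged["mean_env"], "env_sd": merged["sd_env"],
        "res_mean": merged["mean_res"], "res_sd": merged["sd_res"],
    }).reset_index(drop=True)


# -- convergence diagnostics ------------------------------------------------

@dataclass
class DiagnosticsReport:
    """Split-chain R-hat and effective sample size per scalar parameter."""

    table: pd.DataFrame
    available: bool
    threshold: float = 1.1

    @property
    def flagged(self) -> list[str]:
        if not self.available:
            return []
        bad = self.table[self.table["rhat"] > self.threshold]
        return list(bad["parameter"])


def _posterior_arrays(post: JSDMPosterior) -> dict[str, np.ndarray]:
    """Scalar parameter draws reshaped to (chain, draw)."""
    C = post.n_chains
    per = [post.chain == c for c in range(C)]
    dmin = min(int(m.sum()) for m in per)
    out: dict[str, np.ndarray] = {}

    def stack(vec: np.ndarray) -> np.ndarray:
        return np.stack([vec[m][:dmin] for m in per])

    for j, sp_name in enumerate(post.species):
        out[f"alpha[{sp_name}]"] = stack(post.alpha[:, j])
        for p, pname in enumerate(post.predictors):
            out[f"beta[{sp_name},{pname}]"] = stack(post.beta[:, j, p])
    for a in range(len(post.species)):
        for b in range(a + 1, len(post.species)):
            name = f"rcorr[{post.species[a]},{post.species[b]}]"
            out[name] = stack(post.rcorr[:, a, b])
    return out


def convergence_check(post: JSDMPosterior,
                      threshold: float = 1.1) -> DiagnosticsReport:
    """Split-chain potential-scale-reduction (R-hat) and ESS per parameter.

    With a single chain the diagnostics are marked unavailable rather than
    raising.  Parameters with R-hat above ``threshold`` are flagged.
    """
    import arviz as az

    arrays = _posterior_arrays(post)
    if post.n_chains < 2:
        table = pd.DataFrame({"parameter": list(arrays),
                              "rhat": np.nan, "ess": np.nan})
        return DiagnosticsReport(table=table, available=False,
                                 threshold=threshold)
    rows = []
    for name, arr in arrays.items():
        if np.allclose(arr.std(), 0):
            rows.append({"parameter": name, "rhat": 1.0,
                         "ess": float(arr.size)})
            continue
        rows.append({"parameter": name,
                     "rhat": float(az.rhat(az.convert_to_dataset(arr))["x"]),
                     "ess": float(az.ess(az.convert_to_dataset(arr))["x"])})
    return DiagnosticsReport(table=pd.DataFrame(rows), available=True,
                             threshold=threshold)
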