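"""Bayesian GBLUP machinery for sparse multi-environment trials.

The single-response model fitted by :func:`fit_gblup` is

    y_ij = mu + L_i + g_j + gL_ij + e_ij

for line j in environment i, with

    L  ~ N(0, sigma2_E  * Omega_E)                     (environment effects)
    g  ~ N(0, sigma2_g  * G)                           (additive line effects)
    gL ~ N(0, sigma2_gL * (Zg G Zg') o (Ze Omega_E Ze'))   (Hadamard G x E)
    e  ~ iid N(0, sigma2_e)

G is the genomic relationship matrix and Omega_E the environment covariance
kernel.  Six constructions of Omega_E are supported (``METHOD_TAGS``):
identity (GBLUP, GBLUP_TRN), and four derived from a first-stage
multi-response fit with an unstructured between-environment covariance
(:func:`fit_multitrait_unstructured`): the genetic covariance (GBLUP_CE),
its elementwise absolute value (GBLUP_CE_Abs), the genetic/residual average
(GBLUP_CE_mean) and the residual covariance (GBLUP_CE_Res).

Sampling strategy: every random effect is re-parameterized in the
eigenbasis of its covariance kernel (K = U D U'), so the effect is
U D^{1/2} a with i.i.d. prior a ~ N(0, sigma2 I).  Because the Gram matrix
W'W of the whitened covariates is fixed across iterations, one
eigendecomposition per term turns every blocked Gibbs update into two
dense matrix-vector products — exact blocked sampling at O(q^2) per
iteration.  The G x E kernel over the full line-by-environment grid is the
Kronecker product Omega_E (x) G, whose eigenstructure is the Kronecker
product of the factors'; test cells ride along as missing-data nodes, so
their interaction effects have proper posterior means for prediction.

Variance components carry scaled-inverse-chi-square priors; the two
covariance matrices of the first stage carry inverse-Wishart priors with
the conventional 5 degrees of freedom and identity scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from sparsemet.markers import KinshipMatrix

__all__ = [
    "PhenoTable",
    "EnvCovariance",
    "MCMCConfig",
    "MultitraitFit",
    "GBLUPFit",
    "METHOD_TAGS",
    "fit_multitrait_unstructured",
    "build_omega",
    "fit_gblup",
    "predict_cells",
    "gebv_across_tpe",
    "read_pheno_csv",
]

METHOD_TAGS = (
    "GBLUP",
    "GBLUP_CE",
    "GBLUP_CE_Abs",
    "GBLUP_CE_mean",
    "GBLUP_CE_Res",
    "GBLUP_TRN",
)

_EIG_TOL = 1e-10


@dataclass
class PhenoTable:
    """Long-format adjusted phenotypes: one BLUE per (line, environment)."""

    frame: pd.DataFrame  # columns: line, env, value

    def __post_init__(self) -> None:
        required = {"line", "env", "value"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"phenotype table needs columns {sorted(required)}")
        self.frame = self.frame.reset_index(drop=True)
        if self.frame.duplicated(["line", "env"]).any():
            dups = self.frame[self.frame.duplicated(["line", "env"])]
            raise ValueError(f"duplicate (line, env) records: {dups.head(3).values}")

    @property
    def line_ids(self) -> np.ndarray:
        return self.frame["line"].unique()

    @property
    def env_ids(self) -> np.ndarray:
        return self.frame["env"].unique()

    def to_wide(self, line_order=None, env_order=None) -> pd.DataFrame:
        """Lines x environments matrix; unobserved cells are NaN."""
        wide = self.frame.pivot(index="line", columns="env", values="value")
        if line_order is not None:
            wide = wide.reindex(index=line_order)
        if env_order is not None:
            wide = wide.reindex(columns=env_order)
        return wide

    @classmethod
    def from_wide(cls, wide: pd.DataFrame) -> "PhenoTable":
        tall = wide.copy()
        tall.index.name = "line"
        tall = (
            tall.reset_index()
            .melt(id_vars="line", var_name="env", value_name="value")
            .dropna(subset=["value"])
        )
        return cls(tall.reset_index(drop=True))

    def subset_cells(self, mask_cells: set) -> "PhenoTable":
        keep = [
            (line, env) in mask_cells
            for line, env in zip(self.frame["line"], self.frame["env"])
        ]
        return PhenoTable(self.frame[keep].reset_index(drop=True))


@dataclass
class EnvCovariance:
    """Environment covariance kernel Omega_E with its construction tag."""

    omega: np.ndarray
    env_ids: np.ndarray
    method_tag: str
    repair_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.env_ids = np.asarray(self.env_ids, dtype=object)
        n = len(self.env_ids)
        if self.omega.shape != (n, n):
            raise ValueError("omega must be square and match env_ids")
        if not np.allclose(self.omega, self.omega.T, atol=1e-8):
            raise ValueError("omega must be symmetric")


@dataclass
class MCMCConfig:
    """Gibbs sampler settings.

    Defaults mirror the long-chain production settings (20 000 iterations,
    10 000 burn-in); desk-scale analyses typically run a few thousand.
    prior_df is the scaled-inverse-chi-square / inverse-Wishart prior
    degrees of freedom; prior_scale_fraction is the share of the phenotypic
    variance placed a priori on the non-residual terms combined.
    """

    n_iter: int = 20000
    burn_in: int = 10000
    thin: int = 1
    seed: int = 0
    prior_df: float = 5.0
    prior_scale_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not (0 < self.prior_scale_fraction < 1):
            raise ValueError("prior_scale_fraction must be in (0, 1)")

    def replace(self, **kw) -> "MCMCConfig":
        d = self.__dict__.copy()
        d.update(kw)
        return MCMCConfig(**d)


@dataclass
class MultitraitFit:
    """Posterior means from the first-stage unstructured-covariance fit."""

    omega_gen: np.ndarray  # genetic covariance between environments
    omega_res: np.ndarray  # residual covariance between environments
    env_ids: np.ndarray
    n_samples_used: int


@dataclass
class GBLUPFit:
    """Posterior summaries of the single-response GBLUP."""

    mu_hat: float
    env_effects: pd.Series  # indexed by environment id
    gebv: pd.Series  # indexed by line id (posterior-mean g_j)
    gxe_effects: pd.DataFrame  # lines x environments grid of posterior means
    var_env: float
    var_gen: float
    var_gxe: float
    var_res: float
    method_tag: str
    config: MCMCConfig

    def __post_init__(self) -> None:
        for name in ("var_env", "var_gen", "var_gxe", "var_res"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# linear-algebra helpers


def _kernel_eigenbasis(K: np.ndarray, what: str) -> tuple[np.ndarray, np.ndarray]:
    """Eigenbasis of a PSD kernel, dropping numerically-zero directions."""
    K = 0.5 * (K + K.T)
    d, U = np.linalg.eigh(K)
    scale = max(float(d[-1]), 1.0)
    if d[0] < -1e-8 * scale:
        raise ValueError(f"{what} kernel is not PSD (min eigenvalue {d[0]:.3e})")
    keep = d > _EIG_TOL * scale
    if not keep.any():
        raise ValueError(f"{what} kernel is numerically zero")
    return U[:, keep], d[keep]


def _repair_psd(m: np.ndarray, jitter: float = 1e-8) -> tuple[np.ndarray, dict]:
    """Clip negative eigenvalues at zero and add a jitter ridge; log the loss."""
    m = 0.5 * (m + m.T)
    d, U = np.linalg.eigh(m)
    clipped = float(-d[d < 0].sum()) if (d < 0).any() else 0.0
    if clipped > 0:
        m = (U * np.clip(d, 0.0, None)) @ U.T
    m = m + jitter * np.eye(m.shape[0])
    return m, {"clipped_mass": clipped, "jitter": jitter}


class _EffectBlock:
    """Whitened random-effect block with pre-factorized Gram matrix.

    The effect on data rows is W a with a ~ N(0, sigma2 I); the full
    conditional of a is N(C^-1 W' y*, sigma2_e C^-1) with
    C = W'W + (sigma2_e / sigma2) I, diagonalized once via W'W = V S V'.
    """

    def __init__(self, W: np.ndarray):
        self.W = W
        self.q = W.shape[1]
        gram = W.T @ W
        s, V = np.linalg.eigh(0.5 * (gram + gram.T))
        self.s = np.clip(s, 0.0, None)
        self.V = V
        self.a = np.zeros(self.q)
        self.fitted = np.zeros(W.shape[0])

    def update(
        self, resid: np.ndarray, sigma2: float, sigma2_e: float, rng
    ) -> np.ndarray:
        """Blocked draw of the coefficients; returns the updated residual."""
        y_star = resid + self.fitted
        lam = sigma2_e / max(sigma2, 1e-12)
        rhs = self.V.T @ (self.W.T @ y_star)
        denom = self.s + lam
        mean = self.V @ (rhs / denom)
        noise = self.V @ (rng.standard_normal(self.q) / np.sqrt(denom))
        self.a = mean + np.sqrt(sigma2_e) * noise
        self.fitted = self.W @ self.a
        return y_star - self.fitted


def _sample_scaled_inv_chi2(rng, df: float, scale_sum: float) -> float:
    """Draw sigma2 from (df*S0 + SS) / chisq(df); scale_sum = df*S0 + SS."""
    return scale_sum / rng.chisquare(df)


# ---------------------------------------------------------------------------
# first-stage multi-response fit


def fit_multitrait_unstructured(
    pheno_wide: pd.DataFrame,
    g: KinshipMatrix,
    config: MCMCConfig,
) -> MultitraitFit:
    """Gibbs sampler for Y = 1 mu' + U + E with unstructured covariances.

    Rows of U (one per line) follow a matrix-normal with row covariance G
    and column covariance Omega; rows of E are i.i.d. N(0, R).  Omega and R
    carry inverse-Wishart priors with ``config.prior_df`` degrees of freedom
    and identity scale.  Masked (test) cells are NaN and handled by data
    augmentation.  Returns posterior means of Omega (genetic covariance
    between environments) and R (residual covariance).
    """
    env_ids = pheno_wide.columns.to_numpy(dtype=object)
    line_ids = pheno_wide.index.to_numpy(dtype=object)
    J, I = pheno_wide.shape
    Y_obs = pheno_wide.to_numpy(dtype=float)
    obs = ~np.isnan(Y_obs)
    if (obs.sum(axis=0) == 0).any():
        bad = env_ids[obs.sum(axis=0) == 0]
        raise ValueError(f"environments with no observed cells: {list(bad)}")
    gk = g.reorder(line_ids)
    U_g, d_g = _kernel_eigenbasis(gk.values, "genomic relationship")
    q = len(d_g)

    rng = np.random.default_rng(config.seed)
    df0 = config.prior_df
    S0 = np.eye(I)

    # group lines by missingness pattern for vectorized imputation
    patterns: dict[tuple, np.ndarray] = {}
    for j in range(J):
        key = tuple(np.nonzero(~obs[j])[0])
        if key:
            patterns.setdefault(key, []).append(j)
    patterns = {k: np.asarray(v) for k, v in patterns.items()}

    Y = Y_obs.copy()
    col_means = np.nanmean(Y_obs, axis=0)
    for i in range(I):
        Y[~obs[:, i], i] = col_means[i]
    mu = col_means.copy()
    B = np.zeros((q, I))
    Omega = np.eye(I)
    R = np.eye(I)

    omega_sum = np.zeros((I, I))
    res_sum = np.zeros((I, I))
    n_used = 0

    for it in range(config.n_iter):
        # --- coefficients B (rows independent given Omega, R)
        Om_inv = np.linalg.inv(Omega)
        R_inv = np.linalg.inv(R)
        Yt = U_g.T @ (Y - mu)  # orthogonal rotation keeps rows iid N(0, R)
        C = (1.0 / d_g)[:, None, None] * Om_inv + R_inv  # (q, I, I)
        rhs = Yt @ R_inv.T  # (q, I)
        mean = np.linalg.solve(C, rhs[..., None])[..., 0]
        L = np.linalg.cholesky(C)
        z = rng.standard_normal((q, I, 1))
        # cov = C^-1 -> draw = mean + L^-T z
        noise = np.linalg.solve(np.transpose(L, (0, 2, 1)), z)[..., 0]
        B = mean + noise
        U = U_g @ B

        # --- grand means (flat prior)
        resid_rows = Y - U
        mu = resid_rows.mean(axis=0) + np.linalg.cholesky(R / J) @ rng.standard_normal(I)

        # --- Omega | B  (inverse-Wishart)
        S_omega = S0 + (B.T * (1.0 / d_g)) @ B
        Omega = stats.invwishart.rvs(df=df0 + q, scale=S_omega, random_state=rng)
        Omega = np.atleast_2d(Omega)

        # --- R | E
        E = Y - mu - U
        S_res = S0 + E.T @ E
        R = np.atleast_2d(
            stats.invwishart.rvs(df=df0 + J, scale=S_res, random_state=rng)
        )

        # --- impute masked cells from the row-conditional normal
        for key, rows in patterns.items():
            m = np.asarray(key)
            o = np.setdiff1d(np.arange(I), m)
            mean_m = mu[m] + U[np.ix_(rows, m)]
            if len(o):
                Roo = R[np.ix_(o, o)]
                Rmo = R[np.ix_(m, o)]
                gain = np.linalg.solve(Roo, Rmo.T).T  # (|m|, |o|)
                e_o = Y_obs[np.ix_(rows, o)] - mu[o] - U[np.ix_(rows, o)]
                mean_m = mean_m + e_o @ gain.T
                cov = R[np.ix_(m, m)] - gain @ Rmo.T
            else:
                cov = R[np.ix_(m, m)]
            cov = 0.5 * (cov + cov.T) + 1e-10 * np.eye(len(m))
            Lc = np.linalg.cholesky(cov)
            draws = mean_m + rng.standard_normal((len(rows), len(m))) @ Lc.T
            Y[np.ix_(rows, m)] = draws

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            omega_sum += Omega
            res_sum += R
            n_used += 1

    return MultitraitFit(
        omega_gen=omega_sum / n_used,
        omega_res=res_sum / n_used,
        env_ids=env_ids,
        n_samples_used=n_used,
    )


# ---------------------------------------------------------------------------
# Omega_E constructions


def build_omega(
    method_tag: str,
    mt: Optional[MultitraitFit],
    I: Optional[int] = None,
    env_ids: Optional[Sequence] = None,
) -> EnvCovariance:
    """Environment covariance kernel for one of the six methods.

    GBLUP and GBLUP_TRN use the identity; the CE variants transform the
    first-stage genetic (Omega) and residual (R) covariances:
    CE -> Omega, CE_Abs -> |Omega| elementwise, CE_mean -> (Omega + R)/2,
    CE_Res -> R.  Results are PSD-repaired (eigenvalue clipping + 1e-8
    jitter) with the clipped mass recorded, since e.g. an elementwise
    absolute value need not stay PSD.
    """
    if method_tag not in METHOD_TAGS:
        raise ValueError(f"unknown method tag {method_tag!r}; expected one of {METHOD_TAGS}")
    if method_tag in ("GBLUP", "GBLUP_TRN"):
        if env_ids is None:
            if I is None and mt is None:
                raise ValueError("need I or env_ids for the identity kernel")
            env_ids = mt.env_ids if mt is not None else [f"E{i+1}" for i in range(I)]
        omega = np.eye(len(env_ids))
        return EnvCovariance(omega, np.asarray(env_ids, dtype=object), method_tag)
    if mt is None:
        raise ValueError(f"{method_tag} requires a first-stage MultitraitFit")
    if method_tag == "GBLUP_CE":
        raw = mt.omega_gen
    elif method_tag == "GBLUP_CE_Abs":
        raw = np.abs(mt.omega_gen)
    elif method_tag == "GBLUP_CE_mean":
        raw = 0.5 * mt.omega_gen + 0.5 * mt.omega_res
    else:  # GBLUP_CE_Res
        raw = mt.omega_res
    repaired, log = _repair_psd(raw)
    return EnvCovariance(repaired, mt.env_ids, method_tag, repair_log=log)


# ---------------------------------------------------------------------------
# single-response Eq-style GBLUP


def fit_gblup(
    pheno: PhenoTable,
    g: KinshipMatrix,
    omega: EnvCovariance,
    config: MCMCConfig,
    fixed_variances: Optional[Mapping[str, float]] = None,
) -> GBLUPFit:
    """Gibbs sampler for the single-response sparse-MET GBLUP.

    ``pheno`` holds the training cells only.  Every line of the kinship
    matrix must appear in at least one training record — sparse testing
    estimates, it does not extrapolate to never-observed lines.  The grand
    mean has a flat prior; the four variance components have
    scaled-inverse-chi-square priors (df = ``config.prior_df``, prior modes
    partitioning the phenotypic variance: ``prior_scale_fraction`` shared
    equally by the three effect terms, the remainder on the residual).
    ``fixed_variances`` may pin any of {'env', 'gen', 'gxe', 'res'} to a
    constant (no sampling for that component), which reduces the sampler to
    the classic mixed-model-equations BLUP in expectation.

    Returns posterior means of all effects — including the interaction
    effect for every cell of the line x environment grid, observed or not,
    which is what :func:`predict_cells` uses for test cells.
    """
    env_ids = omega.env_ids
    env_pos = {e: i for i, e in enumerate(env_ids)}
    data_envs = set(pheno.frame["env"])
    if data_envs != set(env_ids):
        raise ValueError(
            "omega environments must match the phenotype environments; "
            f"omega has {list(env_ids)}, data has {sorted(map(str, data_envs))}"
        )
    line_ids = g.line_ids
    line_pos = {l: j for j, l in enumerate(line_ids)}
    unknown = set(pheno.frame["line"]) - set(line_ids)
    if unknown:
        raise ValueError(f"phenotype lines absent from kinship matrix: {sorted(map(str, unknown))[:5]}")
    seen = set(pheno.frame["line"])
    absent = [l for l in line_ids if l not in seen]
    if absent:
        raise ValueError(
            f"lines with no training record (sparse-testing premise violated): "
            f"{list(map(str, absent[:5]))}"
        )

    J, I = len(line_ids), len(env_ids)
    j_idx = pheno.frame["line"].map(line_pos).to_numpy()
    i_idx = pheno.frame["env"].map(env_pos).to_numpy()
    y = pheno.frame["value"].to_numpy(dtype=float)
    n = len(y)

    U_o, d_o = _kernel_eigenbasis(omega.omega, "environment")
    U_gk, d_gk = _kernel_eigenbasis(g.values, "genomic relationship")

    W_env = U_o[i_idx] * np.sqrt(d_o)
    W_gen = U_gk[j_idx] * np.sqrt(d_gk)
    # Kronecker eigenbasis of the Hadamard G x E kernel over the full grid;
    # a data row for cell (j, i) is kron(U_o[i], U_gk[j]) scaled by sqrt(d).
    d_grid = np.kron(d_o, d_gk)
    keep = d_grid > _EIG_TOL * max(float(d_grid.max()), 1.0)
    sqrt_d_grid = np.sqrt(d_grid[keep])
    W_gxe = (U_o[i_idx][:, :, None] * U_gk[j_idx][:, None, :]).reshape(n, -1)
    W_gxe = W_gxe[:, keep] * sqrt_d_grid

    blocks = {
        "env": _EffectBlock(W_env),
        "gen": _EffectBlock(W_gen),
        "gxe": _EffectBlock(W_gxe),
    }

    rng = np.random.default_rng(config.seed)
    df0 = config.prior_df
    vy = max(float(np.var(y, ddof=1)) if n > 1 else 0.0, 1e-6)
    frac = config.prior_scale_fraction
    # scaled-inv-chi2 scale chosen so the prior mode hits the target split
    targets = {
        "env": frac * vy / 3.0,
        "gen": frac * vy / 3.0,
        "gxe": frac * vy / 3.0,
        "res": (1.0 - frac) * vy,
    }
    S0 = {k: v * (df0 + 2.0) / df0 for k, v in targets.items()}

    fixed = dict(fixed_variances or {})
    unknown_keys = set(fixed) - set(targets)
    if unknown_keys:
        raise ValueError(f"fixed_variances keys must be in {sorted(targets)}")
    sigma2 = {k: fixed.get(k, targets[k]) for k in targets}

    mu = float(np.mean(y))
    resid = y - mu

    acc = {
        "mu": 0.0,
        "a_env": np.zeros(blocks["env"].q),
        "a_gen": np.zeros(blocks["gen"].q),
        "a_gxe": np.zeros(blocks["gxe"].q),
        "var": dict.fromkeys(targets, 0.0),
    }
    n_used = 0

    for it in range(config.n_iter):
        for name in ("env", "gen", "gxe"):
            resid = blocks[name].update(resid, sigma2[name], sigma2["res"], rng)
            if name not in fixed:
                a = blocks[name].a
                sigma2[name] = max(
                    _sample_scaled_inv_chi2(
                        rng, df0 + blocks[name].q, df0 * S0[name] + a @ a
                    ),
                    1e-12,
                )
        # grand mean, flat prior
        resid = resid + mu
        mu = float(np.mean(resid) + np.sqrt(sigma2["res"] / n) * rng.standard_normal())
        resid = resid - mu
        if "res" not in fixed:
            sigma2["res"] = max(
                _sample_scaled_inv_chi2(
                    rng, df0 + n, df0 * S0["res"] + resid @ resid
                ),
                1e-12,
            )

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            acc["mu"] += mu
            acc["a_env"] += blocks["env"].a
            acc["a_gen"] += blocks["gen"].a
            acc["a_gxe"] += blocks["gxe"].a
            for k in targets:
                acc["var"][k] += sigma2[k]
            n_used += 1

    mu_hat = acc["mu"] / n_used
    L_hat = U_o @ (np.sqrt(d_o) * (acc["a_env"] / n_used))
    g_hat = U_gk @ (np.sqrt(d_gk) * (acc["a_gen"] / n_used))
    # interaction posterior means over the full grid (env-major Kronecker order)
    U_grid = np.kron(U_o, U_gk)[:, keep]
    gl_grid = U_grid @ (sqrt_d_grid * (acc["a_gxe"] / n_used))
    gxe = pd.DataFrame(
        gl_grid.reshape(I, J).T, index=line_ids, columns=env_ids
    )

    var_means = {k: acc["var"][k] / n_used for k in targets}
    return GBLUPFit(
        mu_hat=mu_hat,
        env_effects=pd.Series(L_hat, index=env_ids),
        gebv=pd.Series(g_hat, index=line_ids),
        gxe_effects=gxe,
        var_env=var_means["env"],
        var_gen=var_means["gen"],
        var_gxe=var_means["gxe"],
        var_res=var_means["res"],
        method_tag=omega.method_tag,
        config=config,
    )


def predict_cells(fit: GBLUPFit, cells: Sequence[tuple]) -> pd.Series:
    """Cell predictions mu + L_i + g_j + gL_ij for (line, env) pairs.

    The interaction term for an unobserved cell is its posterior mean under
    the joint Kronecker kernel, carried by the fit.  Deterministic given the
    fit.
    """
    preds = []
    for line, env in cells:
        if line not in fit.gebv.index:
            raise KeyError(f"unknown line {line!r}")
        if env not in fit.env_effects.index:
            raise KeyError(f"unknown environment {env!r}")
        preds.append(
            fit.mu_hat
            + float(fit.env_effects[env])
            + float(fit.gebv[line])
            + float(fit.gxe_effects.at[line, env])
        )
    index = pd.MultiIndex.from_tuples(cells, names=["line", "env"])
    return pd.Series(preds, index=index, name="prediction")


def gebv_across_tpe(fit: GBLUPFit) -> pd.Series:
    """Across-TPE genomic score mu + g_j per line.

    This is the GBLUP_TRN selection criterion: rather than predicting each
    unobserved cell, the line's genomic estimate from its observed cells
    stands in for every test cell.  A monotone shift of the GEBVs, so
    rankings are identical to ranking by g_j.
    """
    return (fit.mu_hat + fit.gebv).rename("score")


def read_pheno_csv(path, sep: str = ",") -> PhenoTable:
    """Read a long-format phenotype CSV with columns line, env, value."""
    df = pd.read_csv(path, sep=sep)
    return PhenoTable(df[["line", "env", "value"]])
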