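"""Synthetic marker and multi-environment phenotype data with known truths.

``simulate_markers`` draws a Hardy-Weinberg dosage matrix (per-marker
allele frequency uniform over a MAF range, dosages Binomial(2, p_j)) with
optional uniform missingness.  ``simulate_met`` then draws one balanced
multi-environment trial from the same generative model the GBLUP fits:

    Y_ij = mu + L_i + g_j + gL_ij + e_ij

with L ~ N(0, sigma2_env * Omega), g ~ N(0, sigma2_gen * G), the
interaction drawn over the full line x environment grid from the Kronecker
kernel sigma2_gxe * (Omega (x) G), and i.i.d. residuals.  Every realized
effect and variance component is returned in a :class:`SimTruth` so
recovery can be measured exactly.

The default scenario mirrors a single wheat TPE-year: 166 lines in 4
environments with 2000 markers and across-environment heritability
h2 = sigma2_gen / (sigma2_gen + sigma2_gxe + sigma2_res) = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sparsemet.engine import PhenoTable
from sparsemet.markers import KinshipMatrix, MarkerMatrix

__all__ = [
    "SimTruth",
    "simulate_markers",
    "simulate_met",
    "compound_symmetry",
    "default_scenario",
]


@dataclass
class SimTruth:
    """Ground truth of one simulated MET."""

    true_mu: float
    true_env_effects: np.ndarray  # length I
    true_gebv: np.ndarray  # length J
    true_gxe: np.ndarray  # J x I
    sigma2_env: float
    sigma2_gen: float
    sigma2_gxe: float
    sigma2_res: float
    omega_true: np.ndarray
    h2: float
    seed: int

    def __post_init__(self) -> None:
        for name in ("sigma2_env", "sigma2_gen", "sigma2_gxe", "sigma2_res"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        denom = self.sigma2_gen + self.sigma2_gxe + self.sigma2_res
        implied = self.sigma2_gen / denom if denom > 0 else 0.0
        if abs(implied - self.h2) > 1e-10:
            raise ValueError(f"stored h2 {self.h2} inconsistent with variances ({implied})")


def simulate_markers(
    J: int,
    p: int,
    maf_range: tuple[float, float] = (0.1, 0.5),
    missing_frac: float = 0.0,
    seed: int = 0,
) -> MarkerMatrix:
    """Hardy-Weinberg dosage matrix with uniform random missingness."""
    if J < 2 or p < 1:
        raise ValueError("need J >= 2 lines and p >= 1 markers")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if not 0.0 <= missing_frac < 1.0:
        raise ValueError("missing_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(lo, hi, size=p)
    values = rng.binomial(2, freqs, size=(J, p)).astype(float)
    if missing_frac > 0:
        mask = rng.random((J, p)) < missing_frac
        # keep at least one observed call per marker so frequencies exist
        all_gone = mask.all(axis=0)
        mask[0, all_gone] = False
        values[mask] = np.nan
    line_ids = np.array([f"L{j+1}" for j in range(J)], dtype=object)
    marker_ids = np.array([f"M{m+1}" for m in range(p)], dtype=object)
    return MarkerMatrix(values, line_ids, marker_ids)


def compound_symmetry(I: int, rho: float = 0.5) -> np.ndarray:
    """Unit-variance exchangeable environment correlation matrix."""
    if not -1.0 / max(I - 1, 1) < rho <= 1.0:
        raise ValueError("rho outside the PSD range for compound symmetry")
    return (1.0 - rho) * np.eye(I) + rho * np.ones((I, I))


def _psd_root(K: np.ndarray, what: str) -> np.ndarray:
    d, U = np.linalg.eigh(0.5 * (K + K.T))
    if d[0] < -1e-8 * max(float(d[-1]), 1.0):
        raise ValueError(f"{what} is not PSD")
    return U * np.sqrt(np.clip(d, 0.0, None))


def simulate_met(
    g: KinshipMatrix,
    I: int,
    mu: float = 0.0,
    sigma2_env: float = 1.0,
    sigma2_gen: float = 1.0,
    sigma2_gxe: float = 0.5,
    sigma2_res: float = 0.5,
    omega_true: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[PhenoTable, SimTruth]:
    """One complete J x I BLUE table drawn from the sparse-MET GBLUP model.

    The interaction surface is drawn exactly from the Kronecker kernel
    Omega (x) G via its eigendecomposition (the grid is small at desk
    scale), so simulated data match the fitted model cell for cell.
    """
    if omega_true is None:
        omega_true = compound_symmetry(I)
    omega_true = np.asarray(omega_true, dtype=float)
    if omega_true.shape != (I, I) or not np.allclose(omega_true, omega_true.T, atol=1e-8):
        raise ValueError("omega_true must be a symmetric I x I matrix")
    J = g.n_lines
    rng = np.random.default_rng(seed)

    root_omega = _psd_root(omega_true, "omega_true")
    root_g = _psd_root(g.values, "kinship matrix")

    L = np.sqrt(sigma2_env) * (root_omega @ rng.standard_normal(I))
    gvec = np.sqrt(sigma2_gen) * (root_g @ rng.standard_normal(J))
    # Kronecker (env-major) draw of the full-grid interaction
    z = rng.standard_normal((I, J))
    gl = np.sqrt(sigma2_gxe) * (root_omega @ z @ root_g.T)  # I x J
    eps = np.sqrt(sigma2_res) * rng.standard_normal((J, I))

    Y = mu + L[None, :] + gvec[:, None] + gl.T + eps
    env_ids = np.array([f"E{i+1}" for i in range(I)], dtype=object)
    wide = pd.DataFrame(Y, index=g.line_ids, columns=env_ids)
    pheno = PhenoTable.from_wide(wide)

    denom = sigma2_gen + sigma2_gxe + sigma2_res
    truth = SimTruth(
        true_mu=mu,
        true_env_effects=L,
        true_gebv=gvec,
        true_gxe=gl.T.copy(),
        sigma2_env=sigma2_env,
        sigma2_gen=sigma2_gen,
        sigma2_gxe=sigma2_gxe,
        sigma2_res=sigma2_res,
        omega_true=omega_true,
        h2=sigma2_gen / denom if denom > 0 else 0.0,
        seed=seed,
    )
    return pheno, truth


def default_scenario(
    seed: int = 0,
    J: int = 166,
    I: int = 4,
    p: int = 2000,
) -> tuple[MarkerMatrix, KinshipMatrix, PhenoTable, SimTruth]:
    """The package's reference synthetic MET: J=166 lines, I=4 environments.

    Markers are complete (2000 of them, MAF uniform on [0.1, 0.5]); variance
    components (1, 1, 0.5, 0.5) for environment, genetic, interaction and
    residual give across-environment heritability 0.5, with an exchangeable
    rho = 0.5 environment correlation.
    """
    from sparsemet.markers import grm_vanraden

    markers = simulate_markers(J, p, seed=seed)
    kin = grm_vanraden(markers)
    pheno, truth = simulate_met(
        kin,
        I,
        mu=5.0,
        sigma2_env=1.0,
        sigma2_gen=1.0,
        sigma2_gxe=0.5,
        sigma2_res=0.5,
        omega_true=compound_symmetry(I, 0.5),
        seed=seed + 1,
    )
    return markers, kin, pheno, truth
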