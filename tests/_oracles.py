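"""Closed-form mixed-model (BLUP) oracle, independent of the Gibbs sampler.

Builds the marginal covariance V of the training observations directly and
computes GLS/BLUP posterior means for every effect block; used to validate
the sampler run with fixed variance components.
"""

import numpy as np
import pandas as pd


def blup_effects(train_frame: pd.DataFrame, G, omega, variances, line_ids, env_ids):
    """GLS mean and BLUP effect blocks for y = mu + L + g + gL + e.

    variances: dict with keys env, gen, gxe, res.  Returns
    (mu, L (I), g (J), gL over the full J x I grid).
    """
    line_pos = {l: j for j, l in enumerate(line_ids)}
    env_pos = {e: i for i, e in enumerate(env_ids)}
    jj = train_frame["line"].map(line_pos).to_numpy()
    ii = train_frame["env"].map(env_pos).to_numpy()
    y = train_frame["value"].to_numpy(dtype=float)
    n = len(y)
    J, I = len(line_ids), len(env_ids)

    k_env = omega[np.ix_(ii, ii)]
    k_gen = G[np.ix_(jj, jj)]
    k_gxe = k_gen * k_env
    V = (
        variances["env"] * k_env
        + variances["gen"] * k_gen
        + variances["gxe"] * k_gxe
        + variances["res"] * np.eye(n)
    )
    Vi = np.linalg.inv(V)
    one = np.ones(n)
    mu = float(one @ Vi @ y / (one @ Vi @ one))
    w = Vi @ (y - mu)
    L = variances["env"] * omega[:, ii] @ w
    g = variances["gen"] * G[:, jj] @ w
    gl = np.empty((J, I))
    for i in range(I):
        gl[:, i] = variances["gxe"] * ((G[:, jj] * omega[i, ii]) @ w)
    return mu, L, g, gl
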