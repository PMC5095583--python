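"""Independent WHAM route for cross-checking: direct maximum-likelihood
optimisation of the window offsets with a quasi-Newton method, instead of
the package's fixed-point iteration.  Operates on the same binned
histograms; used as a test oracle only."""

import numpy as np
from scipy.optimize import minimize


def wham_ml(windows, edges, temperature=1.0):
    """Return (bin centers, F) by minimising the binned WHAM negative
    log-likelihood over window free-energy offsets."""
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows])
    N = counts.sum(axis=1).astype(float)
    M = counts.sum(axis=0).astype(float)
    c = np.stack([np.exp(-0.5 * w.spring_k * (centers - w.center) ** 2 / temperature)
                  for w in windows])

    occupied = M > 0

    def negloglik(f):
        # A(f) = -Σ_i N_i f_i + Σ_b M_b ln Σ_i N_i e^{f_i} c_ib
        denom = (N * np.exp(f)) @ c
        return (-np.dot(N, f)
                + np.dot(M[occupied], np.log(denom[occupied])))

    def grad(f):
        denom = (N * np.exp(f)) @ c
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(denom > 0, M / denom, 0.0)
        return -N + N * np.exp(f) * (c @ p)

    res = minimize(negloglik, np.zeros(len(windows)), jac=grad, method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 5000})
    f = res.x
    denom = (N * np.exp(f)) @ c
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(denom > 0, M / denom, np.nan)
    mask = np.isfinite(p) & (p > 0)
    F = -temperature * np.log(p[mask])
    return centers[mask], F - F.min()
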