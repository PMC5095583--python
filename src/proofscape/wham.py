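"""Weighted Histogram Analysis Method for 1D umbrella-sampling data.

Window samples are binned on a common grid and the standard WHAM
self-consistency equations are iterated until the window free-energy
offsets move by less than ``tol``:

    p_b ∝ Σ_i n_ib / Σ_i N_i exp(f_i) c_ib,    exp(-f_i) = Σ_b c_ib p_b

with ``c_ib`` the Boltzmann factor of window i's bias at bin b.  The
profile F = -k_BT ln p is shifted so its minimum is zero.  Uncertainties
come from a block bootstrap over each window's (decorrelated) time series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .sampler import UmbrellaWindow


@dataclass
class FreeEnergyProfile:
    """F(ρ) in k_BT over contiguous bins; min(F) = 0."""

    centers: np.ndarray
    F: np.ndarray
    uncertainty: np.ndarray | None = None
    bin_width: float = 0.0
    window_f: np.ndarray | None = None       # per-window offsets (k_BT)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.uncertainty is not None:
            self.uncertainty = np.asarray(self.uncertainty, dtype=float)
            if np.any(self.uncertainty < 0):
                raise ValueError("uncertainties must be >= 0")

    def interp(self, x):
        return np.interp(x, self.centers, self.F)

    def barrier_from(self, start: float, end: float) -> float:
        """Max F between start and end minus F at the start position."""
        lo, hi = min(start, end), max(start, end)
        mask = (self.centers >= lo) & (self.centers <= hi)
        return float(np.max(self.F[mask]) - self.interp(start))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("center\tF_kBT\terr_kBT\n")
            err = self.uncertainty if self.uncertainty is not None else np.zeros_like(self.F)
            for c, f, e in zip(self.centers, self.F, err):
                fh.write(f"{c:.8g}\t{f:.8g}\t{e:.8g}\n")

    @classmethod
    def from_tsv(cls, path) -> "FreeEnergyProfile":
        data = np.loadtxt(path, skiprows=1)
        return cls(centers=data[:, 0], F=data[:, 1],
                   uncertainty=data[:, 2] if data.shape[1] > 2 else None,
                   bin_width=float(np.median(np.diff(data[:, 0]))))


def _freedman_diaconis_bins(samples: np.ndarray) -> int:
    q75, q25 = np.percentile(samples, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        return 50
    width = 2 * iqr / len(samples) ** (1 / 3)
    return max(10, int(np.ceil((samples.max() - samples.min()) / width)))


def _bias_matrix(windows, centers, temperature):
    c = np.empty((len(windows), len(centers)))
    for i, w in enumerate(windows):
        c[i] = np.exp(-0.5 * w.spring_k * (centers - w.center) ** 2 / temperature)
    return c


def wham_1d(
    windows: list[UmbrellaWindow],
    n_bins: int | None = None,
    tol: float = 1e-7,
    max_iter: int = 50000,
    temperature: float = 1.0,
) -> FreeEnergyProfile:
    """Self-consistent WHAM over the pooled sampled range.

    ``n_bins`` defaults to the Freedman-Diaconis rule on the pooled
    samples.  Windows with no samples are inert.  Raises ``ValueError``
    naming the offending windows when adjacent histograms do not overlap;
    warns (with the residual) if ``max_iter`` is exhausted.
    """
    if len(windows) == 0:
        raise ValueError("need at least one window")
    pooled = np.concatenate([w.samples for w in windows if w.samples.size])
    if pooled.size == 0:
        raise ValueError("all windows are empty")
    if n_bins is None:
        n_bins = _freedman_diaconis_bins(pooled)
    edges = np.linspace(pooled.min(), pooled.max() + 1e-12, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows])
    N = counts.sum(axis=1).astype(float)

    # histogram connectivity: adjacent biased windows must have occupied
    # bins within a couple of bin widths of each other (the bias Boltzmann
    # factors keep the offsets identifiable across an empty bin or two;
    # larger gaps leave the profile disconnected and are an error)
    biased = [(w, counts[i]) for i, w in enumerate(windows)
              if w.spring_k > 0 and w.samples.size]
    if len(biased) > 1:
        biased.sort(key=lambda t: t[0].center)
        for (wa, ca), (wb, cb) in zip(biased[:-1], biased[1:]):
            hi_a = np.flatnonzero(ca > 0).max()
            lo_b = np.flatnonzero(cb > 0).min()
            if lo_b - hi_a > 2:
                raise ValueError(
                    f"windows at centers {wa.center:.4g} and {wb.center:.4g} "
                    "have non-overlapping histograms")

    c = _bias_matrix(windows, centers, temperature)
    M = counts.sum(axis=0)
    f = np.zeros(len(windows))
    converged = False
    for it in range(max_iter):
        denom = (N * np.exp(f)) @ c            # Σ_i N_i e^{f_i} c_ib
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, M / denom, 0.0)
        newf = -np.log(np.clip(c @ p, 1e-300, None))
        newf -= newf[0]
        delta = np.max(np.abs(newf - f))
        f = newf
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"WHAM did not converge in {max_iter} iterations "
                      f"(residual {delta:.3g})", stacklevel=2)

    denom = (N * np.exp(f)) @ c
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(denom > 0, M / denom, np.nan)
    mask = np.isfinite(p) & (p > 0)
    F = -temperature * np.log(p[mask])
    F -= F.min()
    return FreeEnergyProfile(
        centers=centers[mask], F=F,
        bin_width=float(edges[1] - edges[0]),
        window_f=f,
        provenance={"n_windows": len(windows), "n_bins": n_bins,
                    "tol": tol, "iterations": it + 1, "converged": converged},
    )


def statistical_inefficiency(x: np.ndarray, max_lag: int | None = None) -> float:
    """g = 1 + 2 Σ autocorrelation; ≥ 1; used to decorrelate before bootstrap."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return 1.0
    xc = x - x.mean()
    var = np.dot(xc, xc) / n
    g = 1.0
    max_lag = max_lag or n // 2
    for t in range(1, max_lag):
        c = np.dot(xc[:-t], xc[t:]) / ((n - t) * var)
        if c <= 0:
            break
        g += 2.0 * c * (1.0 - t / n)
    return max(1.0, g)


def profile_uncertainty(
    windows: list[UmbrellaWindow],
    n_bootstrap: int = 20,
    seed: int = 0,
    n_bins: int | None = None,
    temperature: float = 1.0,
) -> FreeEnergyProfile:
    """Block-bootstrap per-bin errors; deterministic under ``seed``.

    Each window's series is cut into blocks of roughly one statistical
    inefficiency (at least 10 samples); blocks are resampled with
    replacement and WHAM re-run; the per-bin standard deviation across
    replicas, interpolated onto the full profile grid, is the uncertainty.
    """
    if n_bootstrap < 10:
        raise ValueError("n_bootstrap must be >= 10")
    rng = np.random.default_rng(seed)
    base = wham_1d(windows, n_bins=n_bins, temperature=temperature)
    n_bins_used = base.provenance["n_bins"]

    block_len = [max(10, int(np.ceil(statistical_inefficiency(w.samples))))
                 for w in windows]
    replicas = np.full((n_bootstrap, len(base.centers)), np.nan)
    for b in range(n_bootstrap):
        resampled = []
        for w, bl in zip(windows, block_len):
            n = len(w.samples)
            if n == 0:
                resampled.append(w)
                continue
            n_blocks = max(1, n // bl)
            starts = rng.integers(0, max(1, n - bl + 1), size=n_blocks)
            samples = np.concatenate([w.samples[s:s + bl] for s in starts])
            resampled.append(UmbrellaWindow(center=w.center, spring_k=w.spring_k,
                                            samples=samples))
        try:
            prof = wham_1d(resampled, n_bins=n_bins_used, temperature=temperature)
        except ValueError:
            continue
        Fb = np.interp(base.centers, prof.centers, prof.F)
        Fb -= Fb[np.argmin(base.F)]        # align at the profile minimum
        replicas[b] = Fb
    err = np.nanstd(replicas, axis=0)
    return FreeEnergyProfile(
        centers=base.centers, F=base.F, uncertainty=err,
        bin_width=base.bin_width, window_f=base.window_f,
        provenance={**base.provenance, "n_bootstrap": n_bootstrap, "seed": seed},
    )
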