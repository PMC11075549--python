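"""Population differentiation statistics.

Two complementary scans:

* per-SNP Weir & Cockerham (1984) theta-hat between two populations, with a
  forward-simulation neutral null;
* a moment-based covariance-aware differentiation statistic ("XtX"): squared
  standardized population allele-frequency deviations whitened by the
  across-population covariance Omega, calibrated by a pseudo-observed
  dataset (POD) quantile threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genomics_io import GenotypeMatrix, PopulationMap
from .synthdata import DemographyConfig, simulate_neutral

__all__ = [
    "FstResult",
    "CovarianceModel",
    "XtXResult",
    "weir_cockerham_fst",
    "fst_null_distribution",
    "estimate_omega",
    "xtx_statistic",
    "pod_calibrate",
]


@dataclass
class FstResult:
    """Per-site W&C variance components and theta-hat (NaN where undefined)."""

    theta: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    pop_labels: tuple[str, str]
    n_per_pop: np.ndarray  # (sites, 2) individuals with calls

    def defined(self) -> np.ndarray:
        return self.theta[~np.isnan(self.theta)]

    def pooled_theta(self) -> float:
        """Multi-locus W&C estimator: components summed over defined sites.

        This ratio-of-sums pooling is the standard multi-locus estimator
        (vcftools' "weighted" value) and, unlike the mean of per-site
        ratios, is free of the O(1/J) Jensen bias at two demes.
        """
        ok = ~np.isnan(self.theta)
        denom = (self.a + self.b + self.c)[ok].sum()
        return float(self.a[ok].sum() / denom)


def weir_cockerham_fst(
    gm: GenotypeMatrix, pops: PopulationMap, level: str = "lineage"
) -> FstResult:
    """Per-SNP Weir & Cockerham theta-hat between exactly two populations.

    Sites need >= 2 non-missing diploid calls in each population; others
    (and sites monomorphic across both samples, where a+b+c = 0) get NaN.
    """
    groups = pops.group_indices(gm, level=level)
    if len(groups) != 2:
        raise ValueError(
            f"weir_cockerham_fst is pairwise only; got {len(groups)} populations"
        )
    (name1, idx1), (name2, idx2) = sorted(groups.items())
    d1, d2 = gm.dosages[idx1], gm.dosages[idx2]

    def pop_stats(d):
        obs = d >= 0
        n = obs.sum(axis=0).astype(float)                 # individuals called
        alt = np.where(obs, d, 0).sum(axis=0).astype(float)
        het = ((d == 1) & obs).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2 * n)
            h = het / n
        return n, p, h

    n1, p1, h1 = pop_stats(d1)
    n2, p2, h2 = pop_stats(d2)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)
    bad = (n1 < 2) | (n2 < 2)
    for arr in (theta, a, b, c):
        arr[bad] = np.nan
    return FstResult(
        theta=theta, a=a, b=b, c=c,
        chrom=gm.chrom.copy(), pos=gm.pos.copy(),
        pop_labels=(name1, name2),
        n_per_pop=np.stack([n1, n2], axis=1),
    )


def fst_null_distribution(
    config: DemographyConfig,
    n_reps: int = 100,
    seed: int = 0,
    level: str = "clade",
) -> tuple[np.ndarray, dict]:
    """Neutral per-SNP theta-hat null: repeat the forward simulation
    ``n_reps`` times, compute per-SNP F_ST each time, and pool.

    Returns the pooled values and summary quantiles (quartiles, the top-5%
    cut, mean, count).
    """
    pooled = []
    for rep in range(n_reps):
        gm, pmap = simulate_neutral(config, seed=seed + rep)
        res = weir_cockerham_fst(gm, pmap, level=level)
        pooled.append(res.defined())
    values = np.concatenate(pooled) if pooled else np.array([])
    summary = {
        "n": int(values.size),
        "mean": float(np.mean(values)) if values.size else float("nan"),
        "q25": float(np.quantile(values, 0.25)) if values.size else float("nan"),
        "median": float(np.quantile(values, 0.5)) if values.size else float("nan"),
        "q75": float(np.quantile(values, 0.75)) if values.size else float("nan"),
        "q95": float(np.quantile(values, 0.95)) if values.size else float("nan"),
    }
    return values, summary


# ---------------------------------------------------------------------------
# Covariance-aware differentiation
# ---------------------------------------------------------------------------

@dataclass
class CovarianceModel:
    """Across-population scaled allele-frequency covariance plus the
    ancestral-frequency Beta parameters and per-population allele-draw
    counts (2 x diploid sample size)."""

    omega: np.ndarray
    pi_params: tuple[float, float]
    sample_sizes: np.ndarray
    pop_names: list[str] | None = None

    @property
    def J(self) -> int:
        return self.omega.shape[0]

    def omega_inv(self) -> np.ndarray:
        """Inverse of Omega; pseudo-inverse when Omega is singular.

        Estimating the ancestral frequency as the count-weighted mean of
        the same sample frequencies imposes an exact linear constraint on
        the standardized deviations, so a data-fitted Omega has rank J - 1;
        the statistic lives in that subspace on both the real-data and POD
        sides, making the pseudo-inverse consistent for calibration.
        """
        w, v = np.linalg.eigh((self.omega + self.omega.T) / 2)
        cutoff = max(w.max(), 0.0) * 1e-8
        inv = np.where(w > cutoff, 1.0 / np.where(w > cutoff, w, 1.0), 0.0)
        return (v * inv) @ v.T


def _nearest_pd(mat: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    sym = (mat + mat.T) / 2
    w, v = np.linalg.eigh(sym)
    if w.min() > eps:
        return sym
    warnings.warn("covariance not positive definite; projecting to nearest PD",
                  stacklevel=3)
    return (v * np.clip(w, eps, None)) @ v.T


def _weighted_pi(freqs: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    w = sizes / sizes.sum()
    return freqs @ w


def estimate_omega(
    freqs: np.ndarray,
    sample_sizes: np.ndarray,
    correct_sampling_noise: bool = True,
    min_sites: int = 200,
    pi: np.ndarray | None = None,
) -> CovarianceModel:
    """Moment estimate of Omega from per-population sample frequencies.

    ``freqs`` is (sites x J); ``sample_sizes`` the allele-draw count per
    population (2 x diploids).  Per site the ancestral frequency is the
    count-weighted mean of the sample frequencies (or the true values when
    ``pi`` is supplied); deviations are standardized by sqrt(pi (1 - pi))
    and averaged into Omega, with an unbiased binomial sampling-noise
    correction (a p(1-p)/(c_j - 1) term).

    With the count-weighted ancestral estimate the deviations satisfy an
    exact linear constraint, so only the projection of Omega onto the
    orthogonal complement of the weight vector is identifiable: the noise
    correction is projected the same way and the result is a PSD matrix of
    rank J - 1.  The scoring statistic consumes that projection identically
    on real data and POD draws, so threshold calibration is unaffected.
    When true ``pi`` values are given there is no constraint and the full
    Omega is recovered.
    """
    freqs = np.asarray(freqs, dtype=float)
    sizes = np.asarray(sample_sizes, dtype=float)
    if freqs.ndim != 2 or freqs.shape[1] != len(sizes):
        raise ValueError("freqs must be (sites x J) matching sample_sizes")
    projected = pi is None
    pi_vals = _weighted_pi(freqs, sizes) if projected else np.asarray(pi, dtype=float)
    keep = (pi_vals > 0) & (pi_vals < 1)
    freqs, pi_vals = freqs[keep], pi_vals[keep]
    n_sites = freqs.shape[0]
    if n_sites < min_sites:
        raise ValueError(f"need >= {min_sites} polymorphic sites, got {n_sites}")
    scale = np.sqrt(pi_vals * (1 - pi_vals))[:, None]
    alpha = (freqs - pi_vals[:, None]) / scale
    omega = alpha.T @ alpha / n_sites
    if correct_sampling_noise:
        # E[(p_hat - p)^2 | p] = p(1-p)/c_j; p_hat(1-p_hat) c/(c-1) is
        # unbiased for p(1-p)
        noise_diag = np.diag(
            ((freqs * (1 - freqs)) / (sizes[None, :] - 1)
             / (pi_vals * (1 - pi_vals))[:, None]).mean(axis=0)
        )
        if projected:
            w = sizes / sizes.sum()
            P = np.eye(len(sizes)) - np.outer(np.ones(len(sizes)), w)
            noise_diag = P @ noise_diag @ P.T
        omega -= noise_diag
    if projected:
        w = sizes / sizes.sum()
        P = np.eye(len(sizes)) - np.outer(np.ones(len(sizes)), w)
        omega = P @ omega @ P.T
        # PSD clip within the identifiable subspace (rank J - 1)
        ev, V = np.linalg.eigh((omega + omega.T) / 2)
        floor = max(ev.max(), 0.0) * 1e-10
        omega = (V * np.clip(ev, floor, None)) @ V.T
        omega = P @ omega @ P.T
    else:
        omega = _nearest_pd(omega)
    mean, var = float(pi_vals.mean()), float(pi_vals.var())
    t = max(mean * (1 - mean) / max(var, 1e-12) - 1, 1e-3)
    pi_params = (max(mean * t, 1e-3), max((1 - mean) * t, 1e-3))
    return CovarianceModel(omega=omega, pi_params=pi_params, sample_sizes=sizes)


def xtx_statistic(freqs: np.ndarray, model: CovarianceModel) -> np.ndarray:
    """Whitened squared-deviation statistic per site.

    alpha_j = (p_j - pi) / sqrt(pi (1 - pi)) with pi the count-weighted
    mean frequency; XtX = alpha' Omega^-1 alpha.  Sites with pi in {0, 1}
    are NaN.  Invariant to allele polarity.
    """
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    pi = _weighted_pi(freqs, model.sample_sizes)
    out = np.full(freqs.shape[0], np.nan)
    ok = (pi > 0) & (pi < 1)
    if ok.any():
        scale = np.sqrt(pi[ok] * (1 - pi[ok]))[:, None]
        alpha = (freqs[ok] - pi[ok][:, None]) / scale
        out[ok] = np.einsum("ij,jk,ik->i", alpha, model.omega_inv(), alpha)
    return out


def pod_sample_frequencies(
    model: CovarianceModel, n_loci: int, seed: int
) -> np.ndarray:
    """Sample-frequency matrix for a pseudo-observed dataset.

    pi ~ Beta(pi_params); population frequencies ~ MVN(pi 1, pi(1-pi) Omega)
    truncated to [0, 1]; allele counts binomial at the observed sample sizes.
    """
    rng = np.random.default_rng(seed)
    a, b = model.pi_params
    pi = rng.beta(a, b, size=n_loci)
    ev, V = np.linalg.eigh((model.omega + model.omega.T) / 2)
    root = V * np.sqrt(np.clip(ev, 0.0, None))
    z = rng.standard_normal((n_loci, model.J)) @ root.T
    p = np.clip(pi[:, None] + np.sqrt(pi * (1 - pi))[:, None] * z, 0.0, 1.0)
    sizes = model.sample_sizes.astype(int)
    counts = rng.binomial(sizes[None, :], p)
    return counts / sizes[None, :]


def pod_calibrate(
    model: CovarianceModel,
    n_loci: int = 100_000,
    quantile: float = 0.99,
    seed: int = 0,
    return_values: bool = False,
):
    """POD-quantile significance threshold for the XtX scan.

    Simulates ``n_loci`` loci from the fitted model, scores them with the
    same statistic used on real data, and returns the requested quantile of
    the defined values (default the 0.99 quantile of 100,000 loci).
    """
    freqs = pod_sample_frequencies(model, n_loci, seed)
    values = xtx_statistic(freqs, model)
    values = values[~np.isnan(values)]
    threshold = float(np.quantile(values, quantile))
    if return_values:
        return threshold, values
    return threshold


@dataclass
class XtXResult:
    """Scored sites with the calibration threshold applied."""

    xtx: np.ndarray
    threshold: float
    outlier: np.ndarray

    @classmethod
    def from_scan(cls, xtx: np.ndarray, threshold: float) -> "XtXResult":
        with np.errstate(invalid="ignore"):
            return cls(xtx=xtx, threshold=threshold,
                       outlier=np.where(np.isnan(xtx), False, xtx > threshold))


def population_frequencies(
    gm: GenotypeMatrix, pops: PopulationMap, level: str = "clade"
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-population alt-allele sample frequencies (sites x J) and
    allele-draw counts, from non-missing calls."""
    groups = pops.group_indices(gm, level=level)
    names = sorted(groups)
    freqs = np.empty((gm.n_sites, len(names)))
    sizes = np.empty(len(names))
    for j, name in enumerate(names):
        d = gm.dosages[groups[name]]
        obs = d >= 0
        n_alleles = 2 * obs.sum(axis=0)
        alt = np.where(obs, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[:, j] = np.where(n_alleles > 0, alt / n_alleles, np.nan)
        sizes[j] = 2 * d.shape[0]
    return freqs, sizes, names
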