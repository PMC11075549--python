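"""Linear-mixed-model association scan with centered kinship, BH-FDR, and
sliding-window peak calling.

Model per SNP: y = 1 b0 + x b + u + e with u ~ N(0, sg^2 K), e ~ N(0, se^2 I).
K is eigendecomposed once, the model rotated, and the variance ratio
lambda = sg^2 / se^2 profiled per SNP by a REML grid-plus-refine search on
log10 lambda in [-5, 5].  The SNP test is a Wald t-test on b.

When K = I the rotation is trivial and every p-value reduces exactly to the
ordinary least-squares t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomics_io import GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "centered_kinship",
    "lmm_assoc",
    "bh_fdr",
    "call_peaks",
]

_LOG10_LAMBDA_GRID = np.linspace(-5.0, 5.0, 101)


@dataclass
class KinshipMatrix:
    K: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self):
        K = np.asarray(self.K, dtype=float)
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        self.K = (K + K.T) / 2


def centered_kinship(gm: GenotypeMatrix) -> KinshipMatrix:
    """K = Wc Wc' / p with Wc the site-centered dosage matrix over p sites.

    Missing dosages are mean-imputed per site for this computation only
    (centering then zeroes them out).  Row sums of K vanish by construction.
    """
    W = gm.dosages.astype(float)
    obs = gm.dosages >= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        site_mean = np.where(obs, W, 0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
    W = np.where(obs, W, site_mean[None, :])
    Wc = W - W.mean(axis=0)
    K = Wc @ Wc.T / gm.n_sites
    return KinshipMatrix(K=K, sample_ids=gm.sample_ids.copy())


def _reml_scan(y_r, one_r, G_r, s, grid=_LOG10_LAMBDA_GRID):
    """Vectorized REML profile over a lambda grid for all SNPs at once.

    Inputs are rotated (U'y, U'1, U'G) with eigenvalues s.  Returns per-SNP
    best log10 lambda plus the grid criterion matrix for refinement.
    """
    m = G_r.shape[1]
    n = len(y_r)
    crit = np.empty((len(grid), m))
    for gi, ll in enumerate(grid):
        lam = 10.0 ** ll
        d = 1.0 / (lam * s + 1.0)
        a11 = d @ (one_r ** 2)
        a12 = (d * one_r) @ G_r
        a22 = d @ (G_r ** 2)
        b1 = d @ (one_r * y_r)
        b2 = (d * y_r) @ G_r
        yy = d @ (y_r ** 2)
        det = a11 * a22 - a12 ** 2
        det = np.where(det <= 0, np.nan, det)
        beta0 = (a22 * b1 - a12 * b2) / det
        beta1 = (a11 * b2 - a12 * b1) / det
        rss = yy - (beta0 * b1 + beta1 * b2)
        rss = np.maximum(rss, 1e-300)
        logdet_v = np.sum(np.log(lam * s + 1.0))
        crit[gi] = (n - 2) * np.log(rss) + logdet_v + np.log(det)
    best = np.nanargmin(crit, axis=0)
    # one parabolic refinement step in log10-lambda
    ll = grid[best].astype(float)
    interior = (best > 0) & (best < len(grid) - 1)
    if interior.any():
        i = best[interior]
        c0 = crit[i - 1, np.flatnonzero(interior)]
        c1 = crit[i, np.flatnonzero(interior)]
        c2 = crit[i + 1, np.flatnonzero(interior)]
        h = grid[1] - grid[0]
        denom = c0 - 2 * c1 + c2
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * h * (c0 - c2) / denom, 0.0)
        ll[interior] = grid[i] + np.clip(shift, -h, h)
    return ll


def _wald_for_lambda(y_r, one_r, g_r, s, log10_lam):
    lam = 10.0 ** log10_lam
    d = 1.0 / (lam * s + 1.0)
    a11 = float(d @ (one_r ** 2))
    a12 = float((d * one_r) @ g_r)
    a22 = float(d @ (g_r ** 2))
    b1 = float(d @ (one_r * y_r))
    b2 = float((d * y_r) @ g_r)
    yy = float(d @ (y_r ** 2))
    det = a11 * a22 - a12 ** 2
    if det <= 0:
        return np.nan, np.nan, np.nan
    beta0 = (a22 * b1 - a12 * b2) / det
    beta1 = (a11 * b2 - a12 * b1) / det
    n = len(y_r)
    rss = max(yy - (beta0 * b1 + beta1 * b2), 0.0)
    sigma2 = rss / (n - 2)
    var_beta1 = sigma2 * a11 / det
    if var_beta1 <= 0:
        return beta1, np.nan, np.nan
    se = np.sqrt(var_beta1)
    return beta1, se, lam


def lmm_assoc(
    gm: GenotypeMatrix,
    phenotype,
    K: KinshipMatrix,
    min_maf: float = 0.05,
) -> pd.DataFrame:
    """Per-SNP mixed-model Wald tests.

    ``phenotype`` is a pandas Series indexed by accession or an array in
    matrix order; it must be complete.  SNPs below ``min_maf`` are excluded.
    Association is complete-case per SNP: SNPs with missing calls are
    re-fit on the called subset (with the matching kinship submatrix).
    Returns a table (chrom, pos, site, maf, beta, se, wald, p, lambda).
    """
    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(gm.sample_ids).to_numpy(dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float)
    if len(y) != gm.n_accessions:
        raise ValueError("phenotype length does not match accessions")
    if np.isnan(y).any():
        raise ValueError("phenotype must be complete for included accessions")
    if np.std(y) == 0:
        raise ValueError("constant phenotype")
    Km = K.K
    evals = np.linalg.eigvalsh(Km)
    if evals.min() < -1e-6 * max(abs(evals.max()), 1.0):
        raise ValueError("kinship matrix is not positive semi-definite")

    f = gm.allele_frequencies()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(f, 1 - f)
    keep = ~np.isnan(maf) & (maf >= min_maf)
    sites = np.flatnonzero(keep)

    rows = []
    patterns: dict[bytes, list[int]] = {}
    for k_i, site in enumerate(sites):
        patterns.setdefault((gm.dosages[:, site] >= 0).tobytes(), []).append(site)

    for pat, pat_sites in patterns.items():
        obs = np.frombuffer(pat, dtype=bool)
        idx = np.flatnonzero(obs)
        if len(idx) < 4:
            continue
        y_sub = y[idx]
        K_sub = Km[np.ix_(idx, idx)]
        s, U = np.linalg.eigh(K_sub)
        s = np.clip(s, 0.0, None)
        y_r = U.T @ y_sub
        one_r = U.T @ np.ones(len(idx))
        G = gm.dosages[np.ix_(idx, np.array(pat_sites))].astype(float)
        G_r = U.T @ G
        ll = _reml_scan(y_r, one_r, G_r, s)
        n = len(idx)
        for col, site in enumerate(pat_sites):
            beta, se, lam = _wald_for_lambda(y_r, one_r, G_r[:, col], s, ll[col])
            if not np.isfinite(se) or se == 0:
                continue
            t = beta / se
            p = 2 * stats.t.sf(abs(t), df=n - 2)
            rows.append((gm.chrom[site], int(gm.pos[site]), int(site),
                         float(maf[site]), beta, se, t, max(p, 1e-300), lam))
    out = pd.DataFrame(
        rows, columns=["chrom", "pos", "site", "maf", "beta", "se", "wald", "p", "lambda"]
    )
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


def bh_fdr(pvals, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up: returns (rejected mask, p cutoff).

    Cutoff is the largest p(i) with p(i) <= i * alpha / m (0.0 when nothing
    is rejected).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= (np.arange(1, m + 1) * alpha / m)
    if not below.any():
        return np.zeros(m, dtype=bool), 0.0
    cutoff = float(ranked[np.flatnonzero(below)[-1]])
    return p <= cutoff, cutoff


def call_peaks(
    fits: pd.DataFrame,
    window_bp: int = 8000,
    step_bp: int = 4000,
    min_markers: int = 4,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Sliding-window peak calling over FDR-significant markers.

    Half-open windows [start, start + window_bp) advance by ``step_bp`` per
    chromosome; a window qualifies with >= ``min_markers`` significant
    markers inside; overlapping or adjacent qualifying windows merge into
    one region.  Output columns: chrom, start, end, n_markers_above, min_p.
    Output is invariant to input row order.
    """
    fits = fits.sort_values(["chrom", "pos"]).reset_index(drop=True)
    rejected, _ = bh_fdr(fits["p"].to_numpy(), alpha=fdr_alpha)
    sig = fits.loc[rejected]
    regions = []
    for chrom, sub in sig.groupby("chrom", sort=True):
        pos = np.sort(sub["pos"].to_numpy())
        if len(pos) < min_markers:
            continue
        lo = (int(pos.min()) // step_bp) * step_bp
        hi = int(pos.max())
        qualifying = []
        start = lo
        while start <= hi:
            count = int(np.sum((pos >= start) & (pos < start + window_bp)))
            if count >= min_markers:
                qualifying.append((start, start + window_bp))
            start += step_bp
        # merge overlapping/adjacent windows
        for win in qualifying:
            if regions and regions[-1][0] == chrom and win[0] <= regions[-1][2]:
                regions[-1][2] = max(regions[-1][2], win[1])
            else:
                regions.append([chrom, win[0], win[1]])
    rows = []
    for chrom, start, end in regions:
        inside = sig[(sig["chrom"] == chrom) & (sig["pos"] >= start) & (sig["pos"] < end)]
        rows.append((chrom, start, end, len(inside), float(inside["p"].min())))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_markers_above", "min_p"])
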