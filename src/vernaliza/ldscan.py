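"""Linkage disequilibrium: genotype-correlation r2, decay curves with
bootstrap confidence bands, and the inter-chromosomal resampling null used
to judge long-range LD among focal candidate-gene loci.

r2 is the squared Pearson correlation of dosage vectors over
pairwise-complete accessions — the genotype-correlation convention, so no
phase information is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomics_io import GenotypeMatrix

__all__ = [
    "LDResult",
    "InterchromNull",
    "R2Pool",
    "geno_r2",
    "pairwise_r2_matrix",
    "ld_decay",
    "interchrom_r2_sample",
    "resampled_mean_null",
    "focal_set_ld",
    "prune_perfect_ld",
]


def _single_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = (x >= 0) & (y >= 0)
    if ok.sum() < 2:
        return np.nan
    xs, ys = x[ok].astype(float), y[ok].astype(float)
    vx, vy = xs.var(), ys.var()
    if vx == 0 or vy == 0:
        return np.nan
    cov = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return cov * cov / (vx * vy)


def pairwise_r2_matrix(dosages: np.ndarray) -> np.ndarray:
    """Pairwise-complete r2 among all columns of a dosage matrix.

    Missing calls (-1) are excluded pair by pair via mask algebra; entries
    with < 2 complete cases or zero variance are NaN.
    """
    X = dosages.astype(float)
    M = (dosages >= 0).astype(float)
    X0 = np.where(dosages >= 0, X, 0.0)
    n = M.T @ M
    sx = X0.T @ M
    sy = sx.T
    sxy = X0.T @ X0
    sxx = (X0 ** 2).T @ M
    syy = sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx ** 2
        vary = n * syy - sy ** 2
        r2 = (cov * cov) / (varx * vary)
        r2[(n < 2) | (varx <= 0) | (vary <= 0)] = np.nan
    return r2


@dataclass
class LDResult:
    """Pair-level r2 records; distance is NaN for inter-chromosomal pairs."""

    site_i: np.ndarray
    site_j: np.ndarray
    distance_bp: np.ndarray
    r2: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "site_i": self.site_i, "site_j": self.site_j,
            "distance_bp": self.distance_bp, "r2": self.r2,
        })


def geno_r2(gm: GenotypeMatrix, pairs) -> LDResult:
    """r2 for explicit site-index pairs (undefined pairs are skipped)."""
    si, sj, dist, vals = [], [], [], []
    for i, j in pairs:
        r2 = _single_r2(gm.dosages[:, i], gm.dosages[:, j])
        if np.isnan(r2):
            continue
        si.append(i)
        sj.append(j)
        dist.append(abs(int(gm.pos[j]) - int(gm.pos[i]))
                    if gm.chrom[i] == gm.chrom[j] else np.nan)
        vals.append(r2)
    return LDResult(np.array(si, dtype=int), np.array(sj, dtype=int),
                    np.array(dist, dtype=float), np.array(vals, dtype=float))


def ld_decay(
    gm: GenotypeMatrix,
    max_dist_bp: int,
    bin_width_bp: int,
    seed: int = 0,
    n_bootstrap: int = 1000,
) -> pd.DataFrame:
    """Distance-binned mean r2 with a bootstrap 95% CI of the mean.

    All intra-chromosomal pairs within ``max_dist_bp`` enter; bins are
    half-open [lo, hi).  Thinning / MAF filtering are upstream concerns.
    Empty bins are omitted.
    """
    rng = np.random.default_rng(seed)
    r2_by_bin: dict[int, list[float]] = {}
    for c in pd.unique(gm.chrom):
        idx = np.flatnonzero(gm.chrom == c)
        pos = gm.pos[idx]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                d = pos[b] - pos[a]
                if d >= max_dist_bp:
                    break
                r2 = _single_r2(gm.dosages[:, idx[a]], gm.dosages[:, idx[b]])
                if not np.isnan(r2):
                    r2_by_bin.setdefault(int(d // bin_width_bp), []).append(r2)
    rows = []
    for b in sorted(r2_by_bin):
        vals = np.array(r2_by_bin[b])
        boots = rng.choice(vals, size=(n_bootstrap, len(vals)), replace=True).mean(axis=1)
        rows.append((
            b * bin_width_bp, (b + 1) * bin_width_bp, len(vals), float(vals.mean()),
            float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)),
        ))
    return pd.DataFrame(
        rows, columns=["bin_lo", "bin_hi", "n_pairs", "mean_r2", "ci_low", "ci_high"]
    )


@dataclass
class R2Pool:
    """A sampled pool of loci supporting on-demand cross-chromosome r2."""

    dosages: np.ndarray     # accessions x loci
    chrom: np.ndarray
    site_index: np.ndarray  # indices into the source matrix

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def cross_chrom_mean_r2(self, loci: np.ndarray) -> float:
        """Mean r2 over all cross-chromosome pairs among the given loci."""
        sub = pairwise_r2_matrix(self.dosages[:, loci])
        chrom = self.chrom[loci]
        cross = chrom[:, None] != chrom[None, :]
        iu = np.triu_indices(len(loci), k=1)
        vals = sub[iu][cross[iu]]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError("no defined cross-chromosome pairs among loci")
        return float(vals.mean())


def interchrom_r2_sample(
    gm: GenotypeMatrix,
    n_loci: int = 100_000,
    genic_regions=None,
    seed: int = 0,
    max_pairs: int = 2_000_000,
) -> tuple[R2Pool, np.ndarray]:
    """Random-locus pool plus a capped sample of cross-chromosome pair r2.

    Loci are drawn uniformly (restricted to ``genic_regions`` when given).
    All cross-chromosome pairs are scored unless their number exceeds
    ``max_pairs``, in which case a random subset of pairs is scored.
    """
    if len(pd.unique(gm.chrom)) < 2:
        raise ValueError("inter-chromosomal LD needs >= 2 chromosomes")
    rng = np.random.default_rng(seed)
    candidates = np.arange(gm.n_sites)
    if genic_regions is not None:
        from .genomics_io import extract_regions
        mask = np.zeros(gm.n_sites, dtype=bool)
        sub, _ = extract_regions(gm, genic_regions)
        lookup = {(c, p) for c, p in zip(sub.chrom, sub.pos)}
        for k in range(gm.n_sites):
            if (gm.chrom[k], gm.pos[k]) in lookup:
                mask[k] = True
        candidates = np.flatnonzero(mask)
    take = min(n_loci, len(candidates))
    chosen = np.sort(rng.choice(candidates, size=take, replace=False))
    pool = R2Pool(
        dosages=gm.dosages[:, chosen],
        chrom=gm.chrom[chosen],
        site_index=chosen,
    )
    cross_i, cross_j = np.nonzero(
        pool.chrom[:, None] != pool.chrom[None, :]
    )
    upper = cross_i < cross_j
    cross_i, cross_j = cross_i[upper], cross_j[upper]
    if len(cross_i) > max_pairs:
        pick = rng.choice(len(cross_i), size=max_pairs, replace=False)
        cross_i, cross_j = cross_i[pick], cross_j[pick]
    vals = np.array([
        _single_r2(pool.dosages[:, i], pool.dosages[:, j])
        for i, j in zip(cross_i, cross_j)
    ])
    return pool, vals[~np.isnan(vals)]


@dataclass
class InterchromNull:
    """Resampled-mean null for a focal set of k loci."""

    k: int
    n_resamples: int
    means: np.ndarray
    ci_low: float
    ci_high: float
    chrom_counts: dict | None = None


def resampled_mean_null(
    pool: R2Pool,
    k: int,
    n_resamples: int = 50_000,
    seed: int = 0,
    match_chrom_counts: dict | None = None,
) -> InterchromNull:
    """Null distribution of the mean cross-chromosome r2 of k random loci.

    Each resample draws k loci without replacement from the pool and takes
    the mean of all cross-chromosome pairwise r2 among them; the CI is the
    2.5/97.5 percentile band of those means.  When ``match_chrom_counts``
    is given (chromosome -> count, summing to k) each resample reproduces
    the focal set's per-chromosome configuration.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if pool.n_loci < k:
        raise ValueError("pool smaller than resample size k")
    rng = np.random.default_rng(seed)
    by_chrom = None
    if match_chrom_counts is not None:
        if sum(match_chrom_counts.values()) != k:
            raise ValueError("match_chrom_counts must sum to k")
        by_chrom = {c: np.flatnonzero(pool.chrom == c) for c in match_chrom_counts}
        for c, need in match_chrom_counts.items():
            if len(by_chrom[c]) < need:
                raise ValueError(f"pool has too few loci on {c}")
    means = np.empty(n_resamples)
    for b in range(n_resamples):
        for attempt in range(1000):
            if by_chrom is None:
                loci = rng.choice(pool.n_loci, size=k, replace=False)
            else:
                loci = np.concatenate([
                    rng.choice(by_chrom[c], size=need, replace=False)
                    for c, need in match_chrom_counts.items()
                ])
            try:
                means[b] = pool.cross_chrom_mean_r2(loci)
                break
            except ValueError:
                continue  # e.g. all loci on one chromosome: redraw
        else:
            raise ValueError("could not draw a resample with cross-chromosome pairs")
    return InterchromNull(
        k=k,
        n_resamples=n_resamples,
        means=means,
        ci_low=float(np.percentile(means, 2.5)),
        ci_high=float(np.percentile(means, 97.5)),
        chrom_counts=dict(match_chrom_counts) if match_chrom_counts else None,
    )


def focal_set_ld(
    gm: GenotypeMatrix, focal_sites, null: InterchromNull
) -> tuple[float, bool]:
    """Mean cross-chromosome r2 among focal sites, flagged against the null CI."""
    focal_sites = np.asarray(focal_sites, dtype=int)
    chroms = gm.chrom[focal_sites]
    if len(pd.unique(chroms)) < 2:
        raise ValueError("focal sites must span >= 2 chromosomes")
    pool = R2Pool(dosages=gm.dosages[:, focal_sites], chrom=chroms,
                  site_index=focal_sites)
    mean = pool.cross_chrom_mean_r2(np.arange(len(focal_sites)))
    return mean, mean > null.ci_high


def prune_perfect_ld(
    gm: GenotypeMatrix, window: int = 50, step: int = 5, r2_threshold: float = 0.9999
) -> GenotypeMatrix:
    """Sliding-window greedy removal of sites in (near-)perfect LD.

    Within each ``window``-SNP window advanced by ``step`` SNPs, the later
    member of any pair with r2 >= threshold is dropped — enough to collapse
    duplicate association signals within a gene.
    """
    drop = np.zeros(gm.n_sites, dtype=bool)
    for c in pd.unique(gm.chrom):
        idx = np.flatnonzero(gm.chrom == c)
        for start in range(0, len(idx), step):
            win = idx[start:start + window]
            keepers = win[~drop[win]]
            if len(keepers) < 2:
                continue
            r2 = pairwise_r2_matrix(gm.dosages[:, keepers])
            for a in range(len(keepers)):
                if drop[keepers[a]]:
                    continue
                for b in range(a + 1, len(keepers)):
                    if not drop[keepers[b]] and r2[a, b] >= r2_threshold:
                        drop[keepers[b]] = True
    return gm.take_sites(np.flatnonzero(~drop))
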