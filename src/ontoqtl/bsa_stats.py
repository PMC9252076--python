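"""Per-SNP bulk-segregant statistics for one pool contrast.

For each biallelic SNP with pooled allele depths (ref_a, alt_a) and
(ref_b, alt_b) this module computes

* the SNP-index of each pool: alt / (ref + alt),
* Delta(SNP-index) = index_b - index_a,
* the G statistic, the likelihood-ratio statistic of the 2x2
  allele-by-pool count table: G = 2 * sum_i n_i ln(n_i / nhat_i), with
  nhat_i the expected counts under row/column independence and the
  convention 0 * ln 0 = 0,
* G', a tricube-kernel weighted local average of G over a physical window
  (default total width 1 Mb), which suppresses single-SNP sampling noise,
* optional p/q-values from a log-normal null fitted robustly to the G'
  distribution, and
* simulation-based two-sided confidence intervals for Delta(SNP-index)
  under the null of no trait linkage, indexed by read depth
  (10,000 replicates and a 95% interval by default).

Candidate SNPs are those with G' above a threshold (default 2.5, strict
inequality) and, optionally, Delta outside the simulated null interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .variant_io import PoolVariant

SUPPORTED_DESIGNS = ("hetxdh-f1", "f2")


@dataclass(frozen=True)
class SmoothingConfig:
    """Tricube smoothing window. ``window_width`` is the total width W of
    the sliding window in bp; the kernel half-width is h = W/2 on each side
    of the focal SNP unless ``halfwidth_is_width`` interprets W as h."""

    window_width: int = 1_000_000
    halfwidth_is_width: bool = False

    def __post_init__(self) -> None:
        if self.window_width <= 0:
            raise ValueError("window_width must be positive")

    @property
    def halfwidth(self) -> float:
        return self.window_width if self.halfwidth_is_width else self.window_width / 2


@dataclass(frozen=True)
class ThresholdConfig:
    gprime_threshold: float = 2.5
    use_delta_ci: bool = True

    def __post_init__(self) -> None:
        if self.gprime_threshold < 0:
            raise ValueError("gprime_threshold must be >= 0")


@dataclass
class CiTable:
    """Empirical null quantiles of Delta(SNP-index) per read depth.

    ``lower``/``upper`` are aligned with ``depths``; ``bounds_at`` serves any
    depth by exact lookup or linear interpolation.
    """

    depths: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    replicates: int
    level: float
    pool_size_a: int
    pool_size_b: int
    design: str
    seed: int | None = None

    def bounds_at(self, depth) -> tuple[np.ndarray, np.ndarray]:
        d = np.asarray(depth, dtype=float)
        lo = np.interp(d, self.depths, self.lower)
        hi = np.interp(d, self.depths, self.upper)
        return lo, hi

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"depth": self.depths, "lower": self.lower, "upper": self.upper}
        )


def snp_index(ref_depth: int, alt_depth: int) -> float:
    """Fraction of reads carrying the alternate allele."""
    total = ref_depth + alt_depth
    if total <= 0:
        raise ValueError("SNP-index undefined at zero total depth")
    return alt_depth / total


def g_statistic(ref_a: int, alt_a: int, ref_b: int, alt_b: int) -> float:
    """Likelihood-ratio G of the 2x2 allele-by-pool table.

    G = 2 sum n ln(n/nhat) over the four cells, expected counts nhat from
    row/column independence; 0 ln 0 = 0. Zero iff the two pools have
    identical allele proportions.
    """
    if ref_a + alt_a <= 0 or ref_b + alt_b <= 0:
        raise ValueError("G undefined when a pool has zero total depth")
    obs = np.array([[ref_a, alt_a], [ref_b, alt_b]], dtype=float)
    total = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    return float(max(2.0 * terms.sum(), 0.0))


def tricube_weights(distances, halfwidth: float) -> np.ndarray:
    """Tricube kernel (1 - (d/h)^3)^3 for d <= h, zero beyond."""
    d = np.abs(np.asarray(distances, dtype=float))
    w = np.zeros_like(d)
    inside = d <= halfwidth
    w[inside] = (1.0 - (d[inside] / halfwidth) ** 3) ** 3
    return w


def smooth_gprime(positions, g, config: SmoothingConfig | None = None) -> np.ndarray:
    """Tricube-smoothed G' for position-sorted SNPs of ONE chromosome.

    G'_i = sum_j k_j G_j / sum_j k_j with k_j the tricube weight of the
    distance |pos_j - pos_i| at half-width h. Never call this across
    chromosome boundaries; smooth each chromosome separately.
    """
    cfg = config or SmoothingConfig()
    pos = np.asarray(positions, dtype=float)
    g = np.asarray(g, dtype=float)
    if pos.shape != g.shape:
        raise ValueError("positions and g must have equal length")
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted within a chromosome")
    h = cfg.halfwidth
    out = np.empty_like(g)
    left = np.searchsorted(pos, pos - h, side="left")
    right = np.searchsorted(pos, pos + h, side="right")
    for i in range(len(pos)):
        sl = slice(left[i], right[i])
        w = tricube_weights(pos[sl] - pos[i], h)
        out[i] = np.dot(w, g[sl]) / w.sum()
    return out


def null_pvalues(gprime, trim_k: float = 5.2) -> tuple[np.ndarray, np.ndarray]:
    """Right-tail p and Benjamini-Hochberg q from a log-normal G' null.

    The null is fitted robustly: ln G' values beyond ``trim_k`` median
    absolute deviations above the median (a one-sided Hampel rule, so real
    QTL peaks do not inflate the null) are set aside, and the log-normal
    location/scale are the median and scaled MAD of the remainder.
    """
    from statsmodels.stats.multitest import multipletests

    gp = np.asarray(gprime, dtype=float)
    if gp.size < 50:
        raise ValueError("need >= 50 SNPs to fit the G' null")
    if np.any(gp <= 0):
        raise ValueError("G' must be positive for the log-normal null")
    lg = np.log(gp)
    med = np.median(lg)
    mad = np.median(np.abs(lg - med))
    if mad == 0:
        raise ValueError(
            "degenerate (constant) G' distribution; use the fixed-threshold "
            "mode instead of fitted p-values"
        )
    keep = lg <= med + trim_k * mad
    mu = np.median(lg[keep])
    sigma = 1.4826 * np.median(np.abs(lg[keep] - mu))
    p = sps.lognorm.sf(gp, s=sigma, scale=np.exp(mu))
    q = multipletests(p, method="fdr_bh")[1]
    return p, q


def _sample_pool_frequencies(rng, n_ind: int, size: int, design: str) -> np.ndarray:
    """Null alt-allele frequency of a pool of ``n_ind`` diploid individuals.

    "hetxdh-f1": F1 of a heterozygous x doubled-haploid cross; each
    individual carries the alt allele on 0 or 1 of its two homologs with
    probability 1/2 (1:1 segregation), so the pool frequency is
    Binomial(n, 1/2) / (2n). "f2": alt dosage per individual is
    Binomial(2, 1/2), pool frequency Binomial(2n, 1/2) / (2n).
    """
    if design == "hetxdh-f1":
        return rng.binomial(n_ind, 0.5, size=size) / (2 * n_ind)
    if design == "f2":
        return rng.binomial(2 * n_ind, 0.5, size=size) / (2 * n_ind)
    raise ValueError(
        f"unknown design {design!r}; supported: {list(SUPPORTED_DESIGNS)}"
    )


def simulate_delta_ci(
    pool_size_a: int,
    pool_size_b: int,
    depths,
    design: str = "hetxdh-f1",
    replicates: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
    max_exact_depths: int = 48,
) -> CiTable:
    """Simulate the null Delta(SNP-index) confidence band per read depth.

    Each replicate draws a true allele frequency for each pool from the
    cross design's segregation, then an alt read count Binomial(depth,
    frequency) per pool; the band is the two-sided empirical ``level``
    quantile interval of index_b - index_a. When more than
    ``max_exact_depths`` distinct depths are requested the band is computed
    on a quantile grid and interpolated.
    """
    if pool_size_a < 1 or pool_size_b < 1:
        raise ValueError("pool sizes must be >= 1")
    depths = np.unique(np.asarray(list(depths), dtype=int))
    if depths.size == 0:
        raise ValueError("depths must be nonempty")
    if np.any(depths < 1):
        raise ValueError("depths must be positive")
    if design not in SUPPORTED_DESIGNS:
        raise ValueError(
            f"unknown design {design!r}; supported: {list(SUPPORTED_DESIGNS)}"
        )
    if depths.size > max_exact_depths:
        grid = np.unique(
            np.quantile(depths, np.linspace(0, 1, max_exact_depths)).astype(int)
        )
    else:
        grid = depths

    rng = np.random.default_rng(seed)
    alpha = (1.0 - level) / 2.0
    lower = np.empty(grid.size)
    upper = np.empty(grid.size)
    for i, d in enumerate(grid):
        fa = _sample_pool_frequencies(rng, pool_size_a, replicates, design)
        fb = _sample_pool_frequencies(rng, pool_size_b, replicates, design)
        delta = rng.binomial(d, fb) / d - rng.binomial(d, fa) / d
        lower[i] = np.quantile(delta, alpha)
        upper[i] = np.quantile(delta, 1.0 - alpha)
    return CiTable(
        depths=grid.astype(float),
        lower=lower,
        upper=upper,
        replicates=replicates,
        level=level,
        pool_size_a=pool_size_a,
        pool_size_b=pool_size_b,
        design=design,
        seed=seed,
    )


def compute_contrast_stats(
    variants,
    contrast,
    smoothing: SmoothingConfig | None = None,
    fit_null: bool = False,
) -> pd.DataFrame:
    """Build the per-SNP statistics table for one pool contrast.

    Takes filtered :class:`~ontoqtl.variant_io.PoolVariant` records (SNPs
    only are used), returns a DataFrame with columns chrom, pos, ref, alt,
    depth_a/b, snp_index_a/b, delta, g, gprime (and p_value/q_value when
    ``fit_null``). Pool order within the contrast is (a, b); positive delta
    means the alt allele is enriched in pool b.
    """
    a, b = contrast
    rows = []
    for v in variants:
        if not isinstance(v, PoolVariant) or not v.is_snp:
            continue
        pa, pb = v.pools[a], v.pools[b]
        if pa.depth == 0 or pb.depth == 0:
            continue
        ia = snp_index(pa.ref_depth, pa.alt_depth)
        ib = snp_index(pb.ref_depth, pb.alt_depth)
        rows.append(
            (
                v.chrom,
                v.pos,
                v.ref_allele,
                v.alt_allele,
                pa.depth,
                pb.depth,
                ia,
                ib,
                ib - ia,
                g_statistic(pa.ref_depth, pa.alt_depth, pb.ref_depth, pb.alt_depth),
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "depth_a",
            "depth_b",
            "snp_index_a",
            "snp_index_b",
            "delta",
            "g",
        ],
    )
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    cfg = smoothing or SmoothingConfig()
    gprime = np.empty(len(df))
    for _, idx in df.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        gprime[idx] = smooth_gprime(
            df.loc[idx, "pos"].to_numpy(), df.loc[idx, "g"].to_numpy(), cfg
        )
    df["gprime"] = gprime
    if fit_null:
        p, q = null_pvalues(df["gprime"].to_numpy())
        df["p_value"] = p
        df["q_value"] = q
    return df


def flag_candidates(
    stats: pd.DataFrame,
    thresholds: ThresholdConfig | None = None,
    ci: CiTable | None = None,
) -> pd.DataFrame:
    """Mark candidate SNPs: G' strictly above the threshold and, when
    ``use_delta_ci``, Delta(SNP-index) outside the simulated null band for
    the SNP's depth (the rounded mean of the two pool depths)."""
    thr = thresholds or ThresholdConfig()
    out = stats.copy()
    flagged = out["gprime"].to_numpy() > thr.gprime_threshold
    if thr.use_delta_ci:
        if ci is None:
            raise ValueError("use_delta_ci requires a CiTable")
        depth = np.round(
            (out["depth_a"].to_numpy() + out["depth_b"].to_numpy()) / 2.0
        )
        lo, hi = ci.bounds_at(depth)
        delta = out["delta"].to_numpy()
        flagged &= (delta < lo) | (delta > hi)
    out["flagged"] = flagged
    return out
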