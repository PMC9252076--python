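"""Collapse flagged SNPs into candidate QTL intervals and export them.

A region is a maximal run of flagged SNPs on one chromosome in which
consecutive flagged SNPs are no more than ``max_gap`` bp apart; runs with
fewer than ``min_snps`` members are discarded. Unflagged SNPs lying inside
a run are ignored — they neither break nor extend it. Region coordinates
are 1-based inclusive internally (VCF/GFF3 convention); BED export is the
only place they are converted to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class RegionConfig:
    max_gap: int = 1_000_000
    min_snps: int = 10

    def __post_init__(self) -> None:
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")


@dataclass(frozen=True)
class QtlRegion:
    """A contiguous candidate interval for one contrast; span = positions
    of the first and last member SNP."""

    contrast: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    n_snps: int
    max_gprime: float
    mean_gprime: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and max(self.start, start) <= min(self.end, end)


def contrast_id(contrast) -> str:
    a, b = contrast
    return f"{a}-{b}"


def call_regions(
    stats: pd.DataFrame,
    contrast: str,
    config: RegionConfig | None = None,
) -> list[QtlRegion]:
    """Call QTL regions from a flagged per-SNP statistics table.

    ``stats`` needs columns chrom, pos, gprime, flagged (see
    :func:`ontoqtl.bsa_stats.flag_candidates`); only flagged SNPs take part.
    """
    cfg = config or RegionConfig()
    regions: list[QtlRegion] = []
    flagged = stats[stats["flagged"]]
    for chrom, grp in flagged.groupby("chrom", sort=True):
        grp = grp.sort_values("pos", kind="stable")
        pos = grp["pos"].to_numpy()
        gp = grp["gprime"].to_numpy()
        run_start = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > cfg.max_gap:
                n = i - run_start
                if n >= cfg.min_snps:
                    gslice = gp[run_start:i]
                    regions.append(
                        QtlRegion(
                            contrast=contrast,
                            chrom=str(chrom),
                            start=int(pos[run_start]),
                            end=int(pos[i - 1]),
                            n_snps=n,
                            max_gprime=float(gslice.max()),
                            mean_gprime=float(gslice.mean()),
                        )
                    )
                run_start = i
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def _bed_score(max_gprime: float) -> int:
    # BED scores are capped at 1000; 100x G' keeps two decimals visible.
    return min(1000, int(round(100 * max_gprime)))


def write_regions(regions, path) -> None:
    """Write regions as BED6+3 (0-based half-open; name = contrast id,
    score = 100 x max G' capped at 1000; extra columns n_snps, max_gprime,
    mean_gprime preserve the full record for round-tripping)."""
    regions = sorted(regions, key=lambda r: (r.chrom, r.start))
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tname\tscore\tstrand\t"
            "n_snps\tmax_gprime\tmean_gprime\n"
        )
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.contrast}\t"
                f"{_bed_score(r.max_gprime)}\t.\t"
                f"{r.n_snps}\t{r.max_gprime:.10g}\t{r.mean_gprime:.10g}\n"
            )


def read_regions(path) -> list[QtlRegion]:
    """Parse a BED6+3 file written by :func:`write_regions`."""
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            regions.append(
                QtlRegion(
                    contrast=f[3],
                    chrom=f[0],
                    start=int(f[1]) + 1,
                    end=int(f[2]),
                    n_snps=int(f[6]),
                    max_gprime=float(f[7]),
                    mean_gprime=float(f[8]),
                )
            )
    return regions


def regions_to_frame(regions) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contrast": r.contrast,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_snps": r.n_snps,
                "max_gprime": r.max_gprime,
                "mean_gprime": r.mean_gprime,
            }
            for r in regions
        ]
    )
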