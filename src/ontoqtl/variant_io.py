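"""Pooled-bulk variant input and genotype filtering.

Reads a joint-genotyped multi-sample VCF of phenotype pools, pairs pools
into contrasts, and applies the depth / genotype-quality / reference-allele
frequency filters that precede bulk-segregant statistics:

* per-pool coverage >= 40x,
* combined coverage of the contrast pair within [100x, 400x]
  (repeat-like excess coverage removed),
* GATK genotype quality >= 99,
* reference-allele frequency >= 0.2 (conservative, assuming one parent is a
  homozygous reference line).

Depth is always taken from the allelic depths (AD), i.e. ref + alt reads,
so the same counts feed the downstream statistics.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Fraction of the summed alt depth one allele must carry for a
#: multi-allelic record to be split into a biallelic one.
MULTIALLELIC_DOMINANCE = 0.95

FILTER_RULES = (
    "pool_depth",
    "combined_depth_low",
    "combined_depth_high",
    "genotype_quality",
    "ref_frequency",
)


@dataclass(frozen=True)
class PoolDepth:
    """Allelic depths and genotype quality of one pool at one site."""

    ref_depth: int
    alt_depth: int
    gq: int

    @property
    def depth(self) -> int:
        return self.ref_depth + self.alt_depth


@dataclass(frozen=True)
class PoolVariant:
    """One biallelic variant with per-pool allelic depths.

    Coordinates are 1-based (VCF convention). ``is_snp`` distinguishes
    single-nucleotide substitutions from indels/MNVs; non-SNP records are
    carried through so the effect classifier can see them, but the BSA
    statistics use SNPs only.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    pools: dict[str, PoolDepth]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for label, pd in self.pools.items():
            if pd.ref_depth < 0 or pd.alt_depth < 0:
                raise ValueError(f"negative depth for pool {label!r}")

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the pooled-genotype filters.

    ``ref_freq_mode`` selects whether the reference-allele frequency is
    computed on the summed depths of the two pools of the contrast
    ("combined", default) or must hold in each pool separately ("per-pool").
    """

    min_pool_depth: int = 40
    min_combined_depth: int = 100
    max_combined_depth: int = 400
    min_gq: int = 99
    min_ref_freq: float = 0.2
    ref_freq_mode: str = "combined"

    def __post_init__(self) -> None:
        if not 0 <= self.min_ref_freq < 1:
            raise ValueError("min_ref_freq must be in [0, 1)")
        if self.min_combined_depth > self.max_combined_depth:
            raise ValueError("min_combined_depth > max_combined_depth")
        if self.ref_freq_mode not in ("combined", "per-pool"):
            raise ValueError(f"unknown ref_freq_mode {self.ref_freq_mode!r}")


@dataclass
class FilterReport:
    """Per-rule removal counts; each record is attributed to the first rule
    it fails, so input = surviving + sum(removed)."""

    n_input: int = 0
    n_surviving: int = 0
    removed: dict[str, int] = field(
        default_factory=lambda: {rule: 0 for rule in FILTER_RULES}
    )

    def as_dict(self) -> dict:
        return {
            "input": self.n_input,
            "surviving": self.n_surviving,
            **{f"removed_{k}": v for k, v in self.removed.items()},
        }


def read_pool_variants(vcf_path, pool_names) -> list[PoolVariant]:
    """Read per-pool allelic depths for ``pool_names`` from a VCF.

    Multi-allelic records are reduced to the dominant alternate allele when
    that allele carries at least 95% of the summed alt depth across the
    requested pools; otherwise the record is dropped (with a log message).
    Records are returned sorted by (chrom, pos).

    Raises ``KeyError`` if a requested pool is missing from the VCF sample
    list and ``ValueError`` if a record lacks the AD format field.
    """
    from cyvcf2 import VCF

    pool_names = list(pool_names)
    vcf = VCF(str(vcf_path))
    missing = [p for p in pool_names if p not in vcf.samples]
    if missing:
        raise KeyError(
            f"pool(s) {missing} not in VCF sample list {vcf.samples}"
        )
    idx = [vcf.samples.index(p) for p in pool_names]

    out: list[PoolVariant] = []
    n_dropped_multi = 0
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            raise ValueError(
                f"record {rec.CHROM}:{rec.POS} has no AD format field"
            )
        gq = rec.format("GQ")
        alts = rec.ALT
        if not alts:
            continue
        if len(alts) > 1:
            # summed alt depth per alt allele across the requested pools
            alt_totals = [
                sum(max(int(ad[i][1 + a]), 0) for i in idx)
                for a in range(len(alts))
            ]
            total = sum(alt_totals)
            best = max(range(len(alts)), key=alt_totals.__getitem__)
            if total == 0 or alt_totals[best] < MULTIALLELIC_DOMINANCE * total:
                n_dropped_multi += 1
                continue
            alt_i = best
        else:
            alt_i = 0
        pools = {}
        for p, i in zip(pool_names, idx):
            rd = max(int(ad[i][0]), 0)
            alt_d = max(int(ad[i][1 + alt_i]), 0)
            g = int(np.asarray(gq[i]).reshape(-1)[0]) if gq is not None else 0
            pools[p] = PoolDepth(ref_depth=rd, alt_depth=alt_d, gq=g)
        out.append(
            PoolVariant(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref_allele=rec.REF,
                alt_allele=alts[alt_i],
                pools=pools,
            )
        )
    if n_dropped_multi:
        logger.info(
            "dropped %d multi-allelic records without a dominant alt allele",
            n_dropped_multi,
        )
    out.sort(key=lambda v: (v.chrom, v.pos))
    return out


def enumerate_contrasts(pool_labels) -> list[tuple[str, str]]:
    """All n(n-1)/2 unordered pool pairs, in lexicographic input order.

    With the four flowering-time pools (EF, IF, LF, NF) this yields the six
    contrasts EF-IF, EF-LF, EF-NF, IF-LF, IF-NF, LF-NF.
    """
    labels = list(pool_labels)
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate pool labels: {dupes}")
    if len(labels) < 2:
        raise ValueError("need at least two pools to form a contrast")
    return list(itertools.combinations(labels, 2))


def _first_failing_rule(
    v: PoolVariant, a: str, b: str, cfg: FilterConfig
) -> str | None:
    pa, pb = v.pools[a], v.pools[b]
    if pa.depth < cfg.min_pool_depth or pb.depth < cfg.min_pool_depth:
        return "pool_depth"
    combined = pa.depth + pb.depth
    if combined < cfg.min_combined_depth:
        return "combined_depth_low"
    if combined > cfg.max_combined_depth:
        return "combined_depth_high"
    if pa.gq < cfg.min_gq or pb.gq < cfg.min_gq:
        return "genotype_quality"
    if cfg.ref_freq_mode == "combined":
        ref = pa.ref_depth + pb.ref_depth
        if ref / combined < cfg.min_ref_freq:
            return "ref_frequency"
    else:
        for p in (pa, pb):
            if p.depth and p.ref_depth / p.depth < cfg.min_ref_freq:
                return "ref_frequency"
    return None


def apply_filters(
    variants, contrast, config: FilterConfig | None = None
) -> tuple[list[PoolVariant], FilterReport]:
    """Apply the pooled-genotype filters for one contrast.

    Rules are evaluated in a fixed order (per-pool depth, combined depth low
    then high, genotype quality, reference-allele frequency) and each removed
    record is counted against the first rule it fails.
    """
    cfg = config or FilterConfig()
    a, b = contrast
    report = FilterReport()
    survivors: list[PoolVariant] = []
    for v in variants:
        report.n_input += 1
        rule = _first_failing_rule(v, a, b, cfg)
        if rule is None:
            survivors.append(v)
        else:
            report.removed[rule] += 1
    report.n_surviving = len(survivors)
    return survivors, report


def write_filtered_vcf(path, variants, pool_names) -> None:
    """Write variants back out as a minimal VCF with AD and GQ."""
    pool_names = list(pool_names)
    variants = list(variants)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted({v.chrom for v in variants}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths">\n'
        )
        fh.write(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,'
            'Description="Genotype Quality">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(pool_names)
            + "\n"
        )
        for v in variants:
            cells = []
            for p in pool_names:
                pd = v.pools[p]
                gt = "0/1" if pd.alt_depth and pd.ref_depth else (
                    "1/1" if pd.alt_depth else "0/0"
                )
                cells.append(f"{gt}:{pd.ref_depth},{pd.alt_depth}:{pd.gq}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\t.\t.\tGT:AD:GQ\t" + "\t".join(cells) + "\n"
            )
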