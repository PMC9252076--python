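"""Synthetic pooled-BSA data with a planted QTL, plus toy fixtures.

Emulates the study design end to end so the whole pipeline can run and be
validated offline:

* an F1 population from a heterozygous x doubled-haploid cross (markers
  segregate 1:1; an F2 design is available), genotyped at evenly spaced
  markers linked through per-interval recombination (Haldane map),
* a quantitative trait = causal-allele dosage x effect + Gaussian noise,
* individuals ranked by trait and binned into pools (default four pools of
  11/8/11/9 individuals), each pool sequenced to ~110x: per-marker read
  depth is Poisson, alternate-read counts Binomial at the pool's true
  allele frequency, genotype quality fixed at 99,
* toy genome/GFF3/OBO/annotation/GMT fixtures with planted coding variants
  (non-synonymous inside the QTL, a stop-gain outside) and a planted
  "circadian-like" pathway enriched among the focus-term genes.

The defaults are the study conditions, not tuning knobs: 500 markers over
two 5-Mb chromosomes (the genome is a scaled-down stand-in, so the
recombination rate of 0.25 crossovers/Mb gives it a realistic ~250 cM
total map), causal locus mid-chromosome, effect/noise-s.d. ratio 2 and
read depth matching the sequenced pools. A ``TruthRecord`` retains every
latent quantity for parameter-recovery checks, and ``generate_fixtures``
writes a manifest of all planted truths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .gene_effects import CdsSegment, GeneModel, revcomp, CODON_TABLE
from .variant_io import PoolDepth, PoolVariant, write_filtered_vcf

DEFAULT_POOL_LABELS = ("EF", "IF", "LF", "NF")
DEFAULT_POOL_SIZES = (11, 8, 11, 9)

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_SAFE_CODONS = sorted(set(CODON_TABLE) - _STOP_CODONS - {"ATG"})


@dataclass(frozen=True)
class PlantedVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    expected_effect: str = ""
    gene_id: str = ""


@dataclass
class SimConfig:
    """Parameters of the pooled-cross simulation."""

    chrom_lengths: dict = field(
        default_factory=lambda: {"C1": 5_000_000, "C2": 5_000_000}
    )
    n_markers: int = 500
    causal_chrom: str = "C1"
    causal_pos: int = 2_500_000
    recombination_rate: float = 0.25  # crossovers per Mb (Haldane map)
    pool_labels: tuple = DEFAULT_POOL_LABELS
    pool_sizes: tuple = DEFAULT_POOL_SIZES
    effect: float = 1.0
    noise_sd: float = 0.5
    mean_depth: float = 110.0
    design: str = "hetxdh-f1"
    gq: int = 99
    error_rate: float = 0.0  # per-read miscall probability
    censor_threshold: float | None = None
    planted: tuple = ()  # extra PlantedVariant markers
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.pool_labels) != len(self.pool_sizes):
            raise ValueError("pool_labels and pool_sizes length mismatch")
        if len(self.pool_sizes) < 2:
            raise ValueError("need >= 2 pools")
        if any(s < 1 for s in self.pool_sizes):
            raise ValueError("pool sizes must be >= 1")
        if self.causal_chrom not in self.chrom_lengths:
            raise ValueError(f"causal chromosome {self.causal_chrom!r} unknown")
        if not 1 <= self.causal_pos <= self.chrom_lengths[self.causal_chrom]:
            raise ValueError("causal position outside its chromosome")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")

    @property
    def n_individuals(self) -> int:
        return int(sum(self.pool_sizes))


@dataclass
class TruthRecord:
    """Latent state of one simulation, aligned with the emitted VCF."""

    causal_chrom: str
    causal_pos: int
    pool_labels: tuple
    pool_sizes: tuple
    assignment: np.ndarray  # individual -> pool index (trait-ranked bins)
    trait: np.ndarray
    positions: dict  # chrom -> marker positions (sorted)
    dosage: dict  # chrom -> (n_individuals, n_markers) alt-allele dosage
    pool_freqs: dict  # chrom -> (n_pools, n_markers) true alt frequency

    def causal_dosage(self) -> np.ndarray:
        i = int(np.searchsorted(self.positions[self.causal_chrom], self.causal_pos))
        return self.dosage[self.causal_chrom][:, i]


def _marker_positions(cfg: SimConfig) -> dict[str, np.ndarray]:
    total = sum(cfg.chrom_lengths.values())
    out = {}
    planted = {}
    for pv in cfg.planted:
        planted.setdefault(pv.chrom, set()).add(pv.pos)
    for chrom, length in cfg.chrom_lengths.items():
        n = max(2, round(cfg.n_markers * length / total))
        pos = {int(length * (i + 1) / (n + 1)) for i in range(n)}
        if chrom == cfg.causal_chrom:
            pos.add(cfg.causal_pos)
        pos |= planted.get(chrom, set())
        out[chrom] = np.array(sorted(pos), dtype=int)
    return out


def _haplotypes(rng, positions: np.ndarray, n_ind: int, rate: float) -> np.ndarray:
    """One gamete per individual along a chromosome, 1:1 segregation with
    Haldane recombination between adjacent markers."""
    n_mark = positions.size
    h = np.empty((n_ind, n_mark), dtype=np.int8)
    h[:, 0] = rng.integers(0, 2, size=n_ind)
    d_mb = np.diff(positions) / 1e6
    r = 0.5 * (1.0 - np.exp(-2.0 * rate * d_mb))
    for j in range(1, n_mark):
        switch = rng.random(n_ind) < r[j - 1]
        h[:, j] = np.where(switch, 1 - h[:, j - 1], h[:, j - 1])
    return h


def _dosages(rng, positions, n_ind, cfg: SimConfig) -> np.ndarray:
    if cfg.design == "hetxdh-f1":
        # DH parent contributes the reference allele everywhere
        return _haplotypes(rng, positions, n_ind, cfg.recombination_rate)
    if cfg.design == "f2":
        return _haplotypes(rng, positions, n_ind, cfg.recombination_rate) + _haplotypes(
            rng, positions, n_ind, cfg.recombination_rate
        )
    raise ValueError(f"unknown design {cfg.design!r}")


def _assign_pools(cfg: SimConfig, trait: np.ndarray) -> np.ndarray:
    n_pools = len(cfg.pool_sizes)
    assignment = np.empty(trait.size, dtype=int)
    order = np.argsort(trait, kind="stable")
    if cfg.censor_threshold is not None:
        censored = trait > cfg.censor_threshold
        assignment[censored] = n_pools - 1
        rest = order[~censored[order]]
        head_sizes = np.array(cfg.pool_sizes[:-1], dtype=float)
        head_sizes = np.round(
            head_sizes / head_sizes.sum() * rest.size
        ).astype(int)
        head_sizes[-1] = rest.size - head_sizes[:-1].sum()
        start = 0
        for p, size in enumerate(head_sizes):
            assignment[rest[start : start + size]] = p
            start += size
        return assignment
    start = 0
    for p, size in enumerate(cfg.pool_sizes):
        assignment[order[start : start + size]] = p
        start += size
    return assignment


def simulate_cross(
    cfg: SimConfig, genome=None, vcf_path=None
) -> tuple[list[PoolVariant], TruthRecord]:
    """Simulate the pooled cross; optionally write the VCF.

    When ``genome`` (mapping chrom -> sequence, or pyfaidx.Fasta) is given,
    reference alleles are read from it; otherwise they are drawn at random.
    The output is byte-reproducible for a fixed config (incl. seed).
    """
    rng = np.random.default_rng(cfg.seed)
    positions = _marker_positions(cfg)
    n_ind = cfg.n_individuals
    n_pools = len(cfg.pool_sizes)

    dosage = {c: _dosages(rng, p, n_ind, cfg) for c, p in positions.items()}
    causal_i = int(
        np.searchsorted(positions[cfg.causal_chrom], cfg.causal_pos)
    )
    causal_dose = dosage[cfg.causal_chrom][:, causal_i].astype(float)
    trait = cfg.effect * causal_dose + rng.normal(0.0, cfg.noise_sd, n_ind)
    assignment = _assign_pools(cfg, trait)

    pool_freqs = {}
    for chrom, dos in dosage.items():
        freqs = np.empty((n_pools, dos.shape[1]))
        for p in range(n_pools):
            members = assignment == p
            freqs[p] = dos[members].sum(axis=0) / (2.0 * members.sum())
        pool_freqs[chrom] = freqs

    planted_alleles = {(pv.chrom, pv.pos): (pv.ref, pv.alt) for pv in cfg.planted}
    bases = np.array(list("ACGT"))
    variants: list[PoolVariant] = []
    for chrom in sorted(positions):
        pos_arr = positions[chrom]
        freqs = pool_freqs[chrom]
        if cfg.error_rate > 0:
            freqs = freqs * (1 - cfg.error_rate) + (1 - freqs) * cfg.error_rate
        depth = np.maximum(
            rng.poisson(cfg.mean_depth, size=(n_pools, pos_arr.size)), 1
        )
        alt_reads = rng.binomial(depth, freqs)
        for j, pos in enumerate(pos_arr):
            if (chrom, int(pos)) in planted_alleles:
                ref, alt = planted_alleles[(chrom, int(pos))]
            else:
                if genome is not None:
                    if hasattr(genome, "get_seq"):
                        ref = str(genome.get_seq(chrom, int(pos), int(pos))).upper()
                    else:
                        ref = genome[chrom][int(pos) - 1].upper()
                else:
                    ref = str(rng.choice(bases))
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            pools = {
                label: PoolDepth(
                    ref_depth=int(depth[p, j] - alt_reads[p, j]),
                    alt_depth=int(alt_reads[p, j]),
                    gq=cfg.gq,
                )
                for p, label in enumerate(cfg.pool_labels)
            }
            variants.append(
                PoolVariant(
                    chrom=chrom,
                    pos=int(pos),
                    ref_allele=ref,
                    alt_allele=alt,
                    pools=pools,
                )
            )
    truth = TruthRecord(
        causal_chrom=cfg.causal_chrom,
        causal_pos=cfg.causal_pos,
        pool_labels=tuple(cfg.pool_labels),
        pool_sizes=tuple(cfg.pool_sizes),
        assignment=assignment,
        trait=trait,
        positions=positions,
        dosage=dosage,
        pool_freqs=pool_freqs,
    )
    if vcf_path is not None:
        write_filtered_vcf(vcf_path, variants, cfg.pool_labels)
    return variants, truth


# ---------------------------------------------------------------------------
# toy genes and genome


def random_coding_gene(
    rng,
    gene_id: str,
    chrom: str,
    start: int,
    strand: str,
    n_exons: int | None = None,
    n_codons: int | None = None,
    forced_codons: dict[int, str] | None = None,
    intron_len: int = 120,
) -> tuple[str, GeneModel]:
    """Construct a random multi-exon protein-coding gene.

    Returns ``(genomic_span_sequence, GeneModel)``; the sequence is meant
    to be pasted into the genome at ``start`` (1-based). The CDS begins
    with ATG, ends with TAA, contains no internal stop, and may be forced
    to carry specific codons (``forced_codons`` maps codon index -> codon)
    so variants with known consequences can be planted.
    """
    n_exons = n_exons or int(rng.integers(2, 4))
    n_codons = n_codons or int(rng.integers(40, 80))
    codons = ["ATG"] + [
        _SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS), n_codons)
    ] + ["TAA"]
    for idx, codon in (forced_codons or {}).items():
        codons[idx] = codon
    cds = "".join(codons)

    # split the CDS into exons (each >= 9 bp) at random cut points
    cuts: list[int] = []
    if n_exons > 1:
        while True:
            cand = sorted(
                rng.choice(
                    np.arange(9, len(cds) - 9), size=n_exons - 1, replace=False
                )
            )
            if all(b - a >= 9 for a, b in zip(cand, cand[1:])):
                cuts = cand
                break
    bounds = [0, *map(int, cuts), len(cds)]
    exon_seqs = [cds[a:b] for a, b in zip(bounds, bounds[1:])]

    bases = "ACGT"
    introns = []
    for _ in range(n_exons - 1):
        mid = "".join(bases[i] for i in rng.integers(0, 4, intron_len - 4))
        introns.append("GT" + mid + "AG")

    parts = []
    for i, ex in enumerate(exon_seqs):
        parts.append(ex)
        if i < len(introns):
            parts.append(introns[i])
    span_tx = "".join(parts)  # transcript-orientation genomic span
    span_len = len(span_tx)

    # transcript-order CDS segments in transcript-span coordinates
    segs_tx = []
    offset = 0
    cum_cds = 0
    for i, ex in enumerate(exon_seqs):
        phase = (3 - cum_cds % 3) % 3
        segs_tx.append((offset, offset + len(ex) - 1, phase))
        cum_cds += len(ex)
        offset += len(ex) + (len(introns[i]) if i < len(introns) else 0)

    if strand == "+":
        span = span_tx
        cds_segs = tuple(
            CdsSegment(start=start + a, end=start + b, phase=ph)
            for a, b, ph in segs_tx
        )
    else:
        span = revcomp(span_tx)
        cds_segs = tuple(
            CdsSegment(
                start=start + span_len - 1 - b,
                end=start + span_len - 1 - a,
                phase=ph,
            )
            for a, b, ph in segs_tx
        )
    model = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        start=start,
        end=start + span_len - 1,
        cds=cds_segs,
        transcript_id=f"{gene_id}.t1",
        complete=True,
    )
    return span, model


def transcript_to_genomic(gene: GeneModel, t_idx: int) -> int:
    """Genomic position (1-based) of transcript-relative CDS index."""
    cum = 0
    for seg in gene.cds:
        length = seg.end - seg.start + 1
        if t_idx < cum + length:
            off = t_idx - cum
            return seg.start + off if gene.strand == "+" else seg.end - off
        cum += length
    raise IndexError(f"CDS index {t_idx} beyond CDS of {gene.gene_id}")


def write_gff3(models, path, chrom_lengths=None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in (chrom_lengths or {}).items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for m in sorted(models, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{m.chrom}\ttoy\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            tid = m.transcript_id or f"{m.gene_id}.t1"
            fh.write(
                f"{m.chrom}\ttoy\tmRNA\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={tid};Parent={m.gene_id}\n"
            )
            for seg in sorted(m.cds, key=lambda s: s.start):
                fh.write(
                    f"{m.chrom}\ttoy\tCDS\t{seg.start}\t{seg.end}\t.\t"
                    f"{m.strand}\t{seg.phase}\tID=cds-{tid};Parent={tid}\n"
                )


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# toy ontology / annotations / gene sets


def toy_ontology(anchor: str = "GO:0003006", focus: str = "GO:0010228"):
    """A >= 30-term DAG echoing the reproductive-development nesting.

    Returns ``(terms, edges)``: terms as (id, name) pairs and is_a edges as
    (child, parent). The anchor subtends the focus; the focus subtends two
    leaves, so transitive annotation is exercised. Unrelated metabolic and
    response branches supply background terms.
    """
    t = {
        "GO:9000001": "biological_process",
        "GO:9000002": "developmental process",
        "GO:9000003": "metabolic process",
        "GO:9000004": "response to stimulus",
        "GO:9000005": "cellular process",
        anchor: "developmental process involved in reproduction",
        "GO:9000010": "flower development",
        focus: "vegetative to reproductive phase transition of meristem",
        "GO:9000011": "flower morphogenesis",
        "GO:9000012": "floral organ development",
        "GO:9000013": "floral whorl development",
        "GO:9000014": "seed maturation",
        "GO:9000020": "photoperiodism, flowering",
        "GO:9000021": "regulation of meristem phase transition",
        "GO:9000030": "carbohydrate metabolic process",
        "GO:9000031": "lipid metabolic process",
        "GO:9000032": "protein metabolic process",
        "GO:9000033": "starch biosynthetic process",
        "GO:9000034": "fatty acid biosynthetic process",
        "GO:9000040": "response to light stimulus",
        "GO:9000041": "response to cold",
        "GO:9000042": "response to red light",
        "GO:9000050": "cell cycle",
        "GO:9000051": "cell division",
        "GO:9000052": "DNA replication",
        "GO:9000060": "root development",
        "GO:9000061": "leaf development",
        "GO:9000062": "shoot system development",
        "GO:9000063": "embryo development",
        "GO:9000064": "post-embryonic development",
        "GO:9000070": "circadian regulation of gene expression",
    }
    e = [
        ("GO:9000002", "GO:9000001"),
        ("GO:9000003", "GO:9000001"),
        ("GO:9000004", "GO:9000001"),
        ("GO:9000005", "GO:9000001"),
        (anchor, "GO:9000002"),
        ("GO:9000010", anchor),
        (focus, anchor),
        ("GO:9000011", "GO:9000010"),
        ("GO:9000012", "GO:9000010"),
        ("GO:9000013", "GO:9000012"),
        ("GO:9000014", anchor),
        ("GO:9000020", focus),
        ("GO:9000021", focus),
        ("GO:9000030", "GO:9000003"),
        ("GO:9000031", "GO:9000003"),
        ("GO:9000032", "GO:9000003"),
        ("GO:9000033", "GO:9000030"),
        ("GO:9000034", "GO:9000031"),
        ("GO:9000040", "GO:9000004"),
        ("GO:9000041", "GO:9000004"),
        ("GO:9000042", "GO:9000040"),
        ("GO:9000050", "GO:9000005"),
        ("GO:9000051", "GO:9000050"),
        ("GO:9000052", "GO:9000050"),
        ("GO:9000060", "GO:9000002"),
        ("GO:9000061", "GO:9000002"),
        ("GO:9000062", "GO:9000002"),
        ("GO:9000063", "GO:9000002"),
        ("GO:9000064", "GO:9000002"),
        ("GO:9000070", "GO:9000004"),
        ("GO:9000070", focus),  # DAG: two parents
    ]
    return list(t.items()), e


def write_obo(terms, edges, path) -> None:
    parents: dict[str, list[str]] = {}
    names = dict(terms)
    for child, parent in edges:
        parents.setdefault(child, []).append(parent)
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: toy\n")
        for tid, name in terms:
            fh.write(f"\n[Term]\nid: {tid}\nname: {name}\n")
            fh.write("namespace: biological_process\n")
            for p in parents.get(tid, []):
                fh.write(f"is_a: {p} ! {names.get(p, '')}\n")


def write_gmt(sets: dict[str, tuple[str, list[str]]], path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# full fixture bundle


def generate_fixtures(out_dir, seed: int = 0, config: SimConfig | None = None) -> dict:
    """Write a complete, internally consistent toy data set.

    Emits genome FASTA, GFF3 gene models, planted-QTL VCF, OBO ontology,
    gene->term annotations, GMT gene sets, and a JSON manifest of every
    planted truth. Genes near the causal locus carry planted
    non-synonymous SNPs and are annotated under the focus term; one gene
    far from the QTL carries a planted stop-gain; a planted
    "circadian-like" gene set collects the focus-term genes.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    cfg = config or SimConfig(seed=int(rng.integers(0, 2**31 - 1)))

    # --- genome scaffold
    bases = np.frombuffer(b"ACGT", dtype="S1")
    genome = {
        chrom: (
            bases[rng.integers(0, 4, size=length)]
            .tobytes()
            .decode("ascii")
        )
        for chrom, length in cfg.chrom_lengths.items()
    }

    # --- genes: 15 per chromosome, alternating strands
    models = []
    gene_seqs = {}
    qtl_lo = cfg.causal_pos - 800_000
    qtl_hi = cfg.causal_pos + 800_000
    qtl_genes = []
    outside_gene = None
    gi = 0
    for chrom in sorted(cfg.chrom_lengths):
        for k in range(15):
            gi += 1
            start = 150_000 + 300_000 * k
            strand = "+" if gi % 2 else "-"
            gene_id = f"BoTOY{gi:03d}"
            in_qtl = chrom == cfg.causal_chrom and qtl_lo <= start <= qtl_hi
            forced = None
            if in_qtl:
                forced = {5: "GCT"}  # Ala codon -> missense target
            elif outside_gene is None and chrom != cfg.causal_chrom:
                forced = {5: "TGG"}  # Trp codon -> stop-gain target
            span, model = random_coding_gene(
                rng, gene_id, chrom, start, strand, forced_codons=forced
            )
            if in_qtl:
                qtl_genes.append(model)
            elif forced is not None:
                outside_gene = model
            g = genome[chrom]
            genome[chrom] = g[: start - 1] + span + g[start - 1 + len(span):]
            gene_seqs[gene_id] = span
            models.append(model)

    # --- planted coding variants (codon 5 occupies CDS indices 15..17)
    planted = []

    def plant(gene, t_idx, tx_ref, tx_alt, expected):
        gpos = transcript_to_genomic(gene, t_idx)
        if gene.strand == "+":
            ref, alt = tx_ref, tx_alt
        else:
            ref, alt = revcomp(tx_ref), revcomp(tx_alt)
        return PlantedVariant(
            chrom=gene.chrom,
            pos=gpos,
            ref=ref,
            alt=alt,
            expected_effect=expected,
            gene_id=gene.gene_id,
        )

    for g in qtl_genes:
        planted.append(plant(g, 15, "G", "A", "non_synonymous"))  # GCT->ACT
    if outside_gene is not None:
        planted.append(plant(outside_gene, 17, "G", "A", "stop_gained"))  # TGG->TGA

    cfg = SimConfig(
        **{
            **{k: v for k, v in asdict(cfg).items() if k != "planted"},
            "planted": tuple(planted),
        }
    )

    # --- pooled-cross VCF
    paths = {k: os.path.join(out_dir, v) for k, v in {
        "fasta": "genome.fa",
        "gff3": "genes.gff3",
        "vcf": "pools.vcf",
        "obo": "ontology.obo",
        "annotations": "annotations.tsv",
        "gmt": "gene_sets.gmt",
        "manifest": "manifest.json",
    }.items()}
    variants, truth = simulate_cross(cfg, genome=genome, vcf_path=paths["vcf"])
    write_fasta(genome, paths["fasta"])
    write_gff3(models, paths["gff3"], cfg.chrom_lengths)

    # --- ontology and annotations
    terms, edges = toy_ontology()
    write_obo(terms, edges, paths["obo"])
    focus = "GO:0010228"
    focus_children = ["GO:9000020", "GO:9000021"]
    background_terms = [
        "GO:9000030", "GO:9000031", "GO:9000032", "GO:9000033",
        "GO:9000034", "GO:9000040", "GO:9000041", "GO:9000042",
        "GO:9000050", "GO:9000051", "GO:9000052", "GO:9000060",
        "GO:9000061", "GO:9000062", "GO:9000063", "GO:9000064",
    ]
    annotations: dict[str, set[str]] = {}
    qtl_ids = {g.gene_id for g in qtl_genes}
    focus_gene_ids = sorted(qtl_ids)
    for m in models:
        if m.gene_id in qtl_ids:
            ann = {focus_children[len(annotations) % 2], focus}
        else:
            picks = rng.choice(len(background_terms), size=2, replace=False)
            ann = {background_terms[i] for i in picks}
        annotations[m.gene_id] = ann
    from .ontology import write_annotations

    write_annotations(annotations, paths["annotations"])

    # --- gene sets: one planted circadian-like set over the focus genes
    all_ids = [m.gene_id for m in models]
    sets = {
        "TOY:04712": (
            "Circadian rhythm - plant (planted)",
            sorted(set(focus_gene_ids) | {all_ids[-1]}),
        )
    }
    for i in range(5):
        picks = rng.choice(len(all_ids), size=6, replace=False)
        sets[f"TOY:{i:05d}"] = (
            f"background set {i}",
            sorted(all_ids[j] for j in picks),
        )
    write_gmt(sets, paths["gmt"])

    manifest = {
        "seed": seed,
        "sim_seed": cfg.seed,
        "causal_chrom": cfg.causal_chrom,
        "causal_pos": cfg.causal_pos,
        "pool_labels": list(cfg.pool_labels),
        "pool_sizes": list(cfg.pool_sizes),
        "effect": cfg.effect,
        "noise_sd": cfg.noise_sd,
        "mean_depth": cfg.mean_depth,
        "n_markers": int(sum(len(p) for p in truth.positions.values())),
        "genes": [m.gene_id for m in models],
        "qtl_genes": sorted(qtl_ids),
        "outside_stopgain_gene": outside_gene.gene_id if outside_gene else None,
        "planted_variants": [asdict(p) for p in planted],
        "anchor_term": "GO:0003006",
        "focus_term": focus,
        "focus_genes": focus_gene_ids,
        "planted_pathway": "TOY:04712",
        "files": {k: os.path.basename(v) for k, v in paths.items()},
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"paths": paths, "manifest": manifest, "config": cfg,
            "models": models, "truth": truth, "variants": variants,
            "annotations": annotations}
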