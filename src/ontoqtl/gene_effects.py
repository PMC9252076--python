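"""Gene models, QTL-gene intersection, and coding-effect classification.

Reimplements the SnpEff-style impact analysis at the level this workflow
needs: each variant is classified against a gene's coding sequence
(strand- and phase-aware, standard nuclear code) as synonymous,
non-synonymous, stop-gained, stop-lost, start-lost, splice-site,
frameshift, in-frame indel, intronic, or intergenic, and the classes map
onto the usual impact tiers:

* high      — start_lost, stop_gained, frameshift, splice_site
  (gene-inactivating),
* moderate  — non_synonymous, inframe_indel, stop_lost (function-altering),
* low       — synonymous,
* modifier  — intronic, intergenic.

Gene models come from GFF3 (gene/mRNA/CDS); one transcript per gene is
analysed, the one with the longest summed CDS. Genes are intersected with
QTL regions by 1-based inclusive overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

IMPACT = {
    "start_lost": "high",
    "stop_gained": "high",
    "frameshift": "high",
    "splice_site": "high",
    "non_synonymous": "moderate",
    "inframe_indel": "moderate",
    "stop_lost": "moderate",
    "synonymous": "low",
    "intronic": "modifier",
    "intergenic": "modifier",
}

SPLICE_WINDOW = 2  # bp into the intron (canonical GT/AG donor/acceptor)


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CdsSegment:
    start: int  # 1-based inclusive, genomic
    end: int
    phase: int


@dataclass(frozen=True)
class GeneModel:
    """One gene with the CDS of its representative transcript.

    ``cds`` is ordered 5'->3' of the transcript (descending genomic
    coordinates on the minus strand).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds: tuple[CdsSegment, ...]
    transcript_id: str | None = None
    complete: bool = True

    @property
    def cds_length(self) -> int:
        return sum(s.end - s.start + 1 for s in self.cds)


@dataclass(frozen=True)
class VariantEffect:
    gene_id: str | None
    chrom: str
    pos: int
    ref: str
    alt: str
    effect: str
    impact: str
    note: str = ""


def _get_seq(genome, chrom: str, start: int, end: int) -> str:
    """1-based inclusive slice of a genome (pyfaidx.Fasta or mapping of
    chromosome name -> sequence string)."""
    if hasattr(genome, "get_seq"):  # pyfaidx
        return str(genome.get_seq(chrom, start, end)).upper()
    seq = genome[chrom]
    return str(seq[start - 1 : end]).upper()


def read_gene_models(gff3_path) -> list[GeneModel]:
    """Parse gene models from GFF3, keeping per gene the transcript with
    the longest summed CDS. CDS features without a resolvable parent are
    skipped with a warning. Models whose CDS length is not a multiple of
    three are flagged ``complete=False`` but kept."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        best: tuple[int, str, list] | None = None
        for mrna in db.children(gene, featuretype="mRNA"):
            segs = list(db.children(mrna, featuretype="CDS"))
            if not segs:
                continue
            length = sum(s.end - s.start + 1 for s in segs)
            if best is None or length > best[0]:
                best = (length, mrna.id, segs)
        if best is None:
            # CDS directly under the gene (annotation without mRNA level)
            segs = list(db.children(gene, featuretype="CDS", level=1))
            if segs:
                best = (sum(s.end - s.start + 1 for s in segs), gene.id, segs)
        if best is None:
            continue
        _, tid, segs = best
        segs.sort(key=lambda s: s.start, reverse=(gene.strand == "-"))
        cds = tuple(
            CdsSegment(
                start=s.start,
                end=s.end,
                phase=int(s.frame) if s.frame not in (None, ".") else 0,
            )
            for s in segs
        )
        length = sum(s.end - s.start + 1 for s in cds)
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                cds=cds,
                transcript_id=tid,
                complete=(length % 3 == 0),
            )
        )
    for model in models:
        if not model.complete:
            logger.warning(
                "gene %s: CDS length %d not divisible by 3",
                model.gene_id,
                model.cds_length,
            )
    models.sort(key=lambda m: (m.chrom, m.start))
    return models


def intersect_genes(regions, genes) -> pd.DataFrame:
    """Genes overlapping >= 1 QTL region, tagged per contrast.

    Overlap is 1-based inclusive: max(starts) <= min(ends). Returns a
    DataFrame (gene_id, contrast, chrom, gene_start, gene_end, region_start,
    region_end). Warns when the two inputs share no chromosome names.
    """
    from intervaltree import IntervalTree

    genes = list(genes)
    regions = list(regions)
    gene_chroms = {g.chrom for g in genes}
    region_chroms = {r.chrom for r in regions}
    if regions and genes and not (gene_chroms & region_chroms):
        logger.warning(
            "no shared chromosome names: genes have %s, regions have %s",
            sorted(gene_chroms - region_chroms),
            sorted(region_chroms - gene_chroms),
        )
    trees: dict[str, IntervalTree] = {}
    for i, g in enumerate(genes):
        # half-open tree interval [start, end+1) encodes inclusive [start, end]
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, i)
    rows = []
    for r in regions:
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(r.start, r.end + 1)):
            g = genes[iv.data]
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "contrast": r.contrast,
                    "chrom": g.chrom,
                    "gene_start": g.start,
                    "gene_end": g.end,
                    "region_start": r.start,
                    "region_end": r.end,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "contrast",
            "chrom",
            "gene_start",
            "gene_end",
            "region_start",
            "region_end",
        ],
    )
    return df.sort_values(["contrast", "chrom", "gene_start"]).reset_index(
        drop=True
    )


def _cds_index(gene: GeneModel, pos: int) -> int | None:
    """Transcript-relative 0-based index of a genomic position within the
    concatenated CDS, or None if the position is not coding."""
    offset = 0
    for seg in gene.cds:
        if seg.start <= pos <= seg.end:
            if gene.strand == "+":
                return offset + (pos - seg.start)
            return offset + (seg.end - pos)
        offset += seg.end - seg.start + 1
    return None


def _is_splice_site(gene: GeneModel, pos: int) -> bool:
    """Within SPLICE_WINDOW bp of a CDS/intron junction, intron side."""
    segs = sorted(gene.cds, key=lambda s: s.start)
    for left, right in zip(segs, segs[1:]):
        if left.end < pos < right.start:  # inside the intron
            if pos - left.end <= SPLICE_WINDOW:
                return True
            if right.start - pos <= SPLICE_WINDOW:
                return True
    return False


def _coding_sequence(gene: GeneModel, genome) -> str:
    parts = []
    for seg in gene.cds:
        s = _get_seq(genome, gene.chrom, seg.start, seg.end)
        parts.append(revcomp(s) if gene.strand == "-" else s)
    return "".join(parts)


def classify_effect(gene: GeneModel, genome, variant) -> VariantEffect:
    """Classify one variant against one gene model.

    ``variant`` is anything with chrom, pos (1-based), ref, alt attributes
    or a (chrom, pos, ref, alt) tuple. The reference allele must match the
    genome at that position.
    """
    if hasattr(variant, "chrom"):
        chrom, pos = variant.chrom, variant.pos
        ref = getattr(variant, "ref", None) or variant.ref_allele
        alt = getattr(variant, "alt", None) or variant.alt_allele
    else:
        chrom, pos, ref, alt = variant
    ref, alt = ref.upper(), alt.upper()

    genome_ref = _get_seq(genome, chrom, pos, pos + len(ref) - 1)
    if genome_ref != ref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: VCF says {ref!r}, "
            f"genome has {genome_ref!r}"
        )

    def make(effect, note=""):
        return VariantEffect(
            gene_id=gene.gene_id,
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            effect=effect,
            impact=IMPACT[effect],
            note=note,
        )

    in_gene = gene.chrom == chrom and gene.start <= pos <= gene.end
    if not in_gene:
        return make("intergenic")

    # indels: the span after the shared anchor base decides CDS overlap
    if len(ref) != len(alt):
        span_lo = pos + 1 if len(ref) > 1 or len(alt) > 1 else pos
        span_hi = pos + len(ref) - 1
        touches_cds = any(
            max(seg.start, span_lo) <= min(seg.end, max(span_hi, span_lo))
            for seg in gene.cds
        )
        # an insertion between two CDS bases also disrupts the frame
        if not touches_cds and len(alt) > len(ref):
            touches_cds = any(
                seg.start <= pos < seg.end for seg in gene.cds
            )
        if touches_cds:
            shift = abs(len(ref) - len(alt)) % 3
            return make("frameshift" if shift else "inframe_indel")
        if _is_splice_site(gene, pos):
            return make("splice_site")
        return make("intronic")

    # substitutions
    idx = _cds_index(gene, pos)
    if idx is None:
        if _is_splice_site(gene, pos):
            return make("splice_site")
        return make("intronic")

    if len(ref) > 1:
        # multi-nucleotide substitution: codon-wise only when it stays
        # inside one codon (and one CDS segment on the genome)
        idx_last = _cds_index(gene, pos + len(ref) - 1)
        offset = gene.cds[0].phase
        same_codon = (
            idx_last is not None
            and abs(idx_last - idx) == len(ref) - 1
            and (min(idx, idx_last) - offset) // 3
            == (max(idx, idx_last) - offset) // 3
            and min(idx, idx_last) >= offset
        )
        if not same_codon:
            return make("non_synonymous", note="mnv_spans_codons")

    cds_seq = _coding_sequence(gene, genome)
    offset = gene.cds[0].phase
    if gene.strand == "-":
        sub_ref, sub_alt = revcomp(ref), revcomp(alt)
        first_idx = _cds_index(gene, pos + len(ref) - 1)
    else:
        sub_ref, sub_alt = ref, alt
        first_idx = idx
    assert cds_seq[first_idx : first_idx + len(sub_ref)] == sub_ref
    mutated = cds_seq[:first_idx] + sub_alt + cds_seq[first_idx + len(sub_ref) :]

    if first_idx < offset:
        return make("non_synonymous", note="partial_leading_codon")
    codon_i = (first_idx - offset) // 3
    old_codon = cds_seq[offset + 3 * codon_i : offset + 3 * codon_i + 3]
    new_codon = mutated[offset + 3 * codon_i : offset + 3 * codon_i + 3]
    if len(old_codon) < 3:
        return make("non_synonymous", note="partial_trailing_codon")
    old_aa = CODON_TABLE.get(old_codon, "X")
    new_aa = CODON_TABLE.get(new_codon, "X")

    if codon_i == 0 and offset == 0 and old_codon == "ATG" and new_codon != "ATG":
        return make("start_lost")
    if old_aa != "*" and new_aa == "*":
        return make("stop_gained")
    if old_aa == "*" and new_aa != "*":
        return make("stop_lost")
    if old_aa == new_aa:
        return make("synonymous")
    return make("non_synonymous")


def classify_variants(variants, genes, genome) -> pd.DataFrame:
    """Classify every variant against every gene whose span contains it.

    Variants hitting no gene are reported once as intergenic with a null
    gene id. Returns a tidy DataFrame of effects.
    """
    genes = list(genes)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for v in variants:
        chrom = v.chrom if hasattr(v, "chrom") else v[0]
        pos = v.pos if hasattr(v, "pos") else v[1]
        hits = [
            g
            for g in by_chrom.get(chrom, [])
            if g.start <= pos <= g.end
        ]
        if not hits:
            ref = getattr(v, "ref", None) or getattr(v, "ref_allele", None) or v[2]
            alt = getattr(v, "alt", None) or getattr(v, "alt_allele", None) or v[3]
            rows.append(
                VariantEffect(
                    gene_id=None,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    effect="intergenic",
                    impact="modifier",
                )
            )
            continue
        for g in hits:
            rows.append(classify_effect(g, genome, v))
    return pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "chrom": e.chrom,
                "pos": e.pos,
                "ref": e.ref,
                "alt": e.alt,
                "effect": e.effect,
                "impact": e.impact,
                "note": e.note,
            }
            for e in rows
        ],
        columns=[
            "gene_id", "chrom", "pos", "ref", "alt", "effect", "impact", "note",
        ],
    )


def impact_summary(
    genes, effects: pd.DataFrame, regions_by_contrast: dict
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize effect classes per gene and cross-tabulate impact tiers
    against QTL membership.

    Returns ``(per_gene, crosstab)``: per_gene has one row per gene with
    effect-class counts and one inside_<contrast> boolean per contrast
    (true iff the gene span overlaps a region of that contrast); crosstab
    counts (contrast, impact, inside/outside) over gene-variant pairs.
    """
    genes = list(genes)
    inside: dict[str, dict[str, bool]] = {}
    for contrast, regions in regions_by_contrast.items():
        for g in genes:
            inside.setdefault(g.gene_id, {})[contrast] = any(
                r.overlaps(g.chrom, g.start, g.end) for r in regions
            )
    genic = effects[effects["gene_id"].notna()]
    counts = (
        genic.groupby(["gene_id", "effect"]).size().unstack(fill_value=0)
        if len(genic)
        else pd.DataFrame()
    )
    per_gene_rows = []
    for g in genes:
        row = {"gene_id": g.gene_id, "chrom": g.chrom}
        for eff in IMPACT:
            row[f"n_{eff}"] = (
                int(counts.loc[g.gene_id, eff])
                if g.gene_id in counts.index and eff in counts.columns
                else 0
            )
        for contrast in regions_by_contrast:
            row[f"inside_{contrast}"] = inside[g.gene_id][contrast]
        per_gene_rows.append(row)
    per_gene = pd.DataFrame(per_gene_rows)

    ct_rows = []
    for contrast in regions_by_contrast:
        for _, e in genic.iterrows():
            ct_rows.append(
                {
                    "contrast": contrast,
                    "impact": e["impact"],
                    "location": "inside"
                    if inside.get(e["gene_id"], {}).get(contrast, False)
                    else "outside",
                }
            )
    crosstab = (
        pd.DataFrame(ct_rows)
        .groupby(["contrast", "impact", "location"])
        .size()
        .rename("n_variants")
        .reset_index()
        if ct_rows
        else pd.DataFrame(columns=["contrast", "impact", "location", "n_variants"])
    )
    return per_gene, crosstab
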