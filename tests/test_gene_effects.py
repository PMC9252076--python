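"""Gene models, QTL intersection, and coding-effect classification.

The classifier is validated against an independent oracle that mutates the
genome, re-extracts and translates the entire CDS with Biopython, and
diffs the protein.
"""

import numpy as np
import pytest
from Bio.Seq import Seq

from ontoqtl.gene_effects import (
    GeneModel,
    CdsSegment,
    IMPACT,
    classify_effect,
    classify_variants,
    impact_summary,
    intersect_genes,
    read_gene_models,
    revcomp,
)
from ontoqtl.qtl_regions import QtlRegion
from ontoqtl.synthetic_data import random_coding_gene, transcript_to_genomic

GFF_TWO_MRNAS = """\
##gff-version 3
C1\ttoy\tgene\t101\t1100\t.\t+\t.\tID=gene1
C1\ttoy\tmRNA\t101\t1100\t.\t+\t.\tID=gene1.t1;Parent=gene1
C1\ttoy\tCDS\t101\t400\t.\t+\t0\tID=c1;Parent=gene1.t1
C1\ttoy\tmRNA\t101\t1100\t.\t+\t.\tID=gene1.t2;Parent=gene1
C1\ttoy\tCDS\t101\t400\t.\t+\t0\tID=c2;Parent=gene1.t2
C1\ttoy\tCDS\t501\t650\t.\t+\t0\tID=c2;Parent=gene1.t2
C1\ttoy\tgene\t2001\t3000\t.\t-\t.\tID=gene2
C1\ttoy\tmRNA\t2001\t3000\t.\t-\t.\tID=gene2.t1;Parent=gene2
C1\ttoy\tCDS\t2001\t2300\t.\t-\t2\tID=c3;Parent=gene2.t1
C1\ttoy\tCDS\t2601\t3000\t.\t-\t0\tID=c3;Parent=gene2.t1
"""


class TestReadGeneModels:
    @pytest.fixture()
    def models(self, tmp_path):
        path = tmp_path / "toy.gff3"
        path.write_text(GFF_TWO_MRNAS)
        return {m.gene_id: m for m in read_gene_models(path)}

    def test_longest_cds_transcript_selected(self, models):
        g = models["gene1"]
        assert g.transcript_id == "gene1.t2"
        assert g.cds_length == 450

    def test_minus_strand_segments_in_transcript_order(self, models):
        g = models["gene2"]
        assert g.strand == "-"
        # 5'->3' of the transcript = descending genomic coordinates
        assert [s.start for s in g.cds] == [2601, 2001]
        assert [s.phase for s in g.cds] == [0, 2]

    def test_two_exon_gene_has_two_segments(self, models):
        assert len(models["gene1"].cds) == 2


def random_gene_fixture(rng, gene_index):
    """A random multi-exon gene on its own little chromosome."""
    strand = "+" if gene_index % 2 else "-"
    flank = 60
    span, model = random_coding_gene(
        rng, f"g{gene_index}", f"chr{gene_index}", flank + 1, strand
    )
    bases = "ACGT"
    left = "".join(bases[i] for i in rng.integers(0, 4, flank))
    right = "".join(bases[i] for i in rng.integers(0, 4, flank))
    genome = {model.chrom: left + span + right}
    return genome, model


def oracle_classify(gene, genome, pos, alt):
    """Translate the entire mutated CDS and diff the protein."""
    chrom_seq = genome[gene.chrom]
    mutated = {
        gene.chrom: chrom_seq[: pos - 1] + alt + chrom_seq[pos:]
    }

    def cds_of(gdict):
        parts = []
        for seg in gene.cds:
            s = gdict[gene.chrom][seg.start - 1 : seg.end]
            parts.append(revcomp(s) if gene.strand == "-" else s)
        return "".join(parts)

    old_prot = str(Seq(cds_of(genome)).translate())
    new_prot = str(Seq(cds_of(mutated)).translate())
    old_cds, new_cds = cds_of(genome), cds_of(mutated)
    if old_cds[:3] == "ATG" and new_cds[:3] != "ATG":
        return "start_lost"
    if old_prot == new_prot:
        return "synonymous"
    diff = [i for i, (a, b) in enumerate(zip(old_prot, new_prot)) if a != b]
    i = diff[0]
    if new_prot[i] == "*" and old_prot[i] != "*":
        return "stop_gained"
    if old_prot[i] == "*" and new_prot[i] != "*":
        return "stop_lost"
    return "non_synonymous"


class TestClassifierAgainstTranslationOracle:
    def test_fuzzed_genes_both_strands_all_phases(self):
        rng = np.random.default_rng(20)
        n_checked = 0
        effects_seen = set()
        for gi in range(100):
            genome, gene = random_gene_fixture(rng, gi)
            cds_len = gene.cds_length
            for _ in range(12):
                t_idx = int(rng.integers(0, cds_len))
                pos = transcript_to_genomic(gene, t_idx)
                ref = genome[gene.chrom][pos - 1]
                alt = "ACGT"[int(rng.integers(0, 4))]
                if alt == ref:
                    continue
                got = classify_effect(gene, genome, (gene.chrom, pos, ref, alt))
                want = oracle_classify(gene, genome, pos, alt)
                assert got.effect == want, (
                    f"gene {gi} strand {gene.strand} pos {pos}: "
                    f"{got.effect} != oracle {want}"
                )
                effects_seen.add(want)
                n_checked += 1
        assert n_checked > 800
        assert {"synonymous", "non_synonymous", "stop_gained"} <= effects_seen

    def test_effect_independent_of_other_genes(self):
        rng = np.random.default_rng(3)
        genome, gene = random_gene_fixture(rng, 0)
        pos = transcript_to_genomic(gene, 9)
        ref = genome[gene.chrom][pos - 1]
        alt = "A" if ref != "A" else "G"
        solo = classify_effect(gene, genome, (gene.chrom, pos, ref, alt))
        table = classify_variants(
            [(gene.chrom, pos, ref, alt)], [gene], genome
        )
        assert table.loc[0, "effect"] == solo.effect


class TestClassifierCases:
    @pytest.fixture()
    def plus_gene(self):
        # single-exon gene, CDS ATG GGA TGG TAT TAA at 101..115
        cds = "ATGGGATGGTATTAA"
        genome = {"C1": "T" * 100 + cds + "T" * 100}
        gene = GeneModel(
            gene_id="g",
            chrom="C1",
            strand="+",
            start=101,
            end=115,
            cds=(CdsSegment(101, 115, 0),),
        )
        return gene, genome

    def test_synonymous_low_impact(self, plus_gene):
        gene, genome = plus_gene
        # GGA -> GGG, both glycine
        e = classify_effect(gene, genome, ("C1", 106, "A", "G"))
        assert (e.effect, e.impact) == ("synonymous", "low")

    def test_stop_gained_high_impact(self, plus_gene):
        gene, genome = plus_gene
        # TGG -> TGA
        e = classify_effect(gene, genome, ("C1", 109, "G", "A"))
        assert (e.effect, e.impact) == ("stop_gained", "high")

    def test_start_lost(self, plus_gene):
        gene, genome = plus_gene
        e = classify_effect(gene, genome, ("C1", 102, "T", "C"))
        assert (e.effect, e.impact) == ("start_lost", "high")

    def test_stop_lost(self, plus_gene):
        gene, genome = plus_gene
        # TAA -> CAA
        e = classify_effect(gene, genome, ("C1", 113, "T", "C"))
        assert (e.effect, e.impact) == ("stop_lost", "moderate")

    def test_reference_mismatch_names_position(self, plus_gene):
        gene, genome = plus_gene
        with pytest.raises(ValueError, match="C1:106"):
            classify_effect(gene, genome, ("C1", 106, "C", "G"))

    def test_frameshift_vs_inframe_indel(self, plus_gene):
        gene, genome = plus_gene
        # 1 bp deletion inside CDS
        e = classify_effect(gene, genome, ("C1", 105, "GA", "G"))
        assert (e.effect, e.impact) == ("frameshift", "high")
        # 3 bp deletion inside CDS
        e = classify_effect(gene, genome, ("C1", 105, "GATG", "G"))
        assert (e.effect, e.impact) == ("inframe_indel", "moderate")

    @pytest.fixture()
    def intron_gene(self):
        # exon1 101..109, intron 110..161 (GT..AG), exon2 162..167
        cds = "ATGGGATGG" + "TATTAA"
        intron = "GT" + "C" * 48 + "AG"
        genome = {"C1": "T" * 100 + cds[:9] + intron + cds[9:] + "T" * 100}
        gene = GeneModel(
            gene_id="g",
            chrom="C1",
            strand="+",
            start=101,
            end=167,
            cds=(CdsSegment(101, 109, 0), CdsSegment(162, 167, 0)),
        )
        return gene, genome

    def test_splice_site_within_two_bp_of_junction(self, intron_gene):
        gene, genome = intron_gene
        for pos in (110, 111, 160, 161):
            base = genome["C1"][pos - 1]
            alt = "A" if base != "A" else "T"
            e = classify_effect(gene, genome, ("C1", pos, base, alt))
            assert e.effect == "splice_site", pos
        # deeper intron positions are intronic / modifier
        e = classify_effect(gene, genome, ("C1", 130, "C", "A"))
        assert (e.effect, e.impact) == ("intronic", "modifier")

    def test_intergenic(self, intron_gene):
        gene, genome = intron_gene
        e = classify_effect(gene, genome, ("C1", 10, "T", "A"))
        assert (e.effect, e.impact) == ("intergenic", "modifier")


class TestIntersectGenes:
    def mk_gene(self, gid, chrom, start, end):
        return GeneModel(
            gene_id=gid, chrom=chrom, strand="+", start=start, end=end,
            cds=(CdsSegment(start, end, 0),),
        )

    def test_inclusive_overlap_boundaries(self):
        gene = self.mk_gene("g", "C1", 100, 200)
        hit = QtlRegion("c", "C1", 150, 300, 10, 3.0, 3.0)
        touch = QtlRegion("c", "C1", 200, 300, 10, 3.0, 3.0)
        miss = QtlRegion("c", "C1", 201, 300, 10, 3.0, 3.0)
        assert len(intersect_genes([hit], [gene])) == 1
        assert len(intersect_genes([touch], [gene])) == 1
        assert len(intersect_genes([miss], [gene])) == 0

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(17)
        genes = [
            self.mk_gene(
                f"g{i}", f"C{rng.integers(1, 4)}",
                int(s := rng.integers(1, 10**6)), int(s + rng.integers(1, 5000)),
            )
            for i in range(50)
        ]
        regions = [
            QtlRegion(
                "c", f"C{rng.integers(1, 4)}",
                int(s := rng.integers(1, 10**6)),
                int(s + rng.integers(1, 300_000)), 10, 3.0, 3.0,
            )
            for _ in range(5)
        ]
        got = set(
            map(tuple, intersect_genes(regions, genes)[
                ["gene_id", "region_start"]
            ].to_numpy())
        )
        oracle = {
            (g.gene_id, r.start)
            for g in genes
            for r in regions
            if g.chrom == r.chrom and max(g.start, r.start) <= min(g.end, r.end)
        }
        assert got == oracle


class TestImpactSummary:
    def test_planted_pattern_recovered(self, fixture_bundle):
        manifest = fixture_bundle["manifest"]
        models = {m.gene_id: m for m in fixture_bundle["models"]}
        import pyfaidx

        genome = pyfaidx.Fasta(fixture_bundle["paths"]["fasta"])
        planted = manifest["planted_variants"]
        effects = classify_variants(
            [(p["chrom"], p["pos"], p["ref"], p["alt"]) for p in planted],
            list(models.values()),
            genome,
        )
        # one synthetic region spanning the planted QTL
        region = QtlRegion(
            "EF-NF", manifest["causal_chrom"],
            manifest["causal_pos"] - 900_000, manifest["causal_pos"] + 900_000,
            10, 5.0, 4.0,
        )
        per_gene, crosstab = impact_summary(
            models.values(), effects, {"EF-NF": [region]}
        )
        ct = crosstab.set_index(["impact", "location"])["n_variants"]
        # moderate-impact variants inside the QTL, high-impact outside
        assert ct.loc[("moderate", "inside")] == len(manifest["qtl_genes"])
        assert ct.loc[("high", "outside")] == 1
        assert ("high", "inside") not in ct.index
        inside_col = per_gene.set_index("gene_id")["inside_EF-NF"]
        for gid in manifest["qtl_genes"]:
            assert inside_col[gid]
        assert not inside_col[manifest["outside_stopgain_gene"]]

    def test_counts_per_gene(self):
        gene = GeneModel(
            gene_id="g", chrom="C1", strand="+", start=101, end=115,
            cds=(CdsSegment(101, 115, 0),),
        )
        genome = {"C1": "T" * 100 + "ATGGGATGGTATTAA" + "T" * 100}
        effects = classify_variants(
            [("C1", 109, "G", "A"), ("C1", 106, "A", "G")], [gene], genome
        )
        per_gene, crosstab = impact_summary([gene], effects, {"c": []})
        row = per_gene.set_index("gene_id").loc["g"]
        assert row["n_stop_gained"] == 1
        assert row["n_synonymous"] == 1
        assert not row["inside_c"]


def test_impact_mapping_is_fixed():
    assert IMPACT["start_lost"] == "high"
    assert IMPACT["stop_gained"] == "high"
    assert IMPACT["frameshift"] == "high"
    assert IMPACT["splice_site"] == "high"
    assert IMPACT["non_synonymous"] == "moderate"
    assert IMPACT["inframe_indel"] == "moderate"
    assert IMPACT["stop_lost"] == "moderate"
    assert IMPACT["synonymous"] == "low"
    assert IMPACT["intronic"] == "modifier"
    assert IMPACT["intergenic"] == "modifier"
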