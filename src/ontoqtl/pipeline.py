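"""End-to-end refinement workflow.

Chains the full cascade on one configuration: genotype filtering ->
per-contrast BSA statistics (G, tricube G', Delta(SNP-index) null CI) ->
QTL region calling -> gene intersection and coding-effect classification
-> per-contrast term enrichment -> cross-contrast merge -> anchored
subgraph pruning -> focus-term zoom -> pathway enrichment. Every stage
writes its artifact into the output directory and the run manifest records
parameters, the seed, and the candidate-gene funnel counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import bsa_stats, enrichment, gene_effects, ontology, qtl_regions, variant_io
from .qtl_regions import contrast_id

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated inputs and per-stage parameters of one refine run."""

    vcf: str
    gff3: str
    fasta: str
    obo: str
    annotations: str
    gmt: str
    out_dir: str
    pool_labels: tuple = ("EF", "IF", "LF", "NF")
    pool_sizes: tuple = (11, 8, 11, 9)
    design: str = "hetxdh-f1"
    filter: variant_io.FilterConfig = field(default_factory=variant_io.FilterConfig)
    smoothing: bsa_stats.SmoothingConfig = field(
        default_factory=bsa_stats.SmoothingConfig
    )
    thresholds: bsa_stats.ThresholdConfig = field(
        default_factory=bsa_stats.ThresholdConfig
    )
    regions: qtl_regions.RegionConfig = field(default_factory=qtl_regions.RegionConfig)
    replicates: int = 10_000
    ci_level: float = 0.95
    fdr_threshold: float = 0.05
    adjust_method: str = "by"
    anchor_term: str = ontology.DEFAULT_ANCHOR
    focus_term: str = ontology.DEFAULT_FOCUS
    seed: int = 0

    def validate(self) -> None:
        for name in ("vcf", "gff3", "fasta", "obo", "annotations", "gmt"):
            path = getattr(self, name)
            if not os.path.exists(path):
                raise FileNotFoundError(f"{name} file not found: {path}")
        if len(self.pool_labels) < 2:
            raise ValueError("need >= 2 pools")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sub = {
            "filter": variant_io.FilterConfig,
            "smoothing": bsa_stats.SmoothingConfig,
            "thresholds": bsa_stats.ThresholdConfig,
            "regions": qtl_regions.RegionConfig,
        }
        kwargs = {}
        for key, value in raw.items():
            if key in sub:
                kwargs[key] = sub[key](**(value or {}))
            elif key in ("pool_labels", "pool_sizes"):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_refine(config: PipelineConfig) -> dict:
    """Run the whole cascade; returns the manifest dictionary.

    A stage failure raises with the stage name; artifacts of completed
    stages remain on disk.
    """
    import pyfaidx

    cfg = config
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "parameters": {
            "filter": dataclasses.asdict(cfg.filter),
            "smoothing": dataclasses.asdict(cfg.smoothing),
            "thresholds": dataclasses.asdict(cfg.thresholds),
            "regions": dataclasses.asdict(cfg.regions),
            "replicates": cfg.replicates,
            "ci_level": cfg.ci_level,
            "fdr_threshold": cfg.fdr_threshold,
            "adjust_method": cfg.adjust_method,
            "anchor_term": cfg.anchor_term,
            "focus_term": cfg.focus_term,
            "pool_labels": list(cfg.pool_labels),
            "pool_sizes": list(cfg.pool_sizes),
            "design": cfg.design,
        },
        "stages": {},
        "outputs": {},
    }
    stage = "setup"

    def out(name: str) -> str:
        path = os.path.join(cfg.out_dir, name)
        manifest["outputs"][name] = path
        return path

    try:
        stage = "read_variants"
        variants = variant_io.read_pool_variants(cfg.vcf, cfg.pool_labels)
        contrasts = variant_io.enumerate_contrasts(cfg.pool_labels)
        manifest["stages"]["read_variants"] = {
            "n_variants": len(variants),
            "n_contrasts": len(contrasts),
        }
        pool_size = dict(zip(cfg.pool_labels, cfg.pool_sizes))
        genome = pyfaidx.Fasta(cfg.fasta)
        genes = gene_effects.read_gene_models(cfg.gff3)
        graph = ontology.parse_obo(cfg.obo)
        annotations = ontology.read_annotations(cfg.annotations)
        propagated = enrichment.propagate_annotations(annotations, graph)
        gene_sets = enrichment.read_gmt(cfg.gmt)
        universe = sorted(annotations)
        rng = np.random.default_rng(cfg.seed)

        regions_by_contrast: dict[str, list] = {}
        study_by_contrast: dict[str, list[str]] = {}
        sea_by_contrast: dict[str, pd.DataFrame] = {}
        genes_in_qtl_all: set[str] = set()
        genes_nonsyn_all: set[str] = set()

        for contrast in contrasts:
            cid = contrast_id(contrast)
            stage = f"filter[{cid}]"
            survivors, report = variant_io.apply_filters(
                variants, contrast, cfg.filter
            )
            stage = f"stats[{cid}]"
            stats = bsa_stats.compute_contrast_stats(
                survivors, contrast, cfg.smoothing
            )
            if len(stats) == 0:
                logger.warning("contrast %s: no SNPs survive filtering", cid)
                manifest["stages"][cid] = {"filter": report.as_dict(),
                                           "n_snps": 0}
                continue
            ci = None
            if cfg.thresholds.use_delta_ci:
                depths = np.round(
                    (stats["depth_a"].to_numpy() + stats["depth_b"].to_numpy())
                    / 2.0
                ).astype(int)
                ci = bsa_stats.simulate_delta_ci(
                    pool_size[contrast[0]],
                    pool_size[contrast[1]],
                    depths,
                    design=cfg.design,
                    replicates=cfg.replicates,
                    level=cfg.ci_level,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                ci.to_frame().to_csv(
                    out(f"ci_{cid}.tsv"), sep="\t", index=False
                )
            flagged = bsa_stats.flag_candidates(stats, cfg.thresholds, ci)
            flagged.to_csv(out(f"stats_{cid}.tsv"), sep="\t", index=False)
            stage = f"regions[{cid}]"
            regions = qtl_regions.call_regions(flagged, cid, cfg.regions)
            qtl_regions.write_regions(regions, out(f"regions_{cid}.bed"))
            regions_by_contrast[cid] = regions

            stage = f"effects[{cid}]"
            flagged_only = flagged[flagged["flagged"]]
            flagged_variants = [
                (r.chrom, int(r.pos), r.ref, r.alt)
                for r in flagged_only.itertuples()
            ]
            effects = gene_effects.classify_variants(
                flagged_variants, genes, genome
            )
            in_qtl = set(
                gene_effects.intersect_genes(regions, genes)["gene_id"]
            )
            nonsyn = set(
                effects.loc[
                    effects["effect"] == "non_synonymous", "gene_id"
                ].dropna()
            )
            study = sorted((in_qtl & nonsyn) & set(universe))
            study_by_contrast[cid] = study
            genes_in_qtl_all |= in_qtl
            genes_nonsyn_all |= in_qtl & nonsyn
            manifest["stages"][cid] = {
                "filter": report.as_dict(),
                "n_snps": int(len(stats)),
                "n_flagged": int(flagged["flagged"].sum()),
                "n_regions": len(regions),
                "n_genes_in_qtl": len(in_qtl),
                "n_genes_nonsyn_in_qtl": len(in_qtl & nonsyn),
                "n_study_genes": len(study),
            }

            stage = f"sea[{cid}]"
            if study:
                res = enrichment.sea(
                    study,
                    universe,
                    propagated,
                    method=cfg.adjust_method,
                    fdr_threshold=cfg.fdr_threshold,
                )
                res.to_csv(out(f"sea_{cid}.tsv"), sep="\t", index=False)
                sea_by_contrast[cid] = res
                manifest["stages"][cid]["n_enriched_terms"] = int(len(res))

        stage = "cross_compare"
        if len(sea_by_contrast) >= 2:
            matrix = enrichment.cross_compare(sea_by_contrast)
            matrix.to_csv(out("cross_compare.tsv"), sep="\t")
            manifest["stages"]["cross_compare"] = {
                "n_terms": int(len(matrix)),
                "n_shared_all": matrix.attrs["n_shared_all"],
                "n_shared_majority": matrix.attrs["n_shared_majority"],
                "n_unique": matrix.attrs["n_unique"],
            }

        stage = "prune"
        pruned_by_contrast = {
            cid: ontology.prune_enriched(
                list(res["term"]), graph, cfg.anchor_term
            )
            for cid, res in sea_by_contrast.items()
        }
        pruned_union = sorted(set().union(*pruned_by_contrast.values())) if (
            pruned_by_contrast
        ) else []
        with open(out("pruned_terms.tsv"), "w") as fh:
            fh.write("term\tcontrasts\n")
            for t in pruned_union:
                cids = [c for c, terms in pruned_by_contrast.items() if t in terms]
                fh.write(f"{t}\t{','.join(cids)}\n")
        manifest["stages"]["prune"] = {
            "anchor": cfg.anchor_term,
            "n_pruned_terms": len(pruned_union),
        }

        stage = "zoom"
        candidate_genes = sorted(set().union(*study_by_contrast.values())) if (
            study_by_contrast
        ) else []
        focus_genes = ontology.genes_for_term(
            {g: propagated.get(g, set()) for g in candidate_genes},
            graph,
            cfg.focus_term,
        )
        final_genes = sorted(focus_genes)
        with open(out("final_genes.txt"), "w") as fh:
            fh.write("\n".join(final_genes) + ("\n" if final_genes else ""))
        manifest["stages"]["zoom"] = {
            "focus": cfg.focus_term,
            "n_candidate_genes": len(candidate_genes),
            "n_final_genes": len(final_genes),
        }

        stage = "pathways"
        if final_genes:
            pathways = enrichment.pathway_enrich(
                final_genes, gene_sets, universe, method=cfg.adjust_method
            )
            pathways.to_csv(out("pathways.tsv"), sep="\t", index=False)
            manifest["stages"]["pathways"] = {
                "n_tested": int(len(pathways)),
                "top_set": pathways.iloc[0]["set"] if len(pathways) else None,
                "top_fdr": float(pathways.iloc[0]["fdr"]) if len(pathways) else None,
            }

        stage = "funnel"
        manifest["funnel"] = {
            "genes_in_qtl": len(genes_in_qtl_all),
            "genes_nonsyn_in_qtl": len(genes_nonsyn_all),
            "final_genes": len(final_genes),
        }
    except Exception as err:
        raise RuntimeError(f"refine failed at stage {stage!r}: {err}") from err

    manifest["checksums"] = {
        name: _sha256(path)
        for name, path in sorted(manifest["outputs"].items())
        if os.path.exists(path)
    }
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
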