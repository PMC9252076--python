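import os

import pytest

from ontoqtl.pipeline import PipelineConfig, run_refine
from ontoqtl.synthetic_data import generate_fixtures
from ontoqtl.variant_io import PoolDepth, PoolVariant


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """Complete synthetic data set with planted truths (fixed seed)."""
    out = tmp_path_factory.mktemp("fixtures")
    return generate_fixtures(str(out), seed=1)


@pytest.fixture(scope="session")
def refine_run(fixture_bundle, tmp_path_factory):
    """One full refine run over the synthetic fixtures."""
    p = fixture_bundle["paths"]
    out_dir = str(tmp_path_factory.mktemp("refine"))
    cfg = PipelineConfig(
        vcf=p["vcf"],
        gff3=p["gff3"],
        fasta=p["fasta"],
        obo=p["obo"],
        annotations=p["annotations"],
        gmt=p["gmt"],
        out_dir=out_dir,
        seed=7,
    )
    manifest = run_refine(cfg)
    return {"manifest": manifest, "out_dir": out_dir, "config": cfg}


def make_variant(chrom="C1", pos=100, ref="A", alt="T", **pools):
    """Terse PoolVariant builder: pools as label=(ref_depth, alt_depth, gq)."""
    return PoolVariant(
        chrom=chrom,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        pools={
            label: PoolDepth(ref_depth=r, alt_depth=a, gq=g)
            for label, (r, a, g) in pools.items()
        },
    )
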