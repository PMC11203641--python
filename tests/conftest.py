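from __future__ import annotations

import pytest

from bulkseg.variants import EffectAnnotation, SampleCall, VariantRecord


def make_record(
    chrom="Chr01",
    pos=100,
    ref="A",
    alt="T",
    genotype="hom_alt",
    ref_depth=0,
    alt_depth=30,
    gq=99.0,
    qual=900.0,
    effect="missense",
    gene="geneA",
    sample="bulk",
    qd=None,
):
    """Compact single-sample record builder used across the test suite."""
    annotations = (
        [EffectAnnotation(effect_class=effect, gene_id=gene, raw=f"{effect}|{gene}")]
        if effect
        else []
    )
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        qual=qual,
        samples={
            sample: SampleCall(
                genotype=genotype, ref_depth=ref_depth, alt_depth=alt_depth, gq=gq
            )
        },
        annotations=annotations,
        qd=qd,
    )


@pytest.fixture
def record_factory():
    return make_record
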