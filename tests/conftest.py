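import pytest

from apobecmut.variant_io import MutationRecord, MutationTable


@pytest.fixture
def toy_reference():
    """Single tiny contig with a hand-countable motif layout."""
    return {"chr1": "AAATCAAAAGCTTGACGTAC"}


@pytest.fixture
def toy_maf(tmp_path):
    text = "\t".join(
        [
            "Tumor_Sample_Barcode",
            "Chromosome",
            "Start_Position",
            "Reference_Allele",
            "Tumor_Seq_Allele2",
            "Variant_Classification",
        ]
    ) + "\n"
    rows = [
        ("S1", "chr1", "5", "C", "T", "Missense_Mutation"),
        ("S1", "chr1", "11", "C", "G", "Silent"),
        ("S1", "chr1", "15", "A", "C", "Missense_Mutation"),
    ]
    text += "".join("\t".join(r) + "\n" for r in rows)
    path = tmp_path / "toy.maf"
    path.write_text(text)
    return path


def make_record(ctx, ref, alt, sample="S1", pos=100, gene=None, vclass="Missense_Mutation"):
    """A context-bearing SNV record for motif tests."""
    return MutationRecord(
        sample_id=sample,
        chrom="chr1",
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        variant_classification=vclass,
        gene_symbol=gene,
        context=ctx,
    )


@pytest.fixture
def record_factory():
    return make_record
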