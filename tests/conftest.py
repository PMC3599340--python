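import pytest

from somavar.variant_io import CallSet, VariantCall


@pytest.fixture
def toy_calls():
    """Small hand-built tumor callset used across modules."""
    return CallSet("s1", [
        VariantCall("chr1", 100, "A", "G", 35.0, 12, "s1"),
        VariantCall("chr1", 200, "C", "T", 50.0, 20, "s1"),
        VariantCall("chr1", 300, "G", "C", 19.0, 8, "s1"),
        VariantCall("chr2", 150, "T", "A", 22.0, 30, "s1"),
        VariantCall("chr2", 400, "AT", "A", 40.0, 15, "s1"),
        VariantCall("chr2", 500, "G", "GACT", 60.0, 25, "s1"),
    ])


@pytest.fixture
def toy_gene_files(tmp_path):
    """One + strand gene, CDS 11..19 = ATGGCGTAA, on a 30-bp chromosome."""
    seq = "GGGGGCCCCC" + "ATGGCGTAA" + "ACGTACGTACG"
    fasta = tmp_path / "toy.fa"
    fasta.write_text(f">chrT\n{seq}\n")
    attrs = 'gene_id "gT"; transcript_id "tT";'
    gtf = tmp_path / "toy.gtf"
    gtf.write_text(
        f"chrT\ttest\texon\t11\t19\t.\t+\t.\t{attrs}\n"
        f"chrT\ttest\tCDS\t11\t19\t.\t+\t0\t{attrs}\n")
    return gtf, fasta, {"chrT": seq}
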