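import numpy as np
import pytest
from Bio.Seq import Seq

from somavar.consequence import (DISRUPTIVE_CATEGORIES, GeneModel,
                                 GeneModelIndex, assign_to_genes,
                                 classify_callset, classify_consequence,
                                 index_gene_models, recurrent_gene_table)
from somavar.variant_io import CallSet, VariantCall

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"


def _revcomp(seq):
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# independent oracle: rebuild the mutant chromosome base-by-base, re-splice
# the CDS, translate the WHOLE protein and compare
# ---------------------------------------------------------------------------

def oracle_category(v, m, genome):
    seq = genome[m.chrom]
    in_cds = m.in_cds

    entries = [(i + 1, base, in_cds(i + 1)) for i, base in enumerate(seq)]
    if v.vclass == "SNV":
        entries[v.pos - 1] = (v.pos, v.alt, in_cds(v.pos))
    elif v.vclass == "DEL":
        removed = set(range(v.pos + 1, v.pos + len(v.ref)))
        entries = [e for e in entries if e[0] not in removed]
    else:  # INS: bases placed between pos and pos+1
        flag = in_cds(v.pos) and in_cds(v.pos + 1) and \
            any(s <= v.pos < e for s, e in m.cds)
        inserted = [(v.pos, b, flag) for b in v.alt[1:]]
        idx = next(i for i, e in enumerate(entries) if e[0] == v.pos)
        entries = entries[:idx + 1] + inserted + entries[idx + 1:]

    def splice(ents):
        s = "".join(b for _, b, f in ents if f)
        return _revcomp(s) if m.strand == "-" else s

    ref_cds = splice([(i + 1, b, in_cds(i + 1)) for i, b in enumerate(seq)])
    mut_cds = splice(entries)

    if v.vclass != "SNV":
        if len(mut_cds) == len(ref_cds):
            return "noncoding"
        return "frameshift" if (len(mut_cds) - len(ref_cds)) % 3 else "inframe_indel"
    if mut_cds == ref_cds:
        return "noncoding"
    p_ref = str(Seq(ref_cds).translate())
    p_mut = str(Seq(mut_cds).translate())
    if p_ref == p_mut:
        return "synonymous"
    i = next(k for k in range(len(p_ref)) if p_ref[k] != p_mut[k])
    if p_ref[i] == "*":
        return "stop_loss"
    if p_mut[i] == "*":
        return "stop_gain"
    return "missense"


def _random_transcript(rng, chrom_len=600):
    """Toy transcript with <=5 exons, CDS <=300 bp, random strand."""
    n_codons = int(rng.integers(4, 34))  # CDS 12..99 bp + stop
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(_BASES[i] for i in rng.integers(0, 4, 3))
        if c not in _STOPS:
            codons.append(c)
    codons.append(_STOPS[rng.integers(0, 3)])
    orf = "".join(codons)
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(1, 6))
    cuts = sorted(rng.choice(np.arange(1, len(orf)), size=n_exons - 1,
                             replace=False)) if n_exons > 1 else []
    pieces, prev = [], 0
    for cut in list(cuts) + [len(orf)]:
        pieces.append(int(cut - prev))
        prev = cut
    genomic_cds = orf if strand == "+" else _revcomp(orf)

    genome_seq = list(_BASES[i] for i in rng.integers(0, 4, chrom_len))
    intervals = []
    cursor = int(rng.integers(10, 40))
    offset = 0
    for width in pieces:
        start = cursor
        end = start + width - 1
        intervals.append((start, end))
        genome_seq[start - 1:end] = genomic_cds[offset:offset + width]
        offset += width
        cursor = end + 1 + int(rng.integers(5, 20))
    genome = {"chrR": "".join(genome_seq)}
    model = GeneModel("gR", "tR", "chrR", strand,
                      exons=tuple(intervals), cds=tuple(intervals))
    return model, genome


def _random_cds_variant(rng, model, genome):
    seq = genome[model.chrom]
    cds_positions = [p for s, e in model.cds for p in range(s, e + 1)]
    kind = rng.random()
    pos = int(rng.choice(cds_positions))
    ref = seq[pos - 1]
    if kind < 0.6:  # SNV
        alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        return VariantCall(model.chrom, pos, ref, alt, 30.0, 10, "s")
    if kind < 0.8:  # insertion
        size = int(rng.integers(1, 5))
        ins = "".join(_BASES[i] for i in rng.integers(0, 4, size))
        return VariantCall(model.chrom, pos, ref, ref + ins, 30.0, 10, "s")
    size = int(rng.integers(1, 5))  # deletion
    if pos + size > len(seq):
        size = 1
    ref_del = seq[pos - 1:pos + size]
    return VariantCall(model.chrom, pos, ref_del, ref_del[0], 30.0, 10, "s")


class TestIndexGeneModels:
    def test_one_gene_cds_sequence(self, toy_gene_files):
        gtf, fasta, genome = toy_gene_files
        index = index_gene_models(gtf, fasta)
        assert len(index) == 1
        m = index.models[0]
        assert m.cds_sequence(genome) == "ATGGCGTAA"

    def test_minus_strand_revcomp(self, tmp_path):
        orf = "ATGGCGTAA"
        seq = "GGGGGCCCCC" + _revcomp(orf) + "ACGTACGTACG"
        fasta = tmp_path / "m.fa"
        fasta.write_text(f">chrM\n{seq}\n")
        attrs = 'gene_id "gM"; transcript_id "tM";'
        gtf = tmp_path / "m.gtf"
        gtf.write_text(f"chrM\tt\texon\t11\t19\t.\t-\t.\t{attrs}\n"
                       f"chrM\tt\tCDS\t11\t19\t.\t-\t0\t{attrs}\n")
        index = index_gene_models(gtf, fasta)
        assert index.models[0].cds_sequence({"chrM": seq}) == orf

    def test_empty_gtf(self, tmp_path):
        fasta = tmp_path / "e.fa"
        fasta.write_text(">chrE\nACGTACGT\n")
        gtf = tmp_path / "e.gtf"
        gtf.write_text("")
        assert len(index_gene_models(gtf, fasta)) == 0

    def test_absent_chromosome_errors(self, tmp_path):
        fasta = tmp_path / "a.fa"
        fasta.write_text(">chrA\nACGTACGTACGT\n")
        attrs = 'gene_id "g"; transcript_id "t";'
        gtf = tmp_path / "a.gtf"
        gtf.write_text(f"chrZ\tt\texon\t1\t9\t.\t+\t.\t{attrs}\n"
                       f"chrZ\tt\tCDS\t1\t9\t.\t+\t0\t{attrs}\n")
        with pytest.raises(ValueError, match="absent chromosome"):
            index_gene_models(gtf, fasta)

    def test_partial_cds_warns(self, tmp_path):
        fasta = tmp_path / "p.fa"
        fasta.write_text(">chrP\nACGTACGTACGT\n")
        attrs = 'gene_id "g"; transcript_id "t";'
        gtf = tmp_path / "p.gtf"
        gtf.write_text(f"chrP\tt\texon\t1\t8\t.\t+\t.\t{attrs}\n"
                       f"chrP\tt\tCDS\t1\t8\t.\t+\t0\t{attrs}\n")
        with pytest.warns(UserWarning, match="partial"):
            index_gene_models(gtf, fasta)


class TestAssign:
    def test_exonic_assigned(self, toy_gene_files):
        gtf, fasta, _ = toy_gene_files
        index = index_gene_models(gtf, fasta)
        cs = CallSet("s", [VariantCall("chrT", 15, "C", "A", 30.0, 10, "s")])
        assigned = assign_to_genes(cs, index)
        assert len(assigned[0][1]) == 1

    def test_intergenic_empty(self, toy_gene_files):
        gtf, fasta, _ = toy_gene_files
        index = index_gene_models(gtf, fasta)
        cs = CallSet("s", [VariantCall("chrT", 3, "G", "A", 30.0, 10, "s")])
        assert assign_to_genes(cs, index)[0][1] == []

    def test_deletion_spanning_boundary(self, toy_gene_files):
        gtf, fasta, genome = toy_gene_files
        index = index_gene_models(gtf, fasta)
        # deletion starting before the exon, reaching into it
        ref = genome["chrT"][8:12]
        cs = CallSet("s", [VariantCall("chrT", 9, ref, ref[0], 30.0, 10, "s")])
        assert len(assign_to_genes(cs, index)[0][1]) == 1


class TestClassify:
    """Toy gene chrT:+ with CDS = ATGGCGTAA at 11..19."""

    def _model(self, toy_gene_files):
        gtf, fasta, genome = toy_gene_files
        return index_gene_models(gtf, fasta).models[0], genome

    def test_missense(self, toy_gene_files):
        m, genome = self._model(toy_gene_files)
        v = VariantCall("chrT", 15, "C", "A", 30.0, 10, "s")  # GCG -> GAG
        cc = classify_consequence(v, m, genome)
        assert cc.category == "missense" and cc.disruptive

    def test_synonymous(self, toy_gene_files):
        m, genome = self._model(toy_gene_files)
        v = VariantCall("chrT", 16, "G", "A", 30.0, 10, "s")  # GCG -> GCA
        cc = classify_consequence(v, m, genome)
        assert cc.category == "synonymous" and not cc.disruptive

    def test_frameshift_insertion(self, toy_gene_files):
        m, genome = self._model(toy_gene_files)
        v = VariantCall("chrT", 14, "G", "GT", 30.0, 10, "s")
        cc = classify_consequence(v, m, genome)
        assert cc.category == "frameshift" and cc.disruptive

    def test_inframe_insertion(self, toy_gene_files):
        m, genome = self._model(toy_gene_files)
        v = VariantCall("chrT", 14, "G", "GTTT", 30.0, 10, "s")
        assert classify_consequence(v, m, genome).category == "inframe_indel"

    def test_stop_loss(self, toy_gene_files):
        m, genome = self._model(toy_gene_files)
        v = VariantCall("chrT", 17, "T", "C", 30.0, 10, "s")  # TAA -> CAA
        assert classify_consequence(v, m, genome).category == "stop_loss"

    def test_stop_gain(self, tmp_path):
        # CDS ATG TGG TAA: TGG (Trp) -> TGA (stop) via G>A at CDS offset 5
        seq = "AAAAA" + "ATGTGGTAA" + "CCCCC"
        fasta = tmp_path / "sg.fa"
        fasta.write_text(f">chrS\n{seq}\n")
        attrs = 'gene_id "gS"; transcript_id "tS";'
        gtf = tmp_path / "sg.gtf"
        gtf.write_text(f"chrS\tt\texon\t6\t14\t.\t+\t.\t{attrs}\n"
                       f"chrS\tt\tCDS\t6\t14\t.\t+\t0\t{attrs}\n")
        index = index_gene_models(gtf, fasta)
        v = VariantCall("chrS", 11, "G", "A", 30.0, 10, "s")
        cc = classify_consequence(v, index.models[0], index.genome)
        assert cc.category == "stop_gain" and cc.disruptive

    def test_noncoding_outside_transcript_errors(self, toy_gene_files):
        m, genome = self._model(toy_gene_files)
        v = VariantCall("chrT", 2, "G", "A", 30.0, 10, "s")
        with pytest.raises(ValueError, match="does not overlap"):
            classify_consequence(v, m, genome)

    def test_ref_mismatch_detected(self, toy_gene_files):
        m, genome = self._model(toy_gene_files)
        v = VariantCall("chrT", 15, "T", "A", 30.0, 10, "s")  # true ref is C
        with pytest.raises(ValueError, match="REF mismatch"):
            classify_consequence(v, m, genome)

    def test_disruptive_set_is_exact(self):
        assert DISRUPTIVE_CATEGORIES == {
            "missense", "stop_gain", "stop_loss", "inframe_indel", "frameshift"}


class TestOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_random_transcripts_match_full_translation(self, seed):
        rng = np.random.default_rng(seed)
        checked = 0
        while checked < 150:
            model, genome = _random_transcript(rng)
            for _ in range(10):
                v = _random_cds_variant(rng, model, genome)
                if v.end > model.span[1]:  # deletion running past the gene
                    continue
                got = classify_consequence(v, model, genome).category
                assert got == oracle_category(v, model, genome), \
                    f"{v} on {model.strand} strand {model.cds}"
                checked += 1

    def test_strand_mirror_property(self):
        rng = np.random.default_rng(99)
        for _ in range(40):
            model, genome = _random_transcript(rng)
            seq = genome[model.chrom]
            length = len(seq)
            mirror_seq = _revcomp(seq)
            mirror_cds = tuple(sorted((length + 1 - e, length + 1 - s)
                                      for s, e in model.cds))
            mirror = GeneModel("gR", "tR", "chrR",
                               "-" if model.strand == "+" else "+",
                               exons=mirror_cds, cds=mirror_cds)
            mirror_genome = {"chrR": mirror_seq}
            v = _random_cds_variant(rng, model, genome)
            if v.vclass != "SNV":
                continue
            mv = VariantCall("chrR", length + 1 - v.pos,
                             _revcomp(v.ref), _revcomp(v.alt), 30.0, 10, "s")
            assert classify_consequence(v, model, genome).category == \
                classify_consequence(mv, mirror, mirror_genome).category


class TestRecurrence:
    def _cc(self, gene, pos, category, sample):
        v = VariantCall("c", pos, "A", "G", 30.0, 10, sample)
        from somavar.consequence import ConsequenceCall
        return ConsequenceCall(v, gene, gene + "_t1", category)

    def test_hit_in_both_samples_flagged(self):
        rows = recurrent_gene_table([
            ("t1", [self._cc("gA", 10, "missense", "t1")]),
            ("t2", [self._cc("gA", 99, "frameshift", "t2")]),
        ])
        assert len(rows) == 1
        assert rows[0].total == 2 and rows[0].samples_hit == 2

    def test_single_sample_not_flagged(self):
        rows = recurrent_gene_table([
            ("t1", [self._cc("gA", 10, "missense", "t1")]),
            ("t2", []),
        ])
        assert rows[0].samples_hit == 1

    def test_nondisruptive_excluded(self):
        rows = recurrent_gene_table([
            ("t1", [self._cc("gA", 10, "synonymous", "t1"),
                    self._cc("gB", 20, "noncoding", "t1")]),
        ])
        assert rows == []

    def test_total_counts_sum(self):
        rows = recurrent_gene_table([
            ("t1", [self._cc("gA", 10, "missense", "t1"),
                    self._cc("gA", 30, "stop_gain", "t1")]),
            ("t2", [self._cc("gA", 50, "inframe_indel", "t2")] * 1),
        ])
        assert rows[0].total == 3

    def test_multi_transcript_counts_once(self):
        v = VariantCall("c", 10, "A", "G", 30.0, 10, "t1")
        from somavar.consequence import ConsequenceCall
        calls = [ConsequenceCall(v, "gA", "tx1", "missense"),
                 ConsequenceCall(v, "gA", "tx2", "missense")]
        rows = recurrent_gene_table([("t1", calls)])
        assert rows[0].total == 1


def test_every_overlap_yields_consequence(toy_gene_files):
    gtf, fasta, _ = toy_gene_files
    index = index_gene_models(gtf, fasta)
    cs = CallSet("s", [VariantCall("chrT", 15, "C", "A", 30.0, 10, "s"),
                       VariantCall("chrT", 3, "G", "A", 30.0, 10, "s")])
    calls = classify_callset(cs, index)
    assert len(calls) == 1  # only the exonic variant maps
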