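"""Gene-model indexing, coding-consequence classification and recurrence.

A variant is "disruptive" when it changes encoded amino acids or the
reading frame: missense, stop gain/loss, in-frame indel or frameshift.
Synonymous and non-CDS exonic variants are not disruptive.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio.Seq import Seq
from pyfaidx import Fasta

from .variant_io import CallSet, VariantCall

log = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "GeneModelIndex",
    "ConsequenceCall",
    "GeneHitSummary",
    "DISRUPTIVE_CATEGORIES",
    "index_gene_models",
    "assign_to_genes",
    "classify_consequence",
    "recurrent_gene_table",
]

DISRUPTIVE_CATEGORIES = frozenset(
    {"missense", "stop_gain", "stop_loss", "inframe_indel", "frameshift"})


def _check_intervals(ivs: Sequence[tuple[int, int]], what: str) -> None:
    prev_end = 0
    for s, e in ivs:
        if s < 1 or e < s:
            raise ValueError(f"bad {what} interval ({s}, {e})")
        if s <= prev_end:
            raise ValueError(f"{what} intervals must be sorted and disjoint")
        prev_end = e


@dataclass(frozen=True)
class GeneModel:
    """One transcript: strand, exon and CDS intervals (1-based, closed)."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        _check_intervals(self.exons, "exon")
        _check_intervals(self.cds, "CDS")
        for cs, ce in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValueError(f"CDS interval ({cs}, {ce}) not nested in an exon")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def complete_orf(self) -> bool:
        return self.cds_length >= 3 and self.cds_length % 3 == 0

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    def cds_sequence(self, genome: Mapping[str, str]) -> str:
        """Spliced CDS in translation orientation (revcomp for - strand)."""
        seq = "".join(str(genome[self.chrom][s - 1:e]) for s, e in self.cds)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq.upper()

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of genomic ``pos`` in the oriented CDS, or None."""
        cum = 0
        plus_off = None
        for s, e in self.cds:
            if s <= pos <= e:
                plus_off = cum + (pos - s)
            cum += e - s + 1
        if plus_off is None:
            return None
        return plus_off if self.strand == "+" else cum - 1 - plus_off

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds)

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)


class GeneModelIndex:
    """Point/interval-queryable collection of gene models plus sequence."""

    def __init__(self, models: Iterable[GeneModel],
                 genome: Mapping[str, str]) -> None:
        self.models = tuple(models)
        self.genome = genome
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for m in self.models:
            if m.chrom not in genome:
                raise ValueError(
                    f"transcript {m.transcript_id} references absent chromosome "
                    f"{m.chrom!r}")
            if not m.complete_orf:
                warnings.warn(
                    f"transcript {m.transcript_id}: CDS length {m.cds_length} not "
                    "divisible by 3; flagged partial", stacklevel=2)
            self._by_chrom.setdefault(m.chrom, []).append(m)

    def __len__(self) -> int:
        return len(self.models)

    def query(self, chrom: str, start: int, end: int | None = None) -> list[GeneModel]:
        """Models with an exon overlapping the closed interval [start, end]."""
        end = start if end is None else end
        hits = []
        for m in self._by_chrom.get(chrom, []):
            if any(s <= end and start <= e for s, e in m.exons):
                hits.append(m)
        return hits


def _load_genome(fasta: str | Mapping[str, str]) -> Mapping[str, str]:
    if isinstance(fasta, (str, bytes)) or hasattr(fasta, "__fspath__"):
        fa = Fasta(str(fasta), as_raw=True, sequence_always_upper=True)
        return {name: str(fa[name][:]) for name in fa.keys()}
    return fasta


def index_gene_models(gtf_path, fasta) -> GeneModelIndex:
    """Build a GeneModelIndex from a GTF and a FASTA (path or dict)."""
    genome = _load_genome(fasta)
    with open(gtf_path) as fh:
        has_features = any(line.strip() and not line.startswith("#") for line in fh)
    if not has_features:
        return GeneModelIndex([], genome)
    db = gffutils.create_db(
        str(gtf_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True)
    per_tx: dict[str, dict] = {}
    for ftype, slot in (("exon", "exons"), ("CDS", "cds")):
        for feat in db.features_of_type(ftype):
            tx = feat.attributes.get("transcript_id", [None])[0]
            gene = feat.attributes.get("gene_id", [None])[0]
            if tx is None:
                raise ValueError(f"{gtf_path}: {ftype} feature lacks transcript_id")
            entry = per_tx.setdefault(
                tx, {"gene": gene, "chrom": feat.seqid, "strand": feat.strand,
                     "exons": [], "cds": []})
            entry[slot].append((feat.start, feat.end))
    models = []
    for tx, entry in sorted(per_tx.items()):
        models.append(GeneModel(
            gene_id=entry["gene"] or tx,
            transcript_id=tx,
            chrom=entry["chrom"],
            strand=entry["strand"],
            exons=tuple(sorted(entry["exons"])),
            cds=tuple(sorted(entry["cds"]))))
    return GeneModelIndex(models, genome)


@dataclass(frozen=True)
class ConsequenceCall:
    variant: VariantCall
    gene_id: str
    transcript_id: str
    category: str

    @property
    def disruptive(self) -> bool:
        return self.category in DISRUPTIVE_CATEGORIES


def assign_to_genes(cs: CallSet, index: GeneModelIndex
                    ) -> list[tuple[VariantCall, list[GeneModel]]]:
    """Pair each call with the transcripts whose exons its REF span hits.

    Calls overlapping no transcript get an empty list (intergenic).
    """
    return [(c, index.query(c.chrom, c.pos, c.end)) for c in cs]


def _snv_category(v: VariantCall, m: GeneModel, genome: Mapping[str, str]) -> str:
    off = m.cds_offset(v.pos)
    if off is None:
        return "noncoding"
    cds = m.cds_sequence(genome)
    codon_i = off // 3
    codon = cds[3 * codon_i:3 * codon_i + 3]
    if len(codon) < 3:
        return "noncoding"  # trailing partial codon: effect indeterminate
    within = off % 3
    ref_b, alt_b = v.ref, v.alt
    if m.strand == "-":
        ref_b = str(Seq(ref_b).reverse_complement())
        alt_b = str(Seq(alt_b).reverse_complement())
    if codon[within] != ref_b:
        raise ValueError(
            f"REF mismatch at {v.chrom}:{v.pos} — CDS has {codon[within]}, "
            f"call has {ref_b} (oriented)")
    mutant = codon[:within] + alt_b + codon[within + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutant).translate())
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_ref == "*":
        return "stop_loss"
    if aa_alt == "*":
        return "stop_gain"
    return "missense"


def _cds_bases_changed(v: VariantCall, m: GeneModel) -> int:
    """Number of CDS bases an indel adds or removes (0 = CDS untouched)."""
    if v.vclass == "INS":
        # inserted bases land between pos and pos+1; inside CDS only if the
        # insertion point is strictly interior to a CDS interval
        if any(s <= v.pos < e for s, e in m.cds):
            return len(v.alt) - len(v.ref)
        return 0
    # DEL: bases pos+1 .. end are removed; only those inside CDS shift frame
    return sum(1 for p in range(v.pos + 1, v.end + 1) if m.in_cds(p))


def classify_consequence(v: VariantCall, m: GeneModel,
                         genome: Mapping[str, str]) -> ConsequenceCall:
    """Classify one variant against one transcript.

    SNVs inside the CDS are translated codon-wise (strand aware, standard
    genetic code); CDS indels are frameshift when the length change is not
    a multiple of 3, in-frame otherwise. Exonic-but-non-CDS is noncoding.
    """
    if not any(s <= v.end and v.pos <= e for s, e in m.exons):
        raise ValueError(
            f"variant {v.chrom}:{v.pos} does not overlap transcript "
            f"{m.transcript_id}")
    if v.vclass == "SNV":
        category = _snv_category(v, m, genome)
    else:
        changed = _cds_bases_changed(v, m)
        if changed == 0:
            category = "noncoding"
        else:
            category = "frameshift" if changed % 3 else "inframe_indel"
    return ConsequenceCall(v, m.gene_id, m.transcript_id, category)


def classify_callset(cs: CallSet, index: GeneModelIndex) -> list[ConsequenceCall]:
    """All ConsequenceCalls for a callset (one per overlapping transcript)."""
    out = []
    for v, models in assign_to_genes(cs, index):
        for m in models:
            out.append(classify_consequence(v, m, index.genome))
    return out


@dataclass
class GeneHitSummary:
    """Disruptive-hit summary for one gene across tumor samples."""

    gene_id: str
    per_sample: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.per_sample.values())

    @property
    def samples_hit(self) -> int:
        return sum(1 for n in self.per_sample.values() if n > 0)


def recurrent_gene_table(per_sample_calls: Iterable[tuple[str, Iterable[ConsequenceCall]]]
                         ) -> list[GeneHitSummary]:
    """Per-gene disruptive-variant counts across samples, sorted by gene.

    Each summary carries ``samples_hit``; genes hit in every sample are the
    recurrence candidates. Variants hitting several transcripts of one gene
    count once per variant per sample.
    """
    samples = []
    genes: dict[str, GeneHitSummary] = {}
    for sample_id, calls in per_sample_calls:
        samples.append(sample_id)
        seen: set[tuple] = set()
        for cc in calls:
            if not cc.disruptive:
                continue
            dedup = (cc.gene_id, cc.variant.key)
            if dedup in seen:
                continue
            seen.add(dedup)
            summary = genes.setdefault(cc.gene_id, GeneHitSummary(cc.gene_id))
            summary.per_sample[sample_id] = summary.per_sample.get(sample_id, 0) + 1
    for summary in genes.values():
        for sid in samples:
            summary.per_sample.setdefault(sid, 0)
    return [genes[g] for g in sorted(genes)]
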