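"""Self-contained simulator for paired tumor/normal callset fixtures.

Generates a toy genome with valid ORFs, a known-variant database, paired
callsets with coverage tracks, and a ground-truth table. Each planted
variant class either survives the whole filter cascade (somatic) or is
constructed to violate exactly one filter predicate:

* ``germline_known`` / ``germline_novel`` — in both samples; removed by
  database or shared-call subtraction.
* ``artifact_lowqual`` — quality below the threshold.
* ``artifact_highdepth`` — depth above the trained coverage cutoff.
* ``artifact_singlecov`` — no coverage in the partner sample.
* ``artifact_shared`` — identical novel call in both samples.
* ``artifact_cluster`` — triplets of calls within one mismatch window.
* ``editing`` — A>G on the transcribed strand in both samples (removed
  as shared), inflating the transition count.

Variants are planted as calls plus depth tracks directly; no reads are
simulated. Identical (seed, config) yields byte-identical outputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np

from .consequence import GeneModel
from .variant_io import (CallSet, CoverageTrack, KnownVariantDB, SamplePair,
                         VariantCall, write_vcf)

__all__ = [
    "SimulationConfig",
    "Reference",
    "TruthRow",
    "SimulatedPair",
    "simulate_reference",
    "simulate_pair",
    "evaluate_against_truth",
    "simulate_to_dir",
    "read_truth",
]

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
LABELS = ("germline_known", "germline_novel", "somatic", "artifact_shared",
          "artifact_lowqual", "artifact_highdepth", "artifact_singlecov",
          "artifact_cluster", "editing")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 100_000
    n_genes: int = 20
    cds_min: int = 300
    cds_max: int = 900
    plus_strand_prob: float = 0.5
    germline_rate: float = 4e-4
    known_db_fraction: float = 0.6
    somatic_rate: float = 1e-4
    shared_artifact_rate: float = 0.0
    lowqual_artifact_rate: float = 0.0
    highdepth_artifact_rate: float = 0.0
    singlecov_artifact_rate: float = 0.0
    cluster_artifact_rate: float = 0.0
    editing_rate: float = 0.0
    indel_fraction: float = 0.1
    transition_prob: float = 0.7
    mean_depth: float = 30.0
    depth_dispersion: float = 5.0
    dup_spike_prob: float = 0.02
    dup_spike_factor: float = 8.0
    qual_true_mean: float = 60.0
    qual_true_sd: float = 10.0
    qual_artifact_mean: float = 10.0
    qual_artifact_sd: float = 4.0
    coverage_quantile: float = 0.975
    min_site_spacing: int = 25
    pair_id: str = "pair1"

    def __post_init__(self) -> None:
        rates = (self.germline_rate, self.somatic_rate, self.shared_artifact_rate,
                 self.lowqual_artifact_rate, self.highdepth_artifact_rate,
                 self.singlecov_artifact_rate, self.cluster_artifact_rate,
                 self.editing_rate)
        if any(r < 0 for r in rates):
            raise ValueError("rates must be non-negative")
        for frac in (self.known_db_fraction, self.plus_strand_prob,
                     self.indel_fraction, self.transition_prob,
                     self.dup_spike_prob):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must be in [0, 1]")
        if self.cds_min < 9 or self.cds_max < self.cds_min:
            raise ValueError("invalid CDS length range")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Reference:
    genome: dict[str, str]
    models: list[GeneModel]

    def fasta_text(self, width: int = 60) -> str:
        chunks = []
        for chrom in sorted(self.genome):
            chunks.append(f">{chrom}\n")
            seq = self.genome[chrom]
            for i in range(0, len(seq), width):
                chunks.append(seq[i:i + width] + "\n")
        return "".join(chunks)

    def gtf_text(self) -> str:
        lines = []
        for m in self.models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            s, e = m.span
            lines.append(f"{m.chrom}\tsim\ttranscript\t{s}\t{e}\t.\t{m.strand}\t.\t{attrs}")
            for xs, xe in m.exons:
                lines.append(f"{m.chrom}\tsim\texon\t{xs}\t{xe}\t.\t{m.strand}\t.\t{attrs}")
            for cs, ce in m.cds:
                lines.append(f"{m.chrom}\tsim\tCDS\t{cs}\t{ce}\t.\t{m.strand}\t0\t{attrs}")
        return "\n".join(lines) + ("\n" if lines else "")


@dataclass(frozen=True)
class TruthRow:
    chrom: str
    pos: int
    ref: str
    alt: str
    label: str
    expected_final_status: str  # tumor_specific / normal_specific / removed

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SimulatedPair:
    pair: SamplePair
    known_db: KnownVariantDB
    truth: list[TruthRow]
    cutoffs: dict[str, int] = field(default_factory=dict)


_REVCOMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons - 2) random non-stop codons + a stop codon."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = "".join(_BASES[i] for i in rng.integers(0, 4, 3))
        if codon not in _STOPS:
            codons.append(codon)
    codons.append(_STOPS[rng.integers(0, 3)])
    return "".join(codons)


def simulate_reference(cfg: SimulationConfig) -> Reference:
    """Random genome plus non-overlapping single-exon ORF transcripts."""
    rng = np.random.default_rng(cfg.seed)
    genome = {}
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    for chrom in chrom_names:
        genome[chrom] = "".join(
            _BASES[i] for i in rng.integers(0, 4, cfg.chrom_length))
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    models: list[GeneModel] = []
    margin = 50
    for gi in range(cfg.n_genes):
        chrom = chrom_names[gi % cfg.n_chroms]
        n_codons = int(rng.integers(cfg.cds_min // 3, cfg.cds_max // 3 + 1))
        orf = _random_orf(rng, n_codons)
        length = len(orf)
        placed = False
        for _ in range(1000):
            start = int(rng.integers(margin + 1, cfg.chrom_length - length - margin))
            end = start + length - 1
            if all(end + margin < s or e + margin < start
                   for s, e in occupied[chrom]):
                placed = True
                break
        if not placed:
            raise RuntimeError(
                "could not place genes without overlap; increase chrom_length")
        occupied[chrom].append((start, end))
        strand = "+" if rng.random() < cfg.plus_strand_prob else "-"
        insert = orf if strand == "+" else _revcomp(orf)
        seq = genome[chrom]
        genome[chrom] = seq[:start - 1] + insert + seq[start + length - 1:]
        models.append(GeneModel(
            gene_id=f"g{gi + 1:04d}", transcript_id=f"t{gi + 1:04d}",
            chrom=chrom, strand=strand,
            exons=((start, end),), cds=((start, end),)))
    models.sort(key=lambda m: (m.chrom, m.span[0]))
    return Reference(genome=genome, models=models)


class _SitePlanner:
    """Allocates planting positions with a minimum pairwise spacing."""

    def __init__(self, rng: np.random.Generator, genome: dict[str, str],
                 spacing: int) -> None:
        self.rng = rng
        self.genome = genome
        self.spacing = spacing
        self.taken: dict[str, list[int]] = {c: [] for c in genome}
        self.chroms = sorted(genome)

    def _free(self, chrom: str, pos: int, slack: int = 0) -> bool:
        return all(abs(pos - p) >= self.spacing + slack for p in self.taken[chrom])

    def claim(self, chrom: str, pos: int) -> None:
        self.taken[chrom].append(pos)

    def alloc(self, span: int = 1, chrom: str | None = None) -> tuple[str, int]:
        for _ in range(10_000):
            c = chrom or self.chroms[int(self.rng.integers(0, len(self.chroms)))]
            pos = int(self.rng.integers(self.spacing,
                                        len(self.genome[c]) - span - self.spacing))
            if self._free(c, pos, slack=span):
                self.claim(c, pos)
                return c, pos
        raise RuntimeError(
            "cannot satisfy site-spacing constraints; lower the rates or "
            "enlarge the genome")


def _draw_depth(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    disp = cfg.depth_dispersion
    p = disp / (disp + max(cfg.mean_depth - 1, 0.1))
    return int(rng.negative_binomial(disp, p)) + 1


def _draw_qual_true(rng: np.random.Generator, cfg: SimulationConfig) -> float:
    return round(max(float(rng.normal(cfg.qual_true_mean, cfg.qual_true_sd)),
                     21.0), 1)


def _draw_qual_artifact(rng: np.random.Generator, cfg: SimulationConfig) -> float:
    q = float(rng.normal(cfg.qual_artifact_mean, cfg.qual_artifact_sd))
    return round(min(max(q, 0.0), 19.5), 1)


def _snv_alt(rng: np.random.Generator, ref: str, transition_prob: float) -> str:
    if rng.random() < transition_prob:
        return _TRANSITION[ref]
    choices = [b for b in _BASES if b != ref and b != _TRANSITION[ref]]
    return choices[int(rng.integers(0, len(choices)))]


def _make_variant(rng: np.random.Generator, cfg: SimulationConfig,
                  genome: dict[str, str], planner: _SitePlanner,
                  allow_indel: bool = True) -> tuple[str, int, str, str]:
    indel = allow_indel and rng.random() < cfg.indel_fraction
    if not indel:
        chrom, pos = planner.alloc()
        ref = genome[chrom][pos - 1]
        return chrom, pos, ref, _snv_alt(rng, ref, cfg.transition_prob)
    size = int(rng.integers(1, 4))
    if rng.random() < 0.5:  # insertion
        chrom, pos = planner.alloc()
        anchor = genome[chrom][pos - 1]
        inserted = "".join(_BASES[i] for i in rng.integers(0, 4, size))
        return chrom, pos, anchor, anchor + inserted
    chrom, pos = planner.alloc(span=size + 1)
    ref = genome[chrom][pos - 1:pos + size]
    return chrom, pos, ref, ref[0]


def _nearest_rank(depths: list[int], q: float) -> int:
    depths = sorted(depths)
    return depths[math.ceil(q * len(depths)) - 1]


def simulate_pair(cfg: SimulationConfig, reference: Reference) -> SimulatedPair:
    """Plant all variant classes and return callsets, DB, tracks and truth."""
    rng = np.random.default_rng(cfg.seed + 1)  # decoupled from reference stream
    genome = reference.genome
    genome_size = sum(len(s) for s in genome.values())
    planner = _SitePlanner(rng, genome, cfg.min_site_spacing)

    tumor_id = f"{cfg.pair_id}_tumor"
    normal_id = f"{cfg.pair_id}_normal"
    tumor_calls: list[VariantCall] = []
    normal_calls: list[VariantCall] = []
    tumor_cov = CoverageTrack()
    normal_cov = CoverageTrack()
    db = KnownVariantDB()
    truth: list[TruthRow] = []

    def n_of(rate: float) -> int:
        return int(round(rate * genome_size))

    def cover(track: CoverageTrack, chrom: str, pos: int, depth: int) -> None:
        track.set_depth(chrom, pos, depth)

    # --- germline (both samples; defines the trainable known set) ---------
    germline: list[dict] = []
    n_germ = n_of(cfg.germline_rate)
    for i in range(n_germ):
        chrom, pos, ref, alt = _make_variant(rng, cfg, genome, planner)
        known = bool(rng.random() < cfg.known_db_fraction)
        d_t, d_n = _draw_depth(rng, cfg), _draw_depth(rng, cfg)
        if known and rng.random() < cfg.dup_spike_prob:
            d_t = int(d_t * cfg.dup_spike_factor)
            d_n = int(d_n * cfg.dup_spike_factor)
        germline.append(dict(chrom=chrom, pos=pos, ref=ref, alt=alt, known=known,
                             d_t=d_t, d_n=d_n,
                             q_t=_draw_qual_true(rng, cfg),
                             q_n=_draw_qual_true(rng, cfg)))
    if germline and not any(g["known"] for g in germline):
        germline[0]["known"] = True
    # cutoffs as the cascade will train them (known calls all pass QUAL)
    known_t = [g["d_t"] for g in germline if g["known"]]
    known_n = [g["d_n"] for g in germline if g["known"]]
    cut_t = _nearest_rank(known_t, cfg.coverage_quantile) if known_t else 10 ** 9
    cut_n = _nearest_rank(known_n, cfg.coverage_quantile) if known_n else 10 ** 9
    for g in germline:
        if not g["known"]:
            # novel germline must survive the coverage stage in BOTH samples
            # so that shared-call subtraction is what removes it
            g["d_t"] = min(g["d_t"], cut_t)
            g["d_n"] = min(g["d_n"], cut_n)
    for g in germline:
        if g["known"]:
            db.add(g["chrom"], g["pos"], g["ref"], g["alt"])
        tumor_calls.append(VariantCall(g["chrom"], g["pos"], g["ref"], g["alt"],
                                       g["q_t"], g["d_t"], tumor_id))
        normal_calls.append(VariantCall(g["chrom"], g["pos"], g["ref"], g["alt"],
                                        g["q_n"], g["d_n"], normal_id))
        cover(tumor_cov, g["chrom"], g["pos"], g["d_t"])
        cover(normal_cov, g["chrom"], g["pos"], g["d_n"])
        label = "germline_known" if g["known"] else "germline_novel"
        truth.append(TruthRow(g["chrom"], g["pos"], g["ref"], g["alt"],
                              label, "removed"))

    def true_depth(cutoff: int) -> int:
        return max(1, min(_draw_depth(rng, cfg), cutoff))

    def plant_tumor_only(label: str, chrom: str, pos: int, ref: str, alt: str,
                         qual: float, depth: int, normal_depth: int,
                         status: str = "removed") -> None:
        tumor_calls.append(VariantCall(chrom, pos, ref, alt, qual, depth, tumor_id))
        cover(tumor_cov, chrom, pos, depth)
        if normal_depth > 0:
            cover(normal_cov, chrom, pos, normal_depth)
        truth.append(TruthRow(chrom, pos, ref, alt, label, status))

    # --- somatic: survives every stage by construction --------------------
    for _ in range(n_of(cfg.somatic_rate)):
        chrom, pos, ref, alt = _make_variant(rng, cfg, genome, planner)
        plant_tumor_only("somatic", chrom, pos, ref, alt,
                         _draw_qual_true(rng, cfg), true_depth(cut_t),
                         _draw_depth(rng, cfg), status="tumor_specific")

    # --- artifact classes: each violates exactly one predicate ------------
    for _ in range(n_of(cfg.lowqual_artifact_rate)):
        chrom, pos, ref, alt = _make_variant(rng, cfg, genome, planner,
                                             allow_indel=False)
        plant_tumor_only("artifact_lowqual", chrom, pos, ref, alt,
                         _draw_qual_artifact(rng, cfg), true_depth(cut_t),
                         _draw_depth(rng, cfg))
    for _ in range(n_of(cfg.highdepth_artifact_rate)):
        chrom, pos, ref, alt = _make_variant(rng, cfg, genome, planner,
                                             allow_indel=False)
        spike = max(cut_t + 1, int(cut_t * cfg.dup_spike_factor))
        plant_tumor_only("artifact_highdepth", chrom, pos, ref, alt,
                         _draw_qual_true(rng, cfg), spike,
                         _draw_depth(rng, cfg))
    for _ in range(n_of(cfg.singlecov_artifact_rate)):
        chrom, pos, ref, alt = _make_variant(rng, cfg, genome, planner,
                                             allow_indel=False)
        plant_tumor_only("artifact_singlecov", chrom, pos, ref, alt,
                         _draw_qual_true(rng, cfg), true_depth(cut_t),
                         normal_depth=0)
    for _ in range(n_of(cfg.shared_artifact_rate)):
        chrom, pos, ref, alt = _make_variant(rng, cfg, genome, planner,
                                             allow_indel=False)
        d_t, d_n = true_depth(cut_t), true_depth(cut_n)
        tumor_calls.append(VariantCall(chrom, pos, ref, alt,
                                       _draw_qual_true(rng, cfg), d_t, tumor_id))
        normal_calls.append(VariantCall(chrom, pos, ref, alt,
                                        _draw_qual_true(rng, cfg), d_n, normal_id))
        cover(tumor_cov, chrom, pos, d_t)
        cover(normal_cov, chrom, pos, d_n)
        truth.append(TruthRow(chrom, pos, ref, alt, "artifact_shared", "removed"))
    for _ in range(n_of(cfg.cluster_artifact_rate)):
        chrom, anchor = planner.alloc(span=9)
        for offset in (0, 4, 8):  # triplet inside one +/-10 bp window
            pos = anchor + offset
            planner.claim(chrom, pos)
            ref = genome[chrom][pos - 1]
            alt = _snv_alt(rng, ref, cfg.transition_prob)
            plant_tumor_only("artifact_cluster", chrom, pos, ref, alt,
                             _draw_qual_true(rng, cfg), true_depth(cut_t),
                             _draw_depth(rng, cfg))

    # --- A>G editing excess on transcribed strands (both samples) ---------
    transcribed = sum(m.cds_length for m in reference.models)
    n_edit = int(round(cfg.editing_rate * transcribed))
    edit_sites = []
    for m in reference.models:
        base = "A" if m.strand == "+" else "T"
        s, e = m.span
        for pos in range(s, e + 1):
            if genome[m.chrom][pos - 1] == base:
                edit_sites.append((m.chrom, pos, m.strand))
    rng.shuffle(edit_sites)
    planted_edit = 0
    for chrom, pos, strand in edit_sites:
        if planted_edit >= n_edit:
            break
        if not planner._free(chrom, pos):
            continue
        planner.claim(chrom, pos)
        ref = genome[chrom][pos - 1]
        alt = "G" if strand == "+" else "C"
        d_t, d_n = true_depth(cut_t), true_depth(cut_n)
        tumor_calls.append(VariantCall(chrom, pos, ref, alt,
                                       _draw_qual_true(rng, cfg), d_t, tumor_id))
        normal_calls.append(VariantCall(chrom, pos, ref, alt,
                                        _draw_qual_true(rng, cfg), d_n, normal_id))
        cover(tumor_cov, chrom, pos, d_t)
        cover(normal_cov, chrom, pos, d_n)
        truth.append(TruthRow(chrom, pos, ref, alt, "editing", "removed"))
        planted_edit += 1

    pair = SamplePair(
        pair_id=cfg.pair_id,
        normal=CallSet(normal_id, normal_calls),
        tumor=CallSet(tumor_id, tumor_calls),
        normal_cov=normal_cov,
        tumor_cov=tumor_cov)
    truth.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    return SimulatedPair(pair=pair, known_db=db, truth=truth,
                         cutoffs={tumor_id: cut_t, normal_id: cut_n})


def evaluate_against_truth(tumor_specific: CallSet, normal_specific: CallSet,
                           truth: list[TruthRow]) -> dict:
    """Confusion summary of cascade output against the planted truth."""
    tkeys, nkeys = tumor_specific.keys(), normal_specific.keys()
    per_label: dict[str, dict[str, int]] = {}
    for row in truth:
        stats = per_label.setdefault(
            row.label, {"planted": 0, "retained_tumor": 0, "retained_normal": 0})
        stats["planted"] += 1
        if row.key in tkeys:
            stats["retained_tumor"] += 1
        if row.key in nkeys:
            stats["retained_normal"] += 1
    somatic = [r for r in truth if r.label == "somatic"]
    negatives = [r for r in truth if r.expected_final_status != "tumor_specific"]
    tp = sum(1 for r in somatic if r.key in tkeys)
    fp = sum(1 for r in negatives if r.key in tkeys)
    sensitivity = tp / len(somatic) if somatic else float("nan")
    specificity = 1 - fp / len(negatives) if negatives else float("nan")
    return {"per_label": per_label, "sensitivity": sensitivity,
            "specificity": specificity, "true_positives": tp,
            "false_positives": fp}


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def _write_coverage_tsv(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, pos, depth in track.items():
            fh.write(f"{chrom}\t{pos}\t{depth}\n")


def _write_known_tsv(db: KnownVariantDB, path) -> None:
    with open(path, "w") as fh:
        for chrom, pos, ref, alt in db.keys():
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")


def _write_truth_tsv(truth: Iterable[TruthRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tlabel\texpected_final_status\n")
        for r in truth:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{r.label}\t"
                     f"{r.expected_final_status}\n")


def read_truth(path) -> list[TruthRow]:
    rows = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            chrom, pos, ref, alt, label, status = line.rstrip("\n").split("\t")
            rows.append(TruthRow(chrom, int(pos), ref, alt, label, status))
    return rows


def simulate_to_dir(cfg: SimulationConfig, outdir) -> dict[str, Path]:
    """Run the simulator and write all fixture files into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = simulate_reference(cfg)
    sim = simulate_pair(cfg, reference)
    paths = {
        "fasta": outdir / "genome.fa",
        "gtf": outdir / "genes.gtf",
        "known": outdir / "known.tsv",
        "tumor_vcf": outdir / "tumor.vcf",
        "normal_vcf": outdir / "normal.vcf",
        "tumor_cov": outdir / "tumor.cov.tsv",
        "normal_cov": outdir / "normal.cov.tsv",
        "truth": outdir / "truth.tsv",
    }
    paths["fasta"].write_text(reference.fasta_text())
    paths["gtf"].write_text(reference.gtf_text())
    _write_known_tsv(sim.known_db, paths["known"])
    write_vcf(sim.pair.tumor, paths["tumor_vcf"])
    write_vcf(sim.pair.normal, paths["normal_vcf"])
    _write_coverage_tsv(sim.pair.tumor_cov, paths["tumor_cov"])
    _write_coverage_tsv(sim.pair.normal_cov, paths["normal_cov"])
    _write_truth_tsv(sim.truth, paths["truth"])
    return paths
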