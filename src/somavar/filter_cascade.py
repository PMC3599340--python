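"""Six-stage somatic-variant filter cascade for matched tumor/normal pairs.

Per-sample stages run in a fixed order: minimum call quality, trained
maximum-coverage cutoff, paired-coverage requirement, known-database
subtraction, shared-call subtraction, and a local mismatch-cluster filter.
"""
from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

from .variant_io import CallSet, CoverageTrack, KnownVariantDB, SamplePair, VariantCall

__all__ = [
    "FilterConfig",
    "FilterReport",
    "StageCount",
    "CutoffTrainingError",
    "filter_min_quality",
    "train_coverage_cutoff",
    "filter_max_coverage",
    "filter_covered_in_both",
    "filter_known_variants",
    "filter_shared_calls",
    "local_mismatch_stats",
    "filter_local_mismatch",
    "run_cascade",
]

STAGES = ("min_quality", "max_coverage", "covered_in_both",
          "known_db", "shared_calls", "local_mismatch")


class CutoffTrainingError(ValueError):
    """No database-member calls available to train the coverage cutoff."""


@dataclass
class FilterConfig:
    """Thresholds for all cascade stages.

    Defaults: quality >= 20, coverage cutoff at the 0.975 nearest-rank
    quantile of known-call depths, +/-10 bp mismatch window discarding at
    rate >= 0.1 or count >= 2, and >=1 read required in both samples.
    """

    qual_min: float = 20.0
    coverage_quantile: float = 0.975
    flank: int = 10
    mismatch_rate_max: float = 0.1
    mismatch_count_max: int = 2
    min_depth_both: int = 1
    db_positional: bool = False
    manual_cutoff: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.coverage_quantile <= 1):
            raise ValueError("coverage_quantile must be in (0, 1]")
        if self.qual_min < 0 or self.flank < 0 or self.mismatch_rate_max < 0 \
                or self.mismatch_count_max < 0 or self.min_depth_both < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class StageCount:
    stage: str
    sample_id: str
    n_in: int
    n_out: int

    def __post_init__(self) -> None:
        if self.n_out > self.n_in:
            raise ValueError("stage output cannot exceed its input")


@dataclass
class FilterReport:
    """Audit trail: per-stage counts plus the trained cutoffs per sample."""

    stages: list[StageCount] = field(default_factory=list)
    cutoffs: dict[str, int] = field(default_factory=dict)

    def record(self, stage: str, sample_id: str, n_in: int, n_out: int) -> None:
        self.stages.append(StageCount(stage, sample_id, n_in, n_out))

    def counts_for(self, sample_id: str) -> list[StageCount]:
        return [s for s in self.stages if s.sample_id == sample_id]

    def to_tsv(self) -> str:
        lines = ["stage\tsample\tin\tout\tcutoff"]
        for s in self.stages:
            cut = self.cutoffs.get(s.sample_id, "")
            cut = cut if s.stage == "max_coverage" else ""
            lines.append(f"{s.stage}\t{s.sample_id}\t{s.n_in}\t{s.n_out}\t{cut}")
        return "\n".join(lines) + "\n"


def filter_min_quality(cs: CallSet, qual_min: float) -> CallSet:
    """Retain calls with quality >= ``qual_min``."""
    return cs.subset(lambda c: c.qual >= qual_min)


def train_coverage_cutoff(cs: CallSet, db: KnownVariantDB, q: float = 0.975) -> int:
    """Nearest-rank ``q``-quantile of the depths of database-member calls.

    Sort known-call depths ascending and return the element at 1-based
    rank ceil(q * n).
    """
    if not (0 < q <= 1):
        raise ValueError("quantile must be in (0, 1]")
    depths = sorted(c.depth for c in cs if db.contains(c))
    if not depths:
        raise CutoffTrainingError(
            "no known-database calls in callset; supply a manual cutoff")
    rank = math.ceil(q * len(depths))  # 1-based nearest rank
    return depths[rank - 1]


def filter_max_coverage(cs: CallSet, cutoff: int) -> CallSet:
    """Retain calls with depth <= ``cutoff`` (boundary inclusive)."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    return cs.subset(lambda c: c.depth <= cutoff)


def filter_covered_in_both(cs: CallSet, own: CoverageTrack, other: CoverageTrack,
                           min_depth: int = 1) -> CallSet:
    """Retain calls whose position is covered >= ``min_depth`` in both tracks."""
    return cs.subset(lambda c: own.depth(c.chrom, c.pos) >= min_depth
                     and other.depth(c.chrom, c.pos) >= min_depth)


def filter_known_variants(cs: CallSet, db: KnownVariantDB) -> CallSet:
    """Retain calls absent from the known-variant database (novel calls)."""
    return cs.subset(lambda c: not db.contains(c))


def filter_shared_calls(cs: CallSet, partner: CallSet) -> CallSet:
    """Retain calls whose (chrom, pos, ref, alt) is absent from ``partner``."""
    partner_keys = partner.keys()
    return cs.subset(lambda c: c.key not in partner_keys)


def _site_positions(all_sites: CallSet) -> dict[str, list[int]]:
    by_chrom: dict[str, set[int]] = {}
    for c in all_sites:
        by_chrom.setdefault(c.chrom, set()).add(c.pos)
    return {chrom: sorted(ps) for chrom, ps in by_chrom.items()}


def local_mismatch_stats(v: VariantCall, all_sites: CallSet,
                         flank: int = 10) -> tuple[int, float]:
    """Count other called variant sites within +/-``flank`` bp of ``v``.

    Returns (count, count / (2 * flank)); the focal site is excluded.
    ``all_sites`` should be the same sample's callset before database
    subtraction so that known variants still mark unreliable regions.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    positions = sorted({c.pos for c in all_sites if c.chrom == v.chrom})
    lo = bisect_left(positions, v.pos - flank)
    hi = bisect_right(positions, v.pos + flank)
    count = hi - lo
    if v.pos in positions[lo:hi]:
        count -= 1  # exclude the focal site
    return count, count / (2 * flank)


def filter_local_mismatch(cs: CallSet, all_sites: CallSet,
                          cfg: FilterConfig) -> CallSet:
    """Discard calls in mismatch clusters (rate or count over threshold)."""
    sites = _site_positions(all_sites)

    def keep(c: VariantCall) -> bool:
        positions = sites.get(c.chrom, [])
        lo = bisect_left(positions, c.pos - cfg.flank)
        hi = bisect_right(positions, c.pos + cfg.flank)
        count = hi - lo
        if c.pos in positions[lo:hi]:
            count -= 1
        rate = count / (2 * cfg.flank)
        return not (rate >= cfg.mismatch_rate_max or count >= cfg.mismatch_count_max)

    return cs.subset(keep)


def run_cascade(pair: SamplePair, db: KnownVariantDB,
                cfg: FilterConfig | None = None
                ) -> tuple[CallSet, CallSet, FilterReport]:
    """Run all six stages on a pair; returns tissue-specific callsets.

    Stage order per sample: min_quality -> max_coverage (cutoff trained
    per sample on known calls) -> covered_in_both -> known_db ->
    shared_calls (cross-sample) -> local_mismatch (neighbors counted in
    the post-paired-coverage, pre-database callset of the same sample).
    """
    cfg = cfg or FilterConfig()
    report = FilterReport()
    post_db: dict[str, CallSet] = {}
    neighbor_sets: dict[str, CallSet] = {}

    for cs, own_cov, other_cov in (
            (pair.tumor, pair.tumor_cov, pair.normal_cov),
            (pair.normal, pair.normal_cov, pair.tumor_cov)):
        sid = cs.sample_id
        c1 = filter_min_quality(cs, cfg.qual_min)
        report.record("min_quality", sid, len(cs), len(c1))

        if cfg.manual_cutoff is not None:
            cutoff = cfg.manual_cutoff
        elif len(c1) == 0:
            cutoff = 0  # nothing to filter
        else:
            cutoff = train_coverage_cutoff(c1, db, cfg.coverage_quantile)
        report.cutoffs[sid] = cutoff
        c2 = filter_max_coverage(c1, cutoff) if len(c1) else c1
        report.record("max_coverage", sid, len(c1), len(c2))

        c3 = filter_covered_in_both(c2, own_cov, other_cov, cfg.min_depth_both)
        report.record("covered_in_both", sid, len(c2), len(c3))
        neighbor_sets[sid] = c3

        c4 = filter_known_variants(c3, db)
        report.record("known_db", sid, len(c3), len(c4))
        post_db[sid] = c4

    t4, n4 = post_db[pair.tumor.sample_id], post_db[pair.normal.sample_id]
    t5 = filter_shared_calls(t4, n4)
    n5 = filter_shared_calls(n4, t4)
    report.record("shared_calls", pair.tumor.sample_id, len(t4), len(t5))
    report.record("shared_calls", pair.normal.sample_id, len(n4), len(n5))

    t6 = filter_local_mismatch(t5, neighbor_sets[pair.tumor.sample_id], cfg)
    n6 = filter_local_mismatch(n5, neighbor_sets[pair.normal.sample_id], cfg)
    report.record("local_mismatch", pair.tumor.sample_id, len(t5), len(t6))
    report.record("local_mismatch", pair.normal.sample_id, len(n5), len(n6))
    return t6, n6, report
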