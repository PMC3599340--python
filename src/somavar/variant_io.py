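"""Variant callsets, coverage tracks and known-variant membership indexes.

All variant handling is 1-based (VCF convention). Interval formats
(BEDGraph) are converted to 1-based points at the read boundary.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator

_BASES = frozenset("ACGT")

__all__ = [
    "VariantCall",
    "CallSet",
    "CoverageTrack",
    "KnownVariantDB",
    "SamplePair",
    "VcfParseError",
    "CoverageParseError",
    "KnownDbParseError",
    "normalize_variant",
    "read_vcf",
    "write_vcf",
    "read_coverage",
    "read_known_db",
]


class VcfParseError(ValueError):
    """Raised for malformed VCF input; message names the offending line."""


class CoverageParseError(ValueError):
    """Raised for malformed coverage-track input."""


class KnownDbParseError(ValueError):
    """Raised for malformed known-variant tables."""


def _open_text(path):
    """Open a possibly gzip-compressed text file for reading."""
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def normalize_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared bases from an allele pair, keeping a 1-bp anchor.

    Shared suffix is removed first, then shared prefix (advancing ``pos``),
    so equivalent indel representations index identically.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True, order=True)
class VariantCall:
    """One called variant at a site, with its quality and read depth."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float = 0.0
    depth: int = 0
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if set(self.ref) - _BASES or set(self.alt) - _BASES:
            raise ValueError(f"alleles must be ACGT: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.qual < 0:
            raise ValueError("qual must be non-negative")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")

    @property
    def vclass(self) -> str:
        """SNV, INS or DEL, by allele-length rule."""
        if len(self.ref) == len(self.alt) == 1:
            return "SNV"
        return "INS" if len(self.alt) > len(self.ref) else "DEL"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def end(self) -> int:
        """Last 1-based reference position spanned by the REF allele."""
        return self.pos + len(self.ref) - 1


class CallSet:
    """An ordered, duplicate-free collection of calls for one sample."""

    def __init__(self, sample_id: str, calls: Iterable[VariantCall] = ()) -> None:
        self.sample_id = sample_id
        calls = sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
        seen: set[tuple] = set()
        for c in calls:
            if c.key in seen:
                raise ValueError(f"duplicate call {c.key} in callset {sample_id!r}")
            seen.add(c.key)
        self.calls: tuple[VariantCall, ...] = tuple(calls)
        self._keys = seen

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self.calls)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CallSet):
            return NotImplemented
        return self.sample_id == other.sample_id and self.calls == other.calls

    def __repr__(self) -> str:
        return f"CallSet({self.sample_id!r}, n={len(self)})"

    def keys(self) -> set[tuple[str, int, str, str]]:
        return set(self._keys)

    def contains_key(self, key: tuple[str, int, str, str]) -> bool:
        return key in self._keys

    def subset(self, predicate: Callable[[VariantCall], bool]) -> "CallSet":
        """New CallSet with the calls satisfying ``predicate``."""
        return CallSet(self.sample_id, (c for c in self.calls if predicate(c)))


class CoverageTrack:
    """Sparse per-position read depth; unstored positions have depth 0."""

    def __init__(self) -> None:
        self._depth: dict[str, dict[int, int]] = {}

    def set_depth(self, chrom: str, pos: int, depth: int) -> None:
        if depth < 0:
            raise ValueError("depth must be non-negative")
        if pos < 1:
            raise ValueError("position must be 1-based positive")
        self._depth.setdefault(chrom, {})[pos] = depth

    def add_interval(self, chrom: str, start0: int, end0: int, depth: int) -> None:
        """Store a half-open 0-based BEDGraph interval as 1-based points."""
        for pos in range(start0 + 1, end0 + 1):
            self.set_depth(chrom, pos, depth)

    def depth(self, chrom: str, pos: int) -> int:
        return self._depth.get(chrom, {}).get(pos, 0)

    def items(self) -> Iterator[tuple[str, int, int]]:
        for chrom in sorted(self._depth):
            for pos in sorted(self._depth[chrom]):
                yield chrom, pos, self._depth[chrom][pos]

    def __len__(self) -> int:
        return sum(len(d) for d in self._depth.values())


class KnownVariantDB:
    """Exact-match membership index over (chrom, pos, ref, alt).

    With ``positional=True`` matching ignores alleles and uses
    (chrom, pos) only; the allele-aware default is the conservative
    reading of database membership.
    """

    def __init__(self, keys: Iterable[tuple[str, int, str, str]] = (),
                 positional: bool = False) -> None:
        self.positional = positional
        self._keys: set[tuple[str, int, str, str]] = set()
        self._positions: set[tuple[str, int]] = set()
        for k in keys:
            self.add(*k)

    def add(self, chrom: str, pos: int, ref: str, alt: str) -> None:
        pos, ref, alt = normalize_variant(pos, ref, alt)
        self._keys.add((chrom, pos, ref, alt))
        self._positions.add((chrom, pos))

    def __len__(self) -> int:
        return len(self._keys)

    def keys(self) -> list[tuple[str, int, str, str]]:
        return sorted(self._keys)

    def contains(self, call: VariantCall) -> bool:
        pos, ref, alt = normalize_variant(call.pos, call.ref, call.alt)
        if self.positional:
            return (call.chrom, pos) in self._positions
        return (call.chrom, pos, ref, alt) in self._keys

    def __contains__(self, item) -> bool:
        if isinstance(item, VariantCall):
            return self.contains(item)
        chrom, pos, ref, alt = item
        pos, ref, alt = normalize_variant(pos, ref, alt)
        if self.positional:
            return (chrom, pos) in self._positions
        return (chrom, pos, ref, alt) in self._keys


@dataclass
class SamplePair:
    """A matched normal/tumor pair: callsets plus coverage tracks."""

    pair_id: str
    normal: CallSet
    tumor: CallSet
    normal_cov: CoverageTrack
    tumor_cov: CoverageTrack

    def __post_init__(self) -> None:
        if self.normal.sample_id == self.tumor.sample_id:
            raise ValueError("normal and tumor sample_ids must differ")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, sample_id: str | None = None) -> CallSet:
    """Read a single-sample (or sites-only) VCF into a CallSet.

    One VariantCall is produced per ALT allele; multi-allelic records are
    split. Depth is taken from INFO/DP (falling back to FORMAT/DP), missing
    QUAL becomes 0, and indel alleles are trimmed/anchored before indexing.
    """
    calls: list[VariantCall] = []
    vcf_sample = None
    saw_header = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 8:
                    raise VcfParseError(f"{path}: line {lineno}: truncated #CHROM header")
                if len(cols) > 10:
                    raise VcfParseError(
                        f"{path}: line {lineno}: multi-sample VCF not supported "
                        f"({len(cols) - 9} sample columns)")
                if len(cols) == 10:
                    vcf_sample = cols[9]
                saw_header = True
                continue
            if not saw_header:
                raise VcfParseError(f"{path}: line {lineno}: data before #CHROM header")
            calls.extend(_parse_vcf_record(line, lineno, path))
    sid = sample_id or vcf_sample or Path(str(path)).name.split(".")[0]
    for i, c in enumerate(calls):
        calls[i] = VariantCall(c.chrom, c.pos, c.ref, c.alt, c.qual, c.depth, sid)
    return CallSet(sid, calls)


def _parse_vcf_record(line: str, lineno: int, path) -> list[VariantCall]:
    fields = line.split("\t")
    if len(fields) < 8:
        raise VcfParseError(f"{path}: line {lineno}: expected >=8 columns, got {len(fields)}")
    chrom, pos_s, _id, ref, alt_s, qual_s, _filt, info = fields[:8]
    try:
        pos = int(pos_s)
    except ValueError:
        raise VcfParseError(f"{path}: line {lineno}: non-integer POS {pos_s!r}") from None
    qual = 0.0
    if qual_s not in (".", ""):
        try:
            qual = float(qual_s)
        except ValueError:
            raise VcfParseError(f"{path}: line {lineno}: bad QUAL {qual_s!r}") from None
    depth = 0
    for kv in info.split(";"):
        if kv.startswith("DP="):
            try:
                depth = int(kv[3:])
            except ValueError:
                raise VcfParseError(f"{path}: line {lineno}: bad INFO DP") from None
            break
    else:
        if len(fields) >= 10 and "DP" in fields[8].split(":"):
            idx = fields[8].split(":").index("DP")
            sample_vals = fields[9].split(":")
            if idx < len(sample_vals) and sample_vals[idx] not in (".", ""):
                depth = int(sample_vals[idx])
    out = []
    for alt in alt_s.split(","):
        if alt == ".":
            continue
        npos, nref, nalt = normalize_variant(pos, ref.upper(), alt.upper())
        try:
            out.append(VariantCall(chrom, npos, nref, nalt, qual, depth))
        except ValueError as exc:
            raise VcfParseError(f"{path}: line {lineno}: {exc}") from None
    return out


def write_vcf(cs: CallSet, path) -> None:
    """Write a CallSet as a minimal single-sample VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{cs.sample_id}\n")
        for c in cs:
            qual = str(int(c.qual)) if c.qual == int(c.qual) else repr(c.qual)
            fh.write(f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t{qual}\t.\t"
                     f"DP={c.depth}\tGT\t./.\n")


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------

def read_coverage(path) -> CoverageTrack:
    """Read a 3-column TSV (chrom, 1-based pos, depth) or 4-column BEDGraph."""
    track = CoverageTrack()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            try:
                if len(fields) == 3:
                    chrom, pos, depth = fields[0], int(fields[1]), int(fields[2])
                    if depth < 0:
                        raise ValueError("negative depth")
                    track.set_depth(chrom, pos, depth)
                elif len(fields) == 4:
                    chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
                    depth = int(fields[3])
                    if depth < 0:
                        raise ValueError("negative depth")
                    track.add_interval(chrom, start0, end0, depth)
                else:
                    raise ValueError(f"expected 3 or 4 columns, got {len(fields)}")
            except ValueError as exc:
                raise CoverageParseError(f"{path}: line {lineno}: {exc}") from None
    return track


# ---------------------------------------------------------------------------
# Known-variant database
# ---------------------------------------------------------------------------

def read_known_db(path, positional: bool = False) -> KnownVariantDB:
    """Read a known-variant index from a VCF or 4-column TSV."""
    with _open_text(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat") or str(path).endswith((".vcf", ".vcf.gz")):
        cs = read_vcf(path, sample_id="knowndb")
        return KnownVariantDB((c.key for c in cs), positional=positional)
    db = KnownVariantDB(positional=positional)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise KnownDbParseError(
                    f"{path}: line {lineno}: expected 4 columns, got {len(fields)}")
            try:
                db.add(fields[0], int(fields[1]), fields[2].upper(), fields[3].upper())
            except ValueError as exc:
                raise KnownDbParseError(f"{path}: line {lineno}: {exc}") from None
    return db
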