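"""Mutation-spectrum summaries and the comparison statistics used on them.

Substitutions collapse to six pyrimidine-reference classes (C>A, C>G,
C>T, T>A, T>C, T>G); insertions and deletions are tallied separately.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy.stats import hypergeom, norm

from .variant_io import CallSet

__all__ = [
    "SUBSTITUTION_CLASSES",
    "SpectrumTable",
    "ContingencyTable2x2",
    "classify_substitution",
    "is_transition",
    "build_spectrum",
    "titv_ratio",
    "fisher_exact_two_sided",
    "rank_sum_test",
    "count_ratio",
    "percent",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def _check_snv_alleles(ref: str, alt: str) -> None:
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"alleles must be single ACGT bases: {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")


def classify_substitution(ref: str, alt: str, collapse: bool = True) -> str:
    """Substitution class label; purine references are complemented so the
    reported reference base is C or T. ``collapse=False`` keeps all 12
    ref>alt labels."""
    _check_snv_alleles(ref, alt)
    if collapse and ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def is_transition(ref: str, alt: str) -> bool:
    _check_snv_alleles(ref, alt)
    return {ref, alt} in ({"A", "G"}, {"C", "T"})


@dataclass
class SpectrumTable:
    """Counts per collapsed substitution class plus insertions/deletions."""

    sample_id: str
    counts: dict[str, int] = field(
        default_factory=lambda: {k: 0 for k in SUBSTITUTION_CLASSES + ("INS", "DEL")})

    @property
    def n_snv(self) -> int:
        return sum(self.counts[k] for k in SUBSTITUTION_CLASSES)

    @property
    def n_indel(self) -> int:
        return self.counts["INS"] + self.counts["DEL"]

    @property
    def n_transitions(self) -> int:
        return self.counts["C>T"] + self.counts["T>C"]

    @property
    def n_transversions(self) -> int:
        return self.n_snv - self.n_transitions

    def to_tsv(self) -> str:
        lines = ["class\tcount"]
        for k in SUBSTITUTION_CLASSES + ("INS", "DEL"):
            lines.append(f"{k}\t{self.counts[k]}")
        return "\n".join(lines) + "\n"


def build_spectrum(cs: CallSet) -> SpectrumTable:
    """Tally every call into exactly one spectrum class."""
    table = SpectrumTable(cs.sample_id)
    for c in cs:
        if c.vclass == "SNV":
            table.counts[classify_substitution(c.ref, c.alt)] += 1
        else:
            table.counts[c.vclass] += 1
    return table


def titv_ratio(cs: CallSet) -> float:
    """Transition/transversion count ratio over SNVs (indels excluded)."""
    ti = tv = 0
    for c in cs:
        if c.vclass != "SNV":
            continue
        if is_transition(c.ref, c.alt):
            ti += 1
        else:
            tv += 1
    if tv == 0:
        raise ValueError("Ti/Tv undefined: no transversions in callset")
    return ti / tv


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 count table; rows are groups, columns are outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table must have at least one positive margin")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact_two_sided(table, rel_tol: float = 1e-7) -> float:
    """Exact conditional two-sided Fisher p-value (point-probability rule).

    Conditional on the margins, sums the hypergeometric probabilities of
    every table whose point probability is <= that of the observed table
    (within ``rel_tol`` relative slack).
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(a, b, c, d)
    a, b, c, d = table.a, table.b, table.c, table.d
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    kmin = max(0, col1 - (c + d))
    kmax = min(row1, col1)
    ks = np.arange(kmin, kmax + 1)
    pmf = hypergeom.pmf(ks, n_total, row1, col1)
    p_obs = pmf[a - kmin]
    p = float(pmf[pmf <= p_obs * (1 + rel_tol)].sum())
    return min(p, 1.0)


def _midranks(values: list[float]) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact by enumeration of all rank assignments when both samples have
    <= 8 observations; otherwise a normal approximation with tie
    correction.
    """
    x, y = list(x), list(y)
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = x + y
    ranks = _midranks(pooled)
    w_obs = sum(ranks[:n1])
    if n1 <= 8 and n2 <= 8:
        eps = 1e-9
        total = n_le = n_ge = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            w = sum(ranks[i] for i in combo)
            total += 1
            if w <= w_obs + eps:
                n_le += 1
            if w >= w_obs - eps:
                n_ge += 1
        return min(1.0, 2 * min(n_le, n_ge) / total)
    mean = n1 * (n1 + n2 + 1) / 2
    n = n1 + n2
    tie_counts: dict[float, int] = {}
    for v in pooled:
        tie_counts[v] = tie_counts.get(v, 0) + 1
    tie_term = sum(t ** 3 - t for t in tie_counts.values())
    var = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return 1.0
    z = (w_obs - mean) / var ** 0.5
    return float(min(1.0, 2 * norm.sf(abs(z))))


def _round_half_up(value: Decimal, decimals: int) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def count_ratio(n_tumor: int, n_normal: int, decimals: int = 2) -> float:
    """n_tumor / n_normal, rounded half-up to ``decimals`` places."""
    if n_normal == 0:
        raise ValueError("denominator must be positive")
    return _round_half_up(Decimal(n_tumor) / Decimal(n_normal), decimals)


def percent(part: int, total: int, decimals: int = 1) -> float:
    """100 * part / total, rounded half-up to ``decimals`` places."""
    if total == 0:
        raise ValueError("total must be positive")
    return _round_half_up(Decimal(100) * Decimal(part) / Decimal(total), decimals)
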