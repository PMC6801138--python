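"""Focused sgRNA library representation and coverage design math.

A pooled CRISPR-activation library is built by cloning a set of *n* guide
constructs in bulk and picking colonies.  The classical library-coverage
question — how many random isolates *N* guarantee that a given construct is
represented at least once with probability *P* — is answered by

    P = 1 - (1 - 1/n)**N

(the per-construct Clarke–Carbon bound).  This module holds the guide
catalogue (gene, guide id, 20-nt spacer, offset to the transcription start
site) and the coverage arithmetic built on that formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "GuideEntry",
    "GuideLibrary",
    "CopyCount",
    "load_guide_table",
    "coverage_probability",
    "all_covered_probability",
    "required_clones",
    "expected_copies_per_guide",
    "flag_optimal_window",
]

SPACER_LENGTH = 20
SPACER_ALPHABET = frozenset("ACGT")

# Activation in yeast works best with the guide landing between the TSS and
# 200 bp upstream of it; offsets are negative upstream, 0 at the TSS.
OPTIMAL_WINDOW = (-200, 0)


class GuideLibraryError(ValueError):
    """Raised for malformed guide tables or invalid library parameters."""


@dataclass(frozen=True)
class GuideEntry:
    """One guide: its target gene, 20-nt spacer and position relative to the TSS."""

    gene_id: str
    guide_id: str
    spacer: str
    tss_offset: int

    def validate(self, row: object = None) -> None:
        where = "" if row is None else f" (row {row})"
        if len(self.spacer) != SPACER_LENGTH:
            raise GuideLibraryError(
                f"guide {self.guide_id!r}{where}: spacer has length "
                f"{len(self.spacer)}, expected {SPACER_LENGTH}"
            )
        bad = set(self.spacer) - SPACER_ALPHABET
        if bad:
            raise GuideLibraryError(
                f"guide {self.guide_id!r}{where}: spacer contains invalid "
                f"characters {sorted(bad)}"
            )


@dataclass
class GuideLibrary:
    """An immutable catalogue of guides with per-gene grouping."""

    entries: list[GuideEntry]
    genes: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        if not self.entries:
            raise GuideLibraryError("guide library is empty")
        seen: set[str] = set()
        for i, e in enumerate(self.entries):
            e.validate(row=i)
            if e.guide_id in seen:
                raise GuideLibraryError(f"duplicate guide_id {e.guide_id!r}")
            seen.add(e.guide_id)
        self.genes = frozenset(e.gene_id for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_guides(self) -> int:
        return len(self.entries)

    def guides_per_gene(self) -> pd.Series:
        """Guide counts per gene, indexed by gene id."""
        return (
            pd.Series([e.gene_id for e in self.entries])
            .value_counts()
            .sort_index()
            .rename("n_guides")
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [e.gene_id for e in self.entries],
                "guide": [e.guide_id for e in self.entries],
                "spacer": [e.spacer for e in self.entries],
                "tss_offset": [e.tss_offset for e in self.entries],
            }
        )


def load_guide_table(path) -> GuideLibrary:
    """Read a delimited guide table (columns gene, guide, spacer, tss_offset).

    Both comma- and tab-separated files are accepted; a header row is
    required.  Validation failures name the offending row.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"gene", "guide", "spacer", "tss_offset"}
    missing = required - set(df.columns)
    if missing:
        raise GuideLibraryError(f"guide table missing columns {sorted(missing)}")
    if df.empty:
        raise GuideLibraryError("guide table has no data rows")
    entries = [
        GuideEntry(
            gene_id=str(r.gene),
            guide_id=str(r.guide),
            spacer=str(r.spacer).upper(),
            tss_offset=int(r.tss_offset),
        )
        for r in df.itertuples(index=False)
    ]
    # validate with row numbers before the library's own (row-less) pass
    for i, e in enumerate(entries):
        e.validate(row=i)
    return GuideLibrary(entries)


def coverage_probability(n_guides: int, n_clones: int) -> float:
    """P(a given guide appears >= once among ``n_clones`` uniform isolates).

    Evaluates ``1 - (1 - 1/n)**N`` in log space so large clone counts do not
    underflow.
    """
    if n_guides < 1:
        raise ValueError("n_guides must be >= 1")
    if n_clones < 0:
        raise ValueError("n_clones must be >= 0")
    if n_guides == 1:
        return 0.0 if n_clones == 0 else 1.0
    return -math.expm1(n_clones * math.log1p(-1.0 / n_guides))


def all_covered_probability(n_guides: int, n_clones: int) -> float:
    """P(every one of ``n_guides`` appears >= once) by inclusion–exclusion.

    The stricter library-wide reading of coverage; exact but only practical
    for moderate ``n_guides``.  The headline design number uses the
    per-guide :func:`coverage_probability`.
    """
    if n_guides < 1:
        raise ValueError("n_guides must be >= 1")
    if n_clones < 0:
        raise ValueError("n_clones must be >= 0")
    total = 0.0
    for j in range(n_guides + 1):
        term = math.comb(n_guides, j) * (1.0 - j / n_guides) ** n_clones
        total += term if j % 2 == 0 else -term
    return min(max(total, 0.0), 1.0)


def required_clones(n_guides: int, target_prob: float) -> int:
    """Smallest N with ``coverage_probability(n_guides, N) >= target_prob``.

    Closed form ``ceil(ln(1-P)/ln(1-1/n))``, nudged to honour the two-sided
    minimality property under floating-point rounding.
    """
    if n_guides < 1:
        raise ValueError("n_guides must be >= 1")
    if not 0.0 < target_prob < 1.0:
        raise ValueError("target_prob must lie strictly between 0 and 1")
    if n_guides == 1:
        return 1
    n = math.ceil(math.log1p(-target_prob) / math.log1p(-1.0 / n_guides))
    n = max(n, 0)
    while coverage_probability(n_guides, n) < target_prob:
        n += 1
    while n > 0 and coverage_probability(n_guides, n - 1) >= target_prob:
        n -= 1
    return n


class CopyCount(NamedTuple):
    """Idealized copies per guide; ``integral`` flags exact divisibility."""

    copies: Fraction
    integral: bool

    def __float__(self) -> float:
        return float(self.copies)


def expected_copies_per_guide(n_clones: int, n_guides: int) -> CopyCount:
    """Exact rational ``n_clones / n_guides`` — the equal-copy count c.

    Non-integer results are flagged rather than rounded: the equal-copy null
    model downstream assumes an integer c.
    """
    if n_guides < 1:
        raise ValueError("n_guides must be >= 1")
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    c = Fraction(n_clones, n_guides)
    return CopyCount(c, c.denominator == 1)


def flag_optimal_window(entry: GuideEntry) -> bool:
    """True iff the guide's TSS offset lies in the closed window [-200, 0]."""
    lo, hi = OPTIMAL_WINDOW
    return lo <= entry.tss_offset <= hi
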