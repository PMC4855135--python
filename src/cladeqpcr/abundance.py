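"""Clade abundance as a fraction of the total bacterial community.

Marker-gene copy numbers from qPCR are converted to cell-based fractions by
correcting the 16S rRNA gene count for multi-copy rrn operons. With
gene-copy-based relative abundances f_i and per-cell rrn copy numbers n_i,
the community-average rrn copy number per cell is

    n̄ = 1 / Σ_i (f_i / n_i)

(total 16S gene copies divided by total cells — the harmonic form of the
Copyrighter-style correction). A clade's share of the community is then

    percent = 100 x ppk1_copies / (16S_copies / n̄)

assuming one marker (ppk1) gene per cell; both copy numbers must come from
the same template mass. Samples without a community profile fall back to a
configurable average (default 2.04 copies per cell).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "DEFAULT_RRN_PER_CELL",
    "CommunityProfile",
    "CladeAbundanceProfile",
    "average_rrn_per_cell",
    "clade_abundance",
    "unclassified_fraction",
    "build_profile",
]

#: Fallback community-average rrn copies per cell for samples lacking a profile.
DEFAULT_RRN_PER_CELL = 2.04

#: Marker-gene copies per cell (ppk1 is single-copy in the target lineage).
MARKER_COPIES_PER_CELL = 1.0


@dataclass
class CommunityProfile:
    """Per-taxon gene-copy relative abundances and rrn copy numbers.

    ``taxa`` holds (taxon_id, relative_gene_abundance, rrn_copies_per_cell);
    abundances are renormalized to sum to one on construction. Taxa with an
    unknown rrn copy number may carry ``None`` and are imputed from the
    profile-wide average of the known taxa.
    """

    taxa: list[tuple[str, float, float | None]]

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValueError("community profile must be non-empty")
        total = 0.0
        for tid, f, n in self.taxa:
            if f < 0:
                raise ValueError(f"taxon {tid!r}: negative abundance")
            if n is not None and n < 1:
                raise ValueError(f"taxon {tid!r}: rrn copies per cell must be >= 1")
            total += f
        if total <= 0:
            raise ValueError("total abundance must be positive")
        self.taxa = [(tid, f / total, n) for tid, f, n in self.taxa]


def average_rrn_per_cell(profile: CommunityProfile | None) -> float:
    """Community-average rrn operon copies per cell, n̄ = 1/Σ(f_i/n_i).

    ``None`` (no profile for the sample) returns the dataset fallback
    ``DEFAULT_RRN_PER_CELL``. Taxa with unknown copy number are imputed with
    the average of the taxa that have one, or the fallback if none do.
    """
    if profile is None:
        return DEFAULT_RRN_PER_CELL
    known = [(f, n) for _, f, n in profile.taxa if n is not None]
    if known and sum(f for f, _ in known) > 0:
        # impute with the weighted harmonic average over known taxa
        impute = sum(f for f, _ in known) / sum(f / n for f, n in known)
    else:
        impute = DEFAULT_RRN_PER_CELL
    denom = sum(f / (n if n is not None else impute) for _, f, n in profile.taxa)
    return 1.0 / denom


def clade_abundance(ppk1_copies: float, s16_copies: float, n_bar: float) -> float:
    """Percent of the total bacterial community occupied by one clade.

    percent = 100 x (ppk1 copies / marker copies per cell)
                  / (16S copies / n̄ rrn copies per cell),
    i.e. clade cells over total bacterial cells in the same template mass.
    """
    if s16_copies <= 0:
        raise ValueError("16S copy number must be positive")
    if n_bar < 1:
        raise ValueError("average rrn copies per cell must be >= 1")
    if ppk1_copies < 0:
        raise ValueError("marker-gene copy number must be non-negative")
    clade_cells = ppk1_copies / MARKER_COPIES_PER_CELL
    total_cells = s16_copies / n_bar
    return 100.0 * clade_cells / total_cells


def unclassified_fraction(
    total_acc_pct: float, clade_pcts: Iterable[float]
) -> tuple[float, bool]:
    """Unclassified remainder = max(0, total - Σ clades).

    Returns (percent, clipped) where ``clipped`` flags a raw negative value
    (clade sum exceeding the lineage-wide total) that was clipped to zero.
    """
    if total_acc_pct < 0:
        raise ValueError("total abundance percentage must be non-negative")
    raw = total_acc_pct - sum(clade_pcts)
    return (max(0.0, raw), raw < 0)


@dataclass
class CladeAbundanceProfile:
    sample_id: str
    clade_pct: dict[str, float]
    total_acc_pct: float | None = None
    unclassified_pct: float | None = None
    clipped: bool = False

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "clade_pct": dict(self.clade_pct),
            "total_acc_pct": self.total_acc_pct,
            "unclassified_pct": self.unclassified_pct,
            "clipped": self.clipped,
        }


def build_profile(
    sample_id: str,
    ppk1_copies_by_clade: Mapping[str, float],
    s16_copies: float,
    profile: CommunityProfile | None = None,
    total_acc_ppk1_copies: float | None = None,
) -> CladeAbundanceProfile:
    """Assemble a per-sample clade abundance profile.

    Per-clade percentages are computed independently from each clade's
    marker-gene copy number. When a lineage-wide marker copy number is
    supplied, the unclassified remainder is reported as well.
    """
    n_bar = average_rrn_per_cell(profile)
    clade_pct = {
        clade: clade_abundance(copies, s16_copies, n_bar)
        for clade, copies in ppk1_copies_by_clade.items()
    }
    total_pct = None
    uncls = None
    clipped = False
    if total_acc_ppk1_copies is not None:
        total_pct = clade_abundance(total_acc_ppk1_copies, s16_copies, n_bar)
        uncls, clipped = unclassified_fraction(total_pct, clade_pct.values())
    return CladeAbundanceProfile(sample_id, clade_pct, total_pct, uncls, clipped)
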