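"""In-silico PCR: primer–template matching under mismatch-allowance patterns.

The matching model is the mismatch-allowance mechanism (MAM): a pattern
``(k, w)`` admits a primer binding site with at most ``k`` primer–template
mismatches, none of which may fall within the ``w`` 3'-terminal primer
positions. The 3'-protected window captures the positional discrimination
that matters for polymerase extension: a mismatch at or near the primer 3'
terminus blocks amplification far more effectively than one near the 5' end.

Named presets follow the convention used for clade-specific primer screening:

========  ===  ===
label      k    w
========  ===  ===
``0MAM``   0    0   (perfect match required)
``1MAM``   1    1   (one mismatch, 3' terminus protected)
``1MAM*``  1    0   (one mismatch anywhere, including the 3' terminus)
``3MAM``   3    0
========  ===  ===

These are an interpretation of a two-parameter family; arbitrary ``(k, w)``
patterns can be constructed directly or parsed from ``"k<INT>w<INT>"``.

Coordinates are 1-based, inclusive, on the reference (plus) strand
throughout. Mismatch positions are reported as distance from the primer
3' end (1 = the 3'-terminal base).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .iupac import base_compatible, encode, normalize, reverse_complement
from .refdb import ReferenceDatabase, SequenceRecord, partition

__all__ = [
    "MAM_PRESETS",
    "MAMPattern",
    "Primer",
    "PrimerPair",
    "MatchResult",
    "AmpliconPrediction",
    "SpecificityReport",
    "base_compatible",
    "match_primer",
    "predict_amplicons",
    "coverage",
    "specificity_report",
]

_NAME_RE = re.compile(r"^(?P<gene>.+)-(?P<pos>\d+)(?P<dir>[fr])$")


@dataclass(frozen=True)
class MAMPattern:
    """A mismatch-allowance setting: at most ``max_mismatches`` total, with a
    3'-terminal window of ``protected_3prime_window`` positions where no
    mismatch is permitted."""

    label: str
    max_mismatches: int
    protected_3prime_window: int

    def __post_init__(self) -> None:
        if self.max_mismatches < 0 or self.protected_3prime_window < 0:
            raise ValueError("MAM parameters must be non-negative")

    @classmethod
    def from_label(cls, label: str) -> "MAMPattern":
        """Resolve a named preset or an inline ``k<INT>w<INT>`` definition."""
        if label in MAM_PRESETS:
            return MAM_PRESETS[label]
        m = re.fullmatch(r"k(\d+)w(\d+)", label)
        if m:
            return cls(label, int(m.group(1)), int(m.group(2)))
        raise ValueError(
            f"unknown MAM pattern {label!r}; use a preset "
            f"({', '.join(MAM_PRESETS)}) or inline 'k<INT>w<INT>'"
        )


MAM_PRESETS: dict[str, MAMPattern] = {
    "0MAM": MAMPattern("0MAM", 0, 0),
    "1MAM": MAMPattern("1MAM", 1, 1),
    "1MAM*": MAMPattern("1MAM*", 1, 0),
    "3MAM": MAMPattern("3MAM", 3, 0),
}


@dataclass(frozen=True)
class Primer:
    """An oligonucleotide primer, sequence written 5'→3'.

    ``ref_coord`` is advisory metadata parsed from names following the
    ``<gene>-<pos><f|r>`` convention: for a forward primer, the 5'-most
    template position of the intended binding site; for a reverse primer,
    the rightmost reference-strand coordinate of the amplicon. Matching
    never trusts it.
    """

    name: str
    seq: str
    orientation: str
    ref_coord: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize(self.seq))
        if not 10 <= len(self.seq) <= 40:
            raise ValueError(
                f"primer {self.name!r}: length {len(self.seq)} outside 10..40 nt"
            )
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward|reverse, got {self.orientation!r}")
        m = _NAME_RE.match(self.name)
        if m:
            named = "forward" if m.group("dir") == "f" else "reverse"
            if named != self.orientation:
                raise ValueError(
                    f"primer {self.name!r}: name suffix implies {named}, "
                    f"orientation says {self.orientation}"
                )
            if self.ref_coord is None:
                object.__setattr__(self, "ref_coord", int(m.group("pos")))

    @classmethod
    def from_name(cls, name: str, seq: str) -> "Primer":
        """Build a primer from a ``<gene>-<pos><f|r>`` name alone."""
        m = _NAME_RE.match(name)
        if not m:
            raise ValueError(f"primer name {name!r} does not follow '<gene>-<pos><f|r>'")
        orientation = "forward" if m.group("dir") == "f" else "reverse"
        return cls(name, seq, orientation, int(m.group("pos")))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: Primer
    reverse: Primer

    def __post_init__(self) -> None:
        if self.forward.orientation != "forward" or self.reverse.orientation != "reverse":
            raise ValueError("pair requires one forward and one reverse primer")


@dataclass
class MatchResult:
    """One admissible primer binding site on a template."""

    primer_name: str
    seq_id: str
    template_start: int  # 1-based leftmost reference-strand coordinate
    template_end: int  # 1-based rightmost reference-strand coordinate
    mismatch_positions_from_3prime: tuple[int, ...]
    satisfied: dict[str, bool] = field(default_factory=dict)

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions_from_3prime)


@dataclass
class AmpliconPrediction:
    seq_id: str
    start: int
    end: int
    forward_match: MatchResult
    reverse_match: MatchResult

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def _scan(primer: Primer, template: str, max_mismatches: int) -> list[tuple[int, tuple[int, ...]]]:
    """All windows of ``template`` the primer binds with ≤ max_mismatches.

    Returns (0-based window start, mismatch distances from primer 3' end).
    Forward primers are compared as written; reverse primers are compared as
    their reverse complement laid on the reference strand, so the primer 3'
    end sits at the *left* edge of the window.
    """
    probe = primer.seq if primer.orientation == "forward" else reverse_complement(primer.seq)
    L = len(probe)
    if L > len(template):
        return []
    tcodes = encode(template)
    pcodes = encode(probe)
    windows = sliding_window_view(tcodes, L)
    mism = (windows & pcodes) == 0  # (n_windows, L) boolean
    counts = mism.sum(axis=1)
    hits = np.nonzero(counts <= max_mismatches)[0]
    # distance from 3' end for probe index i
    if primer.orientation == "forward":
        dist = L - np.arange(L)
    else:
        dist = np.arange(L) + 1
    out = []
    for start in hits:
        pos = tuple(sorted(int(d) for d in dist[mism[start]]))
        out.append((int(start), pos))
    return out


def match_primer(
    primer: Primer,
    record: SequenceRecord | str,
    pattern: MAMPattern,
    extra_patterns: Sequence[MAMPattern] = (),
) -> list[MatchResult]:
    """Find every admissible binding site of ``primer`` on ``record`` under
    ``pattern``.

    Each returned match also carries a ``satisfied`` map for ``pattern`` and
    any ``extra_patterns`` evaluated on the same site.
    """
    if pattern.protected_3prime_window > len(primer):
        raise ValueError(
            f"protected 3' window {pattern.protected_3prime_window} exceeds "
            f"primer length {len(primer)}"
        )
    seq_id, template = (
        (record.id, record.seq) if isinstance(record, SequenceRecord) else ("query", normalize(record))
    )
    L = len(primer)
    results = []
    for start, mm in _scan(primer, template, pattern.max_mismatches):
        if any(d <= pattern.protected_3prime_window for d in mm):
            continue
        satisfied = {pattern.label: True}
        for pat in extra_patterns:
            satisfied[pat.label] = len(mm) <= pat.max_mismatches and not any(
                d <= pat.protected_3prime_window for d in mm
            )
        results.append(
            MatchResult(primer.name, seq_id, start + 1, start + L, mm, satisfied)
        )
    return results


def predict_amplicons(
    pair: PrimerPair,
    record: SequenceRecord | str,
    pattern: MAMPattern,
    max_len: int = 450,
) -> list[AmpliconPrediction]:
    """Enumerate convergent forward/reverse binding-site combinations.

    An amplicon runs from the forward primer's 5'-most (leftmost) template
    coordinate to the reverse primer's rightmost template coordinate,
    inclusive; only products no longer than ``max_len`` and long enough to
    contain the longer primer are reported. Zero predictions is a valid
    outcome.
    """
    fwd = match_primer(pair.forward, record, pattern)
    rev = match_primer(pair.reverse, record, pattern)
    min_len = max(len(pair.forward), len(pair.reverse))
    out = []
    for f in fwd:
        for r in rev:
            length = r.template_end - f.template_start + 1
            if min_len <= length <= max_len:
                seq_id = f.seq_id
                out.append(
                    AmpliconPrediction(seq_id, f.template_start, r.template_end, f, r)
                )
    return out


def coverage(
    pair: PrimerPair,
    targets: Sequence[SequenceRecord],
    pattern: MAMPattern,
    max_len: int = 450,
) -> float:
    """Percent of target records yielding ≥1 predicted amplicon, one decimal.

    A template with multiple binding sites still counts once.
    """
    if not targets:
        raise ValueError("coverage undefined for an empty target set")
    n_hit = sum(1 for rec in targets if predict_amplicons(pair, rec, pattern, max_len))
    return round(100.0 * n_hit / len(targets), 1)


@dataclass
class PatternStats:
    pct_targets_matched: float
    pct_nontargets_matched: float
    n_targets_matched: int
    n_nontargets_matched: int


@dataclass
class OffendingMatch:
    """A non-target template amplified under some pattern, with per-primer
    mismatch positions (distances from each primer's 3' end)."""

    seq_id: str
    clade: str
    pattern: str
    mismatches_by_primer: dict[str, tuple[int, ...]]


@dataclass
class SpecificityReport:
    pair_name: str
    target_clade: str
    n_targets: int
    n_nontargets: int
    per_pattern: dict[str, PatternStats]
    offending_matches: list[OffendingMatch]

    def to_dict(self) -> dict:
        return {
            "pair": self.pair_name,
            "target_clade": self.target_clade,
            "n_targets": self.n_targets,
            "n_nontargets": self.n_nontargets,
            "patterns": {
                label: vars(stats) for label, stats in self.per_pattern.items()
            },
            "offending_matches": [
                {
                    "seq_id": m.seq_id,
                    "clade": m.clade,
                    "pattern": m.pattern,
                    "mismatches_by_primer": {
                        k: list(v) for k, v in m.mismatches_by_primer.items()
                    },
                }
                for m in self.offending_matches
            ],
        }


def specificity_report(
    pair: PrimerPair,
    db: ReferenceDatabase,
    target_clade: str,
    patterns: Sequence[MAMPattern],
    max_len: int = 450,
) -> SpecificityReport:
    """Per-pattern coverage and specificity percentages for a primer pair.

    A template counts as matched under a pattern when both primers bind it
    in amplifiable (convergent) orientation within ``max_len``. Percentages
    use |targets| and |nontargets| denominators respectively. Offending
    non-target matches carry per-primer mismatch positions for 3'-end
    discrimination ranking.
    """
    if not patterns:
        raise ValueError("at least one MAM pattern is required")
    targets, nontargets = partition(db, target_clade)
    per_pattern: dict[str, PatternStats] = {}
    offending: list[OffendingMatch] = []
    for pat in patterns:
        n_t = sum(1 for rec in targets if predict_amplicons(pair, rec, pat, max_len))
        n_nt = 0
        for rec in nontargets:
            preds = predict_amplicons(pair, rec, pat, max_len)
            if preds:
                n_nt += 1
                best = min(preds, key=lambda p: p.forward_match.n_mismatches + p.reverse_match.n_mismatches)
                offending.append(
                    OffendingMatch(
                        rec.id,
                        rec.clade,
                        pat.label,
                        {
                            pair.forward.name: best.forward_match.mismatch_positions_from_3prime,
                            pair.reverse.name: best.reverse_match.mismatch_positions_from_3prime,
                        },
                    )
                )
        per_pattern[pat.label] = PatternStats(
            pct_targets_matched=round(100.0 * n_t / len(targets), 2) if targets else 0.0,
            pct_nontargets_matched=round(100.0 * n_nt / len(nontargets), 2) if nontargets else 0.0,
            n_targets_matched=n_t,
            n_nontargets_matched=n_nt,
        )
    return SpecificityReport(
        pair.name, target_clade, len(targets), len(nontargets), per_pattern, offending
    )
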