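"""Candidate primer-pair enumeration and criterion-based ranking.

Candidate pairs are drawn from windows conserved across the target clade
(found by exact IUPAC-aware scanning of unaligned targets, not multiple
alignment), thermodynamically screened, and ranked by three selection
criteria:

(i)   both primers match all targets and no non-target under the stringent
      pattern (0MAM) — high coverage and specificity assuming no mismatch
      during qPCR;
(ii)  as few non-target matches as possible under flexible patterns —
      robustness to tolerated mismatches during qPCR;
(iii) among remaining non-target matches, mismatches as close to the
      primer 3' end as possible (equivalently, as far from the 5' end),
      where they are most disruptive to extension.

Criterion (iii) is operationalized as the minimum distance-from-3'-end of
the closest-to-3' mismatch over all flexible-pattern non-target matches
(lower is better); ties are broken by the mean of those distances.

Melting temperatures use nearest-neighbor thermodynamics (SantaLucia) at
50 mM monovalent salt and 400 nM primer via Biopython's ``Tm_NN``.
"""

from __future__ import annotations

import itertools
import statistics
from dataclasses import dataclass, field
from typing import Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as mt

from .insilico import (
    MAMPattern,
    Primer,
    PrimerPair,
    coverage,
    match_primer,
    predict_amplicons,
)
from .iupac import IUPAC_SETS, normalize, reverse_complement
from .refdb import SequenceRecord

__all__ = [
    "DesignConstraints",
    "CandidateRanking",
    "DesignResult",
    "conserved_windows",
    "melting_temperature",
    "complementarity_scores",
    "rank_candidates",
]

#: Default Tm conditions: 50 mM monovalent salt, 400 nM primer.
TM_SALT_MM = 50.0
TM_PRIMER_NM = 400.0

_DEGENERATE = set(IUPAC_SETS) - set("ACGT")
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


@dataclass
class DesignConstraints:
    primer_len_min: int = 17
    primer_len_max: int = 25
    min_amplicon_bp: int = 70
    max_amplicon_bp: int = 450
    allow_degenerate: bool = False
    max_tm_diff_C: float = 3.0
    max_self_complementarity_run: int = 8
    max_3prime_complementarity_run: int = 4
    min_target_fraction: float = 1.0  # fraction of targets a window must match

    def __post_init__(self) -> None:
        if self.primer_len_min > self.primer_len_max:
            raise ValueError("primer length range is empty")
        if self.min_amplicon_bp > self.max_amplicon_bp:
            raise ValueError("amplicon length range is empty")
        if not 0 < self.min_target_fraction <= 1:
            raise ValueError("min_target_fraction must be in (0, 1]")


@dataclass
class ConservedWindow:
    start: int  # 1-based on the designated reference target
    length: int
    consensus: str
    target_fraction: float


def _occurs_exact(window: str, targets: Sequence[SequenceRecord]) -> float:
    """Fraction of targets containing ``window`` with zero mismatches
    (IUPAC set-intersection semantics)."""
    from .insilico import _scan  # exact scan with k=0

    probe = Primer("window", window, "forward")
    n = sum(1 for rec in targets if _scan(probe, rec.seq, 0))
    return n / len(targets)


def conserved_windows(
    targets: Sequence[SequenceRecord],
    len_range: tuple[int, int] = (17, 25),
    min_fraction: float = 1.0,
    reference_index: int = 0,
) -> list[ConservedWindow]:
    """Windows of the designated reference target conserved across targets.

    Every window of each length drawn from ``targets[reference_index]`` is
    verified by exact-match scanning against all targets; windows present in
    at least ``min_fraction`` of them are returned. Targets need not be
    aligned.
    """
    if not targets:
        raise ValueError("target set must be non-empty")
    lo, hi = len_range
    ref = targets[reference_index].seq
    out: list[ConservedWindow] = []
    for length in range(lo, hi + 1):
        for start in range(len(ref) - length + 1):
            window = ref[start : start + length]
            frac = _occurs_exact(window, targets)
            if frac >= min_fraction:
                out.append(ConservedWindow(start + 1, length, window, frac))
    return out


def melting_temperature(seq: str, on_degenerate: str = "error") -> float:
    """Nearest-neighbor Tm (°C) at 50 mM Na+, 400 nM primer.

    Degenerate bases raise by default; with ``on_degenerate='average'`` the
    Tm is averaged over all non-degenerate expansions.
    """
    s = normalize(seq)
    degen = [c for c in s if c in _DEGENERATE]
    if degen:
        if on_degenerate != "average":
            raise ValueError(
                f"degenerate bases {degen!r} in primer; pass on_degenerate='average'"
            )
        expansions = itertools.product(*(sorted(IUPAC_SETS[c]) for c in s))
        return statistics.fmean(
            mt.Tm_NN(Seq("".join(e)), Na=TM_SALT_MM, dnac1=TM_PRIMER_NM, dnac2=0)
            for e in expansions
        )
    return float(mt.Tm_NN(Seq(s), Na=TM_SALT_MM, dnac1=TM_PRIMER_NM, dnac2=0))


def complementarity_scores(a: str, b: str) -> tuple[int, int]:
    """(max_run, max_3prime_anchored_run) of Watson–Crick complementarity.

    ``a`` is read 5'→3' and ``b`` 3'→5'; over all relative offsets, max_run
    is the longest contiguous run of complementary pairs and the anchored
    run additionally must include either primer's 3' terminus. Self-
    complementarity (hairpin/self-dimer propensity) is
    ``complementarity_scores(a, a)``.
    """
    a = normalize(a)
    b = normalize(b)
    n, m = len(a), len(b)
    max_run = 0
    max_anchored = 0
    # offset aligns a[i] against b[m-1-(i-offset)] — slide b (3'->5') along a
    for offset in range(-(m - 1), n):
        run = 0
        for i in range(max(0, offset), min(n, offset + m)):
            j = m - 1 - (i - offset)  # b index paired with a[i]
            if (a[i], b[j]) in _WC:
                run += 1
                if run > max_run:
                    max_run = run
                # anchored: the run touches a's 3' end (i == n-1) or b's 3'
                # end (j == m-1, i.e. the first paired position of b)
                if i == n - 1 or j == m - 1:
                    max_anchored = max(max_anchored, run)
            else:
                run = 0
    return max_run, max_anchored


@dataclass
class CandidateRanking:
    pair: PrimerPair
    amplicon_bp: int
    criterion1_pass: bool
    criterion2_score: int
    criterion3_score: float  # min distance-from-3' of closest mismatch; 0 if none
    criterion3_mean: float
    tm_f: float
    tm_r: float
    pct_target_0mam: float
    pct_nontarget_0mam: float
    self_dimer_f: int
    self_dimer_r: int
    cross_dimer: int


@dataclass
class DesignResult:
    """Ranked candidates plus a structured diagnostic of what was filtered."""

    candidates: list[CandidateRanking]
    diagnostics: dict[str, int] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.candidates)

    def __len__(self) -> int:
        return len(self.candidates)

    def __getitem__(self, i):
        return self.candidates[i]


def _closest_3prime_mismatch_dists(
    pair: PrimerPair,
    nontargets: Sequence[SequenceRecord],
    flexible: Sequence[MAMPattern],
    max_len: int,
) -> tuple[int, list[int]]:
    """(total non-target matches over flexible patterns, per-match distance of
    the closest-to-3' mismatch)."""
    total = 0
    dists: list[int] = []
    for pat in flexible:
        for rec in nontargets:
            for primer in (pair.forward, pair.reverse):
                for m in match_primer(primer, rec, pat):
                    total += 1
                    if m.mismatch_positions_from_3prime:
                        dists.append(min(m.mismatch_positions_from_3prime))
    return total, dists


def rank_candidates(
    targets: Sequence[SequenceRecord],
    nontargets: Sequence[SequenceRecord],
    constraints: DesignConstraints | None = None,
    patterns: Sequence[MAMPattern] | None = None,
    gene: str = "amp",
) -> DesignResult:
    """Enumerate, screen, and rank candidate clade-specific primer pairs.

    ``patterns`` must contain the stringent pattern (k=0) first and one or
    more flexible patterns. Only pairs passing all constraints and
    criterion (i) — full target coverage and zero non-target matching at
    the stringent pattern — are returned, sorted by (criterion2 ascending,
    criterion3 ascending, criterion3 mean, amplicon length, pair name).
    An empty candidate list is accompanied by diagnostics counting how many
    pairs each screen rejected.
    """
    constraints = constraints or DesignConstraints()
    if patterns is None:
        from .insilico import MAM_PRESETS

        patterns = [MAM_PRESETS["0MAM"], MAM_PRESETS["1MAM"], MAM_PRESETS["1MAM*"], MAM_PRESETS["3MAM"]]
    stringent = patterns[0]
    if stringent.max_mismatches != 0:
        raise ValueError("patterns[0] must be the stringent (k=0) pattern")
    flexible = [p for p in patterns[1:]]
    if not flexible:
        raise ValueError("at least one flexible pattern is required")

    windows = conserved_windows(
        targets,
        (constraints.primer_len_min, constraints.primer_len_max),
        constraints.min_target_fraction,
    )
    diag = {
        "conserved_windows": len(windows),
        "degenerate": 0,
        "amplicon_length": 0,
        "tm_difference": 0,
        "self_complementarity": 0,
        "cross_complementarity": 0,
        "criterion1": 0,
    }
    if not constraints.allow_degenerate:
        kept = [w for w in windows if not set(w.consensus) & _DEGENERATE]
        diag["degenerate"] = len(windows) - len(kept)
        windows = kept

    tm_cache = {w.consensus: melting_temperature(w.consensus, "average") for w in windows}
    self_cache = {
        w.consensus: complementarity_scores(w.consensus, w.consensus) for w in windows
    }

    candidates: list[CandidateRanking] = []
    for wf, wr in itertools.combinations_with_replacement(sorted(windows, key=lambda w: (w.start, w.length)), 2):
        if wr.start < wf.start:
            wf, wr = wr, wf
        f_start, r_end = wf.start, wr.start + wr.length - 1
        amplicon = r_end - f_start + 1
        if not constraints.min_amplicon_bp <= amplicon <= constraints.max_amplicon_bp:
            diag["amplicon_length"] += 1
            continue
        if wr.start < wf.start + wf.length:  # primers may not overlap each other
            diag["amplicon_length"] += 1
            continue
        fwd = Primer(f"{gene}-{f_start}f", wf.consensus, "forward", f_start)
        rev = Primer(f"{gene}-{r_end}r", reverse_complement(wr.consensus), "reverse", r_end)
        tm_f, tm_r = tm_cache[wf.consensus], tm_cache[wr.consensus]
        if abs(tm_f - tm_r) > constraints.max_tm_diff_C:
            diag["tm_difference"] += 1
            continue
        sd_f = self_cache[wf.consensus][0]
        sd_r = complementarity_scores(rev.seq, rev.seq)[0]
        if max(sd_f, sd_r) > constraints.max_self_complementarity_run:
            diag["self_complementarity"] += 1
            continue
        cross, cross_3p = complementarity_scores(fwd.seq, rev.seq)
        if cross_3p > constraints.max_3prime_complementarity_run:
            diag["cross_complementarity"] += 1
            continue
        pair = PrimerPair(f"{fwd.name}/{rev.name}", fwd, rev)
        pct_t = coverage(pair, targets, stringent, constraints.max_amplicon_bp)
        required = round(100.0 * constraints.min_target_fraction, 1)
        nt_hit = any(
            predict_amplicons(pair, rec, stringent, constraints.max_amplicon_bp)
            for rec in nontargets
        )
        if pct_t < required or nt_hit:
            diag["criterion1"] += 1
            continue
        c2, dists = _closest_3prime_mismatch_dists(pair, nontargets, flexible, constraints.max_amplicon_bp)
        c3 = float(min(dists)) if dists else 0.0
        c3_mean = float(statistics.fmean(dists)) if dists else 0.0
        candidates.append(
            CandidateRanking(
                pair=pair,
                amplicon_bp=amplicon,
                criterion1_pass=True,
                criterion2_score=c2,
                criterion3_score=c3,
                criterion3_mean=c3_mean,
                tm_f=tm_f,
                tm_r=tm_r,
                pct_target_0mam=pct_t,
                pct_nontarget_0mam=0.0,
                self_dimer_f=sd_f,
                self_dimer_r=sd_r,
                cross_dimer=cross,
            )
        )
    candidates.sort(
        key=lambda c: (
            c.criterion2_score,
            c.criterion3_score,
            c.criterion3_mean,
            c.amplicon_bp,
            c.pair.name,
        )
    )
    return DesignResult(candidates, diag)
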