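"""Synthetic clade-structured databases and simulated qPCR Ct data.

The sequence generator emulates a clade-annotated marker-gene reference
set: each clade has a consensus sequence, clade consensuses are separated
by a configurable minimum number of substitutions, and members of a clade
are independent point-substitution variants of their consensus. Primer
binding sites can be *planted*: copied verbatim into every target-clade
sequence (so coverage there is 100% by construction) while every
non-target sequence is forced to carry a configurable minimum number of
mismatches inside each site — optionally exactly one mismatch at the
primer's 3'-terminal position, the construction used to probe 3'-end
discrimination.

The Ct simulator inverts the standard-curve model: with per-cycle
efficiency E, Ct = intercept - log10(copies)/log10(1+E) + N(0, σ); values
beyond the detection limit are emitted as undetected. All randomness comes
from a single integer seed via numpy's PCG64 generator, so outputs are
byte-reproducible across platforms.

Substitutions only (no indels): downstream matching is window-based, and
planted-site guarantees are exact under substitution-only evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .iupac import reverse_complement
from .refdb import ReferenceDatabase, SequenceRecord

__all__ = ["PlantedSite", "FixtureSpec", "CtSimSpec", "generate_clade_db", "simulate_ct"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedSite:
    """A primer pair planted into one clade at fixed reference coordinates.

    ``forward_coord`` is the forward primer's 5'-most (leftmost) template
    position; ``reverse_coord`` is the reverse primer's rightmost template
    position; both 1-based. ``min_nontarget_mismatches`` substitutions are
    forced inside each site of every non-target sequence; with
    ``force_3prime_mismatch`` the non-target sites instead carry exactly
    one mismatch, at the primer's 3'-terminal position (plus extras only if
    the minimum demands them).
    """

    clade: str
    forward_coord: int
    forward_seq: str
    reverse_coord: int
    reverse_seq: str
    min_nontarget_mismatches: int = 4
    force_3prime_mismatch: bool = False


@dataclass
class FixtureSpec:
    n_clades: int = 4
    seqs_per_clade: int = 10
    seq_length_bp: int = 800
    intra_clade_substitution_rate: float = 0.02
    inter_clade_divergence: int = 40
    planted_sites: list[PlantedSite] = field(default_factory=list)
    clade_labels: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.intra_clade_substitution_rate <= 1:
            raise ValueError("substitution rate must be in [0, 1]")
        if self.inter_clade_divergence > self.seq_length_bp:
            raise ValueError("inter-clade divergence exceeds sequence length")
        for site in self.planted_sites:
            for coord, seq, kind in (
                (site.forward_coord, site.forward_seq, "forward"),
                (site.reverse_coord - len(site.reverse_seq) + 1, site.reverse_seq, "reverse"),
            ):
                if coord < 1 or coord + len(seq) - 1 > self.seq_length_bp:
                    raise ValueError(f"{kind} planted site does not fit the sequence")
        labels = self.clade_labels or [f"C{i+1:02d}" for i in range(self.n_clades)]
        if len(labels) != self.n_clades:
            raise ValueError("need one label per clade")
        self.clade_labels = labels
        for site in self.planted_sites:
            if site.clade not in labels:
                raise ValueError(f"planted site clade {site.clade!r} not among labels")


def _site_windows(site: PlantedSite) -> list[tuple[int, str, bool]]:
    """(0-based start, template-strand site sequence, three_prime_at_left)."""
    fwd = (site.forward_coord - 1, site.forward_seq, False)
    rev_start = site.reverse_coord - len(site.reverse_seq)
    rev = (rev_start, reverse_complement(site.reverse_seq), True)
    return [fwd, rev]


def _mutate_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(len(choices))]


def generate_clade_db(spec: FixtureSpec) -> ReferenceDatabase:
    """Generate a clade-annotated database honouring all planted-site
    guarantees; identical specs produce byte-identical databases."""
    rng = np.random.default_rng(spec.seed)
    L = spec.seq_length_bp

    consensuses: list[np.ndarray] = []
    for _ in range(spec.n_clades):
        cons = rng.integers(0, 4, size=L)
        consensuses.append(cons)
    # enforce minimum pairwise divergence between clade consensuses
    # (fixpoint: a repair may perturb an earlier pair, so sweep until stable)
    stable = False
    while not stable:
        stable = True
        for i in range(spec.n_clades):
            for j in range(i):
                if int((consensuses[i] != consensuses[j]).sum()) < spec.inter_clade_divergence:
                    stable = False
                    pos = int(rng.integers(L))
                    consensuses[i][pos] = (consensuses[i][pos] + 1 + rng.integers(3)) % 4

    site_positions: set[int] = set()
    for site in spec.planted_sites:
        for start, seq, _ in _site_windows(site):
            site_positions.update(range(start, start + len(seq)))

    records: list[SequenceRecord] = []
    for ci, clade in enumerate(spec.clade_labels):
        cons_str = "".join(_BASES[consensuses[ci]])
        for si in range(spec.seqs_per_clade):
            seq = list(cons_str)
            # intra-clade point substitutions, sparing planted-site positions
            mutate = rng.random(L) < spec.intra_clade_substitution_rate
            for pos in np.nonzero(mutate)[0]:
                if int(pos) in site_positions:
                    continue
                seq[pos] = _mutate_base(seq[pos], rng)
            for site in spec.planted_sites:
                for start, site_seq, three_prime_left in _site_windows(site):
                    if clade == site.clade:
                        seq[start : start + len(site_seq)] = list(site_seq)
                    else:
                        _plant_nontarget(seq, start, site_seq, three_prime_left, site, rng)
            records.append(SequenceRecord(f"{clade}_{si+1:03d}", clade, "".join(seq)))
    return ReferenceDatabase(records)


def _plant_nontarget(
    seq: list[str],
    start: int,
    site_seq: str,
    three_prime_left: bool,
    site: PlantedSite,
    rng: np.random.Generator,
) -> None:
    """Force the non-target guarantee inside one planted site window."""
    n = len(site_seq)
    if site.force_3prime_mismatch:
        # copy the site, then break exactly the 3'-terminal base
        seq[start : start + n] = list(site_seq)
        term = start if three_prime_left else start + n - 1
        seq[term] = _mutate_base(seq[term], rng)
        extra_needed = site.min_nontarget_mismatches - 1
        interior = [p for p in range(start, start + n) if p != term]
        for pos in rng.permutation(interior)[: max(0, extra_needed)]:
            seq[pos] = _mutate_base(site_seq[pos - start], rng)
        return
    current = [p for p in range(start, start + n) if seq[p] != site_seq[p - start]]
    deficit = site.min_nontarget_mismatches - len(current)
    if deficit > 0:
        matching = [p for p in range(start, start + n) if seq[p] == site_seq[p - start]]
        for pos in rng.permutation(matching)[:deficit]:
            seq[pos] = _mutate_base(site_seq[pos - start], rng)


@dataclass
class CtSimSpec:
    """Standard-curve style qPCR simulation: ten-fold dilution series with
    replicates, Gaussian Ct noise, and a detection ceiling."""

    true_efficiency: float = 1.0  # per-cycle amplification fraction (1.0 = doubling)
    intercept_ct: float = 38.0  # Ct at one template copy
    copies: Sequence[float] = (1e3, 1e4, 1e5, 1e6, 1e7, 1e8)
    replicates: int = 6
    ct_noise_sd: float = 0.15
    undetected_above_ct: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_efficiency <= 0:
            raise ValueError("efficiency must be positive")
        if self.ct_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


def simulate_ct(sim_spec: CtSimSpec) -> pd.DataFrame:
    """Simulate replicate Ct values for a dilution series.

    Columns: copies, log10_copies, replicate, ct (NaN when the true noisy Ct
    exceeds the detection ceiling), detected.
    """
    rng = np.random.default_rng(sim_spec.seed)
    slope = -1.0 / np.log10(1.0 + sim_spec.true_efficiency)
    rows = []
    for copies in sim_spec.copies:
        log10_copies = float(np.log10(copies))
        for rep in range(1, sim_spec.replicates + 1):
            ct = sim_spec.intercept_ct + slope * log10_copies
            if sim_spec.ct_noise_sd > 0:
                ct += rng.normal(0.0, sim_spec.ct_noise_sd)
            detected = ct <= sim_spec.undetected_above_ct
            rows.append(
                {
                    "copies": float(copies),
                    "log10_copies": log10_copies,
                    "replicate": rep,
                    "ct": float(ct) if detected else np.nan,
                    "detected": detected,
                }
            )
    return pd.DataFrame(rows)
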