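"""Primer–template matching under mismatch-allowance patterns.

The matching engine is checked against an independent brute-force
sliding-window comparator written directly from the IUPAC definition.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cladeqpcr import (
    MAM_PRESETS,
    MAMPattern,
    Primer,
    PrimerPair,
    base_compatible,
    coverage,
    match_primer,
    predict_amplicons,
)
from cladeqpcr.refdb import SequenceRecord

from conftest import random_seq

# --- independent IUPAC oracle (typed from the standard code table) ----------

ORACLE_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}
ORACLE_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R",
               "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
               "D": "H", "H": "D", "N": "N"}


def oracle_revcomp(s):
    return "".join(ORACLE_COMP[c] for c in reversed(s))


def oracle_matches(primer_seq, orientation, template, k, w):
    """Brute-force scan of all template windows; returns
    [(1-based start, sorted mismatch distances from the primer 3' end)]."""
    probe = primer_seq if orientation == "forward" else oracle_revcomp(primer_seq)
    L = len(probe)
    hits = []
    for s in range(len(template) - L + 1):
        mm = []
        for i in range(L):
            if not ORACLE_SETS[probe[i]] & ORACLE_SETS[template[s + i]]:
                dist = L - i if orientation == "forward" else i + 1
                mm.append(dist)
        if len(mm) <= k and all(d > w for d in mm):
            hits.append((s + 1, tuple(sorted(mm))))
    return hits


# --- base compatibility ------------------------------------------------------

def test_base_compatible_identity_and_mismatch():
    assert base_compatible("A", "A")
    assert not base_compatible("A", "G")
    assert base_compatible("R", "A")
    assert not base_compatible("R", "C")


def test_base_compatible_full_iupac_enumeration():
    """All 15 x 15 code pairs agree with set-intersection semantics."""
    for p in ORACLE_SETS:
        for t in ORACLE_SETS:
            assert base_compatible(p, t) == bool(ORACLE_SETS[p] & ORACLE_SETS[t])


def test_base_compatible_rejects_non_iupac():
    with pytest.raises(ValueError):
        base_compatible("X", "A")


# --- match_primer ------------------------------------------------------------

def _fwd(seq, name="p-1f"):
    return Primer(name, seq, "forward")


def test_exact_hit_is_found_once():
    primer = _fwd("ACGTACGTAC")
    rec = SequenceRecord("t", "IA", "TTTTT" + "ACGTACGTAC" + "GGGGG")
    hits = match_primer(primer, rec, MAM_PRESETS["0MAM"])
    assert len(hits) == 1
    assert hits[0].template_start == 6
    assert hits[0].n_mismatches == 0


def test_3prime_terminal_mismatch_discriminates_1mam_from_1mam_star():
    """A single mismatch at the primer 3' terminus is rejected when the
    terminal position is protected (1MAM) but admitted when it is not
    (1MAM*) — the positional discrimination the protected window encodes."""
    site = "ACGTACGTAC"
    primer = _fwd(site[:-1] + "G")  # 3'-terminal base incompatible with site
    rec = SequenceRecord("t", "IA", "TTTTT" + site + "GGGGG")
    assert match_primer(primer, rec, MAM_PRESETS["1MAM"]) == []
    hits = match_primer(primer, rec, MAM_PRESETS["1MAM*"])
    assert len(hits) == 1
    assert hits[0].mismatch_positions_from_3prime == (1,)


def test_reverse_primer_binds_as_reverse_complement():
    # reverse primer 5'->3' GTACGT; its revcomp ACGTAC sits at template 4..9
    primer = Primer("p-9r", "GTACGT" + "AAAA", "reverse")
    rec = SequenceRecord("t", "IA", "TTT" + "TTTTACGTAC" + "CCC")
    hits = match_primer(primer, rec, MAM_PRESETS["0MAM"])
    assert len(hits) == 1
    assert hits[0].template_start == 4
    assert hits[0].template_end == 13


def test_primer_longer_than_template_yields_no_match():
    primer = _fwd("ACGTACGTACGTACG")
    rec = SequenceRecord("t", "IA", "ACGT")
    assert match_primer(primer, rec, MAM_PRESETS["3MAM"]) == []


@pytest.mark.parametrize("orientation", ["forward", "reverse"])
def test_matcher_equals_brute_force_on_random_instances(orientation):
    rng = np.random.default_rng(42)
    patterns = [MAM_PRESETS["0MAM"], MAM_PRESETS["1MAM"], MAM_PRESETS["1MAM*"],
                MAM_PRESETS["3MAM"], MAMPattern("k2w3", 2, 3)]
    for trial in range(300):
        L = int(rng.integers(10, 26))
        primer_seq = random_seq(rng, L, "ACGT" + ("RYN" if trial % 3 == 0 else ""))
        template = random_seq(rng, int(rng.integers(40, 200)),
                              "ACGT" + ("N" if trial % 5 == 0 else ""))
        primer = Primer("p-1f" if orientation == "forward" else "p-9r",
                        primer_seq, orientation)
        pat = patterns[trial % len(patterns)]
        got = [(m.template_start, m.mismatch_positions_from_3prime)
               for m in match_primer(primer, template, pat)]
        want = oracle_matches(primer_seq, orientation, template,
                              pat.max_mismatches, pat.protected_3prime_window)
        assert got == want


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    primer_seq=st.text(alphabet="ACGT", min_size=10, max_size=20),
    template=st.text(alphabet="ACGTN", min_size=30, max_size=120),
    k=st.integers(0, 3),
    w=st.integers(0, 3),
)
def test_pattern_monotonicity_property(primer_seq, template, k, w):
    """Relaxing k or shrinking w never loses a match (match-set nesting)."""
    primer = Primer("p-1f", primer_seq, "forward")
    strict = MAMPattern("strict", k, w)
    loose = MAMPattern("loose", k + 1, max(0, w - 1))
    strict_hits = {m.template_start for m in match_primer(primer, template, strict)}
    loose_hits = {m.template_start for m in match_primer(primer, template, loose)}
    assert strict_hits <= loose_hits


def test_preset_chain_is_nested():
    """0MAM ⊆ 1MAM ⊆ 1MAM* ⊆ 3MAM on random instances."""
    rng = np.random.default_rng(3)
    chain = ["0MAM", "1MAM", "1MAM*", "3MAM"]
    for _ in range(100):
        primer = Primer("p-1f", random_seq(rng, 15), "forward")
        template = random_seq(rng, 120)
        hits = {
            lab: {m.template_start for m in match_primer(primer, template, MAM_PRESETS[lab])}
            for lab in chain
        }
        for strict, loose in zip(chain, chain[1:]):
            assert hits[strict] <= hits[loose]


def test_strand_symmetry():
    """Reverse-complementing the template and swapping primer orientations
    yields the same amplicon set with mirrored coordinates."""
    from cladeqpcr import reverse_complement

    rng = np.random.default_rng(8)
    for _ in range(30):
        template = random_seq(rng, 150)
        f_seq = random_seq(rng, 14)
        r_seq = random_seq(rng, 14)
        pair = PrimerPair("p", Primer("g-1f", f_seq, "forward"),
                          Primer("g-9r", r_seq, "reverse"))
        # on the reverse complement, the roles swap: the old reverse primer
        # becomes the forward primer of the mirrored pair
        mirrored = PrimerPair("m", Primer("g-1f", r_seq, "forward"),
                              Primer("g-9r", f_seq, "reverse"))
        pat = MAMPattern("k2w0", 2, 0)
        direct = predict_amplicons(pair, template, pat, max_len=150)
        mirror = predict_amplicons(mirrored, reverse_complement(template), pat, max_len=150)
        n = len(template)
        got = sorted((a.start, a.end) for a in direct)
        want = sorted((n - a.end + 1, n - a.start + 1) for a in mirror)
        assert got == want


# --- amplicon prediction -----------------------------------------------------

def _planted_template(rng, fwd_seq, rev_seq, f_coord, r_coord, length=1200):
    from cladeqpcr import reverse_complement

    t = list(random_seq(rng, length))
    t[f_coord - 1 : f_coord - 1 + len(fwd_seq)] = list(fwd_seq)
    t[r_coord - len(rev_seq) : r_coord] = list(reverse_complement(rev_seq))
    return "".join(t)


@pytest.mark.parametrize(
    "primer_set,expected_bp",
    [
        ("Primer-IB", 282),
        ("Primer-IC", 397),
        ("Primer-ID", 215),
        ("Primer-IIE", 373),
        ("Primer-IIG", 105),
        ("Primer-IIH", 228),
        ("Primer-II-I", 259),
    ],
)
def test_amplicon_length_from_name_coordinates(primer_set, expected_bp):
    """Planting each preset pair at its name-declared coordinates yields the
    published amplicon size under 1-based inclusive arithmetic."""
    from cladeqpcr.presets import ACCUMULIBACTER_PRIMERS, accumulibacter_pair

    rng = np.random.default_rng(1)
    pair = accumulibacter_pair(primer_set)
    _, (_, f_seq), (_, r_seq) = ACCUMULIBACTER_PRIMERS[primer_set]
    template = _planted_template(
        rng, f_seq, r_seq, pair.forward.ref_coord, pair.reverse.ref_coord
    )
    preds = predict_amplicons(pair, template, MAM_PRESETS["0MAM"], max_len=450)
    assert len(preds) == 1
    assert preds[0].length_bp == expected_bp
    assert preds[0].length_bp == pair.reverse.ref_coord - pair.forward.ref_coord + 1


def test_divergent_orientation_yields_no_amplicon():
    """A forward site downstream of the reverse site cannot amplify."""
    rng = np.random.default_rng(2)
    f_seq, r_seq = random_seq(rng, 15), random_seq(rng, 15)
    template = _planted_template(rng, f_seq, r_seq, f_coord=200, r_coord=60, length=400)
    pair = PrimerPair("p", Primer("g-200f", f_seq, "forward"),
                      Primer("g-60r", r_seq, "reverse"))
    assert predict_amplicons(pair, template, MAM_PRESETS["0MAM"], 450) == []


def test_max_len_filters_long_products():
    rng = np.random.default_rng(4)
    f_seq, r_seq = random_seq(rng, 15), random_seq(rng, 15)
    template = _planted_template(rng, f_seq, r_seq, f_coord=50, r_coord=700, length=900)
    pair = PrimerPair("p", Primer("g-50f", f_seq, "forward"),
                      Primer("g-700r", r_seq, "reverse"))
    assert predict_amplicons(pair, template, MAM_PRESETS["0MAM"], max_len=450) == []
    assert len(predict_amplicons(pair, template, MAM_PRESETS["0MAM"], max_len=700)) == 1


# --- coverage ----------------------------------------------------------------

def _pair_from_site(site):
    return PrimerPair(
        "planted",
        Primer(f"g-{site.forward_coord}f", site.forward_seq, "forward"),
        Primer(f"g-{site.reverse_coord}r", site.reverse_seq, "reverse"),
    )


def test_planted_fixture_full_coverage(planted_db, planted_spec):
    from cladeqpcr import partition

    site = planted_spec.planted_sites[0]
    pair = _pair_from_site(site)
    targets, nontargets = partition(planted_db, site.clade)
    assert coverage(pair, targets, MAM_PRESETS["0MAM"]) == 100.0
    assert all(not predict_amplicons(pair, r, MAM_PRESETS["3MAM"]) for r in nontargets)


def test_partial_coverage_ratio():
    """4 of 11 targets amplifiable -> 36.4% to one decimal."""
    rng = np.random.default_rng(9)
    f_seq, r_seq = random_seq(rng, 15), random_seq(rng, 15)
    pair = PrimerPair("p", Primer("g-20f", f_seq, "forward"),
                      Primer("g-150r", r_seq, "reverse"))
    targets = []
    for i in range(11):
        if i < 4:
            seq = _planted_template(rng, f_seq, r_seq, 20, 150, length=200)
        else:
            seq = random_seq(rng, 200)
        targets.append(SequenceRecord(f"t{i}", "IIC", seq))
    assert coverage(pair, targets, MAM_PRESETS["0MAM"]) == 36.4


def test_zero_coverage_and_empty_target_error():
    rng = np.random.default_rng(10)
    pair = PrimerPair("p", Primer("g-1f", random_seq(rng, 15), "forward"),
                      Primer("g-9r", random_seq(rng, 15), "reverse"))
    targets = [SequenceRecord("t", "IA", random_seq(rng, 100))]
    assert coverage(pair, targets, MAM_PRESETS["0MAM"]) == 0.0
    with pytest.raises(ValueError):
        coverage(pair, [], MAM_PRESETS["0MAM"])
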