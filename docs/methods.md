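# Methods

## Matching model

Primer–template comparison uses IUPAC set semantics: primer code *p* and
template code *t* are compatible iff the base sets they denote intersect;
an empty intersection is one mismatch. This is deliberately conservative
for degenerate *template* bases (an `N` in a reference sequence never
creates a mismatch), which inflates coverage rather than specificity;
reports carry per-match mismatch positions so such sites can be audited.

A mismatch-allowance (MAM) pattern is a pair `(k, w)`: a binding site is
admissible when it has at most `k` mismatches and none within the `w`
3′-terminal primer positions. The named presets

| label | k | w |
|-------|---|---|
| 0MAM  | 0 | 0 |
| 1MAM  | 1 | 1 |
| 1MAM* | 1 | 0 |
| 3MAM  | 3 | 0 |

are our parameterization of the mismatch-allowance family used in
clade-specific primer screening; the published screening procedure names
these labels without printing definitions, so the `(k, w)` readings are
documented as an interpretation — one that reproduces the labels'
observable behaviour, in particular that 1MAM and 1MAM\* differ exactly at
the primer 3′-terminal position. Arbitrary `(k, w)` patterns can be given
inline as `k<INT>w<INT>`. The presets are nested (`0MAM ⊆ 1MAM ⊆ 1MAM* ⊆
3MAM` as match sets), which makes reported percentages monotone across the
chain; this is asserted by property tests.

Coordinates are 1-based and inclusive on the reference (plus) strand.
Forward primers are scanned as written; reverse primers are scanned as
their reverse complement, so a reverse primer's 3′ end sits at the *left*
edge of its template window and its rightmost template coordinate is the
amplicon end. An amplicon from a convergent pair runs from the forward
primer's leftmost coordinate to the reverse primer's rightmost coordinate;
its length is `end − start + 1`. This convention makes the primer-name
arithmetic exact: a forward primer at 372 with a reverse primer at 653
yields a 282-bp product. Overlapping primers are allowed down to
`length ≥ max(len_f, len_r)`; products above the configured maximum
(default 450 bp) are discarded. Primer-name coordinates are advisory
metadata only — matching never trusts them.

The scanner is vectorized: sequences are encoded as 4-bit base masks and
all windows are compared at once (`numpy` sliding windows, compatibility =
nonzero bitwise AND). Its contract is checked against a brute-force
character-set comparator on >10⁴ random instances including degenerate
bases and both orientations.

## Primer design

Candidate windows are discovered by exact scanning of a designated
reference target against all target sequences (no multiple alignment is
built; the reference set is used unaligned). The default conservation
threshold is 100 % of targets, configurable downward. Screens, with
defaults chosen as common qPCR design practice: primer length 17–25 nt,
amplicon 70–450 bp, no degenerate bases, nearest-neighbor Tm difference
≤ 3 °C, self-complementarity run ≤ 8, 3′-anchored cross-complementarity
run ≤ 4. Tm uses SantaLucia nearest-neighbor thermodynamics (Biopython's
`Tm_NN` with its default unified table) at 50 mM monovalent salt and
400 nM primer; a hand-written nearest-neighbor summation over the same
published table serves as a cross-check in the tests. The wet-lab step of
tuning annealing temperature on the instrument cannot be simulated; the Tm
difference screen is its in-silico proxy.

Ranking implements the three selection criteria. Criterion (iii)
("mismatches far from the primer 5′ end") is operationalized as the
minimum, over all flexible-pattern non-target matches, of the
distance-from-3′-end of each match's closest-to-3′ mismatch — smaller is
better — with ties broken by the mean of those distances, then amplicon
length, then pair name. This turns the prose criterion into a computable
total order; identical inputs give identical ranked output. A pair with no
flexible-pattern non-target matches (criterion-2 score 0) always precedes
any pair with matches. When nothing passes, the result carries a
diagnostic counting rejections per screen.

## qPCR models

Standard curves are ordinary least squares of Ct on log₁₀ copies over all
replicate points (not level means, so replicate scatter is visible in R²).
Efficiency is `(10^(−1/slope) − 1) × 100`; a non-negative slope leaves
efficiency undefined and the curve invalid with a diagnostic. Validity is
`R² > 0.96` (strict) and efficiency in 85–115 %. Efficiency and R² are
conventionally reported to one and three decimals. Copy numbers from mass
use 660 g·mol⁻¹ per double-stranded base pair and Avogadro's number
6.02214 × 10²³.

Relative efficiency for cross-amplification is `RE = 2^(−ΔCt)` with
`ΔCt = Ct(non-target template) − Ct(primer's own target at equal copies)`,
assuming 100 % amplification efficiency. The reference Ct is the measured
own-target Ct at the same copy number (10⁷ in the emulated assay design),
not a theoretical value. The classification boundary sits exactly at
`RE = 2⁻¹⁰` (a ten-cycle delay, 0.098 % ≈ 0.1 %): undetected → *none*,
detected below the boundary → *negligible*, at or above it →
*interfering*, so a 9.95-cycle delay is interfering. Undetected reactions
are encoded as absent values, never as an artificial Ct of 40, to avoid
fabricating a bound; per-primer nonspecific RE sums therefore run over
detected non-target entries only.

## Abundance normalization

With gene-copy relative abundances `fᵢ` and per-cell rrn operon copy
numbers `nᵢ`, the community average is the weighted harmonic mean
`n̄ = 1/Σ(fᵢ/nᵢ)` — total 16S gene copies over total cells, the standard
copy-number correction (re-implemented here rather than calling an
external tool). `min nᵢ ≤ n̄ ≤ max nᵢ` always. A clade's share of the
community is `100 × ppk1_copies / (16S_copies / n̄)`, assuming one *ppk1*
gene per cell (fixed, documented, overridable via
`abundance.MARKER_COPIES_PER_CELL`); both copy numbers must come from the
same template mass, enforced by sample keys rather than by the formula.
Taxa without a known copy number are imputed with the profile's weighted
harmonic average; samples without any profile fall back to 2.04 copies per
cell, the cross-sample average of the emulated dataset. The unclassified
remainder is `max(0, total − Σ clades)`, with negative raw values clipped
and flagged rather than silently zeroed.

## Clade assignment

Queries are compared to references by global Needleman–Wunsch alignment
(match +1, mismatch −1, gap −2, configurable); identity is matched columns
over alignment columns. Because score-optimal global alignments are not
unique, identity is canonicalized as the maximum number of matched columns
among score-optimal alignments (a lexicographic `(score, matches)` DP),
making the statistic deterministic and symmetric; an independent aligner
is the score oracle in the tests. Global rather than local alignment is
used because cloned amplicons are primer-bounded fragments of the same
region — note this presumes query and reference cover comparable spans;
a short fragment aligned globally to a much longer reference dilutes
identity with end gaps. The default assignment threshold of 93 % reflects
the lower end of intra-clade identity observed between cloned amplicons
and references; it is a configurable interpretation of an observed range,
not a published rule. Ties on identity resolve to the lexicographically
lower reference id.

## Synthetic data

`generate_clade_db` emulates a clade-annotated reference set: one random
consensus per clade, pairwise consensus divergence forced to a minimum
substitution count, members drawn by iid point substitutions at the intra-
clade rate. Planted primer sites are copied verbatim into every target-
clade sequence (mutations there are suppressed, preserving the
100 %-coverage guarantee) while non-target sequences are forced to carry a
minimum number of substitutions inside each site; with
`force_3prime_mismatch` they instead carry exactly one mismatch at the
primer's 3′-terminal position — the construction that separates 1MAM from
1MAM\*. Default shape (4 clades × 10 sequences × 800 bp, intra rate 0.02,
inter-clade divergence 40) mirrors a small multi-clade marker database;
tests use smaller instances sized for sub-second runs. Evolution is
substitution-only — no indels, no tree-structured descent, no chimeras —
so passing tests demonstrate the matching, ranking and bookkeeping
contracts, not robustness to indel-rich or recombinant natural sequence
variation. All randomness flows from one integer seed through numpy's
PCG64 generator; identical specs give byte-identical FASTA.

`simulate_ct` inverts the standard-curve model (Ct = intercept −
log₁₀(copies)/log₁₀(1+E) + Gaussian noise, detection ceiling Ct 40) with
the emulated assay design of six ten-fold levels (10³–10⁸ copies) × six
replicates, σ_Ct = 0.15. At that noise level the median absolute
efficiency-recovery error across 200 seeds is below one percentage point.

## Known limitations

- No thermodynamic (ΔG) off-target model, probe/TaqMan design, multiplex
  optimization, or genome-scale indexes; matching is exhaustive
  window scanning, appropriate for marker-gene databases of 10²–10⁴
  sequences.
- Whether mismatch *type* (purine–pyrimidine vs purine–purine) should be
  weighted in the allowance rule is not modeled; all incompatible pairs
  count equally.
- Specificity percentages use the non-target count as denominator.
- Measured quantities of a real assay — instrument efficiencies, observed
  interference fractions, community abundances — are inputs to this
  package, not things it can derive; fixtures reconstruct their
  bookkeeping only.
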