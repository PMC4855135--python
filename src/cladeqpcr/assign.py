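"""Clade assignment of cloned amplicon sequences by nearest-reference identity.

Cloned qPCR products are primer-bounded fragments of the reference region,
so queries are compared to references by optimal *global* alignment
(Needleman–Wunsch) rather than local search, which avoids spurious short
hits. Percent identity is matches over alignment columns (gaps included).

Because a score-optimal global alignment is generally not unique, identity
is made canonical by maximizing the number of matched columns among all
score-optimal alignments (a lexicographic (score, matches) dynamic
program). This makes ``global_identity`` deterministic and symmetric.

Default scoring: match +1, mismatch -1, gap -2 (linear). The default
assignment threshold of 93% identity reflects the intra-clade divergence
observed between cloned amplicons and their reference clades.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .iupac import normalize
from .refdb import ReferenceDatabase, SequenceRecord

__all__ = ["CladeAssignment", "global_identity", "assign_clade"]

DEFAULT_IDENTITY_THRESHOLD = 93.0


@dataclass
class CladeAssignment:
    query_id: str
    best_ref_id: str
    best_clade: str
    percent_identity: float
    assigned: bool


def _align_stats(
    a: str, b: str, match: int, mismatch: int, gap: int
) -> tuple[int, int, int]:
    """(optimal score, max matches among optimal alignments, alignment length).

    Single integer DP: each cell stores score*M + matches with
    0 <= matches < M, so integer comparison is lexicographic in
    (score, matches). A companion DP recovers the column count of one such
    alignment for the identity denominator.
    """
    n, m = len(a), len(b)
    M = max(n, m) + 1  # matches < M always
    gap_step = gap * M
    # combined value DP; cols[i][j] tracks alignment columns of the argmax path
    prev = [j * gap_step for j in range(m + 1)]
    prev_cols = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i * gap_step]
        cur_cols = [i]
        ai = a[i - 1]
        prev_row = prev
        for j in range(1, m + 1):
            if ai == b[j - 1]:
                diag = prev_row[j - 1] + match * M + 1
            else:
                diag = prev_row[j - 1] + mismatch * M
            up = prev_row[j] + gap_step
            left = cur[j - 1] + gap_step
            best = diag
            cols = prev_cols[j - 1] + 1
            if up > best:
                best, cols = up, prev_cols[j] + 1
            if left > best:
                best, cols = left, cur_cols[j - 1] + 1
            cur.append(best)
            cur_cols.append(cols)
        prev, prev_cols = cur, cur_cols
    combined = prev[m]
    score, matches = divmod(combined, M)  # floor division: matches in [0, M)
    return int(score), int(matches), int(prev_cols[m])


def global_identity(
    a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> float:
    """Percent identity of the optimal global alignment of ``a`` and ``b``.

    identity = matched columns / alignment length x 100, where the alignment
    maximizes score and, among score ties, the number of matched columns.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a = normalize(a)
    b = normalize(b)
    _, n_match, n_cols = _align_stats(a, b, match, mismatch, gap)
    return 100.0 * n_match / n_cols


def assign_clade(
    query: SequenceRecord | str,
    db: ReferenceDatabase,
    threshold_pct: float = DEFAULT_IDENTITY_THRESHOLD,
    query_id: str = "query",
) -> CladeAssignment:
    """Assign a query to the clade of its highest-identity reference.

    Ties on identity are broken by the lexicographically lower reference id.
    ``assigned`` is true iff the best identity reaches ``threshold_pct``.
    """
    if len(db) == 0:
        raise ValueError("reference database is empty")
    if isinstance(query, SequenceRecord):
        qid, qseq = query.id, query.seq
    else:
        qid, qseq = query_id, normalize(query)
    best: tuple[float, str, str] | None = None
    for rec in db:
        ident = global_identity(qseq, rec.seq)
        if best is None or ident > best[0] or (ident == best[0] and rec.id < best[1]):
            best = (ident, rec.id, rec.clade)
    ident, ref_id, clade = best
    return CladeAssignment(qid, ref_id, clade, ident, ident >= threshold_pct)
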