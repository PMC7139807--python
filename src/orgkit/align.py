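"""Seed-and-extend local nucleotide alignment with Karlin-Altschul E-values.

Two presets mirror the two search configurations used throughout the
package: a sensitive word-7 search for dispersed-repeat discovery within a
genome, and a fast word-28 search (MegaBLAST-like) for shared-DNA
quantification between genomes. Both are ordinary BLASTN-style pipelines:
exact word seeding, ungapped x-drop extension, then banded gapped x-drop
extension with affine gaps, followed by E-value filtering.

E-values use ungapped Karlin-Altschul parameters calibrated for the
match/mismatch pair by root-finding (lambda) and the lattice-case clump
series (K); this is a documented approximation for gapped scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.optimize import brentq

from .genome import GenomeRecord, Interval, revcomp

_NEG = -(10**9)


class CalibrationError(ValueError):
    """Scoring scheme cannot support local alignment statistics."""


@lru_cache(maxsize=32)
def karlin_altschul_params(
    match: int, mismatch: int, freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
) -> tuple[float, float, float]:
    """Ungapped (lambda, K, H) for a match/mismatch scheme.

    lambda solves sum_ij p_i p_j exp(lambda * s_ij) = 1 with lambda > 0;
    K comes from the lattice-score clump-size series
    sigma = sum_k (1/k) [P(S_k >= 0) + E(exp(lambda S_k); S_k < 0)],
    K = d * exp(-2 sigma) / (H * (1 - exp(-lambda d))).
    Requires negative expected score and a positive match reward.
    """
    p = np.asarray(freqs, dtype=float)
    if not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise CalibrationError("base frequencies must sum to 1")
    p_match = float(np.sum(p * p))
    probs = {match: p_match, mismatch: 1.0 - p_match}
    mean = sum(s * q for s, q in probs.items())
    if mean >= 0 or match <= 0 or mismatch >= 0:
        raise CalibrationError(
            f"degenerate scheme match={match} mismatch={mismatch}: "
            "expected score per aligned pair must be negative"
        )

    def f(lam: float) -> float:
        return sum(q * math.exp(lam * s) for s, q in probs.items()) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    lam = brentq(f, 1e-9, hi, xtol=1e-12)

    # relative entropy per aligned pair (nats)
    H = sum(s * q * math.exp(lam * s) for s, q in probs.items())

    d = math.gcd(abs(match), abs(mismatch))
    # distribution of partial sums S_k by repeated convolution on a lattice
    lo_s, hi_s = min(probs), max(probs)
    base = np.zeros(hi_s - lo_s + 1)
    for s, q in probs.items():
        base[s - lo_s] = q
    dist = np.array([1.0])
    offset = 0  # score of index 0 in `dist`
    sigma = 0.0
    for k in range(1, 400):
        dist = np.convolve(dist, base)
        offset += lo_s
        scores = offset + np.arange(dist.size)
        neg = scores < 0
        term = float(dist[~neg].sum()) + float(
            np.sum(dist[neg] * np.exp(lam * scores[neg]))
        )
        sigma += term / k
        if term / k < 1e-12 and k > 10:
            break
    K = d * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * d)))
    return lam, K, H


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring plus seeding and significance parameters.

    Gap cost for a run of g gaps is gap_open + g * gap_extend.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    word_size: int = 7
    evalue_cutoff: float = 1e-6
    xdrop: int | None = None  # default 20 * match
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0:
            raise CalibrationError("need match > 0 > mismatch")
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        karlin_altschul_params(self.match, self.mismatch, self.base_freqs)

    @property
    def ka(self) -> tuple[float, float, float]:
        return karlin_altschul_params(self.match, self.mismatch, self.base_freqs)

    @property
    def x_drop(self) -> int:
        return self.xdrop if self.xdrop is not None else 20 * self.match

    def evalue(self, score: float, m: int, n: int) -> float:
        """Expected chance alignments scoring >= score for an m x n search."""
        lam, K, _ = self.ka
        return K * m * n * math.exp(-lam * score)

    def min_significant_score(self, m: int, n: int, cutoff: float | None = None) -> float:
        cutoff = self.evalue_cutoff if cutoff is None else cutoff
        if cutoff is None or math.isinf(cutoff):
            return 0.0
        lam, K, _ = self.ka
        return math.log(K * m * n / cutoff) / lam


#: word 7, BLASTN-default scoring: dispersed-repeat discovery preset
SENSITIVE = ScoringScheme(match=2, mismatch=-3, gap_open=5, gap_extend=2,
                          word_size=7, evalue_cutoff=1e-6)
#: word 28, MegaBLAST-default scoring doubled to integers: shared-DNA preset
FAST = ScoringScheme(match=2, mismatch=-4, gap_open=0, gap_extend=5,
                     word_size=28, evalue_cutoff=1e-6)


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between a query and a subject sequence.

    Subject coordinates are always reported on the forward strand; a minus
    strand means the query aligns to the reverse complement of that
    subject interval. identity_pct counts gap columns in the denominator.
    """

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str
    score: int
    aligned_length: int
    identities: int
    mismatches: int
    gap_opens: int
    gap_columns: int
    evalue: float

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.identities / self.aligned_length

    @property
    def query_interval(self) -> Interval:
        return Interval(self.query_id, self.query_start, self.query_end, "+")

    @property
    def subject_interval(self) -> Interval:
        return Interval(self.subject_id, self.subject_start, self.subject_end, self.strand)


# ---------------------------------------------------------------------------
# extension engines

def _ungapped_extend(q: str, s: str, qi: int, sj: int, match: int, mismatch: int,
                     X: int) -> tuple[int, int, int]:
    """X-drop ungapped extension through anchor pair (qi, sj), 0-based.

    Returns (score, left_cols, right_cols): columns consumed left of the
    anchor and right of it (anchor base included in right_cols).
    """
    # rightward, anchor included
    best_r = 0
    score = 0
    i, j = qi, sj
    k = 0
    best_k = 0
    lq, ls = len(q), len(s)
    while i + k < lq and j + k < ls:
        a, b = q[i + k], s[j + k]
        score += match if (a == b and a != "N") else mismatch
        k += 1
        if score > best_r:
            best_r, best_k = score, k
        elif best_r - score > X:
            break
    right_cols = best_k
    # leftward
    best_l = 0
    score = 0
    k = 1
    best_k = 0
    while qi - k >= 0 and sj - k >= 0:
        a, b = q[qi - k], s[sj - k]
        score += match if (a == b and a != "N") else mismatch
        if score > best_l:
            best_l, best_k = score, k
        elif best_l - score > X:
            break
        k += 1
    return best_r + best_l, best_k, right_cols


@dataclass
class _Ext:
    score: int = 0
    ai: int = 0
    bj: int = 0
    identities: int = 0
    mismatches: int = 0
    gap_opens: int = 0
    gap_columns: int = 0

    @property
    def columns(self) -> int:
        return self.identities + self.mismatches + self.gap_columns


def _xdrop_gapped(a: str, b: str, match: int, mismatch: int, go: int, ge: int,
                  X: int) -> _Ext:
    """Banded affine-gap x-drop extension of a against b from their origins.

    Dynamic programming over prefixes, pruning every cell whose best score
    falls more than X below the running optimum; the surviving window per
    row stays narrow (off-diagonal excursions cost gap penalties), which is
    what keeps long organelle-tract extensions tractable. Traceback is kept
    as one byte per surviving cell.
    """
    la, lb = len(a), len(b)
    best, bi, bj = 0, 0, 0
    if la == 0 or lb == 0:
        return _Ext()
    # row 0: horizontal gaps from the origin
    lo_prev = 0
    H_prev = [0]
    F_prev = [_NEG]
    j = 1
    while j <= lb:
        v = -(go + ge * j)
        if v < best - X:
            break
        H_prev.append(v)
        F_prev.append(_NEG)
        j += 1
    hi_prev = len(H_prev) - 1  # inclusive j bound of row 0
    tb_rows: list[tuple[int, bytearray]] = []

    for i in range(1, la + 1):
        lo = lo_prev  # candidate window start
        hi_cap = min(lb, hi_prev + 1)
        H_row: list[int] = []
        F_row: list[int] = []
        tb = bytearray()
        E = _NEG
        new_lo = -1
        j = lo
        row_best = _NEG
        while True:
            if j > lb:
                break
            # vertical: consume a[i-1] against a gap
            Hup = H_prev[j - lo_prev] if lo_prev <= j <= hi_prev else _NEG
            Fup = F_prev[j - lo_prev] if lo_prev <= j <= hi_prev else _NEG
            f_open = Hup - go - ge
            f_ext = Fup - ge
            F = f_open if f_open >= f_ext else f_ext
            fbit = 0 if f_open >= f_ext else 1
            # diagonal
            if j >= 1 and lo_prev <= j - 1 <= hi_prev:
                Hd = H_prev[j - 1 - lo_prev]
            elif j == 0:
                Hd = _NEG
            else:
                Hd = _NEG
            if j >= 1 and Hd > _NEG // 2:
                ca, cb = a[i - 1], b[j - 1]
                diag = Hd + (match if (ca == cb and ca != "N") else mismatch)
            else:
                diag = _NEG
            # horizontal (E computed left-to-right within the row)
            H = diag
            src = 0
            if E > H:
                H, src = E, 1
            if F > H:
                H, src = F, 2
            cut = best - X
            ebit = 0
            if H < cut:
                H = _NEG
                src = 3
            if F < cut:
                F = _NEG
            viable = H > _NEG // 2 or F > _NEG // 2
            if viable and new_lo < 0:
                new_lo = j
            if new_lo >= 0:
                H_row.append(H)
                F_row.append(F)
            # update E for next cell
            e_open = H - go - ge
            e_ext = E - ge
            E = e_open if e_open >= e_ext else e_ext
            ebit = 0 if e_open >= e_ext else 1
            if E < cut:
                E = _NEG
            if new_lo >= 0:
                tb.append(src | (ebit << 2) | (fbit << 3))
            if H > row_best:
                row_best = H
            if H > best:
                best, bi, bj = H, i, j
            # stopping: past the previous row's reach and nothing viable
            if j >= hi_cap and H < cut and E < cut and F < cut:
                break
            j += 1
        if new_lo < 0:  # no surviving cell: extension exhausted
            break
        # trim dead tail
        while H_row and H_row[-1] < best - X and F_row[-1] < best - X:
            H_row.pop()
            F_row.pop()
            tb.pop()
        if not H_row:
            break
        lo_prev = new_lo
        hi_prev = new_lo + len(H_row) - 1
        H_prev, F_prev = H_row, F_row
        tb_rows.append((new_lo, tb))
        if la > 0 and lo_prev > lb:
            break

    ext = _Ext(score=best, ai=bi, bj=bj)
    # traceback from (bi, bj) to (0, 0); tb_rows[i-1] holds row i
    i, j = bi, bj
    state = "H"
    while i > 0 or j > 0:
        if i == 0:
            # remainder is the row-0 horizontal gap path from the origin
            ext.gap_columns += j
            ext.gap_opens += 1
            break
        lo, tb = tb_rows[i - 1]
        if state == "H":
            byte = tb[j - lo]
            src = byte & 3
            if src == 0:
                ca, cb = a[i - 1], b[j - 1]
                if ca == cb and ca != "N":
                    ext.identities += 1
                else:
                    ext.mismatches += 1
                i -= 1
                j -= 1
            elif src == 1:
                state = "E"
            elif src == 2:
                state = "F"
            else:  # pruned cell on path: numerical safety net
                break
        elif state == "E":
            # E(i, j) provenance is the ebit stored with cell (i, j-1)
            opened = ((tb[j - 1 - lo] >> 2) & 1) == 0
            ext.gap_columns += 1
            j -= 1
            if opened:
                ext.gap_opens += 1
                state = "H"
        else:  # F: provenance is the fbit stored with cell (i, j)
            opened = ((tb[j - lo] >> 3) & 1) == 0
            ext.gap_columns += 1
            i -= 1
            if opened:
                ext.gap_opens += 1
                state = "H"
            if i == 0:
                break
    return ext


def _sw_best(q: str, t: str, match: int, mismatch: int, go: int, ge: int) -> tuple[int, int, int]:
    """Exact affine-gap local-alignment optimum (score, end_i, end_j), 1-based ends.

    Row-vectorized Smith-Waterman; the horizontal gap state is resolved by a
    prefix-maximum scan, which is exact because opening a gap from a cell
    that itself ends in a horizontal gap is always dominated by extending.
    Used as a guaranteed-optimum pass on small search spaces.
    """
    m, n = len(q), len(t)
    tv = np.frombuffer(t.encode(), dtype=np.uint8)
    qv = np.frombuffer(q.encode(), dtype=np.uint8)
    N = ord("N")
    jid = np.arange(1, n + 1, dtype=np.int64)
    H_prev = np.zeros(n + 1, dtype=np.int64)
    F_prev = np.full(n + 1, _NEG, dtype=np.int64)
    best, bi, bj = 0, 0, 0
    oe = go + ge
    for i in range(1, m + 1):
        sub = np.where((tv == qv[i - 1]) & (tv != N), match, mismatch)
        F = np.maximum(H_prev - oe, F_prev - ge)
        H0 = np.zeros(n + 1, dtype=np.int64)
        np.maximum(H_prev[:-1] + sub, F[1:], out=H0[1:])
        np.maximum(H0, 0, out=H0)
        # horizontal gaps via prefix scan over H0
        A = np.maximum.accumulate(H0[:-1] + ge * np.arange(n, dtype=np.int64))
        E = A - go - ge * jid
        H = H0.copy()
        np.maximum(H[1:], E, out=H[1:])
        F[0] = _NEG
        row_max = int(H.max())
        if row_max > best:
            best = row_max
            bi = i
            bj = int(H.argmax())
        H_prev, F_prev = H, F
    return best, bi, bj


# ---------------------------------------------------------------------------
# seeding and the public alignment entry points

def _word_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue
        idx.setdefault(w, []).append(i)
    return idx


def _as_record(x: GenomeRecord | str, fallback_id: str) -> GenomeRecord:
    if isinstance(x, GenomeRecord):
        return x
    return GenomeRecord(id=fallback_id, sequence=x.upper())


def align_pair(
    query: GenomeRecord | str,
    subject: GenomeRecord | str,
    scheme: ScoringScheme = SENSITIVE,
    evalue_cutoff: float | None = None,
    min_len: int = 1,
    exclude_self_diagonal: bool = False,
    exact_cells: int = 1_000_000,
) -> list[AlignmentHit]:
    """All significant seed-and-extend local alignments on both strands.

    Hits are E-value filtered at `evalue_cutoff` (default: the scheme's
    cutoff; pass math.inf to disable), deduplicated on identical
    coordinates, and sorted by descending score then query start.
    `exclude_self_diagonal` suppresses the trivial full-length identity when
    a sequence is searched against itself.

    When the search space m*n is at most `exact_cells` (and the search is
    not a self-search), an exact Smith-Waterman pass per strand guarantees
    that the top reported hit is the true local optimum regardless of word
    seeding; seeding remains the scaling path for larger problems.
    """
    qrec = _as_record(query, "query")
    srec = _as_record(subject, "subject")
    q, s = qrec.sequence, srec.sequence
    m, n = len(q), len(s)
    k = scheme.word_size
    cutoff = scheme.evalue_cutoff if evalue_cutoff is None else evalue_cutoff
    s_min = scheme.min_significant_score(m, n, cutoff)
    trigger = 0.0 if s_min <= 0 else 0.5 * s_min
    X = scheme.x_drop
    hits: dict[tuple, AlignmentHit] = {}

    for strand in "+-":
        target = s if strand == "+" else revcomp(s)
        idx = _word_index(target, k)
        covered: dict[int, int] = {}  # diagonal -> query end already extended
        for qi in range(m - k + 1):
            w = q[qi : qi + k]
            positions = idx.get(w)
            if not positions:
                continue
            for sj in positions:
                diag = qi - sj
                if exclude_self_diagonal and strand == "+" and diag == 0:
                    continue
                if covered.get(diag, -1) >= qi:
                    continue
                u_score, l_cols, r_cols = _ungapped_extend(
                    q, target, qi, sj, scheme.match, scheme.mismatch, X
                )
                covered[diag] = qi + r_cols - 1
                if u_score < trigger:
                    continue
                right = _xdrop_gapped(
                    q[qi:], target[sj:], scheme.match, scheme.mismatch,
                    scheme.gap_open, scheme.gap_extend, X,
                )
                left = _xdrop_gapped(
                    q[:qi][::-1], target[:sj][::-1], scheme.match,
                    scheme.mismatch, scheme.gap_open, scheme.gap_extend, X,
                )
                score = right.score + left.score
                if score <= 0:
                    continue
                q0, q1 = qi - left.ai + 1, qi + right.ai
                t0, t1 = sj - left.bj + 1, sj + right.bj
                if q1 < q0 or t1 < t0:
                    continue
                covered[diag] = max(covered.get(diag, -1), q1 - 1)
                if exclude_self_diagonal and strand == "+" and (q0, q1) == (t0, t1):
                    continue
                ident = left.identities + right.identities
                mism = left.mismatches + right.mismatches
                gcols = left.gap_columns + right.gap_columns
                gopen = left.gap_opens + right.gap_opens
                cols = ident + mism + gcols
                if cols < min_len:
                    continue
                ev = scheme.evalue(score, m, n)
                if cutoff is not None and not math.isinf(cutoff) and ev > cutoff:
                    continue
                if strand == "+":
                    ss, se = t0, t1
                else:
                    ss, se = n - t1 + 1, n - t0 + 1
                key = (q0, q1, ss, se, strand)
                if key not in hits or hits[key].score < score:
                    hits[key] = AlignmentHit(
                        query_id=qrec.id, subject_id=srec.id,
                        query_start=q0, query_end=q1,
                        subject_start=ss, subject_end=se,
                        strand=strand, score=score,
                        aligned_length=cols, identities=ident,
                        mismatches=mism, gap_opens=gopen,
                        gap_columns=gcols, evalue=ev,
                    )
    if not exclude_self_diagonal and m * n <= exact_cells:
        for strand in "+-":
            target = s if strand == "+" else revcomp(s)
            best, bi, bj = _sw_best(
                q, target, scheme.match, scheme.mismatch,
                scheme.gap_open, scheme.gap_extend,
            )
            if best <= 0:
                continue
            back = _xdrop_gapped(
                q[:bi][::-1], target[:bj][::-1], scheme.match, scheme.mismatch,
                scheme.gap_open, scheme.gap_extend,
                X=best + scheme.gap_open + scheme.gap_extend + 1,
            )
            q0, q1 = bi - back.ai + 1, bi
            t0, t1 = bj - back.bj + 1, bj
            cols = back.columns
            if cols < min_len or q1 < q0:
                continue
            ev = scheme.evalue(back.score, m, n)
            if cutoff is not None and not math.isinf(cutoff) and ev > cutoff:
                continue
            if strand == "+":
                ss, se = t0, t1
            else:
                ss, se = n - t1 + 1, n - t0 + 1
            key = (q0, q1, ss, se, strand)
            if key not in hits or hits[key].score < back.score:
                hits[key] = AlignmentHit(
                    query_id=qrec.id, subject_id=srec.id,
                    query_start=q0, query_end=q1,
                    subject_start=ss, subject_end=se,
                    strand=strand, score=back.score,
                    aligned_length=cols, identities=back.identities,
                    mismatches=back.mismatches, gap_opens=back.gap_opens,
                    gap_columns=back.gap_columns, evalue=ev,
                )
    out = sorted(
        hits.values(),
        key=lambda h: (-h.score, h.query_start, h.subject_start, h.strand),
    )
    return out


def self_align(
    genome: GenomeRecord,
    scheme: ScoringScheme = SENSITIVE,
    min_len: int = 31,
    evalue_cutoff: float | None = None,
) -> list[AlignmentHit]:
    """Dispersed-repeat search: the genome against itself, both strands.

    The trivial full-length self-identity is excluded, as is any hit whose
    query and subject intervals coincide on the plus strand. Hits shorter
    than min_len aligned columns (default 31, i.e. repeats larger than
    30 bp) are dropped. Each repeat pair appears in both orientations.
    """
    if min_len < scheme.word_size:
        raise ValueError("min_len must be >= word size")
    return align_pair(
        genome, genome, scheme,
        evalue_cutoff=evalue_cutoff,
        min_len=min_len,
        exclude_self_diagonal=True,
    )


# ---------------------------------------------------------------------------
# tabular output (standard 12-column format)

_TSV_COLS = [
    "query_id", "subject_id", "identity_pct", "aligned_length", "mismatches",
    "gap_opens", "query_start", "query_end", "subject_start", "subject_end",
    "evalue", "score",
]


def hits_to_rows(hits: Iterable[AlignmentHit]) -> list[list]:
    rows = []
    for h in hits:
        ss, se = (h.subject_start, h.subject_end)
        if h.strand == "-":
            ss, se = se, ss  # minus hits conventionally report s.start > s.end
        rows.append([
            h.query_id, h.subject_id, round(h.identity_pct, 2),
            h.aligned_length, h.mismatches, h.gap_opens,
            h.query_start, h.query_end, ss, se,
            f"{h.evalue:.2e}", h.score,
        ])
    return rows


def write_hits_tsv(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLS) + "\n")
        for row in hits_to_rows(hits):
            fh.write("\t".join(str(x) for x in row) + "\n")
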