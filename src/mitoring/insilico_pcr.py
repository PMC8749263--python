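"""In-silico PCR on circular genomes with back-to-back primer geometry.

A single long-range PCR can amplify an entire mitochondrial ring when the
two primers bind adjacently on opposite strands with their 3' ends pointing
away from each other ("back-to-back").  The product then runs the long way
round the circle, and ``product_length + gap == L`` where ``gap`` is the
stretch of ring left between the two 5'-adjacent boundaries.

This module provides

* :func:`scan_primer` — find all tolerated binding sites of one primer on a
  ring.  A site is a semi-global alignment (primer fully consumed, template
  local) with unit-cost edit distance at most ``max_edits`` whose 3'-terminal
  bases match exactly — polymerase extension requires a matched 3' end, so
  mismatches and the occasional single-base template insertion are tolerated
  in the body of the footprint but never at the 3' terminus.
* :func:`pair_back_to_back` — combine forward/reverse sites into amplicon
  predictions using the circular geometry above.
* :func:`find_conserved_motifs` / :func:`design_back_to_back` — the inverse
  problem: scan a vertebrate alignment for low-degeneracy windows and split
  such a window into a back-to-back pair.

The published pan-vertebrate pair targeting the conserved stretch of
*MT-RNR2* is shipped as :data:`FORWARD_PRIMER` / :data:`REVERSE_PRIMER`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .mito_model import (
    CircularSequence,
    IUPAC_CODES,
    iupac_match,
    reverse_complement,
)

__all__ = [
    "FORWARD_PRIMER",
    "REVERSE_PRIMER",
    "Primer",
    "PrimerBindingSite",
    "AmpliconPrediction",
    "ConservedWindow",
    "scan_primer",
    "pair_back_to_back",
    "find_conserved_motifs",
    "design_back_to_back",
]

# The published pan-vertebrate back-to-back pair (5'->3').
FORWARD_PRIMER = "TACGTGATCTGAGTTCAGACCG"
REVERSE_PRIMER = "GTAGGACTTTAATCGTTGAACAAAC"


@dataclass(frozen=True)
class Primer:
    """A plain-ACGT oligo, 15-40 nt, written 5'->3'."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        seq = self.seq.upper().replace(" ", "")
        if not (15 <= len(seq) <= 40):
            raise ValueError(f"primer {self.name!r}: length must be 15-40 nt, got {len(seq)}")
        if set(seq) - set("ACGT"):
            raise ValueError(f"primer {self.name!r}: only plain ACGT allowed")
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PrimerBindingSite:
    """One primer's placement on the ring (span on the plus strand).

    ``insertions`` counts template bases inserted relative to the primer;
    ``deletions`` counts template bases missing.  Hence
    ``end - start == len(primer) + insertions - deletions`` (the span may
    wrap: ``end`` is kept ``> start`` and normalized modulo ``L`` for
    display).
    """

    primer: str
    strand: str
    start: int
    end: int
    mismatches: int
    insertions: int
    deletions: int
    three_prime_exact: bool

    @property
    def edits(self) -> int:
        return self.mismatches + self.insertions + self.deletions

    @property
    def span_length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AmpliconPrediction:
    """A single near-full-circle product predicted from a site pair."""

    fwd_site: PrimerBindingSite
    rev_site: PrimerBindingSite
    product_start: int
    product_end: int  # may exceed L (wrapping span)
    product_length: int
    gap: int

    @property
    def total_edits(self) -> int:
        return self.fwd_site.edits + self.rev_site.edits


@dataclass(frozen=True)
class ConservedWindow:
    """A low-degeneracy window of an alignment.

    ``score`` is the mean per-column count of distinct symbols, a gap in any
    row counting as one extra variant; 1.0 means perfectly invariant.
    """

    start: int
    end: int
    score: float
    column_variants: tuple[int, ...]
    n_rows: int
    consensus: str


# ---------------------------------------------------------------------------
# Primer scanning


def _iupac_masks() -> np.ndarray:
    masks = np.zeros(256, dtype=np.uint8)
    bit = {"A": 1, "C": 2, "G": 4, "T": 8}
    for code, expansion in IUPAC_CODES.items():
        m = 0
        for b in expansion:
            m |= bit[b]
        masks[ord(code)] = m
    return masks


_MASKS = _iupac_masks()


def _end_distances(query: str, text: str) -> np.ndarray:
    """Semi-global DP: best edit distance of the full query ending at each
    text position (free start).  Vectorized over the text axis; the
    insertion (horizontal) dependency is resolved with a min-plus prefix
    scan."""
    q = _MASKS[np.frombuffer(query.encode(), dtype=np.uint8)]
    t = _MASKS[np.frombuffer(text.encode(), dtype=np.uint8)]
    n = len(text)
    jidx = np.arange(n + 1, dtype=np.int32)
    prev = np.zeros(n + 1, dtype=np.int32)
    for i in range(1, len(query) + 1):
        sub = prev[:-1] + ((t & q[i - 1]) == 0)
        dele = prev[1:] + 1
        cur = np.empty(n + 1, dtype=np.int32)
        cur[0] = i
        cur[1:] = np.minimum(sub, dele)
        # cur[j] = min_{j'<=j} cur[j'] + (j - j')
        cur = jidx + np.minimum.accumulate(cur - jidx)
        prev = cur
    return prev[1:]  # distance for alignments ending just after text[j]


def _traceback(query: str, window: str) -> tuple[int, list[str]]:
    """Align the full query against a suffix of ``window`` (the alignment
    must end at the window's right edge; the start within the window is
    free).  Returns (start offset in window, op list) where ops are '=' 'X'
    'I' (template insertion) 'D' (template deletion).  Ties prefer
    diagonal, then template insertion, then template deletion."""
    m, n = len(query), len(window)
    D = np.zeros((m + 1, n + 1), dtype=np.int32)
    D[:, 0] = np.arange(m + 1)  # free start applies along row 0, not column 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            cost = 0 if iupac_match(query[i - 1], window[j - 1]) else 1
            D[i, j] = min(D[i - 1, j - 1] + cost, D[i - 1, j] + 1, D[i, j - 1] + 1)
    i, j = m, n
    ops: list[str] = []
    while i > 0:
        if j > 0:
            cost = 0 if iupac_match(query[i - 1], window[j - 1]) else 1
            if D[i, j] == D[i - 1, j - 1] + cost:
                ops.append("=" if cost == 0 else "X")
                i, j = i - 1, j - 1
                continue
        if j > 0 and D[i, j] == D[i, j - 1] + 1:
            ops.append("I")  # extra template base
            j -= 1
            continue
        ops.append("D")  # missing template base
        i -= 1
    ops.reverse()
    return j, ops


def _ops_profile(ops: Sequence[str]) -> tuple[int, int, int]:
    return ops.count("X"), ops.count("I"), ops.count("D")


def _three_prime_exact(ops: Sequence[str], window: int) -> bool:
    """The alignment must end in a run of >= ``window`` exact matches."""
    if window <= 0:
        return True
    run = 0
    for op in reversed(ops):
        if op == "=":
            run += 1
            if run >= window:
                return True
        else:
            return False
    return run >= window


def _scan_one_strand(
    template: str, L: int, primer: Primer, max_edits: int, three_prime_window: int
) -> list[tuple[int, int, tuple[int, int, int], bool]]:
    """Candidate sites as (start, end, (mm, ins, dele), tp_exact) in template
    coordinates (start taken modulo L for dedup across the wrap junction)."""
    m = len(primer)
    dist = _end_distances(primer.seq, template)
    ends = np.nonzero(dist <= max_edits)[0] + 1  # half-open end positions
    out = []
    seen: set[tuple[int, int]] = set()
    for end in ends:
        lo = max(0, end - m - max_edits)
        start_off, ops = _traceback(primer.seq, template[lo:end])
        start = lo + start_off
        if start >= L:  # duplicate of a site already visible before the junction
            continue
        if not _three_prime_exact(ops, three_prime_window):
            continue
        key = (start, int(end))
        if key in seen:
            continue
        seen.add(key)
        out.append((start, int(end), _ops_profile(ops), True))
    return out


def _cluster_best(
    cands: list[tuple[int, int, tuple[int, int, int], bool]], L: int
) -> list[tuple[int, int, tuple[int, int, int], bool]]:
    """Keep the best candidate per group of mutually overlapping spans:
    sort by (edits, start) and greedily drop candidates overlapping an
    accepted span (circular overlap)."""

    def edits(c):
        return sum(c[2])

    accepted: list[tuple[int, int]] = []
    kept = []
    for c in sorted(cands, key=lambda c: (edits(c), c[0])):
        s, e = c[0], c[1]
        overlap = False
        for (as_, ae) in accepted:
            # compare on the doubled axis to handle wraps
            for shift in (-L, 0, L):
                if s + shift < ae and as_ < e + shift:
                    overlap = True
                    break
            if overlap:
                break
        if not overlap:
            accepted.append((s, e))
            kept.append(c)
    return kept


def scan_primer(
    g: CircularSequence,
    p: Primer,
    max_edits: int = 2,
    three_prime_window: int = 3,
) -> list[PrimerBindingSite]:
    """All tolerated binding sites of ``p`` on either strand of ``g``.

    Sites are semi-global alignments (primer fully consumed, template
    local, unit edit costs) with at most ``max_edits`` edits whose final
    ``three_prime_window`` primer bases align as exact matches.  The search
    wraps the origin on circular genomes.  Overlapping alternative
    placements are reduced to the best one (fewest edits, then smallest
    start).  IUPAC ambiguity codes in the template match their expansion
    sets.  Sites are returned sorted by (edits, start); minus-strand spans
    are reported on the plus strand.
    """
    if max_edits < 0 or three_prime_window < 0:
        raise ValueError("max_edits and three_prime_window must be >= 0")
    L = g.length
    m = len(p)
    if m > L:
        raise ValueError(f"primer {p.name!r} ({m} nt) longer than genome ({L} nt)")
    overhang = min(L, m + max_edits) if g.circular else 0

    sites: list[PrimerBindingSite] = []
    for strand in ("+", "-"):
        base = g.seq if strand == "+" else reverse_complement(g.seq)
        template = base + base[:overhang]
        cands = _cluster_best(
            _scan_one_strand(template, L, p, max_edits, three_prime_window), L
        )
        for start, end, (mm, ins, dele), tp in cands:
            start, end = int(start), int(end)
            if strand == "+":
                s0, e0 = start, end
            else:
                span = end - start
                s0 = (L - end) % L
                e0 = s0 + span
            sites.append(
                PrimerBindingSite(
                    primer=p.name,
                    strand=strand,
                    start=s0,
                    end=e0,
                    mismatches=mm,
                    insertions=ins,
                    deletions=dele,
                    three_prime_exact=tp,
                )
            )
    sites.sort(key=lambda s: (s.edits, s.start % L, s.strand))
    return sites


# ---------------------------------------------------------------------------
# Back-to-back pairing


def pair_back_to_back(
    sites_fwd: Sequence[PrimerBindingSite],
    sites_rev: Sequence[PrimerBindingSite],
    L: int,
    max_gap: int = 50,
) -> list[AmpliconPrediction]:
    """Combine forward/reverse sites into single-product predictions.

    A valid pair has the two sites on opposite strands with 3' ends facing
    away from each other around the ring.  Writing ``P`` for the plus-strand
    site and ``M`` for the minus-strand site, the two 5'-adjacent boundaries
    are ``P.start`` and ``M.end``; ``gap = (P.start - M.end) mod L`` and the
    product runs from ``P.start`` the long way round to ``M.end``, so
    ``product_length + gap == L`` always.  Pairs whose 3' ends face each
    other give a near-``L`` gap and are rejected by ``max_gap``.  Results
    are sorted by (total edits, gap, position).
    """
    out: list[AmpliconPrediction] = []
    for a in sites_fwd:
        for b in sites_rev:
            if a.strand == b.strand:
                continue
            plus, minus = (a, b) if a.strand == "+" else (b, a)
            gap = (plus.start - (minus.end % L)) % L
            if gap > max_gap:
                continue
            product_length = L - gap
            out.append(
                AmpliconPrediction(
                    fwd_site=a,
                    rev_site=b,
                    product_start=plus.start,
                    product_end=plus.start + product_length,
                    product_length=product_length,
                    gap=gap,
                )
            )
    out.sort(key=lambda p: (p.total_edits, p.gap, p.product_start))
    return out


# ---------------------------------------------------------------------------
# Conserved-window discovery and primer design


def find_conserved_motifs(
    alignment: Sequence[str], window_len: int, top_k: int = 5
) -> list[ConservedWindow]:
    """Sliding-window degeneracy scan of a multiple alignment.

    Each column is scored by its number of distinct bases, any gap adding
    one extra variant; a window's score is the mean over its columns (1.0 =
    perfectly invariant).  Returns the ``top_k`` lowest-scoring windows,
    ties broken by leftmost column; overlapping windows are suppressed so
    the returned set is non-redundant.
    """
    rows = [r.upper() for r in alignment]
    if len(rows) < 2:
        raise ValueError("alignment needs at least 2 rows")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("alignment rows differ in length")
    if window_len > ncol:
        raise ValueError(f"window ({window_len}) longer than alignment ({ncol})")

    mat = np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in rows])
    gap_codes = (mat == ord("-")) | (mat == ord("."))
    variants = np.zeros(ncol, dtype=np.int32)
    for code in np.unique(mat):
        if chr(code) in {"-", "."}:
            continue
        variants += (mat == code).any(axis=0)
    variants += gap_codes.any(axis=0)

    csum = np.concatenate([[0], np.cumsum(variants)])
    scores = (csum[window_len:] - csum[:-window_len]) / window_len

    order = np.argsort(scores, kind="stable")
    chosen: list[int] = []
    for c0 in order:
        if any(abs(int(c0) - prev) < window_len for prev in chosen):
            continue
        chosen.append(int(c0))
        if len(chosen) == top_k:
            break

    out = []
    for c0 in chosen:
        cols = mat[:, c0 : c0 + window_len]
        consensus = []
        for j in range(window_len):
            col = cols[:, j]
            vals, counts = np.unique(col[(col != ord("-")) & (col != ord("."))], return_counts=True)
            consensus.append(chr(vals[np.argmax(counts)]) if len(vals) else "N")
        out.append(
            ConservedWindow(
                start=c0,
                end=c0 + window_len,
                score=float(scores[c0]),
                column_variants=tuple(int(v) for v in variants[c0 : c0 + window_len]),
                n_rows=len(rows),
                consensus="".join(consensus),
            )
        )
    return out


def design_back_to_back(
    consensus: str,
    window: ConservedWindow | None = None,
    fwd_len: int = 22,
    rev_len: int = 25,
    junction: int | None = None,
) -> tuple[Primer, Primer]:
    """Split a conserved window into a back-to-back primer pair.

    The window is cut at an internal junction: the reverse-orientation
    primer is the reverse complement of the ``rev_len`` bases ending at the
    junction, and the forward primer is the ``fwd_len`` bases starting at
    it, so both 3' ends face outward from the junction.  ``junction``
    defaults to the window midpoint; both primers are returned 5'->3'.
    """
    w = consensus[window.start : window.end] if window is not None else consensus
    w = w.upper().replace("-", "")
    if len(w) < fwd_len + rev_len:
        raise ValueError(
            f"window of {len(w)} nt too short for {rev_len}+{fwd_len} nt primers"
        )
    j = len(w) // 2 if junction is None else junction
    if j - rev_len < 0 or j + fwd_len > len(w):
        raise ValueError(f"junction {j} leaves no room for the primers")
    rev = Primer("rev", reverse_complement(w[j - rev_len : j]))
    fwd = Primer("fwd", w[j : j + fwd_len])
    return fwd, rev
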