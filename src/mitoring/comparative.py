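"""Pairwise divergence, species delimitation and candidate-site screening.

Divergence here is the uncorrected p-distance: substitutions counted over
mutually ungapped columns of a global pairwise alignment, gap columns
excluded from both numerator and denominator.  The control region (NCR) is
the fastest-evolving, repeat-laden part of the mitogenome and is excluded
by default from whole-mitogenome comparisons, following the usual practice
of avoiding it for phylogenetic purposes; a flag restores full-length
comparison and both values can be reported side by side.

The Genetic Species Concept flags two lineages as distinct species when
their *MT-CYB* p-distance exceeds 11% (strict inequality).

Candidate amino-acid sites (e.g. the cold-adaptation polymorphisms in
*MT-ATP6*/*MT-ND3*/*MT-ND4*, or the high-altitude *MT-ND1* Y30C/H change)
are called by anchoring a reference gene on the genome, codon-aligning in
nucleotide space, and translating the target codon under the vertebrate
mitochondrial code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .mdp_scan import VERTEBRATE_MITO_CODE
from .mito_model import CircularSequence, FeatureAnnotation, circular_slice, reverse_complement

__all__ = [
    "SPECIES_THRESHOLD_PCT",
    "DivergenceResult",
    "CandidateSiteSpec",
    "SiteCall",
    "p_distance",
    "species_flag",
    "call_candidate_site",
    "group_contrast",
]

# MT-CYB divergence above which two lineages are flagged as distinct
# species under the Genetic Species Concept.
SPECIES_THRESHOLD_PCT = 11.0


@dataclass(frozen=True)
class DivergenceResult:
    """Aligned-column identity/divergence between two sequences."""

    id_a: str
    id_b: str
    aligned_columns: int
    differing_columns: int
    gap_columns: int
    excluded: tuple[str, ...] = ()
    region: str = "whole"

    @property
    def compared_columns(self) -> int:
        return self.aligned_columns - self.gap_columns

    @property
    def divergence(self) -> float:
        if self.compared_columns == 0:
            raise ValueError("no comparable columns")
        return 100.0 * self.differing_columns / self.compared_columns

    @property
    def identity(self) -> float:
        return 100.0 - self.divergence


_INF = np.int32(1 << 28)

# Gotoh costs (integers; minimization): a gap must be much more expensive
# than a substitution, otherwise the aligner trades runs of substitutions
# between co-linear genomes for spurious indel pairs and the p-distance is
# biased downwards.
_MATCH, _MISMATCH, _GAP_OPEN, _GAP_EXTEND = 0, 3, 12, 2


def _iupac_codes() -> np.ndarray:
    from .mito_model import IUPAC_CODES

    masks = np.zeros(256, dtype=np.uint8)
    bit = {"A": 1, "C": 2, "G": 4, "T": 8}
    for code, expansion in IUPAC_CODES.items():
        m = 0
        for b in expansion:
            m |= bit[b]
        masks[ord(code)] = m
    return masks


_MASKS = _iupac_codes()


def global_affine_align(a: str, b: str, band: int | None = None) -> str:
    """Banded global alignment with affine gap costs (Gotoh), returning an
    op string over '=', 'X', 'I' (base only in ``a``), 'D' (base only in
    ``b``).

    Mitogenome haplotypes and orthologous genes are co-linear, so the
    optimal path stays near the main diagonal; the band (default 100 nt
    plus the length difference) makes the alignment O(L * band) in time
    and memory.  IUPAC ambiguity codes match their expansion sets.
    """
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return "I" * la + "D" * lb
    if band is None:
        band = 100
    lo = -(band + max(0, la - lb))  # k = j - i in [lo, hi]
    hi = band + max(0, lb - la)
    W = hi - lo + 1
    av = _MASKS[np.frombuffer(a.encode(), dtype=np.uint8)]
    bv = _MASKS[np.frombuffer(b.encode(), dtype=np.uint8)]

    M = np.full((la + 1, W), _INF, dtype=np.int32)
    X = np.full((la + 1, W), _INF, dtype=np.int32)  # gap in b (consumes a)
    Y = np.full((la + 1, W), _INF, dtype=np.int32)  # gap in a (consumes b)
    k0 = -lo  # band index of j == i
    M[0, k0] = 0
    for j in range(1, min(lb, hi) + 1):
        Y[0, k0 + j] = _GAP_OPEN + _GAP_EXTEND * (j - 1)

    kidx = np.arange(W, dtype=np.int32)
    for i in range(1, la + 1):
        jlo = max(0, i + lo)
        jhi = min(lb, i + hi)
        if jlo > jhi:
            raise ValueError("alignment band exhausted; increase band")
        ks = jlo - i - lo
        ke = jhi - i - lo  # inclusive band indices with valid j
        js = np.arange(jlo, jhi + 1)
        valid = slice(ks, ke + 1)

        best_prev = np.minimum(np.minimum(M[i - 1], X[i - 1]), Y[i - 1])
        sub = np.full(W, _INF, dtype=np.int32)
        # diagonal (i-1, j-1) sits at the same band index
        jmask = js >= 1
        cost = np.where((av[i - 1] & bv[js[jmask] - 1]) != 0, _MATCH, _MISMATCH)
        sub_vals = best_prev[valid][jmask]
        sub[ks : ke + 1][jmask] = np.where(
            sub_vals >= _INF, _INF, sub_vals + cost
        )
        M[i, valid] = sub[valid]

        # vertical: from (i-1, j) at band index k+1
        up_m = np.full(W, _INF, dtype=np.int32)
        up_x = np.full(W, _INF, dtype=np.int32)
        up_m[:-1] = M[i - 1, 1:]
        up_x[:-1] = X[i - 1, 1:]
        X[i] = np.minimum(
            np.where(up_m >= _INF, _INF, up_m + _GAP_OPEN),
            np.where(up_x >= _INF, _INF, up_x + _GAP_EXTEND),
        )

        # horizontal: Y[i][k] = min(M[i][k-1]+open, Y[i][k-1]+ext)
        # resolved with a min-accumulate over (M + open - ext*(k+1))
        c = np.where(M[i] >= _INF, _INF, M[i] + _GAP_OPEN - _GAP_EXTEND * (kidx + 1))
        acc = np.minimum.accumulate(c)
        Y[i, 1:] = np.minimum(
            np.where(acc[:-1] >= _INF // 2, _INF, acc[:-1] + _GAP_EXTEND * kidx[1:]),
            _INF,
        )
        # mask out-of-range js
        if ks > 0:
            M[i, :ks] = X[i, :ks] = Y[i, :ks] = _INF
        if ke + 1 < W:
            M[i, ke + 1 :] = X[i, ke + 1 :] = Y[i, ke + 1 :] = _INF

    # traceback
    i, j = la, lb
    k = j - i - lo
    layer = int(np.argmin([M[i, k], X[i, k], Y[i, k]]))
    ops: list[str] = []
    while i > 0 or j > 0:
        k = j - i - lo
        if i == 0:
            ops.append("D")
            j -= 1
            continue
        if j == 0:
            ops.append("I")
            i -= 1
            continue
        if layer == 0:
            cost = _MATCH if (av[i - 1] & bv[j - 1]) != 0 else _MISMATCH
            ops.append("=" if cost == _MATCH else "X")
            i, j = i - 1, j - 1
            k = j - i - lo
            layer = int(np.argmin([M[i, k], X[i, k], Y[i, k]]))
        elif layer == 1:
            ops.append("I")
            if X[i, k] == (M[i - 1, k + 1] + _GAP_OPEN if M[i - 1, k + 1] < _INF else _INF):
                layer = 0
            i -= 1
        else:
            ops.append("D")
            if Y[i, k] == (M[i, k - 1] + _GAP_OPEN if M[i, k - 1] < _INF else _INF):
                layer = 0
            j -= 1
    ops.reverse()
    return "".join(ops)


def _alignment_counts(a: str, b: str, band: int | None = None) -> tuple[int, int, int]:
    """(aligned, differing, gap) column counts of the affine global
    alignment of ``a`` and ``b``."""
    ops = global_affine_align(a, b, band=band)
    aligned = len(ops)
    differing = ops.count("X")
    gaps = ops.count("I") + ops.count("D")
    return aligned, differing, gaps


def _excise(
    g: CircularSequence, annotations: Sequence[FeatureAnnotation] | None, name: str
) -> str:
    feats = [f for f in (annotations or []) if f.name == name]
    if not feats:
        raise ValueError(f"{g.id!r}: no annotation named {name!r} to exclude")
    f = feats[0]
    L = g.length
    # keep everything outside the feature, reading around the ring
    out_start = f.end % L
    out_len = L - f.span_length
    if out_len <= 0:
        raise ValueError(f"{g.id!r}: excluding {name!r} leaves an empty sequence")
    return circular_slice(g, out_start, out_start + out_len)


def _gene_slice(
    g: CircularSequence,
    annotations: Sequence[FeatureAnnotation] | None,
    gene: str,
    reference_nt: str | None = None,
) -> str:
    feats = [f for f in (annotations or []) if f.name == gene]
    if feats:
        f = feats[0]
        s = circular_slice(g, f.start % g.length, (f.start % g.length) + f.span_length)
        return reverse_complement(s) if f.strand == "-" else s
    if reference_nt is None:
        raise ValueError(f"{g.id!r}: gene {gene!r} not annotated and no reference given")
    hit = _locate_gene(g, reference_nt)
    if hit is None:
        raise ValueError(f"{g.id!r}: gene {gene!r} could not be located by homology")
    _, seq, _, _ = hit
    return seq


def _locate_gene(
    g: CircularSequence, reference_nt: str, min_identity: float = 60.0
) -> tuple[str, str, int, float] | None:
    """Best infix placement of a reference gene on either strand.

    Returns (strand, matched subsequence in gene reading sense, start on
    the oriented strand, identity%) or None below ``min_identity``."""
    best = None
    L = g.length
    for strand in ("+", "-"):
        base = g.seq if strand == "+" else reverse_complement(g.seq)
        text = base + base[: min(L, len(reference_nt) // 2)] if g.circular else base
        res = edlib.align(reference_nt, text, mode="HW", task="locations")
        if res["editDistance"] < 0:
            continue
        loc = next((se for se in res["locations"] if se[0] is not None and se[0] < L), None)
        if loc is None:
            continue
        cand = (res["editDistance"], 0 if strand == "+" else 1, strand, base, loc)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        return None
    dist, _, strand, base, (s, e_incl) = best
    identity = 100.0 * (1 - dist / len(reference_nt))
    if identity < min_identity:
        return None
    doubled = base + base if g.circular else base
    return strand, doubled[s : e_incl + 1], s, identity


def p_distance(
    a: CircularSequence,
    b: CircularSequence,
    annotations_a: Sequence[FeatureAnnotation] | None = None,
    annotations_b: Sequence[FeatureAnnotation] | None = None,
    exclude: str | None = None,
    gene: str | None = None,
    reference_gene_nt: str | None = None,
) -> DivergenceResult:
    """Uncorrected pairwise divergence between two genomes.

    With ``gene`` set, the comparison is restricted to that gene (sliced
    from annotations, or located by homology against ``reference_gene_nt``
    in the unannotated genome).  With ``exclude`` set (typically ``NCR``),
    the named region is excised from both genomes before alignment.  The
    two options are mutually exclusive.  Both genomes are assumed
    rotation-normalized (see :func:`mitoring.mito_model.rotate_to_anchor`);
    gene-restricted comparisons are rotation-independent by construction.
    """
    if exclude and gene:
        raise ValueError("exclude and gene are mutually exclusive")
    if gene:
        sa = _gene_slice(a, annotations_a, gene, reference_gene_nt)
        sb = _gene_slice(b, annotations_b, gene, reference_gene_nt)
        region = gene
        excluded: tuple[str, ...] = ()
    elif exclude:
        sa = _excise(a, annotations_a, exclude)
        sb = _excise(b, annotations_b, exclude)
        region = "whole"
        excluded = (exclude,)
    else:
        sa, sb = a.seq, b.seq
        region = "whole"
        excluded = ()
    if not sa or not sb:
        raise ValueError("empty sequence after region exclusion")
    aligned, differing, gaps = _alignment_counts(sa, sb)
    return DivergenceResult(
        id_a=a.id,
        id_b=b.id,
        aligned_columns=aligned,
        differing_columns=differing,
        gap_columns=gaps,
        excluded=excluded,
        region=region,
    )


def species_flag(mtcyb_divergence_percent: float) -> bool:
    """Genetic Species Concept call: True iff MT-CYB divergence > 11%."""
    if not 0.0 <= mtcyb_divergence_percent <= 100.0:
        raise ValueError("divergence must be a percentage in [0, 100]")
    return mtcyb_divergence_percent > SPECIES_THRESHOLD_PCT


# ---------------------------------------------------------------------------
# Candidate amino-acid sites


@dataclass(frozen=True)
class CandidateSiteSpec:
    """A candidate amino-acid site, codon-indexed on a reference protein."""

    gene: str
    codon: int  # 1-based
    reference_residue: str | None = None
    variant_residues: tuple[str, ...] = ()
    phenotype: str = ""
    human_position: int | None = None

    def __post_init__(self) -> None:
        if self.codon < 1:
            raise ValueError("codon index is 1-based and must be >= 1")
        valid = set("ACDEFGHIKLMNPQRSTVWY")
        for r in (self.reference_residue, *self.variant_residues):
            if r is not None and r not in valid:
                raise ValueError(f"invalid amino acid {r!r}")


@dataclass(frozen=True)
class SiteCall:
    gene: str
    codon: int
    genome_id: str
    residue: str | None
    status: str  # called | uncallable
    reason: str = ""
    identity: float = 0.0


def call_candidate_site(
    g: CircularSequence,
    site: CandidateSiteSpec,
    reference_gene_nt: str,
    min_identity: float = 60.0,
) -> SiteCall:
    """Call the residue at a candidate codon of one genome.

    The reference gene is anchored by best infix alignment on either
    strand; the target codon's three reference bases are then mapped
    through a global nucleotide alignment and must land on three
    consecutive, gap-free target bases (otherwise the site is uncallable
    with the reason recorded).  The codon is translated under the
    vertebrate mitochondrial code.
    """
    ref = reference_gene_nt.upper()
    if len(ref) < 3 * site.codon:
        raise ValueError(
            f"reference gene ({len(ref)} nt) does not contain codon {site.codon}"
        )
    hit = _locate_gene(g, ref, min_identity=min_identity)
    if hit is None:
        return SiteCall(site.gene, site.codon, g.id, None, "uncallable", "anchor identity below threshold")
    _, target, _, identity = hit

    ops = global_affine_align(ref, target)
    qpos = tpos = 0
    codon_cols: list[int | None] = [None, None, None]
    q0 = 3 * (site.codon - 1)
    for ch in ops:
        if ch in "=X":
            if q0 <= qpos < q0 + 3:
                codon_cols[qpos - q0] = tpos
            qpos += 1
            tpos += 1
        elif ch == "I":  # reference base absent from target
            qpos += 1
        elif ch == "D":
            tpos += 1
    if any(c is None for c in codon_cols) or not (
        codon_cols[1] == codon_cols[0] + 1 and codon_cols[2] == codon_cols[1] + 1
    ):
        return SiteCall(
            site.gene, site.codon, g.id, None, "uncallable",
            "frame-breaking alignment at the codon", identity,
        )
    codon = target[codon_cols[0] : codon_cols[0] + 3]
    residue = VERTEBRATE_MITO_CODE.aa(codon)
    return SiteCall(site.gene, site.codon, g.id, residue, "called", "", identity)


def group_contrast(
    calls: Sequence[SiteCall],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Residue counts per (site, group) — a descriptive contingency table.

    No inferential statistics are attached: with modest group sizes the
    question is whether any residue segregates cleanly with a phenotype
    group, which is read directly off the table.
    """
    rows = []
    for c in calls:
        if c.genome_id not in groups:
            raise ValueError(f"genome {c.genome_id!r} has no group assignment")
        rows.append(
            {
                "site": f"{c.gene}:{c.codon}",
                "group": groups[c.genome_id],
                "residue": c.residue if c.residue is not None else "uncallable",
            }
        )
    df = pd.DataFrame(rows)
    table = (
        df.groupby(["site", "group", "residue"]).size().unstack("residue", fill_value=0)
    )
    return table.sort_index()
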