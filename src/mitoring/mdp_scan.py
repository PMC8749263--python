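"""sORF-encoded mitochondrial-derived peptide (MDP) prediction.

MDPs (MOTS-c, humanin, SHLP1-6, gau) are micropeptides encoded by short
open reading frames nested inside mitochondrial genes: MOTS-c in *MT-RNR1*,
humanin and the SHLPs in *MT-RNR2*, and gau on the antisense strand of
*MT-CO1*.  Although transcribed inside the mitochondrion, they are held to
be translated in the cytoplasm under the standard (nuclear) genetic code —
so prediction here defaults to NCBI translation table 1 with ATG as the
only start.  gau's first codon is ATA, which is a start only under the
vertebrate-mitochondrial repertoire; :func:`gau_extended_scan` re-runs the
scan with that extended start set.

An sORF call proceeds in three steps: a reference sORF from the shipped
catalog is anchored on the genome by local alignment (:func:`locate_locus`),
all start-to-stop ORFs in the anchored window are enumerated
(:func:`scan_sorfs`), and the locus is classified against the reference
(:func:`classify_mdp`) as ``intact``, ``absent_no_start`` (start codon
lost), ``premature_stop`` or ``frameshift`` — the three recognised modes of
sORF pseudogenization — or ``not_locatable`` when no credible homologous
window exists at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import edlib
import pandas as pd
from Bio import Align
from Bio.Data import CodonTable

from .mito_model import CircularSequence, reverse_complement

__all__ = [
    "GeneticCode",
    "STANDARD_CODE",
    "VERTEBRATE_MITO_CODE",
    "EXTENDED_STARTS",
    "genetic_code",
    "TranslationResult",
    "translate",
    "LocusSpec",
    "LocusHit",
    "SorfRecord",
    "MdpMatrix",
    "locate_locus",
    "scan_sorfs",
    "classify_mdp",
    "predict_mdp",
    "gau_extended_scan",
    "build_conservation_matrix",
    "conserved_core",
]

# Vertebrate-mitochondrial start-codon repertoire used when the start set
# is "extended" beyond the cytoplasmic ATG.
EXTENDED_STARTS = frozenset({"ATG", "ATA", "ATT", "ATC", "GTG"})

MIN_SORF_LEN = 8  # residues; arbitrary floor below which an ORF is not an sORF
MAX_SORF_LEN = 40  # residues; upper bound of the putative mitochondrial sORFome


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry codon table plus a start-codon set.

    ``table`` maps every sense codon to its one-letter residue and every
    terminator to ``*``.
    """

    name: str
    table: dict[str, str]
    start_set: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"codon table {self.name!r} has {len(self.table)} entries, need 64")
        if not self.start_set:
            raise ValueError(f"codon table {self.name!r} has an empty start set")

    def aa(self, codon: str) -> str:
        """Residue for a codon; any ambiguity symbol yields ``X``."""
        return self.table.get(codon, "X")

    def with_starts(self, starts: Iterable[str]) -> "GeneticCode":
        return replace(self, start_set=frozenset(s.upper() for s in starts))


def _from_ncbi(name: str, ncbi_id: int, starts: Iterable[str]) -> GeneticCode:
    t = CodonTable.unambiguous_dna_by_id[ncbi_id]
    table = dict(t.forward_table)
    for stop in t.stop_codons:
        table[stop] = "*"
    return GeneticCode(name=name, table=table, start_set=frozenset(starts))


# Cytoplasmic translation: table 1 with ATG as the only start (the TTG/CTG
# bacterial-style starts listed by NCBI are not used for MDP prediction).
STANDARD_CODE = _from_ncbi("standard", 1, {"ATG"})
VERTEBRATE_MITO_CODE = _from_ncbi("vertebrate_mito", 2, EXTENDED_STARTS)

_CODES = {"standard": STANDARD_CODE, "vertebrate_mito": VERTEBRATE_MITO_CODE}


def genetic_code(name: str) -> GeneticCode:
    try:
        return _CODES[name]
    except KeyError:
        raise ValueError(f"unknown genetic code {name!r}; choose from {sorted(_CODES)}")


@dataclass(frozen=True)
class TranslationResult:
    peptide: str
    status: str  # ok | absent_no_start
    start_index: int | None  # nt offset of the start codon, in-frame from 0
    stop_found: bool


def translate(
    nt: str,
    code: GeneticCode,
    start_policy: str = "require_listed_start",
    start_set: frozenset[str] | None = None,
) -> TranslationResult:
    """Translate ``nt`` in frame 0.

    With ``require_listed_start`` the first in-frame codon from the start
    set opens the reading frame (reported as M regardless of the codon);
    with ``no_start_required`` translation simply begins at position 0.
    Translation stops at the first terminator; a codon containing an
    ambiguity symbol translates to ``X`` (and cannot serve as a start).
    """
    nt = nt.upper()
    if len(nt) < 3:
        raise ValueError("need at least one codon")
    starts = start_set if start_set is not None else code.start_set
    begin = 0
    if start_policy == "require_listed_start":
        begin = None
        for p in range(0, len(nt) - 2, 3):
            if nt[p : p + 3] in starts:
                begin = p
                break
        if begin is None:
            return TranslationResult("", "absent_no_start", None, False)
    elif start_policy != "no_start_required":
        raise ValueError(f"unknown start policy {start_policy!r}")

    residues: list[str] = []
    stop_found = False
    for p in range(begin, len(nt) - 2, 3):
        aa = code.aa(nt[p : p + 3])
        if aa == "*":
            stop_found = True
            break
        residues.append(aa)
    if residues and start_policy == "require_listed_start":
        residues[0] = "M"
    return TranslationResult("".join(residues), "ok", begin, stop_found)


# ---------------------------------------------------------------------------
# Locus model


@dataclass(frozen=True)
class LocusSpec:
    """One catalog entry: a reference sORF and how to read it."""

    mdp_name: str
    host_gene: str
    nt: str
    sense: str = "host-sense"  # reading direction relative to the host gene
    peptide: str = ""
    code: str = "standard"
    start_policy: str = "require_listed_start"

    def __post_init__(self) -> None:
        if len(self.nt) < 24:
            raise ValueError(f"{self.mdp_name}: reference sORF must be >= 24 nt")
        starts = EXTENDED_STARTS if self.start_policy == "extended_starts" else None
        res = translate(self.nt, genetic_code(self.code), "require_listed_start", starts)
        if self.peptide and res.peptide != self.peptide:
            raise ValueError(
                f"{self.mdp_name}: reference nt does not translate to stated peptide "
                f"({res.peptide!r} != {self.peptide!r})"
            )

    @property
    def start_set(self) -> frozenset[str]:
        if self.start_policy == "extended_starts":
            return EXTENDED_STARTS
        return genetic_code(self.code).start_set


@dataclass(frozen=True)
class LocusHit:
    """Best placement of a reference sORF on a genome.

    ``window_nt`` is the hit padded by ``flank`` nt on each side, oriented
    in the sORF reading sense; ``ref_offset`` is the window position the
    reference's first base aligns to.  ``start``/``end`` give the hit span
    on the genome plus strand (``end`` may exceed ``L`` for a wrap).
    ``cigar_ops`` is the global alignment of the reference against the hit
    region ('=', 'X', 'I' = base missing from the genome, 'D' = extra
    genome base).
    """

    mdp_name: str
    strand: str
    start: int
    end: int
    identity: float
    window_nt: str
    window_start: int  # window origin in oriented (strand-local) coordinates
    flank: int
    ref_offset: int
    cigar_ops: str
    locatable: bool = True


_CIG_NUM = "0123456789"


def _expand_cigar(cigar: str) -> str:
    ops = []
    num = ""
    for ch in cigar:
        if ch in _CIG_NUM:
            num += ch
        else:
            ops.append(ch * int(num))
            num = ""
    return "".join(ops)


def locate_locus(
    g: CircularSequence,
    spec: LocusSpec,
    min_identity: float = 60.0,
    flank: int = 30,
) -> LocusHit:
    """Anchor a reference sORF on the genome by best infix alignment.

    Both strands are searched (wrap-aware); identity is
    ``100 * (1 - edits / len(reference))``.  Below ``min_identity`` the
    locus is *not locatable* — a distinct outcome from a located window
    lacking a start codon.
    """
    query = spec.nt.upper()
    L = g.length
    best = None
    for strand in ("+", "-"):
        base = g.seq if strand == "+" else reverse_complement(g.seq)
        text = base + base[: min(L, len(query) + flank)] if g.circular else base
        res = edlib.align(query, text, mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        loc = next((se for se in res["locations"] if se[0] is not None and se[0] < L), None)
        if loc is None:
            continue
        cand = (res["editDistance"], 0 if strand == "+" else 1, loc, res["cigar"], strand, base)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        return LocusHit(spec.mdp_name, "+", 0, 0, 0.0, "", 0, flank, 0, "", locatable=False)

    dist, _, (s, e_incl), cigar, strand, base = best
    e = e_incl + 1
    identity = 100.0 * (1 - dist / len(query))
    if identity < min_identity:
        return LocusHit(spec.mdp_name, strand, 0, 0, identity, "", 0, flank, 0, "", locatable=False)

    doubled = base + base if g.circular else base
    ws = (s - flank) % L if g.circular else max(0, s - flank)
    lead = s - ws if not g.circular else flank
    wlen = (e - s) + lead + flank
    window_nt = doubled[ws : ws + wlen] if g.circular else base[ws : min(len(base), ws + wlen)]

    ops = _expand_cigar(cigar)
    ref_offset = lead + len(ops) - len(ops.lstrip("D"))  # leading extra genome bases

    if strand == "+":
        g_start, g_end = s, e
    else:
        g_start = (L - e) % L
        g_end = g_start + (e - s)
    return LocusHit(
        mdp_name=spec.mdp_name,
        strand=strand,
        start=g_start,
        end=g_end,
        identity=identity,
        window_nt=window_nt,
        window_start=ws,
        flank=flank,
        ref_offset=ref_offset,
        cigar_ops=ops,
    )


# ---------------------------------------------------------------------------
# sORF records


@dataclass(frozen=True)
class SorfRecord:
    """A located/classified short ORF.

    ``start``/``end`` are window-relative when produced by
    :func:`scan_sorfs` and genome plus-strand (0-based half-open, ``end``
    possibly > L) when produced by :func:`classify_mdp`.
    """

    mdp_name: str
    strand: str
    frame: int
    start: int
    end: int
    peptide: str
    code_used: str
    start_policy: str
    status: str
    truncated: bool = False
    identity: float = 100.0
    downstream_starts: int = 0

    @property
    def length(self) -> int:
        return len(self.peptide)


def scan_sorfs(
    window_nt: str,
    code: GeneticCode,
    start_policy: str = "require_listed_start",
    min_len: int = MIN_SORF_LEN,
    max_len: int = MAX_SORF_LEN,
    start_set: frozenset[str] | None = None,
    name: str = "sORF",
) -> list[SorfRecord]:
    """Enumerate start-to-stop ORFs in all 3 frames of one strand.

    Every in-frame start codon opens a candidate (so nested ORFs sharing a
    stop are all reported).  ORFs shorter than ``min_len`` get status
    ``below_min_length``; ORFs longer than ``max_len`` fall outside the
    sORFome definition and are dropped; an ORF lacking an in-window stop is
    reported with ``truncated=True``.  Coordinates are window-relative.
    """
    window_nt = window_nt.upper()
    starts = start_set if start_set is not None else code.start_set
    records: list[SorfRecord] = []
    n = len(window_nt)
    for frame in range(3):
        positions = range(frame, n - 2, 3)
        if start_policy == "require_listed_start":
            opens = [p for p in positions if window_nt[p : p + 3] in starts]
        else:
            # ORFs begin at the frame start and after each terminator
            opens = []
            expect = frame
            for p in positions:
                if p == expect:
                    opens.append(p)
                if code.aa(window_nt[p : p + 3]) == "*":
                    expect = p + 3
        for p in opens:
            res = translate(window_nt[p:], code, "no_start_required")
            peptide = res.peptide
            if start_policy == "require_listed_start" and peptide:
                peptide = "M" + peptide[1:]
            if len(peptide) > max_len:
                continue
            if not peptide:
                continue
            status = "intact" if len(peptide) >= min_len else "below_min_length"
            end = p + 3 * (len(peptide) + (1 if res.stop_found else 0))
            records.append(
                SorfRecord(
                    mdp_name=name,
                    strand="+",
                    frame=frame,
                    start=p,
                    end=end,
                    peptide=peptide,
                    code_used=code.name,
                    start_policy=start_policy,
                    status=status,
                    truncated=not res.stop_found,
                )
            )
    records.sort(key=lambda r: (r.start, r.end))
    return records


def _window_to_genome_span(hit: LocusHit, w_start: int, w_end: int, L: int) -> tuple[int, int]:
    """Map a window-relative span to genome plus-strand coordinates."""
    if hit.strand == "+":
        s = (hit.window_start + w_start) % L
        return s, s + (w_end - w_start)
    # window lives on the reverse complement: rc position i <-> plus L-1-i
    rc_start = hit.window_start + w_start
    rc_end = hit.window_start + w_end
    s = (L - (rc_end % L)) % L
    return s, s + (w_end - w_start)


def classify_mdp(
    records: Sequence[SorfRecord],
    spec: LocusSpec,
    hit: LocusHit,
    L: int,
    min_len: int = MIN_SORF_LEN,
    start_set: frozenset[str] | None = None,
) -> SorfRecord:
    """Classify one locus against its reference placement.

    Order of evidence: a non-multiple-of-3 length change inside the
    reference footprint is a ``frameshift``; a non-start codon at the
    position the reference start maps to is ``absent_no_start``; an
    in-frame terminator before the reference peptide length is
    ``premature_stop``; otherwise the locus is ``intact`` with its observed
    length.  In-frame start codons downstream of the anchor (the reported
    downstream-AUG phenomenon of some MOTS-c variants) are counted in
    ``downstream_starts``.
    """
    code = genetic_code(spec.code)
    starts = start_set if start_set is not None else spec.start_set
    base_kwargs = dict(
        mdp_name=spec.mdp_name,
        strand=hit.strand,
        code_used=code.name,
        start_policy=spec.start_policy,
        identity=hit.identity,
    )
    if not hit.locatable:
        return SorfRecord(frame=0, start=0, end=0, peptide="", status="not_locatable", **base_kwargs)

    ops = hit.cigar_ops
    net = ops.count("D") - ops.count("I")
    if net % 3 != 0:
        s, e = _window_to_genome_span(hit, hit.flank, hit.flank + (hit.end - hit.start), L)
        return SorfRecord(frame=s % 3, start=s, end=e, peptide="", status="frameshift", **base_kwargs)

    w = hit.window_nt
    anchor = hit.ref_offset
    start_codon = w[anchor : anchor + 3]
    downstream = sum(
        1
        for p in range(anchor + 3, len(w) - 2, 3)
        if w[p : p + 3] in starts and p < anchor + len(spec.nt)
    )
    if start_codon not in starts:
        s, e = _window_to_genome_span(hit, anchor, anchor + 3, L)
        return SorfRecord(
            frame=anchor % 3,
            start=s,
            end=e,
            peptide="",
            status="absent_no_start",
            downstream_starts=downstream,
            **base_kwargs,
        )

    res = translate(w[anchor:], code, "no_start_required")
    peptide = ("M" + res.peptide[1:]) if res.peptide else ""
    ref_len = len(spec.peptide) if spec.peptide else (len(spec.nt) // 3 - 1)
    w_end = anchor + 3 * (len(peptide) + (1 if res.stop_found else 0))
    s, e = _window_to_genome_span(hit, anchor, w_end, L)
    if res.stop_found and len(peptide) < ref_len:
        status = "premature_stop"
    elif len(peptide) < min_len:
        status = "below_min_length"
    else:
        status = "intact"
    return SorfRecord(
        frame=anchor % 3,
        start=s,
        end=e,
        peptide=peptide,
        status=status,
        truncated=not res.stop_found,
        downstream_starts=downstream,
        **base_kwargs,
    )


def predict_mdp(
    g: CircularSequence,
    spec: LocusSpec,
    min_identity: float = 60.0,
    flank: int = 30,
    start_set: frozenset[str] | None = None,
) -> SorfRecord:
    """locate -> scan -> classify for one locus on one genome."""
    hit = locate_locus(g, spec, min_identity=min_identity, flank=flank)
    records: list[SorfRecord] = []
    if hit.locatable:
        records = scan_sorfs(
            hit.window_nt,
            genetic_code(spec.code),
            start_policy="require_listed_start",
            start_set=start_set if start_set is not None else spec.start_set,
            name=spec.mdp_name,
        )
    return classify_mdp(records, spec, hit, g.length, start_set=start_set)


def gau_extended_scan(
    g: CircularSequence,
    spec: LocusSpec,
    extended_starts: frozenset[str] = EXTENDED_STARTS,
) -> SorfRecord:
    """Re-scan the gau locus with the extended mitochondrial start set.

    gau sits antisense within *MT-CO1* and opens with ATA, which the
    standard nuclear code does not accept as a start; under the extended
    vertebrate-mitochondrial start repertoire it yields its dwarf peptide.
    """
    return predict_mdp(g, spec, start_set=frozenset(extended_starts))


# ---------------------------------------------------------------------------
# Cross-species matrix


@dataclass
class MdpMatrix:
    """Species x MDP-locus status table with the underlying records."""

    statuses: pd.DataFrame  # cells like "intact(26)" / "premature_stop"
    records: dict[tuple[str, str], SorfRecord] = field(repr=False, default_factory=dict)

    def to_tsv(self, path) -> None:
        self.statuses.to_csv(path, sep="\t", index_label="genome")

    def to_json(self, path) -> None:
        self.statuses.to_json(path, orient="index")

    def peptides_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for (gid, locus), rec in sorted(self.records.items()):
                if rec.peptide:
                    fh.write(f">{gid}|{locus} {rec.status}\n{rec.peptide}\n")


def build_conservation_matrix(
    genomes: Sequence[CircularSequence],
    catalog: Sequence[LocusSpec],
    min_identity: float = 60.0,
    flank: int = 30,
) -> MdpMatrix:
    """One classified record per (genome, locus); rows follow input order,
    columns follow catalog order.  Unlocatable loci are explicit
    ``not_locatable`` cells — the matrix has no empty cells."""
    if not genomes:
        raise ValueError("need at least one genome")
    records: dict[tuple[str, str], SorfRecord] = {}
    cells: dict[str, dict[str, str]] = {}
    for g in genomes:
        row: dict[str, str] = {}
        for spec in catalog:
            rec = predict_mdp(g, spec, min_identity=min_identity, flank=flank)
            records[(g.id, spec.mdp_name)] = rec
            row[spec.mdp_name] = (
                f"intact({rec.length})" if rec.status == "intact" else rec.status
            )
        cells[g.id] = row
    df = pd.DataFrame.from_dict(cells, orient="index")
    df = df.loc[[g.id for g in genomes], [s.mdp_name for s in catalog]]
    return MdpMatrix(statuses=df, records=records)


# ---------------------------------------------------------------------------
# Peptide conservation


def _star_alignment(peptides: Sequence[str]) -> list[str]:
    """Star MSA: every peptide globally aligned to the longest one, gaps
    merged into shared columns.  Adequate for <= 40-residue micropeptides."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -0.5
    ref_i = max(range(len(peptides)), key=lambda i: (len(peptides[i]), -i))
    ref = peptides[ref_i]

    pair_rows = []
    for p in peptides:
        aln = aligner.align(ref, p)[0]
        a, b = str(aln[0]), str(aln[1])
        pair_rows.append((a, b))

    # insertion profile relative to the reference: max gap run before each
    # reference column (and after the last)
    ins = [0] * (len(ref) + 1)
    for a, _ in pair_rows:
        col = 0
        run = 0
        for ch in a:
            if ch == "-":
                run += 1
            else:
                ins[col] = max(ins[col], run)
                run = 0
                col += 1
        ins[len(ref)] = max(ins[len(ref)], run)

    rows = []
    for a, b in pair_rows:
        out = []
        col = 0
        run = []
        for ca, cb in zip(a, b):
            if ca == "-":
                run.append(cb)
            else:
                out.append("-" * (ins[col] - len(run)) + "".join(run))
                out.append(cb)
                run = []
                col += 1
        out.append("-" * (ins[len(ref)] - len(run)) + "".join(run))
        rows.append("".join(out))
    assert len({len(r) for r in rows}) == 1
    return rows


def conserved_core(peptides: Sequence[str]) -> tuple[int, str]:
    """Longest run of columns identical and ungapped across all peptides.

    Returns ``(length, residues)`` of the best run after a star multiple
    alignment; identical inputs trivially give the whole peptide.
    """
    peptides = [p.upper() for p in peptides]
    if len(peptides) < 2:
        raise ValueError("need at least two peptides")
    if any(not p for p in peptides):
        raise ValueError("empty peptide in input")
    rows = _star_alignment(peptides) if len({len(p) for p in peptides}) > 1 else list(peptides)
    ncol = len(rows[0])
    best_len, best_core = 0, ""
    run_start = None
    for j in range(ncol + 1):
        ok = j < ncol and len({r[j] for r in rows}) == 1 and rows[0][j] != "-"
        if ok and run_start is None:
            run_start = j
        elif not ok and run_start is not None:
            if j - run_start > best_len:
                best_len, best_core = j - run_start, rows[0][run_start:j]
            run_start = None
    return best_len, best_core
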