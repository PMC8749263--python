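"""Independent oracles used by the test suite.

Everything here is deliberately written without touching the package's own
algorithmic code paths: codon tables are transcribed by hand, primer sites
come from per-offset edlib prefix alignments, and sORFs from a plain
codon-walking enumerator.
"""

from __future__ import annotations

import edlib

# Hand-transcribed standard genetic code (NCBI table 1), one row per codon
# family.  The vertebrate mitochondrial code (table 2) differs in exactly
# four codons: ATA->M, TGA->W, AGA->*, AGG->*.
_STANDARD_ROWS = """
TTT F TTC F TTA L TTG L
CTT L CTC L CTA L CTG L
ATT I ATC I ATA I ATG M
GTT V GTC V GTA V GTG V
TCT S TCC S TCA S TCG S
CCT P CCC P CCA P CCG P
ACT T ACC T ACA T ACG T
GCT A GCC A GCA A GCG A
TAT Y TAC Y TAA * TAG *
CAT H CAC H CAA Q CAG Q
AAT N AAC N AAA K AAG K
GAT D GAC D GAA E GAG E
TGT C TGC C TGA * TGG W
CGT R CGC R CGA R CGG R
AGT S AGC S AGA R AGG R
GGT G GGC G GGA G GGG G
"""


def standard_table() -> dict[str, str]:
    toks = _STANDARD_ROWS.split()
    table = dict(zip(toks[0::2], toks[1::2]))
    assert len(table) == 64
    return table


def vertebrate_mito_table() -> dict[str, str]:
    table = standard_table()
    table.update({"ATA": "M", "TGA": "W", "AGA": "*", "AGG": "*"})
    return table


# ---------------------------------------------------------------------------
# Primer-site oracle: per-offset anchored prefix alignment


def _rc(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _expand(cigar: str) -> str:
    out, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append(ch * int(num))
            num = ""
    return "".join(out)


def _profile(ops: str) -> tuple[int, int, int]:
    # edlib walks query vs target: its 'D' consumes the target (an extra
    # template base = insertion), its 'I' consumes the query (a missing
    # template base = deletion)
    return ops.count("X"), ops.count("D"), ops.count("I")


def _tp_exact(ops: str, window: int) -> bool:
    run = 0
    for op in reversed(ops):
        if op != "=":
            return False
        run += 1
        if run >= window:
            return True
    return run >= window


def brute_force_sites(genome_seq: str, primer: str, max_edits: int, three_prime_window: int):
    """All tolerated sites by exhaustive per-offset prefix alignment.

    For every start offset on both strands the full primer is aligned
    against the template prefix starting there (edlib SHW); candidates
    within the edit budget whose alignments end in a run of exact matches
    covering the primer's 3'-terminal bases are reduced to the best
    placement per overlap group (fewest edits, then smallest start).
    Returns (strand, start, end, (mm, ins, dele)) tuples with plus-strand
    coordinates, sorted like the scanner's output.
    """
    L = len(genome_seq)
    m = len(primer)
    cands = []
    for strand in ("+", "-"):
        base = genome_seq if strand == "+" else _rc(genome_seq)
        ext = base + base[: m + max_edits]
        for s in range(L):
            chunk = ext[s : s + m + max_edits]
            res = edlib.align(primer, chunk, mode="SHW", task="path", k=max_edits)
            if res["editDistance"] < 0:
                continue
            ops = _expand(res["cigar"])
            if not _tp_exact(ops, three_prime_window):
                continue
            end = s + res["locations"][0][1] + 1
            cands.append((strand, s, end, _profile(ops), res["editDistance"]))
    # best per overlap group, circular overlap on each strand
    kept = []
    accepted: dict[str, list[tuple[int, int]]] = {"+": [], "-": []}
    for strand, s, e, prof, dist in sorted(cands, key=lambda c: (c[4], c[1])):
        clash = False
        for as_, ae in accepted[strand]:
            for shift in (-L, 0, L):
                if s + shift < ae and as_ < e + shift:
                    clash = True
                    break
            if clash:
                break
        if clash:
            continue
        accepted[strand].append((s, e))
        if strand == "+":
            kept.append(("+", s, e, prof))
        else:
            span = e - s
            s0 = (L - e) % L
            kept.append(("-", s0, s0 + span, prof))
    kept.sort(key=lambda c: (sum(c[3]), c[1] % L, c[0]))
    return kept


# ---------------------------------------------------------------------------
# sORF oracle: plain codon walker


def brute_force_sorfs(window: str, table: dict[str, str], starts: set[str],
                      min_len: int = 8, max_len: int = 40):
    """(frame, start, end, peptide, status, truncated) for every
    start-to-stop ORF in the three forward frames."""
    out = []
    for frame in range(3):
        for p in range(frame, len(window) - 2, 3):
            if window[p : p + 3] not in starts:
                continue
            residues = []
            stopped = False
            q = p
            while q + 3 <= len(window):
                aa = table.get(window[q : q + 3], "X")
                if aa == "*":
                    stopped = True
                    break
                residues.append(aa)
                q += 3
            if not residues or len(residues) > max_len:
                continue
            residues[0] = "M"
            status = "intact" if len(residues) >= min_len else "below_min_length"
            end = q + 3 if stopped else q
            out.append((frame, p, end, "".join(residues), status, not stopped))
    out.sort(key=lambda r: (r[1], r[2]))
    return out
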