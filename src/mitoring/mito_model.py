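"""Circular-sequence data model and standard-format I/O.

Vertebrate mitogenomes are double-stranded circular molecules of roughly
14-20 kb.  Everything downstream (primer scanning, sORF prediction,
divergence) operates on a ring, so this module fixes the coordinate
conventions once:

* coordinates are 0-based, half-open, given on the plus strand;
* a span may wrap the origin, in which case ``end > L`` internally and is
  normalized modulo ``L`` on output;
* position arithmetic on a circular sequence is taken modulo ``L``.

GenBank's 1-based inclusive spans are converted at the I/O boundary only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "IUPAC_CODES",
    "CircularSequence",
    "FeatureAnnotation",
    "read_fasta",
    "write_fasta",
    "read_genbank",
    "circular_slice",
    "reverse_complement",
    "rotate_to_anchor",
    "rotate",
    "rotate_annotations",
    "iupac_match",
]

# IUPAC nucleotide one-letter codes and their expansion sets.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)

_VALID = frozenset(IUPAC_CODES)


def _validate_nt(seq: str, where: str = "sequence") -> None:
    for i, ch in enumerate(seq):
        if ch not in _VALID:
            raise ValueError(
                f"invalid nucleotide symbol {ch!r} at position {i} in {where}"
            )


def iupac_match(a: str, b: str) -> bool:
    """True when the expansion sets of two IUPAC symbols intersect.

    ``N`` therefore matches anything; ``R`` matches ``A``, ``G``, ``R``,
    ``D`` ... etc.  Used for primer/template comparisons so that ambiguity
    codes in assemblies do not spuriously count as mismatches.
    """
    return bool(IUPAC_CODES[a] & IUPAC_CODES[b])


@dataclass(frozen=True)
class CircularSequence:
    """A nucleotide ring (or linear sequence when ``circular=False``)."""

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        if not seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        _validate_nt(seq, where=f"record {self.id!r}")
        object.__setattr__(self, "seq", seq)

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.seq)


@dataclass(frozen=True)
class FeatureAnnotation:
    """A named feature on the ring.

    ``start`` lies in ``[0, L)``; ``end`` may exceed ``L`` for a feature
    wrapping the origin (``end <= start + L``).  ``kind`` keeps the original
    GenBank feature class (gene/rRNA/tRNA/D-loop) where known.
    """

    name: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "gene"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(
                f"feature {self.name!r}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def span_length(self) -> int:
        return self.end - self.start

    def normalized(self, L: int) -> tuple[int, int]:
        """(start, end mod L) pair for output; end < start signals a wrap."""
        return self.start % L, self.end % L if self.end > L else self.end


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path, circular: bool = True) -> list[CircularSequence]:
    """Read a (multi-)FASTA file into :class:`CircularSequence` records.

    The topology defaults to ``circular`` but a ``topology=linear`` or
    ``circular`` token in the description overrides it per record.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description.lower()
        circ = circular
        if "topology=linear" in desc or re.search(r"\blinear\b", desc):
            circ = False
        elif "topology=circular" in desc or re.search(r"\bcircular\b", desc):
            circ = True
        records.append(CircularSequence(id=rec.id, seq=str(rec.seq), circular=circ))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[CircularSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in records:
            topo = "circular" if g.circular else "linear"
            fh.write(f">{g.id} topology={topo}\n")
            for i in range(0, g.length, width):
                fh.write(g.seq[i : i + width] + "\n")


_FEATURE_KINDS = {"gene", "rRNA", "tRNA", "CDS", "D-loop", "misc_feature"}


def read_genbank(path: str | Path) -> tuple[CircularSequence, list[FeatureAnnotation]]:
    """Read a GenBank flat file into a ring plus feature annotations.

    Topology is taken from the LOCUS line; GenBank 1-based inclusive
    locations become 0-based half-open spans here.  A feature stored as a
    join of an origin-spanning pair of intervals is composed into a single
    wrapping span.  Only gene/rRNA/tRNA/CDS/D-loop features are kept; a
    D-loop (or a misc_feature named control region) is renamed ``NCR``.
    """
    path = Path(path)
    rec = SeqIO.read(str(path), "genbank")
    try:
        seq = str(rec.seq)
    except Exception as exc:  # undefined sequence: ORIGIN block absent/empty
        raise ValueError(f"{path}: no ORIGIN sequence block") from exc
    if not seq:
        raise ValueError(f"{path}: no ORIGIN sequence block")
    circular = rec.annotations.get("topology", "").lower() == "circular"
    genome = CircularSequence(id=rec.id, seq=seq, circular=circular)
    L = genome.length

    feats: list[FeatureAnnotation] = []
    seen: set[tuple[str, int, int]] = set()
    for f in rec.features:
        if f.type not in _FEATURE_KINDS:
            continue
        name = None
        for key in ("gene", "product", "note", "standard_name"):
            if key in f.qualifiers:
                name = f.qualifiers[key][0]
                break
        if name is None:
            name = f.type
        kind = f.type
        if f.type == "D-loop" or "control region" in name.lower() or name.upper() in {"NCR", "D-LOOP"}:
            name, kind = "NCR", "D-loop"
        parts = sorted(
            ((int(p.start), int(p.end)) for p in f.location.parts),
            key=lambda se: se[0],
        )
        if len(parts) == 1:
            start, end = parts[0]
        elif len(parts) == 2 and parts[1][1] == L and parts[0][0] == 0:
            # join(a..L, 1..b): wraps the origin
            start, end = parts[1][0], L + parts[0][1]
        else:
            start = parts[0][0]
            end = parts[-1][1]
        strand = "-" if f.location.strand == -1 else "+"
        key = (name, start, end)
        if key in seen:  # gene + CDS pairs describe the same locus
            continue
        seen.add(key)
        feats.append(FeatureAnnotation(name=name, start=start, end=end, strand=strand, kind=kind))
    if sum(1 for f in feats if f.name == "NCR") > 1:
        raise ValueError(f"{path}: more than one NCR/control-region feature")
    return genome, feats


# ---------------------------------------------------------------------------
# Ring arithmetic


def circular_slice(g: CircularSequence, start: int, end: int) -> str:
    """Bases ``start .. end-1`` with wraparound.

    ``end`` may exceed ``L`` (up to ``2L``) or be smaller than ``start``
    (interpreted as wrapping once around the origin).  Requesting a wrap on
    a linear sequence is an error.
    """
    L = g.length
    if not (0 <= start < L):
        raise ValueError(f"start {start} out of range [0, {L})")
    if end < start:
        end += L
    if not (start <= end <= start + L) or end > 2 * L:
        raise ValueError(f"end {end} out of range for L={L}")
    if end <= L:
        return g.seq[start:end]
    if not g.circular:
        raise ValueError(
            f"wrapping slice ({start}, {end}) requested on linear sequence {g.id!r}"
        )
    return g.seq[start:] + g.seq[: end - L]


def reverse_complement(s: str) -> str:
    """Reverse complement honouring IUPAC ambiguity codes."""
    s = s.upper()
    _validate_nt(s)
    return s.translate(_COMPLEMENT)[::-1]


def rotate(g: CircularSequence, k: int) -> CircularSequence:
    """Left-rotate the ring by ``k`` so old position ``k`` becomes 0."""
    if not g.circular:
        raise ValueError(f"cannot rotate linear sequence {g.id!r}")
    k %= g.length
    return replace(g, seq=g.seq[k:] + g.seq[:k])


def rotate_annotations(
    features: Sequence[FeatureAnnotation], k: int, L: int
) -> list[FeatureAnnotation]:
    """Shift feature spans after a left-rotation by ``k``."""
    out = []
    for f in features:
        start = (f.start - k) % L
        out.append(replace(f, start=start, end=start + f.span_length))
    return out


def rotate_to_anchor(g: CircularSequence, anchor_motif: str) -> CircularSequence:
    """Rotate the ring so it starts at the first occurrence of ``anchor_motif``.

    The anchor is matched exactly on the plus strand (wrap-aware).  When it
    occurs several times the smallest start position wins, which makes the
    normalization deterministic; assemblies of the same molecule that start
    at arbitrary points then compare equal.
    """
    motif = anchor_motif.upper()
    if not motif:
        raise ValueError("empty anchor motif")
    if not g.circular:
        raise ValueError(f"cannot rotation-normalize linear sequence {g.id!r}")
    doubled = g.seq + g.seq[: len(motif) - 1]
    pos = doubled.find(motif)
    if pos == -1 or pos >= g.length:
        raise ValueError(f"anchor motif not found in {g.id!r}")
    return rotate(g, pos)
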