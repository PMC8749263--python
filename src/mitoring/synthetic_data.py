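"""Synthetic annotated mitogenomes with planted ground truth.

Every pipeline stage is testable without downloads: this module builds
circular vertebrate-like mitogenomes of 14-20 kb with the canonical gene
order laid out as annotated placeholders, and plants into them

* the back-to-back primer-binding motif (the published pan-vertebrate
  oligos by default), optionally carrying mismatches or the single-base
  template insertion observed in some species;
* one reference sORF per MDP catalog locus, either intact or pseudogenized
  by one of the three documented modes (start loss, premature stop,
  frameshifting indel);
* a control region (NCR) with an optional tandem-repeat array;
* haplotype partners at an exactly controlled substitution divergence.

All generators are pure functions of (plan, seed); a truth record listing
every planted coordinate and status accompanies each genome.  Background
composition follows the light-strand base bias typical of vertebrate
mtDNA (A/C-rich, G-poor), which keeps spurious start codons at realistic
rates.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .insilico_pcr import FORWARD_PRIMER, REVERSE_PRIMER
from .mdp_scan import EXTENDED_STARTS, LocusSpec
from .mito_model import CircularSequence, FeatureAnnotation, reverse_complement

__all__ = [
    "GENE_LAYOUT",
    "SimPlan",
    "generate_mitogenome",
    "mutate_haplotype",
    "plant_pseudogenization",
]

# Canonical vertebrate gene order with human-like nominal lengths (nt).
# Protein/rRNA/tRNA placeholders are scaled proportionally to the target
# genome length; the NCR takes the planned remainder.
GENE_LAYOUT: tuple[tuple[str, int, str, str], ...] = (
    ("tRNA-Phe", 71, "+", "tRNA"),
    ("MT-RNR1", 954, "+", "rRNA"),
    ("tRNA-Val", 69, "+", "tRNA"),
    ("MT-RNR2", 1559, "+", "rRNA"),
    ("tRNA-Leu1", 75, "+", "tRNA"),
    ("MT-ND1", 956, "+", "gene"),
    ("tRNA-Ile", 69, "+", "tRNA"),
    ("tRNA-Gln", 69, "-", "tRNA"),
    ("tRNA-Met", 68, "+", "tRNA"),
    ("MT-ND2", 1042, "+", "gene"),
    ("tRNA-Trp", 68, "+", "tRNA"),
    ("tRNA-Ala", 69, "-", "tRNA"),
    ("tRNA-Asn", 73, "-", "tRNA"),
    ("tRNA-Cys", 66, "-", "tRNA"),
    ("tRNA-Tyr", 66, "-", "tRNA"),
    ("MT-CO1", 1542, "+", "gene"),
    ("tRNA-Ser1", 69, "-", "tRNA"),
    ("tRNA-Asp", 68, "+", "tRNA"),
    ("MT-CO2", 684, "+", "gene"),
    ("tRNA-Lys", 70, "+", "tRNA"),
    ("MT-ATP8", 207, "+", "gene"),
    ("MT-ATP6", 681, "+", "gene"),
    ("MT-CO3", 784, "+", "gene"),
    ("tRNA-Gly", 68, "+", "tRNA"),
    ("MT-ND3", 346, "+", "gene"),
    ("tRNA-Arg", 65, "+", "tRNA"),
    ("MT-ND4L", 297, "+", "gene"),
    ("MT-ND4", 1378, "+", "gene"),
    ("tRNA-His", 69, "+", "tRNA"),
    ("tRNA-Ser2", 59, "+", "tRNA"),
    ("tRNA-Leu2", 71, "+", "tRNA"),
    ("MT-ND5", 1812, "+", "gene"),
    ("MT-ND6", 525, "-", "gene"),
    ("tRNA-Glu", 69, "-", "tRNA"),
    ("MT-CYB", 1141, "+", "gene"),
    ("tRNA-Thr", 66, "+", "tRNA"),
    ("tRNA-Pro", 69, "-", "tRNA"),
)

# Light-strand-like composition (A, C, G, T): A/C-rich, G-poor.
_BASE_PROBS = (0.31, 0.31, 0.13, 0.25)
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class SimPlan:
    """Study conditions for one synthetic mitogenome.

    ``length=None`` draws uniformly from the vertebrate 14-20 kb range.
    ``primer_plan`` is one of ``exact``, ``mismatch`` (``primer_mismatches``
    substitutions in the forward footprint, away from the 3' terminus),
    ``insertion`` (a single extra template base inside the reverse
    footprint — the event class seen in the garden and hazel dormice) or
    ``absent``.  ``mdp_plan`` maps locus names to ``intact`` /
    ``absent_no_start`` / ``premature_stop`` / ``frameshift`` (unnamed loci
    default to intact).  ``divergences`` lists haplotype-partner
    divergences in percent.
    """

    seed: int = 0
    length: int | None = None
    primer_plan: str = "exact"
    primer_mismatches: int = 1
    mdp_plan: Mapping[str, str] = field(default_factory=dict)
    ncr_length: int = 1000
    ncr_repeat_unit: str = "TACATACGTA"
    ncr_repeat_copies: int = 4
    divergences: tuple[float, ...] = ()
    genome_id: str = "sim"

    def __post_init__(self) -> None:
        if self.length is not None and not (14_000 <= self.length <= 20_000):
            raise ValueError("genome length must lie in [14000, 20000]")
        if self.primer_plan not in {"exact", "mismatch", "insertion", "absent"}:
            raise ValueError(f"unknown primer plan {self.primer_plan!r}")
        for locus, mode in self.mdp_plan.items():
            if mode not in {"intact", "absent_no_start", "premature_stop", "frameshift"}:
                raise ValueError(f"unknown MDP plan {mode!r} for {locus!r}")
        for d in self.divergences:
            if not 0.0 <= d <= 30.0:
                raise ValueError("divergence must lie in [0, 30] percent")


def _random_background(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(_BASES, size=n, p=_BASE_PROBS)


def plant_pseudogenization(locus_nt: str, mode: str, seed: int = 0) -> str:
    """Realize one pseudogenization mode on a reference sORF.

    ``absent_no_start`` rewrites the middle base of the start codon to C,
    which removes it from both the nuclear and the extended mitochondrial
    start sets; ``premature_stop`` replaces an internal codon in the first
    half of the peptide with TAA; ``frameshift`` inserts or deletes one
    base mid-ORF.  ``intact`` returns the input unchanged.
    """
    nt = locus_nt.upper()
    if mode == "intact":
        return nt
    n_codons = len(nt) // 3
    if len(nt) % 3 != 0 or n_codons < 4:
        raise ValueError("locus must be a whole number of codons, >= 4")
    if nt[:3] not in EXTENDED_STARTS:
        raise ValueError("locus does not begin with a recognizable start codon")
    if nt[-3:] not in _STOPS:
        raise ValueError("locus does not end with a stop codon")
    rng = np.random.default_rng(seed)
    if mode == "absent_no_start":
        return nt[0] + "C" + nt[2:]
    if mode == "premature_stop":
        pep_len = n_codons - 1
        half = pep_len // 2
        if half < 2:
            raise ValueError("locus too short to place a premature stop before half-length")
        idx = int(rng.integers(1, half))  # codon index within the peptide
        return nt[: 3 * idx] + "TAA" + nt[3 * idx + 3 :]
    if mode == "frameshift":
        if len(nt) < 12:
            raise ValueError("locus too short for a mid-ORF frameshift")
        pos = int(rng.integers(4, len(nt) - 5))
        if rng.random() < 0.5:
            base = chr(rng.choice(_BASES))
            return nt[:pos] + base + nt[pos:]
        return nt[:pos] + nt[pos + 1 :]
    raise ValueError(f"unknown pseudogenization mode {mode!r}")


def _mutate_positions(
    seq: str, positions: list[int], rng: np.random.Generator
) -> tuple[str, list[int]]:
    arr = list(seq)
    for pos in positions:
        choices = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(arr), positions


def generate_mitogenome(
    plan: SimPlan, catalog: list[LocusSpec] | None = None
) -> tuple[CircularSequence, list[FeatureAnnotation], dict]:
    """Build one annotated synthetic mitogenome per the plan.

    Returns (genome, annotations, truth).  The truth record lists the
    planted primer footprints with their expected edit profiles, every
    locus span with its planned status, and the NCR/repeat coordinates;
    output is byte-identical for identical (plan, catalog).
    """
    if catalog is None:
        from .catalogs import load_mdp_catalog

        catalog = load_mdp_catalog()
    rng = np.random.default_rng(plan.seed)
    L = int(plan.length) if plan.length is not None else int(rng.integers(14_000, 20_001))

    nominal = sum(length for _, length, _, _ in GENE_LAYOUT)
    ncr_len = plan.ncr_length
    if L - ncr_len < nominal // 2:
        raise ValueError("NCR plan leaves too little room for the gene complement")
    scale = (L - ncr_len) / nominal
    sizes = [max(30, int(round(length * scale))) for _, length, _, _ in GENE_LAYOUT]
    drift = (L - ncr_len) - sum(sizes)
    sizes[-1] += drift  # absorb rounding into the last tRNA
    if sizes[-1] < 30:
        raise ValueError("planned features overflow the genome length")

    features: list[FeatureAnnotation] = []
    pos = 0
    spans: dict[str, tuple[int, int]] = {}
    for (name, _, strand, kind), size in zip(GENE_LAYOUT, sizes):
        features.append(FeatureAnnotation(name=name, start=pos, end=pos + size, strand=strand, kind=kind))
        spans[name] = (pos, pos + size)
        pos += size
    features.append(FeatureAnnotation(name="NCR", start=pos, end=L, strand="+", kind="D-loop"))
    spans["NCR"] = (pos, L)

    seq = _random_background(rng, L)

    def plant(at: int, fragment: str, host: str) -> tuple[int, int]:
        h0, h1 = spans[host]
        if at < h0 or at + len(fragment) > h1:
            raise ValueError(
                f"planted fragment ({len(fragment)} nt at {at}) overflows host {host}"
            )
        seq[at : at + len(fragment)] = np.frombuffer(fragment.encode(), dtype=np.uint8)
        return at, at + len(fragment)

    truth: dict = {
        "seed": plan.seed,
        "length": L,
        "primer_plan": plan.primer_plan,
        "loci": {},
    }

    # --- MDP loci -----------------------------------------------------------
    cursors = {"MT-RNR1": 30, "MT-RNR2": 30, "MT-CO1": 60}
    motif_reserved = len(REVERSE_PRIMER) + len(FORWARD_PRIMER) + 20
    for spec in catalog:
        mode = plan.mdp_plan.get(spec.mdp_name, "intact")
        locus_seed = (plan.seed + zlib.crc32(spec.mdp_name.encode())) % (2**31)
        lesioned = plant_pseudogenization(spec.nt, mode, seed=locus_seed)
        fragment = lesioned if spec.sense == "host-sense" else reverse_complement(lesioned)
        host = spec.host_gene
        at = spans[host][0] + cursors[host]
        span = plant(at, fragment, host)
        cursors[host] += len(fragment) + 12
        truth["loci"][spec.mdp_name] = {
            "status": mode,
            "start": span[0],
            "end": span[1],
            "strand": "+" if spec.sense == "host-sense" else "-",
        }

    # --- primer motif -------------------------------------------------------
    ins_abs: int | None = None
    if plan.primer_plan != "absent":
        motif = reverse_complement(REVERSE_PRIMER) + FORWARD_PRIMER
        rlen, flen = len(REVERSE_PRIMER), len(FORWARD_PRIMER)
        fwd_profile = [0, 0, 0]
        rev_profile = [0, 0, 0]
        if plan.primer_plan == "mismatch":
            k = plan.primer_mismatches
            # interior of the forward footprint, sparing its 3'-terminal bases
            positions = rng.choice(np.arange(rlen + 1, rlen + flen - 4), size=k, replace=False)
            arr = list(motif)
            for p in positions:
                arr[p] = [b for b in "ACGT" if b != arr[p]][int(rng.integers(3))]
            motif = "".join(arr)
            fwd_profile[0] = k
        motif_at = spans["MT-RNR2"][0] + cursors["MT-RNR2"] + 5
        if motif_at + len(motif) + 5 > spans["MT-RNR2"][1]:
            raise ValueError("planted features overflow MT-RNR2")
        plant(motif_at, motif, "MT-RNR2")
        if plan.primer_plan == "insertion":
            # single extra template base inside the reverse footprint,
            # away from the primer's 3' terminus (plus-strand motif start)
            ins_off = int(rng.integers(5, rlen - 4))
            ins_abs = motif_at + ins_off
            rev_profile[1] = 1
        rev_len = rlen + (1 if ins_abs is not None else 0)
        shift = 1 if ins_abs is not None else 0
        truth["primer_sites"] = {
            REVERSE_PRIMER: {
                "strand": "-",
                "start": motif_at,
                "end": motif_at + rev_len,
                "profile": tuple(rev_profile),
            },
            FORWARD_PRIMER: {
                "strand": "+",
                "start": motif_at + rlen + shift,
                "end": motif_at + rlen + shift + flen,
                "profile": tuple(fwd_profile),
            },
        }
        truth["motif_span"] = (motif_at, motif_at + len(motif) + shift)

    # --- NCR repeats --------------------------------------------------------
    unit, copies = plan.ncr_repeat_unit.upper(), plan.ncr_repeat_copies
    if copies > 0:
        array = unit * copies
        at = spans["NCR"][0] + 20
        if at + len(array) + 10 > L:
            raise ValueError("tandem-repeat array overflows the NCR")
        plant(at, array, "NCR")
        truth["ncr_repeats"] = {"unit": unit, "copies": copies, "start": at, "end": at + len(array)}
    truth["ncr_span"] = spans["NCR"]

    genome_seq = seq.tobytes().decode()
    if ins_abs is not None:
        base = chr(rng.choice(_BASES))
        genome_seq = genome_seq[:ins_abs] + base + genome_seq[ins_abs:]
        L += 1
        shifted: list[FeatureAnnotation] = []
        for f in features:
            if f.start > ins_abs:
                shifted.append(FeatureAnnotation(f.name, f.start + 1, f.end + 1, f.strand, f.kind))
            elif f.end > ins_abs:
                shifted.append(FeatureAnnotation(f.name, f.start, f.end + 1, f.strand, f.kind))
            else:
                shifted.append(f)
        features = shifted
        for rec in truth["loci"].values():
            if rec["start"] > ins_abs:
                rec["start"] += 1
                rec["end"] += 1
        truth["length"] = L

    genome = CircularSequence(id=plan.genome_id, seq=genome_seq, circular=True)
    return genome, features, truth


def mutate_haplotype(g: CircularSequence, divergence_percent: float, seed: int = 0) -> CircularSequence:
    """Haplotype partner at an exact planted substitution divergence.

    Exactly ``round(L * d / 100)`` positions, sampled uniformly without
    replacement, are substituted to a different base (no indels), so the
    planted p-distance is exact up to rounding.
    """
    if not 0.0 <= divergence_percent <= 30.0:
        raise ValueError("divergence must lie in [0, 30] percent")
    rng = np.random.default_rng(seed)
    n = int(round(g.length * divergence_percent / 100.0))
    if n == 0:
        return CircularSequence(id=f"{g.id}_d{divergence_percent:g}", seq=g.seq, circular=g.circular)
    positions = sorted(int(p) for p in rng.choice(g.length, size=n, replace=False))
    mutated, _ = _mutate_positions(g.seq, positions, rng)
    return CircularSequence(id=f"{g.id}_d{divergence_percent:g}", seq=mutated, circular=g.circular)
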