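"""Bisulfite methylation-pattern calling and inheritance fidelity.

Sodium bisulfite deaminates unmethylated cytosine to uracil (sequenced as
thymine) while 5-methylcytosine resists conversion, so aligning a converted
amplicon to its reference region reads out per-cytosine methylation.  Plant
cytosines are classed by sequence context — CG, CHG and CHH with
H in {A, C, T} — since maintenance of methylation differs between the
symmetric (CG, CHG) and asymmetric (CHH) contexts.

The aligner is bisulfite-aware: a reference C matched by a read T scores as
a match (that is the expected conversion signal, not an error).  Conversion
efficiency is estimated from an unmethylated lambda-phage spike, and
parent-to-progeny inheritance fidelity is the per-context fraction of
callable sites at which every progeny carries the parental state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "CytosineSite",
    "MethylationPattern",
    "FidelityReport",
    "assign_contexts",
    "bisulfite_align_and_call",
    "conversion_efficiency",
    "inheritance_fidelity",
    "region_methylation_percent",
    "in_silico_convert",
    "check_primer",
]

CONTEXTS = ("CG", "CHG", "CHH")
H_BASES = set("ACT")


@dataclass(frozen=True)
class CytosineSite:
    position: int  # 0-based offset in the region (+ strand coordinates)
    strand: str  # "+" or "-"
    context: str  # CG / CHG / CHH / INDETERMINATE
    state: str | None = None  # METHYLATED / UNMETHYLATED / AMBIGUOUS / None


@dataclass
class MethylationPattern:
    region_id: str
    individual: str
    sites: list[CytosineSite]

    def __post_init__(self) -> None:
        for strand in "+-":
            pos = [s.position for s in self.sites if s.strand == strand]
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise ValueError("site positions must be strictly increasing per strand")

    def site_map(self) -> dict[tuple[int, str], CytosineSite]:
        return {(s.position, s.strand): s for s in self.sites}


def _context_forward(seq: str, i: int) -> str:
    """Context of a + strand C at offset i (seq is the + strand)."""
    if i + 1 >= len(seq):
        return "INDETERMINATE"
    b1 = seq[i + 1]
    if b1 == "G":
        return "CG"
    if b1 not in H_BASES:
        return "INDETERMINATE"  # N
    if i + 2 >= len(seq):
        return "INDETERMINATE"
    b2 = seq[i + 2]
    if b2 == "G":
        return "CHG"
    if b2 in H_BASES:
        return "CHH"
    return "INDETERMINATE"


def assign_contexts(region: str) -> list[CytosineSite]:
    """List every cytosine of both strands with its sequence context.

    A + strand site is a C in the region; a - strand site is a G (a C on
    the reverse complement), reported at its + strand coordinate.  States
    are left unset.
    """
    region = region.upper()
    bad = set(region) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters: {sorted(bad)}")
    rc = str(Seq(region).reverse_complement())
    L = len(region)
    sites: list[CytosineSite] = []
    for i, base in enumerate(region):
        if base == "C":
            sites.append(CytosineSite(i, "+", _context_forward(region, i)))
    for j, base in enumerate(rc):
        if base == "C":
            sites.append(CytosineSite(L - 1 - j, "-", _context_forward(rc, j)))
    sites.sort(key=lambda s: (s.strand, s.position))
    return sites


def _bisulfite_aligner() -> Align.PairwiseAligner:
    alphabet = "ACGTN"
    m = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if "N" in (a, b):
                m[a, b] = 0.0
            elif a == b:
                m[a, b] = 1.0
            else:
                m[a, b] = -1.0
    m["C", "T"] = 1.0  # reference C read as T: expected conversion, cost-free
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = m
    aligner.open_gap_score = -3.0
    aligner.extend_gap_score = -1.0
    aligner.end_gap_score = 0.0  # free end gaps: amplicon may cover part of the region
    return aligner


class AlignmentQualityError(ValueError):
    """Raised when an amplicon fails the identity threshold against its region."""


def _align_read(region: str, read: str) -> dict[int, str]:
    """Map reference offset -> aligned read base (gaps omitted)."""
    aligner = _bisulfite_aligner()
    aln = aligner.align(region, read)[0]
    mapping: dict[int, str] = {}
    for (ts, te), (qs, qe) in zip(*aln.aligned):
        for k in range(te - ts):
            mapping[ts + k] = read[qs + k]
    return mapping


def bisulfite_align_and_call(
    region: str,
    read: str,
    region_id: str = "region",
    individual: str = "sample",
    strand: str = "+",
    identity_threshold: float = 0.8,
) -> MethylationPattern:
    """Call per-cytosine methylation from one converted amplicon.

    The read is globally aligned to the region with C/T conversion scored as
    a match.  At each reference C (on the declared bisulfite strand): read C
    means METHYLATED, read T means UNMETHYLATED, anything else (mismatch,
    gap, N, uncovered) is AMBIGUOUS.  Alignment identity is computed on
    aligned non-C reference positions and must reach ``identity_threshold``.
    """
    region = region.upper()
    read = read.upper()
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    work_region = region if strand == "+" else str(Seq(region).reverse_complement())
    mapping = _align_read(work_region, read)
    # the amplicon must actually derive from the region: nearly all of the
    # read should be placed, not just an opportunistic fragment
    if len(mapping) < 0.8 * len(read):
        raise AlignmentQualityError(
            f"only {len(mapping)}/{len(read)} read bases align to the region"
        )
    non_c = [(i, b) for i, b in enumerate(work_region) if b != "C" and i in mapping]
    if non_c:
        ident = sum(mapping[i] == b for i, b in non_c) / len(non_c)
        if ident < identity_threshold:
            raise AlignmentQualityError(
                f"alignment identity {ident:.2f} below threshold {identity_threshold}"
            )
    L = len(region)
    sites: list[CytosineSite] = []
    for i, base in enumerate(work_region):
        if base != "C":
            continue
        ctx = _context_forward(work_region, i)
        obs = mapping.get(i)
        if obs == "C":
            state = "METHYLATED"
        elif obs == "T":
            state = "UNMETHYLATED"
        else:
            state = "AMBIGUOUS"
        pos = i if strand == "+" else L - 1 - i
        sites.append(CytosineSite(pos, strand, ctx, state))
    if strand == "-":
        sites.sort(key=lambda s: s.position)
    return MethylationPattern(region_id, individual, sites)


def conversion_efficiency(
    lambda_region: str, lambda_read: str, identity_threshold: float = 0.8
) -> float:
    """Percent of (truly unmethylated) lambda cytosines read as converted.

    The lambda spike carries no methylation, so every callable C should read
    as T; the fraction that does estimates the bisulfite conversion rate.
    """
    pattern = bisulfite_align_and_call(
        lambda_region, lambda_read, region_id="lambda", identity_threshold=identity_threshold
    )
    conv = sum(1 for s in pattern.sites if s.state == "UNMETHYLATED")
    callable_ = sum(1 for s in pattern.sites if s.state in ("METHYLATED", "UNMETHYLATED"))
    if callable_ == 0:
        raise ValueError("no callable cytosine positions in the lambda read")
    return 100.0 * conv / callable_


def region_methylation_percent(pattern: MethylationPattern) -> float:
    """Percent methylated among callable (non-ambiguous) cytosines."""
    meth = sum(1 for s in pattern.sites if s.state == "METHYLATED")
    unmeth = sum(1 for s in pattern.sites if s.state == "UNMETHYLATED")
    if meth + unmeth == 0:
        raise ValueError("no callable sites")
    return 100.0 * meth / (meth + unmeth)


@dataclass
class FidelityReport:
    """Per-context parent-to-progeny methylation concordance."""

    per_context: dict  # context -> {"n_sites", "n_concordant", "fraction"}
    overall_fraction: float
    pairwise: dict  # progeny individual -> overall concordance fraction


def inheritance_fidelity(
    parent: MethylationPattern, progeny: Sequence[MethylationPattern]
) -> FidelityReport:
    """Fraction of sites at which every progeny carries the parental state.

    Sites that are AMBIGUOUS (or uncalled) in the parent or any progeny are
    excluded from both numerator and denominator.  Pairwise parent-progeny
    concordance per individual is reported alongside.
    """
    if not progeny:
        raise ValueError("at least one progeny pattern required")
    for p in progeny:
        if p.region_id != parent.region_id:
            raise ValueError(
                f"region mismatch: parent {parent.region_id!r} vs {p.region_id!r}"
            )
    callable_states = ("METHYLATED", "UNMETHYLATED")
    parent_map = parent.site_map()
    progeny_maps = [p.site_map() for p in progeny]
    per_context = {c: {"n_sites": 0, "n_concordant": 0} for c in CONTEXTS}
    total = concordant = 0
    pair_counts = {p.individual: [0, 0] for p in progeny}
    for key, psite in parent_map.items():
        if psite.state not in callable_states or psite.context not in CONTEXTS:
            continue
        states = [m.get(key) for m in progeny_maps]
        if any(s is None or s.state not in callable_states for s in states):
            # pairwise counts still use the callable pairs
            for p, m in zip(progeny, progeny_maps):
                s = m.get(key)
                if s is not None and s.state in callable_states:
                    pair_counts[p.individual][1] += 1
                    pair_counts[p.individual][0] += s.state == psite.state
            continue
        for p, s in zip(progeny, states):
            pair_counts[p.individual][1] += 1
            pair_counts[p.individual][0] += s.state == psite.state
        ok = all(s.state == psite.state for s in states)
        per_context[psite.context]["n_sites"] += 1
        per_context[psite.context]["n_concordant"] += ok
        total += 1
        concordant += ok
    for c, d in per_context.items():
        d["fraction"] = d["n_concordant"] / d["n_sites"] if d["n_sites"] else float("nan")
    pairwise = {
        ind: (k / n if n else float("nan")) for ind, (k, n) in pair_counts.items()
    }
    overall = concordant / total if total else float("nan")
    return FidelityReport(per_context, overall, pairwise)


def in_silico_convert(
    region: str,
    methylated_positions: Iterable[int],
    conversion_rate: float = 1.0,
    rng: np.random.Generator | None = None,
) -> str:
    """Bisulfite-convert the + strand of ``region`` in silico.

    Unmethylated cytosines become T with probability ``conversion_rate``;
    methylated cytosines (given as + strand offsets) are protected.
    """
    if not (0.0 <= conversion_rate <= 1.0):
        raise ValueError("conversion_rate must be in [0, 1]")
    rng = rng or np.random.default_rng()
    protected = set(methylated_positions)
    out = []
    for i, b in enumerate(region.upper()):
        if b == "C" and i not in protected:
            out.append("T" if rng.random() < conversion_rate else "C")
        else:
            out.append(b)
    return "".join(out)


def check_primer(primer: str) -> None:
    """Warn when a bisulfite PCR primer contains cytosine.

    Primers containing C anneal differently to converted templates depending
    on methylation, biasing amplification.
    """
    if "C" in primer.upper():
        warnings.warn(
            "primer contains cytosine; amplification may be methylation-biased",
            stacklevel=2,
        )
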