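"""Rule-based SNP filtering and genotype-class partitioning.

Called variants from control and treated resequenced lines pass through
four filters before interpretation:

a. evidence   — at least ``min_alt_reads`` alternate-supporting reads in at
                least one sample (configurable to total-depth mode);
b. quality    — site quality strictly greater than ``min_quality``;
c. indel      — the site must not lie within w bases of an indel, where w is
                that indel's length (alignment artefacts cluster near indels);
d. shared     — sites where every sample carries one identical genotype are
                uninformative for treatment effects and are removed.

Surviving loci are partitioned into genotype classes: uniformly alternate,
heterozygous in any sample, homozygous-alternate exclusive to treated
samples, and multi-allelic (subdivided by whether the extra alternates are
confined to treated samples).  Annotation effect tables (loss-of-function /
nonsynonymous / synonymous / intergenic / other) are tallied separately.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "VariantRecord",
    "SampleManifest",
    "FilterReport",
    "LOCUS_CLASSES",
    "EFFECT_CLASSES",
    "filter_snps",
    "classify_loci",
    "effect_tally",
]

Genotype = tuple[int, int] | None

LOCUS_CLASSES = (
    "UNIFORM_ALT",
    "MULTI_ALLELIC_TREATED_ONLY",
    "MULTI_ALLELIC_SHARED",
    "HETEROZYGOUS_ANY",
    "TREATED_EXCLUSIVE_HOM_ALT",
)

EFFECT_CLASSES = ("LOF", "nonsynonymous", "synonymous", "intergenic", "other")

# attribution order for records failing more than one rule (reporting only)
RULE_ORDER = ("quality", "min_reads", "indel_adjacent", "shared_genotype")


@dataclass(frozen=True)
class VariantRecord:
    """One called locus across all samples."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: float
    genotypes: Mapping[str, Genotype]  # allele-index pairs; None = missing
    alt_depths: Mapping[str, int]  # alternate-supporting reads per sample
    is_indel: bool = False
    indel_length: int = 0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if not self.alts:
            raise ValueError("at least one alternate allele required")
        if self.is_indel != (self.indel_length > 0):
            raise ValueError("indel_length > 0 exactly when is_indel")

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass(frozen=True)
class SampleManifest:
    """Sample ids with their treatment labels."""

    samples: tuple[str, ...]
    treatment: Mapping[str, str]  # sample -> "control" | "treated"

    def __post_init__(self) -> None:
        bad = [s for s in self.samples if self.treatment.get(s) not in ("control", "treated")]
        if bad:
            raise ValueError(f"samples lacking a control/treated label: {bad}")

    @property
    def control(self) -> tuple[str, ...]:
        return tuple(s for s in self.samples if self.treatment[s] == "control")

    @property
    def treated(self) -> tuple[str, ...]:
        return tuple(s for s in self.samples if self.treatment[s] == "treated")


@dataclass
class FilterReport:
    survivors: list[VariantRecord]
    rejections: Counter  # primary rule -> count (plus "indel" for indel records)
    rejected_rules: dict[str, tuple[str, ...]]  # locus id -> every failed rule
    n_input: int

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_survivors": len(self.survivors),
            "rejections": dict(self.rejections),
        }


def _indel_intervals(records: Iterable[VariantRecord]) -> list[tuple[str, int, int, int]]:
    """(chrom, start, end, length) of each indel's affected interval, 1-based inclusive."""
    out = []
    for r in records:
        if r.is_indel:
            out.append((r.chrom, r.pos, r.pos + r.indel_length, r.indel_length))
    return out


def _near_indel(rec: VariantRecord, intervals) -> bool:
    for chrom, start, end, length in intervals:
        if chrom != rec.chrom:
            continue
        if start <= rec.pos <= end:
            return True
        if min(abs(rec.pos - start), abs(rec.pos - end)) <= length:
            return True
    return False


def _shared_genotype(rec: VariantRecord, manifest: SampleManifest) -> bool:
    gts = [rec.genotypes.get(s) for s in manifest.samples]
    if any(g is None for g in gts):
        return False
    return len({tuple(sorted(g)) for g in gts}) == 1


def filter_snps(
    records: Sequence[VariantRecord],
    manifest: SampleManifest,
    min_alt_reads: int = 3,
    min_quality: float = 3000.0,
    depth_mode: str = "alt",
) -> FilterReport:
    """Apply the four SNP filters; indel records are used only for adjacency.

    ``depth_mode`` is "alt" (default: alternate-supporting reads in >= 1
    sample must reach ``min_alt_reads``) or "total" (total depth per sample,
    when the caller's table carries total rather than allele depths).
    """
    if depth_mode not in ("alt", "total"):
        raise ValueError("depth_mode must be 'alt' or 'total'")
    intervals = _indel_intervals(records)
    survivors: list[VariantRecord] = []
    rejections: Counter = Counter()
    rejected_rules: dict[str, tuple[str, ...]] = {}
    for rec in sorted(records, key=lambda r: (r.chrom, r.pos)):
        if rec.is_indel:
            rejections["indel"] += 1
            rejected_rules[rec.locus_id] = ("indel",)
            continue
        missing = [s for s in manifest.samples if s not in rec.alt_depths]
        if missing:
            raise ValueError(f"{rec.locus_id}: missing read depths for {missing}")
        failed = []
        if not rec.qual > min_quality:
            failed.append("quality")
        depths = [rec.alt_depths[s] for s in manifest.samples]
        if max(depths) < min_alt_reads:
            failed.append("min_reads")
        if _near_indel(rec, intervals):
            failed.append("indel_adjacent")
        if _shared_genotype(rec, manifest):
            failed.append("shared_genotype")
        if failed:
            primary = next(r for r in RULE_ORDER if r in failed)
            rejections[primary] += 1
            rejected_rules[rec.locus_id] = tuple(failed)
        else:
            survivors.append(rec)
    return FilterReport(survivors, rejections, rejected_rules, n_input=len(records))


def _classify_one(rec: VariantRecord, manifest: SampleManifest) -> str:
    gts = {s: rec.genotypes.get(s) for s in manifest.samples}
    if any(g is None for g in gts.values()):
        return "unclassified"
    norm = {s: tuple(sorted(g)) for s, g in gts.items()}
    alleles_by_sample = {s: set(g) for s, g in norm.items()}
    observed_alts = {a for g in norm.values() for a in g if a > 0}

    # all samples share one non-reference genotype
    if len(set(norm.values())) == 1 and observed_alts:
        shared = next(iter(norm.values()))
        if all(a > 0 for a in shared):
            return "UNIFORM_ALT"
    if len(observed_alts) > 1:
        control_alts = {
            a for s in manifest.control for a in alleles_by_sample[s] if a > 0
        }
        return (
            "MULTI_ALLELIC_TREATED_ONLY" if not control_alts else "MULTI_ALLELIC_SHARED"
        )
    if any(g[0] != g[1] for g in norm.values()):
        return "HETEROZYGOUS_ANY"
    hom_alt_treated = {
        norm[s] for s in manifest.treated if norm[s][0] == norm[s][1] and norm[s][0] > 0
    }
    control_gts = {norm[s] for s in manifest.control}
    if hom_alt_treated and not (hom_alt_treated & control_gts):
        return "TREATED_EXCLUSIVE_HOM_ALT"
    return "unclassified"


def classify_loci(
    survivors: Sequence[VariantRecord], manifest: SampleManifest
) -> tuple[Counter, dict[str, str]]:
    """Label each locus with its genotype class.

    Precedence when several descriptions apply: UNIFORM_ALT, then
    MULTI_ALLELIC (treated-only before shared), then HETEROZYGOUS_ANY, then
    TREATED_EXCLUSIVE_HOM_ALT; loci with missing genotypes fall into an
    explicit ``unclassified`` bin.  Counts partition the input.
    """
    labels = {rec.locus_id: _classify_one(rec, manifest) for rec in survivors}
    counts = Counter(labels.values())
    for cls in LOCUS_CLASSES:
        counts.setdefault(cls, 0)
    counts.setdefault("unclassified", 0)
    return counts, labels


def effect_tally(
    annotations: pd.DataFrame, treated_exclusive: Sequence[str] | None = None
) -> pd.DataFrame:
    """Tally annotation effect classes (counts and percentages of total).

    ``annotations`` needs columns ``locus`` and ``effect`` with effect values
    from ``EFFECT_CLASSES``.  When ``treated_exclusive`` locus ids are given,
    a parallel tally restricted to them is included.
    """
    required = {"locus", "effect"}
    if not required <= set(annotations.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    bad = set(annotations["effect"]) - set(EFFECT_CLASSES)
    if bad:
        raise ValueError(f"unknown effect classes: {sorted(bad)}")
    rows = []
    scopes = [("all", annotations)]
    if treated_exclusive is not None:
        keep = set(treated_exclusive)
        scopes.append(("treated_exclusive", annotations[annotations["locus"].isin(keep)]))
    for scope, df in scopes:
        total = len(df)
        for cls in EFFECT_CLASSES:
            n = int((df["effect"] == cls).sum())
            rows.append(
                {
                    "scope": scope,
                    "effect": cls,
                    "count": n,
                    "percent": (100.0 * n / total) if total else 0.0,
                }
            )
    return pd.DataFrame(rows)
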