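"""Synthetic data with truth labels for every pipeline stage.

The generator emulates the statistical structure of a 5-azacytidine
hypomethylation experiment in an inbred plant line:

* MSAP epigenotype matrices whose per-dose band-type frequencies default to
  the observed control/dose profiles (multinomial per cell), so methylation
  percentages decline with dose;
* phenotype tables with Normal control distributions, an optional treated
  variance inflation and planted outliers at a fixed displacement in
  control-sd units (deterministic magnitude so truth labels are exact);
* AT-rich genomes with planted GC/CpG-rich islands;
* bisulfite amplicon families (parent + progeny) with per-context
  methylation rates and inheritance fidelity, plus an unmethylated lambda
  spike converted at a configurable rate;
* variant tables with records planted to pass or fail each filter rule and
  to realize each genotype class.

All randomness flows from one integer seed; per-artifact substreams are
derived deterministically from (seed, artifact name), so equal seeds give
byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bisulfite import CONTEXTS, assign_contexts, in_silico_convert
from .msap import MSAPMatrix, MethylationState
from .variants import SampleManifest, VariantRecord

__all__ = [
    "TABLE_COUNTS",
    "PROGENY_MOMENTS",
    "SimConfig",
    "substream",
    "gen_msap",
    "gen_phenotypes",
    "gen_progeny_families",
    "gen_genome",
    "gen_bisulfite_family",
    "gen_variants",
]

#: observed band-type counts (I, II, III, IV) per 5-azaC dose (mM); the
#: default multinomial frequencies are these rows normalized by their totals
TABLE_COUNTS: dict[float, tuple[int, int, int, int]] = {
    0.0: (110, 11, 73, 52),
    1.0: (112, 11, 78, 46),
    5.0: (114, 9, 74, 51),
    20.0: (117, 8, 77, 44),
    50.0: (129, 11, 70, 35),
}

#: progeny-family trait moments: family -> (trait, mean, sd, n)
PROGENY_MOMENTS: dict[str, tuple[str, float, float, int]] = {
    "ERFv148": ("flowering_time", 60.6, 5.6, 21),
    "ERFv153": ("flowering_time", 62.9, 7.2, 19),
    "control_early": ("flowering_time", 65.8, 6.9, 36),
    "ERFv138": ("flowering_time", 86.9, 3.0, 7),
    "ERFv141": ("flowering_time", 91.7, 6.5, 14),
    "control_late": ("flowering_time", 76.5, 7.1, 37),
    "ERFv65": ("rosette_diameter", 2.2, 0.7, 21),
    "control_diameter": ("rosette_diameter", 2.5, 0.7, 32),
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-artifact generator derived from (seed, name)."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode()) & 0x7FFFFFFF])


@dataclass
class SimConfig:
    """Defaults for every generator; seed is mandatory.

    ``n_per_dose`` defaults to the 27-individual survey design (5 control
    lines plus 22 treated lines spread over the dose classes, with the
    largest class at 20 mM).
    """

    seed: int
    # MSAP
    n_per_dose: dict[float, int] = field(
        default_factory=lambda: {0.0: 5, 1.0: 4, 5.0: 4, 20.0: 9, 50.0: 5}
    )
    n_loci: int = 246
    dose_frequencies: dict[float, tuple[float, ...]] = field(
        default_factory=lambda: {
            dose: tuple(c / sum(counts) for c in counts)
            for dose, counts in TABLE_COUNTS.items()
        }
    )
    # phenotypes
    n_control: int = 59
    n_treated: int = 305
    control_moments: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"flowering_time": (65.8, 6.9), "rosette_diameter": (2.5, 0.7)}
    )
    sd_inflation: float = 1.0
    outlier_fraction: float = 0.05
    outlier_effect_sd: float = 3.0
    # genome
    genome_length: int = 10_000
    islands: tuple[tuple[int, int], ...] = ((3000, 400), (6000, 500))
    background_gc: float = 0.30
    island_gc: float = 0.65
    island_cpg_rate: float = 0.25
    # bisulfite
    region_length: int = 600
    n_progeny: int = 2
    methylation_rates: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.85, "CHG": 0.6, "CHH": 0.3}
    )
    fidelity: dict[str, float] = field(
        default_factory=lambda: {"CG": 1.0, "CHG": 0.9, "CHH": 0.85}
    )
    conversion_rate: float = 0.995
    lambda_length: int = 400
    # variants
    n_records: int = 60
    n_control_samples: int = 3
    n_treated_samples: int = 4
    p_fail_quality: float = 0.1
    p_fail_reads: float = 0.1
    p_fail_indel: float = 0.1
    class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "UNIFORM_ALT": 0.50,
            "HETEROZYGOUS_ANY": 0.30,
            "TREATED_EXCLUSIVE_HOM_ALT": 0.10,
            "MULTI_ALLELIC_SHARED": 0.06,
            "MULTI_ALLELIC_TREATED_ONLY": 0.04,
        }
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for dose, f in self.dose_frequencies.items():
            if abs(sum(f) - 1.0) > 1e-9:
                raise ValueError(f"dose {dose}: frequencies must sum to 1")
        if not (0.0 <= self.outlier_fraction <= 1.0):
            raise ValueError("outlier_fraction must be in [0, 1]")
        for c, v in self.fidelity.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"fidelity[{c}] must be in [0, 1]")


# ---------------------------------------------------------------- MSAP


def gen_msap(config: SimConfig) -> tuple[MSAPMatrix, dict]:
    """Draw an MSAP state matrix cell-wise from per-dose type frequencies."""
    rng = substream(config.seed, "msap")
    individuals: list[str] = []
    groups: list[str] = []
    rows = []
    for dose in sorted(config.n_per_dose):
        freqs = np.asarray(config.dose_frequencies[dose])
        n = config.n_per_dose[dose]
        label = f"{dose:g}mM"
        for k in range(n):
            individuals.append(f"{label}_{k + 1}")
            groups.append(label)
            rows.append(rng.choice(4, size=config.n_loci, p=freqs) + 1)
    calls = np.asarray(rows, dtype=np.int8)
    loci = [f"M{j + 1}" for j in range(config.n_loci)]
    matrix = MSAPMatrix(individuals, groups, loci, calls)
    truth = {
        "dose_frequencies": {f"{d:g}mM": list(config.dose_frequencies[d]) for d in config.n_per_dose},
        "expected_methylated_percent": {
            f"{d:g}mM": 100.0
            * (2 * f[1] + 2 * f[2] + 4 * f[3]) / 4.0
            for d, f in (
                (d, config.dose_frequencies[d]) for d in config.n_per_dose
            )
        },
    }
    return matrix, truth


# ---------------------------------------------------------------- phenotypes


def gen_phenotypes(config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Control and treated phenotype tables with planted outliers.

    Non-outlier values are Normal(mu, sd * inflation); planted outliers sit
    at exactly mu +/- effect * sd (random sign) so the truth labels are
    unambiguous.
    """
    rng = substream(config.seed, "phenotypes")
    rows = []
    outliers: dict[str, list[str]] = {t: [] for t in config.control_moments}
    for trait, (mu, sd) in config.control_moments.items():
        for i in range(config.n_control):
            rows.append(
                {
                    "individual": f"C{i + 1}",
                    "group": "control",
                    "trait": trait,
                    "value": rng.normal(mu, sd),
                }
            )
        n_out = int(round(config.outlier_fraction * config.n_treated))
        out_ids = set(rng.choice(config.n_treated, size=n_out, replace=False).tolist())
        for i in range(config.n_treated):
            ind = f"T{i + 1}"
            if i in out_ids:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                value = mu + sign * config.outlier_effect_sd * sd
                outliers[trait].append(ind)
            else:
                value = rng.normal(mu, sd * config.sd_inflation)
            rows.append(
                {"individual": ind, "group": "treated", "trait": trait, "value": value}
            )
    table = pd.DataFrame(rows)
    return table, {"outliers": {t: sorted(v) for t, v in outliers.items()}}


def gen_progeny_families(config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Progeny-generation family table drawn from the default family moments."""
    rng = substream(config.seed, "families")
    rows = []
    for family, (trait, mu, sd, n) in PROGENY_MOMENTS.items():
        for i in range(n):
            rows.append(
                {
                    "individual": f"{family}_{i + 1}",
                    "group": family,
                    "trait": trait,
                    "value": rng.normal(mu, sd),
                }
            )
    return pd.DataFrame(rows), {"moments": dict(PROGENY_MOMENTS)}


# ---------------------------------------------------------------- genome


def _draw_bases(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(list("ACGT"), size=n, p=p).tolist()


def gen_genome(config: SimConfig) -> tuple[str, list[tuple[int, int]]]:
    """AT-rich background with planted GC- and CpG-rich islands.

    Returns the sequence and the truth intervals (0-based half-open).
    Island sequence interleaves explicit CG dinucleotides (rate
    ``island_cpg_rate``) with GC-rich single bases so the observed/expected
    CpG ratio exceeds 1.
    """
    rng = substream(config.seed, "genome")
    intervals = sorted((s, s + l) for s, l in config.islands)
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ValueError("island intervals overlap")
    if intervals and intervals[-1][1] > config.genome_length:
        raise ValueError("island extends past genome end")
    seq = _draw_bases(rng, config.genome_length, config.background_gc)
    for start, end in intervals:
        chunk: list[str] = []
        while len(chunk) < end - start:
            if rng.random() < config.island_cpg_rate and len(chunk) + 2 <= end - start:
                chunk.extend("CG")
            else:
                chunk.extend(_draw_bases(rng, 1, config.island_gc))
        seq[start:end] = chunk
    return "".join(seq), intervals


# ---------------------------------------------------------------- bisulfite


def gen_bisulfite_family(config: SimConfig) -> tuple[dict, dict]:
    """Parent + progeny bisulfite amplicons for one region, plus lambda spike.

    The parent methylation set is drawn per context from
    ``methylation_rates``; each progeny copies every parental site state
    with per-context probability ``fidelity`` (otherwise the state flips).
    Amplicons are in-silico conversions of the + strand at
    ``conversion_rate``; the lambda spike is fully unmethylated.

    Returns ``(artifacts, truth)`` where artifacts holds the region, reads
    and metadata rows, and truth the planted methylation sets and rates.
    """
    rng = substream(config.seed, "bisulfite")
    region = "".join(_draw_bases(rng, config.region_length, 0.5))
    sites = [s for s in assign_contexts(region) if s.strand == "+" and s.context in CONTEXTS]
    parent_set = {
        s.position
        for s in sites
        if rng.random() < config.methylation_rates[s.context]
    }
    progeny_sets = []
    for _ in range(config.n_progeny):
        child = set()
        for s in sites:
            inherited = rng.random() < config.fidelity[s.context]
            meth = (s.position in parent_set) if inherited else (s.position not in parent_set)
            if meth:
                child.add(s.position)
        progeny_sets.append(child)
    reads = {
        "parent": in_silico_convert(region, parent_set, config.conversion_rate, rng)
    }
    for k, child in enumerate(progeny_sets):
        reads[f"progeny{k + 1}"] = in_silico_convert(
            region, child, config.conversion_rate, rng
        )
    lam = "".join(_draw_bases(rng, config.lambda_length, 0.5))
    lam_read = in_silico_convert(lam, set(), config.conversion_rate, rng)
    meta = [
        {
            "amplicon": name,
            "region": "region1",
            "individual": name,
            "generation": "parent" if name == "parent" else "progeny",
            "strand": "+",
        }
        for name in reads
    ]
    artifacts = {
        "region_id": "region1",
        "region": region,
        "reads": reads,
        "lambda_ref": lam,
        "lambda_read": lam_read,
        "metadata": pd.DataFrame(meta),
    }
    truth = {
        "parent_methylated": sorted(parent_set),
        "progeny_methylated": [sorted(s) for s in progeny_sets],
        "fidelity": dict(config.fidelity),
        "conversion_rate": config.conversion_rate,
        "site_contexts": {s.position: s.context for s in sites},
    }
    return artifacts, truth


# ---------------------------------------------------------------- variants


def _genotypes_for_class(
    cls: str, rng: np.random.Generator, controls: list[str], treated: list[str]
) -> tuple[dict, tuple[str, ...]]:
    """Per-sample genotypes realizing one locus class; returns (genotypes, alts)."""
    samples = controls + treated
    if cls == "UNIFORM_ALT":
        return {s: (1, 1) for s in samples}, ("A",)
    if cls == "HETEROZYGOUS_ANY":
        g = {s: (0, 0) for s in samples}
        g[samples[rng.integers(len(samples))]] = (0, 1)
        return g, ("A",)
    if cls == "TREATED_EXCLUSIVE_HOM_ALT":
        g = {s: (0, 0) for s in samples}
        g[treated[rng.integers(len(treated))]] = (1, 1)
        return g, ("A",)
    if cls == "MULTI_ALLELIC_SHARED":
        g = {s: (0, 0) for s in samples}
        g[controls[rng.integers(len(controls))]] = (1, 1)
        g[treated[rng.integers(len(treated))]] = (2, 2)
        return g, ("A", "T")
    if cls == "MULTI_ALLELIC_TREATED_ONLY":
        g = {s: (0, 0) for s in samples}
        i, j = rng.choice(len(treated), size=2, replace=False)
        g[treated[i]] = (1, 1)
        g[treated[j]] = (2, 2)
        return g, ("A", "T")
    raise ValueError(cls)


def gen_variants(config: SimConfig) -> tuple[list[VariantRecord], SampleManifest, dict]:
    """Variant table with per-record planted filter outcomes and classes.

    Records sit 1000 bp apart so no accidental indel adjacency occurs; a
    record planted to fail the indel rule gets a companion indel record
    within its own length.  Truth labels per record: the planted class, the
    set of rules it fails, and whether it should survive filtering.
    """
    if config.n_treated_samples < 2:
        raise ValueError("need >= 2 treated samples for multi-allelic classes")
    rng = substream(config.seed, "variants")
    controls = [f"ctrl{i + 1}" for i in range(config.n_control_samples)]
    treated = [f"azaC{i + 1}" for i in range(config.n_treated_samples)]
    manifest = SampleManifest(
        samples=tuple(controls + treated),
        treatment={**{s: "control" for s in controls}, **{s: "treated" for s in treated}},
    )
    classes = list(config.class_probs)
    probs = np.asarray([config.class_probs[c] for c in classes])
    probs = probs / probs.sum()
    records: list[VariantRecord] = []
    truth: dict[str, dict] = {}
    pos = 1000
    for i in range(config.n_records):
        cls = classes[rng.choice(len(classes), p=probs)]
        genotypes, alts = _genotypes_for_class(cls, rng, controls, treated)
        fails = []
        if cls == "UNIFORM_ALT":
            fails.append("shared_genotype")
        qual = 5000.0 if rng.random() >= config.p_fail_quality else 1500.0
        if qual <= 3000.0:
            fails.append("quality")
        good_depth = rng.random() >= config.p_fail_reads
        depths = {}
        for s in manifest.samples:
            has_alt = any(a > 0 for a in genotypes[s])
            if good_depth:
                depths[s] = int(rng.integers(5, 20)) if has_alt else 0
            else:
                depths[s] = int(rng.integers(0, 3)) if has_alt else 0
        if not good_depth:
            fails.append("min_reads")
        rec_id = f"chr1:{pos}"
        if rng.random() < config.p_fail_indel:
            ilen = int(rng.integers(2, 6))
            ipos = pos - ilen  # SNP inside the indel's affected interval
            records.append(
                VariantRecord(
                    chrom="chr1",
                    pos=ipos,
                    ref="ATGCA"[: ilen + 1],
                    alts=("A",),
                    qual=6000.0,
                    genotypes={s: (0, 1) for s in manifest.samples},
                    alt_depths={s: 10 for s in manifest.samples},
                    is_indel=True,
                    indel_length=ilen,
                )
            )
            fails.append("indel_adjacent")
        records.append(
            VariantRecord(
                chrom="chr1",
                pos=pos,
                ref="G",
                alts=alts,
                qual=qual,
                genotypes=genotypes,
                alt_depths=depths,
            )
        )
        truth[rec_id] = {
            "class": cls,
            "fails": sorted(set(fails)),
            "passes": not fails,
        }
        pos += 1000
    return records, manifest, {"records": truth}
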