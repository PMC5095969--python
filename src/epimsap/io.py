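"""Readers and writers for the pipeline's plain-text formats.

Band tables are CSV with individuals as rows and a mandatory ``group``
column; MSAP tables carry two 0/1 columns per locus suffixed ``_H``
(EcoRI/HpaII lane) and ``_M`` (EcoRI/MspI lane), AFLP tables one 0/1 column
per locus.  Variant tables are VCF (CHROM, POS, REF, ALT, QUAL, FORMAT
GT:AD) read and written through pysam, or an equivalent flat TSV.  FASTA
goes through Bio.SeqIO.  BED output is 0-based half-open; VCF positions are
1-based (pysam converts centrally).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cpg import CpGIsland
from .msap import MSAPMatrix, MISSING, classify_band_pair
from .structure import BinaryEpiMatrix
from .variants import SampleManifest, VariantRecord

__all__ = [
    "read_band_table",
    "write_band_table",
    "read_states",
    "write_states",
    "read_phenotypes",
    "write_phenotypes",
    "read_binary",
    "write_binary",
    "read_manifest",
    "write_manifest",
    "read_vcf_subset",
    "write_vcf",
    "read_variant_tsv",
    "write_variant_tsv",
    "read_fasta",
    "write_fasta",
    "write_bed",
    "write_report",
]


# ---------------------------------------------------------------- band tables


def read_band_table(path: str | Path, kind: str = "msap"):
    """Read a presence/absence band table.

    ``kind="msap"`` pairs ``<locus>_H`` / ``<locus>_M`` columns and returns
    an :class:`MSAPMatrix`; ``kind="aflp"`` returns the raw DataFrame
    (individuals x loci plus ``group``).
    """
    df = pd.read_csv(path, index_col=0)
    if "group" not in df.columns:
        raise ValueError(f"{path}: band table requires a 'group' column")
    if kind == "aflp":
        return df
    if kind != "msap":
        raise ValueError("kind must be 'msap' or 'aflp'")
    groups = df["group"].astype(str).tolist()
    body = df.drop(columns=["group"])
    h_cols = [c for c in body.columns if c.endswith("_H")]
    loci = [c[:-2] for c in h_cols]
    missing = [l for l in loci if f"{l}_M" not in body.columns]
    if missing:
        raise ValueError(f"{path}: loci missing an _M column: {missing[:5]}")
    calls = np.full((len(df), len(loci)), MISSING, dtype=np.int8)
    for j, locus in enumerate(loci):
        h = body[f"{locus}_H"].to_numpy()
        m = body[f"{locus}_M"].to_numpy()
        for i in range(len(df)):
            if pd.isna(h[i]) or pd.isna(m[i]):
                continue
            calls[i, j] = classify_band_pair(int(h[i]), int(m[i])).value
    return MSAPMatrix(
        individuals=[str(i) for i in df.index],
        groups=groups,
        loci=loci,
        calls=calls,
    )


def write_band_table(matrix: MSAPMatrix, path: str | Path) -> None:
    """Write an MSAP matrix back to its two-columns-per-locus band form."""
    from .msap import state_to_bands, MethylationState

    data: dict[str, list] = {"group": matrix.groups}
    for j, locus in enumerate(matrix.loci):
        hs, ms = [], []
        for i in range(matrix.n_individuals):
            code = int(matrix.calls[i, j])
            if code == MISSING:
                hs.append(pd.NA)
                ms.append(pd.NA)
            else:
                h, m = state_to_bands(MethylationState(code))
                hs.append(h)
                ms.append(m)
        data[f"{locus}_H"] = hs
        data[f"{locus}_M"] = ms
    df = pd.DataFrame(data, index=matrix.individuals)
    df.index.name = "individual"
    df.to_csv(path)


def write_states(matrix: MSAPMatrix, path: str | Path) -> None:
    """Write the four-state call matrix as CSV (state names, blank = missing)."""
    matrix.to_frame().to_csv(path)


def read_states(path: str | Path) -> MSAPMatrix:
    df = pd.read_csv(path, index_col=0, keep_default_na=False, na_values=[""])
    df = df.where(pd.notna(df), None)
    return MSAPMatrix.from_frame(df)


# ---------------------------------------------------------------- phenotypes


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"individual", "group", "trait", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: phenotype CSV needs columns {sorted(required)}")
    df["value"] = df["value"].astype(float)
    if not np.isfinite(df["value"]).all():
        raise ValueError(f"{path}: non-finite phenotype values")
    return df


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


# ---------------------------------------------------------------- binary matrix


def write_binary(
    bin_matrix: BinaryEpiMatrix, path: str | Path, groups: Sequence[str] | None = None
) -> None:
    df = bin_matrix.to_frame()
    if groups is not None:
        df.insert(0, "group", list(groups))
    df.to_csv(path)


def read_binary(path: str | Path) -> tuple[BinaryEpiMatrix, list[str] | None]:
    df = pd.read_csv(path, index_col=0)
    groups = None
    if "group" in df.columns:
        groups = df["group"].astype(str).tolist()
        df = df.drop(columns=["group"])
    bin_matrix = BinaryEpiMatrix(
        individuals=[str(i) for i in df.index],
        loci=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )
    return bin_matrix, groups


# ---------------------------------------------------------------- variants


def read_manifest(path: str | Path) -> SampleManifest:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "treatment"} <= set(df.columns):
        raise ValueError(f"{path}: manifest needs columns sample, treatment")
    return SampleManifest(
        samples=tuple(df["sample"].astype(str)),
        treatment=dict(zip(df["sample"].astype(str), df["treatment"].astype(str))),
    )


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    pd.DataFrame(
        {"sample": manifest.samples, "treatment": [manifest.treatment[s] for s in manifest.samples]}
    ).to_csv(path, sep="\t", index=False)


def _vcf_header(samples: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##contig=<ID=chr1,length=536870912>")
    for i in range(2, 8):
        header.add_line(f"##contig=<ID=chr{i},length=536870912>")
    header.add_line(
        '##INFO=<ID=INDEL_LEN,Number=1,Type=Integer,Description="Length of indel event">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref, alts)">'
    )
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(
    records: Sequence[VariantRecord], samples: Sequence[str], path: str | Path
) -> None:
    """Write the variant subset as an uncompressed text VCF."""
    header = _vcf_header(samples)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos)):
            row = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref,) + rec.alts,
                qual=rec.qual,
            )
            if rec.is_indel:
                row.info["INDEL_LEN"] = rec.indel_length
            for s in samples:
                gt = rec.genotypes.get(s)
                row.samples[s]["GT"] = gt if gt is not None else (None, None)
                ad = [0] * (1 + len(rec.alts))
                ad[1] = int(rec.alt_depths.get(s, 0))
                row.samples[s]["AD"] = tuple(ad)
            out.write(row)


def read_vcf_subset(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Read a VCF back into :class:`VariantRecord` objects.

    Indels are recognised from the INDEL_LEN INFO key when present,
    otherwise from ref/alt length differences.  Extra INFO keys are ignored
    (preserved in the file, opaque to the pipeline).
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for row in vcf:
            alts = tuple(row.alts or ())
            if "INDEL_LEN" in row.info:
                indel_len = int(row.info["INDEL_LEN"])
            else:
                indel_len = max(
                    (abs(len(a) - len(row.ref)) for a in alts), default=0
                )
            genotypes: dict[str, tuple[int, int] | None] = {}
            depths: dict[str, int] = {}
            for s in samples:
                call = row.samples[s]
                gt = call.get("GT")
                if gt is None or any(a is None for a in gt):
                    genotypes[s] = None
                else:
                    genotypes[s] = (int(gt[0]), int(gt[1]))
                ad = call.get("AD")
                depths[s] = int(sum(x or 0 for x in ad[1:])) if ad else 0
            records.append(
                VariantRecord(
                    chrom=row.chrom,
                    pos=row.pos,
                    ref=row.ref,
                    alts=alts,
                    qual=float(row.qual) if row.qual is not None else 0.0,
                    genotypes=genotypes,
                    alt_depths=depths,
                    is_indel=indel_len > 0,
                    indel_length=indel_len,
                )
            )
    return records, samples


_TSV_COLUMNS = [
    "chrom", "pos", "ref", "alts", "qual", "is_indel", "indel_length",
]


def write_variant_tsv(
    records: Sequence[VariantRecord], samples: Sequence[str], path: str | Path
) -> None:
    """Flat TSV equivalent of the VCF subset (one GT/AD column pair per sample)."""
    rows = []
    for rec in records:
        row = {
            "chrom": rec.chrom,
            "pos": rec.pos,
            "ref": rec.ref,
            "alts": ",".join(rec.alts),
            "qual": rec.qual,
            "is_indel": int(rec.is_indel),
            "indel_length": rec.indel_length,
        }
        for s in samples:
            gt = rec.genotypes.get(s)
            row[f"{s}_GT"] = "./." if gt is None else f"{gt[0]}/{gt[1]}"
            row[f"{s}_AD"] = rec.alt_depths.get(s, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_variant_tsv(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: variant TSV missing columns {sorted(missing)}")
    samples = [c[:-3] for c in df.columns if c.endswith("_GT")]
    records = []
    for i, row in df.iterrows():
        genotypes: dict[str, tuple[int, int] | None] = {}
        depths: dict[str, int] = {}
        for s in samples:
            gt = str(row[f"{s}_GT"])
            if "." in gt:
                genotypes[s] = None
            else:
                a, b = gt.split("/")
                genotypes[s] = (int(a), int(b))
            depths[s] = int(row[f"{s}_AD"])
        try:
            records.append(
                VariantRecord(
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    ref=str(row["ref"]),
                    alts=tuple(str(row["alts"]).split(",")),
                    qual=float(row["qual"]),
                    genotypes=genotypes,
                    alt_depths=depths,
                    is_indel=bool(row["is_indel"]),
                    indel_length=int(row["indel_length"]),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: malformed row at line {i + 2}: {exc}") from exc
    return records, samples


# ---------------------------------------------------------------- sequences


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_bed(islands: Iterable[CpGIsland], path: str | Path) -> None:
    """BED6 output; score is the observed/expected ratio scaled to 0-1000."""
    with open(path, "w") as fh:
        for k, isl in enumerate(islands):
            score = int(round(min(isl.obs_exp_ratio, 1.0) * 1000))
            fh.write(
                f"{isl.chrom}\t{isl.start}\t{isl.end}\tCpG_island_{k + 1}\t{score}\t.\n"
            )


# ---------------------------------------------------------------- reports


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        seq = sorted(obj) if isinstance(obj, (set, frozenset)) else obj
        return [_jsonable(v) for v in seq]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
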