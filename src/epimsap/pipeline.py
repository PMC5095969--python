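"""End-to-end pipeline: band scoring -> MSL -> ordination/AMOVA -> phenotypes.

``run_full_pipeline`` wires the per-stage functions together from a single
configuration mapping and writes one JSON report plus per-stage files.
Stage failures raise :class:`PipelineError` naming the stage.
"""

from __future__ import annotations

from pathlib import Path

from . import io as eio
from .msap import methylated_cytosine_percent, methylation_partition, select_msl, unmethylated_percent
from .phenotype import classify_variants, trait_summary
from .structure import amova, encode_binary, pairwise_distance, pcoa

__all__ = ["PipelineError", "run_full_pipeline", "DEFAULTS"]

DEFAULTS = {
    "msl_threshold": 0.05,
    "min_unmethylated_individuals": 2,
    "alpha": 0.05,
    "n_permutations": 9999,
    "n_axes": 2,
    "seed": 0,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_full_pipeline(config: dict, outdir: str | Path | None = None) -> dict:
    """Execute msap-score -> msl -> pcoa/amova and phenotype -> classify.

    ``config`` keys: ``msap_bands`` (CSV path), optional ``aflp_bands``,
    optional ``phenotypes``, plus any of the threshold keys in
    :data:`DEFAULTS`.  Returns the report dict; when ``outdir`` is given the
    report and per-stage tables are written there.
    """
    cfg = {**DEFAULTS, **config}
    report: dict = {"config": {k: v for k, v in cfg.items()}}
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    if "msap_bands" not in cfg:
        raise PipelineError("msap-score", "config key 'msap_bands' is required")
    try:
        matrix = eio.read_band_table(cfg["msap_bands"], kind="msap")
    except (OSError, ValueError) as exc:
        raise PipelineError("msap-score", str(exc)) from exc
    counts = matrix.type_counts()
    report["msap"] = {
        "n_individuals": matrix.n_individuals,
        "n_loci": matrix.n_loci,
        "type_counts": dict(zip(["I", "II", "III", "IV"], counts.as_tuple())),
        "methylated_cytosine_percent": methylated_cytosine_percent(counts),
        "unmethylated_percent": unmethylated_percent(counts),
        "per_group_methylated_percent": {
            g: methylated_cytosine_percent(matrix.type_counts(g))
            for g in matrix.group_labels()
        },
    }
    if counts.n_methylated:
        hemi, internal, full = methylation_partition(counts)
        report["msap"]["methylation_partition"] = {
            "hemimethylated": hemi,
            "internal": internal,
            "full": full,
        }
    if outdir is not None:
        eio.write_states(matrix, outdir / "states.csv")

    if "aflp_bands" in cfg:
        try:
            from .msap import check_uniformity

            aflp = eio.read_band_table(cfg["aflp_bands"], kind="aflp")
            uniform, polymorphic = check_uniformity(aflp)
        except (OSError, ValueError) as exc:
            raise PipelineError("uniformity", str(exc)) from exc
        report["uniformity"] = {"uniform": uniform, "polymorphic_loci": polymorphic}

    try:
        partition = select_msl(
            matrix,
            min_methylated_fraction=cfg["msl_threshold"],
            min_unmethylated_individuals=cfg["min_unmethylated_individuals"],
        )
    except ValueError as exc:
        raise PipelineError("msl", str(exc)) from exc
    report["msl"] = {
        "n_msl": len(partition.msl),
        "n_polymorphic_msl": len(partition.polymorphic_msl),
        "n_nml": len(partition.nml),
    }

    if len(partition.polymorphic_msl) >= 1 and matrix.n_individuals >= 3:
        try:
            binary = encode_binary(matrix, partition)
            d = pairwise_distance(binary)
            ord_res = pcoa(d, n_axes=cfg["n_axes"])
            report["pcoa"] = {
                "proportion_explained": list(ord_res.proportion_explained),
                "n_negative_eigenvalues": int(len(ord_res.negative_eigenvalues)),
            }
            if outdir is not None:
                eio.write_binary(binary, outdir / "binary.csv", groups=matrix.groups)
                ord_res.coordinates.to_csv(outdir / "pcoa.csv")
            groups = matrix.groups
            sizes = {g: groups.count(g) for g in set(groups)}
            if len(sizes) >= 2 and min(sizes.values()) >= 2:
                res = amova(
                    binary,
                    groups,
                    n_permutations=cfg["n_permutations"],
                    seed=cfg["seed"],
                )
                report["amova"] = {
                    "phi_st": res.phi_st,
                    "sigma_among": res.sigma_among,
                    "sigma_within": res.sigma_within,
                    "p_value": res.p_value,
                    "n_permutations": res.n_permutations,
                }
        except ValueError as exc:
            raise PipelineError("structure", str(exc)) from exc

    if "phenotypes" in cfg:
        try:
            pheno = eio.read_phenotypes(cfg["phenotypes"])
            variants = classify_variants(pheno, alpha=cfg["alpha"])
            summary = trait_summary(pheno)
        except (OSError, ValueError) as exc:
            raise PipelineError("phenotype", str(exc)) from exc
        report["phenotype"] = {
            "variants": variants,
            "counts": {
                t: {k: len(v) for k, v in d.items()} for t, d in variants.items()
            },
        }
        if outdir is not None:
            summary.to_csv(outdir / "trait_summary.tsv", sep="\t", index=False)

    if outdir is not None:
        eio.write_report(report, outdir / "report.json")
    return report
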