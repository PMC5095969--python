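"""Cytosine contexts, bisulfite calling, conversion efficiency, fidelity."""

import numpy as np
import pytest
from Bio.Seq import Seq

from epimsap import (
    MethylationPattern,
    SimConfig,
    assign_contexts,
    bisulfite_align_and_call,
    conversion_efficiency,
    gen_bisulfite_family,
    in_silico_convert,
    inheritance_fidelity,
    region_methylation_percent,
)
from epimsap.bisulfite import AlignmentQualityError, check_primer


def plus_sites(sites):
    return {s.position: s for s in sites if s.strand == "+"}


class TestContexts:
    def test_palindromic_cg(self):
        sites = assign_contexts("AACGTT")
        by_key = {(s.position, s.strand): s.context for s in sites}
        assert by_key[(2, "+")] == "CG"
        assert by_key[(3, "-")] == "CG"

    @pytest.mark.parametrize("seq,ctx", [("AACAGT", "CHG"), ("AACAAT", "CHH")])
    def test_forward_contexts(self, seq, ctx):
        assert plus_sites(assign_contexts(seq))[2].context == ctx

    def test_edge_and_n_are_indeterminate(self):
        sites = plus_sites(assign_contexts("ATCNA"))
        assert sites[2].context == "INDETERMINATE"
        assert plus_sites(assign_contexts("AAAC"))[3].context == "INDETERMINATE"

    def test_reverse_complement_mirror(self):
        seq = "ACGGATCCTAGCAATCGA"
        rc = str(Seq(seq).reverse_complement())
        fwd = assign_contexts(seq)
        rev = assign_contexts(rc)
        L = len(seq)
        mirrored = sorted(
            (L - 1 - s.position, "+-"[s.strand == "+"], s.context) for s in rev
        )
        assert mirrored == sorted((s.position, s.strand, s.context) for s in fwd)


class TestAlignAndCall:
    def test_partial_conversion_example(self):
        pattern = bisulfite_align_and_call("CCGG", "TCGG")
        states = {s.position: s.state for s in pattern.sites}
        assert states[0] == "UNMETHYLATED" and states[1] == "METHYLATED"

    def test_unconverted_read_all_methylated(self):
        region = "ACGTCCGGATC"
        pattern = bisulfite_align_and_call(region, region)
        assert all(s.state == "METHYLATED" for s in pattern.sites)

    def test_fully_converted_read_all_unmethylated(self):
        region = "ACGTCCGGATC"
        read = region.replace("C", "T")
        pattern = bisulfite_align_and_call(region, read)
        assert all(s.state == "UNMETHYLATED" for s in pattern.sites)

    def test_round_trip_recovers_planted_set(self):
        rng = np.random.default_rng(0)
        region = "".join(rng.choice(list("ACGT"), size=400))
        cs = [i for i, b in enumerate(region) if b == "C"]
        planted = set(cs[::3])
        read = in_silico_convert(region, planted, conversion_rate=1.0, rng=rng)
        pattern = bisulfite_align_and_call(region, read)
        called = {s.position for s in pattern.sites if s.state == "METHYLATED"}
        assert called == planted

    def test_minus_strand_calls_g_positions(self):
        region = "AACGTT"
        # bottom-strand amplicon of the unmethylated region: revcomp fully converted
        read = in_silico_convert(
            str(Seq(region).reverse_complement()), set(), 1.0, np.random.default_rng(1)
        )
        pattern = bisulfite_align_and_call(region, read, strand="-")
        assert [s.position for s in pattern.sites] == [3]
        assert pattern.sites[0].strand == "-"
        assert pattern.sites[0].state == "UNMETHYLATED"

    def test_unrelated_read_rejected(self):
        with pytest.raises(AlignmentQualityError):
            bisulfite_align_and_call("ACGTAGGTAGGTAGGA", "TTTTTTCCCCCCAAAA")

    def test_region_methylation_percent(self):
        sites = [
            ("METHYLATED", 3),
            ("UNMETHYLATED", 1),
        ]
        from epimsap import CytosineSite

        pattern = MethylationPattern(
            "r",
            "x",
            [
                CytosineSite(i, "+", "CG", state)
                for i, state in enumerate(["METHYLATED"] * 3 + ["UNMETHYLATED"])
            ],
        )
        assert region_methylation_percent(pattern) == pytest.approx(75.0)
        empty = MethylationPattern("r", "x", [CytosineSite(0, "+", "CG", "AMBIGUOUS")])
        with pytest.raises(ValueError):
            region_methylation_percent(empty)


class TestConversionEfficiency:
    def test_full_conversion(self):
        rng = np.random.default_rng(2)
        lam = "".join(rng.choice(list("ACGT"), size=300))
        read = in_silico_convert(lam, set(), 1.0, rng)
        assert conversion_efficiency(lam, read) == pytest.approx(100.0)

    def test_no_conversion(self):
        rng = np.random.default_rng(3)
        lam = "".join(rng.choice(list("ACGT"), size=300))
        assert conversion_efficiency(lam, lam) == pytest.approx(0.0)

    def test_partial_rate_recovered_within_3_se(self):
        rng = np.random.default_rng(4)
        lam = "".join(rng.choice(list("ACGT"), size=1200))
        n_c = lam.count("C")
        rate = 0.95
        read = in_silico_convert(lam, set(), rate, rng)
        est = conversion_efficiency(lam, read) / 100.0
        se = np.sqrt(rate * (1 - rate) / n_c)
        assert abs(est - rate) <= 3 * se


class TestInheritanceFidelity:
    def test_identical_patterns_full_fidelity(self):
        rng = np.random.default_rng(5)
        region = "".join(rng.choice(list("ACGT"), size=300))
        cs = {i for i, b in enumerate(region) if b == "C"}
        parent = bisulfite_align_and_call(
            region, in_silico_convert(region, cs, 1.0, rng), individual="p"
        )
        kids = [
            bisulfite_align_and_call(
                region, in_silico_convert(region, cs, 1.0, rng), individual=f"k{i}"
            )
            for i in range(2)
        ]
        rep = inheritance_fidelity(parent, kids)
        assert rep.overall_fraction == 1.0
        assert all(
            d["fraction"] == 1.0 for d in rep.per_context.values() if d["n_sites"]
        )

    def test_opposite_patterns_zero_fidelity(self):
        rng = np.random.default_rng(6)
        region = "".join(rng.choice(list("ACGT"), size=300))
        cs = {i for i, b in enumerate(region) if b == "C"}
        parent = bisulfite_align_and_call(
            region, in_silico_convert(region, cs, 1.0, rng), individual="p"
        )
        kid = bisulfite_align_and_call(
            region, in_silico_convert(region, set(), 1.0, rng), individual="k"
        )
        assert inheritance_fidelity(parent, [kid]).overall_fraction == 0.0

    def test_region_mismatch_rejected(self):
        from epimsap import CytosineSite

        a = MethylationPattern("r1", "p", [CytosineSite(0, "+", "CG", "METHYLATED")])
        b = MethylationPattern("r2", "k", [CytosineSite(0, "+", "CG", "METHYLATED")])
        with pytest.raises(ValueError, match="region mismatch"):
            inheritance_fidelity(a, [b])

    def test_progeny_order_invariance(self):
        cfg = SimConfig(seed=12, conversion_rate=1.0)
        artifacts, _ = gen_bisulfite_family(cfg)
        region = artifacts["region"]
        parent = bisulfite_align_and_call(region, artifacts["reads"]["parent"], individual="p")
        kids = [
            bisulfite_align_and_call(region, artifacts["reads"][k], individual=k)
            for k in ("progeny1", "progeny2")
        ]
        f1 = inheritance_fidelity(parent, kids)
        f2 = inheritance_fidelity(parent, kids[::-1])
        assert f1.per_context == f2.per_context
        assert f1.overall_fraction == f2.overall_fraction

    def test_generator_truth_recovered_within_3_se(self):
        cfg = SimConfig(
            seed=13,
            region_length=2400,
            conversion_rate=1.0,
            fidelity={"CG": 1.0, "CHG": 0.85, "CHH": 0.85},
            n_progeny=1,
        )
        artifacts, truth = gen_bisulfite_family(cfg)
        region = artifacts["region"]
        parent = bisulfite_align_and_call(region, artifacts["reads"]["parent"], individual="p")
        kid = bisulfite_align_and_call(region, artifacts["reads"]["progeny1"], individual="k")
        rep = inheritance_fidelity(parent, [kid])
        assert rep.per_context["CG"]["fraction"] == 1.0
        for ctx in ("CHG", "CHH"):
            n = rep.per_context[ctx]["n_sites"]
            se = np.sqrt(0.85 * 0.15 / n)
            assert abs(rep.per_context[ctx]["fraction"] - 0.85) <= 3 * se


def test_primer_with_cytosine_warns():
    with pytest.warns(UserWarning, match="cytosine"):
        check_primer("ATTCGGA")
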