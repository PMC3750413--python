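"""EMS site enumeration, calling criteria, and effect annotation,
anchored on the published per-pool base-count rows."""

import math

import pytest

from batseq import (
    AmpliconPanel,
    AmpliconTarget,
    AnnotationInterval,
    PanelError,
    PileupMatrix,
    RunConfig,
    annotate_effect,
    detect_from_count_table,
    detect_mutations,
    ems_sites,
    interparalogue_mask,
    variant_ratio,
)
from batseq.datasets import (
    MIXED_GENES,
    mutation_screen_count_rows,
    mutation_screen_counts,
)


class TestEmsSites:
    def test_g_and_c_positions_enumerated(self):
        t = AmpliconTarget("T", "ATGC", "GG", "CC")
        sites = ems_sites(t)
        assert [(s.position, s.ref_base, s.candidate_variant) for s in sites] \
            == [(3, "G", "A"), (4, "C", "T")]

    def test_at_only_insert_has_no_sites(self):
        t = AmpliconTarget("T", "AATT", "GG", "CC")
        assert ems_sites(t) == []

    def test_published_rows_are_all_ems_consistent(self):
        """Every published ref-G row has candidate A, every ref-C row T."""
        df = mutation_screen_counts()
        assert set(df["ref_base"]) == {"G", "C"}
        for rec in df.itertuples():
            variant = "A" if rec.ref_base == "G" else "T"
            others = {"A", "C", "G", "T"} - {rec.ref_base, variant}
            counts = {"A": rec.A, "C": rec.C, "G": rec.G, "T": rec.T}
            # the candidate variant dominates the two non-candidate bases
            assert counts[variant] > max(counts[b] for b in others)


class TestInterparalogueMask:
    def test_single_difference_masked(self):
        a = AmpliconTarget("A", "ATGC", "GG", "CC", paralogue_group="P")
        b = AmpliconTarget("B", "ATGA", "GG", "CC", paralogue_group="P")
        assert interparalogue_mask([a, b]) == {4}

    def test_singleton_group_empty(self):
        a = AmpliconTarget("A", "ATGC", "GG", "CC")
        assert interparalogue_mask([a]) == set()

    def test_identical_members_empty(self):
        ts = [AmpliconTarget(n, "ATGCATGC", "GG", "CC", paralogue_group="P")
              for n in "ABC"]
        assert interparalogue_mask(ts) == set()

    def test_unequal_lengths_error(self):
        a = AmpliconTarget("A", "ATGC", "GG", "CC", paralogue_group="P")
        b = AmpliconTarget("B", "ATGCA", "GG", "CC", paralogue_group="P")
        with pytest.raises(PanelError, match="unequal length"):
            interparalogue_mask([a, b])


class TestVariantRatio:
    @pytest.mark.parametrize("counts,ref,var,expected", [
        ({"A": 183, "C": 0, "G": 1640, "T": 0}, "G", "A", 0.111585),
        ({"A": 0, "C": 3555, "G": 0, "T": 246}, "C", "T", 0.069198),
        ({"A": 97, "C": 0, "G": 352, "T": 0}, "G", "A", 0.275568),
    ])
    def test_published_spot_checks(self, counts, ref, var, expected):
        assert round(variant_ratio(counts, ref, var), 6) == expected

    def test_all_51_published_ratios_reproduced(self):
        """Recomputing variant/reference from the printed counts reproduces
        the printed ratio at its printed precision for every row."""
        with open_counts_with_printed_precision() as rows:
            for rec, printed, decimals in rows:
                counts = {b: getattr(rec, b) for b in "ACGT"}
                var = "A" if rec.ref_base == "G" else "T"
                assert round(variant_ratio(counts, rec.ref_base, var),
                             decimals) == pytest.approx(printed)

    def test_zero_reference_with_variant_is_infinite(self):
        assert math.isinf(variant_ratio(
            {"A": 5, "C": 0, "G": 0, "T": 0}, "G", "A"))

    def test_all_zero_is_undefined(self):
        assert math.isnan(variant_ratio(
            {"A": 0, "C": 0, "G": 0, "T": 0}, "G", "A"))


import contextlib
from importlib import resources


@contextlib.contextmanager
def open_counts_with_printed_precision():
    """Rows paired with the printed ratio string's own decimal precision."""
    import pandas as pd

    with resources.files("batseq.data").joinpath(
        "bnapus_mutation_screen_counts.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"ratio": str})
    out = []
    for rec in df.itertuples():
        printed = rec.ratio
        decimals = len(printed.split(".")[1])
        out.append((rec, float(printed), decimals))
    yield out


class TestDetector:
    def test_published_rows_verdicts(self, cfg):
        """49 of the 51 published rows pass the strict criteria; the two
        documented borderline rows surface as near-misses, not drops."""
        cands = detect_from_count_table(mutation_screen_count_rows(), cfg)
        assert len(cands) == 51
        passes = [c for c in cands if c.is_pass]
        nears = [c for c in cands if c.near_miss]
        assert len(passes) == 49
        near_keys = {(c.pool, c.target_name, c.position) for c in nears}
        assert near_keys == {("B00118", "BnaA.FAD2.b", 237),
                             ("B00115", "BnaC.GL2.b", 143)}
        # the signal near-miss fails criterion 2 only; the SNR one criterion 3
        by_key = {(c.pool, c.target_name, c.position): c for c in cands}
        assert by_key[("B00118", "BnaA.FAD2.b", 237)].passes == {
            "min_reads": True, "signal": False, "snr": True}
        assert by_key[("B00115", "BnaC.GL2.b", 143)].passes == {
            "min_reads": True, "signal": True, "snr": False}

    def test_snr_uses_max_not_sum_of_other_bases(self, cfg):
        # 77 candidate vs others 7 and 2: max gives 11 (pass), sum would
        # give 8.6 (fail) -- the published row passes
        row = {"pool": "p", "target": "t", "position": 46, "ref_base": "C",
               "A": 7, "C": 5431, "G": 2, "T": 77, "is_mixed": True}
        (cand,) = detect_from_count_table([row], cfg)
        assert cand.snr == pytest.approx(77 / 7)
        assert cand.is_pass

    def test_nine_variant_reads_fail_min_reads(self, cfg):
        row = {"pool": "p", "target": "t", "position": 1, "ref_base": "C",
               "A": 5, "C": 32262, "G": 0, "T": 9, "is_mixed": False}
        (cand,) = detect_from_count_table([row], cfg)
        assert not cand.passes["min_reads"] and not cand.is_pass

    def test_specific_threshold_accepts_low_signal(self, cfg):
        row = {"pool": "p", "target": "t", "position": 113, "ref_base": "C",
               "A": 5, "C": 32262, "G": 0, "T": 70, "is_mixed": False}
        (cand,) = detect_from_count_table([row], cfg)
        assert cand.is_pass
        # the same counts at mixed thresholds fail on signal
        row["is_mixed"] = True
        (cand2,) = detect_from_count_table([row], cfg)
        assert not cand2.passes["signal"]

    def test_threshold_monotonicity(self):
        """Raising any threshold never adds a passing candidate."""
        rows = mutation_screen_count_rows()
        base = RunConfig()
        base_pass = {(c.pool, c.target_name, c.position)
                     for c in detect_from_count_table(rows, base)
                     if c.is_pass}
        for stricter in (
            RunConfig(min_variant_reads=20),
            RunConfig(signal_threshold_mixed=0.02),
            RunConfig(signal_threshold_specific=0.004),
            RunConfig(snr_threshold=20),
        ):
            strict_pass = {(c.pool, c.target_name, c.position)
                           for c in detect_from_count_table(rows, stricter)
                           if c.is_pass}
            assert strict_pass <= base_pass

    def test_only_transitions_ever_emitted(self, cfg):
        """No candidate for A/T reference bases; candidates are G->A / C->T."""
        panel = AmpliconPanel([AmpliconTarget("T", "ATGCATGC", "GG", "CC")])
        pileup = PileupMatrix(panel)
        # passing-strength transition signal at every position, whatever the
        # reference base there
        for pos, base in enumerate("ATGCATGC", start=1):
            counts = {"A": 2, "C": 1, "G": 3, "T": 2}
            counts[base] = 1500
            counts["A" if base in "GA" else "T"] += 150
            pileup.set_counts("p", "T", pos,
                              [counts[b] for b in "ACGT"])
        cands = detect_mutations(pileup, panel, cfg)
        assert len(cands) == 4  # only the two G and two C sites
        assert all(c.ref_base in "GC" for c in cands)
        assert all((c.ref_base, c.variant_base) in {("G", "A"), ("C", "T")}
                   for c in cands)

    def test_masked_positions_skipped(self, cfg):
        a = AmpliconTarget("A", "AAGAAAAA", "GG", "CC", paralogue_group="P")
        b = AmpliconTarget("B", "AACAAAAA", "GG", "CC", paralogue_group="P")
        panel = AmpliconPanel([a, b])
        pileup = PileupMatrix(panel)
        pileup.set_counts("p", "A", 3, [100, 0, 900, 0])  # divergent position
        assert detect_mutations(pileup, panel, cfg) == []


class TestAnnotateEffect:
    @pytest.fixture
    def coding_target(self):
        # insert: ATG GAA TGG TAT | intron TTTTTT
        return AmpliconTarget(
            "T", "ATGGAATGGTAT" + "TTTTTT", "GG", "CC",
            annotation=[AnnotationInterval(1, 12, "exon", frame_offset=0),
                        AnnotationInterval(13, 18, "intron")],
        )

    def test_missense(self, coding_target):
        # GAA (Glu) -> AAA (Lys) at codon position 1
        assert annotate_effect(coding_target, 4, "G", "A") \
            == "missense(Glu->Lys)"

    def test_stop_gain(self, coding_target):
        # TGG (Trp) -> TAG at codon position 2
        assert annotate_effect(coding_target, 8, "G", "A") == "STOP"

    def test_synonymous(self, coding_target):
        # TAT (Tyr) -> TAC would be synonymous but not EMS; use GAA->GAG? not
        # EMS either -- check via TGG position 9 G->A = TGA stop... instead
        # test a real wobble: codon GGA if present; fall back to direct codon
        t = AmpliconTarget("T", "CTCTTTTTT", "GG", "CC",
                           annotation=[AnnotationInterval(1, 9, "exon")])
        # CTC (Leu) -> CTT (Leu): wobble C->T at position 3
        assert annotate_effect(t, 3, "C", "T") == "synonymous(Leu)"

    def test_intron_and_uncovered(self, coding_target):
        assert annotate_effect(coding_target, 15, "T", "A") == "intron"
        t = AmpliconTarget("T", "ATGGAATGG", "GG", "CC",
                           annotation=[AnnotationInterval(1, 6, "exon")])
        assert annotate_effect(t, 8, "G", "A") == "not_covered"
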