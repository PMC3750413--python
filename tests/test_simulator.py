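"""Simulator determinism, noise-free limits, and planted-mutation fractions."""

import numpy as np
import pytest

from batseq import (
    PlantedMutation,
    ReadCategory,
    RunConfig,
    SimulationConfig,
    classify_read,
    build_references,
    make_barcode_set,
    make_genotyping_panel,
    make_mutation_panel,
    make_spike_references,
    map_reads,
    simulate_run,
)
from batseq.barcode_engine import mung_read
from batseq.simulator import covered_windows
from batseq.tilling import EMS_CANDIDATE, interparalogue_mask


@pytest.fixture(scope="module")
def setup():
    cfg = RunConfig()
    bset = make_barcode_set(8, seed=31)
    panel = make_genotyping_panel(n_targets=3, seed=31)
    spikes = make_spike_references(bset, cfg.m13_seq, seed=31)
    return cfg, bset, panel, spikes


def test_identical_seed_identical_output(setup):
    cfg, bset, panel, spikes = setup
    sim = SimulationConfig(mode="genotyping", n_lines=4,
                           reads_per_product_mean=30, rng_seed=9)
    reads1, truth1 = simulate_run(sim, bset, panel, cfg, spikes)
    reads2, truth2 = simulate_run(sim, bset, panel, cfg, spikes)
    assert [(r.read_id, r.seq, r.quals) for r in reads1] \
        == [(r.read_id, r.seq, r.quals) for r in reads2]
    assert truth1.reads.equals(truth2.reads)


def test_noise_free_intact_run_maps_perfectly(setup):
    """With no error, no truncation and no spike, every read is an intact
    6 bp BAT read and maps to its generating (barcode, target) with 0
    mismatches."""
    cfg, bset, panel, spikes = setup
    # reference-parent genotypes everywhere (variant fraction 0), so reads
    # are exact copies of their reference
    genotypes = {line: {f"{t.name}:{s.position}": "A"
                        for t in panel for s in t.snp_sites}
                 for line in bset.labels[:4]}
    sim = SimulationConfig(mode="genotyping", n_lines=4,
                           reads_per_product_mean=25, per_base_error=0.0,
                           truncation_probs=(1.0, 0.0, 0.0, 0.0),
                           spike_fraction=0.0, genotypes=genotypes,
                           rng_seed=10)
    reads, truth = simulate_run(sim, bset, panel, cfg, [])
    truth_by_id = truth.reads.set_index("read_id")
    munged = []
    expected = []
    for read in reads:
        cat, obs = classify_read(read, bset, [], cfg.m13_seq, cfg)
        assert cat is ReadCategory.M13_6BP
        munged.append(mung_read(read, obs.repaired, cfg.m13_seq))
        row = truth_by_id.loc[read.read_id]
        expected.append((row["barcode_label"], row["target"]))
    refs = build_references(bset, panel, cfg.m13_seq,
                            occupied=bset.labels[:4])
    for mr, (label, target) in zip(map_reads(munged, refs, cfg), expected):
        assert mr is not None and mr.mismatches == 0
        assert (mr.barcode_label, mr.target_name) == (label, target)


def test_forced_two_base_truncation_always_repairs(setup):
    cfg, bset, panel, spikes = setup
    sim = SimulationConfig(mode="genotyping", n_lines=4,
                           reads_per_product_mean=25, per_base_error=0.0,
                           truncation_probs=(0.0, 0.0, 1.0, 0.0),
                           spike_fraction=0.0, rng_seed=11)
    reads, truth = simulate_run(sim, bset, panel, cfg, [])
    truth_by_id = truth.reads.set_index("read_id")
    for read in reads:
        cat, obs = classify_read(read, bset, [], cfg.m13_seq, cfg)
        assert cat is ReadCategory.M13_4BP
        label = truth_by_id.loc[read.read_id, "barcode_label"]
        assert obs.repaired == bset.barcode_of(label)


def test_planted_heterozygous_pool_fraction_is_binomial(setup):
    """A het mutation in 1 of 8 equally weighted pooled lines puts the
    variant on ~1/16 of the locus' reads (within 3 binomial SE)."""
    cfg, bset, _, _ = setup
    panel = make_mutation_panel(seed=12)
    target = panel["SPEC.a"]
    fwd_sim = SimulationConfig(mode="mutation_screen", paired=False)
    site = next(p for p in sorted(covered_windows(target, cfg, fwd_sim))
                if target.insert_seq[p - 1] in EMS_CANDIDATE)
    sim = SimulationConfig(mode="mutation_screen", n_pools=1,
                           reads_per_product_mean=5000,
                           per_base_error=0.0, spike_fraction=0.0,
                           truncation_probs=(1.0, 0.0, 0.0, 0.0),
                           mutations=[PlantedMutation(
                               pool=bset.labels[0], line_index=3,
                               target_name="SPEC.a", position=site)],
                           rng_seed=13)
    reads, truth = simulate_run(sim, bset, panel, cfg, [])
    assert truth.mutations.iloc[0]["expected_fraction"] == pytest.approx(1 / 16)
    prefix = 6 + len(cfg.m13_seq) + len(target.fwd_primer)
    variant = EMS_CANDIDATE[target.insert_seq[site - 1]]
    spec_ids = set(truth.reads.query("target == 'SPEC.a'")["read_id"])
    n = k = 0
    for read in reads:
        if read.read_id in spec_ids:
            n += 1
            if read.seq[prefix + site - 1] == variant:
                k += 1
    p = 1 / 16
    se = np.sqrt(n * p * (1 - p))
    assert abs(k - n * p) <= 3 * se


def test_mutation_panel_has_discriminating_divergence():
    """Co-amplified paralogues differ at >=3 positions inside each read
    window, so error-free reads never tie across paralogues."""
    cfg = RunConfig()
    panel = make_mutation_panel(seed=14)
    sim = SimulationConfig(mode="mutation_screen")
    group = panel.paralogue_groups["PARA"]
    mask = interparalogue_mask(group)
    fwd = covered_windows(group[0], cfg, SimulationConfig(
        mode="mutation_screen", paired=False))
    both = covered_windows(group[0], cfg, sim)
    tail = both - fwd
    for i in range(len(group)):
        for j in range(i + 1, len(group)):
            diffs = {p + 1 for p, (a, b) in enumerate(
                zip(group[i].insert_seq, group[j].insert_seq)) if a != b}
            assert len(diffs & fwd) >= 3
            assert len(diffs & tail) >= 3
    assert mask == {p + 1 for p, bases in enumerate(zip(
        *[t.insert_seq for t in group])) if len(set(bases)) > 1}


def test_expected_tally_closed_form():
    sim = SimulationConfig(mode="genotyping", spike_fraction=1 / 11)
    exp = expected = None
    from batseq import expected_tally

    exp = expected_tally(sim)
    assert exp[ReadCategory.SPIKE] == pytest.approx(1 / 11)
    assert sum(exp.values()) == pytest.approx(1.0)
    # the genotyping defaults reproduce the observed class mix shape
    m13_total = sum(exp[c] for c in (ReadCategory.M13_6BP, ReadCategory.M13_5BP,
                                     ReadCategory.M13_4BP,
                                     ReadCategory.M13_LT4BP))
    assert exp[ReadCategory.M13_6BP] / m13_total == pytest.approx(0.023)
    assert exp[ReadCategory.M13_4BP] / m13_total == pytest.approx(0.422)
    # all mass on >=3 lost bases -> nothing mungeable
    sim2 = SimulationConfig(mode="genotyping",
                            truncation_probs=(0.0, 0.0, 0.0, 1.0))
    exp2 = expected_tally(sim2)
    assert exp2[ReadCategory.M13_6BP] == exp2[ReadCategory.M13_5BP] \
        == exp2[ReadCategory.M13_4BP] == 0.0
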