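"""End-to-end orchestration: classify -> mung -> map -> pile up -> call.

Thin glue over the stage modules, used by the command-line interface and the
recovery tests.  Both runners take in-memory reads so simulated runs can be
pushed through without touching disk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .barcode_engine import mung_read
from .demux import DemuxTally, ReadCategory, classify_read, tally
from .genotyper import call_genotypes, scoring_strings
from .mapper import (
    PileupMatrix,
    attach_mate_tag,
    build_pileup,
    build_references,
    map_reads,
)
from .panel_io import AmpliconPanel, BarcodeSet, ReadRecord, RunConfig
from .tilling import detect_mutations

__all__ = ["RunResult", "demux_and_map", "genotype_run", "mutation_run"]


@dataclass
class RunResult:
    tally: DemuxTally
    pileup: PileupMatrix
    mapped_count: int
    genotype_calls: Optional[list] = None
    scoring: Optional[list] = None
    candidates: Optional[list] = None


def demux_and_map(
    reads: Sequence[ReadRecord],
    bset: BarcodeSet,
    panel: AmpliconPanel,
    cfg: RunConfig,
    spikes: Sequence[str] = (),
    occupied: Optional[Sequence[str]] = None,
    paired: bool = False,
) -> tuple:
    """Classify, repair, mung and competitively map a whole run.

    Returns (tally, pileup, n_mapped).  In paired mode the mate of every
    repairable read is tagged with its pair's munged barcode and mapped
    against the reverse-orientation references.
    """
    classifications = []
    munged = []
    mates = []
    for read in reads:
        cat, obs = classify_read(read, bset, spikes, cfg.m13_seq, cfg)
        classifications.append(cat)
        if obs is not None and obs.repaired is not None:
            munged.append(mung_read(read, obs.repaired, cfg.m13_seq))
            if paired:
                mate = attach_mate_tag(read, obs.repaired, cfg.m13_seq)
                if mate is not None:
                    mates.append(mate)
    t = tally(classifications)
    fwd_refs = build_references(bset, panel, cfg.m13_seq, occupied, "fwd")
    mapped = list(zip(map_reads(munged, fwd_refs, cfg), munged))
    if mates:
        rev_refs = build_references(bset, panel, cfg.m13_seq, occupied, "rev")
        mapped += list(zip(map_reads(mates, rev_refs, cfg), mates))
    pileup = build_pileup(mapped, panel, cfg)
    n_mapped = sum(1 for mr, _ in mapped if mr is not None and mr.used)
    return t, pileup, n_mapped


def genotype_run(
    reads: Sequence[ReadRecord],
    bset: BarcodeSet,
    panel: AmpliconPanel,
    cfg: RunConfig,
    spikes: Sequence[str] = (),
    lines: Optional[Sequence[str]] = None,
) -> RunResult:
    """Full genotyping pipeline -> per-line calls and A/B/U scoring strings."""
    lines = list(lines) if lines is not None else list(bset.labels)
    t, pileup, n_mapped = demux_and_map(
        reads, bset, panel, cfg, spikes, occupied=lines, paired=False
    )
    calls = call_genotypes(pileup, panel, lines, cfg)
    strings = scoring_strings(calls, lines)
    return RunResult(tally=t, pileup=pileup, mapped_count=n_mapped,
                     genotype_calls=calls, scoring=strings)


def mutation_run(
    reads: Sequence[ReadRecord],
    bset: BarcodeSet,
    panel: AmpliconPanel,
    cfg: RunConfig,
    spikes: Sequence[str] = (),
    pools: Optional[Sequence[str]] = None,
    paired: bool = True,
) -> RunResult:
    """Full pooled mutation screen -> per-pool mutation candidates."""
    pools = list(pools) if pools is not None else list(bset.labels)
    t, pileup, n_mapped = demux_and_map(
        reads, bset, panel, cfg, spikes, occupied=pools, paired=paired
    )
    candidates = detect_mutations(pileup, panel, cfg)
    return RunResult(tally=t, pileup=pileup, mapped_count=n_mapped,
                     candidates=candidates)
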