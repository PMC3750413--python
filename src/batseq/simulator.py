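"""Synthetic BAT sequencing runs with ground truth.

Emulates the read structure of a BAT library -- a possibly 5'-truncated
6-base barcode, the M13(-21) anchor, the locus-specific forward primer and
the template -- together with the nuisance processes of a real run:
exonucleolytic barcode truncation, spike admixture at ~1:10, amplification
bias between co-amplified paralogues, substitution sequencing error, and
(in mutation-screen mode) one-dimensional 8-fold line pooling with planted
EMS mutations at their expected allele fractions.

Two run modes mirror the two applications:

* ``genotyping`` -- single-end reads from individually barcoded doubled-
  haploid lines with hemi-SNP markers (default truncation mix 2.3 / 18.4 /
  42.2 / 37.1 % for 0/1/2/>=3 lost bases, the composition of the original
  genotyping lane);
* ``mutation_screen`` -- paired-end reads from 8-fold pools (default
  truncation mix 89.5 / 3.7 / 1.7 / 3.8 %, the improved-protocol lanes),
  with planted G->A / C->T mutations.

Identical seeds give byte-identical output.  The quality model is
deliberately simple: a fixed high Phred (38) with error bases assigned
random lower qualities, enough to exercise the base-quality filter without
modelling full instrument error profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .barcode_engine import design_spike_prefix
from .demux import ReadCategory
from .panel_io import (
    AmpliconPanel,
    AmpliconTarget,
    AnnotationInterval,
    BarcodeSet,
    PanelError,
    ReadRecord,
    RunConfig,
    SnpSite,
    iupac_set,
    revcomp,
)
from .tilling import EMS_CANDIDATE

__all__ = [
    "PlantedMutation",
    "SimulationConfig",
    "TruthTable",
    "simulate_run",
    "expected_tally",
    "covered_windows",
    "make_barcode_set",
    "make_spike_references",
    "make_genotyping_panel",
    "make_mutation_panel",
]

_BASE_QUALITY = 38
_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


@dataclass(frozen=True)
class PlantedMutation:
    """An EMS mutation planted in one line of one pool."""

    pool: str  # barcode label of the pool
    line_index: int  # 0-based line within the pool
    target_name: str
    position: int  # 1-based insert coordinate; must be an EMS-mutable base
    zygosity: str = "het"  # "het" (allele fraction 1/2) or "hom" (1)


@dataclass
class SimulationConfig:
    """Study conditions of a simulated run.

    ``truncation_probs`` are the probabilities of losing 0, 1, 2 or >=3
    barcode bases; mode-specific defaults reproduce the observed class
    mixes of the original runs.  ``spike_fraction`` defaults to 1/11
    (a 1:10 spike admixture).
    """

    mode: str = "genotyping"  # "genotyping" | "mutation_screen"
    n_lines: int = 46
    n_pools: int = 8
    pool_size: int = 8
    read_length: int = 76
    paired: Optional[bool] = None  # default: mutation_screen yes, genotyping no
    reads_per_product_mean: float = 400.0
    reads_per_product_dispersion: Optional[float] = None  # NB size; None=Poisson
    truncation_probs: Optional[Tuple[float, float, float, float]] = None
    per_base_error: float = 0.001
    spike_fraction: float = 1.0 / 11.0
    paralogue_bias: Dict[str, float] = field(default_factory=dict)
    line_weights: Optional[Sequence[float]] = None  # within-pool DNA balance
    mutations: List[PlantedMutation] = field(default_factory=list)
    mutation_rate: float = 0.0  # alternative: random placement per pool
    m13_truncation_prob: float = 0.0  # truncation reaching into the M13 anchor
    genotypes: Optional[Dict[str, Dict[str, str]]] = None  # line -> marker -> A/B
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("genotyping", "mutation_screen"):
            raise PanelError(f"mode {self.mode!r}")
        if self.paired is None:
            self.paired = self.mode == "mutation_screen"
        if self.truncation_probs is None:
            # observed class mixes of the two original run types (the
            # improved-protocol percentages are renormalised to sum to 1)
            raw = ((0.023, 0.184, 0.422, 0.371) if self.mode == "genotyping"
                   else (0.895, 0.037, 0.017, 0.038))
            scale = (1.0 - self.m13_truncation_prob) / sum(raw)
            self.truncation_probs = tuple(p * scale for p in raw)
        total = sum(self.truncation_probs) + self.m13_truncation_prob
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise PanelError(
                "truncation_probs (+ m13_truncation_prob) must sum to 1"
            )
        if not 0.0 <= self.spike_fraction < 1.0:
            raise PanelError("spike_fraction must be in [0, 1)")
        if any(w <= 0 for w in self.paralogue_bias.values()):
            raise PanelError("paralogue_bias weights must be positive")


@dataclass
class TruthTable:
    """Ground truth of a simulated run."""

    reads: pd.DataFrame  # read_id, barcode_label, target, truncation, is_spike, line_index
    genotypes: pd.DataFrame  # line, marker, allele (genotyping mode)
    mutations: pd.DataFrame  # pool, line_index, target, position, ref, variant,
    #                          zygosity, expected_fraction


def covered_windows(target: AmpliconTarget, cfg: RunConfig, sim: SimulationConfig
                    ) -> set:
    """Insert positions covered by every read of this target.

    With an intact barcode the forward read reaches
    ``read_length - 24 - len(m13) - len(fwd_primer)`` insert bases (barcode
    truncation only shortens the prefix, extending coverage); the mate covers
    the last ``read_length - len(rev_primer)`` bases.  Sites outside the
    guaranteed window cannot reach full per-read depth.
    """
    fwd_span = sim.read_length - 6 - len(cfg.m13_seq) - len(target.fwd_primer)
    window = set(range(1, max(0, min(fwd_span, target.insert_len)) + 1))
    if sim.paired:
        rev_span = sim.read_length - len(target.rev_primer)
        start = max(1, target.insert_len - rev_span + 1)
        window |= set(range(start, target.insert_len + 1))
    return window


# ---------------------------------------------------------------------------
# Read construction
# ---------------------------------------------------------------------------

def _apply_errors(seq: str, rate: float, rng: np.random.Generator
                  ) -> Tuple[str, list]:
    """Substitution errors at ``rate``; error bases get a random low quality."""
    quals = [_BASE_QUALITY] * len(seq)
    if rate <= 0:
        return seq, quals
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq, quals
    chars = list(seq)
    positions = rng.choice(len(seq), size=n_err, replace=False)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(3)]
        quals[pos] = int(rng.integers(2, _BASE_QUALITY + 1))
    return "".join(chars), quals


def _draw_truncation(sim: SimulationConfig, rng: np.random.Generator) -> int:
    """Number of barcode bases lost; 7 encodes truncation into the M13 anchor."""
    probs = list(sim.truncation_probs) + [sim.m13_truncation_prob]
    choice = rng.choice(5, p=np.array(probs) / sum(probs))
    if choice <= 2:
        return int(choice)
    if choice == 3:
        return int(rng.integers(3, 7))  # lose 3..6 barcode bases
    return 7


def _draw_counts(n_products: int, sim: SimulationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    mean = sim.reads_per_product_mean
    k = sim.reads_per_product_dispersion
    if k is None:
        return rng.poisson(mean, size=n_products)
    p = k / (k + mean)
    return rng.negative_binomial(k, p, size=n_products)


def _instantiate_iupac(pattern: str, rng: np.random.Generator) -> str:
    out = []
    for letter in pattern:
        choices = sorted(iupac_set(letter))
        out.append(choices[rng.integers(len(choices))] if len(choices) > 1
                   else choices[0])
    return "".join(out)


def _build_read(
    read_id: str,
    barcode: str,
    target: AmpliconTarget,
    insert: str,
    lost: int,
    sim: SimulationConfig,
    m13: str,
    rng: np.random.Generator,
) -> Optional[ReadRecord]:
    if lost >= 7:  # truncation into the anchor: unmatched read
        template = (barcode + m13)[lost + 2:] + target.fwd_primer + insert
    else:
        template = barcode[lost:] + m13 + target.fwd_primer + insert
    fwd = template[: sim.read_length]
    seq, quals = _apply_errors(fwd, sim.per_base_error, rng)
    mate = None
    if sim.paired:
        amplicon = target.fwd_primer + insert
        raw_mate = (target.rev_primer + revcomp(amplicon))[: sim.read_length]
        mseq, mquals = _apply_errors(raw_mate, sim.per_base_error, rng)
        mate = (mseq, mquals)
    return ReadRecord(read_id=read_id, seq=seq, quals=quals, mate=mate)


# ---------------------------------------------------------------------------
# Run simulation
# ---------------------------------------------------------------------------

def simulate_run(
    sim: SimulationConfig,
    bset: BarcodeSet,
    panel: AmpliconPanel,
    cfg: RunConfig,
    spikes: Sequence[str] = (),
) -> Tuple[list, TruthTable]:
    """Generate a full run -> (reads, truth).

    Non-spike reads follow the BAT layout with the configured truncation,
    error, bias and pooling processes; spike reads are drawn from the given
    spike references with their degenerate prefixes instantiated at random.
    """
    rng = np.random.default_rng(sim.rng_seed)
    if sim.mode == "genotyping":
        reads, truth_rows, geno_rows = _simulate_genotyping(
            sim, bset, panel, cfg, rng
        )
        mut_df = pd.DataFrame(
            columns=["pool", "line_index", "target", "position", "ref",
                     "variant", "zygosity", "expected_fraction"]
        )
        geno_df = pd.DataFrame(geno_rows, columns=["line", "marker", "allele"])
    else:
        reads, truth_rows, mut_rows = _simulate_mutation_screen(
            sim, bset, panel, cfg, rng
        )
        geno_df = pd.DataFrame(columns=["line", "marker", "allele"])
        mut_df = pd.DataFrame(
            mut_rows,
            columns=["pool", "line_index", "target", "position", "ref",
                     "variant", "zygosity", "expected_fraction"],
        )

    # Spike admixture: s/(1-s) spike reads per template read.
    if sim.spike_fraction > 0 and spikes:
        n_spike = rng.poisson(
            len(reads) * sim.spike_fraction / (1.0 - sim.spike_fraction)
        )
        for i in range(n_spike):
            ref = spikes[rng.integers(len(spikes))]
            mol = _instantiate_iupac(ref, rng)
            seq, quals = _apply_errors(
                mol[: sim.read_length], sim.per_base_error, rng
            )
            mate = None
            if sim.paired:
                raw = revcomp(mol)[: sim.read_length]
                mseq, mquals = _apply_errors(raw, sim.per_base_error, rng)
                mate = (mseq, mquals)
            rid = f"spike:{i}"
            reads.append(ReadRecord(rid, seq, quals, mate=mate))
            truth_rows.append(
                {"read_id": rid, "barcode_label": "", "target": "",
                 "truncation": 0, "is_spike": True, "line_index": -1}
            )

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth_rows = [truth_rows[i] for i in order]
    truth = TruthTable(
        reads=pd.DataFrame(
            truth_rows,
            columns=["read_id", "barcode_label", "target", "truncation",
                     "is_spike", "line_index"],
        ),
        genotypes=geno_df,
        mutations=mut_df,
    )
    return reads, truth


def _target_weights(panel: AmpliconPanel, sim: SimulationConfig) -> np.ndarray:
    w = np.array([sim.paralogue_bias.get(t.name, 1.0) for t in panel])
    return w / w.sum()


def _simulate_genotyping(sim, bset, panel, cfg, rng):
    lines = list(bset.labels[: sim.n_lines])
    if len(lines) < sim.n_lines:
        raise PanelError("barcode panel smaller than n_lines")
    genotypes = sim.genotypes
    if genotypes is None:
        genotypes = {
            line: {
                f"{t.name}:{s.position}": ("A" if rng.random() < 0.5 else "B")
                for t in panel for s in t.snp_sites
            }
            for line in lines
        }
    reads: list = []
    truth_rows: list = []
    geno_rows = [
        {"line": line, "marker": marker, "allele": allele}
        for line, markers in genotypes.items()
        for marker, allele in markers.items()
    ]
    weights = _target_weights(panel, sim)
    counter = 0
    for line in lines:
        barcode = bset.barcode_of(line)
        counts = _draw_counts(len(panel), sim, rng)
        for target, n in zip(panel, (counts * weights * len(panel)).astype(int)):
            for _ in range(n):
                insert = list(target.insert_seq)
                for site in target.snp_sites:
                    marker = f"{target.name}:{site.position}"
                    allele = genotypes[line].get(marker)
                    frac = (site.expected_a_fraction if allele == "A"
                            else site.expected_b_fraction)
                    base = (site.allele_a_base if allele == "A"
                            else site.allele_b_base)
                    if rng.random() < frac:
                        insert[site.position - 1] = base
                lost = _draw_truncation(sim, rng)
                rid = f"r{counter}"
                counter += 1
                read = _build_read(rid, barcode, target, "".join(insert),
                                   lost, sim, cfg.m13_seq, rng)
                reads.append(read)
                truth_rows.append(
                    {"read_id": rid, "barcode_label": line,
                     "target": target.name, "truncation": lost,
                     "is_spike": False, "line_index": -1}
                )
    return reads, truth_rows, geno_rows


def _simulate_mutation_screen(sim, bset, panel, cfg, rng):
    pools = list(bset.labels[: sim.n_pools])
    if len(pools) < sim.n_pools:
        raise PanelError("barcode panel smaller than n_pools")
    mutations = list(sim.mutations)
    if sim.mutation_rate > 0 and not mutations:
        for pool in pools:
            for target in panel:
                if rng.random() >= sim.mutation_rate:
                    continue
                window = covered_windows(target, cfg, sim)
                sites = [p for p in sorted(window)
                         if target.insert_seq[p - 1] in EMS_CANDIDATE]
                if sites:
                    mutations.append(PlantedMutation(
                        pool=pool,
                        line_index=int(rng.integers(sim.pool_size)),
                        target_name=target.name,
                        position=sites[rng.integers(len(sites))],
                    ))
    planted: dict = {}
    mut_rows = []
    for m in mutations:
        target = panel[m.target_name]
        ref = target.insert_seq[m.position - 1]
        if ref not in EMS_CANDIDATE:
            raise PanelError(
                f"planted mutation at {m.target_name}:{m.position}: "
                f"reference base {ref!r} is not EMS-mutable"
            )
        allele_fraction = 0.5 if m.zygosity == "het" else 1.0
        planted.setdefault((m.pool, m.target_name), []).append(
            (m.line_index, m.position, EMS_CANDIDATE[ref], allele_fraction)
        )
        weights = sim.line_weights or [1.0] * sim.pool_size
        line_share = weights[m.line_index] / sum(weights)
        mut_rows.append(
            {"pool": m.pool, "line_index": m.line_index,
             "target": m.target_name, "position": m.position, "ref": ref,
             "variant": EMS_CANDIDATE[ref], "zygosity": m.zygosity,
             "expected_fraction": line_share * allele_fraction}
        )
    line_w = np.array(sim.line_weights or [1.0] * sim.pool_size, dtype=float)
    line_w = line_w / line_w.sum()
    weights = _target_weights(panel, sim)
    reads: list = []
    truth_rows: list = []
    counter = 0
    for pool in pools:
        barcode = bset.barcode_of(pool)
        counts = _draw_counts(len(panel), sim, rng)
        for target, n in zip(panel, (counts * weights * len(panel)).astype(int)):
            muts_here = planted.get((pool, target.name), [])
            for _ in range(n):
                line_idx = int(rng.choice(sim.pool_size, p=line_w))
                insert = target.insert_seq
                for (midx, pos, var, frac) in muts_here:
                    if midx == line_idx and rng.random() < frac:
                        insert = insert[: pos - 1] + var + insert[pos:]
                lost = _draw_truncation(sim, rng)
                rid = f"r{counter}"
                counter += 1
                read = _build_read(rid, barcode, target, insert, lost,
                                   sim, cfg.m13_seq, rng)
                reads.append(read)
                truth_rows.append(
                    {"read_id": rid, "barcode_label": pool,
                     "target": target.name, "truncation": lost,
                     "is_spike": False, "line_index": line_idx}
                )
    return reads, truth_rows, mut_rows


def expected_tally(sim: SimulationConfig) -> Dict[ReadCategory, float]:
    """Closed-form expected category proportions of a simulated run."""
    s = sim.spike_fraction
    p0, p1, p2, p3 = sim.truncation_probs
    rest = 1.0 - s
    return {
        ReadCategory.SPIKE: s,
        ReadCategory.M13_6BP: rest * p0,
        ReadCategory.M13_5BP: rest * p1,
        ReadCategory.M13_4BP: rest * p2,
        ReadCategory.M13_LT4BP: rest * p3,
        ReadCategory.UNMATCHED: rest * sim.m13_truncation_prob,
    }


# ---------------------------------------------------------------------------
# Synthetic panels (programmatic fixtures)
# ---------------------------------------------------------------------------

def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(4, size=n)])


def make_barcode_set(n: int, seed: int = 0, suffix_len: int = 4) -> BarcodeSet:
    """A synthetic panel of n 6-base barcodes with distinct suffixes."""
    rng = np.random.default_rng(seed)
    if n > 4 ** suffix_len:
        raise PanelError("suffix address space too small for n barcodes")
    suffix_idx = rng.choice(4 ** suffix_len, size=n, replace=False)
    barcodes = []
    for idx in suffix_idx:
        sfx = ""
        v = int(idx)
        for _ in range(suffix_len):
            sfx = "ACGT"[v % 4] + sfx
            v //= 4
        barcodes.append(_random_seq(6 - suffix_len, rng) + sfx)
    labels = [f"B{i + 1:05d}" for i in range(n)]
    return BarcodeSet(barcodes=barcodes, labels=labels,
                      address_suffix_len=suffix_len)


def make_spike_references(bset: BarcodeSet, m13: str, seed: int = 0,
                          n: int = 2, length: int = 280) -> list:
    """Synthetic spike references: degenerate complementing prefix + random body."""
    rng = np.random.default_rng(seed)
    prefix = design_spike_prefix(bset, m13)
    return [prefix + _random_seq(length - len(prefix), rng) for _ in range(n)]


def make_genotyping_panel(
    n_targets: int = 12,
    snps_per_target: int = 2,
    insert_len: int = 120,
    seed: int = 0,
) -> AmpliconPanel:
    """Synthetic hemi-SNP genotyping panel.

    SNP positions are placed in the first ~35 insert bases so that every
    truncation class of a 76-base read covers them; each site's variant is
    assigned to parent B at the hemi-SNP expected fraction of 0.5.
    """
    rng = np.random.default_rng(seed)
    targets = []
    for i in range(n_targets):
        insert = _random_seq(insert_len, rng)
        positions = sorted(
            rng.choice(np.arange(5, 35), size=snps_per_target, replace=False)
        )
        sites = []
        for pos in positions:
            ref = insert[pos - 1]
            variant = "ACGT"[("ACGT".index(ref) + 1 + int(rng.integers(3))) % 4]
            sites.append(
                SnpSite(position=int(pos), allele_a_base=ref,
                        allele_b_base=variant,
                        expected_a_fraction=0.0, expected_b_fraction=0.5)
            )
        targets.append(
            AmpliconTarget(
                name=f"SNP{i + 1:03d}",
                insert_seq=insert,
                fwd_primer=_random_seq(12, rng),
                rev_primer=_random_seq(12, rng),
                snp_sites=sites,
            )
        )
    return AmpliconPanel(targets)


def _diverge(seq: str, positions: Sequence[int], shift: int) -> str:
    """Rotate the base at each position by a fixed amount; distinct shifts
    give sequences that differ pairwise at every listed position."""
    chars = list(seq)
    for pos in positions:
        chars[pos - 1] = "ACGT"[("ACGT".index(chars[pos - 1]) + shift) % 4]
    return "".join(chars)


def make_mutation_panel(seed: int = 0, insert_len: int = 234,
                        specific_len: int = 134) -> AmpliconPanel:
    """Synthetic mutation-screen panel.

    A trio of co-amplified paralogues (mixed 276 bp-scale product) with
    inter-paralogue polymorphisms inside both read windows, plus one
    locus-specific target with an exon/intron annotation track for
    effect-calling.
    """
    rng = np.random.default_rng(seed)
    base = _random_seq(insert_len, rng)
    # >=3 diverged positions inside each covered window so reads always
    # discriminate the paralogues at the default mismatch budget
    head = [int(p) for p in rng.choice(np.arange(2, 14), 3, replace=False)]
    tail = [int(p) for p in
            rng.choice(np.arange(insert_len - 40, insert_len), 3, replace=False)]
    targets = [
        AmpliconTarget(
            name="PARA.a", insert_seq=base,
            fwd_primer=_random_seq(21, rng), rev_primer=_random_seq(21, rng),
            paralogue_group="PARA",
        )
    ]
    fwd, rev = targets[0].fwd_primer, targets[0].rev_primer
    for shift, suffix in ((1, "b"), (2, "c")):
        targets.append(
            AmpliconTarget(
                name=f"PARA.{suffix}",
                insert_seq=_diverge(base, head + tail, shift),
                fwd_primer=fwd, rev_primer=rev, paralogue_group="PARA",
            )
        )
    specific = _random_seq(specific_len, rng)
    intron_start = specific_len // 2
    targets.append(
        AmpliconTarget(
            name="SPEC.a", insert_seq=specific,
            fwd_primer=_random_seq(21, rng), rev_primer=_random_seq(21, rng),
            annotation=[
                AnnotationInterval(1, intron_start - 1, "exon", frame_offset=0),
                AnnotationInterval(intron_start, specific_len, "intron"),
            ],
        )
    )
    return AmpliconPanel(targets)
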