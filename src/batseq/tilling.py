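"""Pooled EMS mutation detection in locus-specific and mixed amplicons.

EMS (ethyl methanesulfonate) induces almost exclusively G->A and C->T
transitions, so only G and C reference positions are screened and each has a
single candidate variant.  A pool of (typically eight) lines containing one
heterozygous mutant shows the variant in roughly 1/16 of that locus' reads;
candidates are called per pool from quality-filtered pileup counts by four
heuristics:

1. at least ``min_variant_reads`` reads carrying the candidate variant;
2. signal -- the ratio of candidate calls to reference-base calls -- above
   ``signal_threshold_mixed`` for co-amplified (mixed-paralogue) targets or
   ``signal_threshold_specific`` for locus-specific ones;
3. signal-to-noise: the candidate at least ``snr_threshold``-fold more
   abundant than the larger of the two other possible substitutions;
4. the position is not an inter-paralogue / inter-homoeologue polymorphism
   (such positions are masked before scanning).

Rows that fail a criterion but come within a configurable margin are
reported as near-misses with per-criterion booleans rather than silently
dropped.  Coding consequences are annotated through the standard genetic
code using the target's exon/intron track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .mapper import PileupMatrix
from .panel_io import AmpliconPanel, AmpliconTarget, PanelError, RunConfig

__all__ = [
    "EmsSite",
    "MutationCandidate",
    "EMS_CANDIDATE",
    "ems_sites",
    "interparalogue_mask",
    "variant_ratio",
    "evaluate_counts",
    "detect_mutations",
    "detect_from_count_table",
    "annotate_effect",
    "candidate_report_rows",
]

#: The EMS-mutable reference bases and their single candidate variants.
EMS_CANDIDATE = {"G": "A", "C": "T"}


@dataclass(frozen=True)
class EmsSite:
    """One EMS-mutable position of an amplicon insert."""

    target_name: str
    position: int  # 1-based insert coordinate
    ref_base: str  # G or C

    @property
    def candidate_variant(self) -> str:
        return EMS_CANDIDATE[self.ref_base]


@dataclass
class MutationCandidate:
    """A pool x position candidate with its evidence and per-criterion flags."""

    pool: str
    target_name: str
    position: int
    ref_base: str
    variant_base: str
    counts: dict  # {A,C,G,T}
    variant_reads: int
    signal: float  # candidate / reference calls; inf when reference count is 0
    snr: float  # candidate / max(other two substitutions)
    passes: dict  # {"min_reads": bool, "signal": bool, "snr": bool}
    is_pass: bool
    near_miss: bool
    effect: Optional[str] = None
    lane: Optional[str] = None


def ems_sites(target: AmpliconTarget,
              positions: Optional[Iterable[int]] = None) -> list:
    """Every G (candidate A) and C (candidate T) position of the insert.

    ``positions`` optionally restricts the scan to a covered window.
    """
    wanted = set(positions) if positions is not None else None
    sites = []
    for pos0, base in enumerate(target.insert_seq):
        pos = pos0 + 1
        if base in EMS_CANDIDATE and (wanted is None or pos in wanted):
            sites.append(EmsSite(target.name, pos, base))
    return sites


def interparalogue_mask(group: Sequence[AmpliconTarget]) -> Set[int]:
    """Positions at which any two co-amplified paralogues differ.

    A variant signal at such a position reflects fixed divergence between the
    gene copies, not an induced mutation, so it is masked in all members.
    Members must be positionally comparable (equal insert lengths).
    """
    if len(group) <= 1:
        return set()
    lengths = {t.insert_len for t in group}
    if len(lengths) != 1:
        raise PanelError(
            "interparalogue_mask: co-amplified inserts of unequal length "
            f"({sorted(lengths)}) cannot be positionally compared"
        )
    mask: Set[int] = set()
    first = group[0].insert_seq
    for other in group[1:]:
        for pos0, (a, b) in enumerate(zip(first, other.insert_seq)):
            if a != b:
                mask.add(pos0 + 1)
    # pairwise beyond the first anchor member
    for i in range(1, len(group)):
        for j in range(i + 1, len(group)):
            for pos0, (a, b) in enumerate(
                zip(group[i].insert_seq, group[j].insert_seq)
            ):
                if a != b:
                    mask.add(pos0 + 1)
    return mask


def variant_ratio(counts: dict, ref_base: str, variant_base: str) -> float:
    """Signal: candidate-variant calls divided by reference-base calls.

    A zero reference count with variant evidence is reported as infinite
    signal; an all-zero site is undefined (NaN) and skipped by the detector.
    """
    total = sum(counts.values())
    if total == 0:
        return math.nan
    ref = counts[ref_base]
    var = counts[variant_base]
    if ref == 0:
        return math.inf if var > 0 else 0.0
    return var / ref


def evaluate_counts(counts: dict, ref_base: str, is_mixed: bool,
                    cfg: RunConfig) -> Optional[dict]:
    """Apply the calling criteria to one site's ACGT counts.

    Returns None for a non-EMS-mutable reference base or an uncovered
    (all-zero) site; otherwise a dict with signal, snr, variant reads,
    per-criterion booleans, the strict verdict and the near-miss verdict.
    """
    if ref_base not in EMS_CANDIDATE:
        return None
    variant_base = EMS_CANDIDATE[ref_base]
    signal = variant_ratio(counts, ref_base, variant_base)
    if math.isnan(signal):
        return None
    variant_reads = counts[variant_base]
    others = [counts[b] for b in "ACGT" if b not in (ref_base, variant_base)]
    noise = max(others)
    if noise == 0:
        snr = math.inf if variant_reads > 0 else 0.0
    else:
        snr = variant_reads / noise
    threshold = (cfg.signal_threshold_mixed if is_mixed
                 else cfg.signal_threshold_specific)
    passes = {
        "min_reads": variant_reads >= cfg.min_variant_reads,
        "signal": signal > threshold,
        "snr": snr > cfg.snr_threshold,
    }
    m = cfg.near_miss_margin
    near = (
        variant_reads >= m * cfg.min_variant_reads
        and signal > m * threshold
        and snr > m * cfg.snr_threshold
    )
    return {
        "variant_base": variant_base,
        "variant_reads": variant_reads,
        "signal": signal,
        "snr": snr,
        "passes": passes,
        "is_pass": all(passes.values()),
        "near_miss": near and not all(passes.values()),
    }


def detect_mutations(
    pileup: PileupMatrix,
    panel: AmpliconPanel,
    cfg: RunConfig,
    report_near_misses: bool = True,
) -> list:
    """Scan every pool x unmasked EMS-mutable site of the pileup.

    Emits strict passes and (optionally) near-misses, each with per-criterion
    booleans and a coding-effect annotation.
    """
    masks: Dict[str, Set[int]] = {}
    for t in panel:
        masks[t.name] = interparalogue_mask(panel.group_members(t))
    out = []
    for (pool, target_name) in sorted(pileup.keys()):
        target = panel[target_name]
        mask = masks[target_name]
        for site in ems_sites(target):
            if site.position in mask:
                continue
            counts = pileup.base_counts(pool, target_name, site.position)
            verdict = evaluate_counts(counts, site.ref_base, target.is_mixed, cfg)
            if verdict is None:
                continue
            if not (verdict["is_pass"]
                    or (report_near_misses and verdict["near_miss"])):
                continue
            out.append(
                MutationCandidate(
                    pool=pool,
                    target_name=target_name,
                    position=site.position,
                    ref_base=site.ref_base,
                    variant_base=verdict["variant_base"],
                    counts=counts,
                    variant_reads=verdict["variant_reads"],
                    signal=verdict["signal"],
                    snr=verdict["snr"],
                    passes=verdict["passes"],
                    is_pass=verdict["is_pass"],
                    near_miss=verdict["near_miss"],
                    effect=annotate_effect(
                        target, site.position, site.ref_base,
                        verdict["variant_base"],
                    ) if target.annotation else None,
                )
            )
    return out


def detect_from_count_table(rows, cfg: RunConfig) -> list:
    """Run the calling criteria over an external per-pool base-count table.

    ``rows`` is an iterable of mappings with keys pool, target, position,
    ref_base, A, C, G, T, is_mixed (and optionally lane) -- e.g. a published
    mutation report's count columns.  Masking and annotation are the caller's
    concern; every EMS-mutable row is returned with its verdict.
    """
    out = []
    for row in rows:
        counts = {b: int(row[b]) for b in "ACGT"}
        verdict = evaluate_counts(
            counts, row["ref_base"], bool(row["is_mixed"]), cfg
        )
        if verdict is None:
            continue
        out.append(
            MutationCandidate(
                pool=row["pool"],
                target_name=row["target"],
                position=int(row["position"]),
                ref_base=row["ref_base"],
                variant_base=verdict["variant_base"],
                counts=counts,
                variant_reads=verdict["variant_reads"],
                signal=verdict["signal"],
                snr=verdict["snr"],
                passes=verdict["passes"],
                is_pass=verdict["is_pass"],
                near_miss=verdict["near_miss"],
                lane=str(row.get("lane")) if "lane" in row else None,
            )
        )
    return out


def annotate_effect(target: AmpliconTarget, position: int, ref_base: str,
                    variant_base: str) -> str:
    """Coding consequence of a substitution at an insert position.

    Intron positions return "intron"; exon positions are translated through
    the standard genetic code in the exon's declared frame: "synonymous(AA)",
    "missense(AA->AA)" or "STOP"; positions outside the annotation (or in a
    codon truncated by the exon boundary) return "not_covered".
    """
    interval = next(
        (a for a in target.annotation if a.start <= position <= a.end), None
    )
    if interval is None:
        return "not_covered"
    if interval.kind == "intron":
        return "intron"
    coding_start = interval.start + interval.frame_offset
    idx = position - coding_start
    if idx < 0:
        return "not_covered"
    codon_start = coding_start + 3 * (idx // 3)
    if codon_start + 2 > interval.end:
        return "not_covered"
    codon = target.insert_seq[codon_start - 1: codon_start + 2]
    within = position - codon_start
    if codon[within] != ref_base:
        raise PanelError(
            f"{target.name}:{position}: reference base {ref_base!r} does not "
            f"match insert ({codon[within]!r})"
        )
    mutant = codon[:within] + variant_base + codon[within + 1:]
    wt_aa = str(Seq(codon).translate())
    mut_aa = str(Seq(mutant).translate())
    if mut_aa == "*":
        return "STOP"
    if wt_aa == mut_aa:
        return f"synonymous({seq3(wt_aa)})"
    return f"missense({seq3(wt_aa)}->{seq3(mut_aa)})"


def candidate_report_rows(candidates: Sequence[MutationCandidate]) -> list:
    """Mutation-report rows: lane, pool, gene, position, base, ACGT counts,
    ratio, effect, plus per-criterion pass flags."""
    rows = []
    for c in candidates:
        rows.append(
            {
                "lane": c.lane or "",
                "pool": c.pool,
                "gene": c.target_name,
                "position": c.position,
                "base": c.ref_base,
                "A": c.counts["A"],
                "C": c.counts["C"],
                "G": c.counts["G"],
                "T": c.counts["T"],
                "ratio": round(c.signal, 6) if math.isfinite(c.signal) else "inf",
                "effect": c.effect or "",
                "pass_min_reads": c.passes["min_reads"],
                "pass_signal": c.passes["signal"],
                "pass_snr": c.passes["snr"],
                "pass": c.is_pass,
                "near_miss": c.near_miss,
            }
        )
    return rows
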