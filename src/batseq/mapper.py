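"""Competitive ungapped mapping of munged reads and pileup construction.

All BAT products share an exact prefix structure (24-base munged barcode +
M13 + locus primer), so read assignment reduces to an offset-0, end-anchored
Hamming comparison against every munged pseudo-reference.  A read is "used"
only when its minimal mismatch count is within the budget *and* strictly
unique -- any tie across barcodes, targets or co-amplified paralogues leaves
the read unassigned.  Munging guarantees >=4 mismatches against every wrong
barcode, so with the default budget of 2 cross-sample assignment is
impossible.

Paired-end runs carry sample identity into the reverse read by prefixing the
mate with the munged barcode and M13 of its (repaired) forward read; mates
are mapped against reverse-orientation pseudo-references (munged barcode +
M13 + reverse primer + reverse-complemented insert) and their base calls are
complemented back into forward insert coordinates at pileup time, so one
coordinate system serves all reports.

Indels are not modelled: EMS induces substitutions and amplicons are
fixed-length, so any read requiring gaps simply goes unmapped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .barcode_engine import (
    SYNTH_QUALITY,
    mung_barcode,
    munged_prefix_len,
)
from .panel_io import (
    AmpliconPanel,
    AmpliconTarget,
    BarcodeSet,
    PanelError,
    ReadRecord,
    RunConfig,
    revcomp,
)

__all__ = [
    "MungedReference",
    "MappedRead",
    "PileupMatrix",
    "build_references",
    "attach_mate_tag",
    "map_read",
    "map_reads",
    "build_pileup",
]

# Byte codes for vectorised comparison.  WILD never mismatches (used to pad
# ragged arrays / beyond-window positions); UNKNOWN always mismatches.
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_WILD = 200
_UNKNOWN_READ = 210
_UNKNOWN_REF = 211


@dataclass(frozen=True)
class MungedReference:
    """One competitive reference: a (barcode, target, orientation) product."""

    barcode_label: str
    barcode: str
    target_name: str
    seq: str
    orientation: str = "fwd"  # "fwd" | "rev" (mate-side)


@dataclass
class MappedRead:
    """A read assigned to its best (barcode, target) reference."""

    read_id: str
    barcode_label: str
    barcode: str
    target_name: str
    mismatches: int
    used: bool
    orientation: str = "fwd"
    offset: int = 0


def build_references(
    bset: BarcodeSet,
    panel: AmpliconPanel,
    m13: str,
    occupied: Optional[Sequence[str]] = None,
    orientation: str = "fwd",
) -> list:
    """Munged pseudo-references for every occupied barcode x target.

    ``occupied`` restricts the address space to the barcode labels actually
    used in the run (default: the whole panel).  ``orientation="rev"`` builds
    the mate-side references.
    """
    labels = list(occupied) if occupied is not None else list(bset.labels)
    refs = []
    for label in labels:
        bc = bset.barcode_of(label)
        prefix = mung_barcode(bc) + m13
        for t in panel:
            if orientation == "fwd":
                seq = prefix + t.fwd_primer + t.insert_seq
            elif orientation == "rev":
                seq = prefix + t.rev_primer + revcomp(t.insert_seq)
            else:
                raise PanelError(f"orientation {orientation!r}")
            refs.append(MungedReference(label, bc, t.name, seq, orientation))
    return refs


def attach_mate_tag(read: ReadRecord, repaired: Optional[str], m13: str
                    ) -> Optional[ReadRecord]:
    """Prefix the mate with the forward read's munged barcode + M13.

    The mate (reverse-primer-side read) carries no barcode of its own; tagging
    it with its pair's repaired identity lets it be mapped competitively like
    any munged read, against the reverse-orientation references.  Returns the
    tagged mate as a standalone read, or None for single-end input or an
    unrepaired forward barcode (the pair is then discarded).
    """
    if read.mate is None or repaired is None:
        return None
    prefix = mung_barcode(repaired) + m13
    mseq, mquals = read.mate
    return ReadRecord(
        read_id=read.read_id,
        seq=prefix + mseq,
        quals=[SYNTH_QUALITY] * len(prefix) + list(mquals),
    )


def _encode(seq: str, width: int, unknown: int) -> np.ndarray:
    arr = np.full(width, _WILD, dtype=np.uint8)
    for i, base in enumerate(seq):
        arr[i] = _CODE.get(base, unknown)
    return arr


def map_reads(
    reads: Sequence[ReadRecord],
    refs: Sequence[MungedReference],
    cfg: RunConfig,
    chunk: int = 2048,
) -> list:
    """Competitively map munged reads; returns one MappedRead-or-None per read.

    For each read and reference the mismatch count is taken over the aligned
    window (the shorter of the two); the read maps iff its minimum is within
    ``cfg.max_map_mismatches`` and attained by exactly one reference.
    """
    if not refs:
        return [None] * len(reads)
    min_len = munged_prefix_len(cfg.m13_seq)
    width = max(
        max((len(r.seq) for r in reads), default=0),
        max(len(ref.seq) for ref in refs),
    )
    ref_mat = np.stack([_encode(ref.seq, width, _UNKNOWN_REF) for ref in refs])
    out: list = []
    for start in range(0, len(reads), chunk):
        block = reads[start:start + chunk]
        read_mat = np.stack(
            [_encode(r.seq, width, _UNKNOWN_READ) for r in block]
        )
        r = read_mat[:, None, :]
        f = ref_mat[None, :, :]
        mm = ((r != f) & (r != _WILD) & (f != _WILD)).sum(axis=2)
        best = mm.min(axis=1)
        best_idx = mm.argmin(axis=1)
        n_best = (mm == best[:, None]).sum(axis=1)
        for i, read in enumerate(block):
            if (
                len(read.seq) < min_len
                or best[i] > cfg.max_map_mismatches
                or n_best[i] != 1
            ):
                out.append(None)
                continue
            ref = refs[best_idx[i]]
            out.append(
                MappedRead(
                    read_id=read.read_id,
                    barcode_label=ref.barcode_label,
                    barcode=ref.barcode,
                    target_name=ref.target_name,
                    mismatches=int(best[i]),
                    used=True,
                    orientation=ref.orientation,
                )
            )
    return out


def map_read(read: ReadRecord, refs: Sequence[MungedReference],
             cfg: RunConfig) -> Optional[MappedRead]:
    """Single-read convenience wrapper around :func:`map_reads`."""
    return map_reads([read], refs, cfg)[0]


class PileupMatrix:
    """Per-(barcode, target) base counts over quality-filtered mapped reads.

    Counts are indexed by 1-based insert position and base; only base calls
    with Phred >= ``min_base_quality`` contribute.  The synthesized prefix and
    the locus primer are excluded -- reports are in insert coordinates.
    """

    def __init__(self, panel: AmpliconPanel):
        self.panel = panel
        self._mats: dict = {}

    def _mat(self, label: str, target_name: str) -> np.ndarray:
        key = (label, target_name)
        if key not in self._mats:
            n = self.panel[target_name].insert_len
            self._mats[key] = np.zeros((n, 4), dtype=np.int64)
        return self._mats[key]

    def keys(self):
        return self._mats.keys()

    def counts(self, label: str, target_name: str) -> np.ndarray:
        """(insert_len, 4) count matrix, columns A/C/G/T."""
        return self._mat(label, target_name)

    def base_counts(self, label: str, target_name: str, position: int) -> dict:
        """{A,C,G,T} counts at a 1-based insert position."""
        row = self._mat(label, target_name)[position - 1]
        return dict(zip("ACGT", (int(c) for c in row)))

    def depth(self, label: str, target_name: str, position: int) -> int:
        return int(self._mat(label, target_name)[position - 1].sum())

    def set_counts(self, label: str, target_name: str, position: int,
                   acgt: Sequence[int]) -> None:
        """Directly set counts at a position (fixtures / imported pileups)."""
        self._mat(label, target_name)[position - 1] = np.asarray(acgt)

    def to_rows(self, label: str, target_name: str) -> list:
        """TSV-ready rows: target, position, ref_base, A, C, G, T."""
        target = self.panel[target_name]
        mat = self._mat(label, target_name)
        rows = []
        for pos0 in range(target.insert_len):
            a, c, g, t = (int(x) for x in mat[pos0])
            rows.append(
                {"target": target_name, "position": pos0 + 1,
                 "ref_base": target.insert_seq[pos0],
                 "A": a, "C": c, "G": g, "T": t}
            )
        return rows


def build_pileup(
    mapped: Iterable,
    panel: AmpliconPanel,
    cfg: RunConfig,
) -> PileupMatrix:
    """Accumulate (MappedRead, ReadRecord) pairs into a pileup.

    Reverse-orientation (mate) reads are counted complemented at their
    forward-strand insert positions.  Only positions actually covered by the
    read window contribute.
    """
    prefix_base = munged_prefix_len(cfg.m13_seq)
    pileup = PileupMatrix(panel)
    groups: dict = {}
    for mr, read in mapped:
        if mr is None or not mr.used:
            continue
        key = (mr.barcode_label, mr.target_name, mr.orientation)
        groups.setdefault(key, []).append(read)
    for (label, target_name, orientation), reads in groups.items():
        target = panel[target_name]
        primer = target.fwd_primer if orientation == "fwd" else target.rev_primer
        prefix = prefix_base + len(primer)
        width = max(len(r.seq) for r in reads)
        seqs = np.stack([_encode(r.seq, width, _UNKNOWN_READ) for r in reads])
        quals = np.zeros((len(reads), width), dtype=np.int16)
        for i, r in enumerate(reads):
            quals[i, : len(r.quals)] = r.quals
        payload = seqs[:, prefix:]
        pq = quals[:, prefix:]
        if payload.shape[1] == 0:
            continue
        span = payload.shape[1]
        if orientation == "fwd":
            pos0 = np.arange(span)
            codes = payload
        else:
            pos0 = target.insert_len - 1 - np.arange(span)
            codes = np.where(payload < 4, 3 - payload, payload)  # complement
        valid = (0 <= pos0) & (pos0 < target.insert_len)
        mask = (pq >= cfg.min_base_quality) & (codes < 4) & valid[None, :]
        mat = pileup._mat(label, target_name)
        rows, cols = np.nonzero(mask)
        np.add.at(mat, (pos0[cols], codes[rows, cols]), 1)
    return pileup
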