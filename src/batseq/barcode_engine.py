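"""Barcode detection, truncation repair, and four-fold "munging".

Inline 6-base barcodes are frequently 5'-truncated by exonuclease activity
before adapter ligation, so a read may retain only the last 4-6 barcode
bases ahead of its M13(-21) anchor.  Provided the trailing
``address_suffix_len`` bases of the panel are unique, such reads can be
repaired back to the full barcode.

Repaired barcodes are then "munged" -- replicated four-fold in silico -- so
that a single-base difference between two barcodes becomes four mismatches,
which defeats cross-assignment by any mapper with a mismatch budget below 4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .panel_io import (
    DNA_ALPHABET,
    AmpliconTarget,
    BarcodeSet,
    PanelError,
    ReadRecord,
    iupac_code,
)

__all__ = [
    "MUNG_FOLD",
    "SYNTH_QUALITY",
    "BarcodeObservation",
    "detect_barcode",
    "repair_barcode",
    "mung_barcode",
    "mung_read",
    "mung_reference",
    "munged_prefix_len",
    "design_spike_prefix",
]

#: In-silico replication factor of the barcode: a 1-base barcode difference
#: becomes MUNG_FOLD mismatches between munged sequences.
MUNG_FOLD = 4

#: Phred score given to synthesized (munged/tagged) bases.  They carry sample
#: identity, not base-call evidence, so they must never fail quality filters.
SYNTH_QUALITY = 40

#: Longest prefix that can precede the M13 anchor (a full 6-base barcode).
_MAX_BARCODE_LEN = 6


@dataclass
class BarcodeObservation:
    """The barcode bases seen ahead of the M13 match, and their repair.

    ``barcode_len_class`` is 6, 5 or 4 (repairable classes) or ``"lt4"``.
    ``repaired`` is set iff the observation maps to exactly one panel barcode,
    in which case ``observed`` is a suffix of ``repaired``.
    """

    observed: str
    repaired: Optional[str] = None

    @property
    def barcode_len_class(self):
        n = len(self.observed)
        return n if n >= 4 else "lt4"


def detect_barcode(read: ReadRecord, m13: str) -> Optional[BarcodeObservation]:
    """Find a perfect, full-length M13 match at offset 0-6 of the read.

    The bases preceding the smallest matching offset are the observed
    (possibly truncated) barcode.  A read without a perfect M13 match returns
    None (it is Unmatched unless it is spike).
    """
    if len(m13) < 10:
        raise PanelError("m13: anchor must be >= 10 bases")
    seq = read.seq
    for offset in range(_MAX_BARCODE_LEN + 1):
        if seq.startswith(m13, offset) and offset + len(m13) <= len(seq):
            return BarcodeObservation(observed=seq[:offset])
    return None


def repair_barcode(obs: BarcodeObservation, bset: BarcodeSet) -> Optional[str]:
    """Reconstruct the full 6-base barcode from a (possibly truncated) observation.

    An intact observation must itself be a panel barcode; a 4- or 5-base
    observation is repaired to the unique panel barcode having it as suffix;
    anything shorter than the address space is unrepairable (None).
    """
    observed = obs.observed
    n = len(observed)
    if n == 6:
        return observed if observed in bset else None
    if n >= bset.address_suffix_len:
        return bset.by_suffix(observed)
    return None


def mung_barcode(barcode: str) -> str:
    """Replicate a 6-base barcode four-fold (6-mer -> 24-mer).

    Munging multiplies pairwise Hamming distance by exactly four, so barcodes
    one base apart end up four mismatches apart.
    """
    if len(barcode) != 6 or not set(barcode) <= DNA_ALPHABET:
        raise PanelError(f"mung_barcode: not a 6-base ACGT barcode: {barcode!r}")
    return barcode * MUNG_FOLD


def munged_prefix_len(m13: str) -> int:
    """Length of the synthesized prefix of every munged read/reference."""
    return 6 * MUNG_FOLD + len(m13)


def mung_read(read: ReadRecord, repaired: str, m13: str) -> ReadRecord:
    """Rewrite a read as ``mung_barcode(repaired) + m13 + payload``.

    The payload (everything after the observed barcode and M13 anchor) and its
    qualities are preserved; synthesized bases get :data:`SYNTH_QUALITY`.
    """
    obs = detect_barcode(read, m13)
    if obs is None:
        raise PanelError(f"read {read.read_id!r}: no M13 anchor to mung at")
    cut = len(obs.observed) + len(m13)
    prefix = mung_barcode(repaired) + m13
    return ReadRecord(
        read_id=read.read_id,
        seq=prefix + read.seq[cut:],
        quals=[SYNTH_QUALITY] * len(prefix) + read.quals[cut:],
        mate=read.mate,
    )


def mung_reference(target: AmpliconTarget, barcode: str, m13: str) -> str:
    """Pseudo-reference for one (barcode, target): munged barcode + M13 + primer + insert."""
    return mung_barcode(barcode) + m13 + target.fwd_primer + target.insert_seq


def design_spike_prefix(bset: BarcodeSet, m13: str) -> str:
    """Degenerate prefix complementing library base composition per cycle.

    Over the barcode+M13 window (6 + len(m13) cycles) the pooled library is
    highly skewed -- identical across all clusters in the M13 region -- which
    would fault real-time base calling.  For each cycle this emits the IUPAC
    code of the bases whose pooled frequency is *below* uniform (1/4), so a
    spike molecule always has a good chance of differing from the modal base;
    a perfectly uniform cycle degenerates to N.
    """
    if len(bset) == 0:
        raise PanelError("design_spike_prefix: empty barcode set")
    letters = []
    for pos in range(6):
        freqs = {b: 0 for b in "ACGT"}
        for bc in bset.barcodes:
            freqs[bc[pos]] += 1
        n = len(bset)
        under = {b for b, c in freqs.items() if c / n < 0.25}
        letters.append(iupac_code(under) if under else "N")
    for base in m13:
        letters.append(iupac_code(DNA_ALPHABET - {base}))
    return "".join(letters)
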