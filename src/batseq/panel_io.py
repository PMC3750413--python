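"""Core domain types and I/O for BAT amplicon-sequencing pipelines.

A BAT (barcoded amplification tag) library consists of PCR products whose
5' read layout is::

    [<=6 nt sample barcode][M13(-21) universal tail][locus-specific forward primer][template]

This module defines the panel objects shared by every pipeline stage -- the
barcode panel with its repair address space, the amplicon targets with their
SNP and coding annotation, and the numeric thresholds -- together with
readers/writers for the standard formats the pipeline touches (FASTQ, FASTA,
TSV reports and a YAML panel configuration).

Coordinate convention: positions are 1-based and intervals closed, measured
within the amplicon insert (the template between the two locus-specific
primers).  All reference sequences are stored in forward-read orientation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence, Union

import yaml
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

__all__ = [
    "DNA_ALPHABET",
    "M13_MINUS_21",
    "PanelError",
    "BarcodeSet",
    "SnpSite",
    "AnnotationInterval",
    "AmpliconTarget",
    "AmpliconPanel",
    "RunConfig",
    "ReadRecord",
    "revcomp",
    "complement",
    "iupac_set",
    "iupac_code",
    "iupac_matches",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "load_panel",
    "write_panel",
    "write_tsv_report",
]

DNA_ALPHABET = frozenset("ACGT")

#: Standard M13(-21) universal sequencing-primer sequence (18 nt).  The tag
#: between the sample barcode and the locus-specific primer in every read.
M13_MINUS_21 = "TGTAAAACGACGGCCAGT"

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

#: IUPAC degenerate code -> set of concrete bases (e.g. "B" -> {C, G, T}).
IUPAC_SETS = {
    code: frozenset(bases)
    for code, bases in ambiguous_dna_values.items()
    if code != "X"
}
_SET_TO_CODE = {bases: code for code, bases in IUPAC_SETS.items()}


class PanelError(ValueError):
    """A panel/configuration invariant was violated (reported with field path)."""


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def iupac_set(code: str) -> frozenset:
    """Concrete bases matched by one IUPAC letter."""
    try:
        return IUPAC_SETS[code.upper()]
    except KeyError:
        raise PanelError(f"not an IUPAC DNA code: {code!r}") from None


def iupac_code(bases: Iterable[str]) -> str:
    """IUPAC letter for a non-empty set of concrete bases."""
    key = frozenset(b.upper() for b in bases)
    try:
        return _SET_TO_CODE[key]
    except KeyError:
        raise PanelError(f"no IUPAC code for base set {sorted(key)}") from None


def iupac_matches(observed: str, pattern: str) -> bool:
    """True if a concrete base is compatible with an IUPAC pattern base."""
    return observed in IUPAC_SETS.get(pattern, frozenset())


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class BarcodeSet:
    """The panel of 6-base barcodes plus the suffix address space used for repair.

    Because barcode truncation is 5'-exonucleolytic, repair matches *suffixes*:
    the trailing ``address_suffix_len`` bases of every barcode must be unique
    so that a read retaining at least that many barcode bases can be
    reconstructed to exactly one full barcode.
    """

    barcodes: list
    labels: list
    address_suffix_len: int = 4

    def __post_init__(self) -> None:
        if len(self.barcodes) != len(self.labels):
            raise PanelError("barcodes/labels: must be the same length")
        if len(set(self.labels)) != len(self.labels):
            raise PanelError("labels: duplicates present")
        for i, bc in enumerate(self.barcodes):
            if len(bc) != 6 or not set(bc) <= DNA_ALPHABET:
                raise PanelError(
                    f"barcodes[{i}]={bc!r}: must be 6 letters over ACGT"
                )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise PanelError("barcodes: duplicates present")
        k = self.address_suffix_len
        if not 1 <= k <= 6:
            raise PanelError(f"address_suffix_len={k}: must be in 1..6")
        suffixes = [bc[-k:] for bc in self.barcodes]
        seen: dict = {}
        for bc, sfx in zip(self.barcodes, suffixes):
            if sfx in seen:
                raise PanelError(
                    f"barcodes: suffix collision {sfx!r} between "
                    f"{seen[sfx]!r} and {bc!r} (repair would be ambiguous)"
                )
            seen[sfx] = bc
        self._label_of = dict(zip(self.barcodes, self.labels))
        self._barcode_of = dict(zip(self.labels, self.barcodes))

    def __len__(self) -> int:
        return len(self.barcodes)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self._label_of

    def label_of(self, barcode: str) -> str:
        return self._label_of[barcode]

    def barcode_of(self, label: str) -> str:
        return self._barcode_of[label]

    def by_suffix(self, suffix: str) -> Optional[str]:
        """The unique panel barcode ending in ``suffix``, or None.

        ``suffix`` must be at least ``address_suffix_len`` long; consistency is
        required at the full observed length (a 5-base observation must match
        a 5-base suffix, not merely its last four bases).
        """
        if len(suffix) < self.address_suffix_len:
            return None
        hits = [bc for bc in self.barcodes if bc.endswith(suffix)]
        return hits[0] if len(hits) == 1 else None


@dataclass(frozen=True)
class SnpSite:
    """A (hemi-)SNP assayed within an amplicon insert.

    ``allele_a_base``/``allele_b_base`` are the diagnostic bases of the two
    parental alleles at this position; for a hemi-SNP exactly one of them
    differs from the reference insert base and is expected at a partial read
    fraction (~0.5 in a homozygous line, since the invariant homoeologue
    contributes the reference base to the mixed amplicon).
    """

    position: int
    allele_a_base: str
    allele_b_base: str
    expected_a_fraction: float = 0.0
    expected_b_fraction: float = 0.5


@dataclass(frozen=True)
class AnnotationInterval:
    """A 1-based closed interval of the insert, exon or intron.

    ``frame_offset`` (exons only) is the number of bases at the start of the
    exon belonging to a codon begun upstream, 0-2.
    """

    start: int
    end: int
    kind: str  # "exon" | "intron"
    frame_offset: int = 0


@dataclass
class AmpliconTarget:
    """One amplified target: reference insert, primers, SNP and coding tracks.

    Targets sharing a ``paralogue_group`` are co-amplified by the same primer
    pair (e.g. the three FAD2 copies in a mixed amplicon); ``is_mixed`` is set
    by :class:`AmpliconPanel` when the group has more than one member.
    """

    name: str
    insert_seq: str
    fwd_primer: str
    rev_primer: str
    paralogue_group: Optional[str] = None
    snp_sites: list = field(default_factory=list)
    annotation: list = field(default_factory=list)
    is_mixed: bool = False

    def __post_init__(self) -> None:
        for attr in ("insert_seq", "fwd_primer", "rev_primer"):
            seq = getattr(self, attr)
            if not seq or not set(seq) <= DNA_ALPHABET:
                raise PanelError(f"{self.name}.{attr}: non-ACGT or empty sequence")
        n = len(self.insert_seq)
        self.snp_sites = [
            s if isinstance(s, SnpSite) else SnpSite(**s) for s in self.snp_sites
        ]
        for s in self.snp_sites:
            if not 1 <= s.position <= n:
                raise PanelError(
                    f"{self.name}.snp_sites: position {s.position} outside [1, {n}]"
                )
        self.annotation = [
            a if isinstance(a, AnnotationInterval) else AnnotationInterval(**a)
            for a in self.annotation
        ]
        for a in self.annotation:
            if not (1 <= a.start <= a.end <= n):
                raise PanelError(
                    f"{self.name}.annotation: interval [{a.start},{a.end}] "
                    f"outside [1, {n}]"
                )
            if a.kind not in ("exon", "intron"):
                raise PanelError(f"{self.name}.annotation: kind {a.kind!r}")
            if a.kind == "exon" and not 0 <= a.frame_offset <= 2:
                raise PanelError(f"{self.name}.annotation: frame_offset {a.frame_offset}")

    @property
    def insert_len(self) -> int:
        return len(self.insert_seq)


class AmpliconPanel:
    """An ordered collection of amplicon targets with paralogue grouping."""

    def __init__(self, targets: Sequence[AmpliconTarget]):
        names = [t.name for t in targets]
        if len(set(names)) != len(names):
            raise PanelError("targets: duplicate names")
        self.targets = list(targets)
        self._by_name = {t.name: t for t in targets}
        groups: dict = {}
        for t in targets:
            if t.paralogue_group:
                groups.setdefault(t.paralogue_group, []).append(t)
        self.paralogue_groups = groups
        for members in groups.values():
            mixed = len(members) > 1
            for t in members:
                t.is_mixed = mixed

    def __iter__(self) -> Iterator[AmpliconTarget]:
        return iter(self.targets)

    def __len__(self) -> int:
        return len(self.targets)

    def __getitem__(self, name: str) -> AmpliconTarget:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def group_members(self, target: AmpliconTarget) -> list:
        if target.paralogue_group:
            return self.paralogue_groups[target.paralogue_group]
        return [target]


@dataclass
class RunConfig:
    """Numeric constants of the pipeline.

    Defaults are the operating points of the original screens: genotypes are
    called only at >=20 high-quality reads; a pooled mutation candidate needs
    >=10 variant reads, a variant/reference signal above 1% (mixed-paralogue
    amplicons) or 0.2% (locus-specific), and a >=10-fold signal-to-noise
    ratio over the other two possible substitutions.
    """

    m13_seq: str = M13_MINUS_21
    min_genotype_depth: int = 20
    min_variant_reads: int = 10
    signal_threshold_specific: float = 0.002
    signal_threshold_mixed: float = 0.01
    snr_threshold: float = 10.0
    min_base_quality: int = 20
    max_map_mismatches: int = 2
    het_fraction_call: float = 0.15
    ref_fraction_call: float = 0.05
    spike_first: bool = True
    near_miss_margin: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.m13_seq) < 10 or not set(self.m13_seq) <= DNA_ALPHABET:
            raise PanelError("m13_seq: must be >=10 ACGT letters")
        for name in (
            "min_genotype_depth", "min_variant_reads",
            "signal_threshold_specific", "signal_threshold_mixed",
            "snr_threshold", "min_base_quality", "het_fraction_call",
            "ref_fraction_call",
        ):
            if getattr(self, name) <= 0:
                raise PanelError(f"{name}: must be strictly positive")
        if self.max_map_mismatches < 0:
            raise PanelError("max_map_mismatches: must be >= 0")
        if self.het_fraction_call <= self.ref_fraction_call:
            raise PanelError("het_fraction_call must exceed ref_fraction_call")


@dataclass
class ReadRecord:
    """A sequencing read (optionally with its unaligned mate)."""

    read_id: str
    seq: str
    quals: list
    mate: Optional[tuple] = None  # (seq, quals)

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.seq):
            raise PanelError(
                f"read {self.read_id!r}: {len(self.quals)} qualities "
                f"for {len(self.seq)} bases"
            )
        if self.mate is not None and len(self.mate[1]) != len(self.mate[0]):
            raise PanelError(f"read {self.read_id!r}: mate length mismatch")

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------

def _strip_pair_suffix(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def read_fastq(path, path2=None) -> Iterator[ReadRecord]:
    """Stream Sanger-FASTQ records; two files are zipped into read pairs.

    Paired files are matched by record index; ids (after stripping any /1,/2
    suffix) must agree.  Malformed records are fatal, reported with the index
    of the offending record.
    """
    if path2 is None:
        for i, rec in enumerate(_iter_fastq(path)):
            yield rec
        return
    it1, it2 = _iter_fastq(path), _iter_fastq(path2)
    for i, (r1, r2) in enumerate(zip(it1, it2)):
        if _strip_pair_suffix(r1.read_id) != _strip_pair_suffix(r2.read_id):
            raise PanelError(
                f"record {i}: paired ids disagree "
                f"({r1.read_id!r} vs {r2.read_id!r})"
            )
        r1.mate = (r2.seq, r2.quals)
        yield r1
    if next(it1, None) is not None or next(it2, None) is not None:
        raise PanelError("paired FASTQ files have unequal record counts")


def _iter_fastq(path) -> Iterator[ReadRecord]:
    index = -1
    try:
        for index, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            seq = str(rec.seq).upper()
            bad = set(seq) - set(IUPAC_SETS)
            if bad:
                raise PanelError(f"non-IUPAC characters {sorted(bad)}")
            yield ReadRecord(
                read_id=rec.id,
                seq=seq,
                quals=list(rec.letter_annotations["phred_quality"]),
            )
    except PanelError as exc:
        raise PanelError(f"{path}: record {index}: {exc}") from None
    except ValueError as exc:  # Biopython parse errors (length mismatch etc.)
        raise PanelError(f"{path}: record {index + 1}: {exc}") from None


def write_fastq(records: Iterable[ReadRecord], path, path2=None) -> None:
    """Write reads as Sanger FASTQ; mates (if any) go to ``path2``."""
    f2: Optional[IO] = open(path2, "w") if path2 is not None else None
    with open(path, "w") as f1:
        for rec in records:
            f1.write(_fastq_block(rec.read_id, rec.seq, rec.quals))
            if f2 is not None and rec.mate is not None:
                f2.write(_fastq_block(rec.read_id, rec.mate[0], rec.mate[1]))
    if f2 is not None:
        f2.close()


def _fastq_block(read_id: str, seq: str, quals) -> str:
    qstr = "".join(chr(q + 33) for q in quals)
    return f"@{read_id}\n{seq}\n+\n{qstr}\n"


def read_fasta(path) -> dict:
    """FASTA file -> ordered {name: sequence} (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict, path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# Panel configuration (YAML)
# ---------------------------------------------------------------------------

def load_panel(path):
    """Load a panel config file -> (BarcodeSet, AmpliconPanel, RunConfig, spikes).

    The file is a single human-editable YAML document; all type invariants are
    verified at load and violations reported with field paths.  Omitted
    thresholds take the :class:`RunConfig` defaults.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise PanelError(f"{path}: not a mapping")
    try:
        bsec = doc["barcodes"]
        bset = BarcodeSet(
            barcodes=[str(e["seq"]).upper() for e in bsec["panel"]],
            labels=[str(e["label"]) for e in bsec["panel"]],
            address_suffix_len=int(bsec.get("address_suffix_len", 4)),
        )
        targets = []
        for tsec in doc.get("targets", []):
            targets.append(
                AmpliconTarget(
                    name=str(tsec["name"]),
                    insert_seq=str(tsec["insert"]).upper(),
                    fwd_primer=str(tsec["fwd_primer"]).upper(),
                    rev_primer=str(tsec["rev_primer"]).upper(),
                    paralogue_group=tsec.get("paralogue_group"),
                    snp_sites=[
                        SnpSite(
                            position=int(s["position"]),
                            allele_a_base=str(s["allele_a"]).upper(),
                            allele_b_base=str(s["allele_b"]).upper(),
                            expected_a_fraction=float(s.get("fraction_a", 0.0)),
                            expected_b_fraction=float(s.get("fraction_b", 0.5)),
                        )
                        for s in tsec.get("snp_sites", [])
                    ],
                    annotation=[
                        AnnotationInterval(
                            start=int(a["start"]),
                            end=int(a["end"]),
                            kind=str(a["kind"]),
                            frame_offset=int(a.get("frame_offset", 0)),
                        )
                        for a in tsec.get("annotation", [])
                    ],
                )
            )
        panel = AmpliconPanel(targets)
        cfg = RunConfig(**doc.get("config", {}))
        spikes = [str(s).upper() for s in doc.get("spikes", [])]
    except KeyError as exc:
        raise PanelError(f"{path}: missing field {exc}") from None
    except TypeError as exc:
        raise PanelError(f"{path}: {exc}") from None
    return bset, panel, cfg, spikes


def write_panel(path, bset: BarcodeSet, panel: AmpliconPanel,
                cfg: Optional[RunConfig] = None, spikes=()) -> None:
    """Inverse of :func:`load_panel` (round-trips exactly)."""
    doc: dict = {
        "barcodes": {
            "address_suffix_len": bset.address_suffix_len,
            "panel": [
                {"label": lab, "seq": bc}
                for lab, bc in zip(bset.labels, bset.barcodes)
            ],
        },
        "targets": [
            {
                "name": t.name,
                "insert": t.insert_seq,
                "fwd_primer": t.fwd_primer,
                "rev_primer": t.rev_primer,
                **({"paralogue_group": t.paralogue_group}
                   if t.paralogue_group else {}),
                **({"snp_sites": [
                    {"position": s.position,
                     "allele_a": s.allele_a_base,
                     "allele_b": s.allele_b_base,
                     "fraction_a": s.expected_a_fraction,
                     "fraction_b": s.expected_b_fraction}
                    for s in t.snp_sites]} if t.snp_sites else {}),
                **({"annotation": [
                    {"start": a.start, "end": a.end, "kind": a.kind,
                     "frame_offset": a.frame_offset}
                    for a in t.annotation]} if t.annotation else {}),
            }
            for t in panel
        ],
    }
    if cfg is not None:
        doc["config"] = dataclasses.asdict(cfg)
    if spikes:
        doc["spikes"] = list(spikes)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# TSV reports
# ---------------------------------------------------------------------------

def write_tsv_report(rows, path, columns=None) -> None:
    """Write homogeneous rows (dicts or dataclasses) as a TSV report.

    An empty row list yields a header-only file (``columns`` required then);
    non-rectangular rows are an error.
    """
    import pandas as pd

    rows = [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
            for r in rows]
    if rows:
        keys = list(rows[0].keys())
        for i, r in enumerate(rows):
            if list(r.keys()) != keys:
                raise PanelError(f"rows[{i}]: columns differ from rows[0]")
        df = pd.DataFrame(rows, columns=columns or keys)
    else:
        if not columns:
            raise PanelError("empty report needs explicit columns")
        df = pd.DataFrame(columns=list(columns))
    df.to_csv(path, sep="\t", index=False)
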