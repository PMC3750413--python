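"""Hemi-SNP genotype calling from pileups and scoring-string export.

In an allopolyploid, most assayable SNPs are hemi-SNPs: the amplicon is
amplified from both ancestral genomes but only one of them varies between
the parents.  The parent carrying the variant shows it at a partial read
fraction (~0.5 in a homozygous line, the invariant homoeologue contributing
the reference base), while the other parent shows essentially none.  Calls
are therefore made on the variant-base fraction with a dead zone between the
two classes, and only at sufficient high-quality depth.

Output follows the standard A/B/U convention -- A for the maternal parent's
allele, B for the paternal parent's, U unclassified -- assembled into
per-marker scoring strings ready for linkage-mapping software.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

from .mapper import PileupMatrix
from .panel_io import AmpliconPanel, AmpliconTarget, PanelError, RunConfig, SnpSite

__all__ = [
    "GenotypeCall",
    "ScoringString",
    "marker_id",
    "variant_allele_of_site",
    "call_genotype",
    "call_genotypes",
    "scoring_strings",
    "scoring_matrix_rows",
]


@dataclass
class GenotypeCall:
    """One line x marker call: allele in {A, B, U} with its evidence."""

    line: str
    marker: str
    allele: str
    depth: int
    variant_fraction: float


@dataclass
class ScoringString:
    """Ordered A/B/U string for one marker, one character per line."""

    marker: str
    string: str


def marker_id(target_name: str, position: int) -> str:
    return f"{target_name}:{position}"


def variant_allele_of_site(target: AmpliconTarget, site: SnpSite) -> Tuple[str, str]:
    """(variant base, parent carrying it) for a hemi-SNP site.

    The variant base is whichever parental allele base differs from the
    reference insert; exactly one may differ.
    """
    ref = target.insert_seq[site.position - 1]
    a_var = site.allele_a_base != ref
    b_var = site.allele_b_base != ref
    if a_var == b_var:
        raise PanelError(
            f"{target.name}:{site.position}: exactly one parental allele must "
            f"differ from the reference base {ref!r} "
            f"(A={site.allele_a_base}, B={site.allele_b_base})"
        )
    return (site.allele_a_base, "A") if a_var else (site.allele_b_base, "B")


def call_genotype(
    pileup: PileupMatrix,
    line: str,
    target: AmpliconTarget,
    site: SnpSite,
    cfg: RunConfig,
) -> GenotypeCall:
    """Call one line at one declared SNP position.

    U below ``min_genotype_depth``; otherwise the variant-base fraction f
    decides: f >= het_fraction_call -> the variant-bearing parent's allele,
    f <= ref_fraction_call -> the other parent's, in between -> U.
    """
    counts = pileup.base_counts(line, target.name, site.position)
    depth = sum(counts.values())
    variant_base, variant_parent = variant_allele_of_site(target, site)
    other_parent = "B" if variant_parent == "A" else "A"
    marker = marker_id(target.name, site.position)
    if depth < cfg.min_genotype_depth:
        return GenotypeCall(line, marker, "U", depth, 0.0)
    f = counts[variant_base] / depth
    if f >= cfg.het_fraction_call:
        allele = variant_parent
    elif f <= cfg.ref_fraction_call:
        allele = other_parent
    else:
        allele = "U"
    return GenotypeCall(line, marker, allele, depth, f)


def call_genotypes(
    pileup: PileupMatrix,
    panel: AmpliconPanel,
    lines: Sequence[str],
    cfg: RunConfig,
) -> list:
    """All lines x all declared markers."""
    calls = []
    for line in lines:
        for target in panel:
            for site in target.snp_sites:
                calls.append(call_genotype(pileup, line, target, site, cfg))
    return calls


def scoring_strings(calls: Iterable[GenotypeCall], line_order: Sequence[str]
                    ) -> list:
    """Assemble per-marker A/B/U strings in panel line order.

    Missing (line, marker) combinations score U; duplicate calls are an error.
    """
    table: Dict[str, Dict[str, str]] = {}
    for call in calls:
        per_marker = table.setdefault(call.marker, {})
        if call.line in per_marker:
            raise PanelError(
                f"duplicate call for line {call.line!r} at marker {call.marker!r}"
            )
        per_marker[call.line] = call.allele
    return [
        ScoringString(
            marker=marker,
            string="".join(per_marker.get(line, "U") for line in line_order),
        )
        for marker, per_marker in table.items()
    ]


def scoring_matrix_rows(strings: Sequence[ScoringString],
                        line_order: Sequence[str]) -> list:
    """Marker x line matrix rows for TSV export to linkage-mapping software."""
    rows = []
    for s in strings:
        row = {"marker": s.marker}
        row.update(dict(zip(line_order, s.string)))
        rows.append(row)
    return rows
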