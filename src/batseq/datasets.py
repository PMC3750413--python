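"""Packaged reference datasets from the original BAT screening experiments.

Two small tables ship with the package:

* the per-pool base-count rows of the published mutation report from the
  *B. napus* EMS screen (three FAD2 orthologues co-amplified as a mixed
  276 bp product, plus a locus-specific BnaC.GL2.b amplicon; one-dimensional
  8-fold pools addressed by 192 barcodes over three sequencing lanes); and
* the read-accounting tables of the SNP-genotyping lane and the three
  mutation-screen lanes (per-category read counts).

They serve as fixed inputs for exercising the ratio arithmetic, the calling
criteria and the tally accounting on real printed numbers.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "MIXED_GENES",
    "mutation_screen_counts",
    "mutation_screen_count_rows",
    "read_accounting_genotyping",
    "read_accounting_mutation",
]

#: Genes screened as a mixed (co-amplified paralogue) product; BnaC.GL2.b is
#: the locus-specific target.
MIXED_GENES = frozenset({"BnaA.FAD2.a", "BnaA.FAD2.b", "BnaC.FAD2.a"})


def _read(name: str) -> pd.DataFrame:
    with resources.files("batseq.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def mutation_screen_counts() -> pd.DataFrame:
    """The 51 published mutation-report rows: lane, pool, gene, position,
    ref_base, A/C/G/T counts, the printed ratio, and amino-acid annotations."""
    df = _read("bnapus_mutation_screen_counts.tsv")
    df["ratio"] = df["ratio"].astype(float)
    return df


def mutation_screen_count_rows() -> list:
    """The same rows shaped for :func:`batseq.tilling.detect_from_count_table`."""
    rows = []
    for rec in mutation_screen_counts().to_dict("records"):
        rows.append(
            {
                "lane": rec["lane"],
                "pool": rec["pool"],
                "target": rec["gene"],
                "position": rec["position"],
                "ref_base": rec["ref_base"],
                "A": rec["A"],
                "C": rec["C"],
                "G": rec["G"],
                "T": rec["T"],
                "is_mixed": rec["gene"] in MIXED_GENES,
            }
        )
    return rows


def read_accounting_genotyping() -> pd.Series:
    """Per-category read counts of the single-end genotyping lane."""
    df = _read("read_accounting_genotyping.tsv")
    return df.set_index("category")["reads"]


def read_accounting_mutation() -> pd.DataFrame:
    """Per-category read counts of the three paired-end mutation-screen lanes."""
    return _read("read_accounting_mutation.tsv").set_index("category")
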