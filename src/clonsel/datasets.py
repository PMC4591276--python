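"""Bundled worked-example data.

The package ships one small published dataset: the mutant allele
fractions (mutant AF, used interchangeably with AAR) of the variants
that were positively selected during the emergence of secondary nutlin
resistance in three soft-tissue sarcoma cell-line pairs (IB111, IB115,
IB128; sensitive parental line vs. secondary-resistant derivative).
The raw sequencing data behind these fractions were never deposited,
so this table is the reproducible entry point for the selection rules.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .variants import DEFAULT_THRESHOLDS, Thresholds


def mutant_af_table() -> pd.DataFrame:
    """Published mutant-AF pairs of positively selected variants.

    Columns: ``cell_line`` (IB111/IB115/IB128), ``gene``,
    ``transcript`` (opaque transcript/protein-change label),
    ``af_sensitive``, ``af_resistant``.
    """
    ref = resources.files("clonsel.data").joinpath("sarcoma_mutant_af.tsv")
    with ref.open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df


def selected_counts_by_delta(table: pd.DataFrame | None = None,
                             thresholds: Thresholds = DEFAULT_THRESHOLDS) -> pd.Series:
    """Per-cell-line count of variants whose AF rose by at least the
    minimum selection effect size (dAAR >= delta_aar_min)."""
    if table is None:
        table = mutant_af_table()
    delta = table["af_resistant"] - table["af_sensitive"]
    qualifying = table[delta >= thresholds.delta_aar_min]
    return qualifying.groupby("cell_line").size().reindex(
        sorted(table["cell_line"].unique()), fill_value=0)


def gene_counts(gene: str, table: pd.DataFrame | None = None) -> pd.Series:
    """Per-cell-line number of selected variants in one gene."""
    if table is None:
        table = mutant_af_table()
    hits = table[table["gene"] == gene]
    return hits.groupby("cell_line").size().reindex(
        sorted(table["cell_line"].unique()), fill_value=0)
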