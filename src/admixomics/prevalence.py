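"""Group-stratified pathogenic-alteration prevalence and disparity testing.

A patient carries an alteration in a gene if any pathogenic or likely
pathogenic variant (SNV/indel/CNV/rearrangement, merged) was called in it.
This module tabulates per-gene carrier frequencies in the AA and EA
groups, optionally within a breast-cancer subtype stratum, ranks the most
frequently mutated genes for oncoplot-style export, and tests the AA-vs-EA
frequency difference per gene with a continuity-corrected chi-squared,
Benjamini-Hochberg-adjusted across genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .stats import bh_adjust, two_by_two_chisq

__all__ = ["prevalence_table", "rank_top_genes", "compare_prevalence"]


def prevalence_table(mutations: pd.DataFrame, clinical: pd.DataFrame, stratum: str = "all") -> pd.DataFrame:
    """Per-gene carrier counts and frequencies by ancestry group.

    Parameters
    ----------
    mutations : boolean DataFrame, patients x genes, indexed by patient id.
    clinical : DataFrame with ``patient_id``, ``group`` and ``subtype``.
    stratum : "all" or a subtype level (e.g. "HRpos_HER2neg", "TNBC").

    Returns a DataFrame indexed by gene with columns
    ``n_carrier_AA, n_AA, n_carrier_EA, n_EA, freq_AA, freq_EA``.
    """
    if mutations.dtypes.map(lambda d: d != bool).any():
        mut = mutations.astype(bool)
    else:
        mut = mutations
    clin = clinical.set_index("patient_id") if "patient_id" in clinical.columns else clinical
    clin = clin.loc[mut.index]
    if stratum != "all":
        keep = clin["subtype"] == stratum
        clin = clin[keep]
        mut = mut.loc[keep.index[keep]]
    rows = {}
    for g in ("AA", "EA"):
        ids = clin.index[clin["group"] == g]
        if len(ids) == 0:
            raise ValueError(f"stratum {stratum!r} has no {g} patients")
        sub = mut.loc[ids]
        rows[f"n_carrier_{g}"] = sub.sum(axis=0).astype(int)
        rows[f"n_{g}"] = len(ids)
    tbl = pd.DataFrame(rows)
    tbl["freq_AA"] = tbl["n_carrier_AA"] / tbl["n_AA"]
    tbl["freq_EA"] = tbl["n_carrier_EA"] / tbl["n_EA"]
    tbl.index.name = "gene"
    return tbl


def rank_top_genes(table: pd.DataFrame, n: int = 15) -> list:
    """Top-n genes by pooled carrier frequency, ties broken alphabetically."""
    if table.empty:
        raise ValueError("prevalence table is empty")
    if n > len(table):
        warnings.warn(f"requested top {n} of only {len(table)} genes; returning all")
        n = len(table)
    pooled = (table["n_carrier_AA"] + table["n_carrier_EA"]) / (table["n_AA"] + table["n_EA"])
    order = pooled.to_frame("pooled").reset_index().sort_values(
        ["pooled", "gene"], ascending=[False, True]
    )
    return order["gene"].head(n).tolist()


def compare_prevalence(table: pd.DataFrame, adjust_beyond_top: int = 15) -> pd.DataFrame:
    """Chi-squared AA-vs-EA test per gene with BH adjustment.

    Each gene gets a 2x2 continuity-corrected chi-squared on
    (carrier, non-carrier) x (AA, EA); zero-margin tables (genes nobody
    carries) get p = 1 flagged degenerate. ``p_adj`` is Benjamini-Hochberg
    over all genes; by the published convention raw p is what is
    interpreted for the ``adjust_beyond_top`` most frequent genes, and the
    returned ``use_adjusted`` column records which genes fall beyond that
    rank.
    """
    tbl = table.copy()
    stats_rows = [
        two_by_two_chisq(
            int(r.n_carrier_AA),
            int(r.n_AA - r.n_carrier_AA),
            int(r.n_carrier_EA),
            int(r.n_EA - r.n_carrier_EA),
        )
        for r in tbl.itertuples()
    ]
    tbl["chi2"] = [s.statistic for s in stats_rows]
    tbl["p"] = [s.p for s in stats_rows]
    tbl["degenerate"] = [s.degenerate for s in stats_rows]
    tbl["p_adj"] = bh_adjust(tbl["p"].to_numpy())
    top = set(rank_top_genes(tbl, n=min(adjust_beyond_top, len(tbl))))
    tbl["use_adjusted"] = [g not in top for g in tbl.index]
    tbl.attrs["adjustment"] = "benjamini-hochberg"
    return tbl
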