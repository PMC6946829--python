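"""Subclone calling from QC-passed ternary genotype matrices.

Cells sharing an identical ternary genotype vector form a candidate
subclone. Two error filters are applied before phylogeny reconstruction:

(a) an FDR hard cut-off — a genotype must be carried by at least
    ``ceil(fdr * n_profiled)`` cells (2% FDR: 4 cells of 192 profiled, 8 of
    384, 10 of 480), otherwise it is treated as technical error;
(b) a per-assay error-rate rule — a genotype one legal event away from a
    retained genotype cannot define a minor subclone if its proportion does
    not exceed that assay's measured false-positive rate.

Proportions are reported over all genotyped cells and are not renormalised
after filtering (a ``renormalize`` flag is available).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .qc import AssayPanel

__all__ = [
    "min_cells_for_fdr",
    "enumerate_genotypes",
    "filter_subclones",
    "sc_allele_burden",
    "SubcloneCaller",
]

#: legal single events, as (from_code, to_code)
LEGAL_EVENTS = {(0, 1), (1, 2), (1, 0)}


def min_cells_for_fdr(n_profiled: int, fdr: float = 0.02) -> int:
    """Minimum cell count for a genotype to clear the FDR cut-off.

    ``ceil(fdr * n_profiled)`` with a floor of 1.
    """
    if not 0.0 < fdr < 1.0:
        raise ValueError("fdr must be in (0, 1)")
    if n_profiled < 1:
        raise ValueError("n_profiled must be >= 1")
    return max(1, math.ceil(fdr * n_profiled))


def _as_matrix(matrix) -> pd.DataFrame:
    df = pd.DataFrame(matrix)
    if df.empty:
        raise ValueError("genotype matrix is empty")
    if df.isna().any().any():
        raise ValueError("genotype matrix has missing entries (QC should discard such cells)")
    if not df.isin([0, 1, 2]).all().all():
        raise ValueError("genotype codes must be in {0, 1, 2}")
    return df.astype(int)


def enumerate_genotypes(matrix) -> pd.DataFrame:
    """Group cells by identical ternary genotype vector.

    Returns the subclone table: one row per distinct genotype with columns
    ``genotype`` (tuple of codes), ``n_cells``, ``proportion``, ``passed``
    (all True here) and ``reason``. Rows are ordered by descending cell
    count, ties broken lexicographically on the genotype — a deterministic
    order invariant to cell-row permutation.
    """
    df = _as_matrix(matrix)
    total = len(df)
    counts = df.apply(tuple, axis=1).value_counts()
    table = pd.DataFrame({
        "genotype": counts.index,
        "n_cells": counts.values,
    })
    table = table.sort_values(
        ["n_cells", "genotype"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["proportion"] = table["n_cells"] / total
    table["passed"] = True
    table["reason"] = "pass"
    table.attrs["n_profiled"] = total
    table.attrs["assays"] = list(df.columns)
    return table[["genotype", "n_cells", "proportion", "passed", "reason"]]


def _single_event_assay(candidate, retained) -> int | None:
    """Index of the single assay by which ``candidate`` = ``retained`` + one legal event."""
    diff = [i for i, (r, c) in enumerate(zip(retained, candidate)) if r != c]
    if len(diff) != 1:
        return None
    i = diff[0]
    return i if (retained[i], candidate[i]) in LEGAL_EVENTS else None


def filter_subclones(table: pd.DataFrame, n_profiled: int, panel: AssayPanel | None = None,
                     fdr: float = 0.02, renormalize: bool = False,
                     assays=None) -> pd.DataFrame:
    """Apply the FDR hard cut-off and the per-assay error-rate rule.

    Rule (a) first: genotypes with fewer than ``min_cells_for_fdr(n_profiled,
    fdr)`` cells fail. Then rule (b), ascending by count: a still-passing
    genotype fails if it differs from a retained genotype by exactly one
    legal event (0->1, 1->2 or 1->0) at some assay and its proportion is at
    or below that assay's false-positive rate; when several retained
    neighbours exist the one with the largest cell count is used. Failures
    carry a machine-readable reason (the audit log standing in for manual
    review). The filter is idempotent.
    """
    out = table.copy()
    if assays is None:
        assays = table.attrs.get("assays")
    min_cells = min_cells_for_fdr(n_profiled, fdr)

    fail_a = out["n_cells"] < min_cells
    out.loc[fail_a, "passed"] = False
    out.loc[fail_a, "reason"] = f"below FDR cut-off ({int(min_cells)} cells for {n_profiled} profiled)"

    if panel is not None:
        # ascending count so the weakest candidates are tested against the
        # currently retained set; retained set shrinks as rule (b) fires
        order = out.sort_values(["n_cells", "genotype"], ascending=[True, True], kind="mergesort").index
        for idx in order:
            if not out.at[idx, "passed"]:
                continue
            cand = out.at[idx, "genotype"]
            retained = out[(out["passed"]) & (out.index != idx)]
            neighbours = []
            for ridx in retained.index:
                a_idx = _single_event_assay(cand, out.at[ridx, "genotype"])
                if a_idx is not None:
                    neighbours.append((out.at[ridx, "n_cells"], ridx, a_idx))
            if not neighbours:
                continue
            neighbours.sort(key=lambda t: (-t[0], t[1]))  # largest retained genotype first
            _, _, a_idx = neighbours[0]
            assay = assays[a_idx] if assays is not None else a_idx
            rate = panel[assay] if isinstance(assay, str) else list(panel.fpr.values())[a_idx]
            if out.at[idx, "proportion"] <= rate:
                out.at[idx, "passed"] = False
                out.at[idx, "reason"] = f"single-event neighbour below assay error rate ({assay}: {rate:.4g})"

    if renormalize:
        total = out.loc[out["passed"], "n_cells"].sum()
        out["proportion"] = np.where(out["passed"], out["n_cells"] / max(total, 1), out["proportion"])
    out.attrs.update(table.attrs)
    out.attrs["n_profiled"] = n_profiled
    return out


def sc_allele_burden(column) -> float:
    """VAF-equivalent mutant-allele fraction of one assay across cells.

    ``(n_het + 2 * n_hom) / (2 * n_cells)`` — comparable to the bulk VAF of
    the same mutation in the sorted compartment.
    """
    codes = np.asarray(column, dtype=int)
    if codes.size == 0:
        raise ValueError("empty genotype column")
    n1 = int((codes == 1).sum())
    n2 = int((codes == 2).sum())
    return (n1 + 2 * n2) / (2 * codes.size)


class SubcloneCaller(BaseEstimator):
    """Genotype grouping plus error filtering, scikit-learn style.

    ``fit(X)`` takes a cells x assays ternary matrix (DataFrame or array),
    optionally with an :class:`~mfclone.qc.AssayPanel` for the per-assay
    error rule, and exposes the filtered subclone table.

    Attributes
    ----------
    table_ : full subclone table with pass/fail flags and reasons.
    subclones_ : passing rows only.
    n_profiled_ : number of genotyped cells.
    """

    def __init__(self, fdr: float = 0.02, renormalize: bool = False):
        self.fdr = fdr
        self.renormalize = renormalize

    def fit(self, X, y=None, panel: AssayPanel | None = None):
        df = _as_matrix(X)
        self.n_profiled_ = len(df)
        table = enumerate_genotypes(df)
        self.table_ = filter_subclones(
            table, self.n_profiled_, panel=panel, fdr=self.fdr,
            renormalize=self.renormalize, assays=list(df.columns),
        )
        self.subclones_ = self.table_[self.table_["passed"]].reset_index(drop=True)
        return self

    def fit_predict(self, X, y=None, panel: AssayPanel | None = None):
        """Cluster labels per cell: index into ``table_`` (-1 for filtered cells)."""
        self.fit(X, panel=panel)
        df = _as_matrix(X)
        lookup = {g: (i if ok else -1)
                  for i, (g, ok) in enumerate(zip(self.table_["genotype"], self.table_["passed"]))}
        return np.array([lookup[tuple(r)] for r in df.itertuples(index=False)])
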