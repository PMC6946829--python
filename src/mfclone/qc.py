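"""Single-cell qPCR plate quality control and ternary genotype calling.

Each well of a genotyping plate carries, per SNV assay, a paired pair of
allele-specific reactions (a WT probe and a MUT probe) plus two copy-number
control probes located in diploid regions (default names SLC2A9/PPIP5K1).
QC proceeds in experiment order:

1. well classification from the control probes — empty (neither amplified),
   doublet (both CTs one template doubling earlier than the singlet
   reference), ambiguous (exactly one amplified), else singlet;
2. CT quartile filtering of singlets (Tukey fences per probe);
3. per-assay false-positive-rate estimation on a wild-type control cell
   line plate;
4. ternary genotype calling: (WT+, MUT-) -> 0, (WT+, MUT+) -> 1,
   (WT-, MUT+) -> 2; both negative is a failed reaction and any failed
   reaction discards the whole cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ReactionSignal",
    "Well",
    "Plate",
    "AssayPanel",
    "control_ct_reference",
    "classify_well",
    "classify_plate",
    "estimate_sorting_failure",
    "quartile_filter",
    "estimate_fpr",
    "genotype_cell",
    "genotype_plate",
    "PlateGenotyper",
]

DEFAULT_CONTROL_PROBES = ("SLC2A9", "PPIP5K1")

# well / cell statuses, in decision order
EMPTY = "empty"
DOUBLET = "doublet"
AMBIGUOUS = "ambiguous"
SINGLET = "singlet"
CT_OUTLIER = "ct_outlier"
DISCARDED = "discarded"
GENOTYPED = "genotyped"


@dataclass(frozen=True)
class ReactionSignal:
    """One qPCR reaction: amplified flag plus CT (cycles) iff amplified."""

    amplified: bool
    ct: float | None = None

    def __post_init__(self) -> None:
        if self.amplified != (self.ct is not None):
            raise ValueError("ct must be present iff the reaction amplified")


NEGATIVE = ReactionSignal(False)


@dataclass
class Well:
    """One well: paired (WT, MUT) signals per assay plus control-probe signals."""

    well_id: str
    reactions: dict = field(default_factory=dict)  # assay -> (wt: ReactionSignal, mut: ReactionSignal)
    controls: dict = field(default_factory=dict)   # probe -> ReactionSignal
    truth: dict | None = None                      # simulator-only labels


@dataclass
class Plate:
    """A genotyping plate: wells, assay panel, control probe names."""

    wells: list
    assays: list
    control_probes: tuple = DEFAULT_CONTROL_PROBES
    plate_id: str = "plate"
    time_point: str = ""

    def __post_init__(self) -> None:
        for w in self.wells:
            for a in self.assays:
                if a not in w.reactions:
                    raise ValueError(f"well {w.well_id} missing assay {a}")
            for p in self.control_probes:
                if p not in w.controls:
                    raise ValueError(f"well {w.well_id} missing control probe {p}")

    def __len__(self) -> int:
        return len(self.wells)


@dataclass
class AssayPanel:
    """Per-assay false-positive rates estimated on a wild-type control line."""

    fpr: dict  # assay -> probability
    n_evaluable: int = 0

    def __post_init__(self) -> None:
        for a, v in self.fpr.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"fpr for {a} must be in [0, 1]")

    def __getitem__(self, assay: str) -> float:
        return self.fpr[assay]


def control_ct_reference(plate: Plate) -> dict:
    """Median CT per control probe over wells where both control probes amplified.

    Serves as the singlet reference: doublets are rare enough (a few percent)
    that the median is dominated by singlets.
    """
    ref = {}
    both = [w for w in plate.wells
            if all(w.controls[p].amplified for p in plate.control_probes)]
    if not both:
        raise ValueError("no well with both control probes amplified; cannot build CT reference")
    for p in plate.control_probes:
        ref[p] = float(np.median([w.controls[p].ct for w in both]))
    return ref


def classify_well(well: Well, singlet_ct_reference: dict, delta: float = 0.5,
                  control_probes=DEFAULT_CONTROL_PROBES) -> str:
    """Classify a well as empty / doublet / ambiguous / singlet.

    Empty: neither control probe amplified. Doublet: both control CTs at or
    below reference - ``delta`` (a doublet carries twice the template, i.e. a
    one-cycle-earlier CT; ``delta`` is the decision boundary, default 0.5 =
    the symmetric midpoint of that one-cycle shift). Exactly one probe
    amplified: ambiguous, excluded downstream. Otherwise singlet.
    """
    sig = [well.controls[p] for p in control_probes]
    n_amp = sum(s.amplified for s in sig)
    if n_amp == 0:
        return EMPTY
    if n_amp == 1:
        return AMBIGUOUS
    if all(well.controls[p].ct <= singlet_ct_reference[p] - delta for p in control_probes):
        return DOUBLET
    return SINGLET


def classify_plate(plate: Plate, delta: float = 0.5, reference: dict | None = None) -> pd.Series:
    """Classify every well; returns a Series indexed by well id."""
    if reference is None:
        reference = control_ct_reference(plate)
    return pd.Series(
        {w.well_id: classify_well(w, reference, delta, plate.control_probes) for w in plate.wells},
        name="status",
    )


@dataclass
class SortingFailure:
    empty_rate: float
    doublet_rate: float
    failure_rate: float

    def __iter__(self):
        return iter((self.empty_rate, self.doublet_rate, self.failure_rate))


def estimate_sorting_failure(plate_or_statuses, delta: float = 0.5) -> SortingFailure:
    """Empty/doublet/failure rates of a classified calibration plate.

    Rates are counts over attempted wells (ambiguous wells count as attempted
    but contribute to neither the empty nor the doublet numerator).
    """
    if isinstance(plate_or_statuses, Plate):
        statuses = classify_plate(plate_or_statuses, delta=delta)
    else:
        statuses = pd.Series(plate_or_statuses)
    n = len(statuses)
    if n == 0:
        raise ValueError("zero wells")
    empty = float((statuses == EMPTY).sum()) / n
    doublet = float((statuses == DOUBLET).sum()) / n
    return SortingFailure(empty, doublet, empty + doublet)


def quartile_filter(ct_table: pd.DataFrame, k: float = 1.5) -> pd.Series:
    """Retain cells whose amplified CTs fall inside per-probe quartile fences.

    ``ct_table`` is cells x probes with NaN for unamplified reactions. For
    each probe, Q1 and Q3 are computed over amplified cells and a cell is
    retained only if every one of its amplified CTs lies within
    ``[Q1 - k*IQR, Q3 + k*IQR]``. The default k = 1.5 is the standard Tukey
    fence; k = 0 reproduces a literal between-the-quartiles reading (retains
    the middle half per probe). Degenerate IQR = 0 retains cells equal to the
    common value. Probes with fewer than 4 amplified cells carry no estimable
    quartiles and are skipped; if no probe is estimable the filter errors.

    Returns a boolean Series indexed like ``ct_table``.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    keep = pd.Series(True, index=ct_table.index)
    n_estimable = 0
    for probe in ct_table.columns:
        col = ct_table[probe]
        vals = col.dropna()
        if len(vals) < 4:
            continue
        n_estimable += 1
        q1, q3 = vals.quantile(0.25), vals.quantile(0.75)
        iqr = q3 - q1
        # small tolerance so boundary values are not lost to float rounding
        eps = 1e-9 * max(1.0, abs(float(q3)))
        lo, hi = q1 - k * iqr - eps, q3 + k * iqr + eps
        ok = col.isna() | ((col >= lo) & (col <= hi))
        keep &= ok
    if n_estimable == 0:
        raise ValueError("no probe has >= 4 amplified cells; quartiles not estimable")
    return keep


def _singlet_ct_table(plate: Plate, statuses: pd.Series) -> pd.DataFrame:
    """CT matrix (singlet wells x all probes, NaN when unamplified)."""
    rows = {}
    for w in plate.wells:
        if statuses[w.well_id] != SINGLET:
            continue
        row = {}
        for p in plate.control_probes:
            s = w.controls[p]
            row[p] = s.ct if s.amplified else np.nan
        for a in plate.assays:
            wt, mut = w.reactions[a]
            row[f"{a}_WT"] = wt.ct if wt.amplified else np.nan
            row[f"{a}_MUT"] = mut.ct if mut.amplified else np.nan
        rows[w.well_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def genotype_cell(well: Well, assays) -> np.ndarray | None:
    """Ternary genotype vector of a QC-passed singlet, or None when discarded.

    Per assay: (WT+, MUT-) -> 0, (WT+, MUT+) -> 1, (WT-, MUT+) -> 2;
    (WT-, MUT-) is a failed reaction and a single failed reaction discards
    the whole cell (no imputation of missing genotypes).
    """
    codes = np.empty(len(assays), dtype=int)
    for i, a in enumerate(assays):
        wt, mut = well.reactions[a]
        if wt.amplified and not mut.amplified:
            codes[i] = 0
        elif wt.amplified and mut.amplified:
            codes[i] = 1
        elif mut.amplified:
            codes[i] = 2
        else:
            return None
    return codes


def genotype_plate(plate: Plate, delta: float = 0.5, quartile_k: float = 1.5):
    """Run the full QC + genotyping cascade on one plate.

    Returns ``(matrix, report)``: ``matrix`` is a cells x assays DataFrame of
    ternary codes (index = well id, QC-passed cells only); ``report`` has one
    row per attempted well with its final status
    (empty/doublet/ambiguous/ct_outlier/discarded/genotyped) and the rule
    that produced it.
    """
    statuses = classify_plate(plate, delta=delta)
    final = statuses.copy()
    reasons = statuses.map({
        EMPTY: "no control probe amplified",
        DOUBLET: f"both control CTs <= reference - {delta}",
        AMBIGUOUS: "exactly one control probe amplified",
        SINGLET: "",
    })

    ct = _singlet_ct_table(plate, statuses)
    retained = quartile_filter(ct, k=quartile_k) if len(ct) else pd.Series(dtype=bool)

    rows = {}
    for w in plate.wells:
        if statuses[w.well_id] != SINGLET:
            continue
        if not retained.get(w.well_id, False):
            final[w.well_id] = CT_OUTLIER
            reasons[w.well_id] = f"CT outside quartile fences (k={quartile_k})"
            continue
        codes = genotype_cell(w, plate.assays)
        if codes is None:
            final[w.well_id] = DISCARDED
            reasons[w.well_id] = "failed reaction (both probes negative) at >=1 assay"
        else:
            final[w.well_id] = GENOTYPED
            reasons[w.well_id] = "pass"
            rows[w.well_id] = codes

    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=plate.assays, dtype=int)
    matrix = matrix.reindex([w.well_id for w in plate.wells if w.well_id in rows])
    report = pd.DataFrame({"status": final, "reason": reasons})
    report.index.name = "well_id"
    return matrix, report


def estimate_fpr(control_plate: Plate, delta: float = 0.5, quartile_k: float = 1.5) -> AssayPanel:
    """Per-assay false-positive rate from a wild-type control-line plate.

    All cells on the plate are truly wild type at every assay, so any
    mutant-positive call (code 1 or 2) among QC-passed singlets is a false
    positive: fpr(assay) = mutant-positive cells / evaluable cells. Assays
    with zero false positives get fpr 0 (no pseudocount).
    """
    matrix, _ = genotype_plate(control_plate, delta=delta, quartile_k=quartile_k)
    n = len(matrix)
    if n == 0:
        raise ValueError("zero evaluable cells on control plate")
    fpr = {a: float((matrix[a] > 0).sum()) / n for a in control_plate.assays}
    return AssayPanel(fpr=fpr, n_evaluable=n)


class PlateGenotyper(TransformerMixin, BaseEstimator):
    """QC + ternary genotyping of plates, as a scikit-learn transformer.

    ``fit`` learns the control-probe CT reference from the plate;
    ``transform`` returns the cells x assays ternary genotype matrix.

    Parameters
    ----------
    delta_ct : doublet decision boundary in cycles below the singlet
        reference (default 0.5; a doublet's extra genome shifts CT by ~1).
    quartile_k : Tukey-fence multiplier of the CT quartile filter
        (default 1.5; 0 = literal middle-half reading).

    Attributes
    ----------
    reference_ : median singlet CT per control probe.
    report_ : per-well QC report from the last transform.
    statuses_ : final status per well.
    """

    def __init__(self, delta_ct: float = 0.5, quartile_k: float = 1.5):
        self.delta_ct = delta_ct
        self.quartile_k = quartile_k

    def fit(self, X: Plate, y=None):
        self.reference_ = control_ct_reference(X)
        return self

    def transform(self, X: Plate) -> pd.DataFrame:
        matrix, report = genotype_plate(X, delta=self.delta_ct, quartile_k=self.quartile_k)
        self.report_ = report
        self.statuses_ = report["status"]
        return matrix

    def fit_transform(self, X: Plate, y=None, **kwargs) -> pd.DataFrame:
        return self.fit(X).transform(X)
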