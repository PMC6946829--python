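"""Readers and writers for the pipeline's plain-text formats.

Formats: mutation tables as TSV (named columns) and a minimal VCF dialect
(AF/DP/CNT/CNN in INFO, read via cyvcf2); plate CSV (one row per well,
paired ``{assay}_WT_CT``/``{assay}_MUT_CT`` columns plus one CT column per
control probe, blank = not amplified); genotype matrices as TSV; Newick for
trees; JSON for subclone tables, assay panels and truth files. Every writer
is the inverse of the matching reader.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd

from .bulk import MUTATION_COLUMNS, mutations_to_frame
from .qc import DEFAULT_CONTROL_PROBES, AssayPanel, Plate, ReactionSignal, Well

__all__ = [
    "read_mutations_tsv",
    "write_mutations_tsv",
    "read_vcf",
    "write_plate_csv",
    "read_plate_csv",
    "write_genotype_matrix",
    "read_genotype_matrix",
    "write_subclone_table",
    "read_subclone_table",
    "write_assay_panel",
    "read_assay_panel",
]


# -- mutation tables --------------------------------------------------------

def read_mutations_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return mutations_to_frame(df)


def write_mutations_tsv(df: pd.DataFrame, path) -> None:
    mutations_to_frame(df).to_csv(path, sep="\t", index=False)


def read_vcf(path) -> pd.DataFrame:
    """Minimal VCF reader: fixed columns plus AF/DP/CNT/CNN INFO fields.

    Missing CNT/CNN default to 2 copies with a warning; missing AF/DP are
    errors (a mutation table is useless without them).
    """
    from cyvcf2 import VCF

    rows = []
    defaulted = False
    for v in VCF(str(path)):
        af = v.INFO.get("AF")
        dp = v.INFO.get("DP")
        if af is None or dp is None:
            raise ValueError(f"{path}: record {v.CHROM}:{v.POS} missing AF or DP INFO field")
        cnt = v.INFO.get("CNT")
        cnn = v.INFO.get("CNN")
        if cnt is None or cnn is None:
            defaulted = True
        ref, alt = v.REF, v.ALT[0]
        indel_len = abs(len(alt) - len(ref))
        rows.append({
            "gene": v.INFO.get("GENE", "") or "",
            "chrom": v.CHROM,
            "pos": v.POS,  # cyvcf2 POS is 1-based
            "ref": ref,
            "alt": alt,
            "vaf": float(af),
            "depth": int(dp),
            "cn_tumor": float(cnt) if cnt is not None else 2.0,
            "cn_normal": float(cnn) if cnn is not None else 2.0,
            "is_indel": indel_len > 0,
            "indel_len": indel_len,
        })
    if defaulted:
        warnings.warn(f"{path}: CNT/CNN missing for some records; defaulting to 2 copies")
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


# -- plates -----------------------------------------------------------------

def _sig_to_value(sig: ReactionSignal):
    return sig.ct if sig.amplified else np.nan


def _value_to_sig(v) -> ReactionSignal:
    return ReactionSignal(True, float(v)) if pd.notna(v) else ReactionSignal(False)


def write_plate_csv(plate: Plate, path, truth_path=None) -> None:
    """One row per well; blank CT = reaction did not amplify.

    Truth labels (when present, i.e. simulated plates) go to a separate JSON.
    """
    rows = []
    for w in plate.wells:
        row = {"well_id": w.well_id}
        for a in plate.assays:
            wt, mut = w.reactions[a]
            row[f"{a}_WT_CT"] = _sig_to_value(wt)
            row[f"{a}_MUT_CT"] = _sig_to_value(mut)
        for p in plate.control_probes:
            row[f"{p}_CT"] = _sig_to_value(w.controls[p])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.4f")
    if truth_path is not None:
        truth = {w.well_id: w.truth for w in plate.wells}
        with open(truth_path, "w") as fh:
            json.dump({"plate_id": plate.plate_id, "time_point": plate.time_point,
                       "wells": truth}, fh, indent=2)


def read_plate_csv(path, assays=None, control_probes=DEFAULT_CONTROL_PROBES,
                   truth_path=None) -> Plate:
    """Read a plate CSV (the simulator dialect / generic wide export).

    Assay names are inferred from paired ``*_WT_CT``/``*_MUT_CT`` columns
    when not given explicitly; control probes from ``{probe}_CT`` columns.
    """
    df = pd.read_csv(path)
    if "well_id" not in df.columns:
        raise ValueError(f"{path}: missing well_id column")
    if assays is None:
        assays = [c[: -len("_WT_CT")] for c in df.columns if c.endswith("_WT_CT")]
        for a in assays:
            if f"{a}_MUT_CT" not in df.columns:
                raise ValueError(f"{path}: assay {a} has a WT column but no MUT column")
    truth = None
    if truth_path is not None:
        with open(truth_path) as fh:
            truth = json.load(fh)["wells"]
    wells = []
    for _, r in df.iterrows():
        reactions = {a: (_value_to_sig(r[f"{a}_WT_CT"]), _value_to_sig(r[f"{a}_MUT_CT"]))
                     for a in assays}
        controls = {p: _value_to_sig(r[f"{p}_CT"]) for p in control_probes}
        wells.append(Well(str(r["well_id"]), reactions, controls,
                          truth.get(str(r["well_id"])) if truth else None))
    return Plate(wells=wells, assays=list(assays), control_probes=tuple(control_probes))


# -- genotype matrices & subclone tables ------------------------------------

def write_genotype_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index=True, index_label="cell_id")


def read_genotype_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="cell_id")
    if not df.isin([0, 1, 2]).all().all():
        raise ValueError(f"{path}: genotype codes must be 0/1/2")
    return df.astype(int)


def write_subclone_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["genotype"] = out["genotype"].map(lambda g: "".join(map(str, g)))
    out.to_csv(path, sep="\t", index=False)


def read_subclone_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["genotype"] = df["genotype"].map(lambda s: tuple(int(c) for c in str(s)))
    return df


# -- assay panels -----------------------------------------------------------

def write_assay_panel(panel: AssayPanel, path) -> None:
    with open(path, "w") as fh:
        json.dump({"fpr": panel.fpr, "n_evaluable": panel.n_evaluable}, fh, indent=2)


def read_assay_panel(path) -> AssayPanel:
    with open(path) as fh:
        d = json.load(fh)
    return AssayPanel(fpr=d["fpr"], n_evaluable=d.get("n_evaluable", 0))
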