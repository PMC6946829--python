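"""End-to-end orchestration: QC -> genotyping -> subclones -> phylogeny -> reports."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import io as mfio
from .phylogeny import ErrorModel, FiniteSitesTreeML, to_newick, tree_log_likelihood
from .qc import AssayPanel, Plate, PlateGenotyper, estimate_fpr, estimate_sorting_failure
from .subclones import SubcloneCaller, sc_allele_burden

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Stage parameters of one pipeline run; persisted into every output header.

    ``plate`` / ``control_plate`` may be :class:`~mfclone.qc.Plate` objects or
    paths to plate CSVs.
    """

    plate: object = None
    control_plate: object = None
    out_dir: str | None = None
    fdr: float = 0.02
    detect_vaf: float = 0.05
    quartile_k: float = 1.5
    doublet_delta_ct: float = 0.5
    n_restarts: int = 20
    seed: int = 0
    disease_assay: int = 0
    renormalize: bool = False
    verbosity: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr < 1.0:
            raise ValueError("fdr must be in (0, 1)")
        if not 0.0 <= self.detect_vaf <= 1.0:
            raise ValueError("detect_vaf must be in [0, 1]")
        if self.quartile_k < 0:
            raise ValueError("quartile_k must be >= 0")
        if self.doublet_delta_ct <= 0:
            raise ValueError("doublet_delta_ct must be > 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")

    def params(self) -> dict:
        """Stage parameters only — input/output paths are not part of them."""
        d = asdict(self)
        for key in ("plate", "control_plate", "out_dir"):
            d.pop(key)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.params(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    qc_report: pd.DataFrame
    sorting_failure: object
    panel: AssayPanel | None
    matrix: pd.DataFrame
    subclone_table: pd.DataFrame
    subclones: pd.DataFrame
    tree: object
    newick: str
    events: pd.DataFrame
    burdens: dict
    log_likelihood: float | None
    stamp: dict = field(default_factory=dict)


def _load_plate(obj) -> Plate:
    if isinstance(obj, Plate):
        return obj
    return mfio.read_plate_csv(obj)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run QC, genotyping, subclone calling and phylogeny on one plate.

    Deterministic given the configuration and seed: repeated runs produce
    byte-identical outputs. When ``out_dir`` is set, writes the QC report
    TSV, genotype matrix TSV, subclone table TSV, assay-panel JSON, Newick
    tree, event table TSV and a JSON run stamp (config hash + seed).
    """
    if config.plate is None:
        raise ValueError("config.plate is required")
    plate = _load_plate(config.plate)

    panel = None
    if config.control_plate is not None:
        panel = estimate_fpr(_load_plate(config.control_plate),
                             delta=config.doublet_delta_ct, quartile_k=config.quartile_k)

    genotyper = PlateGenotyper(delta_ct=config.doublet_delta_ct, quartile_k=config.quartile_k)
    matrix = genotyper.fit_transform(plate)
    qc_report = genotyper.report_
    failure = estimate_sorting_failure(qc_report["status"])

    caller = SubcloneCaller(fdr=config.fdr, renormalize=config.renormalize)
    caller.fit(matrix, panel=panel)

    alpha = panel.fpr if panel is not None else 0.0
    model = ErrorModel(alpha=alpha)
    est = FiniteSitesTreeML(
        method="auto", alpha=alpha, n_restarts=config.n_restarts,
        disease_assay=config.disease_assay, random_state=config.seed,
    )
    est.fit(caller.subclones_, assays=list(matrix.columns))
    tree = est.tree_

    retained_genotypes = set(caller.subclones_["genotype"])
    retained_cells = matrix[matrix.apply(tuple, axis=1).isin(retained_genotypes)]
    loglik = tree_log_likelihood(tree, retained_cells, model) if len(retained_cells) else None

    burdens = {a: sc_allele_burden(matrix[a]) for a in matrix.columns}
    stamp = {"config_hash": config.config_hash(), "seed": config.seed, **config.params()}

    result = PipelineResult(
        qc_report=qc_report,
        sorting_failure=failure,
        panel=panel,
        matrix=matrix,
        subclone_table=caller.table_,
        subclones=caller.subclones_,
        tree=tree,
        newick=to_newick(tree),
        events=est.events_,
        burdens=burdens,
        log_likelihood=loglik,
        stamp=stamp,
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        qc_report.to_csv(out / "qc_report.tsv", sep="\t")
        mfio.write_genotype_matrix(matrix, out / "genotype_matrix.tsv")
        mfio.write_subclone_table(caller.table_, out / "subclones.tsv")
        if panel is not None:
            mfio.write_assay_panel(panel, out / "assay_panel.json")
        (out / "tree.nwk").write_text(result.newick + "\n")
        tree.to_json(out / "tree.json")
        est.events_.to_csv(out / "events.tsv", sep="\t")
        with open(out / "run_stamp.json", "w") as fh:
            json.dump(stamp, fh, indent=2, sort_keys=True)
    return result
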