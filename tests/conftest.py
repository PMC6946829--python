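import numpy as np
import pytest

import mfclone as m


@pytest.fixture
def small_tree():
    """Deterministic 4-assay tree with one LOH event."""
    return m.simulate_clone_tree(4, 1, seed=7)


@pytest.fixture
def default_config():
    return m.SimulationConfig(n_wells=400, seed=123)


def planted_parent_genotypes(tree):
    """genotype -> parent genotype map of a planted CloneTreeSpec."""
    by_id = {c.id: c for c in tree.clones}
    return {
        tuple(c.genotype): (tuple(by_id[c.parent_id].genotype) if c.parent_id else None)
        for c in tree.clones
    }


def topology_recovered(truth_tree, fitted) -> bool:
    """True when every fitted parent edge matches the planted tree.

    Planted ancestors that were filtered out (or absorbed into the fitted
    root) are contracted before comparison; any spurious retained genotype
    counts as a failure.
    """
    pm = planted_parent_genotypes(truth_tree)
    fitted_parent = {
        tuple(fitted.genotypes[i]): tuple(fitted.genotypes[p])
        for i, p in enumerate(fitted.parent)
        if p is not None
    }
    for geno, parent in fitted_parent.items():
        if geno not in pm:
            return False
        truth_parent = pm[geno]
        while (
            truth_parent is not None
            and truth_parent not in fitted_parent
            and truth_parent != tuple(fitted.genotypes[0])
        ):
            anc = next(c for c in truth_tree.clones if tuple(c.genotype) == truth_parent)
            truth_parent = (
                tuple(truth_tree.clone_by_id(anc.parent_id).genotype) if anc.parent_id else None
            )
        if truth_parent is None:
            continue
        if parent != truth_parent:
            return False
    return True


def simulate_and_call(seed, n_assays=6, n_loh=1, n_wells=400, fpr=0.005):
    """One full replicate: simulate plate -> QC -> subclones -> fitted tree."""
    tree = m.simulate_clone_tree(n_assays, n_loh, seed=seed)
    cfg = m.SimulationConfig(n_wells=n_wells, fpr_per_assay=fpr, seed=10_000 + seed)
    plate = m.simulate_plate(tree, "t1", cfg)
    matrix, report = m.genotype_plate(plate)
    caller = m.SubcloneCaller().fit(matrix)
    est = m.FiniteSitesTreeML(random_state=seed).fit(caller.subclones_, assays=list(matrix.columns))
    return tree, matrix, caller, est
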