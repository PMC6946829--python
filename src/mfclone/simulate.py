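"""Synthetic clone trees, bulk time-point read data, and single-cell plates.

The generator emulates the data a longitudinal myelofibrosis study produces:
a rooted clone tree over a small assay panel (4-8 mutations typical) whose
edges are single events from the alphabet {0->1 mutation gain, 1->2
copy-neutral LOH to homozygous mutant, 1->0 LOH reversion to wild type};
per-time-point clone prevalences (the remainder being wild-type cells); bulk
read counts drawn binomially around the analytic expected VAF; and
192-480-well genotyping plates with empty wells (~9%), cell doublets
(~3.5%, modelled as the signal union of two cells with control-probe CTs one
template doubling earlier) and per-assay false-positive mutant signals.

LOH events default to the disease-defining assay: copy-neutral LOH at that
locus (9pUPD at JAK2) is the recurrent event in this disease, and it keeps
planted topologies identifiable for recovery experiments. Truth labels are
retained on every well for testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .bulk import mutations_to_frame
from .qc import (
    DEFAULT_CONTROL_PROBES,
    Plate,
    ReactionSignal,
    Well,
)

__all__ = [
    "Assay",
    "Clone",
    "CloneTreeSpec",
    "SimulationConfig",
    "simulate_clone_tree",
    "simulate_bulk",
    "simulate_plate",
    "simulate_control_plate",
]

#: legal single-assay state changes along a tree edge
LEGAL_EVENTS = {(0, 1), (1, 2), (1, 0)}

GENE_POOL = [
    "TET2", "ASXL1", "SF3B1", "SRSF2", "KRAS", "NRAS",
    "IDH2", "EZH2", "CBL", "U2AF1", "DNMT3A", "FGF1",
]

WT_ID = "WT"


@dataclass(frozen=True)
class Assay:
    name: str
    is_disease_defining: bool = False


@dataclass
class Clone:
    id: str
    parent_id: str | None
    genotype: tuple


@dataclass
class CloneTreeSpec:
    """A planted clone tree with per-time-point prevalences.

    ``prevalence[time_point][clone_id]`` are fractions summing to <= 1 at
    each time point; the remainder is the wild-type cell fraction.
    """

    assays: list
    clones: list
    prevalence: dict

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def clone_by_id(self, clone_id: str) -> Clone:
        for c in self.clones:
            if c.id == clone_id:
                return c
        raise KeyError(clone_id)

    def events(self, clone: Clone) -> list:
        """(assay_name, from_code, to_code) changes on the edge into ``clone``."""
        if clone.parent_id is None:
            return []
        parent = self.clone_by_id(clone.parent_id)
        return [
            (self.assays[i].name, a, b)
            for i, (a, b) in enumerate(zip(parent.genotype, clone.genotype))
            if a != b
        ]

    def all_events(self) -> list:
        return [ev for c in self.clones for ev in self.events(c)]

    @property
    def time_points(self) -> list:
        return list(self.prevalence)

    def validate(self) -> None:
        n = len(self.assays)
        ids = [c.id for c in self.clones]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate clone ids")
        roots = [c for c in self.clones if c.parent_id is None]
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root clone")
        root = roots[0]
        disease = [i for i, a in enumerate(self.assays) if a.is_disease_defining]
        allowed_root = {tuple([0] * n)}
        for i in disease:
            g = [0] * n
            g[i] = 1
            allowed_root.add(tuple(g))
        if tuple(root.genotype) not in allowed_root:
            raise ValueError("root must be wild-type or carry only the disease-defining assay")
        for c in self.clones:
            if len(c.genotype) != n:
                raise ValueError(f"clone {c.id} genotype length != n_assays")
            if c.parent_id is not None:
                evs = self.events(c)
                if not evs:
                    raise ValueError(f"clone {c.id} identical to its parent")
                for _, a, b in evs:
                    if (a, b) not in LEGAL_EVENTS:
                        raise ValueError(f"illegal event {a}->{b} into clone {c.id}")
        for tp, prev in self.prevalence.items():
            unknown = set(prev) - set(ids)
            if unknown:
                raise ValueError(f"prevalence at {tp} names unknown clones {unknown}")
            total = sum(prev.values())
            if total > 1.0 + 1e-9 or any(v < 0 for v in prev.values()):
                raise ValueError(f"prevalences at {tp} must be nonnegative and sum to <= 1")

    # -- derived quantities ------------------------------------------------
    def wt_fraction(self, time_point: str) -> float:
        return 1.0 - sum(self.prevalence[time_point].values())

    def expected_vaf(self, time_point: str, purity: float = 1.0) -> np.ndarray:
        """Analytic expected bulk VAF per assay.

        Copy-neutral events keep the locus diploid, so the mutant-allele
        fraction of the tumor compartment is sum(prevalence * code / 2) and
        the bulk VAF scales linearly with purity.
        """
        if time_point not in self.prevalence:
            raise ValueError(f"no prevalence defined at time point {time_point!r}")
        prev = self.prevalence[time_point]
        vaf = np.zeros(len(self.assays))
        for cid, p in prev.items():
            g = np.asarray(self.clone_by_id(cid).genotype, dtype=float)
            vaf += p * g / 2.0
        return purity * vaf

    def clone_ids_and_probs(self, time_point: str):
        """Sampling distribution over clones plus the wild-type remainder."""
        prev = self.prevalence[time_point]
        ids = [c.id for c in self.clones if prev.get(c.id, 0.0) > 0]
        probs = [prev[c] for c in ids]
        wt = self.wt_fraction(time_point)
        if wt > 1e-12:
            ids.append(WT_ID)
            probs.append(wt)
        probs = np.asarray(probs, dtype=float)
        return ids, probs / probs.sum()

    def genotype_of(self, clone_id: str) -> tuple:
        if clone_id == WT_ID:
            return tuple([0] * len(self.assays))
        return tuple(self.clone_by_id(clone_id).genotype)

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "assays": [asdict(a) for a in self.assays],
            "clones": [{"id": c.id, "parent_id": c.parent_id, "genotype": list(c.genotype)}
                       for c in self.clones],
            "prevalence": self.prevalence,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CloneTreeSpec":
        return cls(
            assays=[Assay(**a) for a in d["assays"]],
            clones=[Clone(c["id"], c["parent_id"], tuple(c["genotype"])) for c in d["clones"]],
            prevalence={tp: dict(p) for tp, p in d["prevalence"].items()},
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CloneTreeSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SimulationConfig:
    """Study conditions for plate and bulk simulation.

    Defaults follow the study design being emulated: 9% empty wells, 3.5%
    doublets, ultra-deep bulk coverage, and per-assay false-positive rates of
    0.5% (most assays on the wild-type control line showed ~0; a small
    minority reached ~5%, which scenario configs can set explicitly).
    CT values of positive reactions are Normal(probe mean, ``ct_sd``); 0.2
    cycles is a realistic replicate precision for qPCR CTs.
    """

    n_wells: int = 400
    empty_rate: float = 0.09
    doublet_rate: float = 0.035
    fpr_per_assay: dict | float = 0.005
    fn_rate: float = 0.0
    bulk_depth: int = 10000
    purity: float = 1.0
    ct_sd: float = 0.2
    control_ct_mean: float = 24.0
    assay_ct_mean: float = 26.0
    doublet_ct_shift: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("empty_rate", "doublet_rate", "fn_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0, 1]")
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")

    def fpr(self, assay: str) -> float:
        if isinstance(self.fpr_per_assay, dict):
            return float(self.fpr_per_assay.get(assay, 0.0))
        return float(self.fpr_per_assay)


def simulate_clone_tree(n_assays: int, n_loh: int, seed: int, *,
                        root: str = "disease", loh_assay: str = "disease",
                        time_points=("t1", "t2"), wt_max: float = 0.05) -> CloneTreeSpec:
    """Generate a random clone tree with ``n_assays`` assays and ``n_loh`` LOH events.

    The root clone carries only the disease-defining assay (heterozygous), or
    is wild type when ``root="wt"``. Every other clone is its parent plus
    exactly one event: each non-disease assay is gained (0->1) once on a
    uniformly chosen existing clone, then ``n_loh`` LOH events (1->2 or 1->0,
    equiprobable) are placed — on the disease-defining assay by default, or
    on a random heterozygous assay with ``loh_assay="random"``. Genotypes are
    kept distinct; an event budget that cannot be realised raises ValueError.

    Per-time-point prevalences are Dirichlet-distributed over clones with a
    per-clone floor of ``min(0.05, 0.8/n_clones)``, scaled to leave a small
    wild-type remainder (uniform on [0, ``wt_max``]).
    """
    if not 2 <= n_assays <= 12:
        raise ValueError("n_assays must be in [2, 12]")
    if not 0 <= n_loh <= n_assays:
        raise ValueError("n_loh must be in [0, n_assays]")
    if root not in ("disease", "wt"):
        raise ValueError("root must be 'disease' or 'wt'")
    if loh_assay not in ("disease", "random"):
        raise ValueError("loh_assay must be 'disease' or 'random'")

    rng = np.random.default_rng(seed)
    assays = [Assay("JAK2", True)] + [Assay(g) for g in GENE_POOL[: n_assays - 1]]

    clones: list[Clone] = []
    genotypes: set[tuple] = set()

    def add(parent_id, genotype) -> Clone:
        c = Clone(f"C{len(clones) + 1}", parent_id, tuple(genotype))
        clones.append(c)
        genotypes.add(c.genotype)
        return c

    if root == "disease":
        g0 = [0] * n_assays
        g0[0] = 1
        add(None, g0)
        gain_idx = list(range(1, n_assays))
    else:
        add(None, [0] * n_assays)
        gain_idx = list(range(n_assays))

    rng.shuffle(gain_idx)
    if root == "wt" and 0 in gain_idx:  # disease mutation is the earliest gain
        gain_idx.remove(0)
        gain_idx.insert(0, 0)
    for idx in gain_idx:
        parent = clones[rng.integers(len(clones))]
        g = list(parent.genotype)
        g[idx] = 1
        add(parent.id, g)

    for _ in range(n_loh):
        placed = False
        for _try in range(200):
            if loh_assay == "disease":
                idx = 0
            else:
                parent = clones[rng.integers(len(clones))]
                het = [i for i, v in enumerate(parent.genotype) if v == 1]
                if not het:
                    continue
                idx = int(rng.choice(het))
            if loh_assay == "disease":
                candidates = [c for c in clones if c.genotype[0] == 1]
                if not candidates:
                    break
                parent = candidates[rng.integers(len(candidates))]
            to_code = int(rng.choice([2, 0]))
            g = list(parent.genotype)
            g[idx] = to_code
            if tuple(g) in genotypes:
                continue
            add(parent.id, g)
            placed = True
            break
        if not placed:
            raise ValueError(
                f"impossible event budget: cannot place {n_loh} LOH events on "
                f"{n_assays} assays without duplicating a genotype"
            )

    n_clones = len(clones)
    floor = min(0.05, 0.8 / n_clones)
    prevalence = {}
    for tp in time_points:
        wt = float(rng.uniform(0.0, wt_max))
        raw = rng.dirichlet(np.ones(n_clones))
        p = (1.0 - wt) * (floor + (1.0 - n_clones * floor) * raw)
        prevalence[tp] = {c.id: float(v) for c, v in zip(clones, p)}

    return CloneTreeSpec(assays=assays, clones=clones, prevalence=prevalence)


def simulate_bulk(tree: CloneTreeSpec, time_point: str, config: SimulationConfig,
                  rng: np.random.Generator | None = None):
    """Bulk mutation table at one time point: binomial read counts per assay.

    Expected VAF per assay is ``purity * sum(prevalence * code / 2)`` (loci
    stay diploid under copy-neutral events); alt reads are drawn binomially
    at ``config.bulk_depth``. Returns a mutation-table DataFrame.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    evaf = tree.expected_vaf(time_point, config.purity)
    rows = []
    for i, assay in enumerate(tree.assays):
        depth = config.bulk_depth
        alt = int(rng.binomial(depth, evaf[i]))
        rows.append({
            "gene": assay.name,
            "chrom": f"chr{i + 1}",
            "pos": 1_000_000 + i,
            "ref": "A",
            "alt": "T",
            "vaf": alt / depth,
            "depth": depth,
            "cn_tumor": 2.0,
            "cn_normal": 2.0,
            "is_indel": False,
            "indel_len": 0,
        })
    return mutations_to_frame(rows)


def _code_to_signals(code: int):
    """(wt_amplified, mut_amplified) for a ternary genotype code."""
    return {0: (True, False), 1: (True, True), 2: (False, True)}[code]


def _make_well(well_id, status, clone_ids, tree_or_assays, config, rng,
               control_probes=DEFAULT_CONTROL_PROBES) -> Well:
    if isinstance(tree_or_assays, CloneTreeSpec):
        assay_names = [a.name for a in tree_or_assays.assays]
        genos = [tree_or_assays.genotype_of(cid) for cid in clone_ids]
    else:
        assay_names = list(tree_or_assays)
        genos = [tuple([0] * len(assay_names)) for _ in clone_ids]

    truth = {"status": status, "clone_ids": list(clone_ids), "genotype": None}
    reactions = {}
    controls = {}

    if status == "empty":
        for a in assay_names:
            reactions[a] = (ReactionSignal(False), ReactionSignal(False))
        for p in control_probes:
            controls[p] = ReactionSignal(False)
        return Well(well_id, reactions, controls, truth)

    # union of the drawn cells' channel signals
    wt_amp = [False] * len(assay_names)
    mut_amp = [False] * len(assay_names)
    union = [0] * len(assay_names)
    for g in genos:
        for i, code in enumerate(g):
            w, m = _code_to_signals(code)
            wt_amp[i] = wt_amp[i] or w
            mut_amp[i] = mut_amp[i] or m
    for i in range(len(assay_names)):
        union[i] = {(True, False): 0, (True, True): 1, (False, True): 2}[(wt_amp[i], mut_amp[i])]
    truth["genotype"] = union

    for i, a in enumerate(assay_names):
        m = mut_amp[i]
        if m and config.fn_rate > 0 and rng.random() < config.fn_rate:
            m = False  # allelic dropout of the mutant signal
        if not m and rng.random() < config.fpr(a):
            m = True  # false-positive mutant signal
        w = wt_amp[i]
        wt_sig = ReactionSignal(True, float(rng.normal(config.assay_ct_mean, config.ct_sd))) if w \
            else ReactionSignal(False)
        mut_sig = ReactionSignal(True, float(rng.normal(config.assay_ct_mean, config.ct_sd))) if m \
            else ReactionSignal(False)
        reactions[a] = (wt_sig, mut_sig)

    shift = config.doublet_ct_shift if status == "doublet" else 0.0
    for p in control_probes:
        controls[p] = ReactionSignal(True, float(rng.normal(config.control_ct_mean - shift, config.ct_sd)))
    return Well(well_id, reactions, controls, truth)


def simulate_plate(tree: CloneTreeSpec, time_point: str, config: SimulationConfig,
                   rng: np.random.Generator | None = None, plate_id: str = "plate") -> Plate:
    """Simulate one genotyping plate at a time point.

    Each well is independently empty (probability ``empty_rate``; no signal
    at all), a doublet (``doublet_rate``; two cells drawn from the clone
    prevalences, signal union per channel, control-probe CTs one doubling
    earlier), or a singlet. False-positive mutant signals are injected per
    assay at the configured rate. Truth labels ride along on every well.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ids, probs = tree.clone_ids_and_probs(time_point)
    assay_names = [a.name for a in tree.assays]
    wells = []
    for w in range(config.n_wells):
        r = rng.random()
        if r < config.empty_rate:
            status, drawn = "empty", []
        elif r < config.empty_rate + config.doublet_rate:
            status = "doublet"
            drawn = list(rng.choice(ids, size=2, p=probs))
        else:
            status = "singlet"
            drawn = [str(rng.choice(ids, p=probs))]
        wells.append(_make_well(f"{plate_id}_W{w + 1:04d}", status, drawn, tree, config, rng))
    return Plate(wells=wells, assays=assay_names, plate_id=plate_id, time_point=time_point)


def simulate_control_plate(fpr_per_assay, n_wells: int, seed: int, *,
                           assays=None, empty_rate: float = 0.0, doublet_rate: float = 0.0,
                           ct_sd: float = 0.2, plate_id: str = "K562") -> Plate:
    """Simulate a wild-type control-line (K562-style) calibration plate.

    Every cell is truly wild type at every assay; mutant signals appear only
    as false positives at the configured per-assay rates. Empty/doublet rates
    default to 0 (pure genotyping control) but can be set to emulate the
    sorting-calibration plates.
    """
    if assays is None:
        if isinstance(fpr_per_assay, dict):
            assays = list(fpr_per_assay)
        else:
            assays = ["ASSAY1", "ASSAY2"]
    config = SimulationConfig(
        n_wells=n_wells, empty_rate=empty_rate, doublet_rate=doublet_rate,
        fpr_per_assay=fpr_per_assay, ct_sd=ct_sd, seed=seed,
    )
    rng = np.random.default_rng(seed)
    wells = []
    for w in range(n_wells):
        r = rng.random()
        if r < empty_rate:
            status, drawn = "empty", []
        elif r < empty_rate + doublet_rate:
            status, drawn = "doublet", [WT_ID, WT_ID]
        else:
            status, drawn = "singlet", [WT_ID]
        wells.append(_make_well(f"{plate_id}_W{w + 1:04d}", status, drawn, assays, config, rng))
    return Plate(wells=wells, assays=list(assays), plate_id=plate_id)
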