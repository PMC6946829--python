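"""Maximum-likelihood subclone trees under a finite-sites event model.

Nodes carry ternary genotype vectors (0 wild type, 1 heterozygous, 2
homozygous mutant via copy-neutral LOH); edges carry event lists over the
alphabet {0->1 mutation gain, 1->2 LOH to homozygous mutant, 1->0 LOH
reversion to wild type}. The same assay may change repeatedly along the tree
(finite sites): recurrent LOH of the disease-defining mutation (homoplasy)
and reversion to wild type are first-class outcomes. 2->1 and 0->2 are not
single events — a homozygous mutant cannot revert in one step, and reaching
homozygosity requires mutation followed by LOH (0->2 therefore costs two
events on one edge).

The tree score is ``sum_cells log P(observed | assigned node genotype,
alpha, beta)`` minus an event-count prior (``event_weight`` per mutation
gain, default 1.0, and ``loh_weight`` per LOH event, default 0.9: a
copy-neutral LOH at an already-mutated locus is a more frequent event than
an independent recurrence of the identical point mutation, so among
otherwise equally parsimonious explanations the LOH one — including
reversion to wild type — is preferred). Because QC-passed
cells match their genotype exactly, the cell term is topology-independent
and the search reduces to weighted minimum-event (maximum-parsimony)
reconstruction over rooted node-labelled trees; the root is constrained to
be wild type or to carry only the disease-defining mutation.

``exhaustive_ml`` enumerates every rooted tree on <= 6 genotypes and is the
oracle for ``heuristic_ml_search`` (multi-restart subtree prune-regraft
hill climbing, deterministic given its seed).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "Event",
    "ErrorModel",
    "PhyloTree",
    "tree_log_likelihood",
    "exhaustive_ml",
    "heuristic_ml_search",
    "to_newick",
    "from_newick",
    "report_events",
    "FiniteSitesTreeML",
]

#: minimal legal event path per (from_code, to_code); None entries are illegal
_PATHS = {
    (0, 0): (), (1, 1): (), (2, 2): (),
    (0, 1): ((0, 1),),
    (1, 2): ((1, 2),),
    (1, 0): ((1, 0),),
    (0, 2): ((0, 1), (1, 2)),
}

GAIN, LOH_HOM, REVERSION = (0, 1), (1, 2), (1, 0)


def event_path(a: int, b: int):
    """Minimal legal event sequence taking code ``a`` to ``b`` (None if illegal)."""
    return _PATHS.get((int(a), int(b)))


@dataclass(frozen=True)
class Event:
    assay: str
    from_code: int
    to_code: int

    @property
    def kind(self) -> str:
        return {GAIN: "gain", LOH_HOM: "loh_homozygous", REVERSION: "loh_reversion"}[
            (self.from_code, self.to_code)
        ]


@dataclass
class ErrorModel:
    """Observation error and event prior of the finite-sites model.

    ``alpha`` is the per-assay false-positive probability (observing a mutant
    signal on a truly wild-type allele), either a scalar or an assay -> rate
    mapping as measured on the control cell line; ``beta`` is the
    false-negative (allelic dropout) probability, 0 by default because the
    genotyping design provides no positive controls to measure it.
    ``event_weight``/``loh_weight`` are the log-scale prior penalties per
    mutation gain and per LOH event; the LOH default (0.9) sits below the
    gain default (1.0) so that a reversion or recurrent LOH is preferred
    over positing the same point mutation arising twice independently.
    """

    alpha: float | dict = 0.0
    beta: float = 0.0
    event_weight: float = 1.0
    loh_weight: float = 0.9

    def __post_init__(self) -> None:
        rates = list(self.alpha.values()) if isinstance(self.alpha, dict) else [self.alpha]
        for v in rates + [self.beta]:
            if not 0.0 <= v <= 1.0:
                raise ValueError("error probabilities must be in [0, 1]")

    def alpha_for(self, assay) -> float:
        if isinstance(self.alpha, dict):
            return float(self.alpha.get(assay, 0.0))
        return float(self.alpha)

    def weight(self, from_code: int, to_code: int) -> float:
        return self.event_weight if (from_code, to_code) == GAIN else self.loh_weight


@dataclass
class PhyloTree:
    """Rooted node-labelled tree over subclone genotypes.

    Node 0 is the root; ``parent[i]`` is the parent index (None for the
    root). ``genotypes[i]`` is the ternary vector at node ``i`` and
    ``counts[i]`` the number of cells carrying it (0 for an unobserved
    root). Edge events are derived from the genotypes.
    """

    assays: list
    names: list
    genotypes: list
    parent: list
    counts: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = [0] * len(self.names)
        if self.genotypes and any(g is not None for g in self.genotypes):
            for i, p in enumerate(self.parent):
                if p is None:
                    continue
                for a, b in zip(self.genotypes[p], self.genotypes[i]):
                    if event_path(a, b) is None:
                        raise ValueError(f"illegal transition {a}->{b} on edge into node {self.names[i]}")

    def __len__(self) -> int:
        return len(self.names)

    def children(self, i: int) -> list:
        return [j for j, p in enumerate(self.parent) if p == i]

    def edge_events(self, i: int) -> list:
        """Events on the edge from ``parent[i]`` into node ``i``."""
        p = self.parent[i]
        if p is None:
            return []
        events = []
        for a_idx, (a, b) in enumerate(zip(self.genotypes[p], self.genotypes[i])):
            for step in event_path(a, b):
                events.append(Event(self.assays[a_idx], *step))
        return events

    def all_events(self) -> list:
        return [ev for i in range(len(self)) for ev in self.edge_events(i)]

    def branch_length(self, i: int) -> int:
        return len(self.edge_events(i))

    def total_events(self) -> int:
        return sum(self.branch_length(i) for i in range(len(self)))

    def to_dict(self) -> dict:
        return {
            "assays": list(self.assays),
            "names": list(self.names),
            "genotypes": [list(g) if g is not None else None for g in self.genotypes],
            "parent": list(self.parent),
            "counts": list(self.counts),
            "events": {
                self.names[i]: [[e.assay, e.from_code, e.to_code] for e in self.edge_events(i)]
                for i in range(len(self)) if self.parent[i] is not None
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PhyloTree":
        return cls(
            assays=list(d["assays"]),
            names=list(d["names"]),
            genotypes=[tuple(g) if g is not None else None for g in d["genotypes"]],
            parent=[p if p is None else int(p) for p in d["parent"]],
            counts=[int(c) for c in d.get("counts", [])],
        )


# ---------------------------------------------------------------------------
# likelihood

def _emission_logp(obs: int, true: int, alpha: float, beta: float) -> float:
    table = {
        0: {0: 1.0 - alpha, 1: alpha, 2: 0.0},
        1: {0: beta, 1: 1.0 - beta, 2: 0.0},
        2: {0: 0.0, 1: beta, 2: 1.0 - beta},
    }
    p = table[int(true)][int(obs)]
    return float(np.log(p)) if p > 0 else -np.inf


def _matrix_codes(matrix, assays) -> np.ndarray:
    if isinstance(matrix, pd.DataFrame):
        missing = [a for a in assays if a not in matrix.columns]
        if missing:
            raise ValueError(f"genotype matrix missing assays {missing}")
        return matrix[list(assays)].to_numpy(dtype=int)
    arr = np.asarray(matrix, dtype=int)
    if arr.shape[1] != len(assays):
        raise ValueError("genotype matrix width != number of assays")
    return arr


def tree_log_likelihood(tree: PhyloTree, matrix, model: ErrorModel) -> float:
    """Log-likelihood of a genotype matrix under a tree and error model.

    Each cell is assigned to the node maximizing its emission probability
    (its exact-match node whenever alpha < 0.5); a cell with zero probability
    under every node raises (matrix/tree mismatch). The event-count prior is
    subtracted: ``sum_events weight(event)``.
    """
    codes = _matrix_codes(matrix, tree.assays)
    alphas = np.array([model.alpha_for(a) for a in tree.assays])
    node_geno = [np.asarray(g, dtype=int) for g in tree.genotypes]

    total = 0.0
    for row in codes:
        best = -np.inf
        for g in node_geno:
            lp = 0.0
            for obs, true, al in zip(row, g, alphas):
                lp += _emission_logp(obs, true, al, model.beta)
                if lp == -np.inf:
                    break
            best = max(best, lp)
        if best == -np.inf:
            raise ValueError(f"cell {row.tolist()} assignable to no tree node")
        total += best
    penalty = sum(model.weight(e.from_code, e.to_code) for e in tree.all_events())
    return total - penalty


# ---------------------------------------------------------------------------
# search machinery

def _normalise_subclones(subclones):
    """-> list of (genotype tuple, count) in canonical order (desc count, lex)."""
    if isinstance(subclones, pd.DataFrame):
        df = subclones[subclones["passed"]] if "passed" in subclones.columns else subclones
        items = [(tuple(g), int(n)) for g, n in zip(df["genotype"], df["n_cells"])]
    else:
        items = []
        for s in subclones:
            if isinstance(s, tuple) and len(s) == 2 and isinstance(s[1], (int, np.integer)) \
                    and not isinstance(s[0], (int, np.integer)):
                items.append((tuple(s[0]), int(s[1])))
            else:
                items.append((tuple(s), 1))
    if len(set(g for g, _ in items)) != len(items):
        raise ValueError("duplicate subclone genotypes")
    return sorted(items, key=lambda t: (-t[1], t[0]))


def _cost_matrices(genotypes, model: ErrorModel):
    """Weighted cost and unweighted event count per directed node pair (inf = illegal)."""
    n = len(genotypes)
    cost = np.full((n, n), np.inf)
    nev = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            c, k, ok = 0.0, 0, True
            for a, b in zip(genotypes[i], genotypes[j]):
                path = event_path(a, b)
                if path is None:
                    ok = False
                    break
                for step in path:
                    c += model.weight(*step)
                    k += 1
            if ok:
                cost[i, j] = c
                nev[i, j] = k
    return cost, nev


def _is_acyclic(parent, n) -> bool:
    for start in range(1, n):
        seen = set()
        i = start
        while i != 0:
            if i in seen:
                return False
            seen.add(i)
            i = parent[i]
    return True


def _vector_score(parent, cost, nev):
    c = k = 0.0
    for i in range(1, len(parent) + 1):
        e = cost[parent[i - 1], i]
        if not np.isfinite(e):
            return None
        c += e
        k += nev[parent[i - 1], i]
    return c, k


def _build_tree(assays, root_genotype, root_observed, items, parent_vec, root_count=0) -> PhyloTree:
    names = ["root"] + [f"G{i + 1}" for i in range(len(items))]
    genotypes = [tuple(root_genotype)] + [g for g, _ in items]
    counts = [root_count] + [n for _, n in items]
    parent = [None] + [int(p) for p in parent_vec]
    return PhyloTree(assays=list(assays), names=names, genotypes=genotypes,
                     parent=parent, counts=counts)


def _root_candidates(items, n_assays, disease_assay):
    """(root_genotype, observed_flag, count) candidates honouring the root constraint."""
    wt = tuple([0] * n_assays)
    disease = tuple(1 if i == disease_assay else 0 for i in range(n_assays))
    observed = {g: n for g, n in items}
    if wt in observed:
        return [(wt, True, observed[wt])]
    if disease in observed:
        return [(disease, True, observed[disease])]
    return [(disease, False, 0), (wt, False, 0)]


def _search_one_root(items, root_genotype, model, mode, rng=None, n_restarts=20):
    """Optimise the parent vector for a fixed root; returns (cost, nev, parents)."""
    genotypes = [tuple(root_genotype)] + [g for g, _ in items]
    cost, nev = _cost_matrices(genotypes, model)
    K = len(items)
    if K == 0:
        return (0.0, 0, ())

    best = None  # (cost, events, parent tuple)

    def consider(parent):
        res = _vector_score(parent, cost, nev)
        if res is None:
            return
        cand = (res[0], res[1], tuple(parent))
        nonlocal best
        if best is None or cand < best:
            best = cand

    if mode == "exhaustive":
        for parent in itertools.product(range(K + 1), repeat=K):
            if any(parent[i] == i + 1 for i in range(K)):
                continue
            if not _is_acyclic([0] + list(parent), K + 1):
                continue
            consider(parent)
    else:
        starts = [[0] * K]  # star
        chain = [0] + list(range(1, K))
        starts.append(chain)
        for _ in range(max(0, n_restarts - 2)):
            order = rng.permutation(K) + 1
            parent = [0] * K
            pool = [0]
            for node in order:
                legal = [p for p in pool if np.isfinite(cost[p, node])]
                parent[node - 1] = int(rng.choice(legal)) if legal else 0
                pool.append(int(node))
            starts.append(parent)

        for start in starts:
            parent = list(start)
            if _vector_score(parent, cost, nev) is None:
                parent = [0] * K
            while True:
                cur = _vector_score(parent, cost, nev)
                best_move = None

                def consider_trial(trial):
                    nonlocal best_move
                    res = _vector_score(trial, cost, nev)
                    if res is None:
                        return
                    cand = (res[0], res[1], tuple(trial))
                    if cand < (cur[0], cur[1], tuple(parent)) and (best_move is None or cand < best_move):
                        best_move = cand

                # edge-flip (local re-rooting): reverse the edge parent[i] -> i
                for i in range(1, K + 1):
                    p = parent[i - 1]
                    if p == 0:
                        continue
                    trial = list(parent)
                    trial[i - 1] = parent[p - 1]
                    trial[p - 1] = i
                    consider_trial(trial)

                for i in range(1, K + 1):
                    # nodes in i's subtree cannot become i's parent
                    blocked = {i}
                    changed = True
                    while changed:
                        changed = False
                        for j in range(1, K + 1):
                            if j not in blocked and parent[j - 1] in blocked:
                                blocked.add(j)
                                changed = True
                    for p in range(K + 1):
                        if p in blocked or p == parent[i - 1]:
                            continue
                        if not np.isfinite(cost[p, i]):
                            continue
                        trial = list(parent)
                        trial[i - 1] = p
                        consider_trial(trial)
                if best_move is None:
                    break
                parent = list(best_move[2])
            consider(parent)

    if best is None:
        raise ValueError("no legal tree exists for the given genotypes and root")
    return best


def _ml_tree(subclones, model, mode, disease_assay=0, seed=0, n_restarts=20,
             assays=None) -> PhyloTree:
    items = _normalise_subclones(subclones)
    if not items:
        raise ValueError("no subclones given")
    n_assays = len(items[0][0])
    if assays is None:
        if isinstance(subclones, pd.DataFrame) and subclones.attrs.get("assays"):
            assays = subclones.attrs["assays"]
        else:
            assays = [f"A{i + 1}" for i in range(n_assays)]
    if mode == "exhaustive" and len(items) > 6:
        raise ValueError("exhaustive search refuses more than 6 genotypes")

    model = model or ErrorModel()
    best = None
    for root_genotype, observed, root_count in _root_candidates(items, n_assays, disease_assay):
        others = [it for it in items if it[0] != root_genotype]
        rng = np.random.default_rng(seed)
        res = _search_one_root(others, root_genotype, model, mode, rng=rng, n_restarts=n_restarts)
        cand = (res[0], res[1], 0 if observed else 1, res[2], root_genotype, observed, root_count, others)
        if best is None or cand[:4] < best[:4]:
            best = cand
    _, _, _, parent_vec, root_genotype, observed, root_count, others = best
    return _build_tree(assays, root_genotype, observed, others, parent_vec, root_count)


def exhaustive_ml(subclones, model: ErrorModel | None = None, *, disease_assay: int = 0,
                  assays=None) -> PhyloTree:
    """Globally optimal tree by enumeration of all rooted node-labelled trees.

    Refuses more than 6 genotypes (combinatorial guard). Ties are broken by
    fewer total events, then by the lexicographically smallest parent vector
    over the canonical genotype order.
    """
    return _ml_tree(subclones, model, "exhaustive", disease_assay=disease_assay, assays=assays)


def heuristic_ml_search(subclones, model: ErrorModel | None = None, *, n_restarts: int = 20,
                        seed: int = 0, disease_assay: int = 0, assays=None) -> PhyloTree:
    """Multi-restart hill climbing over tree space.

    Moves are subtree prune-regraft (reattach one node's subtree under a
    different parent) and local re-rooting (reverse one edge). Restart 0 is
    the star topology and restart 1 a count-ordered chain (so
    the result is never worse than either baseline); remaining restarts start
    from random legal trees. Deterministic given ``seed``.
    """
    if len(_normalise_subclones(subclones)) < 2:
        raise ValueError("need at least 2 genotypes")
    return _ml_tree(subclones, model, "heuristic", disease_assay=disease_assay,
                    seed=seed, n_restarts=n_restarts, assays=assays)


# ---------------------------------------------------------------------------
# serialisation & reporting

def to_newick(tree: PhyloTree) -> str:
    """Newick string: node labels = genotype ids, branch lengths = event counts."""
    def render(i: int) -> str:
        kids = tree.children(i)
        label = tree.names[i]
        inner = f"({','.join(render(j) for j in kids)})" if kids else ""
        if tree.parent[i] is None:
            return f"{inner}{label}"
        return f"{inner}{label}:{tree.branch_length(i)}"

    return render(0) + ";"


def from_newick(newick: str) -> PhyloTree:
    """Parse a Newick string back into a (topology-only) PhyloTree.

    Genotypes are not encoded in Newick; the returned tree carries None
    genotypes but full names, parent structure and branch lengths (kept in
    ``attrs``-free form via the parsed edge lengths, which equal the event
    counts the writer emitted).
    """
    t = dendropy.Tree.get(data=newick, schema="newick", suppress_internal_node_taxa=False)
    nodes = list(t.preorder_node_iter())

    def label(nd):
        return nd.taxon.label if nd.taxon is not None else nd.label

    names = [label(nd) for nd in nodes]
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = [None if nd.parent_node is None else index[id(nd.parent_node)] for nd in nodes]
    tree = PhyloTree(assays=[], names=names, genotypes=[None] * len(nodes), parent=parent)
    tree.edge_lengths = [None if nd.edge.length is None else float(nd.edge.length) for nd in nodes]
    return tree


def report_events(tree: PhyloTree) -> pd.DataFrame:
    """Per-assay event census with a homoplasy flag.

    Columns: counts of gains (0->1), homozygous LOH (1->2) and reversions
    (1->0), their total, and ``homoplasy`` — True when the assay changes on
    two or more edges (parallel/convergent evolution).
    """
    rows = {a: {"n_gain": 0, "n_loh_homozygous": 0, "n_loh_reversion": 0} for a in tree.assays}
    for ev in tree.all_events():
        key = {GAIN: "n_gain", LOH_HOM: "n_loh_homozygous", REVERSION: "n_loh_reversion"}[
            (ev.from_code, ev.to_code)
        ]
        rows[ev.assay][key] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "assay"
    df["n_events"] = df.sum(axis=1)
    df["homoplasy"] = df["n_events"] >= 2
    return df


class FiniteSitesTreeML(BaseEstimator):
    """Finite-sites ML tree reconstruction, scikit-learn style.

    ``fit(X)`` accepts a subclone table (the passing rows of
    :func:`~mfclone.subclones.filter_subclones`) or a list of genotypes.
    ``method="auto"`` uses exhaustive enumeration up to 6 genotypes and the
    heuristic search above that.

    Attributes
    ----------
    tree_ : fitted :class:`PhyloTree`.
    events_ : per-assay event census (:func:`report_events`).
    log_likelihood_ : score of ``tree_`` when a genotype matrix is supplied.
    """

    def __init__(self, method: str = "auto", alpha=0.0, beta: float = 0.0,
                 event_weight: float = 1.0, loh_weight: float = 0.9,
                 n_restarts: int = 20, disease_assay: int = 0, random_state: int = 0):
        self.method = method
        self.alpha = alpha
        self.beta = beta
        self.event_weight = event_weight
        self.loh_weight = loh_weight
        self.n_restarts = n_restarts
        self.disease_assay = disease_assay
        self.random_state = random_state

    def _model(self) -> ErrorModel:
        return ErrorModel(alpha=self.alpha, beta=self.beta,
                          event_weight=self.event_weight, loh_weight=self.loh_weight)

    def fit(self, X, y=None, matrix=None, assays=None):
        model = self._model()
        n = len(_normalise_subclones(X))
        method = self.method
        if method == "auto":
            method = "exhaustive" if n <= 6 else "heuristic"
        if method == "exhaustive":
            self.tree_ = exhaustive_ml(X, model, disease_assay=self.disease_assay, assays=assays)
        else:
            self.tree_ = heuristic_ml_search(
                X, model, n_restarts=self.n_restarts, seed=self.random_state,
                disease_assay=self.disease_assay, assays=assays,
            )
        self.events_ = report_events(self.tree_)
        if matrix is not None:
            self.log_likelihood_ = tree_log_likelihood(self.tree_, matrix, model)
        return self
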