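"""Bulk-DNA clonal analysis.

Cancer cell fractions (CCF) from VAF, purity and local copy number; the
copy-number-adjusted VAFs used as clustering input; a 1-D binomial-mixture
clustering of adjusted VAFs with BIC model selection; and longitudinal
gain/loss accounting of mutations between time points.

The CCF of a mutation observed at variant allele frequency ``VAF`` in a bulk
sample of tumor purity ``p`` with local tumor copy number ``CNt`` and local
normal copy number ``CNn`` is

    CCF = VAF * (1/p) * (p * CNt + CNn * (1 - p))

so that a clonal heterozygous mutation in a pure diploid sample (VAF 0.5,
p 1, CNt = CNn = 2) has CCF 1. Adjusted VAF = CCF / 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "MutationCall",
    "TimepointSample",
    "compute_ccf",
    "adjusted_vaf",
    "filter_for_clustering",
    "BinomialMixtureVAFClusterer",
    "cluster_vafs",
    "track_mutations",
    "TrackResult",
]

#: column order used whenever mutation tables are materialised as DataFrames
MUTATION_COLUMNS = [
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "vaf",
    "depth",
    "cn_tumor",
    "cn_normal",
    "is_indel",
    "indel_len",
]


@dataclass
class MutationCall:
    """One somatic variant at one time point.

    Coordinates are 1-based, fully closed (VCF convention). ``cn_tumor`` and
    ``cn_normal`` are the local copy numbers at the locus; copy-neutral LOH
    keeps both at 2.
    """

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    depth: int
    cn_tumor: float = 2.0
    cn_normal: float = 2.0
    is_indel: bool = False
    indel_len: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.cn_tumor < 0 or self.cn_normal < 0:
            raise ValueError("copy numbers must be >= 0")

    @property
    def key(self) -> tuple:
        """Identity key (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)


def mutations_to_frame(mutations) -> pd.DataFrame:
    """Materialise a list of :class:`MutationCall` (or a DataFrame) as a DataFrame."""
    if isinstance(mutations, pd.DataFrame):
        missing = [c for c in ("chrom", "pos", "ref", "alt", "vaf", "depth") if c not in mutations.columns]
        if missing:
            raise ValueError(f"mutation table missing columns: {missing}")
        df = mutations.copy()
        for col, default in (("gene", ""), ("cn_tumor", 2.0), ("cn_normal", 2.0),
                             ("is_indel", False), ("indel_len", 0)):
            if col not in df.columns:
                df[col] = default
        return df[MUTATION_COLUMNS]
    rows = [m if isinstance(m, dict) else {c: getattr(m, c) for c in MUTATION_COLUMNS}
            for m in mutations]
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


@dataclass
class TimepointSample:
    """A patient sample at one time point: purity plus its mutation calls."""

    patient: str
    time_point: str
    purity: float
    mutations: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=MUTATION_COLUMNS))

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        self.mutations = mutations_to_frame(self.mutations)


def compute_ccf(vaf, purity, cn_tumor=2.0, cn_normal=2.0):
    """Cancer cell fraction: ``VAF * (1/p) * (p*CNt + CNn*(1-p))``.

    Accepts scalars or arrays. Values above 1 are returned as-is (they flag a
    wrong copy-number context, e.g. unrecognised copy-neutral LOH); callers
    may use :func:`flag_suprafractional` semantics downstream.
    """
    purity = np.asarray(purity, dtype=float)
    if np.any(purity <= 0):
        raise ValueError("purity must be > 0")
    vaf = np.asarray(vaf, dtype=float)
    ccf = vaf * (1.0 / purity) * (purity * np.asarray(cn_tumor, float) + np.asarray(cn_normal, float) * (1.0 - purity))
    return float(ccf) if ccf.ndim == 0 else ccf


def adjusted_vaf(ccf):
    """Copy-number-adjusted VAF: CCF divided by 2."""
    ccf = np.asarray(ccf, dtype=float)
    if np.any(ccf < 0):
        raise ValueError("ccf must be >= 0")
    out = ccf / 2.0
    return float(out) if out.ndim == 0 else out


def filter_for_clustering(baseline: TimepointSample, followup: TimepointSample,
                          min_depth: int = 25, max_indel_len: int = 2) -> pd.DataFrame:
    """Select mutations eligible as clustering input across two time points.

    A mutation (matched across time points by chrom/pos/ref/alt) is retained
    when sequencing depth is >= ``min_depth`` at *both* time points and, for
    indels, the indel length is <= ``max_indel_len`` bp (3 bp and longer are
    excluded). Mutations observed at only one time point are retained when
    they pass wherever observed, and flagged as unmatched.

    Returns a DataFrame with one row per distinct mutation key and columns
    ``retained`` (bool), ``matched`` (bool) and ``reason``.
    """
    base = mutations_to_frame(baseline.mutations)
    foll = mutations_to_frame(followup.mutations)
    key_cols = ["chrom", "pos", "ref", "alt"]
    merged = base.merge(foll, on=key_cols, how="outer", suffixes=("_base", "_follow"), indicator=True)

    rows = []
    for _, r in merged.iterrows():
        matched = r["_merge"] == "both"
        depths = []
        indel_bad = False
        for side in ("base", "follow"):
            d = r.get(f"depth_{side}")
            if pd.notna(d):
                depths.append(float(d))
                if bool(r.get(f"is_indel_{side}", False)) and int(r.get(f"indel_len_{side}", 0)) > max_indel_len:
                    indel_bad = True
        reason = ""
        retained = True
        if any(d < min_depth for d in depths):
            retained, reason = False, f"depth<{min_depth}"
        elif indel_bad:
            retained, reason = False, f"indel>={max_indel_len + 1}bp"
        gene = r.get("gene_base")
        if pd.isna(gene):
            gene = r.get("gene_follow", "")
        rows.append({
            "gene": gene,
            **{c: r[c] for c in key_cols},
            "retained": retained,
            "matched": matched,
            "reason": reason if reason else ("unmatched" if not matched else "pass"),
        })
    out = pd.DataFrame(rows)
    return out.sort_values(key_cols).reset_index(drop=True)


class BinomialMixtureVAFClusterer(ClusterMixin, BaseEstimator):
    """1-D binomial-mixture clustering of (adjusted) VAFs.

    Each mutation i contributes alt-read count ``k_i = round(vaf_i * depth_i)``
    out of ``depth_i`` trials; a K-component binomial mixture is fitted by EM
    and K is selected by BIC over ``1..max_clusters``. Cluster labels are
    canonicalised by decreasing component success probability, so labels are
    invariant to input order.

    Parameters
    ----------
    max_clusters : largest number of mixture components considered.
    n_init : EM restarts per K (quantile-anchored starts with seeded jitter).
    max_iter, tol : EM stopping rule.
    random_state : seed; fitting is deterministic given it.

    Attributes
    ----------
    labels_ : cluster index per mutation.
    n_clusters_ : selected number of components.
    component_probs_ : success probability (mean VAF) per component, decreasing.
    weights_ : mixture weights per component.
    bic_ : BIC of the selected model.
    """

    def __init__(self, max_clusters: int = 6, n_init: int = 4, max_iter: int = 500,
                 tol: float = 1e-8, random_state: int | None = 0):
        self.max_clusters = max_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    @staticmethod
    def _loglik_matrix(k, n, probs):
        p = np.clip(probs, 1e-9, 1 - 1e-9)
        return binom.logpmf(k[:, None], n[:, None], p[None, :])

    def _em(self, k, n, n_comp, p_init, w_init):
        probs, weights = p_init.copy(), w_init.copy()
        ll_old = -np.inf
        for _ in range(self.max_iter):
            log_resp = self._loglik_matrix(k, n, probs) + np.log(np.clip(weights, 1e-12, None))
            norm = np.logaddexp.reduce(log_resp, axis=1)
            ll = float(norm.sum())
            resp = np.exp(log_resp - norm[:, None])
            weights = resp.mean(axis=0)
            denom = resp.T @ n
            probs = np.where(denom > 0, (resp.T @ k) / np.clip(denom, 1e-12, None), probs)
            if abs(ll - ll_old) < self.tol:
                break
            ll_old = ll
        return probs, weights, ll

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): columns [vaf, depth]")
        if X.shape[0] < 1:
            raise ValueError("need at least one mutation")
        vaf, depth = X[:, 0], X[:, 1]
        k = np.round(vaf * depth)
        n = np.asarray(depth, dtype=float)
        n_obs = len(k)
        rng = np.random.default_rng(self.random_state)

        best = None  # (bic, n_comp, probs, weights, ll)
        k_max = min(self.max_clusters, n_obs)
        if np.allclose(vaf, vaf[0]):
            k_max = 1
        for n_comp in range(1, k_max + 1):
            anchors = np.quantile(vaf, np.linspace(0.1, 0.9, n_comp))
            for init in range(self.n_init if n_comp > 1 else 1):
                jitter = rng.normal(0, 0.02, size=n_comp) if init else 0.0
                p0 = np.clip(anchors + jitter, 1e-4, 1 - 1e-4)
                w0 = np.full(n_comp, 1.0 / n_comp)
                probs, weights, ll = self._em(k, n, n_comp, p0, w0)
                n_params = 2 * n_comp - 1
                bic = -2.0 * ll + n_params * np.log(n_obs)
                cand = (bic, n_comp, probs, weights, ll)
                if best is None or bic < best[0] - 1e-9:
                    best = cand

        bic, n_comp, probs, weights, ll = best
        order = np.argsort(-probs)
        probs, weights = probs[order], weights[order]
        log_resp = self._loglik_matrix(k, n, probs) + np.log(np.clip(weights, 1e-12, None))
        self.labels_ = np.argmax(log_resp, axis=1)
        self.n_clusters_ = int(len(np.unique(self.labels_)))
        self.component_probs_ = probs
        self.weights_ = weights
        self.bic_ = float(bic)
        self.log_likelihood_ = float(ll)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_vafs(adjusted_vafs, depths, max_clusters: int = 6, seed: int = 0) -> np.ndarray:
    """Cluster adjusted VAFs (with depths) by binomial mixture; returns labels.

    Thin wrapper over :class:`BinomialMixtureVAFClusterer`.
    """
    vafs = np.asarray(adjusted_vafs, dtype=float)
    if vafs.size == 1:
        return np.zeros(1, dtype=int)
    X = np.column_stack([vafs, np.asarray(depths, dtype=float)])
    return BinomialMixtureVAFClusterer(max_clusters=max_clusters, random_state=seed).fit_predict(X)


@dataclass
class TrackResult:
    """Gain/loss accounting between a baseline and a follow-up mutation set."""

    n_retained: int
    n_lost: int
    n_gained: int
    retained: set = field(default_factory=set)
    lost: set = field(default_factory=set)
    gained: set = field(default_factory=set)

    def __iter__(self):
        return iter((self.n_retained, self.n_lost, self.n_gained))


def track_mutations(baseline, followup, detect_vaf: float = 0.05) -> TrackResult:
    """Count mutations retained, lost and gained between two time points.

    A mutation is "present" at a time point when its VAF is >= ``detect_vaf``
    (default 0.05, the whole-exome selection floor; for ultra-deep targeted
    data pass e.g. 0.001). Sets are keyed by (chrom, pos, ref, alt).
    """
    def present(muts):
        df = mutations_to_frame(muts)
        keep = df["vaf"] >= detect_vaf
        return set(map(tuple, df.loc[keep, ["chrom", "pos", "ref", "alt"]].itertuples(index=False)))

    b, f = present(baseline), present(followup)
    retained, lost, gained = b & f, b - f, f - b
    return TrackResult(len(retained), len(lost), len(gained), retained, lost, gained)
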