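"""Design calculations: subclone detection power and bulk/single-cell concordance.

With ``n_sorted`` cells sorted and a fraction ``loss_rate`` lost to QC, a
subclone at frequency ``f`` contributes ``n_sorted * (1 - loss_rate) * f``
informative cells in expectation (400 sorted cells, 10% loss, 2% frequency:
7.2, i.e. ~7 cells). Detection power is the exact binomial tail probability
of observing at least ``min_cells`` such cells — the FDR minimum from
:func:`mfclone.subclones.min_cells_for_fdr` is the natural choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PowerSpec",
    "expected_subclone_cells",
    "detection_power",
    "bulk_sc_concordance",
]


@dataclass
class PowerSpec:
    n_sorted: int
    loss_rate: float
    subclone_freq: float
    min_cells: int

    def __post_init__(self) -> None:
        if self.n_sorted < 1:
            raise ValueError("n_sorted must be >= 1")
        for name in ("loss_rate", "subclone_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_cells < 0:
            raise ValueError("min_cells must be >= 0")


def expected_subclone_cells(n_sorted: int, loss_rate: float, subclone_freq: float):
    """Expected informative cells from a subclone: real value and nearest integer."""
    expected = n_sorted * (1.0 - loss_rate) * subclone_freq
    return expected, int(round(expected))


def detection_power(spec: PowerSpec) -> float:
    """P(X >= min_cells), X ~ Binomial(round(n_sorted*(1-loss)), subclone_freq).

    Exact binomial evaluation — no normal approximation, since the expected
    count is small (a handful of cells).
    """
    n = int(round(spec.n_sorted * (1.0 - spec.loss_rate)))
    if spec.min_cells == 0:
        return 1.0
    if n == 0:
        return 0.0
    return float(stats.binom.sf(spec.min_cells - 1, n, spec.subclone_freq))


def bulk_sc_concordance(bulk_vafs, sc_burdens) -> float:
    """Squared Pearson correlation between bulk VAFs and single-cell burdens.

    Pairs are pooled across mutations and samples, as in a scatter
    comparison of the two measurements. Requires >= 3 finite pairs and
    nonzero variance on both sides; note r^2 is sign-blind.
    """
    x = np.asarray(bulk_vafs, dtype=float)
    y = np.asarray(sc_burdens, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1-D lists required")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)
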