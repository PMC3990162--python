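"""Validation-arm statistics: relative copy number from Ct tables, the
Kruskal-Wallis group comparison, and a two-sided Fisher's exact test.

The Fisher p-value uses the point-probability convention: the sum of
hypergeometric probabilities of every margin-consistent table as or less
probable than the observed one (probabilities compared with relative
tolerance 1e-12). Amplification efficiency in the ddCt model is fixed at 2.0
per cycle; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtRecord",
    "ContingencyTable2x2",
    "delta_delta_ct",
    "relative_quantity_table",
    "kruskal_wallis",
    "fisher_exact_2x2",
]


@dataclass(frozen=True)
class CtRecord:
    """One replicate's target and reference Ct for a sample/gene pair."""

    sample_id: str
    gene: str
    ct_target: float
    ct_reference: float
    replicate: int = 1

    def __post_init__(self) -> None:
        for name, ct in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not 0.0 < ct < 45.0:
                raise ValueError(f"{name} {ct} outside the plausible (0, 45) cycle range")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a,b / c,d with rows = groups and columns = exposure yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")


def _mean_delta_ct(records: Sequence[CtRecord]) -> float:
    """Average target and reference Ct over replicates, then difference."""
    return float(np.mean([r.ct_target for r in records]) - np.mean([r.ct_reference for r in records]))


def delta_delta_ct(
    record: CtRecord | Sequence[CtRecord],
    calibrator: CtRecord | Sequence[CtRecord],
) -> float:
    """Relative quantity 2**(-ddCt) of a sample against its calibrator.

    Accepts single records or replicate lists (replicates are averaged on the
    Ct scale before differencing). The calibrator must be for the same gene.
    """
    recs = [record] if isinstance(record, CtRecord) else list(record)
    cals = [calibrator] if isinstance(calibrator, CtRecord) else list(calibrator)
    if not recs or not cals:
        raise ValueError("need at least one replicate on each side")
    genes = {r.gene for r in recs} | {c.gene for c in cals}
    if len(genes) != 1:
        raise ValueError(f"gene mismatch between sample and calibrator: {sorted(genes)}")
    ddct = _mean_delta_ct(recs) - _mean_delta_ct(cals)
    return float(2.0 ** (-ddct))


def relative_quantity_table(
    records: Sequence[CtRecord], calibrator_sample: str
) -> pd.DataFrame:
    """Per (sample, gene) fold quantities relative to the calibrator sample."""
    by_key: dict[tuple[str, str], list[CtRecord]] = {}
    for r in records:
        by_key.setdefault((r.sample_id, r.gene), []).append(r)
    calibrators = {
        gene: recs
        for (sid, gene), recs in by_key.items()
        if sid == calibrator_sample
    }
    if not calibrators:
        raise ValueError(f"no records for calibrator sample {calibrator_sample!r}")
    rows = []
    for (sid, gene), recs in sorted(by_key.items()):
        if gene not in calibrators:
            raise ValueError(f"no calibrator records for gene {gene!r}")
        rows.append(
            {
                "sample_id": sid,
                "gene": gene,
                "n_replicates": len(recs),
                "fold": delta_delta_ct(recs, calibrators[gene]),
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "gene", "n_replicates", "fold"])


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value (k-1 df).

    All observations identical yields H = 0, p = 1 (the tie correction is
    degenerate there and is defined by convention).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    if sum(len(a) for a in arrays) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p by the point-probability method.

    Sums hypergeometric probabilities over all tables with the observed
    margins whose probability is <= the observed table's (relative tolerance
    1e-12). A zero margin gives p = 1 by convention.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        return 1.0
    k_min = max(0, row1 + col1 - n)
    k_max = min(row1, col1)
    ks = np.arange(k_min, k_max + 1)
    pmf = stats.hypergeom.pmf(ks, n, row1, col1)
    p_obs = pmf[a - k_min]
    total = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    return min(total, 1.0)
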