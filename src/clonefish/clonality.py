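"""Subclone tabulation and per-sample clonal-heterogeneity statistics.

The clonal composition of one sample is the empirical distribution of
subclone codes over its hyperdiploid blasts.  Heterogeneity is summarised
two ways: the Shannon entropy H = −Σ P_i log2 P_i of the clone-frequency
distribution (in bits), and the percentage of the major clone (PMC) — the
frequency of the most abundant subclone.  Low PMC and high entropy both
indicate a heterogeneous, chromosomally unstable sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .core import DEFAULT_PANEL, ChromosomePanel, SubcloneCode

__all__ = [
    "ClonalDistribution",
    "TrisomyProfile",
    "tabulate_clones",
    "shannon_entropy",
    "gain_rates",
    "combined_trisomy_fraction",
    "compare_groups",
    "sample_statistics",
]

Codes = Sequence[SubcloneCode]


def _as_codes(cells: Iterable[Union[SubcloneCode, str]]) -> List[SubcloneCode]:
    out = []
    for c in cells:
        out.append(c if isinstance(c, SubcloneCode) else SubcloneCode.from_string(str(c)))
    return out


@dataclass
class ClonalDistribution:
    """Subclone code → cell count, with derived frequencies, PMC and entropy.

    ``total`` allows frequencies to stay relative to a larger denominator
    (e.g. all blasts before cutoff filtering); by default it is the sum of
    the stored counts.
    """

    counts: Dict[SubcloneCode, int]
    panel: ChromosomePanel = DEFAULT_PANEL
    total: Optional[int] = None
    major_tie: bool = field(default=False, init=False)

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("empty clonal distribution")
        if any(c <= 0 for c in self.counts.values()):
            raise ValueError("clone counts must be positive")
        if self.total is None:
            self.total = sum(self.counts.values())
        maxc = max(self.counts.values())
        ties = [code for code, c in self.counts.items() if c == maxc]
        self.major_tie = len(ties) > 1

    @property
    def n(self) -> int:
        return int(self.total)

    @property
    def n_clones(self) -> int:
        return len(self.counts)

    @property
    def frequencies(self) -> Dict[SubcloneCode, float]:
        return {code: c / self.n for code, c in self.counts.items()}

    @property
    def major_clone(self) -> SubcloneCode:
        """Most abundant subclone; ties broken by lexicographically smallest
        string code (``major_tie`` flags when that happened)."""
        maxc = max(self.counts.values())
        return min(
            (code for code, c in self.counts.items() if c == maxc), key=str
        )

    @property
    def pmc(self) -> float:
        """Percentage of the major clone (0–100)."""
        return 100.0 * self.counts[self.major_clone] / self.n

    @property
    def entropy_bits(self) -> float:
        return shannon_entropy(self)

    def top(self, k: int, min_frequency: float = 0.0) -> List[SubcloneCode]:
        """Top-k codes by frequency (ties by code string, stable).

        ``min_frequency`` drops codes below that blast fraction first, so
        "major clone" membership can exclude minor noise-derived clones.
        """
        eligible = [c for c in self.counts if self.counts[c] / self.n >= min_frequency]
        return sorted(eligible, key=lambda c: (-self.counts[c], str(c)))[:k]


def tabulate_clones(
    cells: Iterable[Union[SubcloneCode, str]],
    panel: ChromosomePanel = DEFAULT_PANEL,
) -> ClonalDistribution:
    """Count blasts by exact subclone code."""
    codes = _as_codes(cells)
    if not codes:
        raise ValueError("no blasts to tabulate")
    counts: Dict[SubcloneCode, int] = {}
    for code in codes:
        counts[code] = counts.get(code, 0) + 1
    return ClonalDistribution(counts=counts, panel=panel)


def shannon_entropy(dist: Union[ClonalDistribution, Sequence[float]]) -> float:
    """Shannon entropy H = −Σ P_i log2 P_i in bits, with 0·log 0 ≡ 0."""
    if isinstance(dist, ClonalDistribution):
        p = np.array([c for c in dist.counts.values()], dtype=float)
        p /= p.sum()  # entropy is over the clone distribution itself
    else:
        p = np.asarray(dist, dtype=float)
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("probabilities must sum to 1")
    return float(stats.entropy(p, base=2))


@dataclass
class TrisomyProfile:
    """Per-chromosome gain fractions (%) and total-gains histogram.

    ``table`` columns: chromosome, pct_gain, pct_trisomy, pct_tetrasomy,
    pct_higher (gain >= 3).  ``total_gains_hist`` maps the number of gained
    chromosomes per cell to its blast fraction (%).
    """

    table: pd.DataFrame
    total_gains_hist: Dict[int, float]
    n_blasts: int

    def pct_gain(self, chromosome: str) -> float:
        sel = self.table[self.table.chromosome == str(chromosome)]
        if sel.empty:
            raise KeyError(f"chromosome {chromosome} not in profile")
        return float(sel.pct_gain.iloc[0])


def gain_rates(
    cells: Iterable[Union[SubcloneCode, str]],
    panel: ChromosomePanel = DEFAULT_PANEL,
) -> TrisomyProfile:
    """Marginal gain fraction per chromosome, split trisomy/tetrasomy."""
    codes = _as_codes(cells)
    if not codes:
        raise ValueError("no blasts")
    n = len(codes)
    gains = np.array([code.gains for code in codes], dtype=int)
    rows = []
    for j, label in enumerate(panel.labels):
        col = gains[:, j]
        rows.append(
            (
                label,
                100.0 * np.mean(col >= 1),
                100.0 * np.mean(col == 1),
                100.0 * np.mean(col == 2),
                100.0 * np.mean(col >= 3),
            )
        )
    table = pd.DataFrame(
        rows,
        columns=["chromosome", "pct_gain", "pct_trisomy", "pct_tetrasomy", "pct_higher"],
    )
    per_cell = (gains >= 1).sum(axis=1)
    hist = {int(k): 100.0 * v / n for k, v in zip(*np.unique(per_cell, return_counts=True))}
    return TrisomyProfile(table=table, total_gains_hist=hist, n_blasts=n)


def combined_trisomy_fraction(
    cells: Iterable[Union[SubcloneCode, str]],
    chromosomes: Sequence[str],
    panel: ChromosomePanel = DEFAULT_PANEL,
) -> float:
    """Percent of blasts gaining *every* chromosome in the set simultaneously,
    irrespective of other chromosomal gains (e.g. the triple trisomy 4+10+17
    or single trisomy 18 prognostic markers)."""
    if not chromosomes:
        raise ValueError("chromosome set must be non-empty")
    idx = [panel.index(c) for c in chromosomes]  # KeyError for non-panel
    codes = _as_codes(cells)
    if not codes:
        raise ValueError("no blasts")
    hits = sum(1 for code in codes if all(code.gains[j] >= 1 for j in idx))
    return 100.0 * hits / len(codes)


def compare_groups(
    values: Sequence[float],
    labels: Sequence[str],
    paired: bool = False,
) -> Dict[str, object]:
    """Two-group comparison of per-sample statistics by t-test.

    Unpaired: two-sided Student t-test between the groups.  Paired: the two
    groups must be aligned pairs (same order) and a two-sided paired t-test
    is used.  Returns group means, SEMs, the test statistic and p-value.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal group sizes")
        if len(a) < 2:
            raise ValueError("need at least 2 pairs")
        res = stats.ttest_rel(a, b)
    else:
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 samples per group")
        res = stats.ttest_ind(a, b)
    return {
        "groups": groups,
        "means": (float(a.mean()), float(b.mean())),
        "sems": (float(stats.sem(a)) if len(a) > 1 else 0.0,
                 float(stats.sem(b)) if len(b) > 1 else 0.0),
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "paired": paired,
    }


def sample_statistics(
    samples: Mapping[str, Sequence[Union[SubcloneCode, str]]],
    panel: ChromosomePanel = DEFAULT_PANEL,
) -> pd.DataFrame:
    """Per-sample summary table: blasts, clones, PMC, entropy, gain rates,
    triple-trisomy(4,10,17) and trisomy-18 fractions."""
    rows = []
    for sample_id, cells in samples.items():
        dist = tabulate_clones(cells, panel)
        prof = gain_rates(cells, panel)
        row = {
            "sample_id": sample_id,
            "n_blasts": dist.n,
            "n_clones": dist.n_clones,
            "pmc": dist.pmc,
            "entropy_bits": dist.entropy_bits,
        }
        for rec in prof.table.itertuples(index=False):
            row[f"pct_gain_{rec.chromosome}"] = rec.pct_gain
            row[f"pct_trisomy_{rec.chromosome}"] = rec.pct_trisomy
            row[f"pct_tetrasomy_{rec.chromosome}"] = rec.pct_tetrasomy
        row["pct_tt_4_10_17"] = combined_trisomy_fraction(cells, ["4", "10", "17"], panel)
        row["pct_trisomy18_any"] = combined_trisomy_fraction(cells, ["18"], panel)
        rows.append(row)
    return pd.DataFrame(rows)
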