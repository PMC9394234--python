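"""FISH positivity cutoffs from diploid controls and cell/sample filters.

Interphase FISH miscounts a small fraction of nuclei even in euploid
controls (signal overlap → false losses, split spots → false gains).  To
separate real subclones from this technical noise, per-chromosome and
per-direction error rates are estimated from constitutionally diploid
control samples, and a positivity cutoff is derived from the exact
binomial tail: a clone-level aneusomy is treated as real only when its
marginal frequency in a sample exceeds the cutoff fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import DEFAULT_PANEL, CellProfile, ChromosomePanel, SubcloneCode, encode_subclone

__all__ = [
    "CalibrationConfig",
    "CutoffTable",
    "estimate_error_rates",
    "binomial_cutoff",
    "build_cutoff_table",
    "filter_cells",
    "qc_sample",
    "apply_cutoffs",
]


@dataclass(frozen=True)
class CalibrationConfig:
    """Tuning knobs for cutoff calibration and sample QC.

    alpha            significance level for the exact binomial tail, applied
                     per chromosome and direction (no multiplicity
                     correction by default; set ``bonferroni=True`` to divide
                     alpha by the 8x2 tests).
    min_blasts       minimum informative hyperdiploid nuclei per sample.
    min_control_cells  minimum informative control nuclei for rate estimation.
    """

    alpha: float = 0.05
    min_blasts: int = 200
    min_control_cells: int = 100
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_blasts < 1 or self.min_control_cells < 1:
            raise ValueError("minimum cell counts must be >= 1")

    @property
    def effective_alpha(self) -> float:
        return self.alpha / 16 if self.bonferroni else self.alpha


@dataclass
class CutoffTable:
    """Per chromosome x direction: control error rate and cutoff fraction."""

    table: pd.DataFrame  # columns: chromosome, direction, p_hat, k_star, c_star
    n_reference: int
    alpha: float

    def cutoff(self, chromosome: str, direction: str) -> float:
        sel = self.table[
            (self.table.chromosome == chromosome) & (self.table.direction == direction)
        ]
        if sel.empty:
            raise KeyError(f"no cutoff for chr{chromosome} {direction}")
        return float(sel.c_star.iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def estimate_error_rates(
    control_cells: Sequence[Tuple[CellProfile, str]],
    panel: ChromosomePanel = DEFAULT_PANEL,
) -> pd.DataFrame:
    """Per-chromosome gain/loss error rates from diploid control nuclei.

    ``control_cells`` is a sequence of (cell, donor sex) pairs pooled across
    control samples.  The rate is the fraction of informative cells whose
    count deviates from the constitutional baseline in the given direction.
    """
    informative = [(c, s) for c, s in control_cells if c.informative]
    if not informative:
        raise ValueError("no informative control cells")
    n = len(informative)
    rows = []
    for label in panel.labels:
        j = panel.index(label)
        gains = losses = 0
        for cell, sex in informative:
            code = encode_subclone(cell, sex, panel)
            if code.gains[j] > 0:
                gains += 1
            elif code.gains[j] < 0:
                losses += 1
        rows.append((label, "gain", gains / n, gains, n))
        rows.append((label, "loss", losses / n, losses, n))
    return pd.DataFrame(rows, columns=["chromosome", "direction", "rate", "count", "n"])


def binomial_cutoff(p_hat: float, n_cells: int, alpha: float = 0.05) -> Tuple[int, float]:
    """Minimal count k* with Pr[Binomial(n, p_hat) >= k*] < alpha.

    The tail is computed exactly (summation of binomial pmf terms via the
    survival function), never by a normal approximation.  Returns
    (k*, c* = k*/n).
    """
    if not 0 <= p_hat < 1:
        raise ValueError(f"p_hat must be in [0, 1), got {p_hat}")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if p_hat == 0.0:
        return 1, 1.0 / n_cells
    for k in range(1, n_cells + 2):
        # Pr[X >= k] = sf(k - 1)
        if stats.binom.sf(k - 1, n_cells, p_hat) < alpha:
            return k, k / n_cells
    raise RuntimeError("unreachable: tail probability never fell below alpha")


def build_cutoff_table(
    control_cells: Sequence[Tuple[CellProfile, str]],
    n_reference: int = 200,
    config: CalibrationConfig = CalibrationConfig(),
    panel: ChromosomePanel = DEFAULT_PANEL,
) -> CutoffTable:
    """Calibrate per-chromosome/direction cutoffs from pooled controls."""
    rates = estimate_error_rates(control_cells, panel)
    if int(rates.n.iloc[0]) < config.min_control_cells:
        raise ValueError(
            f"only {int(rates.n.iloc[0])} informative control cells; "
            f"need >= {config.min_control_cells}"
        )
    alpha = config.effective_alpha
    rows = []
    for rec in rates.itertuples(index=False):
        k_star, c_star = binomial_cutoff(rec.rate, n_reference, alpha)
        rows.append((rec.chromosome, rec.direction, rec.rate, k_star, c_star))
    table = pd.DataFrame(
        rows, columns=["chromosome", "direction", "p_hat", "k_star", "c_star"]
    )
    return CutoffTable(table=table, n_reference=n_reference, alpha=alpha)


@dataclass
class FilterResult:
    blasts: List[Tuple[CellProfile, SubcloneCode]]
    excluded: List[Tuple[CellProfile, str]]  # reason: missing-signal | no-gain

    @property
    def n_blasts(self) -> int:
        return len(self.blasts)


def filter_cells(
    cells: Iterable[CellProfile], sex: str, panel: ChromosomePanel = DEFAULT_PANEL
) -> FilterResult:
    """Keep informative hyperdiploid blasts (>= 1 chromosome gain).

    Nuclei with a missing signal in any channel are excluded
    ("missing-signal"); informative nuclei with no gain on any panel
    chromosome are normal/healthy hematopoietic cells ("no-gain") — losses
    alone do not qualify a nucleus as a hyperdiploid blast.
    """
    blasts: List[Tuple[CellProfile, SubcloneCode]] = []
    excluded: List[Tuple[CellProfile, str]] = []
    for cell in cells:
        if not cell.informative:
            excluded.append((cell, "missing-signal"))
            continue
        code = encode_subclone(cell, sex, panel)
        if code.is_hyperdiploid():
            blasts.append((cell, code))
        else:
            excluded.append((cell, "no-gain"))
    return FilterResult(blasts=blasts, excluded=excluded)


def qc_sample(
    filtered: FilterResult, config: CalibrationConfig = CalibrationConfig()
) -> Dict[str, object]:
    """Pass/fail a sample on its informative hyperdiploid blast count."""
    n = filtered.n_blasts
    return {
        "n_blasts": n,
        "n_excluded": len(filtered.excluded),
        "min_required": config.min_blasts,
        "pass": n >= config.min_blasts,
    }


def apply_cutoffs(
    distribution: "ClonalDistribution",
    cutoffs: CutoffTable,
    renormalize: bool = False,
):
    """Remove subclones whose aneusomies are not supported above cutoff.

    A subclone is retained iff, for every non-zero gain digit it carries,
    the marginal frequency of that aneusomy (fraction of blasts in the
    sample deviating in that direction on that chromosome) exceeds the
    chromosome/direction cutoff.  By default frequencies of the retained
    clones stay relative to all blasts so the major-clone percentage remains
    comparable across filtering choices; ``renormalize=True`` rescales them
    to sum to one.
    """
    from .clonality import ClonalDistribution  # local import: avoid cycle

    panel = distribution.panel
    n = distribution.n
    # marginal aneusomy frequencies across the whole sample
    marg = {}
    for j, label in enumerate(panel.labels):
        gain_cells = sum(c for code, c in distribution.counts.items() if code.gains[j] > 0)
        loss_cells = sum(c for code, c in distribution.counts.items() if code.gains[j] < 0)
        marg[(label, "gain")] = gain_cells / n
        marg[(label, "loss")] = loss_cells / n

    kept: Dict[SubcloneCode, int] = {}
    removed: Dict[SubcloneCode, int] = {}
    for code, count in distribution.counts.items():
        ok = True
        for j, label in enumerate(panel.labels):
            g = code.gains[j]
            if g == 0:
                continue
            direction = "gain" if g > 0 else "loss"
            if marg[(label, direction)] <= cutoffs.cutoff(label, direction):
                ok = False
                break
        (kept if ok else removed)[code] = count

    filtered = ClonalDistribution(
        counts=kept,
        panel=panel,
        total=None if renormalize else n,
    )
    return filtered, removed
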