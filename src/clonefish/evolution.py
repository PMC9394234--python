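"""Longitudinal diagnosis–relapse (DX–REL) clonal-evolution analysis.

Matched sample pairs are compared clone-by-clone and classified into two
patterns: *shared* — the major leukemic clones persist from diagnosis to
relapse — or *replacement* — the relapse is driven by clones absent from
the top of the diagnostic distribution (a clonal sweep).  The default
call: shared iff any of the top-k (k = 3) DX clones appears among the
top-k REL clones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .clonality import ClonalDistribution, gain_rates, shannon_entropy
from .core import DEFAULT_PANEL, ChromosomePanel

__all__ = [
    "EvolutionPattern",
    "match_pairs",
    "classify_evolution",
    "paired_gain_shift",
    "sensitivity_over_k",
]

SHARED = "shared"
REPLACEMENT = "replacement"


@dataclass
class EvolutionPattern:
    patient_id: str
    pattern: str  # shared | replacement
    top_k: int
    major_clone_persists: bool
    shared_mass_dx: float  # frequency mass of shared clones at DX, in [0,1]
    shared_mass_rel: float
    entropy_change: float  # REL - DX, bits


def match_pairs(
    samples: Iterable[Tuple[str, str, ClonalDistribution]],
) -> Tuple[List[Tuple[str, ClonalDistribution, ClonalDistribution]], List[Tuple[str, str]]]:
    """Pair DX and REL distributions by patient id.

    ``samples`` yields (patient_id, timepoint, distribution).  Returns the
    matched (patient, dx, rel) triples plus the unmatched (patient,
    timepoint) leftovers.  A duplicated timepoint for a patient is an error.
    """
    by_patient: Dict[str, Dict[str, ClonalDistribution]] = {}
    for pid, tp, dist in samples:
        if tp not in ("DX", "REL"):
            raise ValueError(f"timepoint must be DX or REL, got {tp!r}")
        slot = by_patient.setdefault(pid, {})
        if tp in slot:
            raise ValueError(f"duplicate {tp} sample for patient {pid}")
        slot[tp] = dist
    pairs, unmatched = [], []
    for pid in sorted(by_patient):
        slot = by_patient[pid]
        if "DX" in slot and "REL" in slot:
            pairs.append((pid, slot["DX"], slot["REL"]))
        else:
            unmatched.extend((pid, tp) for tp in slot)
    return pairs, unmatched


def classify_evolution(
    dx: ClonalDistribution,
    rel: ClonalDistribution,
    patient_id: str = "",
    top_k: int = 3,
    min_frequency: float = 0.05,
) -> EvolutionPattern:
    """Call shared-clone vs clonal-replacement for one DX–REL pair.

    Only clones reaching ``min_frequency`` of the blasts qualify as major
    clones for the top-k overlap, so single-cell FISH noise variants (false
    losses of a true clone's gains appear as distinct minor codes) cannot
    fake a shared pattern.
    """
    top_dx = set(dx.top(top_k, min_frequency))
    top_rel = set(rel.top(top_k, min_frequency))
    overlap = top_dx & top_rel
    shared_codes = set(dx.counts) & set(rel.counts)
    fdx, frel = dx.frequencies, rel.frequencies
    return EvolutionPattern(
        patient_id=patient_id,
        pattern=SHARED if overlap else REPLACEMENT,
        top_k=top_k,
        major_clone_persists=dx.major_clone in rel.counts,
        shared_mass_dx=float(sum(fdx[c] for c in shared_codes)),
        shared_mass_rel=float(sum(frel[c] for c in shared_codes)),
        entropy_change=rel.entropy_bits - dx.entropy_bits,
    )


def sensitivity_over_k(
    dx: ClonalDistribution,
    rel: ClonalDistribution,
    ks: Sequence[int] = (1, 2, 3, 5),
) -> pd.DataFrame:
    """Pattern call as a function of the top-k overlap depth."""
    rows = [
        (k, classify_evolution(dx, rel, top_k=k).pattern) for k in ks
    ]
    return pd.DataFrame(rows, columns=["k", "pattern"])


def paired_gain_shift(
    pairs: Sequence[Tuple[str, ClonalDistribution, ClonalDistribution]],
    panel: ChromosomePanel = DEFAULT_PANEL,
) -> Dict[str, object]:
    """Per-chromosome DX→REL gain-rate differences and paired entropy test.

    Gain rates are recomputed from each distribution's clone codes weighted
    by cell counts.  With fewer than 2 pairs only descriptive output is
    returned (no test).
    """
    if not pairs:
        raise ValueError("no matched pairs")

    def rates(dist: ClonalDistribution) -> np.ndarray:
        cells = [code for code, c in dist.counts.items() for _ in range(c)]
        return gain_rates(cells, panel).table.pct_gain.to_numpy()

    diff_rows, ent_dx, ent_rel = [], [], []
    for pid, dx, rel in pairs:
        diff_rows.append(rates(rel) - rates(dx))
        ent_dx.append(dx.entropy_bits)
        ent_rel.append(rel.entropy_bits)
    diffs = pd.DataFrame(diff_rows, columns=list(panel.labels),
                         index=[p for p, _, _ in pairs])
    out: Dict[str, object] = {
        "gain_rate_diff": diffs,  # REL minus DX, percentage points
        "mean_diff": diffs.mean(axis=0),
        "entropy_dx": ent_dx,
        "entropy_rel": ent_rel,
    }
    if len(pairs) >= 2:
        if np.allclose(ent_dx, ent_rel):
            out["entropy_paired_p"] = 1.0
            out["entropy_statistic"] = 0.0
        else:
            res = stats.ttest_rel(ent_rel, ent_dx)
            out["entropy_paired_p"] = float(res.pvalue)
            out["entropy_statistic"] = float(res.statistic)
    return out
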