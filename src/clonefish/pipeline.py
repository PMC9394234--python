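"""End-to-end convenience wrappers: cells → per-sample statistics → risk calls."""

from __future__ import annotations

from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd

from .calibration import filter_cells
from .clonality import sample_statistics
from .core import CellProfile
from .predictor import PredictorConfig, chr18_chr10_rule, classification_report

__all__ = ["cohort_statistics", "risk_classify"]


def cohort_statistics(
    cells: Mapping[str, Sequence[CellProfile]],
    sexes: Mapping[str, str],
) -> pd.DataFrame:
    """Filter each sample to hyperdiploid blasts and summarise it.

    Returns the per-sample statistics table (PMC, entropy, per-chromosome
    gain percentages, ...) indexed by ``sample_id``.
    """
    blasts = {
        sample_id: [code for _, code in filter_cells(sample, sexes[sample_id]).blasts]
        for sample_id, sample in cells.items()
    }
    return sample_statistics(blasts)


def risk_classify(
    stats: pd.DataFrame,
    outcomes: Mapping[str, str] | None = None,
    config: PredictorConfig = PredictorConfig(),
) -> Tuple[pd.DataFrame, Dict[str, object] | None]:
    """Apply the chr18→chr10 rule to a per-sample statistics table.

    Returns the table with ``risk_label`` / ``risk_trace`` columns appended
    and, when true outcome labels are supplied, the classification report.
    """
    calls = [
        chr18_chr10_rule({"18": row.pct_gain_18, "10": row.pct_gain_10}, config)
        for row in stats.itertuples()
    ]
    out = stats.copy()
    out["risk_label"] = [c.label for c in calls]
    out["risk_trace"] = [c.rule_trace for c in calls]
    report = None
    if outcomes is not None:
        truth = [outcomes[s] for s in out.sample_id]
        report = classification_report([c.label for c in calls], truth)
    return out, report
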