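"""Synthetic HHD-B-ALL cohort generator.

The raw single-cell FISH data this pipeline was designed around are not
publicly deposited, so every stage is exercised on generated cohorts
carrying the same statistical structure: multi-clone samples whose clones
arise by ordered gain acquisition (chromosome 21 first, then 14 and X,
with 4 and 6 late) plus chromosomal-instability perturbations;
clone-frequency distributions of tunable entropy (symmetric Dirichlet);
FISH observation noise at the diploid-control error rates (false gains
<= 0.37%, false losses <= 5% per chromosome); admixed normal diploid
cells; and patient-level outcomes with planted trisomy-18/-10 group
effects and exponential relapse-free survival with a planted hazard
ratio.  Ground truth is recorded alongside for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_PANEL,
    CellProfile,
    ChromosomePanel,
    SubcloneCode,
    constitutional_baseline,
)

__all__ = [
    "SyntheticCohortSpec",
    "CohortResult",
    "simulate_clone_tree",
    "sample_cells",
    "generate_patient_sample",
    "generate_cohort",
    "generate_matched_pairs",
]

_PROTOCOLS = ("PETHEMA", "SHOP", "AIEOP-BFM", "UKALL2003")


@dataclass
class SyntheticCohortSpec:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the validation-cohort conditions the pipeline targets:
    33 favorable vs 17 unfavorable patients, 500 cells per sample, group
    mean %+18 and %+10 of 60 (favorable) vs 25 (unfavorable) with SD 10,
    control-level FISH noise, and a relapse hazard ratio of 11 on a base
    hazard giving ~88% favorable RFS at 10 years.
    """

    n_favorable: int = 33
    n_unfavorable: int = 17
    cells_per_sample: int = 500
    gain_order: Tuple[str, ...] = ("21", "14", "X", "18", "17", "10", "6", "4")
    founder_gains: Tuple[int, int] = (3, 6)  # inclusive range of founder K
    n_subclones: int = 12
    tree_depth: int = 3
    cin_rate: Union[float, Sequence[float]] = 0.05
    cin_gain_bias: float = 0.8  # P(perturbation is +1 rather than -1)
    dirichlet_concentration: float = 0.5
    # couples heterogeneity to aneuploidy: the per-patient concentration is
    # dirichlet_concentration * (mean planted %+18/%+10 / 40) ** coupling, so
    # high-trisomy samples are more heterogeneous (higher entropy, lower PMC)
    heterogeneity_coupling: float = 3.0
    mean_p18: Tuple[float, float] = (60.0, 25.0)  # (favorable, unfavorable), %
    mean_p10: Tuple[float, float] = (60.0, 25.0)
    sd_p: float = 10.0
    false_gain_rate: float = 0.0037
    false_loss_rate: float = 0.05
    admixture: float = 0.10
    missing_rate: float = 0.0
    base_hazard: float = 0.0129  # events/year in the favorable group
    hazard_ratio: float = 11.0
    horizon_years: float = 10.0
    seed: int = 0
    panel: ChromosomePanel = field(default_factory=lambda: DEFAULT_PANEL)

    def __post_init__(self) -> None:
        if self.cells_per_sample < 1:
            raise ValueError("cells_per_sample must be >= 1")
        for name in ("false_gain_rate", "false_loss_rate", "admixture",
                     "missing_rate", "cin_gain_bias"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for pair in (self.mean_p18, self.mean_p10):
            if any(not 0 <= m <= 100 for m in pair):
                raise ValueError(f"group mean percentages must be in [0, 100]: {pair}")
        if tuple(sorted(self.gain_order)) != tuple(sorted(self.panel.labels)):
            raise ValueError("gain_order must be a permutation of the panel labels")

    def cin_vector(self) -> np.ndarray:
        v = np.asarray(self.cin_rate, dtype=float)
        if v.ndim == 0:
            v = np.full(len(self.panel), float(v))
        if v.shape != (len(self.panel),) or np.any((v < 0) | (v > 1)):
            raise ValueError("cin_rate must be a probability or one per chromosome")
        return v


def simulate_clone_tree(
    spec: SyntheticCohortSpec, rng: np.random.Generator
) -> Tuple[List[SubcloneCode], List[int]]:
    """Grow a clone tree by ordered gain acquisition plus CIN.

    The founder gains the first K chromosomes of ``gain_order`` (K drawn
    uniformly from ``founder_gains``).  Each descendant derives from a
    random existing clone by independent per-chromosome ±1 perturbations
    at the CIN rate (gain-biased), with digits clipped to [−1, 2].
    Returns (clones, parent index per clone; founder parent = −1).
    """
    cin = spec.cin_vector()
    if np.all(cin >= 1.0) and spec.tree_depth > 8:
        raise ValueError("degenerate spec: CIN rate 1 with depth > 8")
    panel = spec.panel
    lo, hi = spec.founder_gains
    k = int(rng.integers(lo, hi + 1))
    founder = [0] * len(panel)
    for label in spec.gain_order[:k]:
        founder[panel.index(label)] = 1
    clones: List[Tuple[int, ...]] = [tuple(founder)]
    parents: List[int] = [-1]
    for _ in range(spec.tree_depth):
        n_new = max(1, (spec.n_subclones - 1) // max(spec.tree_depth, 1))
        for _ in range(n_new):
            if len(clones) >= spec.n_subclones:
                break
            pi = int(rng.integers(0, len(clones)))
            gains = list(clones[pi])
            for j in range(len(panel)):
                if rng.random() < cin[j]:
                    step = 1 if rng.random() < spec.cin_gain_bias else -1
                    gains[j] = int(np.clip(gains[j] + step, -1, 2))
            clones.append(tuple(gains))
            parents.append(pi)
    return [SubcloneCode(tuple(g)) for g in clones], parents


def _plant_marginal(
    clones: List[Tuple[int, ...]],
    freqs: np.ndarray,
    chrom_index: int,
    target_pct: float,
) -> Tuple[List[Tuple[int, ...]], np.ndarray, float]:
    """Override one chromosome's digits so the clone-mass gain fraction
    equals ``target_pct``: clones are taken in decreasing-frequency order
    and gain the chromosome until the target mass is covered; the clone
    straddling the boundary is split into a gained and an ungained part so
    the planted marginal is exact."""
    order = np.argsort(-freqs)
    target = target_pct / 100.0
    out_gains: List[Tuple[int, ...]] = []
    out_freqs: List[float] = []
    cum = 0.0
    for idx in order:
        g = list(clones[idx])
        f = float(freqs[idx])
        remaining = target - cum
        if remaining >= f - 1e-12:
            g[chrom_index] = max(1, g[chrom_index])
            out_gains.append(tuple(g))
            out_freqs.append(f)
            cum += f
        elif remaining > 1e-9:
            g_gain = list(g)
            g_gain[chrom_index] = max(1, g_gain[chrom_index])
            out_gains.append(tuple(g_gain))
            out_freqs.append(remaining)
            g[chrom_index] = 0
            out_gains.append(tuple(g))
            out_freqs.append(f - remaining)
            cum = target
        else:
            g[chrom_index] = 0
            out_gains.append(tuple(g))
            out_freqs.append(f)
    return out_gains, np.asarray(out_freqs), 100.0 * min(cum, target)


def sample_cells(
    clones: Sequence[SubcloneCode],
    frequencies: Sequence[float],
    n_cells: int,
    sex: str,
    sample_id: str,
    rng: np.random.Generator,
    false_gain_rate: float = 0.0,
    false_loss_rate: float = 0.0,
    admixture: float = 0.0,
    missing_rate: float = 0.0,
    panel: ChromosomePanel = DEFAULT_PANEL,
) -> Tuple[List[CellProfile], List[SubcloneCode]]:
    """Draw nuclei from a clone mixture and apply FISH observation noise.

    Each cell is a normal diploid with probability ``admixture``, otherwise
    drawn from ``clones`` with the given frequencies.  Independently per
    chromosome, a false gain (+1 copy) occurs at ``false_gain_rate`` and a
    false loss (−1 copy, floored at 0) at ``false_loss_rate``; a channel
    drops out (missing signal) at ``missing_rate``.  Returns the observed
    cells and each cell's true source code.
    """
    freqs = np.asarray(frequencies, dtype=float)
    if not np.isclose(freqs.sum(), 1.0):
        raise ValueError("clone frequencies must sum to 1")
    baseline = np.array(
        [constitutional_baseline(lbl, sex) for lbl in panel.labels], dtype=int
    )
    diploid = SubcloneCode((0,) * len(panel))
    cells: List[CellProfile] = []
    sources: List[SubcloneCode] = []
    clone_idx = rng.choice(len(clones), size=n_cells, p=freqs)
    is_normal = rng.random(n_cells) < admixture
    for i in range(n_cells):
        source = diploid if is_normal[i] else clones[int(clone_idx[i])]
        counts = baseline + np.asarray(source.gains, dtype=int)
        counts = np.maximum(counts, 0)
        if false_gain_rate or false_loss_rate:
            u = rng.random(len(panel))
            counts = counts + (u < false_gain_rate).astype(int)
            counts = np.maximum(
                counts - ((u >= false_gain_rate)
                          & (u < false_gain_rate + false_loss_rate)).astype(int),
                0,
            )
        observed: List[Optional[int]] = [int(c) for c in counts]
        if missing_rate and rng.random() < missing_rate:
            observed[int(rng.integers(0, len(panel)))] = None
        cells.append(
            CellProfile(
                cell_id=f"{sample_id}_c{i:05d}",
                sample_id=sample_id,
                counts=tuple(observed),
                panel=panel,
            )
        )
        sources.append(source)
    return cells, sources


def generate_patient_sample(
    spec: SyntheticCohortSpec,
    group: str,
    sex: str,
    sample_id: str,
    rng: np.random.Generator,
    clones: Optional[List[SubcloneCode]] = None,
) -> Dict[str, object]:
    """One sample: clone tree, planted %+18/%+10, frequencies, noisy cells."""
    gi = 0 if group == "favorable" else 1
    target18 = float(np.clip(rng.normal(spec.mean_p18[gi], spec.sd_p), 2.0, 98.0))
    target10 = float(np.clip(rng.normal(spec.mean_p10[gi], spec.sd_p), 2.0, 98.0))
    if clones is None:
        clones, _ = simulate_clone_tree(spec, rng)
    mean_target = 0.5 * (target18 + target10)
    alpha = spec.dirichlet_concentration * (mean_target / 40.0) ** spec.heterogeneity_coupling
    freqs = rng.dirichlet([alpha] * len(clones))
    raw = [c.gains for c in clones]
    raw, freqs, realized18 = _plant_marginal(raw, freqs, spec.panel.index("18"), target18)
    raw, freqs, realized10 = _plant_marginal(raw, freqs, spec.panel.index("10"), target10)
    # planting may collide codes; merge duplicates, drop zero-mass clones
    merged: Dict[Tuple[int, ...], float] = {}
    for g, f in zip(raw, freqs):
        if f > 0.0:
            merged[g] = merged.get(g, 0.0) + float(f)
    codes = [SubcloneCode(g) for g in merged]
    cfreqs = np.array(list(merged.values()))
    cfreqs = cfreqs / cfreqs.sum()
    cells, sources = sample_cells(
        codes, cfreqs, spec.cells_per_sample, sex, sample_id, rng,
        false_gain_rate=spec.false_gain_rate,
        false_loss_rate=spec.false_loss_rate,
        admixture=spec.admixture,
        missing_rate=spec.missing_rate,
        panel=spec.panel,
    )
    p = cfreqs / cfreqs.sum()
    true_entropy = float(-(p * np.log2(p)).sum())
    return {
        "cells": cells,
        "sources": sources,
        "clones": codes,
        "frequencies": cfreqs,
        "true_entropy_bits": true_entropy,
        "true_p18": realized18,
        "true_p10": realized10,
        "target_p18": target18,
        "target_p10": target10,
    }


@dataclass
class CohortResult:
    cells: Dict[str, List[CellProfile]]  # sample_id -> nuclei
    clinical: pd.DataFrame
    truth: Dict[str, object]


def generate_cohort(spec: SyntheticCohortSpec) -> CohortResult:
    """Generate the full synthetic validation-style cohort.

    Per patient: a diagnostic sample (cells with planted %+18/%+10 group
    effects), sex/age/WBC covariates, and relapse-free survival drawn from
    group-wise exponential hazards (favorable: ``base_hazard``;
    unfavorable: ``base_hazard × hazard_ratio``) with censoring at a random
    follow-up horizon.  All randomness descends from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    cells: Dict[str, List[CellProfile]] = {}
    rows = []
    truth_patients = {}
    plan = [("favorable", i) for i in range(spec.n_favorable)] + [
        ("unfavorable", i) for i in range(spec.n_unfavorable)
    ]
    for group, i in plan:
        pid = f"{'FAV' if group == 'favorable' else 'UNF'}{i + 1:02d}"
        sex = "M" if rng.random() < 0.55 else "F"
        sample = generate_patient_sample(spec, group, sex, pid, rng)
        cells[pid] = sample["cells"]
        hazard = spec.base_hazard * (spec.hazard_ratio if group == "unfavorable" else 1.0)
        t_event = rng.exponential(1.0 / hazard)
        t_censor = rng.uniform(0.5 * spec.horizon_years, 1.5 * spec.horizon_years)
        event = int(t_event <= t_censor)
        rows.append(
            {
                "patient_id": pid,
                "timepoint": "DX",
                "group": group,
                "outcome": "CR" if group == "favorable" else "REL",
                "event": event,
                "time_years": float(min(t_event, t_censor)),
                "age": float(rng.uniform(1, 15)),
                "sex": sex,
                "wbc": float(rng.lognormal(2.5, 1.0)),
                "mrd": "neg" if rng.random() < 0.96 else "pos",
                "protocol": _PROTOCOLS[int(rng.integers(0, len(_PROTOCOLS)))],
            }
        )
        truth_patients[pid] = {
            "true_entropy_bits": sample["true_entropy_bits"],
            "true_p18": sample["true_p18"],
            "true_p10": sample["true_p10"],
            "clone_frequencies": {
                str(c): float(f)
                for c, f in zip(sample["clones"], sample["frequencies"])
            },
        }
    truth = {
        "hazard_ratio": spec.hazard_ratio,
        "base_hazard": spec.base_hazard,
        "patients": truth_patients,
        "spec_seed": spec.seed,
    }
    return CohortResult(cells=cells, clinical=pd.DataFrame(rows), truth=truth)


def generate_matched_pairs(
    spec: SyntheticCohortSpec,
    n_patients: int = 10,
    scenario: str = "persistent",
    rel_gain_drop: float = 10.0,
) -> Dict[str, object]:
    """Matched DX–REL samples under a fixed clonal-evolution scenario.

    ``persistent``: the relapse keeps the diagnostic clone set and the DX
    major clone keeps at least half of the relapse mass (shared pattern by
    construction).  ``sweep``: relapse clones are regenerated until their
    codes are disjoint from the diagnostic ones (clonal replacement by
    construction).
    """
    if scenario not in ("persistent", "sweep"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(spec.seed + 1)
    out_cells: Dict[str, List[CellProfile]] = {}
    meta = []
    for i in range(n_patients):
        pid = f"PAIR{i + 1:02d}"
        sex = "M" if rng.random() < 0.55 else "F"
        dx = generate_patient_sample(spec, "unfavorable", sex, f"{pid}_DX", rng)
        out_cells[f"{pid}_DX"] = dx["cells"]
        if scenario == "persistent":
            codes = dx["clones"]
            major = int(np.argmax(dx["frequencies"]))
            base = rng.dirichlet([spec.dirichlet_concentration] * len(codes))
            freqs = 0.5 * base
            freqs[major] += 0.5
        else:
            dx_set = {c.gains for c in dx["clones"]}
            for _ in range(100):
                rel_clones, _ = simulate_clone_tree(spec, rng)
                uniq = [c for c in {c.gains for c in rel_clones} if c not in dx_set]
                if len(uniq) >= 2:
                    break
            else:
                raise RuntimeError("could not generate disjoint relapse clones")
            codes = [SubcloneCode(g) for g in uniq]
            freqs = rng.dirichlet([spec.dirichlet_concentration] * len(codes))
        cells, _ = sample_cells(
            codes, freqs, spec.cells_per_sample, sex, f"{pid}_REL", rng,
            false_gain_rate=spec.false_gain_rate,
            false_loss_rate=spec.false_loss_rate,
            admixture=min(1.0, spec.admixture + rel_gain_drop / 100.0),
            missing_rate=spec.missing_rate,
            panel=spec.panel,
        )
        out_cells[f"{pid}_REL"] = cells
        meta.append({"patient_id": pid, "sex": sex, "scenario": scenario})
    return {"cells": out_cells, "meta": pd.DataFrame(meta), "scenario": scenario}
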