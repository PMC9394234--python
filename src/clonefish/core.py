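"""Core data types for sequential-iFISH clonality analysis.

High-hyperdiploid B-ALL (HHD-B-ALL) blasts typically gain chromosomes
X, 4, 6, 10, 14, 17, 18 and 21.  Sequential interphase FISH counts all
eight chromosomes in the same nucleus over three hybridization rounds;
each informative nucleus is summarised as an 8-digit *subclone code*
giving the per-chromosome gain relative to the constitutional baseline
(autosomes: 2 copies; X: 1 in males, 2 in females).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

__all__ = [
    "DEFAULT_PANEL",
    "ChromosomePanel",
    "CellProfile",
    "SubcloneCode",
    "SampleRecord",
    "constitutional_baseline",
    "encode_subclone",
]


@dataclass(frozen=True)
class ChromosomePanel:
    """Ordered FISH probe panel.

    The default order (X, 4, 6, 10, 14, 17, 18, 21) is the order in which
    subclone-code digits are written; round indices record which of the
    three successive hybridization rounds each probe belongs to.
    """

    labels: Tuple[str, ...] = ("X", "4", "6", "10", "14", "17", "18", "21")
    probes: Tuple[str, ...] = (
        "DXZ1", "CEP4", "D6Z1", "CEP10", "D14S1420", "D17Z1", "D18Z1", "LSI21",
    )
    rounds: Tuple[int, ...] = (2, 1, 1, 1, 3, 2, 2, 3)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("panel chromosome labels must be unique")
        if len(self.probes) != len(self.labels) or len(self.rounds) != len(self.labels):
            raise ValueError("probes and rounds must align with labels")
        if any(r not in (1, 2, 3) for r in self.rounds):
            raise ValueError("hybridization round index must be 1, 2 or 3")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(str(label))
        except ValueError:
            raise KeyError(f"chromosome {label!r} not in panel {self.labels}") from None


DEFAULT_PANEL = ChromosomePanel()


def constitutional_baseline(label: str, sex: str) -> int:
    """Constitutional copy number: 2 for autosomes, X depends on sex."""
    if label == "X":
        if sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
        return 1 if sex == "M" else 2
    return 2


@dataclass(frozen=True)
class CellProfile:
    """One nucleus's integer copy-number calls over the panel.

    ``counts`` holds one entry per panel chromosome; ``None`` flags a
    missing hybridization signal in that channel.  A cell is *informative*
    iff every channel produced a signal.
    """

    cell_id: str
    sample_id: str
    counts: Tuple[Optional[int], ...]
    panel: ChromosomePanel = DEFAULT_PANEL

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.panel):
            raise ValueError(
                f"cell {self.cell_id}: {len(self.counts)} counts for a "
                f"{len(self.panel)}-chromosome panel"
            )
        for label, c in zip(self.panel.labels, self.counts):
            if c is not None and c < 0:
                raise ValueError(
                    f"cell {self.cell_id}: negative copy count {c} for chr{label}"
                )

    @property
    def informative(self) -> bool:
        return all(c is not None for c in self.counts)


@dataclass(frozen=True, order=True)
class SubcloneCode:
    """Per-chromosome gains relative to the constitutional baseline.

    The canonical string form concatenates the digits when all gains lie
    in [0, 9] (the usual 8-digit code, e.g. ``"11111012"``); whenever a
    loss (−1) or a gain > 9 occurs, a comma-separated expanded form is
    used instead so the string round-trips unambiguously.
    """

    gains: Tuple[int, ...]

    def __str__(self) -> str:
        if all(0 <= g <= 9 for g in self.gains):
            return "".join(str(g) for g in self.gains)
        return ",".join(str(g) for g in self.gains)

    @classmethod
    def from_string(cls, s: str) -> "SubcloneCode":
        if "," in s:
            return cls(tuple(int(tok) for tok in s.split(",")))
        return cls(tuple(int(ch) for ch in s))

    @property
    def n_gained(self) -> int:
        """Number of panel chromosomes with at least one extra copy."""
        return sum(1 for g in self.gains if g >= 1)

    @property
    def total_gains(self) -> int:
        return sum(g for g in self.gains if g > 0)

    def is_hyperdiploid(self) -> bool:
        return any(g >= 1 for g in self.gains)


@dataclass
class SampleRecord:
    """Patient/timepoint metadata attached to one seq-iFISH sample."""

    patient_id: str
    timepoint: str = "DX"  # DX | REL
    outcome: Optional[str] = None  # CR | REL
    relapse: Optional[bool] = None
    death: Optional[bool] = None
    time_years: Optional[float] = None
    age: Optional[float] = None
    sex: Optional[str] = None  # M | F
    wbc: Optional[float] = None
    mrd: Optional[str] = None
    protocol: Optional[str] = None
    karyotype: Optional[str] = None
    modal_number: Optional[int] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.timepoint not in ("DX", "REL"):
            raise ValueError(f"timepoint must be DX or REL, got {self.timepoint!r}")
        if self.time_years is not None and self.time_years < 0:
            raise ValueError("follow-up time must be non-negative")
        if self.outcome is not None and self.relapse is not None:
            if (self.outcome == "REL") != bool(self.relapse):
                raise ValueError(
                    f"{self.patient_id}: outcome {self.outcome} inconsistent with "
                    f"relapse={self.relapse}"
                )


def encode_subclone(
    cell: CellProfile, sex: str, panel: Optional[ChromosomePanel] = None
) -> SubcloneCode:
    """Encode one informative nucleus as a subclone code.

    gain = observed copies − constitutional baseline, per panel chromosome.
    """
    panel = panel or cell.panel
    if not cell.informative:
        raise ValueError(
            f"cell {cell.cell_id} is non-informative (missing signal); "
            "exclude it before encoding"
        )
    if sex not in ("M", "F"):
        raise ValueError(f"sex is required for X baselining, got {sex!r}")
    gains = tuple(
        int(c) - constitutional_baseline(label, sex)
        for label, c in zip(panel.labels, cell.counts)
    )
    return SubcloneCode(gains)


def encode_cells(
    cells: Iterable[CellProfile], sex: str
) -> Tuple[Tuple[CellProfile, SubcloneCode], ...]:
    """Encode every informative cell, skipping non-informative ones."""
    return tuple(
        (cell, encode_subclone(cell, sex)) for cell in cells if cell.informative
    )
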