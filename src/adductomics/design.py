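"""Stepped-MRM acquisition design.

A triple quadrupole monitors one precursor/product ("transition") at a
time. Protonated 2'-deoxynucleosides fragment under CID by losing the
2'-deoxyribose sugar as a 116 Da neutral, so an exhaustive neutral-loss
screen monitors [M+H]+ -> [M+H-116]+ for every integer precursor mass
in a range. The range is split into contiguous per-injection windows so
each injection carries a tractable transition table.

Default geometry: 6 injections x 50 Da windows starting at m/z 225,
i.e. 300 transitions from 225->109 through 524->408.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: Mass of the 2'-deoxyribose neutral lost from [M+H]+ under CID, Da.
DEOXYRIBOSE_NEUTRAL_LOSS = 116

#: Protonated canonical 2'-deoxynucleoside precursors (dC, dT, dA, dG), Da.
CANONICAL_PRECURSORS = (228, 243, 252, 268)


def neutral_loss_product(precursor_mz: float, neutral_loss: float = DEOXYRIBOSE_NEUTRAL_LOSS) -> float:
    """Product-ion m/z after a constant neutral loss.

    Parameters
    ----------
    precursor_mz : float
        Q1 (precursor) m/z; must exceed the neutral loss.
    neutral_loss : float
        Mass of the neutral fragment, Da (default 116, 2'-deoxyribose).

    Returns
    -------
    float
        Q3 (product) m/z, ``precursor_mz - neutral_loss``.
    """
    if precursor_mz <= neutral_loss:
        raise ValueError(
            f"precursor m/z {precursor_mz} must exceed the neutral loss {neutral_loss}"
        )
    return precursor_mz - neutral_loss


@dataclass(frozen=True)
class Transition:
    """One monitored reaction: an integer-resolution Q1/Q3 pair."""

    precursor_mz: int
    product_mz: int
    injection_index: int  # 1-based acquisition window
    is_canonical: bool = False

    def __post_init__(self) -> None:
        if self.injection_index < 1:
            raise ValueError("injection_index is 1-based and must be >= 1")


@dataclass(frozen=True)
class AcquisitionDesign:
    """An ordered stepped-MRM transition list with its window geometry."""

    transitions: tuple[Transition, ...]
    neutral_loss: int = DEOXYRIBOSE_NEUTRAL_LOSS
    window_width: int = 50
    n_injections: int = 6
    start_mz: int = 225

    def __len__(self) -> int:
        return len(self.transitions)

    @property
    def precursors(self) -> tuple[int, ...]:
        return tuple(t.precursor_mz for t in self.transitions)

    def non_canonical(self) -> tuple[Transition, ...]:
        return tuple(t for t in self.transitions if not t.is_canonical)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "precursor_mz": [t.precursor_mz for t in self.transitions],
                "product_mz": [t.product_mz for t in self.transitions],
                "injection_index": [t.injection_index for t in self.transitions],
                "is_canonical": [t.is_canonical for t in self.transitions],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, neutral_loss: int | None = None) -> "AcquisitionDesign":
        df = pd.read_csv(path, sep="\t", comment="#")
        transitions = tuple(
            Transition(int(r.precursor_mz), int(r.product_mz), int(r.injection_index), bool(r.is_canonical))
            for r in df.itertuples()
        )
        if neutral_loss is None:
            neutral_loss = transitions[0].precursor_mz - transitions[0].product_mz
        widths = df.groupby("injection_index").size()
        return cls(
            transitions=transitions,
            neutral_loss=int(neutral_loss),
            window_width=int(widths.iloc[0]),
            n_injections=int(len(widths)),
            start_mz=int(df.precursor_mz.min()),
        )


def generate_stepped_mrm(
    start_mz: int = 225,
    window_width: int = 50,
    n_injections: int = 6,
    neutral_loss: int = DEOXYRIBOSE_NEUTRAL_LOSS,
    canonical_precursors: Sequence[int] = CANONICAL_PRECURSORS,
) -> AcquisitionDesign:
    """Build the exhaustive 1 Da stepped-MRM design.

    Injection ``k`` (1-based) covers precursors
    ``[start + (k-1)*width, start + k*width - 1]``; every product ion is
    ``precursor - neutral_loss``. Transitions of canonical nucleosides
    are generated but flagged so downstream code can ignore them.
    """
    if window_width < 1 or n_injections < 1:
        raise ValueError("window_width and n_injections must be positive")
    if start_mz <= neutral_loss:
        raise ValueError("start_mz must exceed the neutral loss")
    canonical = frozenset(int(m) for m in canonical_precursors)
    transitions = []
    for k in range(1, n_injections + 1):
        lo = start_mz + (k - 1) * window_width
        for mz in range(lo, lo + window_width):
            transitions.append(
                Transition(
                    precursor_mz=mz,
                    product_mz=mz - neutral_loss,
                    injection_index=k,
                    is_canonical=mz in canonical,
                )
            )
    return AcquisitionDesign(
        transitions=tuple(transitions),
        neutral_loss=neutral_loss,
        window_width=window_width,
        n_injections=n_injections,
        start_mz=start_mz,
    )


def flag_canonicals(
    design: AcquisitionDesign, canonical_precursors: Iterable[int] = CANONICAL_PRECURSORS
) -> AcquisitionDesign:
    """Return a copy of ``design`` with canonical precursors flagged.

    Any prior flags are replaced: a transition is canonical iff its
    precursor is in ``canonical_precursors``.
    """
    canonical = frozenset(int(m) for m in canonical_precursors)
    flagged = tuple(
        replace(t, is_canonical=t.precursor_mz in canonical) for t in design.transitions
    )
    return replace(design, transitions=flagged)
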