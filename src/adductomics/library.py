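"""Standards library, satellite offsets, and the artifact blacklist.

The library holds known 2'-deoxyribonucleoside damage products,
epigenetic marks, and canonicals with their MRM transitions and, where
established by standard injection, retention times. Two species can
legitimately share a transition (isobaric nucleobases), so lookups by
transition return every match.

Offset constants describe the satellite signals an abundant species
throws in an ESI source: natural-isotope M+1/M+2 peaks, and in-source
Na+/K+ cationization at +21.98 / +37.96 Da relative to [M+H]+. At unit
(triple-quadrupole) resolution these round to +22 and +38.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from adductomics.design import DEOXYRIBOSE_NEUTRAL_LOSS

ROLE_DAMAGE = "damage"
ROLE_EPIGENETIC = "epigenetic"
ROLE_ARTIFACT = "artifact"
ROLE_CANONICAL = "canonical"


@dataclass(frozen=True)
class StandardEntry:
    """One library species: name, transition, optional retention time."""

    name: str
    abbreviation: str
    precursor_mz: int
    product_mz: int
    retention_time: float | None = None  # minutes
    role: str = ROLE_DAMAGE
    #: alternative quantification transition where the targeted assay
    #: uses a different product ion than the discovery screen
    alt_product_mz: int | None = None


@dataclass(frozen=True)
class OffsetConstants:
    """Exact satellite mass offsets (Da) relative to [M+H]+."""

    sodium_minus_H: float = 21.9819
    potassium_minus_H: float = 37.9559
    isotopomer_1: float = 1.0
    isotopomer_2: float = 2.0
    neutral_loss: float = float(DEOXYRIBOSE_NEUTRAL_LOSS)

    @property
    def sodium_unit(self) -> int:
        return round(self.sodium_minus_H)

    @property
    def potassium_unit(self) -> int:
        return round(self.potassium_minus_H)


DEFAULT_OFFSETS = OffsetConstants()

# (name, abbreviation, precursor, retention_time, role, alt_product)
_LIBRARY_ROWS: list[tuple] = [
    ("N2-carboxymethyl-2'-deoxyguanosine", "N2-CMdG", 326, 3.45, ROLE_DAMAGE, None),
    ("5-hydroxymethyl-2'-deoxycytidine", "5-HMdC", 258, 2.72, ROLE_EPIGENETIC, None),
    ("1,N6-etheno-2'-deoxyadenosine", "1,N6-edA", 276, 2.93, ROLE_DAMAGE, None),
    ("5-methyl-2'-deoxycytidine", "5-MdC", 242, None, ROLE_EPIGENETIC, None),
    ("4-thio-2'-deoxyuridine", "4-thio-dU", 245, None, ROLE_DAMAGE, None),
    ("3,N4-etheno-2'-deoxycytidine", "3,N4-edC", 252, None, ROLE_DAMAGE, None),
    ("5-formyl-2'-deoxycytidine", "5-FdC", 256, None, ROLE_EPIGENETIC, None),
    ("5-chloro-2'-deoxycytidine", "5-CldC", 262, None, ROLE_DAMAGE, None),
    ("7-deaza-2'-deoxyxanthosine", "7-deaza-dX", 268, None, ROLE_DAMAGE, None),
    ("8-oxo-2'-deoxyadenosine", "8-Oxo-dA", 268, None, ROLE_DAMAGE, None),
    ("2'-deoxyxanthosine", "dX", 269, None, ROLE_DAMAGE, None),
    ("guanidinohydantoin", "Gh", 274, None, ROLE_DAMAGE, None),
    ("O6-methyl-2'-deoxyguanosine", "O6-MdG", 282, None, ROLE_DAMAGE, None),
    ("N2-methyl-2'-deoxyguanosine", "N2-MdG", 282, None, ROLE_DAMAGE, None),
    ("8-oxo-7,8-dihydro-2'-deoxyguanosine", "8-Oxo-dG", 284, 6.65, ROLE_DAMAGE, 170),
    ("6-thio-2'-deoxyguanosine", "S6-dG", 284, None, ROLE_DAMAGE, None),
    ("2'-deoxycytidine-5-carboxylic acid", "dC-COOH", 294, None, ROLE_DAMAGE, None),
    ("spiroiminodihydantoin", "Sp", 300, None, ROLE_DAMAGE, None),
    ("pyrimidopurinone adduct of dG", "M1-dG", 304, None, ROLE_DAMAGE, None),
    ("8-chloro-2'-deoxyadenosine", "8-Cl-dA", 286, None, ROLE_DAMAGE, None),
    ("8-chloro-2'-deoxyguanosine", "8-Cl-dG", 302, None, ROLE_DAMAGE, None),
    ("2-chloro-2'-deoxyadenosine", "2-Cl-dA", 286, None, ROLE_DAMAGE, None),
    ("5-fluoro-2'-deoxycytidine", "5-F-dC", 246, None, ROLE_DAMAGE, None),
    ("2'-deoxycytidine", "dC", 228, None, ROLE_CANONICAL, None),
    ("2'-deoxythymidine", "dT", 243, None, ROLE_CANONICAL, None),
    ("2'-deoxyadenosine", "dA", 252, None, ROLE_CANONICAL, None),
    ("2'-deoxyguanosine", "dG", 268, None, ROLE_CANONICAL, None),
]


def builtin_library() -> list[StandardEntry]:
    """The built-in standards cocktail plus the four canonicals.

    Every entry monitors the -116 neutral loss for discovery matching;
    8-Oxo-dG additionally carries the 284->170 transition used by its
    targeted isotope-dilution assay (``alt_product_mz``).
    """
    return [
        StandardEntry(
            name=name,
            abbreviation=abbr,
            precursor_mz=prec,
            product_mz=prec - DEOXYRIBOSE_NEUTRAL_LOSS,
            retention_time=rt,
            role=role,
            alt_product_mz=alt,
        )
        for name, abbr, prec, rt, role, alt in _LIBRARY_ROWS
    ]


@dataclass(frozen=True)
class BlacklistEntry:
    """A known non-adduct signal removed during curation (rule vi)."""

    label: str
    precursor_mz: int
    product_mz: int
    retention_time: float | None  # minutes; None matches any RT
    reason: str


#: Retention time of dC under the default gradient; the dC dimer
#: co-elutes with dC, which identifies it as an ionization artifact.
DC_RETENTION_TIME = 1.80


def builtin_blacklist() -> list[BlacklistEntry]:
    """Known-artifact blacklist: the protonated dC dimer.

    A 455->339 signal co-eluting with dC is a gas-phase dimer of dC
    formed during ionization, not a pre-existing DNA lesion.
    """
    return [
        BlacklistEntry(
            label="dC dimer",
            precursor_mz=455,
            product_mz=339,
            retention_time=DC_RETENTION_TIME,
            reason="co-eluting ionization artifact (protonated dC dimer)",
        )
    ]


def lookup(entries: Iterable[StandardEntry], abbreviation: str) -> StandardEntry:
    """Find a library entry by abbreviation (exact match)."""
    for e in entries:
        if e.abbreviation == abbreviation:
            return e
    raise KeyError(abbreviation)


def lookup_transition(
    entries: Iterable[StandardEntry], precursor_mz: int, product_mz: int
) -> list[StandardEntry]:
    """All entries whose discovery or alternate transition matches."""
    out = []
    for e in entries:
        if e.precursor_mz == precursor_mz and (
            e.product_mz == product_mz or e.alt_product_mz == product_mz
        ):
            out.append(e)
    return out


def expected_satellites(
    precursor_mz: int, offsets: OffsetConstants = DEFAULT_OFFSETS
) -> list[tuple[int, str]]:
    """Satellite precursors an abundant species at ``precursor_mz`` throws.

    Returns unit-mass (rounded) offsets: isotopomers at +1/+2 and salt
    adducts at +22 (Na) / +38 (K). A zeroed salt constant suppresses
    that satellite.
    """
    if precursor_mz <= DEOXYRIBOSE_NEUTRAL_LOSS:
        raise ValueError("precursor must exceed the neutral loss")
    sats: list[tuple[int, str]] = []
    if offsets.isotopomer_1:
        sats.append((precursor_mz + round(offsets.isotopomer_1), "M+1"))
    if offsets.isotopomer_2:
        sats.append((precursor_mz + round(offsets.isotopomer_2), "M+2"))
    if offsets.sodium_minus_H:
        sats.append((precursor_mz + offsets.sodium_unit, "Na adduct"))
    if offsets.potassium_minus_H:
        sats.append((precursor_mz + offsets.potassium_unit, "K adduct"))
    return sats


def library_to_tsv(entries: Iterable[StandardEntry], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "name": e.name,
                "abbreviation": e.abbreviation,
                "precursor_mz": e.precursor_mz,
                "product_mz": e.product_mz,
                "rt_min": e.retention_time,
                "role": e.role,
                "alt_product_mz": e.alt_product_mz,
            }
            for e in entries
        ]
    ).to_csv(path, sep="\t", index=False)


def library_from_tsv(path: str | Path) -> list[StandardEntry]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for r in df.itertuples():
        rt = None if pd.isna(r.rt_min) else float(r.rt_min)
        alt = None
        if "alt_product_mz" in df.columns and not pd.isna(r.alt_product_mz):
            alt = int(r.alt_product_mz)
        out.append(
            StandardEntry(
                name=str(r.name),
                abbreviation=str(r.abbreviation),
                precursor_mz=int(r.precursor_mz),
                product_mz=int(r.product_mz),
                retention_time=rt,
                role=str(r.role),
                alt_product_mz=alt,
            )
        )
    return out
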