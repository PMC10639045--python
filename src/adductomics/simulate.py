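"""Seeded synthetic MRM data with ground truth.

The generator emulates the statistical structure of a stepped-MRM DNA
adductomics experiment so that every downstream stage (peak detection,
normalization, curation, quantification, statistics) can be exercised
and validated without instrument data:

- per-transition Gaussian elution peaks on a 0-24 min gradient;
- a dominant 5-MdC signal orders of magnitude above other species,
  matching its presence at ~1% of genomic dC;
- planted adducts with lognormal biological variation (default CV 22%)
  and multiplicative tissue, age, and sex effects;
- deterministic M+1/M+2 isotopomer and Na+/K+ salt satellites sharing
  the parent's retention time and peak shape;
- a dC-dimer ionization artifact (455->339) co-eluting with dC;
- blank and no-nuclease (intact DNA) control injections carrying only
  baseline noise, with no canonical-nucleoside UV signal;
- a UV channel whose four canonical areas scale with injected DNA mass.

Truth generation (abundances) and chromatogram rendering are separate
steps: :func:`simulate_cohort` builds the sample table, truth table and
UV channel; :func:`render_chromatograms` draws ion-count traces from
them. Statistical properties can be studied on the abundance layer
directly; peak-level code consumes the rendered traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from adductomics.design import CANONICAL_PRECURSORS, DEOXYRIBOSE_NEUTRAL_LOSS
from adductomics.library import DC_RETENTION_TIME

TISSUES = ("liver", "kidney", "brain", "heart")
SEXES = ("F", "M")

#: age fold-changes over the 1->26 month span, per validated species and
#: tissue, as established by targeted isotope-dilution measurements
DEFAULT_AGE_FOLDS: dict[str, dict[str, float]] = {
    "5-HMdC": {"liver": 2.8, "kidney": 1.7, "brain": 1.4, "heart": 1.0},
    "N2-CMdG": {"liver": 3.0, "heart": 1.5, "kidney": 1.0, "brain": 1.0},
    "8-Oxo-dG": {"liver": 1.8},
}

#: female/male abundance ratios for the sex-biased oxidized cytosine marks
DEFAULT_SEX_RATIOS: dict[str, dict[str, float]] = {
    "5-HMdC": {"heart": 1.5, "kidney": 1.5},
    "5-FdC": {"kidney": 1.5},
}

# named planted species: (key, precursor, rt_min, base normalized abundance)
_NAMED_PANEL: list[tuple[str, int, float, float]] = [
    ("5-MdC", 242, 3.60, 5.0e4),   # epigenetic mark, ~1% of dC: dominates
    ("5-HMdC", 258, 2.72, 120.0),
    ("5-FdC", 256, 3.10, 25.0),
    ("N2-CMdG", 326, 3.45, 40.0),
    ("1,N6-edA", 276, 2.93, 15.0),
    ("8-Oxo-dG", 284, 6.65, 60.0),
    ("3,N4-edC", 252, 4.20, 10.0),
    ("O6-MdG", 282, 6.00, 8.0),
    ("M1-dG", 304, 7.50, 6.0),
    ("Gh", 274, 2.20, 90.0),
]


@dataclass
class SimulationConfig:
    """Generator settings; defaults encode the study conditions."""

    tissues: Sequence[str] = TISSUES
    ages: Sequence[float] = (1.0, 5.0, 16.0, 26.0)  # months
    n_per_cell: int = 4          # animals per tissue x age x sex cell
    #: seed of the *biology* (unnamed species panel, retention times,
    #: tissue biases). Cohorts simulated with different sampling seeds
    #: but the same panel_seed measure the same underlying species, as
    #: two independent studies of the same organism would.
    panel_seed: int = 2024
    cv: float = 0.22             # lognormal biological CV
    n_unnamed: int = 40          # unnamed planted adduct transitions
    n_blanks: int = 2
    n_controls: int = 2
    # satellite areas as fractions of the parent area
    frac_m1: float = 0.15
    frac_m2: float = 0.02
    frac_na: float = 0.05
    frac_k: float = 0.02
    # species below this mean abundance emit no satellites (they would
    # fall below any realistic noise floor anyway)
    satellite_min_parent: float = 5.0
    artifact_abundance: float = 30.0  # dC dimer at dC retention time
    # chromatogram rendering
    time_max: float = 24.0       # min
    dt: float = 0.02             # min per sample point
    sigma_min: float = 0.05     # Gaussian peak sigma range, min
    sigma_max: float = 0.11
    noise_sd: float = 0.5        # baseline ion-count noise (0 = noiseless)
    # UV channel: canonical areas ~ genome composition x DNA mass
    dna_mass_ug: float = 10.0
    uv_per_ug: float = 2500.0    # UV area units per microgram of injected DNA
    gc_arm: float = 0.21         # dG and dC fractions (dA/dT get 0.29)
    uv_cv: float = 0.02          # injection-to-injection UV variability
    norm_scale: float = 1000.0   # normalized intensity = scale*area/UVsum
    # effect structure
    age_folds: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_AGE_FOLDS
    )
    sex_ratios: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_SEX_RATIOS
    )
    unnamed_tissue_sd: float = 0.5   # log-sd of per-tissue bias, unnamed species
    null_effects: bool = False       # force all tissue/age/sex effects to 1
    named_panel: Sequence[tuple[str, int, float, float]] = field(
        default_factory=lambda: list(_NAMED_PANEL)
    )

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if not self.named_panel and self.n_unnamed == 0:
            raise ValueError("adduct panel is empty")


@dataclass
class CohortData:
    """Output of :func:`simulate_cohort`."""

    meta: pd.DataFrame        # sample_id, cohort, tissue, age, sex, sample_type
    species: pd.DataFrame     # per planted species: transition, rt, class, parent
    abundance: pd.DataFrame   # species x sample true normalized abundance
    uv: pd.DataFrame          # sample x (dC, dT, dA, dG) canonical areas
    config: SimulationConfig
    seed: int

    def hydrolysate_ids(self) -> list[str]:
        return list(self.meta.loc[self.meta.sample_type == "hydrolysate", "sample_id"])


@dataclass
class ChromatogramSet:
    """Rendered ion-count traces per (sample, transition)."""

    time: np.ndarray
    traces: dict[tuple[str, tuple[int, int]], np.ndarray]
    uv: pd.DataFrame

    def transitions(self) -> list[tuple[int, int]]:
        return sorted({key[1] for key in self.traces})


def _lognormal_multiplier(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one lognormal noise with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _build_sample_table(config: SimulationConfig, cohort: str) -> pd.DataFrame:
    rows = []
    for tissue in config.tissues:
        for age in config.ages:
            for sex in SEXES:
                for i in range(config.n_per_cell):
                    rows.append(
                        {
                            "sample_id": f"{cohort}_{tissue}_a{age:g}_{sex}{i + 1}",
                            "cohort": cohort,
                            "tissue": tissue,
                            "age": age,
                            "sex": sex,
                            "sample_type": "hydrolysate",
                        }
                    )
    for i in range(config.n_controls):
        rows.append(
            {
                "sample_id": f"{cohort}_control{i + 1}",
                "cohort": cohort,
                "tissue": "none",
                "age": np.nan,
                "sex": "NA",
                "sample_type": "intact_control",
            }
        )
    for i in range(config.n_blanks):
        rows.append(
            {
                "sample_id": f"{cohort}_blank{i + 1}",
                "cohort": cohort,
                "tissue": "none",
                "age": np.nan,
                "sex": "NA",
                "sample_type": "blank",
            }
        )
    return pd.DataFrame(rows)


def _sample_unnamed_precursors(rng: np.random.Generator, config: SimulationConfig) -> list[int]:
    """Unnamed adduct precursors, unique and clear of canonicals.

    Small panels additionally stay clear of every satellite position of
    every planted species, so species never collide with satellites; a
    dense panel falls back to uniqueness only once strict spacing is
    exhausted (the mass range only holds a few dozen fully isolated
    species)."""
    if config.n_unnamed <= 0:
        return []
    reserved = set(CANONICAL_PRECURSORS)
    for _, prec, _, _ in config.named_panel:
        reserved.add(prec)
    reserved.add(455)  # artifact
    offsets = (0, 1, 2, 22, 38, -1, -2, -22, -38)
    taken = set(reserved)
    chosen: list[int] = []
    candidates = [int(m) for m in np.arange(225, 525)]
    rng.shuffle(candidates)
    for mz in candidates:
        if any(mz + o in taken or mz - o in taken for o in (0, 1, 2, 22, 38)):
            continue
        chosen.append(mz)
        for o in offsets:
            taken.add(mz + o)
        if len(chosen) >= config.n_unnamed:
            break
    if len(chosen) < config.n_unnamed:
        used = set(chosen) | reserved
        for mz in candidates:
            if mz in used:
                continue
            chosen.append(mz)
            used.add(mz)
            if len(chosen) >= config.n_unnamed:
                break
    if len(chosen) < config.n_unnamed:
        raise ValueError("mass range cannot hold that many unnamed adducts")
    return chosen


def _age_factor(fold: float, age: float, ages: Sequence[float]) -> float:
    a0, a1 = min(ages), max(ages)
    if a1 == a0 or fold == 1.0:
        return 1.0
    return float(fold ** ((age - a0) / (a1 - a0)))


def simulate_cohort(config: SimulationConfig, seed: int, cohort: str = "group1") -> CohortData:
    """Generate one cohort: sample table, planted truth, UV channel.

    The abundance table holds true *normalized* intensities (the scale
    the curation thresholds are defined on). Identical seed and config
    give identical output.
    """
    rng = np.random.default_rng(seed)
    panel_rng = np.random.default_rng(config.panel_seed)
    meta = _build_sample_table(config, cohort)
    hydro = meta[meta.sample_type == "hydrolysate"]

    # --- species panel (biology: drawn from panel_seed, shared across
    # cohorts simulated with different sampling seeds) ------------------
    rows = []
    for key, prec, rt, base in config.named_panel:
        cls = "epigenetic" if key in ("5-MdC", "5-HMdC", "5-FdC") else "adduct"
        rows.append((key, None, cls, prec, rt, base))
    for j, prec in enumerate(_sample_unnamed_precursors(panel_rng, config)):
        rt = float(panel_rng.uniform(1.5, 16.0))
        base = float(panel_rng.lognormal(np.log(20.0), 1.0))
        rows.append((f"adduct_{prec}", None, "adduct", prec, rt, base))
    if config.artifact_abundance > 0:
        rows.append(("dC_dimer", None, "artifact", 455, DC_RETENTION_TIME, config.artifact_abundance))

    species = pd.DataFrame(
        rows, columns=["key", "parent", "species_class", "precursor_mz", "rt", "base"]
    )
    species["product_mz"] = species.precursor_mz - DEOXYRIBOSE_NEUTRAL_LOSS
    species.loc[species.species_class == "artifact", "product_mz"] = 339
    species["sigma"] = panel_rng.uniform(config.sigma_min, config.sigma_max, len(species))

    # --- per-species effect parameters --------------------------------
    tissue_mult: dict[str, dict[str, float]] = {}
    age_fold: dict[str, dict[str, float]] = {}
    sex_ratio: dict[str, dict[str, float]] = {}
    for r in species.itertuples():
        if config.null_effects:
            tissue_mult[r.key] = {t: 1.0 for t in config.tissues}
            age_fold[r.key] = {t: 1.0 for t in config.tissues}
            sex_ratio[r.key] = {t: 1.0 for t in config.tissues}
            continue
        if r.key.startswith("adduct_"):
            tm = {
                t: float(panel_rng.lognormal(0.0, config.unnamed_tissue_sd))
                for t in config.tissues
            }
        else:
            tm = {t: 1.0 for t in config.tissues}
        tissue_mult[r.key] = tm
        af = dict(config.age_folds.get(r.key, {}))
        age_fold[r.key] = {t: float(af.get(t, 1.0)) for t in config.tissues}
        sr = dict(config.sex_ratios.get(r.key, {}))
        sex_ratio[r.key] = {t: float(sr.get(t, 1.0)) for t in config.tissues}

    # --- abundances ----------------------------------------------------
    sample_ids = list(meta.sample_id)
    abundance = pd.DataFrame(0.0, index=species.key, columns=sample_ids)
    parent_rows = species[species.species_class != "salt"]
    for r in parent_rows.itertuples():
        vals = np.zeros(len(hydro))
        noise = _lognormal_multiplier(rng, config.cv, len(hydro))
        for i, s in enumerate(hydro.itertuples()):
            mult = tissue_mult[r.key][s.tissue]
            mult *= _age_factor(age_fold[r.key][s.tissue], s.age, config.ages)
            ratio = sex_ratio[r.key][s.tissue]
            mult *= np.sqrt(ratio) if s.sex == "F" else 1.0 / np.sqrt(ratio)
            vals[i] = r.base * mult * noise[i]
        abundance.loc[r.key, list(hydro.sample_id)] = vals

    # --- deterministic satellites --------------------------------------
    sat_fracs = [
        ("M+1", 1, config.frac_m1),
        ("M+2", 2, config.frac_m2),
        ("Na", 22, config.frac_na),
        ("K", 38, config.frac_k),
    ]
    sat_rows = []
    sat_abund = {}
    for r in species.itertuples():
        if r.species_class == "artifact":
            continue
        if r.base < config.satellite_min_parent:
            continue
        for label, off, frac in sat_fracs:
            if frac <= 0:
                continue
            key = f"{r.key}:{label}"
            cls = "isotopomer" if label.startswith("M+") else "salt"
            sat_rows.append(
                (key, r.key, cls, r.precursor_mz + off,
                 r.rt, r.base * frac, r.product_mz + off, r.sigma)
            )
            sat_abund[key] = abundance.loc[r.key] * frac
    if sat_rows:
        sats = pd.DataFrame(
            sat_rows,
            columns=["key", "parent", "species_class", "precursor_mz",
                     "rt", "base", "product_mz", "sigma"],
        )
        species = pd.concat([species, sats], ignore_index=True)
        abundance = pd.concat(
            [abundance, pd.DataFrame(sat_abund).T[sample_ids]], axis=0
        )

    species = species.set_index("key", drop=False).rename_axis(None)

    # --- UV channel -----------------------------------------------------
    arms = {"dC": config.gc_arm, "dG": config.gc_arm,
            "dA": 0.5 - config.gc_arm, "dT": 0.5 - config.gc_arm}
    uv_rows = {}
    for s in meta.itertuples():
        if s.sample_type == "hydrolysate":
            total = config.dna_mass_ug * config.uv_per_ug * float(
                _lognormal_multiplier(rng, config.uv_cv, 1)[0]
            )
            uv_rows[s.sample_id] = {k: total * f for k, f in arms.items()}
        else:
            # intact DNA is not hydrolyzed and blanks have no DNA:
            # neither yields free canonical nucleosides at the detector
            uv_rows[s.sample_id] = {k: 0.0 for k in arms}
    uv = pd.DataFrame(uv_rows).T[["dC", "dT", "dA", "dG"]]
    uv.index.name = "sample_id"

    return CohortData(meta=meta, species=species, abundance=abundance,
                      uv=uv, config=config, seed=seed)


def simulate_pooled_discovery(cohort: CohortData) -> CohortData:
    """Equal-mass pooling: per tissue, one hydrolysate whose species
    abundances are the across-sample means, plus the cohort's blank and
    intact-control injections."""
    meta = cohort.meta
    hydro = meta[meta.sample_type == "hydrolysate"]
    pool_rows = []
    pool_abund = {}
    pool_uv = {}
    for tissue, grp in hydro.groupby("tissue", sort=False):
        sid = f"{meta.cohort.iloc[0]}_pool_{tissue}"
        pool_rows.append(
            {"sample_id": sid, "cohort": meta.cohort.iloc[0], "tissue": tissue,
             "age": np.nan, "sex": "NA", "sample_type": "hydrolysate"}
        )
        pool_abund[sid] = cohort.abundance[list(grp.sample_id)].mean(axis=1)
        pool_uv[sid] = cohort.uv.loc[list(grp.sample_id)].mean(axis=0)
    ctrl = meta[meta.sample_type != "hydrolysate"]
    pooled_meta = pd.concat([pd.DataFrame(pool_rows), ctrl], ignore_index=True)
    abund = pd.DataFrame(pool_abund)
    for sid in ctrl.sample_id:
        abund[sid] = cohort.abundance[sid]
    uv = pd.DataFrame(pool_uv).T
    uv = pd.concat([uv, cohort.uv.loc[list(ctrl.sample_id)]])
    uv.index.name = "sample_id"
    return CohortData(meta=pooled_meta, species=cohort.species,
                      abundance=abund[list(pooled_meta.sample_id)],
                      uv=uv, config=cohort.config, seed=cohort.seed)


def render_chromatograms(
    cohort: CohortData,
    sample_ids: Sequence[str] | None = None,
    rng_seed_offset: int = 10_000,
) -> ChromatogramSet:
    """Draw Gaussian ion-count traces for every planted species.

    Raw MS peak area is reconstructed from the true normalized abundance
    as ``area = abundance * uv_sum / norm_scale`` so that UV-based
    normalization recovers the truth. Control and blank channels carry
    baseline noise only. Rendering is deterministic given the cohort's
    seed (a fixed offset decorrelates it from truth generation).
    """
    config = cohort.config
    rng = np.random.default_rng(cohort.seed + rng_seed_offset)
    time = np.arange(0.0, config.time_max + config.dt / 2, config.dt)
    if sample_ids is None:
        sample_ids = list(cohort.meta.sample_id)
    mean_uv_sum = cohort.uv.sum(axis=1)
    positive = mean_uv_sum[mean_uv_sum > 0]
    fallback_uv = float(positive.mean()) if len(positive) else config.norm_scale

    transitions = sorted(
        {(int(r.precursor_mz), int(r.product_mz)) for r in cohort.species.itertuples()}
    )
    traces: dict[tuple[str, tuple[int, int]], np.ndarray] = {}
    meta_by_id = cohort.meta.set_index("sample_id")
    for sid in sample_ids:
        uv_sum = float(cohort.uv.loc[sid].sum())
        denom = uv_sum if uv_sum > 0 else fallback_uv
        is_sample = meta_by_id.loc[sid, "sample_type"] == "hydrolysate"
        for trans in transitions:
            y = np.zeros_like(time)
            if is_sample:
                hits = cohort.species[
                    (cohort.species.precursor_mz == trans[0])
                    & (cohort.species.product_mz == trans[1])
                ]
                for r in hits.itertuples():
                    abund = float(cohort.abundance.loc[r.key, sid])
                    if abund <= 0:
                        continue
                    # area is in counts*s; the trace lives on a minute
                    # grid, so divide by 60 before shaping the Gaussian
                    area = abund * denom / config.norm_scale
                    amp = (area / 60.0) / (r.sigma * np.sqrt(2 * np.pi))
                    y = y + amp * np.exp(-0.5 * ((time - r.rt) / r.sigma) ** 2)
            if config.noise_sd > 0:
                y = y + rng.normal(0.0, config.noise_sd, len(time))
            y = np.clip(y, 0.0, None)
            if y.max() > 0:
                traces[(sid, trans)] = y
    return ChromatogramSet(time=time, traces=traces, uv=cohort.uv.loc[list(sample_ids)])
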