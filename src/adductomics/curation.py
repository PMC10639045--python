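"""The signal-curation decision tree.

Raw stepped-MRM signals are a mixture of genuine nucleoside adducts,
in-source satellites of abundant species, contaminants, and noise.
Seven filters reduce them to a basis set of putative DNA adducts:

  i.   the monitored fragmentation must correspond to loss of
       2'-deoxyribose (structural for a -116 design);
  ii.  the signal is at least 3x the average background in at least one
       tissue and detected in all individual samples of that tissue;
  iii. the signal is absent from no-DNA blanks and no-nuclease (intact
       DNA) controls;
  iv.  Na+/K+ salt satellites (+22/+38 Da of a retained signal at the
       same retention time) are removed;
  v.   M+1/M+2 isotopomer satellites of a stronger signal (same RT,
       matching peak shape, minority intensity) are removed;
  vi.  known artifacts (e.g. the dC dimer at 455->339 co-eluting with
       dC) are removed;
  vii. signals with normalized intensity <= 2.0 are removed unless
       shared between two independent cohorts.

Rules are applied in the order iii -> ii -> iv -> v -> vi -> vii (after
the structural rule i): control/blank presence must precede intensity
comparisons, and the satellite rules only reference signals that
survive the control filter. Each removed signal records its first
failing rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from adductomics.library import BlacklistEntry, builtin_blacklist
from adductomics.peaks import AlignedSignals

RULE_NAMES = {
    "i": "fragment_ok",
    "ii": "above_3x_background_and_in_all_samples",
    "iii": "absent_in_controls",
    "iv": "not_salt",
    "v": "not_isotopomer",
    "vi": "not_known_artifact",
    "vii": "intensity_or_shared",
}
RULE_ORDER = ("i", "iii", "ii", "iv", "v", "vi", "vii")
SALT_OFFSETS = (22, 38)
ISOTOPOMER_OFFSETS = (1, 2)


@dataclass
class CurationParams:
    rt_tol: float = 0.2
    min_fold_background: float = 3.0
    min_intensity: float = 2.0
    shape_corr_min: float = 0.9
    satellite_max_frac: float = 0.5
    neutral_loss: int = 116
    #: absolute normalized intensity above which a signal counts as
    #: "present" in a blank/control channel (a detected baseline noise
    #: blip in a blank is far below this; a contaminant is far above)
    control_presence_threshold: float = 0.5
    #: floor for the per-transition blank background when blanks are clean
    blank_floor: float = 0.05


@dataclass
class CurationResult:
    basis: pd.DataFrame   # surviving species with per-tissue means
    flags: pd.DataFrame   # one row per input signal, all seven flags
    params: CurationParams

    @property
    def n_kept(self) -> int:
        return len(self.basis)

    def removal_counts(self) -> pd.Series:
        removed = self.flags[~self.flags.final_keep]
        return removed.removal_reason.value_counts()


def _sample_partition(meta: pd.DataFrame):
    hydro = list(meta.loc[meta.sample_type == "hydrolysate", "sample_id"])
    controls = list(meta.loc[meta.sample_type == "intact_control", "sample_id"])
    blanks = list(meta.loc[meta.sample_type == "blank", "sample_id"])
    if not blanks or not controls:
        raise ValueError("aligned matrix must include blank and intact-control columns")
    return hydro, controls, blanks


def _shape_correlation(a: np.ndarray | None, b: np.ndarray | None) -> float | None:
    if a is None or b is None:
        return None
    if np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def curate(
    aligned: AlignedSignals,
    meta: pd.DataFrame,
    blacklist: Sequence[BlacklistEntry] | None = None,
    params: CurationParams | None = None,
    other_cohort_keys: Iterable[tuple[int, int, float]] | None = None,
    cohort: str = "group1",
) -> CurationResult:
    """Apply the seven-rule decision tree to an aligned signal matrix.

    ``other_cohort_keys`` holds (precursor, product, rt) keys of the
    second cohort's pre-rule-vii survivors; a weak signal (rule vii) is
    kept when it matches one of them. Without them rule vii removes all
    signals at or below the intensity threshold.
    """
    params = params or CurationParams()
    blacklist = builtin_blacklist() if blacklist is None else list(blacklist)
    table = aligned.table
    hydro, controls, blanks = _sample_partition(meta)
    # a channel with no detected peaks at all (e.g. a clean blank) is
    # simply absent from the aligned matrix; treat it as all-NaN
    missing = [s for s in hydro + controls + blanks if s not in table.columns]
    if missing:
        table = table.copy()
        for s in missing:
            table[s] = np.nan
    tissue_of = meta.set_index("sample_id")["tissue"].to_dict()
    tissues = [t for t in meta.tissue.unique() if t != "none"]

    if len(table) == 0:
        empty_flags = pd.DataFrame(
            columns=[RULE_NAMES[k] for k in RULE_ORDER] + ["final_keep", "removal_reason"]
        )
        basis = pd.DataFrame(
            columns=["precursor_mz", "product_mz", "rt", "cohort"]
            + [f"mean_{t}" for t in tissues]
        )
        return CurationResult(basis=basis, flags=empty_flags, params=params)

    filled = table[hydro + controls + blanks].fillna(0.0)
    presence_thr = params.control_presence_threshold

    n = len(table)
    flags = pd.DataFrame(
        {RULE_NAMES[k]: np.ones(n, dtype=bool) for k in RULE_ORDER},
        index=table.index,
    )

    # per-tissue means (NaN treated as non-detection, i.e. zero signal)
    tissue_cols = {t: [s for s in hydro if tissue_of[s] == t] for t in tissues}
    tissue_means = pd.DataFrame(
        {t: filled[cols].mean(axis=1) for t, cols in tissue_cols.items()}
    )
    hydro_mean = filled[hydro].mean(axis=1)

    # rule i: fragment consistent with 2'-deoxyribose loss
    flags[RULE_NAMES["i"]] = (
        table.precursor_mz - table.product_mz == params.neutral_loss
    ).to_numpy()

    # rule iii: absent from blank and no-nuclease control channels
    ctrl_max = filled[controls + blanks].max(axis=1)
    flags[RULE_NAMES["iii"]] = (ctrl_max < presence_thr).to_numpy()

    # rule ii: >= 3x background and detected in all samples of >= 1 tissue
    blank_mean = filled[blanks].mean(axis=1)
    background = np.maximum(blank_mean.to_numpy(), params.blank_floor)
    ok_ii = np.zeros(n, dtype=bool)
    detected = table[hydro].notna() & (table[hydro].fillna(0.0) > 0)
    for t, cols in tissue_cols.items():
        if not cols:
            continue
        strong = tissue_means[t].to_numpy() >= params.min_fold_background * background
        complete = detected[cols].all(axis=1).to_numpy()
        ok_ii |= strong & complete
    flags[RULE_NAMES["ii"]] = ok_ii

    # parent pool for the satellite rules: survivors of rules i, iii, ii
    pool = flags[RULE_NAMES["i"]] & flags[RULE_NAMES["iii"]] & flags[RULE_NAMES["ii"]]
    pool_idx = table.index[pool]
    prec = table.precursor_mz
    rt = table.rt

    def _satellite_of(sig, offsets, need_stronger: bool, check_shape: bool) -> bool:
        for parent in pool_idx:
            if parent == sig:
                continue
            off = prec[sig] - prec[parent]
            if off not in offsets:
                continue
            if abs(rt[sig] - rt[parent]) > params.rt_tol:
                continue
            if need_stronger:
                if hydro_mean[parent] <= 0:
                    continue
                frac = hydro_mean[sig] / hydro_mean[parent]
                if not (frac < params.satellite_max_frac):
                    continue
                if check_shape:
                    corr = _shape_correlation(
                        aligned.shapes.get(sig), aligned.shapes.get(parent)
                    )
                    if corr is not None and corr < params.shape_corr_min:
                        continue
            return True
        return False

    for sig in table.index:
        if _satellite_of(sig, SALT_OFFSETS, need_stronger=False, check_shape=False):
            flags.loc[sig, RULE_NAMES["iv"]] = False
        if _satellite_of(sig, ISOTOPOMER_OFFSETS, need_stronger=True, check_shape=True):
            flags.loc[sig, RULE_NAMES["v"]] = False

    # rule vi: known-artifact blacklist (transition + retention time)
    for e in blacklist:
        hit = (table.precursor_mz == e.precursor_mz) & (table.product_mz == e.product_mz)
        if e.retention_time is not None:
            hit &= (table.rt - e.retention_time).abs() <= params.rt_tol
        flags.loc[hit, RULE_NAMES["vi"]] = False

    # rule vii: weak signals are dropped unless shared with the other cohort
    peak_tissue_mean = tissue_means.max(axis=1) if tissues else hydro_mean
    weak = peak_tissue_mean <= params.min_intensity
    shared = np.zeros(n, dtype=bool)
    if other_cohort_keys is not None:
        keys = list(other_cohort_keys)
        for i, sig in enumerate(table.index):
            for kp, kq, krt in keys:
                if (
                    kp == table.precursor_mz[sig]
                    and kq == table.product_mz[sig]
                    and abs(krt - table.rt[sig]) <= params.rt_tol
                ):
                    shared[i] = True
                    break
    flags[RULE_NAMES["vii"]] = (~weak.to_numpy()) | shared

    # final verdict and first-failing reason in evaluation order
    flags["final_keep"] = np.ones(n, dtype=bool)
    reasons = []
    for sig in table.index:
        reason = ""
        for k in RULE_ORDER:
            if not flags.loc[sig, RULE_NAMES[k]]:
                reason = k
                break
        reasons.append(reason)
        if reason:
            flags.loc[sig, "final_keep"] = False
    flags["removal_reason"] = reasons

    kept = table[flags.final_keep]
    basis = kept[["precursor_mz", "product_mz", "rt"]].copy()
    basis["cohort"] = cohort
    for t in tissues:
        basis[f"mean_{t}"] = tissue_means.loc[kept.index, t]
    return CurationResult(basis=basis, flags=flags, params=params)


def pre_vii_survivor_keys(
    aligned: AlignedSignals,
    meta: pd.DataFrame,
    blacklist: Sequence[BlacklistEntry] | None = None,
    params: CurationParams | None = None,
) -> list[tuple[int, int, float]]:
    """Keys of signals surviving rules i-vi (the "shared" reference for
    rule vii is evaluated on each cohort's pre-rule-vii survivors)."""
    res = curate(
        aligned, meta, blacklist=blacklist,
        params=params, other_cohort_keys=None,
    )
    f = res.flags
    ok = np.ones(len(f), dtype=bool)
    for k in ("i", "iii", "ii", "iv", "v", "vi"):
        ok &= f[RULE_NAMES[k]].to_numpy()
    tab = aligned.table[ok]
    return [
        (int(r.precursor_mz), int(r.product_mz), float(r.rt))
        for r in tab.itertuples()
    ]


def curate_two_cohorts(
    aligned1: AlignedSignals,
    meta1: pd.DataFrame,
    aligned2: AlignedSignals,
    meta2: pd.DataFrame,
    blacklist: Sequence[BlacklistEntry] | None = None,
    params: CurationParams | None = None,
) -> tuple[CurationResult, CurationResult, "MergeResult"]:
    """Curate two independent cohorts with mutual rule-vii sharing, then
    merge the surviving basis sets."""
    params = params or CurationParams()
    keys1 = pre_vii_survivor_keys(aligned1, meta1, blacklist, params)
    keys2 = pre_vii_survivor_keys(aligned2, meta2, blacklist, params)
    res1 = curate(aligned1, meta1, blacklist, params, other_cohort_keys=keys2, cohort="group1")
    res2 = curate(aligned2, meta2, blacklist, params, other_cohort_keys=keys1, cohort="group2")
    merged = merge_cohorts(res1.basis, res2.basis, rt_tol=params.rt_tol)
    return res1, res2, merged


@dataclass
class MergeResult:
    union: pd.DataFrame
    n_set1: int
    n_set2: int
    n_shared: int

    @property
    def n_union(self) -> int:
        return len(self.union)

    @property
    def shared_fraction(self) -> float:
        return self.n_shared / self.n_union if self.n_union else 0.0


def merge_cohorts(
    set1: pd.DataFrame, set2: pd.DataFrame, rt_tol: float = 0.2
) -> MergeResult:
    """Union of two curated basis sets keyed by transition + RT bin.

    Each species of set1 is matched to the nearest same-transition
    species of set2 within ``rt_tol``; matched pairs count once
    (membership "both"), so |union| = |set1| + |set2| - |shared|.
    """
    used2: set = set()
    rows = []
    for i1, r1 in set1.iterrows():
        cand = set2[
            (set2.precursor_mz == r1.precursor_mz)
            & (set2.product_mz == r1.product_mz)
            & (~set2.index.isin(used2))
        ]
        if len(cand):
            drt = (cand.rt - r1.rt).abs()
            j = drt.idxmin()
            if drt[j] <= rt_tol:
                used2.add(j)
                row = r1.to_dict()
                row["membership"] = "both"
                rows.append(row)
                continue
        row = r1.to_dict()
        row["membership"] = "group1"
        rows.append(row)
    for i2, r2 in set2.iterrows():
        if i2 in used2:
            continue
        row = r2.to_dict()
        row["membership"] = "group2"
        rows.append(row)
    union = pd.DataFrame(rows)
    n_shared = len(used2)
    return MergeResult(union=union, n_set1=len(set1), n_set2=len(set2), n_shared=n_shared)


def tissue_sets(
    basis: pd.DataFrame, threshold: float = 2.0, tissues: Sequence[str] | None = None
) -> dict:
    """Per-tissue detection sets and all Venn region counts.

    A species is "detected" in a tissue when its mean normalized
    intensity there is at or above ``threshold``. For four tissues the
    15 non-empty membership regions are returned as a dict keyed by
    frozenset of tissue names, alongside the shared-in-all count.
    """
    if tissues is None:
        tissues = [c[5:] for c in basis.columns if c.startswith("mean_")]
    membership = {}
    for t in tissues:
        col = f"mean_{t}"
        membership[t] = set(basis.index[basis[col] >= threshold]) if col in basis else set()
    regions: dict[frozenset, int] = {}
    from itertools import combinations

    for k in range(1, len(tissues) + 1):
        for combo in combinations(tissues, k):
            inside = set(basis.index)
            for t in combo:
                inside &= membership[t]
            for t in tissues:
                if t not in combo:
                    inside -= membership[t]
            regions[frozenset(combo)] = len(inside)
    shared_in_all = regions.get(frozenset(tissues), 0)
    return {
        "tissues": list(tissues),
        "sets": membership,
        "regions": regions,
        "shared_in_all": shared_in_all,
    }
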