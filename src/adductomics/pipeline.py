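"""End-to-end pipeline: design -> simulate -> detect -> normalize ->
curate -> annotate -> statistics, with every stage writing its table.

The discovery phase curates pooled per-tissue injections from two
independent synthetic cohorts; the targeted phase then re-measures the
curated species in the individual samples of cohort 1 and runs the
statistical layer (adduct loads, sex and age tests, clustering).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from adductomics import __version__
from adductomics.curation import CurationParams, curate_two_cohorts
from adductomics.design import generate_stepped_mrm
from adductomics.io import config_hash, write_table
from adductomics.library import StandardEntry, builtin_library, lookup_transition
from adductomics.peaks import detect_all, match_across_samples, normalize_signals
from adductomics.simulate import (
    SimulationConfig,
    render_chromatograms,
    simulate_cohort,
    simulate_pooled_discovery,
)
from adductomics.stats import adduct_load, age_tests, cluster_profiles, sex_tests

log = logging.getLogger("adductomics")


def annotate_basis_set(
    basis: pd.DataFrame,
    library: list[StandardEntry] | None = None,
    mz_tol: int = 0,
    rt_tol: float = 0.2,
) -> pd.DataFrame:
    """Attach standard identities to curated species.

    A species matching a library transition *and* retention time (where
    the library has one) is "validated"; a transition-only match is
    "consistent with" (all isobaric candidates reported); anything else
    is "unknown". ``mz_tol`` is in integer Da (0 = exact unit mass).
    """
    library = builtin_library() if library is None else library
    labels = []
    for r in basis.itertuples():
        matches = []
        for dm in range(-mz_tol, mz_tol + 1):
            matches.extend(
                lookup_transition(library, int(r.precursor_mz) + dm, int(r.product_mz) + dm)
            )
        if not matches:
            labels.append("unknown")
            continue
        validated = [
            e for e in matches
            if e.retention_time is not None and abs(e.retention_time - r.rt) <= rt_tol
        ]
        if validated:
            labels.append("validated: " + " | ".join(e.abbreviation for e in validated))
        else:
            consistent = [e for e in matches if e.retention_time is None]
            if consistent:
                labels.append(
                    "consistent with: " + " | ".join(e.abbreviation for e in consistent)
                )
            else:
                labels.append("unknown")
    out = basis.copy()
    out["annotation"] = labels
    return out


@dataclass
class PipelineConfig:
    """Full configuration of a demo run; serializable to/from YAML."""

    seed: int = 1
    outdir: str = "adductomics_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    min_snr: float = 5.0
    min_width: float = 0.05
    curation: CurationParams = field(default_factory=CurationParams)
    variance_threshold: float = 0.80
    run_stats: bool = True

    @classmethod
    def demo(cls, seed: int = 1, outdir: str = "adductomics_run") -> "PipelineConfig":
        """A desk-scale demo: 4 tissues, 2 ages, 2 per cell, 8 unnamed
        species — small enough to run in seconds yet exercising every
        stage."""
        sim = SimulationConfig(ages=(1.0, 26.0), n_per_cell=2, n_unnamed=8)
        return cls(seed=seed, outdir=outdir, simulation=sim)


def _species_matrix(cohort, basis: pd.DataFrame, rt_tol: float) -> pd.DataFrame:
    """Targeted re-measurement: true per-sample normalized intensities of
    the curated species (matched by transition + RT) in cohort 1's
    individual hydrolysate samples."""
    hydro = cohort.hydrolysate_ids()
    rows = {}
    for r in basis.itertuples():
        hits = cohort.species[
            (cohort.species.precursor_mz == r.precursor_mz)
            & (cohort.species.product_mz == r.product_mz)
            & ((cohort.species.rt - r.rt).abs() <= rt_tol)
        ]
        if len(hits) == 0:
            continue
        key = hits.key.iloc[0]
        rows[key] = cohort.abundance.loc[hits.key, hydro].sum(axis=0)
    return pd.DataFrame(rows).T


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain and write all tables under ``outdir``.

    Returns a dict of the in-memory stage outputs. A stage failure
    propagates with the failing stage named; earlier tables remain on
    disk.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta_block = {
        "tool": f"adductomics {__version__}",
        "seed": config.seed,
        "config": config_hash(config.simulation),
    }
    results: dict = {}
    stage = "design"
    try:
        design = generate_stepped_mrm()
        write_table(design.to_frame(), out / "transitions.tsv", meta_block)
        log.info("design: %d transitions", len(design))
        results["design"] = design

        stage = "simulate"
        sim = config.simulation
        cohort1 = simulate_cohort(sim, seed=config.seed, cohort="group1")
        cohort2 = simulate_cohort(sim, seed=config.seed + 1, cohort="group2")
        results["cohort1"], results["cohort2"] = cohort1, cohort2
        write_table(cohort1.meta, out / "samples_group1.tsv", meta_block)
        write_table(
            cohort1.species.drop(columns=["sigma"]), out / "truth_group1.tsv", meta_block
        )
        write_table(cohort1.uv.reset_index(), out / "uv_group1.tsv", meta_block)

        stage = "detect"
        aligned = {}
        for name, cohort in (("group1", cohort1), ("group2", cohort2)):
            pooled = simulate_pooled_discovery(cohort)
            chrom = render_chromatograms(pooled)
            peaks = detect_all(chrom, min_snr=config.min_snr, min_width=config.min_width)
            log.info("%s: %d peaks detected in pooled discovery", name, len(peaks))
            stage = "normalize"
            uv_sums = pooled.uv.sum(axis=1)
            fallback = float(uv_sums[uv_sums > 0].mean())
            norm = normalize_signals(
                peaks, pooled.uv, scale=sim.norm_scale, fallback_uv_sum=fallback
            )
            write_table(
                norm.drop(columns=["shape"]), out / f"signals_{name}.tsv", meta_block
            )
            stage = "curate"
            aligned[name] = (match_across_samples(norm, rt_tol=config.curation.rt_tol),
                             pooled.meta)

        res1, res2, merged = curate_two_cohorts(
            aligned["group1"][0], aligned["group1"][1],
            aligned["group2"][0], aligned["group2"][1],
            params=config.curation,
        )
        results["curation"] = (res1, res2, merged)
        log.info(
            "curation: %d + %d species, %d shared, %d union",
            merged.n_set1, merged.n_set2, merged.n_shared, merged.n_union,
        )
        for name, res in (("group1", res1), ("group2", res2)):
            write_table(
                res.flags.reset_index(names="signal_id"),
                out / f"curation_flags_{name}.tsv", meta_block,
            )

        stage = "annotate"
        basis = annotate_basis_set(merged.union, rt_tol=config.curation.rt_tol)
        results["basis"] = basis
        write_table(basis, out / "basis_set.tsv", meta_block)

        if not config.run_stats:
            return results

        stage = "stats"
        matrix = _species_matrix(cohort1, basis, rt_tol=config.curation.rt_tol)
        results["matrix"] = matrix
        write_table(matrix.reset_index(names="species"), out / "adduct_matrix.tsv", meta_block)
        loads = adduct_load(matrix, cohort1.meta)
        results["loads"] = loads
        write_table(loads.reset_index(names="tissue"), out / "adduct_load.tsv", meta_block)
        stats_rows = []
        for tissue in [t for t in cohort1.meta.tissue.unique() if t != "none"]:
            sex = sex_tests(matrix, cohort1.meta, tissue)
            age = age_tests(matrix, cohort1.meta, tissue)
            t = sex.table.join(age[["p_value", "fold_change"]], rsuffix="_age")
            t.insert(0, "tissue", tissue)
            stats_rows.append(t)
        stats_table = pd.concat(stats_rows)
        results["stats"] = stats_table
        write_table(
            stats_table.reset_index(names="species"), out / "stats_by_tissue.tsv", meta_block
        )
        shared = basis[basis.membership == "both"] if "membership" in basis else basis
        shared_matrix = _species_matrix(cohort1, shared, rt_tol=config.curation.rt_tol)
        if len(shared_matrix) >= 2 and shared_matrix.shape[1] >= 3:
            clust = cluster_profiles(
                shared_matrix, variance_threshold=config.variance_threshold,
                seed=config.seed,
            )
            results["clustering"] = clust
            write_table(
                pd.DataFrame(
                    {"sample_id": clust.sample_ids, "cluster": clust.labels}
                ),
                out / "clusters.tsv", meta_block,
            )
        return results
    except Exception as err:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
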