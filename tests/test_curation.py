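"""Curation decision tree vs an exhaustive brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from adductomics.curation import (
    CurationParams,
    curate,
    merge_cohorts,
    tissue_sets,
)
from conftest import make_aligned, make_meta

PARAMS = CurationParams()


# --------------------------------------------------------------------------
# independent oracle: evaluates all seven predicates exhaustively on plain
# Python structures, with no shared code with the implementation
# --------------------------------------------------------------------------

def oracle_curate(signals, meta, params=PARAMS, blacklist=((455, 339, 1.80),),
                  other_keys=()):
    """signals: list of dicts with keys precursor, product, rt and a
    values dict {sample_id: intensity or None}. Returns (kept ids,
    first-failing rule per removed id)."""
    hydro = [r["sample_id"] for _, r in meta.iterrows() if r["sample_type"] == "hydrolysate"]
    ctrl = [r["sample_id"] for _, r in meta.iterrows()
            if r["sample_type"] in ("intact_control", "blank")]
    blanks = [r["sample_id"] for _, r in meta.iterrows() if r["sample_type"] == "blank"]
    tissue = {r["sample_id"]: r["tissue"] for _, r in meta.iterrows()}
    tissues = sorted({tissue[s] for s in hydro})

    def val(sig, sid):
        v = sig["values"].get(sid)
        return 0.0 if v is None else v

    def hydro_mean(sig):
        return sum(val(sig, s) for s in hydro) / len(hydro)

    def tissue_mean(sig, t):
        cols = [s for s in hydro if tissue[s] == t]
        return sum(val(sig, s) for s in cols) / len(cols)

    def rule_i(sig):
        return sig["precursor"] - sig["product"] == params.neutral_loss

    def rule_iii(sig):
        return all(val(sig, s) < params.control_presence_threshold for s in ctrl)

    def rule_ii(sig):
        bg = max(sum(val(sig, s) for s in blanks) / len(blanks), params.blank_floor)
        for t in tissues:
            cols = [s for s in hydro if tissue[s] == t]
            strong = tissue_mean(sig, t) >= params.min_fold_background * bg
            complete = all(sig["values"].get(s) not in (None, 0) for s in cols)
            if strong and complete:
                return True
        return False

    pool = [s for s in signals if rule_i(s) and rule_iii(s) and rule_ii(s)]

    def rule_iv(sig):
        for p in pool:
            if p is sig:
                continue
            if sig["precursor"] - p["precursor"] in (22, 38) \
                    and abs(sig["rt"] - p["rt"]) <= params.rt_tol:
                return False
        return True

    def rule_v(sig):
        for p in pool:
            if p is sig:
                continue
            if sig["precursor"] - p["precursor"] not in (1, 2):
                continue
            if abs(sig["rt"] - p["rt"]) > params.rt_tol:
                continue
            pm = hydro_mean(p)
            if pm <= 0:
                continue
            if hydro_mean(sig) / pm < params.satellite_max_frac:
                return False
        return True

    def rule_vi(sig):
        for bp, bq, brt in blacklist:
            if sig["precursor"] == bp and sig["product"] == bq:
                if brt is None or abs(sig["rt"] - brt) <= params.rt_tol:
                    return False
        return True

    def rule_vii(sig):
        peak = max(tissue_mean(sig, t) for t in tissues)
        if peak > params.min_intensity:
            return True
        return any(
            kp == sig["precursor"] and kq == sig["product"]
            and abs(krt - sig["rt"]) <= params.rt_tol
            for kp, kq, krt in other_keys
        )

    kept, reasons = [], {}
    checks = [("i", rule_i), ("iii", rule_iii), ("ii", rule_ii), ("iv", rule_iv),
              ("v", rule_v), ("vi", rule_vi), ("vii", rule_vii)]
    for sig in signals:
        reason = next((name for name, fn in checks if not fn(sig)), None)
        if reason is None:
            kept.append(sig["id"])
        else:
            reasons[sig["id"]] = reason
    return kept, reasons


def to_aligned(signals, meta):
    sample_ids = list(meta.sample_id)
    rows = [
        (s["id"], s["precursor"], s["product"], s["rt"],
         {k: v for k, v in s["values"].items() if v is not None})
        for s in signals
    ]
    return make_aligned(rows, sample_ids)


HAND_FIXTURE = [
    # contaminants seen in blank / no-nuclease control
    {"id": "s_blank", "precursor": 300, "product": 184, "rt": 5.0,
     "values": {"L1": 10, "L2": 10, "H1": 10, "H2": 10, "blank1": 8}},
    {"id": "s_ctrl", "precursor": 310, "product": 194, "rt": 6.0,
     "values": {"L1": 12, "L2": 12, "H1": 12, "H2": 12, "ctrl1": 5}},
    # clean adducts
    {"id": "s_keep1", "precursor": 326, "product": 210, "rt": 3.45,
     "values": {"L1": 50, "L2": 52, "H1": 48, "H2": 51}},
    {"id": "s_keep2", "precursor": 284, "product": 168, "rt": 6.65,
     "values": {"L1": 30, "L2": 31, "H1": 29, "H2": 30}},
    {"id": "s_keep3", "precursor": 400, "product": 284, "rt": 10.0,
     "values": {"L1": 5, "L2": 5, "H1": 5, "H2": 5}},
    {"id": "s_keep4", "precursor": 290, "product": 174, "rt": 2.0,
     "values": {"L1": 100, "L2": 99, "H1": 101, "H2": 100}},
    # satellites of kept signals
    {"id": "s_salt", "precursor": 348, "product": 232, "rt": 3.45,
     "values": {"L1": 2.5, "L2": 2.6, "H1": 2.4, "H2": 2.5}},
    {"id": "s_m1", "precursor": 285, "product": 169, "rt": 6.66,
     "values": {"L1": 4.5, "L2": 4.6, "H1": 4.4, "H2": 4.5}},
    # known artifact: dC dimer at the dC retention time
    {"id": "s_dimer", "precursor": 455, "product": 339, "rt": 1.80,
     "values": {"L1": 20, "L2": 20, "H1": 20, "H2": 20}},
    # weak and not shared with the other cohort
    {"id": "s_low", "precursor": 440, "product": 324, "rt": 9.0,
     "values": {"L1": 1.5, "L2": 1.5, "H1": 1.5, "H2": 1.5}},
]


@pytest.fixture
def hand_meta():
    return make_meta({"liver": ["L1", "L2"], "heart": ["H1", "H2"]})


class TestHandTracedFixture:
    def test_four_clean_signals_kept_with_constructed_reasons(self, hand_meta):
        aligned = to_aligned(HAND_FIXTURE, hand_meta)
        res = curate(aligned, hand_meta, params=PARAMS)
        kept = set(res.flags.index[res.flags.final_keep])
        assert kept == {"s_keep1", "s_keep2", "s_keep3", "s_keep4"}
        reasons = res.flags.removal_reason.to_dict()
        assert reasons["s_blank"] == "iii"
        assert reasons["s_ctrl"] == "iii"
        assert reasons["s_salt"] == "iv"
        assert reasons["s_m1"] == "v"
        assert reasons["s_dimer"] == "vi"
        assert reasons["s_low"] == "vii"

    def test_matches_brute_force_oracle(self, hand_meta):
        kept_o, reasons_o = oracle_curate(HAND_FIXTURE, hand_meta)
        res = curate(to_aligned(HAND_FIXTURE, hand_meta), hand_meta, params=PARAMS)
        assert set(res.flags.index[res.flags.final_keep]) == set(kept_o)
        got = res.flags.loc[~res.flags.final_keep, "removal_reason"].to_dict()
        assert got == reasons_o

    def test_weak_signal_shared_between_cohorts_is_kept(self, hand_meta):
        aligned = to_aligned(HAND_FIXTURE, hand_meta)
        res = curate(aligned, hand_meta, params=PARAMS,
                     other_cohort_keys=[(440, 324, 9.05)])
        assert res.flags.loc["s_low", "final_keep"]

    def test_empty_fixture_gives_empty_basis(self, hand_meta):
        aligned = to_aligned([], hand_meta)
        res = curate(aligned, hand_meta, params=PARAMS)
        assert res.n_kept == 0

    def test_missing_blank_columns_error(self):
        meta = make_meta({"liver": ["L1"]}, n_blanks=0)
        with pytest.raises(ValueError):
            curate(to_aligned(HAND_FIXTURE, meta), meta, params=PARAMS)


class TestOracleEquivalenceRandomized:
    @pytest.mark.parametrize("seed", range(8))
    def test_random_small_fixtures(self, seed, hand_meta):
        """On arbitrary fixtures of <= 20 signals the decision tree
        equals the exhaustive predicate evaluation, including the
        first-failing rule."""
        rng = np.random.default_rng(seed)
        signals = []
        n = int(rng.integers(5, 21))
        used = set()
        for i in range(n):
            prec = int(rng.integers(225, 525))
            prod = prec - (116 if rng.random() > 0.1 else int(rng.integers(10, 120)))
            rt = float(np.round(rng.uniform(1.5, 12.0), 2))
            base = float(np.round(10 ** rng.uniform(-0.5, 2.0), 2))
            vals = {}
            for sid in ["L1", "L2", "H1", "H2"]:
                vals[sid] = None if rng.random() < 0.1 else float(
                    np.round(base * rng.uniform(0.7, 1.3), 2)
                )
            if rng.random() < 0.15:
                vals["blank1"] = float(np.round(base * 0.8, 2))
            if rng.random() < 0.1:
                vals["ctrl1"] = float(np.round(base * 0.8, 2))
            sig = {"id": f"r{i}", "precursor": prec, "product": prod,
                   "rt": rt, "values": vals}
            signals.append(sig)
            # occasionally add a deliberate satellite of this signal
            if rng.random() < 0.3 and prec + 38 < 560:
                off = int(rng.choice([1, 2, 22, 38]))
                frac = float(rng.choice([0.05, 0.3, 0.8]))
                sat_vals = {k: (None if v is None else np.round(v * frac, 3))
                            for k, v in vals.items() if k in ("L1", "L2", "H1", "H2")}
                signals.append({"id": f"r{i}_sat{off}", "precursor": prec + off,
                                "product": prod + off, "rt": rt,
                                "values": sat_vals})
        signals = signals[:20]
        kept_o, reasons_o = oracle_curate(signals, hand_meta)
        res = curate(to_aligned(signals, hand_meta), hand_meta, params=PARAMS)
        assert set(res.flags.index[res.flags.final_keep]) == set(kept_o), seed
        got = res.flags.loc[~res.flags.final_keep, "removal_reason"].to_dict()
        assert got == reasons_o, seed


class TestMergeCohorts:
    @staticmethod
    def _basis(keys):
        return pd.DataFrame(
            [{"precursor_mz": p, "product_mz": p - 116, "rt": rt} for p, rt in keys]
        )

    def test_published_merge_arithmetic(self):
        """92 + 94 with 72 shared gives a union of 114 (63% shared)."""
        shared = [(230 + i, 2.0 + 0.05 * i) for i in range(72)]
        only1 = [(330 + i, 3.0 + 0.05 * i) for i in range(20)]
        only2 = [(430 + i, 4.0 + 0.05 * i) for i in range(22)]
        m = merge_cohorts(self._basis(shared + only1), self._basis(shared + only2))
        assert (m.n_set1, m.n_set2, m.n_shared, m.n_union) == (92, 94, 72, 114)
        assert m.n_union == m.n_set1 + m.n_set2 - m.n_shared
        assert round(100 * m.shared_fraction) == 63

    def test_identical_sets(self):
        b = self._basis([(250, 2.0), (260, 3.0)])
        m = merge_cohorts(b, b.copy())
        assert (m.n_union, m.n_shared) == (2, 2)
        assert set(m.union.membership) == {"both"}

    def test_disjoint_sets(self):
        m = merge_cohorts(
            self._basis([(250, 2.0), (260, 3.0), (270, 4.0)]),
            self._basis([(350, 2.0), (360, 3.0), (370, 4.0), (380, 5.0)]),
        )
        assert (m.n_union, m.n_shared) == (7, 0)

    def test_same_transition_different_rt_not_merged(self):
        m = merge_cohorts(self._basis([(250, 2.0)]), self._basis([(250, 6.0)]))
        assert (m.n_union, m.n_shared) == (2, 0)


class TestTissueSets:
    def test_all_above_threshold_everywhere(self):
        basis = pd.DataFrame({
            "precursor_mz": [250, 260], "product_mz": [134, 144], "rt": [2.0, 3.0],
            "mean_liver": [5.0, 6.0], "mean_heart": [5.0, 6.0],
        })
        out = tissue_sets(basis, threshold=2.0)
        assert out["shared_in_all"] == 2

    def test_constructed_pattern_by_enumeration(self):
        """6 species over 4 tissues with a known membership table."""
        tissues = ["liver", "kidney", "brain", "heart"]
        patterns = [
            ("liver",), ("liver", "kidney"), ("liver", "kidney", "brain"),
            tuple(tissues), tuple(tissues), ("heart",),
        ]
        rows = []
        for i, pat in enumerate(patterns):
            row = {"precursor_mz": 300 + i, "product_mz": 184 + i, "rt": 2.0 + i}
            for t in tissues:
                row[f"mean_{t}"] = 10.0 if t in pat else 0.0
            rows.append(row)
        out = tissue_sets(pd.DataFrame(rows), threshold=2.0, tissues=tissues)
        regions = out["regions"]
        # brute-force expectation from the membership patterns
        from collections import Counter

        expected = Counter(frozenset(p) for p in patterns)
        for region, count in regions.items():
            assert count == expected.get(region, 0), region
        assert out["shared_in_all"] == 2

    def test_empty_basis(self):
        basis = pd.DataFrame(columns=["precursor_mz", "product_mz", "rt",
                                      "mean_liver", "mean_heart"])
        out = tissue_sets(basis, threshold=2.0, tissues=["liver", "heart"])
        assert all(v == 0 for v in out["regions"].values())
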