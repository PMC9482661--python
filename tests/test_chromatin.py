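import numpy as np
import pandas as pd
import pytest

from cistrack.chromatin import (
    call_states,
    derive_label,
    differential_binding,
    merge_intervals,
    overlaps_any,
    tabulate_transitions,
    transition_marginals,
)
from cistrack.config import AnalysisConfig, STAGES
from cistrack.intervals import GenomicInterval, ValidationError, overlaps
from cistrack.pipeline import consensus_all
from cistrack.simulate import SimParams, simulate_study


def _frame(coords, prefix="p"):
    return pd.DataFrame(
        [
            {"chrom": c, "start": s, "end": e, "name": f"{prefix}{i}"}
            for i, (c, s, e) in enumerate(coords)
        ],
        columns=["chrom", "start", "end", "name"],
    )


# ---------------------------------------------------------------------------
# label derivation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "k4,ac,me3,label",
    [
        (True, False, True, "bivalent"),
        (True, True, True, "bivalent"),
        (True, True, False, "active_promoter"),
        (False, True, False, "active"),
        (True, False, False, "active_promoter"),  # k4-only
        (False, True, True, "repressed"),          # conflict combination
        (False, False, True, "repressed"),
        (False, False, False, "none"),
    ],
)
def test_derive_label(k4, ac, me3, label):
    assert derive_label(k4, ac, me3) == label


def test_bivalent_iff_k4_and_k27me3():
    for k4 in (False, True):
        for ac in (False, True):
            for me3 in (False, True):
                assert (derive_label(k4, ac, me3) == "bivalent") == (k4 and me3)


# ---------------------------------------------------------------------------
# call_states
# ---------------------------------------------------------------------------


def _histone_sets(per_stage):
    """per_stage: stage -> {mark: coords}"""
    out = {}
    for stage in STAGES:
        marks = per_stage.get(stage, {})
        for mark in ("H3K4me3", "H3K27ac", "H3K27me3"):
            out[(mark, stage)] = _frame(marks.get(mark, []), prefix=f"{mark}_{stage}_")
    return out


def test_bivalent_call_from_intersection(cfg):
    chd2 = _frame([("chr1", 1000, 1400)])
    hsets = _histone_sets(
        {"D15": {"H3K4me3": [("chr1", 900, 1500)], "H3K27me3": [("chr1", 950, 1600)]}}
    )
    states = call_states(chd2, hsets, cfg)
    d15 = states[(states["stage"] == "D15")].iloc[0]
    assert d15["bivalent"] and d15["label"] == "bivalent"


def test_no_overlap_gives_none(cfg):
    chd2 = _frame([("chr1", 1000, 1400)])
    states = call_states(chd2, _histone_sets({}), cfg)
    assert (states["label"] == "none").all()
    assert not states[["k4me3", "k27ac", "k27me3"]].any().any()


def test_missing_mark_stage_rejected(cfg):
    chd2 = _frame([("chr1", 0, 100)])
    hsets = _histone_sets({})
    del hsets[("H3K27me3", "D35")]
    with pytest.raises(ValidationError, match="H3K27me3"):
        call_states(chd2, hsets, cfg)


def test_call_states_brute_force_oracle(cfg, rng):
    chd2 = _frame(
        [("chr1", int(s), int(s + rng.integers(100, 500))) for s in rng.integers(0, 50_000, 300)]
    )
    hsets = {}
    for mark in ("H3K4me3", "H3K27ac", "H3K27me3"):
        for stage in STAGES:
            hsets[(mark, stage)] = _frame(
                [
                    ("chr1", int(s), int(s + rng.integers(100, 800)))
                    for s in rng.integers(0, 50_000, 50)
                ],
                prefix=f"{mark}{stage}",
            )
    states = call_states(chd2, hsets, cfg)
    flag_col = {"H3K4me3": "k4me3", "H3K27ac": "k27ac", "H3K27me3": "k27me3"}
    for _, row in states.sample(100, random_state=0).iterrows():
        q = chd2[chd2["name"] == row["peak"]].iloc[0]
        qi = GenomicInterval(q["chrom"], int(q["start"]), int(q["end"]))
        for mark, col in flag_col.items():
            expected = any(
                overlaps(
                    qi,
                    GenomicInterval(r["chrom"], int(r["start"]), int(r["end"])),
                    cfg.overlap_frac_query,
                    cfg.overlap_frac_subject,
                    cfg.overlap_either,
                )
                for _, r in hsets[(mark, row["stage"])].iterrows()
            )
            assert row[col] == expected


def test_call_states_order_invariant(cfg, rng):
    chd2 = _frame(
        [("chr1", int(s), int(s + 300)) for s in rng.integers(0, 30_000, 50)]
    )
    hsets = _histone_sets(
        {"D0": {"H3K4me3": [("chr1", 100, 900)], "H3K27ac": [("chr1", 5000, 5600)]}}
    )
    s1 = call_states(chd2, hsets, cfg)
    shuffled = chd2.sample(frac=1, random_state=1).reset_index(drop=True)
    s2 = call_states(shuffled, hsets, cfg)
    key = ["peak", "stage"]
    pd.testing.assert_frame_equal(
        s1.sort_values(key).reset_index(drop=True),
        s2.sort_values(key).reset_index(drop=True),
    )


def test_coupling_raises_k27ac_flag_fraction(cfg):
    study = simulate_study(SimParams.tiny(seed=3))
    cons = consensus_all(study, cfg)
    universe = pd.concat(
        [cons[("CHD2", s, "WT")] for s in STAGES], ignore_index=True
    )
    hsets = {(m, s): cons[(m, s, "WT")] for m in ("H3K4me3", "H3K27ac", "H3K27me3") for s in STAGES}
    states = call_states(universe, hsets, cfg)
    truth = study.truth.peaks
    # map consensus peaks back to planted peaks via midpoint containment
    flagged = {True: [], False: []}
    d35 = states[states["stage"] == "D35"].set_index("peak")
    for _, p in truth.iterrows():
        if "D35" not in p["class"]:
            continue
        mid = (p["start"] + p["end"]) // 2
        m = universe[
            (universe["chrom"] == p["chrom"])
            & (universe["start"] <= mid)
            & (universe["end"] > mid)
        ]
        for name in m["name"]:
            if name in d35.index:
                flagged[bool(p["k27ac_coupled"])].append(bool(d35.loc[name, "k27ac"]))
    frac_coupled = np.mean(flagged[True])
    frac_uncoupled = np.mean(flagged[False]) if flagged[False] else 0.0
    assert frac_coupled - frac_uncoupled >= 0.5  # planted margin 0.7 vs 0.05


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------


def _states_frame(triples):
    rows = []
    for i, (a, b, c) in enumerate(triples):
        for stage, label in zip(STAGES, (a, b, c)):
            rows.append({"peak": f"p{i}", "stage": stage, "label": label})
    return pd.DataFrame(rows)


def test_single_transition_record():
    tab = tabulate_transitions(_states_frame([("active", "active", "bivalent")]))
    assert len(tab) == 1
    row = tab.iloc[0]
    assert (row["D0"], row["D15"], row["D35"], row["count"]) == (
        "active", "active", "bivalent", 1,
    )


def test_transitions_conserve_total(rng):
    labels = ["active_promoter", "active", "bivalent", "repressed", "none"]
    triples = [tuple(rng.choice(labels, 3)) for _ in range(200)]
    tab = tabulate_transitions(_states_frame(triples))
    assert tab["count"].sum() == 200
    marg = transition_marginals(tab, "D15")
    assert marg.sum() == 200


def test_transitions_missing_stage_rejected():
    df = _states_frame([("active", "active", "active")])
    with pytest.raises(ValidationError):
        tabulate_transitions(df[df["stage"] != "D35"])


def test_planted_converter_fraction(rng):
    # 30% of peaks planted as active_promoter -> bivalent converters
    n = 400
    conv = rng.random(n) < 0.3
    triples = [
        ("active_promoter", "bivalent", "bivalent") if c else ("active", "active", "active")
        for c in conv
    ]
    tab = tabulate_transitions(_states_frame(triples))
    got = tab.loc[
        (tab["D0"] == "active_promoter") & (tab["D15"] == "bivalent"), "count"
    ].sum()
    se = np.sqrt(0.3 * 0.7 / n)
    assert abs(got / n - 0.3) <= 4 * se


# ---------------------------------------------------------------------------
# differential binding
# ---------------------------------------------------------------------------


def _peak_counts(rng, mu_wt, mu_mut, n=3, phi=0.05):
    def nb(mu):
        lam = rng.gamma(1 / phi, np.asarray(mu)[:, None] * phi, size=(len(mu), n))
        return rng.poisson(lam)

    wt = [f"wt{i}" for i in range(n)]
    mut = [f"mut{i}" for i in range(n)]
    counts = pd.DataFrame(
        np.hstack([nb(mu_wt), nb(mu_mut)]),
        columns=wt + mut,
        index=[f"peak{i}" for i in range(len(mu_wt))],
    )
    return counts, wt, mut


def test_dbr_null_calibration():
    fracs = []
    for seed in range(20):
        rng = np.random.default_rng(seed + 100)
        mu = np.exp(rng.normal(np.log(100), 0.5, 200))
        counts, wt, mut = _peak_counts(rng, mu, mu, n=4)
        res = differential_binding(counts, wt, mut, AnalysisConfig())
        fracs.append((res["qvalue"] < 0.05).mean())
    se = np.sqrt(0.05 * 0.95 / (200 * 20))
    assert np.mean(fracs) <= 0.05 + 3 * se


def test_dbr_power_and_sign(rng):
    mu = np.exp(rng.normal(np.log(100), 0.5, 1000))
    lfc = np.zeros(1000)
    lfc[:100] = -2.0  # planted 4-fold acetylation loss
    counts, wt, mut = _peak_counts(rng, mu, mu * 2.0**lfc, n=3)
    res = differential_binding(counts, wt, mut, AnalysisConfig())
    planted = res.iloc[:100]
    assert (planted["direction"] == "down").mean() >= 0.85
    false_sign = (res.iloc[100:]["direction"] != "ns").mean()
    assert false_sign < 0.05


def test_identical_counts_not_dbr(rng):
    counts, wt, mut = _peak_counts(rng, np.full(50, 100.0), np.full(50, 100.0), n=3)
    counts[mut] = counts[wt].to_numpy()
    res = differential_binding(counts, wt, mut, AnalysisConfig())
    assert (res["direction"] == "ns").all()


def test_dbr_antisymmetry(rng):
    mu = np.exp(rng.normal(np.log(100), 0.5, 100))
    counts, wt, mut = _peak_counts(rng, mu, mu * rng.choice([0.25, 1, 4], 100), n=3)
    res1 = differential_binding(counts, wt, mut, AnalysisConfig())
    res2 = differential_binding(counts, mut, wt, AnalysisConfig())
    np.testing.assert_allclose(res1["log2fc"], -res2["log2fc"], atol=1e-6)
    swapped = res2["direction"].map({"up": "down", "down": "up", "ns": "ns"})
    assert (res1["direction"] == swapped).all()


def test_empty_union_rejected():
    with pytest.raises(ValidationError):
        differential_binding(pd.DataFrame(), ["a"], ["b"], AnalysisConfig())


def test_merge_intervals():
    f1 = _frame([("chr1", 0, 100), ("chr1", 90, 200), ("chr2", 0, 50)])
    f2 = _frame([("chr1", 300, 400)])
    merged = merge_intervals([f1, f2])
    got = merged[["chrom", "start", "end"]].to_records(index=False).tolist()
    assert got == [("chr1", 0, 200), ("chr1", 300, 400), ("chr2", 0, 50)]
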