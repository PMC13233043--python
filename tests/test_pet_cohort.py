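"""PET cohort handling: SUVR loading, unstable-region correction,
composites, positivity classification, group assignment and scan pairing."""

import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tauseed.atlas import Region, RegionAtlas
from tauseed.pet import (ScanRecord, assign_biomarker_group, classify_amyloid,
                         classify_tau, composite_suvr,
                         correct_unstable_regions, load_suvr_table,
                         pair_scans)


def _scan(atlas, values, modality="tau", sid="S1", date=dt.date(2016, 1, 1)):
    return ScanRecord(subject_id=sid, modality=modality, date=date,
                      suvr=np.asarray(values, float), atlas=atlas)


@pytest.fixture(scope="module")
def unstable_atlas():
    """Four regions; the entorhinal pair is marked unstable, each with the
    opposite-pair regions as neighbours (and each other, to exercise the
    simultaneous-update rule)."""
    regions = tuple(
        Region(i, n, h, "cortical") for i, (n, h) in enumerate([
            ("entorhinal-L", "left"), ("entorhinal-R", "right"),
            ("cuneus-L", "left"), ("cuneus-R", "right")])
    )
    return RegionAtlas(
        regions=regions,
        braak_map={"entorhinal-L": 1, "entorhinal-R": 1},
        composites={
            "amyloid_cortical_summary": frozenset({"cuneus-L", "cuneus-R"}),
            "tau_mtl_composite": frozenset({"entorhinal-L", "entorhinal-R"}),
            "tau_neo_composite": frozenset({"cuneus-L", "cuneus-R"}),
            "unstable_regions": frozenset({"entorhinal-L", "entorhinal-R"}),
        },
        neighbour_map={
            "entorhinal-L": ("entorhinal-R", "cuneus-L", "cuneus-R"),
            "entorhinal-R": ("entorhinal-L", "cuneus-L", "cuneus-R"),
        },
        name="unstable4",
    )


# -- loading ---------------------------------------------------------------

def _table(atlas, n=3):
    rows = []
    for i in range(n):
        row = {"subject_id": f"S{i}", "date": f"2016-0{i+1}-15"}
        row.update({nm: 1.0 + 0.1 * i for nm in atlas.region_names})
        rows.append(row)
    return pd.DataFrame(rows)


def test_load_suvr_table(tmp_path, atlas5):
    path = tmp_path / "t.csv"
    _table(atlas5).to_csv(path, index=False)
    records = load_suvr_table(path, atlas5, "tau")
    assert len(records) == 3
    assert records[1].date == dt.date(2016, 2, 15)
    np.testing.assert_allclose(records[2].suvr, 1.2)


def test_load_suvr_table_column_order_invariant(tmp_path, atlas5):
    df = _table(atlas5)
    shuffled = df[["subject_id", "date"] + list(atlas5.region_names)[::-1]]
    a, b = tmp_path / "a.csv", tmp_path / "b.csv"
    df.to_csv(a, index=False)
    shuffled.to_csv(b, index=False)
    ra = load_suvr_table(a, atlas5, "tau")
    rb = load_suvr_table(b, atlas5, "tau")
    for x, y in zip(ra, rb):
        np.testing.assert_array_equal(x.suvr, y.suvr)


def test_load_suvr_table_errors(tmp_path, atlas5):
    df = _table(atlas5)
    df["mystery"] = 1.0
    path = tmp_path / "extra.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="mystery"):
        load_suvr_table(path, atlas5, "tau")
    df2 = _table(atlas5)
    df2.loc[1, atlas5.region_names[0]] = -0.5
    path2 = tmp_path / "neg.csv"
    df2.to_csv(path2, index=False)
    with pytest.raises(ValueError, match="S1"):
        load_suvr_table(path2, atlas5, "tau")


# -- unstable-region correction -------------------------------------------

def test_correction_mean_of_self_and_neighbours(unstable_atlas):
    scan = _scan(unstable_atlas, [2.0, 2.0, 1.0, 1.0], modality="FDG")
    out = correct_unstable_regions(scan, unstable_atlas)
    # mean over {self(2.0), neighbour(2.0), 1.0, 1.0} = 6/4
    np.testing.assert_allclose(out.suvr[:2], 1.5)
    np.testing.assert_array_equal(out.suvr[2:], scan.suvr[2:])


def test_correction_two_neighbour_example(unstable_atlas):
    # single unstable region at 2.0 with two neighbours at 1.0:
    # replacement is mean{2.0, 1.0, 1.0} = 4/3
    regions = tuple(r for r in unstable_atlas.regions)
    atlas = RegionAtlas(
        regions=regions,
        braak_map=dict(unstable_atlas.braak_map),
        composites={**{k: v for k, v in unstable_atlas.composites.items()},
                    "unstable_regions": frozenset({"entorhinal-L"})},
        neighbour_map={"entorhinal-L": ("cuneus-L", "cuneus-R")},
        name="one-unstable",
    )
    scan = _scan(atlas, [2.0, 9.0, 1.0, 1.0], modality="FDG")
    out = correct_unstable_regions(scan, atlas)
    assert out.suvr[0] == pytest.approx(4 / 3)
    np.testing.assert_array_equal(out.suvr[1:], scan.suvr[1:])


def test_correction_uses_precorrection_values(unstable_atlas):
    # the two unstable regions neighbour each other: both must read the
    # other's ORIGINAL value (no cascade)
    scan = _scan(unstable_atlas, [2.0, 4.0, 1.0, 1.0], modality="FDG")
    out = correct_unstable_regions(scan, unstable_atlas)
    np.testing.assert_allclose(out.suvr[0], (2.0 + 4.0 + 1.0 + 1.0) / 4)
    np.testing.assert_allclose(out.suvr[1], (4.0 + 2.0 + 1.0 + 1.0) / 4)
    # mutually-neighbouring unstable regions: applying twice differs
    twice = correct_unstable_regions(out, unstable_atlas)
    assert not np.allclose(twice.suvr[:2], out.suvr[:2])


def test_correction_identity_without_unstable(atlas5):
    scan = _scan(atlas5, np.linspace(1, 2, 5), modality="FDG")
    out = correct_unstable_regions(scan, atlas5)
    np.testing.assert_array_equal(out.suvr, scan.suvr)
    # and is therefore idempotent
    np.testing.assert_array_equal(
        correct_unstable_regions(out, atlas5).suvr, out.suvr)


def test_correction_default_atlas_preserves_stable_regions(atlas84):
    rng = np.random.default_rng(0)
    scan = _scan(atlas84, rng.uniform(0.8, 1.8, 84), modality="FDG")
    out = correct_unstable_regions(scan, atlas84)
    unstable_idx = [atlas84.index_of(r)
                    for r in atlas84.composites["unstable_regions"]]
    stable = np.setdiff1d(np.arange(84), unstable_idx)
    np.testing.assert_array_equal(out.suvr[stable], scan.suvr[stable])
    assert not np.array_equal(out.suvr[unstable_idx], scan.suvr[unstable_idx])


# -- composites and classification ----------------------------------------

def test_composite_suvr(atlas5):
    scan = _scan(atlas5, [1.2, 1.4, 1.6, 2.0, 3.0])
    names = atlas5.region_names
    assert composite_suvr(scan, [names[0]]) == pytest.approx(1.2)
    assert composite_suvr(scan, names[:3]) == pytest.approx(1.4)
    with pytest.raises(ValueError, match="empty"):
        composite_suvr(scan, [])


@pytest.mark.parametrize("value, expected", [
    (1.20, True), (1.11, False), (0.95, False)])
def test_classify_amyloid_threshold(unstable_atlas, value, expected):
    scan = _scan(unstable_atlas, [1.0, 1.0, value, value], modality="amyloid")
    assert classify_amyloid(scan, unstable_atlas) is expected


@pytest.mark.parametrize("mtl, neo, expected", [
    (1.40, 1.30, (True, False)),
    (1.375, 1.395, (False, False)),   # strict inequalities
    (1.50, 1.50, (True, True)),
])
def test_classify_tau_thresholds(unstable_atlas, mtl, neo, expected):
    scan = _scan(unstable_atlas, [mtl, mtl, neo, neo], modality="tau")
    assert classify_tau(scan, unstable_atlas) == expected


def test_group_assignment_covers_all_combinations():
    labels = {combo: assign_biomarker_group(*combo)
              for combo in itertools.product([False, True], repeat=3)}
    # amyloid-negatives pool regardless of tau
    for combo, label in labels.items():
        if not combo[0]:
            assert label == "Abeta-"
    assert labels[(True, True, False)] == "Abeta+tauMTL+tauNEO-"
    assert labels[(True, True, True)] == "Abeta+tauMTL+tauNEO+"
    assert labels[(True, False, False)] == "Abeta+tauMTL-tauNEO-"
    excluded = [c for c, l in labels.items() if l == "EXCLUDED"]
    assert excluded == [(True, False, True)]


# -- pairing ---------------------------------------------------------------

def _dated(atlas, sid, modality, *dates):
    return [_scan(atlas, np.ones(atlas.n_regions), modality=modality,
                  sid=sid, date=d) for d in dates]


def test_pair_within_window(atlas5):
    fdg = _dated(atlas5, "S1", "FDG", dt.date(2016, 1, 1))
    tau = _dated(atlas5, "S1", "tau", dt.date(2016, 11, 30))
    (pair,) = pair_scans(fdg, tau)
    assert pair.gap_days == 334


def test_pair_outside_window(atlas5):
    fdg = _dated(atlas5, "S1", "FDG", dt.date(2016, 1, 1))
    tau = _dated(atlas5, "S1", "tau", dt.date(2017, 2, 1))
    assert pair_scans(fdg, tau) == []


def test_pair_policy_and_tiebreaks(atlas5):
    fdg = _dated(atlas5, "S1", "FDG", dt.date(2016, 6, 1))
    tau = _dated(atlas5, "S1", "tau",
                 dt.date(2016, 3, 1), dt.date(2016, 9, 1))
    (earliest,) = pair_scans(fdg, tau, policy="earliest")
    assert earliest.tau_scan.date == dt.date(2016, 3, 1)
    (latest,) = pair_scans(fdg, tau, policy="latest")
    assert latest.tau_scan.date == dt.date(2016, 9, 1)
    # same tau date reachable from two primaries: smallest gap wins
    fdg2 = _dated(atlas5, "S1", "FDG",
                  dt.date(2016, 2, 1), dt.date(2016, 8, 25))
    (p,) = pair_scans(fdg2, tau, policy="latest")
    assert p.primary_scan.date == dt.date(2016, 8, 25)


def test_pair_one_per_subject_and_order_invariance(atlas5):
    rng = np.random.default_rng(3)
    fdg, tau = [], []
    for i in range(6):
        base = dt.date(2015, 1, 1) + dt.timedelta(days=int(rng.integers(0, 900)))
        fdg += _dated(atlas5, f"S{i}", "FDG", base,
                      base + dt.timedelta(days=500))
        tau += _dated(atlas5, f"S{i}", "tau",
                      base + dt.timedelta(days=int(rng.integers(-400, 400))))
    pairs = pair_scans(fdg, tau)
    assert len({p.subject_id for p in pairs}) == len(pairs)
    shuffled = pair_scans(fdg[::-1], tau[::-1])
    assert [(p.subject_id, p.gap_days) for p in pairs] == \
        [(p.subject_id, p.gap_days) for p in shuffled]


def test_pair_duplicate_rows_rejected(atlas5):
    fdg = _dated(atlas5, "S1", "FDG", dt.date(2016, 1, 1), dt.date(2016, 1, 1))
    tau = _dated(atlas5, "S1", "tau", dt.date(2016, 2, 1))
    with pytest.raises(ValueError, match="duplicate"):
        pair_scans(fdg, tau)
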