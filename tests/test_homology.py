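"""Homology assignment from relative position and size."""

import math

import numpy as np
import pytest

from sixocellus.homology import (
    FIRM,
    TIE_BROKEN,
    SectorConfig,
    label_side,
    pdmi_position_class,
    sector_of,
    split_size_tiers,
)
from sixocellus.obsmodel import (
    OcellusIdentity,
    OcellusObservation,
    SideRecord,
    ValidationError,
    records_from_frame,
    records_to_frame,
)
from sixocellus.patterns import MEMBER_SETS, PatternName
from sixocellus.synthetic_data import POSITION_TEMPLATES, side_from_identities

I = OcellusIdentity
NAMED = [p for p in PatternName if p not in (PatternName.ABNORMAL, PatternName.ABSENT)]


def obs(ap, dv, diameter):
    return OcellusObservation(ap=ap, dv=dv, diameter=diameter)


def side_of(identities, **kw):
    record, _ = side_from_identities(sorted(identities, key=lambda i: i.value), **kw)
    return record


# --- sectors ----------------------------------------------------------------


@pytest.mark.parametrize(
    "dap, ddv, name",
    [
        (1.0, 0.0, "posterior"),
        (1.0, 1.0, "posterodorsal"),
        (0.0, 1.0, "dorsal"),
        (-1.0, 1.0, "anterodorsal"),
        (-1.0, 0.0, "anterior"),
        (-1.0, -1.0, "anteroventral"),
        (0.0, -1.0, "ventral"),
        (1.0, -1.0, "posteroventral"),
    ],
)
def test_sector_compass(dap, ddv, name):
    assert sector_of(dap, ddv) == name


def test_sectors_partition_the_circle():
    seen = set()
    for deg in range(0, 360):
        seen.add(sector_of(math.cos(math.radians(deg)), math.sin(math.radians(deg))))
    assert len(seen) == 8


# --- size tiers -------------------------------------------------------------


@pytest.mark.parametrize(
    "diameters, n_major, n_minor, tie",
    [
        ([1.0, 0.95, 0.9, 0.4, 0.35], 3, 2, False),
        ([], 0, 0, False),
        ([1.0, 0.45], 1, 1, False),  # large major + smaller satellite
        ([1.0, 0.95], 2, 0, False),  # two similar large: both majors
        ([1.0], 1, 0, False),
        ([1.0, 0.97, 0.94], 3, 0, True),  # no gap, >2: flagged
    ],
)
def test_split_size_tiers(diameters, n_major, n_minor, tie, cfg):
    observations = [obs(0.1 * i, 0.0, d) for i, d in enumerate(diameters)]
    majors, minors, tied = split_size_tiers(observations, cfg)
    assert (len(majors), len(minors), tied) == (n_major, n_minor, tie)


def test_split_matches_exhaustive_gap_oracle(cfg):
    # first split point whose multiplicative gap exceeds the ratio
    rng = np.random.default_rng(11)
    for _ in range(200):
        n = int(rng.integers(1, 8))
        diams = np.sort(rng.uniform(0.1, 1.0, n))[::-1]
        observations = [obs(0.1 * i, 0.0, float(d)) for i, d in enumerate(diams)]
        majors, minors, tied = split_size_tiers(observations, cfg)
        expected = next(
            (
                k
                for k in range(1, min(4, n - 1) + 1)
                if diams[k - 1] / diams[k] > cfg.major_minor_ratio
            ),
            None,
        )
        if expected is not None:
            assert len(majors) == expected and not tied
        else:
            assert len(majors) == min(n, 4)


def test_split_rejects_more_than_ten(cfg):
    with pytest.raises(ValidationError):
        split_size_tiers([obs(0.1, 0.0, 0.5)] * 11, cfg)


# --- major row --------------------------------------------------------------


@pytest.mark.parametrize(
    "pattern, expected_majors",
    [
        (PatternName.T1, {I.PLMA}),
        (PatternName.T2A, {I.MLMA, I.PLMA}),
        (PatternName.T5, {I.ALMA, I.MLMA, I.PLMA}),
    ],
)
def test_major_row_assignment(pattern, expected_majors, cfg):
    labeled = label_side(side_of(MEMBER_SETS[pattern]), cfg)
    majors = {ident for ident in labeled.identity_set if ident.tier == "major"}
    assert majors == expected_majors


def test_four_majors_put_accessory_first(cfg):
    labeled = label_side(
        side_of({I.AALMA, I.ALMA, I.MLMA, I.PLMA}), cfg
    )
    assert labeled.identity_set == {I.AALMA, I.ALMA, I.MLMA, I.PLMA}
    by_ident = {ident: k for k, ident in labeled.labels.items()}
    aps = [labeled.observations[by_ident[i]].ap for i in (I.AALMA, I.ALMA, I.MLMA, I.PLMA)]
    assert aps == sorted(aps)


# --- minors -----------------------------------------------------------------


def _minor_pair_side(offsets):
    """PLMa anchor at (0.56, 0) with minors at given offsets."""
    observations = [obs(0.56, 0.0, 1.0)] + [
        obs(0.56 + dx, dy, 0.5) for dx, dy in offsets
    ]
    return SideRecord(side="sinistral", observations=observations)


def test_anterodorsal_and_posterodorsal_minors_are_admi_pdmi(cfg):
    labeled = label_side(_minor_pair_side([(-0.08, 0.08), (0.08, 0.08)]), cfg)
    assert labeled.identity_set == {I.PLMA, I.ADMI, I.PDMI}
    assert all(c == FIRM for c in labeled.confidence.values())


def test_posterodorsal_plus_sub_ventral_minor_is_pdmi_plmi(cfg):
    labeled = label_side(_minor_pair_side([(0.08, 0.08), (0.08, -0.02)]), cfg)
    assert labeled.identity_set == {I.PLMA, I.PDMI, I.PLMI}


def test_lone_dorsal_minor_defaults_to_pdmi_tie_broken(cfg):
    labeled = label_side(_minor_pair_side([(0.0, 0.10)]), cfg)
    (minor_idx,) = [k for k, v in labeled.labels.items() if v is I.PDMI]
    assert labeled.confidence[minor_idx] == TIE_BROKEN


def test_lone_anterodorsal_minor_is_admi(cfg):
    labeled = label_side(_minor_pair_side([(-0.08, 0.08)]), cfg)
    assert I.ADMI in labeled.identity_set


def test_minor_without_any_major_anchor_is_flagged(cfg):
    # two similar small ocelli: treated as a two-major row, no minors
    record = SideRecord(
        side="sinistral", observations=[obs(0.4, 0.0, 1.0), obs(0.6, 0.3, 0.2)]
    )
    labeled = label_side(record, cfg)
    assert labeled.identity_set == {I.PLMA, I.PDMI} or labeled.flags


# --- full sides -------------------------------------------------------------


def test_type5_worked_example(cfg):
    # row of three large similar majors + two smaller dorsal satellites
    record = SideRecord(
        side="sinistral",
        observations=[
            obs(0.20, 0.0, 0.9),
            obs(0.38, 0.0, 1.0),
            obs(0.56, 0.0, 0.92),
            obs(0.48, 0.08, 0.4),
            obs(0.64, 0.08, 0.5),
        ],
    )
    labeled = label_side(record, cfg)
    assert labeled.identity_set == MEMBER_SETS[PatternName.T5]


def test_empty_side_labels_nothing(cfg):
    labeled = label_side(SideRecord(side="sinistral"), cfg)
    assert labeled.identity_set == frozenset()
    assert not labeled.unassigned


@pytest.mark.parametrize("pattern", NAMED + [PatternName.SIX])
def test_zero_noise_templates_recover_every_named_pattern(pattern, cfg):
    labeled = label_side(side_of(MEMBER_SETS[pattern]), cfg)
    assert labeled.identity_set == MEMBER_SETS[pattern]
    assert not labeled.unassigned


@pytest.mark.parametrize("pattern", NAMED)
def test_implication_chain_holds_on_every_labeling(pattern, cfg):
    rng = np.random.default_rng(23)
    for _ in range(20):
        record, _ = side_from_identities(
            sorted(MEMBER_SETS[pattern], key=lambda i: i.value),
            rng=rng,
            position_noise_sd=0.02,
        )
        members = label_side(record, cfg).identity_set
        if I.ALMA in members:
            assert {I.MLMA, I.PLMA} <= members
        if I.MLMA in members:
            assert I.PLMA in members
        if I.AALMA in members:
            assert I.ALMA in members


def test_mirror_invariance_through_the_shared_frame(cfg):
    left = side_of(MEMBER_SETS[PatternName.T5])
    right = SideRecord(side="dextral", observations=list(left.observations))
    rec_frame = records_to_frame(
        [
            __import__("sixocellus").obsmodel.IndividualRecord(
                specimen_id="m1", sides={"sinistral": left, "dextral": right}
            )
        ]
    )
    (rec,) = records_from_frame(rec_frame)
    lab_l = label_side(rec.sides["sinistral"], cfg)
    lab_r = label_side(rec.sides["dextral"], cfg)
    assert lab_l.identity_set == lab_r.identity_set


@pytest.mark.parametrize("pattern", NAMED + [PatternName.SIX])
def test_rotational_noise_below_half_sector_preserves_identities(pattern, cfg):
    """Rotating every non-anchor ocellus about PLMa by < half the sector
    width never changes the assigned identity set."""
    rng = np.random.default_rng(37)
    base, idents = side_from_identities(
        sorted(MEMBER_SETS[pattern], key=lambda i: i.value)
    )
    ax, ay = POSITION_TEMPLATES[I.PLMA]
    for _ in range(25):
        rotated = []
        for o in base.observations:
            dx, dy = o.ap - ax, o.dv - ay
            if abs(dx) < 1e-12 and abs(dy) < 1e-12:
                rotated.append(o)
                continue
            theta = math.radians(rng.uniform(-15.0, 15.0))
            rx = dx * math.cos(theta) - dy * math.sin(theta)
            ry = dx * math.sin(theta) + dy * math.cos(theta)
            rotated.append(obs(ax + rx, ay + ry, o.diameter))
        labeled = label_side(SideRecord(side="sinistral", observations=rotated), cfg)
        assert labeled.identity_set == MEMBER_SETS[pattern]


# --- PDMi position class ----------------------------------------------------


def _t5_with_pdmi_dv(dv, cfg):
    record = SideRecord(
        side="sinistral",
        observations=[
            obs(0.20, 0.0, 0.9),
            obs(0.38, 0.0, 1.0),
            obs(0.56, 0.0, 0.92),
            obs(0.48, 0.08, 0.4),
            obs(0.64, dv, 0.5),
        ],
    )
    return label_side(record, cfg)


@pytest.mark.parametrize(
    "dv, expected",
    [
        (0.0, "P1"),      # in the plane of the major row
        (0.02, "P1"),
        (0.099, "P2"),    # just below the P2/P3 edge
        (0.101, "P3"),    # just above it
    ],
)
def test_pdmi_position_bands(dv, expected, cfg):
    labeled = _t5_with_pdmi_dv(dv, cfg)
    assert I.PDMI in labeled.identity_set
    assert pdmi_position_class(labeled, cfg) == expected


def test_pdmi_position_requires_three_major_row(cfg):
    labeled = label_side(side_of(MEMBER_SETS[PatternName.T4C]), cfg)
    assert pdmi_position_class(labeled, cfg) == "not_applicable"
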