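"""Bilateral reconciliation, species aggregation and survey statistics."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from sixocellus.homology import FIRM, LabeledSide
from sixocellus.obsmodel import IDENTITY_ORDER, OcellusIdentity, ValidationError
from sixocellus.patterns import MEMBER_SETS, PatternName
from sixocellus.pipeline import run_survey
from sixocellus.reconcile import (
    aggregate_species,
    reconcile_individual,
    survey_stats,
)
from sixocellus.synthetic_data import GeneratorConfig, generate_survey, side_from_identities

I = OcellusIdentity


def labeled(identities, side="sinistral"):
    """A LabeledSide with the given identity set (template positions)."""
    record, idents = side_from_identities(sorted(identities, key=lambda i: i.value), side=side)
    return LabeledSide(
        side=side,
        observations=record.observations,
        labels=dict(enumerate(idents)),
        confidence={k: FIRM for k in range(len(idents))},
    )


def summary(left, right=None, specimen="s", taxon=("F", "G", "sp")):
    return reconcile_individual(
        labeled(left) if left is not None else None,
        labeled(right, side="dextral") if right is not None else None,
        specimen_id=specimen,
        taxon=taxon,
    )


def test_subset_asymmetry_keeps_the_union():
    s = summary({I.MLMA, I.PLMA}, {I.PLMA})
    assert s.complement == {I.MLMA, I.PLMA}
    assert s.asymmetric and not s.discordant
    assert s.symmetric is False
    assert s.patterns["complement"].name is PatternName.T2A
    assert s.patterns["dextral"].name is PatternName.T1


def test_identical_sides_are_symmetric():
    s = summary(MEMBER_SETS[PatternName.T3A], MEMBER_SETS[PatternName.T3A])
    assert s.symmetric and not s.asymmetric and not s.discordant
    assert s.complement == MEMBER_SETS[PatternName.T3A]


def test_discordant_sides_still_union():
    left = {I.MLMA, I.PLMA, I.PDMI, I.PLMI, I.APLMI2}
    right = {I.MLMA, I.PLMA, I.PDMI, I.PLMI, I.ADMI}
    s = summary(left, right)
    assert s.discordant and s.asymmetric
    assert len(s.complement) == 6


def test_single_sided_records_no_symmetry_claim():
    s = summary(MEMBER_SETS[PatternName.T2B], None)
    assert s.single_sided and s.symmetric is None
    assert not s.asymmetric
    assert s.complement == MEMBER_SETS[PatternName.T2B]


def test_reconcile_requires_a_side():
    with pytest.raises(ValidationError):
        reconcile_individual(None, None)


def _closure(subset):
    s = set(subset)
    if I.AALMA in s:
        s.add(I.ALMA)
    if I.ALMA in s:
        s |= {I.MLMA, I.PLMA}
    if I.MLMA in s:
        s.add(I.PLMA)
    return frozenset(s)


@given(
    st.frozensets(st.sampled_from(list(IDENTITY_ORDER)), max_size=8),
    st.frozensets(st.sampled_from(list(IDENTITY_ORDER)), max_size=8),
)
def test_complement_conservation(a, b):
    left, right = _closure(a), _closure(b)
    s = summary(left, right)
    assert len(s.complement) >= max(len(left), len(right))
    nested = left <= right or right <= left
    assert (len(s.complement) == max(len(left), len(right))) == nested


# --- species aggregation ----------------------------------------------------


def test_nested_morphs_make_a_polymorphic_species():
    inds = [summary({I.MLMA, I.PLMA}, {I.MLMA, I.PLMA}) for _ in range(3)] + [
        summary({I.ALMA, I.MLMA, I.PLMA}, {I.ALMA, I.MLMA, I.PLMA}) for _ in range(2)
    ]
    sp = aggregate_species(inds)
    assert sp.polymorphic and sp.morphs_nested
    assert sp.n_individuals == 5
    assert sp.presence_freq[I.ALMA] == pytest.approx(0.4)
    assert sp.presence_freq[I.PLMA] == 1.0


def test_single_individual_is_not_polymorphic():
    sp = aggregate_species([summary(MEMBER_SETS[PatternName.T4C])])
    assert not sp.polymorphic
    assert sp.modal_pattern is PatternName.T4C


def test_lattice_adjacent_morphs_are_nested():
    inds = [summary(MEMBER_SETS[PatternName.T3A])] + [
        summary(MEMBER_SETS[PatternName.T4C])
    ]
    sp = aggregate_species(inds)
    assert sp.polymorphic and sp.morphs_nested
    # tie between T3A and T4C: the pattern with more ocelli wins
    assert sp.modal_pattern is PatternName.T4C


def test_mixed_species_input_rejected():
    a = summary(MEMBER_SETS[PatternName.T1], taxon=("F", "G", "one"))
    b = summary(MEMBER_SETS[PatternName.T1], taxon=("F", "G", "two"))
    with pytest.raises(ValidationError, match="mixed"):
        aggregate_species([a, b])


def test_eyespot_state_priority():
    sp = aggregate_species(
        [summary(MEMBER_SETS[PatternName.T1])],
        eyespots=["unknown", "present", "absent"],
    )
    assert sp.eyespot == "present"
    assert sp.eyespot_counts == {"present": 1, "absent": 1, "unknown": 1}


# --- survey statistics ------------------------------------------------------


def test_all_symmetric_survey_has_no_asymmetry():
    inds = [
        summary(MEMBER_SETS[PatternName.T3A], MEMBER_SETS[PatternName.T3A], specimen=f"s{i}")
        for i in range(4)
    ]
    sp = aggregate_species(inds)
    report = survey_stats([sp], inds)
    assert report.asymmetric_count == 0
    assert report.asymmetric_fraction == 0.0
    assert report.n_two_sided == 4


def test_adding_a_symmetric_individual_never_raises_asymmetry():
    asym = summary({I.MLMA, I.PLMA}, {I.PLMA}, specimen="a")
    sym = summary({I.MLMA, I.PLMA}, {I.MLMA, I.PLMA}, specimen="b")
    sp1 = aggregate_species([asym])
    before = survey_stats([sp1], [asym]).asymmetric_count
    sp2 = aggregate_species([asym, sym])
    after = survey_stats([sp2], [asym, sym]).asymmetric_count
    assert after == before == 1


def test_fractions_recompute_from_counts_exactly():
    inds = [
        summary({I.MLMA, I.PLMA}, {I.PLMA}, specimen="a"),
        summary({I.MLMA, I.PLMA}, {I.MLMA, I.PLMA}, specimen="b"),
    ]
    report = survey_stats([aggregate_species(inds)], inds)
    assert report.asymmetric_fraction == report.asymmetric_count / report.n_individuals
    assert report.asymmetric_fraction_two_sided == 1 / 2


def test_synthetic_survey_asymmetry_within_binomial_band():
    """With a loss rate of 0.11 over ~519 individuals, the recovered
    asymmetric count must fall within 3 binomial standard deviations of
    the mean n*p (= 57.1, sd 7.1)."""
    df, _ = generate_survey(GeneratorConfig(seed=12))
    _, _, report = run_survey(df)
    mean, sd = 519 * 0.11, (519 * 0.11 * 0.89) ** 0.5
    assert abs(report.asymmetric_count - mean) <= 3 * sd
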