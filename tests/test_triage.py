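"""Rule-engine behavior: aggregation, moderation, override, shortcut."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedtriage.config import NEWBORN_AGE_DAYS, age_band_of
from pedtriage.errors import (
    InvalidLevelError,
    NoItemsError,
    RangeCoverageError,
    UnknownItemError,
)
from pedtriage.triage import (
    FRACTILE_MINUTES,
    Presentation,
    VitalSigns,
    aggregate_items,
    apply_risk_overrides,
    evaluate,
    fractile_target,
    moderate_by_vitals,
    nurse_override,
)


def labels_at_levels(config, levels):
    """One item label per requested base level, from the shipped table."""
    by_level = {}
    for item in config.items:
        by_level.setdefault(item.base_level, item.label)
    return [by_level[lv] for lv in levels]


# --- item aggregation ------------------------------------------------------


@pytest.mark.parametrize(
    "levels,expected",
    [({4, 2}, 2), ({5}, 5), ({3, 3, 1}, 1), ({1, 2, 3, 4, 5}, 1)],
)
def test_aggregate_is_max_severity(config, levels, expected):
    labels = labels_at_levels(config, levels)
    assert aggregate_items(labels, config) == expected


def test_aggregate_rejects_empty_and_unknown(config):
    with pytest.raises(NoItemsError):
        aggregate_items([], config)
    with pytest.raises(UnknownItemError) as err:
        aggregate_items(["no such complaint"], config)
    assert "no such complaint" in str(err.value)


# --- risk overrides --------------------------------------------------------


@pytest.mark.parametrize(
    "level,age,conditions,expected",
    [
        (4, 10, set(), 2),  # newborn matched automatically from age
        (1, 10, {"newborn"}, 1),  # cannot downgrade severity
        (3, 400, set(), 3),  # identity without conditions
        (4, 400, {"immunosuppressed"}, 2),
        (4, 400, {"unconfigured condition"}, 4),  # unknown labels carry no level
    ],
)
def test_risk_overrides(config, level, age, conditions, expected):
    assert apply_risk_overrides(level, conditions, age, config) == expected


def test_risk_override_rejects_bad_level(config):
    with pytest.raises(InvalidLevelError):
        apply_risk_overrides(0, set(), 100, config)


# --- vitals moderation -----------------------------------------------------


def test_absent_vitals_are_normal(config):
    assert moderate_by_vitals(4, VitalSigns(), 1000, config) == 4


def test_in_range_vitals_are_identity(config):
    band = config.ranges_for_age(1000)
    vs = VitalSigns(
        glasgow=15,
        heart_rate=band.vitals["heart_rate"].low + 1,
        resp_rate=band.vitals["resp_rate"].low + 1,
        spo2=98,
    )
    assert moderate_by_vitals(4, vs, 1000, config) == 4


def test_out_of_range_vital_escalates_to_configured_level(config):
    # independent scan of the shipped fixture: find the configured
    # escalation level for a low heart rate in this band
    band = config.ranges_for_age(1000)
    hr_range = band.vitals["heart_rate"]
    low_hr = VitalSigns(heart_rate=hr_range.low - 5)
    assert moderate_by_vitals(4, low_hr, 1000, config) == hr_range.escalation_level


def test_oxygen_support_escalates(config):
    assert (
        moderate_by_vitals(4, VitalSigns(oxygen_support=2.0), 1000, config)
        == config.oxygen_escalation_level
    )


def test_uncovered_age_band_raises(config):
    with pytest.raises(RangeCoverageError):
        moderate_by_vitals(4, VitalSigns(), 25 * 365, config)


# --- fractile mapping ------------------------------------------------------


@pytest.mark.parametrize("level,minutes", [(1, 0), (2, 15), (3, 60), (4, 120), (5, 240)])
def test_fractile_targets(level, minutes):
    assert fractile_target(level) == minutes


def test_fractile_rejects_out_of_range():
    with pytest.raises(InvalidLevelError):
        fractile_target(6)


# --- end-to-end evaluate ---------------------------------------------------


def test_critical_shortcut(config):
    pres = Presentation(age_days=1000, sex="male", critical_flag=True)
    res = evaluate(pres, config)
    assert res.final_level == 1
    assert res.fractile_minutes == 0
    assert res.moderation_applied == ("critical",)


def test_newborn_with_level4_item_becomes_level2(config):
    (label,) = labels_at_levels(config, [4])
    pres = Presentation(age_days=5, sex="female", selected_items={label})
    res = evaluate(pres, config)
    assert res.suggested_level == 4
    assert res.final_level == 2
    assert "risk" in res.moderation_applied


def test_unmoderated_level5(config):
    (label,) = labels_at_levels(config, [5])
    pres = Presentation(age_days=5 * 365, sex="male", selected_items={label})
    res = evaluate(pres, config)
    assert res.final_level == 5
    assert res.fractile_minutes == 240
    assert res.moderation_applied == ()


def test_presentation_requires_some_item_or_flag():
    with pytest.raises(ValueError):
        Presentation(age_days=100, sex="male")


# --- nurse override --------------------------------------------------------


def test_override_upgrade_applies(config):
    (label,) = labels_at_levels(config, [3])
    res = evaluate(Presentation(age_days=2000, sex="male", selected_items={label}), config)
    upgraded = nurse_override(res, 2)
    assert upgraded.final_level == 2
    assert upgraded.override_applied
    assert upgraded.fractile_minutes == 15


def test_override_downgrade_refused(config):
    (label,) = labels_at_levels(config, [3])
    res = evaluate(Presentation(age_days=2000, sex="male", selected_items={label}), config)
    refused = nurse_override(res, 4)
    assert refused.final_level == 3
    assert refused.override_refused
    assert not refused.override_applied


def test_override_identity(config):
    (label,) = labels_at_levels(config, [1])
    res = evaluate(Presentation(age_days=2000, sex="male", selected_items={label}), config)
    assert nurse_override(res, 1) == res


# --- properties ------------------------------------------------------------


def _brute_force_level(pres, config):
    """Independent enumeration of all rules, no shared code path."""
    if pres.critical_flag:
        return 1
    candidates = [config.item_index[lbl].base_level for lbl in pres.selected_items]
    for cond in pres.risk_conditions:
        if cond in config.risk_index:
            candidates.append(config.risk_index[cond].assigned_level)
    if pres.age_days < NEWBORN_AGE_DAYS and "newborn" in config.risk_index:
        candidates.append(config.risk_index["newborn"].assigned_level)
    band = config.ranges_for_age(pres.age_days).vitals
    for name in ("glasgow", "heart_rate", "resp_rate", "spo2"):
        v = getattr(pres.vitals, name)
        if v is not None and name in band:
            r = band[name]
            if (r.low is not None and v < r.low) or (r.high is not None and v > r.high):
                candidates.append(r.escalation_level)
    ox = pres.vitals.oxygen_support
    if ox is not None and ox > 0 and config.oxygen_escalation_level is not None:
        candidates.append(config.oxygen_escalation_level)
    return min(candidates)


@st.composite
def presentations(draw, config):
    labels = sorted(config.item_index)
    items = draw(st.sets(st.sampled_from(labels), min_size=1, max_size=5))
    age = draw(st.integers(min_value=0, max_value=17 * 365))
    risk = draw(st.sets(st.sampled_from(sorted(config.risk_index)), max_size=2))
    hr = draw(st.one_of(st.none(), st.integers(min_value=20, max_value=250)))
    spo2 = draw(st.one_of(st.none(), st.integers(min_value=70, max_value=100)))
    critical = draw(st.booleans())
    return Presentation(
        age_days=age,
        sex=draw(st.sampled_from(["male", "female"])),
        critical_flag=critical,
        selected_items=frozenset(items),
        risk_conditions=frozenset(risk),
        vitals=VitalSigns(heart_rate=hr, spo2=spo2),
    )


@settings(max_examples=200, deadline=None, derandomize=True)
@given(data=st.data())
def test_evaluate_matches_brute_force_oracle(config, data):
    pres = data.draw(presentations(config))
    assert evaluate(pres, config).final_level == _brute_force_level(pres, config)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(data=st.data())
def test_adding_an_item_never_decreases_severity(config, data):
    pres = data.draw(presentations(config))
    extra = data.draw(st.sampled_from(sorted(config.item_index)))
    before = evaluate(pres, config).final_level
    bigger = Presentation(
        age_days=pres.age_days,
        sex=pres.sex,
        critical_flag=pres.critical_flag,
        selected_items=pres.selected_items | {extra},
        risk_conditions=pres.risk_conditions,
        vitals=pres.vitals,
    )
    assert evaluate(bigger, config).final_level <= before


@settings(max_examples=100, deadline=None, derandomize=True)
@given(data=st.data())
def test_bare_presentation_reduces_to_aggregation(config, data):
    """No vitals, no risk set, non-newborn: evaluate == aggregate_items."""
    labels = sorted(config.item_index)
    items = data.draw(st.sets(st.sampled_from(labels), min_size=1, max_size=5))
    pres = Presentation(age_days=1000, sex="male", selected_items=frozenset(items))
    res = evaluate(pres, config)
    assert res.final_level == aggregate_items(items, config)
    assert res.moderation_applied == ()


@settings(max_examples=200, deadline=None, derandomize=True)
@given(data=st.data())
def test_audit_completeness(config, data):
    """final != aggregate implies at least one moderation flag."""
    pres = data.draw(presentations(config))
    res = evaluate(pres, config)
    if pres.critical_flag:
        assert res.moderation_applied == ("critical",)
    elif res.final_level != aggregate_items(pres.selected_items, config):
        assert res.moderation_applied


@settings(max_examples=100, deadline=None, derandomize=True)
@given(data=st.data())
def test_override_is_upgrade_only(config, data):
    pres = data.draw(presentations(config))
    res = evaluate(pres, config)
    requested = data.draw(st.integers(min_value=1, max_value=5))
    after = nurse_override(res, requested)
    assert after.final_level == min(res.final_level, requested)
    assert after.final_level in FRACTILE_MINUTES
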