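import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrcomplexity.records import orders_by_patient
from mrcomplexity.scoring import (active_orders, dichotomize, mrc_icu_score,
                                  mrci_score, score_cohort, score_panel)

from .conftest import make_order, make_patient


def brute_force_mrci(orders, tables):
    """Independent section-by-section summation (set comprehensions, no engine)."""
    a_pairs = set()
    b_by_drug = {}
    c_pairs = set()
    for o in orders:
        a_pairs.add((o.drug_name, o.dosage_form))
        b_by_drug.setdefault(o.drug_name, set()).add(o.frequency_code)
        for d in o.additional_directions:
            c_pairs.add((o.drug_name, d))
    total = 0.0
    for _, form in a_pairs:
        total += tables["MRCI_A"].entries[form]
    for codes in b_by_drug.values():
        total += max(tables["MRCI_B"].entries[c] for c in codes)
    for _, d in c_pairs:
        total += tables["MRCI_C"].entries[d]
    return total


def brute_force_mrc_icu(orders, table):
    items = {(o.drug_name, o.mrc_icu_item) for o in orders if o.mrc_icu_item}
    return sum(table.entries[item] for _, item in items)


def random_regimen(rng, fixture_tables, n_orders, pid="P1"):
    forms = list(fixture_tables["MRCI_A"].entries)
    freqs = list(fixture_tables["MRCI_B"].entries)
    dirs = list(fixture_tables["MRCI_C"].entries)
    items = list(fixture_tables["MRC_ICU"].entries) + [None, None]
    orders = []
    for k in range(n_orders):
        start = float(rng.uniform(-5, 40))
        orders.append(make_order(
            pid=pid,
            drug=f"drug{rng.integers(0, max(2, n_orders))}",
            form=forms[rng.integers(len(forms))],
            freq=freqs[rng.integers(len(freqs))],
            directions=tuple(
                d for d in dirs if rng.random() < 0.3
            ),
            item=items[rng.integers(len(items))],
            start=start,
            stop=None if rng.random() < 0.2 else start + float(rng.uniform(0, 80)),
        ))
    return orders


class TestActiveOrders:
    def test_order_inside_window_included(self):
        order = make_order(start=2.0, stop=10.0)
        assert active_orders([order], 0.0, 24.0) == [order]

    def test_late_start_excluded_at_24h_included_at_48h(self):
        order = make_order(start=30.0, stop=35.0)
        assert active_orders([order], 0.0, 24.0) == []
        assert active_orders([order], 0.0, 48.0) == [order]

    def test_pre_admission_order_active_at_admission_is_retained(self):
        order = make_order(start=-6.0, stop=1.0)
        assert active_orders([order], 0.0, 24.0) == [order]

    def test_pre_admission_order_stopped_before_admission_is_dropped(self):
        order = make_order(start=-6.0, stop=-1.0)
        assert active_orders([order], 0.0, 24.0) == []

    def test_open_order_active_until_window_end(self):
        order = make_order(start=1.0, stop=None)
        assert active_orders([order], 0.0, 24.0) == [order]

    def test_matches_interval_intersection_oracle(self, rng, fixture_tables):
        admission = 5.0
        for _ in range(200):
            orders = random_regimen(rng, fixture_tables, int(rng.integers(1, 8)))
            for end in (6.0, 24.0, 48.0):
                got = {id(o) for o in active_orders(orders, admission, end)}
                want = set()
                for o in orders:
                    stop = np.inf if o.stop_time is None else o.stop_time
                    # closed order interval vs half-open window
                    if o.start_time < admission + end and stop >= admission:
                        want.add(id(o))
                assert got == want


class TestMrciScore:
    def test_empty_regimen_scores_zero(self, fixture_tables):
        assert mrci_score([], fixture_tables) == 0.0

    def test_single_medication_sums_form_and_frequency(self, fixture_tables):
        order = make_order(form="tablet", freq="once_daily")
        assert mrci_score([order], fixture_tables) == 2.0

    def test_directions_add_section_c_weight(self, fixture_tables):
        order = make_order(form="tablet", freq="once_daily",
                           directions=("with_food", "taper"))
        assert mrci_score([order], fixture_tables) == 2.0 + 1.0 + 2.0

    def test_duplicate_orders_score_once(self, fixture_tables):
        order = make_order(form="tablet", freq="once_daily")
        dup = make_order(form="tablet", freq="once_daily", start=5.0, stop=30.0)
        assert mrci_score([order, dup], fixture_tables) == 2.0

    def test_multiple_schedules_take_highest_frequency_weight(self, fixture_tables):
        a = make_order(freq="once_daily")
        b = make_order(freq="q6h")
        assert mrci_score([a, b], fixture_tables) == pytest.approx(1.0 + 4.5)
        assert mrci_score([a, b], fixture_tables,
                          frequency_rule="per_schedule") == pytest.approx(1.0 + 1.0 + 4.5)

    def test_prn_orders_are_scored(self, fixture_tables):
        order = make_order(freq="q6h_prn", prn=True)
        assert mrci_score([order], fixture_tables) == pytest.approx(1.0 + 2.5)


class TestMrcIcuScore:
    def test_empty_regimen_scores_zero(self, fixture_tables):
        assert mrc_icu_score([], fixture_tables["MRC_ICU"]) == 0.0

    def test_published_anchor_regimen_scores_four(self, tables):
        regimen = [
            make_order(drug="vancomycin", drug_class="anti_infectives",
                       form="iv_infusion", freq="q12h", item="vancomycin"),
            make_order(drug="normal_saline", drug_class="iv_fluids",
                       form="iv_infusion", freq="continuous",
                       item="continuous_iv_saline", continuous=True),
        ]
        assert mrc_icu_score(regimen, tables["MRC_ICU"]) == 4.0

    def test_orders_without_item_contribute_nothing(self, fixture_tables):
        order = make_order(item=None)
        assert mrc_icu_score([order], fixture_tables["MRC_ICU"]) == 0.0


class TestOracleEquivalence:
    def test_engine_equals_brute_force_on_random_regimens(self, rng, fixture_tables):
        for _ in range(300):
            orders = random_regimen(rng, fixture_tables, int(rng.integers(0, 12)))
            assert mrci_score(orders, fixture_tables) == pytest.approx(
                brute_force_mrci(orders, fixture_tables), abs=1e-12)
            assert mrc_icu_score(orders, fixture_tables["MRC_ICU"]) == pytest.approx(
                brute_force_mrc_icu(orders, fixture_tables["MRC_ICU"]), abs=1e-12)


@settings(max_examples=50, deadline=None)
@given(split=st.integers(min_value=0, max_value=10), seed=st.integers(0, 10_000))
def test_disjoint_regimen_additivity(split, seed):
    """Scores over disjoint drug sets add; adding orders never lowers a score."""
    from mrcomplexity.weights import default_weight_tables

    tables = default_weight_tables()
    rng = np.random.default_rng(seed)
    forms = list(tables["MRCI_A"].entries)
    freqs = list(tables["MRCI_B"].entries)
    orders = [
        make_order(drug=f"drug{k}", form=forms[rng.integers(len(forms))],
                   freq=freqs[rng.integers(len(freqs))],
                   item="vancomycin" if rng.random() < 0.3 else None)
        for k in range(10)
    ]
    left, right = orders[:split], orders[split:]
    whole_mrci = mrci_score(orders, tables)
    assert whole_mrci == pytest.approx(
        mrci_score(left, tables) + mrci_score(right, tables))
    # MRC-ICU additivity holds per distinct (drug, item) pair
    assert mrc_icu_score(orders, tables["MRC_ICU"]) == pytest.approx(
        mrc_icu_score(left, tables["MRC_ICU"])
        + mrc_icu_score(right, tables["MRC_ICU"]))
    assert whole_mrci >= mrci_score(left, tables)


class TestScorePanel:
    def test_patient_with_no_orders_scores_zero_everywhere(self, tables):
        panel = score_panel(make_patient(), [], tables)
        assert panel.mrci_24h == panel.mrci_48h == 0.0
        assert panel.mrc_icu_24h == panel.mrc_icu_48h == 0.0

    def test_order_starting_hour_30_counts_only_in_48h_window(self, tables):
        patient = make_patient()
        orders = [make_order(form="tablet", freq="once_daily", start=30.0, stop=40.0)]
        panel = score_panel(patient, orders, tables)
        assert panel.mrci_24h == 0.0
        assert panel.mrci_48h > 0.0

    def test_cumulative_windows_are_monotone_for_every_patient(
            self, small_cohort, tables):
        patients, orders, _ = small_cohort
        panels = score_cohort(patients, orders_by_patient(orders), tables)
        for panel in panels.values():
            assert panel.mrci_48h >= panel.mrci_24h
            assert panel.mrc_icu_48h >= panel.mrc_icu_24h

    def test_daily_mode_scores_only_second_day(self, tables):
        patient = make_patient()
        orders = [make_order(form="tablet", freq="once_daily", start=1.0, stop=5.0)]
        panel = score_panel(patient, orders, tables, window_mode="daily")
        assert panel.mrci_24h > 0.0
        assert panel.mrci_48h == 0.0  # order inactive within [24, 48)

    def test_generated_cohort_median_near_configured_target(self, small_cohort):
        _, _, truth = small_cohort
        assert truth["score_medians"]["mrc_icu_24h"] == pytest.approx(6.0, abs=1.5)
        assert truth["score_medians"]["mrci_24h"] == pytest.approx(63.0, rel=0.15)


class TestDichotomize:
    def test_strict_inequality_at_the_cutoffs(self):
        from mrcomplexity.scoring import ScorePanel

        at_cut = ScorePanel("A", {24: 63.0, 48: 63.0}, {24: 6.0, 48: 6.0}, (24, 48))
        above = ScorePanel("B", {24: 63.5, 48: 64.0}, {24: 6.5, 48: 7.0}, (24, 48))
        labels = dichotomize([at_cut, above])
        assert labels["A"] == {"mrci_high": False, "mrc_icu_high": False}
        assert labels["B"] == {"mrci_high": True, "mrc_icu_high": True}

    def test_median_mode_matches_fixed_mode_when_median_is_the_cutoff(self):
        from mrcomplexity.scoring import ScorePanel

        # odd cohort built so the 24 h medians are exactly 63 and 6
        scores = [(50, 3), (63, 6), (80, 9)]
        panels = [ScorePanel(f"P{i}", {24: float(m), 48: float(m)},
                             {24: float(c), 48: float(c)}, (24, 48))
                  for i, (m, c) in enumerate(scores)]
        assert dichotomize(panels, mode="median") == dichotomize(panels, mode="fixed")

    def test_median_mode_empty_cohort_errors(self):
        with pytest.raises(ValueError, match="empty"):
            dichotomize([], mode="median")
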