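"""Folding rules, E_FRET banding and additive decomposition."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import kturnfold as kf
from kturnfold.errors import RankDeficient
from kturnfold.motif import substitute_many
from kturnfold.rules import ELEMENT_ORDER, ExchangePanel


def test_kt7_is_ion_folding(kt7_ann):
    """Every Kt-7 element predisposes unassisted ion-induced folding."""
    cls = kf.rule_classify(kt7_ann)
    assert cls.call == "ion_folding"
    assert cls.evidence["MINUS1_PAIR"] == "favorable"
    assert cls.evidence["PAIR_3"] == "favorable"
    assert cls.evidence["PAIR_4"] == "favorable"
    assert cls.evidence["LOOP"] == "neutral"


def test_boxcd_is_protein_dependent(boxcd_ann):
    cls = kf.rule_classify(boxcd_ann)
    assert cls.call == "protein_dependent"
    assert cls.evidence["MINUS1_PAIR"] == "unfavorable"


def test_inosine_blocks_folding(catalog):
    """Removing the G-1n exocyclic amine (G→I) impairs unassisted folding."""
    ann = kf.annotate_kturn(catalog["kt7_g1ni"])
    assert kf.rule_classify(ann).call == "protein_dependent"


def test_four_change_flips_call(catalog):
    """box C/D with all four Kt-7 elements classifies as ion-folding."""
    four = kf.annotate_kturn(catalog["boxcd_all4_from_kt7"])
    assert kf.rule_classify(four).call == "ion_folding"


def test_single_minus1_exchange_in_boxcd(catalog):
    """-1b:-1n→C:G is the one single change giving detectable folding,
    though 3b:3n = U:U keeps it impaired rather than fully ion-folding."""
    ann = kf.annotate_kturn(catalog["boxcd_x_minus1_pair"])
    cls = kf.rule_classify(ann)
    assert cls.call == "impaired"
    assert cls.evidence["MINUS1_PAIR"] == "favorable"


def test_unknown_pair_class_caps_call(kt7_ann):
    """An element with no assigned class keeps the call conservative."""
    variant = kf.annotate_kturn(substitute_many(kt7_ann, {"3b": "C", "3n": "G"}))
    cls = kf.rule_classify(variant)
    assert cls.call == "impaired"
    assert cls.evidence["PAIR_3"] == "unknown"


@given(
    minus1n=st.sampled_from("ACGUI"),
    pair3=st.sampled_from(["A:G", "U:G", "U:U", "C:G", "G:C"]),
    pair4=st.sampled_from(["C:G", "G:C", "A:U", "U:A"]),
)
def test_minus1n_dominance_property(minus1n, pair3, pair4):
    """A blocking -1n forces protein_dependent for any other elements."""
    catalog = kf.fixtures()
    kt7_ann = kf.annotate_kturn(catalog["kt7_fret"])
    p3b, p3n = pair3.split(":")
    p4b, p4n = pair4.split(":")
    edits = {"-1n": minus1n, "3b": p3b, "3n": p3n, "4b": p4b, "4n": p4n}
    variant = kf.annotate_kturn(substitute_many(kt7_ann, edits))
    cls = kf.rule_classify(variant)
    if minus1n in {"C", "I"}:
        assert cls.call == "protein_dependent"
    else:
        assert cls.call != "protein_dependent"


@pytest.mark.parametrize(
    "final, band",
    [(0.63, "folds"), (0.36, "folds"), (0.35, "folds"),
     (0.335, "indeterminate"), (0.32, "none"), (0.30, "none")],
)
def test_final_efret_banding(final, band):
    assert kf.classify_final_efret(final) == band


def test_final_efret_banding_monotone():
    order = {"none": 0, "indeterminate": 1, "folds": 2}
    values = [kf.classify_final_efret(x) for x in np.linspace(0.0, 1.0, 101)]
    ranks = [order[v] for v in values]
    assert ranks == sorted(ranks)


def test_rule_config_file_round_trip(tmp_path):
    config = kf.RuleConfig(folded_min=0.4, unfolded_max=0.3)
    path = tmp_path / "rules.json"
    config.to_file(path)
    back = kf.RuleConfig.from_file(path)
    assert back.folded_min == 0.4
    assert back.minus1n_blocking_residues == frozenset({"C", "I"})
    with pytest.raises(ValueError):
        kf.RuleConfig(folded_min=0.3, unfolded_max=0.35)


# ---------------------------------------------------------------------------
# additive decomposition

def full_factorial_panel(baseline, effects, interaction=0.0,
                         interacting=("MINUS1_PAIR", "PAIR_3")):
    rows = []
    for bits in itertools.product((0, 1), repeat=4):
        indicator = dict(zip(ELEMENT_ORDER, bits))
        value = baseline + sum(effects[e] * indicator[e] for e in ELEMENT_ORDER)
        value += interaction * indicator[interacting[0]] * indicator[interacting[1]]
        rows.append({"variant_id": "v" + "".join(map(str, bits)),
                     **indicator, "final_efret": value})
    return ExchangePanel(pd.DataFrame(rows))


EFFECTS = {"MINUS1_PAIR": -0.32, "LOOP": 0.02, "PAIR_3": -0.10, "PAIR_4": -0.08}


def test_exact_additive_panel_recovered():
    panel = full_factorial_panel(0.63, EFFECTS)
    result = kf.additive_decomposition(panel)
    assert result.baseline == pytest.approx(0.63, abs=1e-12)
    for element, effect in EFFECTS.items():
        assert result.effects[element] == pytest.approx(effect, abs=1e-12)
    assert result.additivity_score < 1e-12


def test_effects_match_group_mean_oracle(rng):
    """On the full factorial each effect equals the difference of group
    means between its indicator levels."""
    panel = full_factorial_panel(0.63, EFFECTS)
    noisy = panel.table.copy()
    noisy["final_efret"] += rng.normal(0, 0.01, len(noisy))
    panel = ExchangePanel(noisy)
    result = kf.additive_decomposition(panel)
    for element in ELEMENT_ORDER:
        on = noisy.loc[noisy[element] == 1, "final_efret"].mean()
        off = noisy.loc[noisy[element] == 0, "final_efret"].mean()
        assert result.effects[element] == pytest.approx(on - off, abs=1e-10)


def test_injected_interaction_detected():
    """A pairwise interaction of size delta leaves residuals >= delta/4,
    localized by sign to rows containing that pair."""
    delta = 0.08
    panel = full_factorial_panel(0.63, EFFECTS, interaction=delta)
    result = kf.additive_decomposition(panel)
    assert result.additivity_score >= delta / 4 - 1e-12
    both_on = panel.table[
        (panel.table["MINUS1_PAIR"] == 1) & (panel.table["PAIR_3"] == 1)
    ]["variant_id"]
    assert (result.residuals.loc[both_on] > 0).all()


def test_decomposition_idempotent():
    """Refitting on model-generated values returns the same effects."""
    panel = full_factorial_panel(0.63, EFFECTS)
    first = kf.additive_decomposition(panel)
    regenerated = panel.table.copy()
    regenerated["final_efret"] = first.baseline + sum(
        first.effects[e] * regenerated[e] for e in ELEMENT_ORDER
    )
    second = kf.additive_decomposition(ExchangePanel(regenerated))
    for element in ELEMENT_ORDER:
        assert second.effects[element] == pytest.approx(
            first.effects[element], abs=1e-10
        )


def test_rank_deficient_panel_raises():
    table = full_factorial_panel(0.63, EFFECTS).table
    collinear = table[table["MINUS1_PAIR"] == table["PAIR_3"]].reset_index(drop=True)
    with pytest.raises(RankDeficient):
        kf.additive_decomposition(ExchangePanel(collinear))


def test_panel_validation():
    table = full_factorial_panel(0.63, EFFECTS).table
    with pytest.raises(ValueError):
        ExchangePanel(table.head(4))  # too few rows
    duplicated = pd.concat([table.head(5), table.head(1)], ignore_index=True)
    with pytest.raises(ValueError):
        ExchangePanel(duplicated)
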