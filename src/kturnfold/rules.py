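"""Sequence->folding-propensity rules and additive element decomposition.

The rule layer encodes the empirical relation between standard k-turn
sequence elements and unassisted (ion-induced) folding: the -1n position
dominates (G permits folding; C, or inosine lacking the guanine N2 amine,
blocks it so the k-turn needs a bound protein such as L7Ae to fold), while
the 3b:3n and 4b:4n pairs modulate the extent of folding in a smaller,
approximately additive way.  The loop sequence is recorded but never
changes a call.

The additive decomposition fits final E_FRET over an element-exchange
panel as baseline + sum of per-element effects, exposing departures from
additivity as residuals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import RankDeficient
from .motif import ElementId, KTurnAnnotation

#: element class vocabulary
FAVORABLE, UNFAVORABLE, NEUTRAL, UNKNOWN = (
    "favorable", "unfavorable", "neutral", "unknown",
)


@dataclass(frozen=True)
class RuleConfig:
    """Configurable sequence rules and E_FRET thresholds.

    ``folded_min``/``unfolded_max`` delimit the empirical bands: every
    -1n = G construct reached a final E_FRET above 0.35, every -1n = C
    construct stayed below 0.32; values between are an indeterminate band
    rather than a single cut.
    """

    minus1n_folding_residue: str = "G"
    minus1n_blocking_residues: frozenset[str] = frozenset({"C", "I"})
    pair3_classes: dict = field(
        default_factory=lambda: {"A:G": "folding", "U:G": "folding", "U:U": "intermediate"}
    )
    pair4_classes: dict = field(
        default_factory=lambda: {"C:G": "folding", "G:C": "impaired"}
    )
    loop_effect: str = "minor"
    folded_min: float = 0.35
    unfolded_max: float = 0.32

    def __post_init__(self) -> None:
        if self.folded_min <= self.unfolded_max:
            raise ValueError("folded_min must exceed unfolded_max")

    def to_file(self, path) -> None:
        payload = asdict(self)
        payload["minus1n_blocking_residues"] = sorted(self.minus1n_blocking_residues)
        payload["version"] = 1
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_file(cls, path) -> "RuleConfig":
        import yaml  # safe_load also reads JSON

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload.pop("version", None)
        payload["minus1n_blocking_residues"] = frozenset(
            payload.get("minus1n_blocking_residues", {"C", "I"})
        )
        return cls(**payload)


@dataclass(frozen=True)
class FoldingClassification:
    """Rule-based call with per-element evidence and a short rationale."""

    call: str  # ion_folding | impaired | protein_dependent
    evidence: dict  # element name -> favorable/unfavorable/neutral/unknown
    rationale: str


def _pair_evidence(pair_class: str) -> str:
    return {
        "folding": FAVORABLE,
        "intermediate": UNFAVORABLE,
        "impaired": UNFAVORABLE,
    }.get(pair_class, UNKNOWN)


def rule_classify(
    annotation: KTurnAnnotation, config: RuleConfig | None = None
) -> FoldingClassification:
    """Classify a standard k-turn as ion-folding, impaired or
    protein-dependent from its sequence elements.

    The -1n dominance rule applies first: a blocking residue there makes
    the call protein_dependent regardless of the other elements.  With
    -1n favorable, the 3b:3n and 4b:4n classes combine: all favorable
    gives ion_folding, any intermediate/impaired gives impaired, and
    unknown classes conservatively cap the call at impaired.
    """
    config = config or RuleConfig()
    minus1n = annotation.residue("-1n")
    pair3 = annotation.pair("3b", "3n")
    pair4 = annotation.pair("4b", "4n")
    pair3_class = config.pair3_classes.get(pair3, "unknown")
    pair4_class = config.pair4_classes.get(pair4, "unknown")
    evidence = {
        "MINUS1_PAIR": UNKNOWN,
        "LOOP": NEUTRAL,
        "PAIR_3": _pair_evidence(pair3_class),
        "PAIR_4": _pair_evidence(pair4_class),
    }

    if minus1n in config.minus1n_blocking_residues:
        evidence["MINUS1_PAIR"] = UNFAVORABLE
        reason = (
            f"-1n = {minus1n} blocks unassisted folding; "
            "protein binding (L7Ae family) required"
        )
        return FoldingClassification("protein_dependent", evidence, reason)

    if minus1n == config.minus1n_folding_residue:
        evidence["MINUS1_PAIR"] = FAVORABLE
    else:
        # neither the folding nor a blocking residue: undetermined position
        return FoldingClassification(
            "impaired",
            evidence,
            f"-1n = {minus1n} has no assigned rule; conservative call",
        )

    if pair3_class == "folding" and pair4_class == "folding":
        return FoldingClassification(
            "ion_folding",
            evidence,
            f"-1n = G with folding-class 3b:3n = {pair3} and 4b:4n = {pair4}",
        )
    return FoldingClassification(
        "impaired",
        evidence,
        f"-1n = G but 3b:3n = {pair3} ({pair3_class}) / 4b:4n = {pair4} "
        f"({pair4_class}) limit folding",
    )


def classify_final_efret(final: float, config: RuleConfig | None = None) -> str:
    """Band a final E_FRET: 'folds' / 'none' / 'indeterminate'."""
    config = config or RuleConfig()
    if not np.isfinite(final):
        raise ValueError("final E_FRET must be finite")
    if final >= config.folded_min:
        return "folds"
    if final <= config.unfolded_max:
        return "none"
    return "indeterminate"


# ---------------------------------------------------------------------------
# additive element-effect decomposition

ELEMENT_ORDER = tuple(e.value for e in ElementId)


@dataclass(frozen=True)
class ExchangePanel:
    """Variant x element-indicator x final-E_FRET table.

    Indicators are 0 for the reference parent's element and 1 for the
    alternate parent's, so the decomposition applies to any two-parent
    exchange design.
    """

    table: pd.DataFrame  # columns: variant_id, one per element, final_efret

    def __post_init__(self) -> None:
        required = {"variant_id", "final_efret", *ELEMENT_ORDER}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        indicators = self.table[list(ELEMENT_ORDER)].to_numpy()
        if not np.isin(indicators, (0, 1)).all():
            raise ValueError("indicators must be 0/1")
        if len(np.unique(indicators, axis=0)) != len(indicators):
            raise ValueError("indicator vectors must be unique")
        if len(self.table) < 5:
            raise ValueError("need >= 5 variants for the decomposition")


@dataclass(frozen=True)
class Decomposition:
    baseline: float
    effects: dict  # element -> additive effect on final E_FRET
    residuals: pd.Series  # per variant_id
    additivity_score: float  # max |residual|


def additive_decomposition(panel: ExchangePanel) -> Decomposition:
    """Least-squares additive model final_efret ~ baseline + sum(effects).

    Residuals localize non-additive (interaction) structure; the
    additivity score is the largest absolute residual.
    """
    table = panel.table
    x = np.column_stack(
        [np.ones(len(table))] + [table[e].to_numpy(float) for e in ELEMENT_ORDER]
    )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise RankDeficient("element effects not identifiable from this design")
    y = table["final_efret"].to_numpy(float)
    coef, *_ = np.linalg.lstsq(x, y)
    resid = pd.Series(y - x @ coef, index=table["variant_id"].to_numpy())
    return Decomposition(
        baseline=float(coef[0]),
        effects={e: float(c) for e, c in zip(ELEMENT_ORDER, coef[1:])},
        residuals=resid,
        additivity_score=float(np.abs(resid.to_numpy()).max()),
    )
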