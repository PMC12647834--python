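"""Classify fitted quadratic relationships into qualitative shape scenarios.

A distance-probability relationship is summarized by the signs and
significance of its linear (beta1) and quadratic (beta2) coefficients.
Bidirectional distances map to scenarios a-e, unidirectional to f-j:

========== =========================== ==============================
scenario    coefficients                meaning
========== =========================== ==============================
a          beta2 ns, beta1 sig > 0      favors higher values (directional)
b          beta2 sig < 0, beta1 sig > 0 optimum at moderately higher values
c          beta2 sig < 0, beta1 ns      optimum at zero distance (similarity)
d          beta2 sig < 0, beta1 sig < 0 optimum at moderately lower values
e          beta2 ns, beta1 sig < 0      favors lower values (directional)
f/j        beta2 ns, beta1 sig > 0      any dissimilarity favored
g/i        beta2 sig < 0, beta1 sig > 0 optimum at intermediate dissimilarity
h          beta1 sig < 0                similarity favored (peak at/below 0)
null       both ns                      no signal
========== =========================== ==============================

"Non-significant" operationalizes the framework's "= 0"; a significant
positive quadratic term (a U-shape) falls outside the framework and is
labelled ``monotone-unclassified``. Schematically duplicate unidirectional
panels are emitted as the combined labels ``f/j`` and ``g/i``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["ScenarioLabel", "classify", "classify_model"]

_DESCRIPTIONS = {
    "a": "naturalization favored at higher values than donors (directional, no optimum)",
    "b": "optimum at moderately higher values than donors",
    "c": "optimum at zero distance: similarity favored",
    "d": "optimum at moderately lower values than donors",
    "e": "naturalization favored at lower values than donors (directional, no optimum)",
    "f/j": "any dissimilarity favored (monotone increase)",
    "g/i": "optimum at intermediate dissimilarity",
    "h": "similarity favored (probability declines with distance)",
    "null": "no significant relationship",
    "monotone-unclassified": "significant positive quadratic term: outside the framework",
}


@dataclass(frozen=True)
class ScenarioLabel:
    predictor: str | None
    direction_type: str  # bidirectional | unidirectional
    scenario: str
    description: str


def classify(
    beta1: float,
    beta2: float,
    p1: float,
    p2: float,
    direction_type: str,
    alpha_level: float = 0.05,
    predictor: str | None = None,
) -> ScenarioLabel:
    """Map (beta1, beta2) signs and significance to a shape scenario."""
    if direction_type not in ("bidirectional", "unidirectional"):
        raise ValueError(f"invalid direction_type {direction_type!r}")
    if not 0.0 < alpha_level < 1.0:
        raise ValueError("alpha_level must lie in (0, 1)")
    sig1 = p1 < alpha_level
    sig2 = p2 < alpha_level
    if sig2 and beta2 > 0:
        scen = "monotone-unclassified"
    elif direction_type == "bidirectional":
        if sig2:  # beta2 < 0
            scen = "b" if (sig1 and beta1 > 0) else ("d" if (sig1 and beta1 < 0) else "c")
        else:
            scen = "a" if (sig1 and beta1 > 0) else ("e" if (sig1 and beta1 < 0) else "null")
    else:
        if sig2:  # beta2 < 0: a peak exists on the standardized scale
            if sig1 and beta1 > 0:
                scen = "g/i"
            else:
                # beta1 ns or sig<0: the peak sits at or below zero distance,
                # collapsing to similarity-favored
                scen = "h"
        elif sig1 and beta1 > 0:
            scen = "f/j"
        elif sig1 and beta1 < 0:
            scen = "h"
        else:
            scen = "null"
    return ScenarioLabel(
        predictor=predictor,
        direction_type=direction_type,
        scenario=scen,
        description=_DESCRIPTIONS[scen],
    )


def classify_model(tests: pd.DataFrame, direction_types: dict, alpha_level: float = 0.05) -> pd.DataFrame:
    """Classify every predictor of a Wald-test table.

    ``tests`` is the output of :func:`naturadist.model.wald_tests`;
    ``direction_types`` maps predictor name to bidirectional/unidirectional.
    """
    rows = []
    t = tests.set_index("term")
    for pred, dtype in direction_types.items():
        lab = classify(
            beta1=float(t.loc[f"{pred}_linear", "estimate"]),
            beta2=float(t.loc[f"{pred}_quadratic", "estimate"]),
            p1=float(t.loc[f"{pred}_linear", "p"]),
            p2=float(t.loc[f"{pred}_quadratic", "p"]),
            direction_type=dtype,
            alpha_level=alpha_level,
            predictor=pred,
        )
        rows.append(
            {
                "predictor": pred,
                "direction_type": dtype,
                "scenario": lab.scenario,
                "description": lab.description,
            }
        )
    return pd.DataFrame(rows)
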