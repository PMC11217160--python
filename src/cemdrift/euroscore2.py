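"""EuroSCORE II baseline risk calculator.

Evaluates the published 18-item logistic model for in-hospital mortality
after adult cardiac surgery:

    risk = logistic(constant + sum_i beta_i * x_i)

Coefficients are the published constants of the original EuroSCORE II
model (Nashef et al., Eur J Cardiothorac Surg 2012;41:734-44, Table 6),
shipped verbatim as a versioned constant table; they are never refitted.

Canonical record encoding (matching the synthetic registry columns):

==========================  =========================================
age                         years (continuous)
nyha                        0=I, 1=II, 2=III, 3=IV
renal_impairment            0=normal, 1=moderate (CC 50-85 mL/min),
                            2=on dialysis, 3=severe (CC<50, off dialysis)
lv_function                 0=good(>50%), 1=moderate(31-50%),
                            2=poor(21-30%), 3=very poor(<=20%)
pulmonary_hypertension      0=PA sys <31, 1=31-55, 2=>55 mm Hg
urgency                     0=elective, 1=urgent, 2=emergency, 3=salvage
weight_of_intervention      0=isolated CABG, 1=single non-CABG,
                            2=two procedures, 3=three procedures
(remaining 11 items)        binary 0/1 flags
==========================  =========================================

The age term contributes 1 unit for age <= 60 and one additional unit per
year above 60 (x = max(1, age - 59)), per the published model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = ["euroscore2_risk", "EUROSCORE2_VERSION", "EUROSCORE2_COEFFICIENTS",
           "EUROSCORE2_CONSTANT", "EUROSCORE2_COLUMNS"]

EUROSCORE2_VERSION = "2012 (Nashef et al., EJCTS 41:734-744, Table 6)"

EUROSCORE2_CONSTANT = -5.324537

#: Published log-odds coefficients.  Ordinal items map level code -> beta.
EUROSCORE2_COEFFICIENTS: dict[str, object] = {
    "age": 0.0285181,  # per unit of max(1, age - 59)
    "nyha": (0.0, 0.1070545, 0.2958358, 0.5597929),
    "renal_impairment": (0.0, 0.303553, 0.6421508, 0.8592256),
    "chronic_lung_disease": 0.1886564,
    "poor_mobility": 0.2407181,
    "previous_cardiac_surgery": 1.118599,
    "lv_function": (0.0, 0.3150652, 0.8084096, 0.9346919),
    "pulmonary_hypertension": (0.0, 0.1788899, 0.3491475),
    "ccs4_angina": 0.2226147,
    "urgency": (0.0, 0.3174673, 0.7039121, 1.362947),
    "weight_of_intervention": (0.0, 0.0062118, 0.5521478, 0.9724533),
    "diabetes_on_insulin": 0.3542749,
    "female": 0.2196434,
    "recent_mi": 0.1528943,
    "critical_preoperative_state": 1.086517,
    "extracardiac_arteriopathy": 0.5360268,
    "active_endocarditis": 0.6194522,
    "thoracic_aorta_surgery": 0.6527205,
}

EUROSCORE2_COLUMNS: tuple[str, ...] = tuple(EUROSCORE2_COEFFICIENTS)


def _age_units(age: np.ndarray) -> np.ndarray:
    return np.maximum(1.0, age - 59.0)


def euroscore2_risk(records) -> np.ndarray | float:
    """Predicted in-hospital mortality probability under EuroSCORE II.

    ``records`` may be a DataFrame with the canonical columns, a Series, or
    a mapping.  Raises ``ValueError`` for a missing item or an
    out-of-range ordinal level.
    """
    single = not isinstance(records, pd.DataFrame)
    df = pd.DataFrame([records]) if single else records
    missing = set(EUROSCORE2_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records missing EuroSCORE II items: {sorted(missing)}")

    eta = np.full(len(df), EUROSCORE2_CONSTANT)
    for item, beta in EUROSCORE2_COEFFICIENTS.items():
        x = df[item].to_numpy(dtype=float)
        if item == "age":
            if np.any(x < 18) or np.any(x > 120):
                raise ValueError("age outside plausible adult range [18, 120]")
            eta += beta * _age_units(x)
        elif isinstance(beta, tuple):
            codes = x.astype(int)
            if np.any(x != codes) or codes.min() < 0 or codes.max() >= len(beta):
                raise ValueError(
                    f"{item}: level out of range 0..{len(beta) - 1}")
            eta += np.asarray(beta)[codes]
        else:
            if np.any((x != 0) & (x != 1)):
                raise ValueError(f"{item}: binary flag must be 0/1")
            eta += beta * x
    p = expit(eta)
    return float(p[0]) if single else p
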