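"""Published reference values for a TCGA-LUAD eight-pair immune-lncRNA signature.

The multivariate Cox output of the published eight-pair model (coefficient,
hazard ratio, 95% CI bounds, Wald p) and the matching cohort stage counts.
These serve as worked reference data for validating hazard-ratio and
Wald-test arithmetic: exp(coef) must reproduce the printed HR, and the SE
recovered from the CI must reproduce the printed p.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .signature import Z95

#: columns: pair, coef, HR, HR.95L, HR.95H, p_value
LUAD_SIGNATURE_ROWS: list[tuple[str, float, float, float, float, float]] = [
    ("LINC00958|HIF1A-AS3", -0.559056064, 0.571748503, 0.404824948, 0.807500506, 0.00150468),
    ("ITGB1-DT|FENDRR", 0.372948657, 1.452009787, 1.060841449, 1.9874152, 0.019871749),
    ("AC004264.1|LINC02036", 0.39121285, 1.478773237, 1.076738936, 2.030919672, 0.015661584),
    ("AC026355.2|AL049836.1", -0.42262269, 0.655325847, 0.480477131, 0.893803134, 0.00760824),
    ("LINC02195|LINC01116", -0.513869512, 0.598176444, 0.437208026, 0.81840917, 0.00131407),
    ("LINC02362|LINC00941", -0.534861917, 0.585750167, 0.411859423, 0.833059143, 0.002916854),
    ("LINC01116|LINC02154", 0.621835544, 1.86234332, 1.229948538, 2.819892489, 0.003305756),
    ("AL606489.1|AC006017.1", 0.443770725, 1.558573103, 1.084414844, 2.240056129, 0.016491365),
]

#: TCGA-LUAD cohort stage distribution (count, cohort size 490)
LUAD_STAGE_COUNTS = {"I": 263, "II": 115, "III": 79, "IV": 25, "unknown": 8}
LUAD_COHORT_SIZE = 490


def hr_from_coef(coef: float) -> float:
    """Hazard ratio implied by a Cox log-hazard coefficient."""
    return float(np.exp(coef))


def se_from_ci(ci_low: float, ci_high: float) -> float:
    """Wald SE recovered from a 95% CI on the hazard-ratio scale."""
    return float((np.log(ci_high) - np.log(ci_low)) / (2.0 * Z95))


def wald_p_from_ci(coef: float, ci_low: float, ci_high: float) -> float:
    """Two-sided normal Wald p recomputed from the coefficient and its CI."""
    se = se_from_ci(ci_low, ci_high)
    return float(2.0 * stats.norm.sf(abs(coef) / se))


def stage_fraction_percent(stage: str) -> float:
    """Stage share of the published cohort, in percent."""
    return round(100.0 * LUAD_STAGE_COUNTS[stage] / LUAD_COHORT_SIZE, 2)
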