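"""Published aggregate data of the 18-patient neoadjuvant immunochemotherapy
cohort in EGFR-mutant NSCLC used throughout the examples and tests.

The baseline-characteristics table is reconstructed patient-by-patient from
the published per-variable counts stratified by major pathological response
(MPR, n=8) versus non-MPR (n=10).  Only per-variable margins were published,
so the joint assignment across variables is arbitrary — every per-variable
crosstab against MPR status matches the printed counts, which is all the
association tests consume.  Ages were published only as group summaries
(mean +/- sd), available via :func:`age_summaries`.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["cohort_characteristics", "age_summaries", "simon_design_parameters"]

# per-variable counts as (category -> (n_mpr, n_nmpr)); 8 MPR, 10 nMPR
_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "gender": {"male": (1, 7), "female": (7, 3)},
    "smoking": {"non-smoker": (8, 5), "ever-smoker": (0, 5)},
    "ps": {"0": (4, 9), "1": (4, 1)},
    "staging": {"PET/CT+MRI": (5, 8), "PET/CT": (3, 2)},
    "histology": {"adenocarcinoma": (6, 10), "adeno-squamous": (2, 0)},
    "egfr": {"19del": (2, 3), "L858R": (1, 4), "20ins": (3, 1), "uncommon": (2, 2)},
    "t_stage": {"T1": (0, 4), "T2": (4, 4), "T3": (3, 0), "T4": (1, 2)},
    "n_stage": {"N1": (1, 3), "N2": (7, 7)},
    "tnm": {"IIB": (1, 2), "IIIA": (3, 7), "IIIB": (4, 1)},
    "pdl1": {"negative": (4, 5), "1-49%": (2, 4), ">=50%": (2, 1)},
}


def cohort_characteristics() -> pd.DataFrame:
    """Patient-level baseline characteristics with an ``mpr`` flag.

    18 rows; each variable's crosstab against ``mpr`` reproduces the
    published counts.  Joint structure across variables is not informative.
    """
    n_mpr, n_nmpr = 8, 10
    data: dict[str, list] = {"mpr": [True] * n_mpr + [False] * n_nmpr}
    for var, cats in _COUNTS.items():
        col_mpr: list[str] = []
        col_nmpr: list[str] = []
        for cat, (a, b) in cats.items():
            col_mpr.extend([cat] * a)
            col_nmpr.extend([cat] * b)
        assert len(col_mpr) == n_mpr and len(col_nmpr) == n_nmpr
        data[var] = col_mpr + col_nmpr
    df = pd.DataFrame(data, index=[f"PT{i + 1:02d}" for i in range(18)])
    return df


def age_summaries() -> dict[str, tuple[float, float, int]]:
    """Published age summaries: group -> (mean, sd, n)."""
    return {"mpr": (57.3, 9.1, 8), "nmpr": (60.2, 4.5, 10)}


def simon_design_parameters() -> dict:
    """The trial's Simon two-stage design parameters.

    Stage 1 enrolls 18 patients; at least 3 responses are required to
    continue (futility bound r1=2).  The treatment is declared active if
    more than 6 of 35 total patients respond.  Null and alternative MPR
    rates are 10% and 30%.
    """
    return {"n1": 18, "r1": 2, "n": 35, "r": 6, "p0": 0.10, "p1": 0.30}
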