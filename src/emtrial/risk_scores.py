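"""CHA2DS2-VASc and HAS-BLED risk scores from component flags.

Both scores are simple additive clinical indices used in atrial
fibrillation: CHA2DS2-VASc grades stroke risk (0-9), HAS-BLED grades
bleeding risk (0-9).  Functions are vectorised: every argument may be a
scalar, a numpy array, or a pandas Series; broadcasting follows numpy
rules and the result has the broadcast shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cha2ds2_vasc", "has_bled", "CHA2DS2_VASC_COMPONENTS", "HAS_BLED_COMPONENTS"]

#: baseline-table column names the scores are computed from
CHA2DS2_VASC_COMPONENTS = (
    "chf",
    "hypertension",
    "diabetes",
    "stroke_tia_history",
    "vascular_disease",
)
HAS_BLED_COMPONENTS = (
    "uncontrolled_htn",
    "renal_disease",
    "liver_disease",
    "stroke_tia_history",
    "bleeding_history",
    "labile_inr",
    "antiplatelet_or_nsaid",
    "alcohol_use",
)


def _as_int(x) -> np.ndarray:
    return np.asarray(x).astype(int)


def cha2ds2_vasc(
    age,
    sex,
    chf,
    hypertension,
    diabetes,
    stroke_tia_history,
    vascular_disease,
):
    """CHA2DS2-VASc stroke-risk score.

    Points: CHF 1, hypertension 1, age 65-74 1 / age >=75 2, diabetes 1,
    prior stroke or TIA 2, vascular disease 1, female sex 1.  Total in
    [0, 9].

    Parameters
    ----------
    age : scalar or array of years, must be >= 0.
    sex : "male"/"female" strings (or an array of them).
    remaining arguments : boolean component flags.

    Returns
    -------
    int or ndarray of int
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be non-negative")
    sex = np.asarray(sex)
    age_pts = np.where(age >= 75, 2, np.where(age >= 65, 1, 0))
    score = (
        _as_int(chf)
        + _as_int(hypertension)
        + age_pts
        + _as_int(diabetes)
        + 2 * _as_int(stroke_tia_history)
        + _as_int(vascular_disease)
        + (sex == "female").astype(int)
    )
    return score if score.ndim else int(score)


def has_bled(
    uncontrolled_htn,
    renal_disease,
    liver_disease,
    stroke_tia_history,
    bleeding_history,
    labile_inr,
    age_over_65,
    antiplatelet_or_nsaid,
    alcohol_use,
):
    """HAS-BLED bleeding-risk score: one point per component, capped at 9.

    Drug (antiplatelet/NSAID) and alcohol use are scored separately, so
    the "drugs/alcohol" axis can contribute up to 2 points as in the
    original score.
    """
    score = (
        _as_int(uncontrolled_htn)
        + _as_int(renal_disease)
        + _as_int(liver_disease)
        + _as_int(stroke_tia_history)
        + _as_int(bleeding_history)
        + _as_int(labile_inr)
        + _as_int(age_over_65)
        + _as_int(antiplatelet_or_nsaid)
        + _as_int(alcohol_use)
    )
    score = np.minimum(score, 9)
    return score if score.ndim else int(score)


def scores_from_frame(df):
    """Compute both scores from a baseline-table frame.

    Expects the component columns named as in
    :data:`CHA2DS2_VASC_COMPONENTS` / :data:`HAS_BLED_COMPONENTS` plus
    ``age_at_index`` and ``sex``.  Returns ``(cha2ds2_vasc, has_bled)``
    integer Series aligned to ``df``.
    """
    import pandas as pd

    chads = cha2ds2_vasc(
        df["age_at_index"],
        df["sex"],
        df["chf"],
        df["hypertension"],
        df["diabetes"],
        df["stroke_tia_history"],
        df["vascular_disease"],
    )
    hb = has_bled(
        df["uncontrolled_htn"],
        df["renal_disease"],
        df["liver_disease"],
        df["stroke_tia_history"],
        df["bleeding_history"],
        df["labile_inr"],
        df["age_at_index"] > 65,
        df["antiplatelet_or_nsaid"],
        df["alcohol_use"],
    )
    return pd.Series(chads, index=df.index), pd.Series(hb, index=df.index)
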