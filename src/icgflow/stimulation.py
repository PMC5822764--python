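"""Pre/post cuff-stimulation pairing and response measures.

Endothelial reactivity is probed by brachial-artery cuff occlusion:
each limb is imaged at rest and again shortly after cuff release, and the
response is summarized as absolute differences of the digit-region
parameters, |ΔBFI|, |ΔI_max| and |ΔT_rising|.  A non-responding limb sits
on the y = x line of the pre-vs-post BFI scatter; the perpendicular
distance to that line, |post − pre|/√2, quantifies the response per point.

By default only hands are analyzed for stimulation response — the cuff is
applied to the upper arm, and brachial reactivity does not transfer to
the lower extremities.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["pair_conditions", "response_scatter", "KEY_COLUMNS"]

KEY_COLUMNS = ["subject", "limb", "side", "region"]
_PARAM_COLS = {"bfi": "bfi", "i_max": "i_max", "t_rising": "t_rising"}


def pair_conditions(
    records: pd.DataFrame,
    limbs: tuple[str, ...] = ("hand",),
    region: str = "digits",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair rest and post-stimulus rows and compute absolute deltas.

    Parameters
    ----------
    records
        One row per (subject, limb, side, region, condition) with at
        least columns ``condition`` (``rest``/``post``), ``group``,
        ``bfi``, ``i_max``, ``t_rising``.
    limbs, region
        Restriction applied before pairing (default: digit regions of the
        hands; pass ``limbs=("hand", "foot")`` to include feet).

    Returns
    -------
    (responses, unpaired)
        ``responses`` has one row per complete rest/post pair with
        ``bfi_pre``, ``bfi_post`` and ``abs_delta_{bfi,imax,trising}``;
        ``unpaired`` reports keys missing one condition.

    Raises
    ------
    ValueError
        If any (key, condition) occurs more than once.
    """
    df = records[records["limb"].isin(limbs) & (records["region"] == region)]
    dup = df.duplicated(subset=KEY_COLUMNS + ["condition"], keep=False)
    if dup.any():
        offender = df.loc[dup, KEY_COLUMNS + ["condition"]].iloc[0]
        raise ValueError(
            "duplicate record for key "
            f"{tuple(offender[c] for c in KEY_COLUMNS)} "
            f"condition {offender['condition']!r}"
        )

    pre = df[df["condition"] == "rest"].set_index(KEY_COLUMNS)
    post = df[df["condition"] == "post"].set_index(KEY_COLUMNS)
    common = pre.index.intersection(post.index)
    missing = pre.index.symmetric_difference(post.index)

    rows = []
    for key in common:
        a, b = pre.loc[key], post.loc[key]
        rows.append(
            {
                **dict(zip(KEY_COLUMNS, key)),
                "group": a["group"],
                "bfi_pre": a["bfi"],
                "bfi_post": b["bfi"],
                "abs_delta_bfi": abs(b["bfi"] - a["bfi"]),
                "abs_delta_imax": abs(b["i_max"] - a["i_max"]),
                "abs_delta_trising": abs(b["t_rising"] - a["t_rising"]),
            }
        )
    responses = pd.DataFrame(
        rows,
        columns=KEY_COLUMNS
        + ["group", "bfi_pre", "bfi_post", "abs_delta_bfi", "abs_delta_imax", "abs_delta_trising"],
    )
    unpaired = pd.DataFrame(list(missing), columns=KEY_COLUMNS)
    return responses, unpaired


def response_scatter(responses: pd.DataFrame) -> pd.DataFrame:
    """Pre-vs-post BFI table for the identity-line scatter.

    Appends ``identity_distance`` = |post − pre| / √2, the perpendicular
    distance of each point from the y = x non-responder line.
    """
    if responses.empty:
        raise ValueError("no responses to plot")
    table = responses[KEY_COLUMNS + ["group", "bfi_pre", "bfi_post"]].copy()
    table["identity_distance"] = (
        (responses["bfi_post"] - responses["bfi_pre"]).abs() / math.sqrt(2.0)
    )
    return table
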