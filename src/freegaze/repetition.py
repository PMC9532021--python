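"""Short-term-memory repetition analysis.

Exploration narrows when an image is encountered again: the entropy of the
second presentation within a trial pair drops relative to the first, and
this narrowing is specific to *identical* repeats (it does not generalize
to a new image of the same category, or an unrelated image).  This module
joins per-exploration entropy values to the trial design and prepares the
long-format frame for the mixed-effects order contrast (fitting is
delegated to :mod:`freegaze.stats`).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import pandas as pd

from .entropy import EntropyResult
from .geometry import PAIR_TYPES, TrialPair

__all__ = ["build_repetition_table", "repetition_contrast"]


class JoinError(ValueError):
    """Trial pairs reference explorations that cannot be matched."""


def build_repetition_table(
    entropies: Sequence[EntropyResult],
    pairs: Sequence[TrialPair],
) -> pd.DataFrame:
    """Join entropies to trial structure.

    Returns a long-format frame with one row per surviving exploration:
    columns ``participant, group, pair_type, trial_index, image_order``
    (``first``/``second``), ``image_id, entropy_bits``.  Pairs with a
    discarded member (e.g. by the validity filter) are dropped entirely —
    the within-pair contrast is undefined for half-pairs.
    """
    by_key: dict[tuple[str, int, int], EntropyResult] = {}
    for e in entropies:
        by_key[(e.participant_id, e.trial_index, e.presentation)] = e

    known_images = {e.image_id for e in entropies}
    rows = []
    for pair in pairs:
        for image_id in (pair.first_image_id, pair.second_image_id):
            if known_images and image_id not in known_images:
                raise JoinError(
                    f"trial pair references unknown image {image_id!r} "
                    f"(participant {pair.participant_id}, trial {pair.trial_index})"
                )
        first = by_key.get((pair.participant_id, pair.trial_index, 1))
        second = by_key.get((pair.participant_id, pair.trial_index, 2))
        if first is None or second is None:
            continue  # completeness rule: drop half-pairs
        if (first.image_id, second.image_id) != (pair.first_image_id, pair.second_image_id):
            raise JoinError(
                f"trial {pair.trial_index} of {pair.participant_id}: entropy "
                "image ids do not match the trial table"
            )
        for order, e in (("first", first), ("second", second)):
            rows.append({
                "participant": pair.participant_id,
                "group": e.group,
                "pair_type": pair.pair_type,
                "trial_index": pair.trial_index,
                "image_order": order,
                "image_id": e.image_id,
                "entropy_bits": e.H,
            })
    return pd.DataFrame(rows, columns=[
        "participant", "group", "pair_type", "trial_index",
        "image_order", "image_id", "entropy_bits",
    ])


def repetition_contrast(
    table: pd.DataFrame, pair_type: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Model frame and descriptive summary for one pair type.

    Returns ``(model_frame, summary)``: the long-format rows of that pair
    type (inputs to the repetition mixed model, with ``image_order`` coded
    first/second), and the mean first/second entropy with their difference
    per group.  Groups with no second-order rows are excluded with a warning.
    """
    if pair_type not in PAIR_TYPES:
        raise ValueError(f"unknown pair_type {pair_type!r}")
    frame = table[table["pair_type"] == pair_type].copy()
    if frame.empty:
        return frame, pd.DataFrame(
            columns=["group", "mean_first", "mean_second", "mean_change"])
    keep_groups = []
    for group, sub in frame.groupby("group"):
        if (sub["image_order"] == "second").any():
            keep_groups.append(group)
        else:
            warnings.warn(f"group {group} has no second-order rows; excluded")
    frame = frame[frame["group"].isin(keep_groups)]
    if frame["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants for the order contrast")

    summary_rows = []
    for group, sub in frame.groupby("group"):
        m1 = sub.loc[sub["image_order"] == "first", "entropy_bits"].mean()
        m2 = sub.loc[sub["image_order"] == "second", "entropy_bits"].mean()
        summary_rows.append({
            "group": group, "mean_first": m1, "mean_second": m2,
            "mean_change": m2 - m1,
        })
    return frame, pd.DataFrame(summary_rows)
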