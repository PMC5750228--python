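"""Isolate exometabolite classification.

An isolate is grown in a defined, environment-mimicking metabolite
mixture; spent media is profiled against an uninoculated control. The
fold-change (inoculated mean peak area / control mean peak area) of each
metabolite classifies it as consumed (<= 0.5), released (>= 2) or
unchanged, and the class maps directly to the correlation sign expected
in situ between the metabolite and the isolate's closest environmental
relative: consumed -> negative, released -> positive.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

CONSUMED_THRESHOLD = 0.5
RELEASED_THRESHOLD = 2.0
EXPECTED_SIGN = {"consumed": -1, "released": +1, "unchanged": 0}


def fold_change(mean_area_inoculated: float, mean_area_control: float) -> float:
    """Spent-media fold-change: inoculated / control mean peak area."""
    if not mean_area_control > 0:
        raise ValueError("control mean peak area must be strictly positive")
    if mean_area_inoculated < 0:
        raise ValueError("negative inoculated peak area")
    return mean_area_inoculated / mean_area_control


def classify(
    fc: float,
    consumed_threshold: float = CONSUMED_THRESHOLD,
    released_threshold: float = RELEASED_THRESHOLD,
) -> str:
    """Map a fold-change to consumed / released / unchanged.

    Thresholds are inclusive: 0.5 is consumed, 2.0 is released.
    """
    if fc < 0 or math.isnan(fc):
        raise ValueError(f"fold-change must be >= 0, got {fc}")
    if fc <= consumed_threshold:
        return "consumed"
    if fc >= released_threshold:
        return "released"
    return "unchanged"


def build_profiles(
    spent: pd.DataFrame,
    consumed_threshold: float = CONSUMED_THRESHOLD,
    released_threshold: float = RELEASED_THRESHOLD,
) -> pd.DataFrame:
    """Classify every (isolate, metabolite) spent-media record.

    ``spent`` needs columns isolate_id, metabolite_id,
    mean_area_inoculated, mean_area_control. Records with a missing
    inoculated mean are skipped (logged); a non-positive control mean is
    unclassifiable and skipped as well, since depletion and release are
    both measured against it.

    Returns columns isolate_id, metabolite_id, fold_change, exo_class,
    expected_sign.
    """
    required = {"isolate_id", "metabolite_id",
                "mean_area_inoculated", "mean_area_control"}
    missing = required - set(spent.columns)
    if missing:
        raise ValueError(f"spent-media table lacks columns {sorted(missing)}")
    rows = []
    for rec in spent.itertuples(index=False):
        if pd.isna(rec.mean_area_inoculated):
            logger.info("exoprofile: skipping %s/%s (inoculated mean missing)",
                        rec.isolate_id, rec.metabolite_id)
            continue
        if not rec.mean_area_control > 0:
            logger.info("exoprofile: skipping %s/%s (no control signal)",
                        rec.isolate_id, rec.metabolite_id)
            continue
        fc = fold_change(rec.mean_area_inoculated, rec.mean_area_control)
        cls = classify(fc, consumed_threshold, released_threshold)
        rows.append({
            "isolate_id": rec.isolate_id,
            "metabolite_id": rec.metabolite_id,
            "fold_change": fc,
            "exo_class": cls,
            "expected_sign": EXPECTED_SIGN[cls],
        })
    return pd.DataFrame(rows)


def predict_signs(
    profiles: pd.DataFrame, isolate_to_taxon: Mapping[str, str]
) -> pd.DataFrame:
    """Emit in-situ correlation-sign predictions from isolate profiles.

    One prediction per (matched environmental taxon, metabolite) with a
    non-zero expected sign; unchanged metabolites and isolates without a
    matched taxon are omitted (the latter logged).

    Returns columns taxon_id, metabolite_id, isolate_id, predicted
    (consumed/released), expected_sign.
    """
    rows = []
    for rec in profiles.itertuples(index=False):
        if rec.expected_sign == 0:
            continue
        taxon = isolate_to_taxon.get(rec.isolate_id)
        if taxon is None:
            logger.info("predict_signs: isolate %s has no matched taxon; "
                        "skipping", rec.isolate_id)
            continue
        rows.append({
            "taxon_id": taxon,
            "metabolite_id": rec.metabolite_id,
            "isolate_id": rec.isolate_id,
            "predicted": rec.exo_class,
            "expected_sign": rec.expected_sign,
        })
    return pd.DataFrame(
        rows, columns=["taxon_id", "metabolite_id", "isolate_id",
                       "predicted", "expected_sign"],
    )
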