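"""Rule-based CTC identification on candidate-event tables.

Candidate cell-like events detected on stained slides are filtered by
morphological and immunophenotypic criteria: DAPI-positive nucleus, CD45
negativity (leukocyte exclusion), non-multilobed nucleus, round-to-oval
shape, diameter 8-40 µm (inclusive), and a positive CK18 (slide 1) or MGB
(slide 2) marker signal.  Each sample is split onto two slides with
different marker panels, so CK18 and MGB counts are independent per-channel
tallies.

Every excluded event is attributed to the *first* failing rule in a fixed
order — DAPI, CD45, multilobed, diameter, shape, marker — which makes the
exclusion tallies deterministic and auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SLIDE_CK18",
    "SLIDE_MGB",
    "RULE_ORDER",
    "GatingCriteria",
    "CTCCounts",
    "gate_events",
    "simulate_events",
    "EVENT_COLUMNS",
]

SLIDE_CK18 = "slide1_CK18"
SLIDE_MGB = "slide2_MGB"

RULE_ORDER = ("dapi", "cd45", "multilobed", "diameter", "shape", "marker")

EVENT_COLUMNS = [
    "event_id",
    "sample_id",
    "slide",
    "diameter",
    "shape",
    "dapi_positive",
    "nucleus_multilobed",
    "ck18_positive",
    "mgb_positive",
    "pan_ck_positive",
    "cd45_positive",
]

_SHAPES = ("round", "oval", "irregular")


@dataclass(frozen=True)
class GatingCriteria:
    """Morphology and immunophenotype gates for calling an event a CTC."""

    diameter_min: float = 8.0
    diameter_max: float = 40.0
    allowed_shapes: frozenset = frozenset({"round", "oval"})
    require_dapi: bool = True
    exclude_cd45: bool = True
    exclude_multilobed: bool = True
    require_pan_ck_for_mgb: bool = False  # optional stricter slide-2 criterion

    def __post_init__(self) -> None:
        if not 0 < self.diameter_min < self.diameter_max:
            raise ValueError("need 0 < diameter_min < diameter_max")
        if not self.allowed_shapes:
            raise ValueError("allowed_shapes must be non-empty")


@dataclass
class CTCCounts:
    """Per-sample CTC tally with per-rule exclusion bookkeeping."""

    sample_id: str
    ck18_count: int
    mgb_count: int
    n_candidates: int
    n_excluded_by_rule: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ck18_count + self.mgb_count > self.n_candidates:
            raise ValueError("counted CTCs exceed candidate events")
        n_pass = self.ck18_count + self.mgb_count
        if n_pass + sum(self.n_excluded_by_rule.values()) != self.n_candidates:
            raise ValueError("exclusion tallies inconsistent with pass counts")


def _as_bool(col: pd.Series) -> np.ndarray:
    """Booleanise a CSV column that may hold booleans, 0/1 or true/false text."""
    if col.dtype == bool:
        return col.to_numpy()
    mapped = col.map(
        lambda v: v
        if isinstance(v, (bool, np.bool_))
        else str(v).strip().lower() in {"true", "1", "yes", "t"}
    )
    return mapped.to_numpy(dtype=bool)


def _validate_events(events: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table lacks columns {missing}")
    bad = ~events["slide"].isin([SLIDE_CK18, SLIDE_MGB])
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # 1-based + header
        raise ValueError(
            f"unknown slide tag {events.loc[bad, 'slide'].iloc[0]!r} "
            f"at line(s) {lines[:10]}"
        )
    if (events["diameter"] <= 0).any():
        raise ValueError("event diameters must be positive")
    # panel consistency: each slide carries only its own marker channel
    on1 = events["slide"] == SLIDE_CK18
    if events.loc[on1, "mgb_positive"].notna().any() or events.loc[
        on1, "pan_ck_positive"
    ].notna().any():
        raise ValueError("slide-1 events must have NA mgb/pan-CK channels")
    if events.loc[~on1, "ck18_positive"].notna().any():
        raise ValueError("slide-2 events must have NA ck18 channel")
    return events


def gate_events(
    events: pd.DataFrame, criteria: GatingCriteria | None = None
) -> pd.DataFrame:
    """Apply the CTC gates to a candidate-event table.

    Returns one row per sample with ``ck18_count``, ``mgb_count``,
    ``n_candidates`` and one ``excluded_<rule>`` column per rule in
    :data:`RULE_ORDER`.  Events failing several gates are attributed to the
    first failing rule only.
    """
    criteria = criteria or GatingCriteria()
    events = _validate_events(events)

    dapi = _as_bool(events["dapi_positive"])
    cd45 = _as_bool(events["cd45_positive"])
    lobed = _as_bool(events["nucleus_multilobed"])
    diam = events["diameter"].to_numpy(dtype=float)
    shape_ok = events["shape"].isin(list(criteria.allowed_shapes)).to_numpy()
    on_slide1 = (events["slide"] == SLIDE_CK18).to_numpy()

    ck18 = events["ck18_positive"].map(lambda v: v is True or str(v).lower() == "true")
    mgb = events["mgb_positive"].map(lambda v: v is True or str(v).lower() == "true")
    panck = events["pan_ck_positive"].map(
        lambda v: v is True or str(v).lower() == "true"
    )
    marker_ok = np.where(
        on_slide1,
        ck18.to_numpy(dtype=bool),
        mgb.to_numpy(dtype=bool)
        & (panck.to_numpy(dtype=bool) if criteria.require_pan_ck_for_mgb else True),
    )

    fails = {
        "dapi": criteria.require_dapi & ~dapi,
        "cd45": criteria.exclude_cd45 & cd45,
        "multilobed": criteria.exclude_multilobed & lobed,
        "diameter": (diam < criteria.diameter_min) | (diam > criteria.diameter_max),
        "shape": ~shape_ok,
        "marker": ~marker_ok,
    }

    first_fail = np.full(len(events), "", dtype=object)
    undecided = np.ones(len(events), dtype=bool)
    for rule in RULE_ORDER:
        hit = undecided & fails[rule]
        first_fail[hit] = rule
        undecided &= ~hit
    passed = first_fail == ""

    out_rows = []
    tally = pd.DataFrame(
        {
            "sample_id": events["sample_id"].to_numpy(),
            "passed": passed,
            "slide1": on_slide1,
            "rule": first_fail,
        }
    )
    for sample_id, grp in tally.groupby("sample_id", sort=True):
        row = {
            "sample_id": sample_id,
            "ck18_count": int((grp["passed"] & grp["slide1"]).sum()),
            "mgb_count": int((grp["passed"] & ~grp["slide1"]).sum()),
            "n_candidates": int(len(grp)),
        }
        for rule in RULE_ORDER:
            row[f"excluded_{rule}"] = int((grp["rule"] == rule).sum())
        CTCCounts(  # invariant check
            sample_id=str(sample_id),
            ck18_count=row["ck18_count"],
            mgb_count=row["mgb_count"],
            n_candidates=row["n_candidates"],
            n_excluded_by_rule={r: row[f"excluded_{r}"] for r in RULE_ORDER},
        )
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def simulate_events(
    n_ctc_true: int,
    n_leukocyte: int,
    n_debris: int,
    seed: int,
    sample_id: str = "SAMPLE1",
) -> pd.DataFrame:
    """Simulate a candidate-event table with known ground truth.

    True CTCs satisfy every gate on a randomly assigned slide; leukocytes are
    CD45+, multilobed, DAPI+ cells; debris is DAPI-negative or out-of-range
    in diameter.  The ``truth`` column records the planted class.
    """
    if min(n_ctc_true, n_leukocyte, n_debris) < 0:
        raise ValueError("event counts must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []

    def base(i, truth):
        return {
            "event_id": f"E{i:05d}",
            "sample_id": sample_id,
            "ck18_positive": pd.NA,
            "mgb_positive": pd.NA,
            "pan_ck_positive": pd.NA,
            "truth": truth,
        }

    i = 0
    for _ in range(n_ctc_true):
        row = base(i, "ctc")
        slide = SLIDE_CK18 if rng.uniform() < 0.5 else SLIDE_MGB
        row.update(
            slide=slide,
            diameter=float(rng.uniform(8.0, 40.0)),
            shape=str(rng.choice(["round", "oval"])),
            dapi_positive=True,
            nucleus_multilobed=False,
            cd45_positive=False,
        )
        if slide == SLIDE_CK18:
            row["ck18_positive"] = True
        else:
            row["mgb_positive"] = True
            row["pan_ck_positive"] = bool(rng.uniform() < 0.7)
        rows.append(row)
        i += 1
    for _ in range(n_leukocyte):
        row = base(i, "leukocyte")
        slide = SLIDE_CK18 if rng.uniform() < 0.5 else SLIDE_MGB
        row.update(
            slide=slide,
            diameter=float(rng.uniform(7.0, 15.0)),
            shape=str(rng.choice(["round", "oval", "irregular"])),
            dapi_positive=True,
            nucleus_multilobed=True,
            cd45_positive=True,
        )
        if slide == SLIDE_CK18:
            row["ck18_positive"] = bool(rng.uniform() < 0.05)
        else:
            row["mgb_positive"] = bool(rng.uniform() < 0.05)
            row["pan_ck_positive"] = False
        rows.append(row)
        i += 1
    for _ in range(n_debris):
        row = base(i, "debris")
        slide = SLIDE_CK18 if rng.uniform() < 0.5 else SLIDE_MGB
        if rng.uniform() < 0.5:  # anucleate fragment
            dapi, diameter = False, float(rng.uniform(2.0, 60.0))
        else:  # out-of-range size
            dapi = True
            diameter = float(
                rng.uniform(1.0, 7.9) if rng.uniform() < 0.5 else rng.uniform(40.1, 80.0)
            )
        row.update(
            slide=slide,
            diameter=diameter,
            shape=str(rng.choice(["round", "irregular"])),
            dapi_positive=dapi,
            nucleus_multilobed=False,
            cd45_positive=False,
        )
        if slide == SLIDE_CK18:
            row["ck18_positive"] = bool(rng.uniform() < 0.3)
        else:
            row["mgb_positive"] = bool(rng.uniform() < 0.3)
            row["pan_ck_positive"] = False
        rows.append(row)
        i += 1

    frame = pd.DataFrame(rows, columns=EVENT_COLUMNS + ["truth"])
    return frame
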