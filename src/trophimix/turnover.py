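"""Tissue turnover: matching isotope samples to the diet they integrate.

Different tissues incorporate diet at different rates: the delta15N
50%-turnover (half-life) is about 66 days for blood plasma, 88 days for
red blood cells, and 126 days for muscle in a coral-trout-sized
serranid. A tissue sampled on some date therefore chiefly reflects diet
roughly one half-life earlier, so stomach-content samples from that
past window are the right comparison for a mixing-model output.

Matching is by calendar-day arithmetic: a tissue event (group, reef,
date, tissue) is paired with the stomach-content event of the same
group and reef whose lag is nearest the tissue's half-life, within a
tolerance (+/-45 days by default; sampling campaigns are months apart).
Ties go to the earlier stomach event. These windows are approximate by
nature — incorporation is gradual, not a step at the half-life.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trophimix.community import morisita_simplified

DEFAULT_TOLERANCE_DAYS = 45


@dataclass(frozen=True)
class TurnoverParams:
    """delta15N half-lives in days per tissue (used for both isotopes)."""

    half_life_days: dict = field(
        default_factory=lambda: {"plasma": 66.0, "RBC": 88.0, "muscle": 126.0}
    )

    def __post_init__(self) -> None:
        hl = self.half_life_days
        if any(v < 0 for v in hl.values()):
            raise ValueError("half-lives must be nonnegative")
        if {"plasma", "RBC", "muscle"} <= set(hl):
            if not hl["plasma"] < hl["RBC"] < hl["muscle"]:
                raise ValueError("expected plasma < RBC < muscle half-life ordering")

    def half_life(self, tissue: str) -> float:
        try:
            return float(self.half_life_days[tissue])
        except KeyError:
            raise KeyError(
                f"unknown tissue {tissue!r}; known: {sorted(self.half_life_days)}"
            ) from None


def diet_window(
    sample_date,
    tissue: str,
    params: TurnoverParams | None = None,
    tolerance_days: int = DEFAULT_TOLERANCE_DAYS,
) -> tuple[pd.Timestamp, int]:
    """Target past date a tissue sample reflects, with its tolerance.

    Returns ``(sample_date - half_life(tissue), tolerance_days)``.
    """
    params = params or TurnoverParams()
    hl = params.half_life(tissue)
    date = pd.Timestamp(sample_date)
    return date - pd.Timedelta(days=hl), int(tolerance_days)


def match_events(
    tissue_events: pd.DataFrame,
    stomach_events: pd.DataFrame,
    params: TurnoverParams | None = None,
    tolerance_days: int = DEFAULT_TOLERANCE_DAYS,
) -> pd.DataFrame:
    """Pair tissue-sampling events with temporally matched stomach events.

    ``tissue_events`` needs columns group, reef, date, tissue;
    ``stomach_events`` needs group, reef, date. For each tissue event,
    candidate stomach events share its group and reef; the candidate
    whose lag (tissue date minus stomach date, days) is closest to the
    tissue's half-life wins, provided ``|lag - half_life| <=
    tolerance_days``; ties are broken toward the earlier stomach event.
    A stomach event may serve several tissue events.

    Returns the matched-pair table (unmatched tissue events appear with
    null stomach date and ``matched=False``).
    """
    params = params or TurnoverParams()
    stomach = stomach_events.copy()
    stomach["date"] = pd.to_datetime(stomach["date"])
    rows = []
    for _, ev in tissue_events.iterrows():
        hl = params.half_life(str(ev["tissue"]))
        tdate = pd.Timestamp(ev["date"])
        cand = stomach[(stomach["group"] == ev["group"]) & (stomach["reef"] == ev["reef"])]
        best = None
        for _, st in cand.iterrows():
            lag = (tdate - st["date"]).days
            dev = abs(lag - hl)
            if dev > tolerance_days:
                continue
            key = (dev, st["date"])  # nearest lag, then earlier event
            if best is None or key < best[0]:
                best = (key, st, lag)
        row = {
            "group": ev["group"],
            "reef": ev["reef"],
            "tissue": ev["tissue"],
            "tissue_date": tdate,
            "stomach_date": pd.NaT,
            "lag_days": np.nan,
            "window_days": tolerance_days,
            "matched": False,
        }
        if best is not None:
            row.update(stomach_date=best[1]["date"], lag_days=int(best[2]), matched=True)
        rows.append(row)
    return pd.DataFrame(rows)


def validate_against_stomachs(posterior_summary, matched_diet_composition) -> dict:
    """Check mixing-model credibility intervals against a DNA composition.

    For each shared prey category, reports whether the DNA-derived diet
    proportion lies inside the posterior credibility interval, plus the
    simplified Morisita overlap between the CI midvalues and the DNA
    composition. Categories are aligned by intersection (with a warning
    when the sets differ).
    """
    import warnings

    comp = pd.Series(matched_diet_composition, dtype=float)
    summ = pd.Series(posterior_summary.midvalue, index=posterior_summary.source_names)
    lo = pd.Series(posterior_summary.ci_low, index=posterior_summary.source_names)
    hi = pd.Series(posterior_summary.ci_high, index=posterior_summary.source_names)
    shared = [c for c in posterior_summary.source_names if c in comp.index]
    if set(shared) != set(comp.index) or len(shared) != len(posterior_summary.source_names):
        warnings.warn("category sets differ; aligned by intersection", stacklevel=2)
    if not shared:
        raise ValueError("no shared prey categories to validate against")
    comp = comp.loc[shared]
    comp = comp / comp.sum()
    inside = {c: bool(lo[c] <= comp[c] <= hi[c]) for c in shared}
    overlap = morisita_simplified(summ.loc[shared].to_numpy(), comp.to_numpy())
    return {
        "categories": shared,
        "inside_ci": inside,
        "n_inside": int(sum(inside.values())),
        "n_categories": len(shared),
        "proportion_inside": sum(inside.values()) / len(shared),
        "morisita_overlap": overlap.index,
        "ci_level": posterior_summary.ci_level,
    }
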