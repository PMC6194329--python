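"""Jacobs' electivity: prey selection relative to environmental abundance.

Jacobs' (1974) index D = (r - p) / (r + p - 2rp), where r is a prey
family's proportion in the diet and p its proportion in the
environment. D ranges from -1 (maximum avoidance, the family is never
eaten despite being available) through 0 (consumed in proportion to
abundance) to +1 (maximum preference).

One D is computed per survey reef (pooled diet r against that reef's
p), giving replicate values for a 95% t-interval. Conservatively, a
family whose confidence interval lies entirely inside (-0.25, +0.25)
is classified as consumed in proportion to its abundance (neutral).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

NEUTRAL_BAND = 0.25


def jacobs_d(r, p):
    """Jacobs' D for diet proportion(s) ``r`` and availability ``p``.

    Vectorised; r = p yields exactly 0 (including r = p = 1), while
    r = p = 0 is undefined and returns NaN.
    """
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any((r < 0) | (r > 1)) or np.any((p < 0) | (p > 1)):
        raise ValueError("r and p must be proportions in [0, 1]")
    denom = r + p - 2.0 * r * p
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(r == p, 0.0, (r - p) / denom)
    d = np.clip(d, -1.0, 1.0)  # |D| <= 1 mathematically; guard roundoff
    d = np.where((r == 0) & (p == 0), np.nan, d)
    if d.ndim == 0:
        return float(d)
    return d


def _classify(ci_low: float, ci_high: float, band: float) -> str:
    if np.isnan(ci_low) or np.isnan(ci_high):
        return "indeterminate"
    if -band < ci_low and ci_high < band:
        return "neutral"
    if ci_low > 0:
        return "preference"
    if ci_high < 0:
        return "avoidance"
    return "indeterminate"


def electivity_profile(
    diet_composition: pd.Series,
    surveys: pd.DataFrame,
    alpha: float = 0.05,
    neutral_band: float = NEUTRAL_BAND,
) -> pd.DataFrame:
    """Per-family electivity with reef-replicate confidence intervals.

    ``diet_composition`` is the pooled diet proportion per family;
    ``surveys`` has columns ``reef``, ``family``, ``count``. For each
    family present in the surveys, D is computed per reef (that reef's
    availability against the pooled diet), then summarised by its mean
    and a (1 - alpha) t-interval across reefs.

    Classification: ``neutral`` if the CI lies inside
    (-neutral_band, +neutral_band); ``preference``/``avoidance`` if the
    CI lies entirely above/below 0 (and not inside the band);
    ``indeterminate`` otherwise, or when fewer than two reefs yield a
    defined D. Diet families absent from every survey are excluded and
    listed in ``result.attrs['excluded_families']``.
    """
    for col in ("reef", "family", "count"):
        if col not in surveys.columns:
            raise ValueError(f"surveys table missing column {col!r}")
    diet = pd.Series(diet_composition, dtype=float)
    diet = diet / diet.sum()
    env = surveys.pivot_table(index="reef", columns="family", values="count", aggfunc="sum").fillna(0.0)
    env_props = env.div(env.sum(axis=1), axis=0)
    families = list(env_props.columns)
    excluded = sorted(set(diet.index) - set(families))

    reefs = list(env_props.index)
    rows = []
    for fam in families:
        r = float(diet.get(fam, 0.0))
        d_per_reef = np.array([jacobs_d(r, float(env_props.loc[reef, fam])) for reef in reefs])
        valid = d_per_reef[~np.isnan(d_per_reef)]
        if valid.size >= 2:
            mean = float(valid.mean())
            se = float(valid.std(ddof=1) / np.sqrt(valid.size))
            tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, valid.size - 1))
            lo, hi = mean - tcrit * se, mean + tcrit * se
        elif valid.size == 1:
            mean, lo, hi = float(valid[0]), np.nan, np.nan
        else:
            mean, lo, hi = np.nan, np.nan, np.nan
        rows.append(
            {
                "family": fam,
                "D_per_reef": list(np.round(d_per_reef, 10)),
                "D_mean": mean,
                "ci_low": lo,
                "ci_high": hi,
                "classification": _classify(lo, hi, neutral_band),
            }
        )
    out = pd.DataFrame(rows).set_index("family")
    out.attrs["excluded_families"] = excluded
    out.attrs["reefs"] = reefs
    out.attrs["alpha"] = alpha
    out.attrs["neutral_band"] = neutral_band
    return out
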