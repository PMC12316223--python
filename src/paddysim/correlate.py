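"""Preliminary yield-climate correlation analysis.

Pearson correlations of seasonal yield against the eleven climate
covariates (year, whole-season accumulated temperature / GDD /
precipitation / radiation, and per-stage accumulated temperature and GDD),
with two-sided p-values and a significance mark at p < 0.05.  P-values are
reported unadjusted for multiple testing.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .exceptions import ConfigurationError
from .weather import ClimateSummary

__all__ = ["yield_climate_correlations"]

ALPHA = 0.05


def yield_climate_correlations(
    yields_by_year: Mapping[int, float],
    summaries_by_year: Mapping[int, ClimateSummary],
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-variable Pearson r and two-sided p against yearly yields.

    Years present in both mappings are paired; at least 4 pairs are
    required.  A constant climate variable has an undefined correlation and
    is reported with missing r and p (never as zero).
    """
    years = sorted(set(yields_by_year) & set(summaries_by_year))
    if len(years) < 4:
        raise ConfigurationError(f"need at least 4 paired years, got {len(years)}")
    y = np.asarray([yields_by_year[t] for t in years], float)
    table = pd.DataFrame([summaries_by_year[t].as_dict() for t in years])

    rows = []
    for var in ClimateSummary._FIELDS:
        x = table[var].to_numpy(float)
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            r, p = np.nan, np.nan
        else:
            r, p = scipy.stats.pearsonr(x, y)
        rows.append(
            {
                "variable": var,
                "r": float(r) if np.isfinite(r) else np.nan,
                "p_value": float(p) if np.isfinite(p) else np.nan,
                "significant": bool(np.isfinite(p) and p < alpha),
                "n": len(years),
            }
        )
    return pd.DataFrame(rows)
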