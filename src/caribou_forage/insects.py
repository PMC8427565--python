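"""Mosquito (MI) and oestrid-fly (OI) activity indices from temperature and wind.

Both indices live in [0, 1]; 1 means maximal insect activity. The binding
endpoint conditions are: both indices equal 1 at >=18 deg C with calm air
(0 m/s); MI is 0 below 6 deg C or above 6 m/s wind; OI is 0 below 13 deg C or
above 9 m/s wind. Between endpoints each index is a separable product of a
linear temperature ramp and a linear wind ramp (clamped to [0, 1]); the
original field-calibrated equations are not public, so the ramp product is
this module's own construction, kept behind these two function boundaries so
it can be swapped without touching attribution or the models.

At exactly the lower temperature or upper wind endpoint the ramp value (0)
applies, consistent with continuity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MI_TEMP_LO, MI_TEMP_HI = 6.0, 18.0
MI_WIND_HI = 6.0
OI_TEMP_LO, OI_TEMP_HI = 13.0, 18.0
OI_WIND_HI = 9.0


def _ramp_index(temperature, wind, t_lo, t_hi, w_hi):
    t = np.asarray(temperature, dtype=float)
    w = np.asarray(wind, dtype=float)
    if np.any(w < 0):
        raise ValueError("wind speed must be non-negative")
    f_t = np.clip((t - t_lo) / (t_hi - t_lo), 0.0, 1.0)
    f_w = np.clip(1.0 - w / w_hi, 0.0, 1.0)
    out = f_t * f_w
    return out.item() if out.ndim == 0 else out


def mosquito_index(temperature, wind):
    """MI in [0, 1]: linear 6->18 deg C ramp times linear 0->6 m/s wind ramp."""
    return _ramp_index(temperature, wind, MI_TEMP_LO, MI_TEMP_HI, MI_WIND_HI)


def oestrid_index(temperature, wind):
    """OI in [0, 1]: linear 13->18 deg C ramp times linear 0->9 m/s wind ramp."""
    return _ramp_index(temperature, wind, OI_TEMP_LO, OI_TEMP_HI, OI_WIND_HI)


def attribute_insects(points: pd.DataFrame, weather) -> pd.DataFrame:
    """Attach ``mi`` and ``oi`` columns looked up at each point's cell-hour.

    Each point takes the weather of its nearest coarse cell at the containing
    hour. Points outside the weather field's space-time extent raise a
    ``ValueError`` listing the offending row labels. Which index enters an
    analysis is decided downstream: MI within mosquito-period models, OI
    within oestrid-period models.
    """
    out = points.copy()
    t0 = _season_start_like(out["t"])
    hours = ((pd.to_datetime(out["t"]) - t0).dt.total_seconds() // 3600).astype(int)
    bad = (hours < 0) | (hours >= weather.n_hours)
    bad |= (out["x"] < 0) | (out["x"] > weather.extent_x)
    bad |= (out["y"] < 0) | (out["y"] > weather.extent_y)
    if bad.any():
        rows = list(out.index[bad][:20])
        raise ValueError(
            f"{int(bad.sum())} point(s) outside the weather space-time extent; "
            f"first offending rows: {rows}"
        )
    temp, wind = weather.at(hours.to_numpy(), out["x"].to_numpy(), out["y"].to_numpy())
    out["mi"] = mosquito_index(temp, wind)
    out["oi"] = oestrid_index(temp, wind)
    return out


def _season_start_like(tcol: pd.Series) -> pd.Timestamp:
    from .config import SEASON_START

    t0 = pd.Timestamp(SEASON_START)
    if pd.to_datetime(tcol).dt.tz is None:
        t0 = t0.tz_localize(None)
    return t0
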