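"""Shock / Threshold heatwave taxonomy.

Lethal heatwaves divide by impact mechanism: Shock Heatwaves have modest
absolute conditions but aggressive thermo-temporal differentials from the
local acclimation point, while Threshold Heatwaves combine heat and
humidity beyond the body's capacity to dissipate heat. Any lethal heatwave
below a wet-bulb temperature of 25 °C is almost certainly a Shock
Heatwave, so the default cutoff is 25 °C; an optional indeterminate band
can be enabled for the 25–35 °C range where the rule is less certain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import stull_wbt

__all__ = ["TaxonomyLabel", "assign_taxonomy", "taxonomy_table"]

SHOCK_CUTOFF_DEFAULT = 25.0


@dataclass(frozen=True)
class TaxonomyLabel:
    """Taxonomy assignment for one event: the class, the wet-bulb
    temperature it was judged at, and whether the lethal label was
    observed or model-predicted."""

    label: str  # Shock | Threshold | NotLethal | Indeterminate
    wbt_at_event: float
    basis: str = "observed"  # observed | predicted


def assign_taxonomy(
    tmax: float,
    rh_mean: float,
    lethal: int,
    shock_cutoff: float = SHOCK_CUTOFF_DEFAULT,
    basis: str = "observed",
    indeterminate_band: tuple[float, float] | None = None,
) -> TaxonomyLabel:
    """Pure function of (label, tmax, rh_mean, cutoff).

    Nonlethal events are NotLethal. Lethal events with wet-bulb
    temperature below ``shock_cutoff`` are Shock, otherwise Threshold;
    with ``indeterminate_band=(lo, hi)``, lethal events whose WBT lies in
    [lo, hi) are labelled Indeterminate instead.
    """
    wbt = stull_wbt(tmax, rh_mean)
    if not int(lethal):
        return TaxonomyLabel("NotLethal", wbt, basis)
    if indeterminate_band is not None:
        lo, hi = indeterminate_band
        if lo <= wbt < hi:
            return TaxonomyLabel("Indeterminate", wbt, basis)
    label = "Shock" if wbt < shock_cutoff else "Threshold"
    return TaxonomyLabel(label, wbt, basis)


def taxonomy_table(
    events: pd.DataFrame,
    lethal: np.ndarray | pd.Series | None = None,
    shock_cutoff: float = SHOCK_CUTOFF_DEFAULT,
    basis: str = "observed",
    indeterminate_band: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Vectorised taxonomy over an events frame (tmax_c, rh_mean_pct).

    ``lethal`` defaults to the frame's own observed labels; pass model
    predictions with ``basis="predicted"``.
    """
    y = events["lethal"].to_numpy() if lethal is None else np.asarray(lethal)
    wbt = np.asarray(
        stull_wbt(events["tmax_c"].to_numpy(float), events["rh_mean_pct"].to_numpy(float))
    )
    labels = np.where(wbt < shock_cutoff, "Shock", "Threshold").astype(object)
    if indeterminate_band is not None:
        lo, hi = indeterminate_band
        labels[(wbt >= lo) & (wbt < hi)] = "Indeterminate"
    labels[y.astype(int) == 0] = "NotLethal"
    return pd.DataFrame(
        {
            "event_id": events["event_id"].to_numpy()
            if "event_id" in events.columns
            else events.index,
            "taxonomy": labels,
            "wbt_at_event": wbt,
            "basis": basis,
        }
    )
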