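"""Redox and methane zonation of a stratified water column.

Classifies a depth profile into an oxic zone, the oxycline (interval of
steepest O₂ decline), a suboxic zone and the anoxic zone (O₂ below a trace
threshold, default 20 nM), and — from the CH₄ concentration and δ¹³C-CH₄
profiles — into methane zones: a methanogenic source zone at depth, a
non-reactive diffusion zone (concentration falls upward while δ¹³C stays
invariant), an oxidation zone (concentration falls upward while the residual
pool enriches in ¹³C), and the oxic zone above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .flux import steepest_gradient
from .profiles import MissingAnalyteError, Profile

__all__ = [
    "Zone",
    "ZoneMap",
    "find_oxycline",
    "find_anoxia_onset",
    "classify_ch4_zones",
    "build_zone_map",
]


@dataclass(frozen=True)
class Zone:
    name: str
    top_m: float
    bottom_m: float

    def __post_init__(self) -> None:
        if self.top_m >= self.bottom_m:
            raise ValueError(f"zone {self.name}: top must be above bottom")


@dataclass(frozen=True)
class ZoneMap:
    """Redox and methane zones of one profile (depths in m, downward)."""

    oxycline_depth_m: float
    anoxia_onset_m: float | None
    zones: tuple[Zone, ...]
    ch4_zones: tuple[Zone, ...]
    indeterminate: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "redox", "zone": z.name, "top_m": z.top_m, "bottom_m": z.bottom_m}
            for z in self.zones
        ] + [
            {"kind": "ch4", "zone": z.name, "top_m": z.top_m, "bottom_m": z.bottom_m}
            for z in self.ch4_zones
        ]
        return pd.DataFrame(rows)


def find_oxycline(
    profile: Profile, o2_column: str = "o2_uM", window_points: int = 3
) -> float:
    """Depth (m) of the oxycline: midpoint of the steepest-O₂-gradient window.

    Warns if O₂ increases with depth over that window (inverted orientation).
    """
    gradient = steepest_gradient(profile, o2_column, window_points)
    if gradient.slope > 0:
        warnings.warn(
            "O2 increases with depth over the steepest window; "
            "profile orientation may be inverted",
            stacklevel=2,
        )
    top, bottom = gradient.depth_window
    return 0.5 * (top + bottom)


def find_anoxia_onset(
    profile: Profile, threshold_nM: float = 20.0, o2_column: str = "o2_uM"
) -> float | None:
    """Shallowest depth below which O₂ stays under the trace threshold.

    Linear interpolation between the bracketing samples locates the
    threshold crossing; returns None if the column never goes anoxic.
    """
    depths, o2 = profile.analyte(o2_column)
    threshold_uM = threshold_nM * 1e-3
    below = o2 < threshold_uM
    if not below[-1]:
        return None
    # shallowest index from which the profile stays below the threshold
    idx = len(below) - 1
    while idx > 0 and below[idx - 1]:
        idx -= 1
    if idx == 0:
        return float(depths[0])
    z0, z1 = depths[idx - 1], depths[idx]
    c0, c1 = o2[idx - 1], o2[idx]
    if c0 == c1:
        return float(z1)
    return float(z0 + (c0 - threshold_uM) / (c0 - c1) * (z1 - z0))


def _local_slopes(
    depths: np.ndarray, values: np.ndarray, window_m: float
) -> np.ndarray:
    """OLS slope of values vs depth in a centred window around each sample."""
    slopes = np.full(len(depths), np.nan)
    half = window_m / 2.0
    for i, z in enumerate(depths):
        mask = (depths >= z - half) & (depths <= z + half)
        if mask.sum() >= 2:
            slopes[i] = stats.linregress(depths[mask], values[mask]).slope
    return slopes


def classify_ch4_zones(
    profile: Profile,
    delta_enrichment_threshold: float = 2.0,
    assessment_window_m: float = 2.0,
    ch4_column: str = "ch4_uM",
    delta_column: str = "d13c_ch4_permil",
) -> tuple[tuple[Zone, ...], bool]:
    """Partition the column into methane zones from concentration and δ¹³C.

    Local trends are estimated by OLS over a sliding depth window of
    ``assessment_window_m`` (keeps the classification invariant to profile
    super-sampling).  A sample belongs to the *oxidation* zone when δ¹³C-CH₄
    increases upward by more than the threshold per window while the
    concentration decreases upward; to the *diffusion* zone when the
    concentration decreases upward but δ¹³C is invariant within the
    threshold.  Depths below the diffusion zone form the methanogenic source
    zone; depths above the oxidation zone are the oxic zone.

    Returns (zones, indeterminate): ``indeterminate`` is True when neither
    an oxidation nor a diffusion signal was found.
    """
    for col in (ch4_column, delta_column):
        if not profile.has(col):
            raise MissingAnalyteError(col)
    sub = profile.data[["depth_m", ch4_column, delta_column]].dropna()
    depths = sub["depth_m"].to_numpy(float)
    conc = sub[ch4_column].to_numpy(float)
    delta = sub[delta_column].to_numpy(float)
    if len(depths) < 3:
        raise MissingAnalyteError("need >= 3 joint CH4/delta samples")

    slope_c = _local_slopes(depths, conc, assessment_window_m)
    slope_d = _local_slopes(depths, delta, assessment_window_m)
    # δ increases upward  <=>  dδ/dz < 0 (depth positive downward)
    delta_rate = delta_enrichment_threshold / assessment_window_m
    oxidizing = (slope_d < -delta_rate) & (slope_c > 0)
    diffusing = (slope_c > 0) & (np.abs(slope_d) <= delta_rate) & ~oxidizing

    zones: list[Zone] = []
    if not oxidizing.any() and not diffusing.any():
        return (
            (Zone("diffusion/indeterminate", float(depths[0]), float(depths[-1])),),
            True,
        )

    def longest_run(mask: np.ndarray) -> tuple[int, int] | None:
        best = None
        start = None
        for i, flag in enumerate(np.append(mask, False)):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                if best is None or i - start > best[1] - best[0]:
                    best = (start, i - 1)
                start = None
        return best

    ox_run = longest_run(oxidizing)
    if ox_run is not None:
        ox_top, ox_bottom = depths[ox_run[0]], depths[ox_run[1]]
        if ox_top > depths[0]:
            zones.append(Zone("oxic", float(depths[0]), float(ox_top)))
        zones.append(Zone("oxidation", float(ox_top), float(ox_bottom)))
        below = diffusing & (depths > ox_bottom)
        diff_run = longest_run(below)
        if diff_run is not None:
            diff_bottom = depths[diff_run[1]]
            zones.append(Zone("diffusion", float(ox_bottom), float(diff_bottom)))
            if diff_bottom < depths[-1]:
                zones.append(
                    Zone("methanogenic-source", float(diff_bottom), float(depths[-1]))
                )
        elif ox_bottom < depths[-1]:
            zones.append(
                Zone("methanogenic-source", float(ox_bottom), float(depths[-1]))
            )
        return tuple(zones), False

    # diffusion signal without oxidation: no isotopic enrichment anywhere
    diff_run = longest_run(diffusing)
    assert diff_run is not None
    diff_top, diff_bottom = depths[diff_run[0]], depths[diff_run[1]]
    if diff_top > depths[0]:
        zones.append(Zone("oxic", float(depths[0]), float(diff_top)))
    zones.append(Zone("diffusion", float(diff_top), float(diff_bottom)))
    if diff_bottom < depths[-1]:
        zones.append(
            Zone("methanogenic-source", float(diff_bottom), float(depths[-1]))
        )
    return tuple(zones), False


def build_zone_map(
    profile: Profile,
    anoxia_threshold_nM: float = 20.0,
    delta_enrichment_threshold: float = 2.0,
    assessment_window_m: float = 2.0,
) -> ZoneMap:
    """Full redox + methane zonation of one profile."""
    oxycline = find_oxycline(profile)
    onset = find_anoxia_onset(profile, anoxia_threshold_nM)
    depths = profile.depths
    top, bottom = float(depths[0]), float(depths[-1])

    o2_gradient = steepest_gradient(profile, "o2_uM")
    oxy_top, oxy_bottom = o2_gradient.depth_window
    redox: list[Zone] = []
    if oxy_top > top:
        redox.append(Zone("oxic", top, float(oxy_top)))
    redox.append(Zone("oxycline", float(oxy_top), float(oxy_bottom)))
    if onset is not None and onset > oxy_bottom:
        redox.append(Zone("suboxic", float(oxy_bottom), float(onset)))
        if onset < bottom:
            redox.append(Zone("anoxic", float(onset), bottom))
    elif oxy_bottom < bottom:
        redox.append(Zone("suboxic", float(oxy_bottom), bottom))

    ch4_zones, indeterminate = classify_ch4_zones(
        profile,
        delta_enrichment_threshold=delta_enrichment_threshold,
        assessment_window_m=assessment_window_m,
    )
    return ZoneMap(
        oxycline_depth_m=oxycline,
        anoxia_onset_m=onset,
        zones=tuple(redox),
        ch4_zones=ch4_zones,
        indeterminate=indeterminate,
    )
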