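"""Stimulus design: conditions, trial types, and the trial-table schema.

The task is a two-alternative forced choice (2AFC) audiovisual localization:
on each trial a visual grating of some contrast may appear on the left or
right, and an auditory click train is played from the left, center, or right
speaker. The subject turns a wheel to report the perceived side.

Sign conventions used throughout the package: right is positive — for
azimuth (degrees), for choice (+1 = rightward) and for log odds of a
rightward choice. Contrast is stored as a fraction in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default azimuths (degrees); the extended design adds -30/+30.
AZIMUTHS = (-60.0, 0.0, 60.0)
AZIMUTHS_EXTENDED = (-60.0, -30.0, 0.0, 30.0, 60.0)

#: Default nonzero contrast fractions.
CONTRASTS = (0.1, 0.2, 0.4, 0.8)

#: unisensory_visual / unisensory_auditory / coherent / conflict / neutral
TRIAL_TYPES = (
    "unisensory_visual",
    "unisensory_auditory",
    "coherent",
    "conflict",
    "neutral",
)
DEFAULT_TYPE_RATIO = (10.0, 10.0, 5.0, 5.0, 1.0)

#: Canonical trial-table columns (CSV interface).
TRIAL_COLUMNS = [
    "trial_id",
    "session_id",
    "subject_id",
    "vis_contrast_L",
    "vis_contrast_R",
    "aud_azimuth_deg",
    "trial_type",
    "choice",
    "rt_s",
    "timeout",
    "repeat_flag",
    "laser_on",
    "laser_ap_mm",
    "laser_ml_mm",
    "laser_onset_s",
]


def classify_trial_type(vis_contrast_L: float, vis_contrast_R: float,
                        aud_azimuth_deg: float) -> str:
    """Trial type as a pure function of contrasts and auditory azimuth.

    A visual stimulus is present when either contrast is nonzero (at most one
    may be); the auditory stimulus is lateral when azimuth != 0.
    """
    if vis_contrast_L < 0 or vis_contrast_R < 0:
        raise ValueError("contrasts must be non-negative")
    if vis_contrast_L * vis_contrast_R != 0:
        raise ValueError("at most one of vis_contrast_L/R may be nonzero")
    vis = vis_contrast_L > 0 or vis_contrast_R > 0
    aud = aud_azimuth_deg != 0
    if vis and not aud:
        return "unisensory_visual"
    if aud and not vis:
        return "unisensory_auditory"
    if not vis and not aud:
        return "neutral"
    vis_side = 1.0 if vis_contrast_R > 0 else -1.0
    return "coherent" if np.sign(aud_azimuth_deg) == vis_side else "conflict"


@dataclass(frozen=True)
class StimulusCondition:
    """One audiovisual stimulus condition.

    ``AR``/``AL`` are the binary indicators for a right/left auditory
    stimulus; both are 0 for a central (or absent) sound.
    """

    vis_contrast_L: float = 0.0
    vis_contrast_R: float = 0.0
    aud_azimuth_deg: float = 0.0

    def __post_init__(self):
        if self.vis_contrast_L * self.vis_contrast_R != 0:
            raise ValueError("at most one visual contrast may be nonzero")
        for c in (self.vis_contrast_L, self.vis_contrast_R):
            if not 0 <= c <= 1:
                raise ValueError("contrast must lie in [0, 1]")

    @property
    def AR(self) -> int:
        return int(self.aud_azimuth_deg > 0)

    @property
    def AL(self) -> int:
        return int(self.aud_azimuth_deg < 0)

    @property
    def trial_type(self) -> str:
        return classify_trial_type(
            self.vis_contrast_L, self.vis_contrast_R, self.aud_azimuth_deg)

    def as_row(self) -> dict:
        return {
            "vis_contrast_L": self.vis_contrast_L,
            "vis_contrast_R": self.vis_contrast_R,
            "aud_azimuth_deg": self.aud_azimuth_deg,
            "trial_type": self.trial_type,
        }


def validate_trials(trials: pd.DataFrame, require_choice: bool = False) -> pd.DataFrame:
    """Validate a trial table against the canonical schema.

    Missing optional columns (laser, repeat, rt) are added with defaults.
    Returns the (possibly augmented) table; raises on structural problems.
    """
    trials = trials.copy()
    needed = ["vis_contrast_L", "vis_contrast_R", "aud_azimuth_deg"]
    for col in needed:
        if col not in trials.columns:
            raise ValueError(f"trial table missing column {col!r}")
    if (trials["vis_contrast_L"] * trials["vis_contrast_R"] != 0).any():
        raise ValueError("found trials with both visual contrasts nonzero")
    if "trial_type" not in trials.columns:
        trials["trial_type"] = [
            classify_trial_type(l, r, a) for l, r, a in zip(
                trials["vis_contrast_L"], trials["vis_contrast_R"],
                trials["aud_azimuth_deg"])
        ]
    defaults = {
        "trial_id": lambda n: np.arange(n),
        "session_id": lambda n: np.zeros(n, dtype=int),
        "subject_id": lambda n: np.zeros(n, dtype=int),
        "repeat_flag": lambda n: np.zeros(n, dtype=bool),
        "timeout": lambda n: np.zeros(n, dtype=bool),
        "laser_on": lambda n: np.zeros(n, dtype=bool),
    }
    for col, make in defaults.items():
        if col not in trials.columns:
            trials[col] = make(len(trials))
    if require_choice and "choice" not in trials.columns:
        raise ValueError("trial table has no 'choice' column")
    return trials


def choice_to_sign(choice) -> np.ndarray:
    """Map choice labels {'L','R'} (or +-1) to signed values -1/+1."""
    arr = np.asarray(choice)
    if arr.dtype.kind in "UO":
        out = np.where(arr == "R", 1.0, np.where(arr == "L", -1.0, np.nan))
    else:
        out = arr.astype(float)
    return out


@dataclass(frozen=True)
class LaserSite:
    """A unilateral inactivation target in stereotaxic mm from bregma."""

    ap_mm: float
    ml_mm: float
    region: str = "none"  # visual | frontal | lateral | somatosensory | none

    @property
    def hemisphere(self) -> str:
        return "right" if self.ml_mm > 0 else ("left" if self.ml_mm < 0 else "midline")


#: Region site lists (AP, ML) in mm, right hemisphere; mirrored for left.
REGION_SITES = {
    "visual": [(-4.0, 1.8), (-4.0, 3.0), (-3.0, 3.0)],
    "frontal": [(2.0, 0.6), (2.0, 1.8), (3.0, 0.6)],
    "lateral": [(-4.0, 4.2), (-2.0, 4.2)],
    "somatosensory": [(1.0, 3.0), (0.0, 3.0), (0.0, 4.2)],
}

#: AP and |ML| coordinates of the full inactivation grid.
GRID_AP = (0.0, 1.0, -1.0, 2.0, -2.0, 3.0, -3.0, -4.0)
GRID_ML = (0.6, 1.8, 3.0, 4.2)


def default_site_grid(regions: dict | None = None) -> list[LaserSite]:
    """Bilateral site grid: the AP x |ML| product mirrored over hemispheres.

    The region labelling assigns each site to at most one named region via
    ``REGION_SITES`` (coordinates are right-hemisphere; the mirror-image site
    gets the same label). Callers with an explicit 52-site list should pass it
    directly; this default enumerates the full coordinate product.
    """
    if regions is None:
        regions = REGION_SITES
    lookup = {}
    for name, coords in regions.items():
        for ap, ml in coords:
            lookup[(ap, abs(ml))] = name
    sites = []
    for ap in GRID_AP:
        for ml in GRID_ML:
            for sgn in (-1.0, 1.0):
                region = lookup.get((ap, ml), "none")
                sites.append(LaserSite(ap_mm=ap, ml_mm=sgn * ml, region=region))
    return sites
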