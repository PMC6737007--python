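"""Chemical-shift-perturbation interface mapping and backbone-dynamics QC.

Turns paired peak lists (apo vs ligand-added, or medium A vs medium B) into
per-residue perturbation profiles and binary interface/mobility flags.

Conventions
-----------
* Combined CSP: ``sqrt(ddH^2 + (alpha_N * ddN)^2)`` with ``alpha_N = 0.2``
  by default (the 15N shift range is ~5x the 1H range).
* Intensity ratios are corrected for sample dilution before thresholding;
  a residue is "broadened" below 0.6.
* Interface flags: CSP >= 0.015 ppm is the usual ligand-side threshold and
  0.08 ppm the receptor-side one; both are explicit arguments.
* HNCO intensity classes: high above twice the mean, low below half the
  mean (mean taken on the raw intensity scale).
* Heteronuclear 15N-{1H} NOE below 0.6 marks high-amplitude ps-ns motion
  (strict inequality; boundary values are not flagged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PEAK_COLUMNS",
    "combined_csp",
    "intensity_ratio",
    "build_profile",
    "map_interface",
    "secondary_shift_diff",
    "hnco_mobility_classes",
    "hetnoe_flag",
    "SECCalibration",
    "SEC_STANDARDS",
    "construct_to_channel",
    "channel_to_construct",
    "CHANNEL_OFFSET",
]

PEAK_COLUMNS = ["residue_id", "aa", "dH_ppm", "dN_ppm", "intensity"]

#: Residue-numbering offset between the expressed construct (Met1 = 1) and
#: the full-length channel sequence: construct 47 -> channel 598.
CHANNEL_OFFSET = 551


def construct_to_channel(construct_number):
    """Map construct numbering to full-length channel numbering (+551)."""
    n = np.asarray(construct_number)
    if np.any(n < 1):
        raise ValueError("construct numbering starts at 1")
    out = n + CHANNEL_OFFSET
    return out.item() if np.isscalar(construct_number) else out


def channel_to_construct(channel_number):
    """Inverse of :func:`construct_to_channel`."""
    n = np.asarray(channel_number)
    out = n - CHANNEL_OFFSET
    if np.any(out < 1):
        raise ValueError("channel number below the construct range")
    return out.item() if np.isscalar(channel_number) else out


def combined_csp(dd_h, dd_n, alpha_n: float = 0.2):
    """Weighted-Euclidean combined 1H/15N chemical-shift perturbation (ppm)."""
    if alpha_n <= 0:
        raise ValueError("alpha_n must be positive")
    dd_h = np.asarray(dd_h, dtype=float)
    dd_n = np.asarray(dd_n, dtype=float)
    if not (np.all(np.isfinite(dd_h)) and np.all(np.isfinite(dd_n))):
        raise ValueError("shift differences must be finite")
    out = np.sqrt(dd_h**2 + (alpha_n * dd_n) ** 2)
    return out.item() if out.ndim == 0 else out


def intensity_ratio(i_after, i_before, dilution_factor: float = 1.0):
    """Dilution-corrected intensity ratio ``(I_after/dilution)/I_before``.

    ``dilution_factor`` is the concentration ratio C_after/C_before of the
    observed species.  Returns NaN where ``i_before`` is zero (undefined,
    reported per residue rather than raised).
    """
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be positive")
    i_after = np.asarray(i_after, dtype=float)
    i_before = np.asarray(i_before, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(i_before > 0, (i_after / dilution_factor) / i_before, np.nan)
    return out.item() if out.ndim == 0 else out


def build_profile(
    apo: pd.DataFrame,
    bound: pd.DataFrame,
    dilution_factor: float = 1.0,
    alpha_n: float = 0.2,
) -> pd.DataFrame:
    """Per-residue perturbation profile from two peak lists.

    Both inputs follow :data:`PEAK_COLUMNS`.  Only residues present in both
    lists are profiled; residues present in one list only are returned with
    NaN metrics (they are excluded from interface statistics and counted by
    the caller).  Columns added: ``dd_H``, ``dd_N``, ``csp``, ``ratio``,
    ``broadened``.
    """
    merged = apo.merge(bound, on=["residue_id", "aa"], how="outer",
                       suffixes=("_apo", "_bound"), sort=True)
    dd_h = merged.dH_ppm_bound - merged.dH_ppm_apo
    dd_n = merged.dN_ppm_bound - merged.dN_ppm_apo
    csp = np.sqrt(dd_h**2 + (alpha_n * dd_n) ** 2)
    ratio = intensity_ratio(
        merged.intensity_bound.to_numpy(),
        merged.intensity_apo.to_numpy(),
        dilution_factor,
    )
    out = merged[["residue_id", "aa"]].copy()
    out["dd_H"] = dd_h
    out["dd_N"] = dd_n
    out["csp"] = csp
    out["ratio"] = ratio
    out["broadened"] = out.ratio < 0.6
    return out


def map_interface(
    profile: pd.DataFrame,
    csp_threshold: float = 0.08,
    ratio_threshold: float = 0.6,
) -> dict:
    """Interface residues: CSP >= threshold OR intensity ratio <= threshold.

    Residues without both metrics (unmatched between the two lists) are
    excluded and counted separately.  Returns a dict with the flagged
    ``residues`` (sorted ids), the flagged ``table`` and ``n_excluded``.
    """
    ok = profile.csp.notna() & profile.ratio.notna()
    scored = profile[ok]
    flagged = scored[
        (scored.csp >= csp_threshold) | (scored.ratio <= ratio_threshold)
    ]
    return {
        "residues": sorted(flagged.residue_id.tolist()),
        "table": flagged,
        "n_excluded": int((~ok).sum()),
    }


def secondary_shift_diff(
    shifts_a: pd.DataFrame, shifts_b: pd.DataFrame, nucleus: str
) -> tuple[pd.DataFrame, float]:
    """Per-residue shift difference A - B for one nucleus, plus mean |dd|.

    Shift tables carry columns ``residue_id``, ``nucleus``, ``shift_ppm``.
    Sign convention: positive means the shift is larger in table A (in the
    micelle-comparison use case A is the zwitterionic DPC/LDAO condition and
    B the anionic LPPG one).  Only residues assigned in both tables enter.
    """
    if nucleus not in {"CA", "C", "HN"}:
        raise ValueError("nucleus must be one of CA, C, HN")
    a = shifts_a[shifts_a.nucleus == nucleus]
    b = shifts_b[shifts_b.nucleus == nucleus]
    merged = a.merge(b, on="residue_id", suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError(f"no residues with {nucleus} shifts common to both tables")
    out = pd.DataFrame(
        {
            "residue_id": merged.residue_id,
            "dd_ppm": merged.shift_ppm_a - merged.shift_ppm_b,
        }
    )
    return out, float(out.dd_ppm.abs().mean())


def hnco_mobility_classes(intensities: pd.Series) -> pd.DataFrame:
    """Classify residues by HNCO cross-peak intensity.

    ``high`` above twice the mean (high ps-ns mobility), ``low`` below half
    the mean (rigid TM core or us-ms exchange), else ``normal``.  The mean is
    taken over the raw intensities (any log axis is display only).
    """
    inten = pd.Series(intensities, dtype=float)
    if len(inten) < 2:
        raise ValueError("need at least 2 residues")
    if (inten < 0).any():
        raise ValueError("intensities must be non-negative")
    mean = inten.mean()
    if mean == 0:
        raise ValueError("all-zero intensities")
    cls = np.where(inten > 2 * mean, "high", np.where(inten < mean / 2, "low", "normal"))
    return pd.DataFrame({"intensity": inten, "hnco_class": cls}, index=inten.index)


def hetnoe_flag(noe_value, threshold: float = 0.6):
    """Mobile flag: steady-state 15N-{1H} NOE strictly below ``threshold``."""
    v = np.asarray(noe_value, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("NOE values must be finite")
    out = v < threshold
    return out.item() if out.ndim == 0 else out


#: Stokes radii (nm) of the usual SEC calibration standards.
SEC_STANDARDS = {
    "ferritin": 6.10,
    "catalase": 5.22,
    "aldolase": 4.81,
    "BSA": 3.55,
    "ovalbumin": 3.05,
}


@dataclass
class SECCalibration:
    """Linear SEC calibration: log10(Stokes radius) vs elution volume.

    Fitted by ordinary least squares on >= 2 standards; prediction inverts
    the line, returning a radius in nm for a query volume in ml.
    """

    slope: float
    intercept: float
    r_value: float

    @classmethod
    def fit(cls, volumes_ml, radii_nm) -> "SECCalibration":
        v = np.asarray(volumes_ml, dtype=float)
        r = np.asarray(radii_nm, dtype=float)
        if len(v) < 2 or len(np.unique(v)) < 2:
            raise ValueError("need at least 2 standards with distinct volumes")
        res = stats.linregress(v, np.log10(r))
        return cls(slope=res.slope, intercept=res.intercept, r_value=res.rvalue)

    def predict(self, volume_ml):
        v = np.asarray(volume_ml, dtype=float)
        out = 10 ** (self.intercept + self.slope * v)
        return out.item() if out.ndim == 0 else out
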