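"""Secondary plate-screen quantification.

Scanned 96-well plates are converted to grayscale, the mean pixel intensity
over each well's full circular sampling area is measured, and each mutant's
growth is expressed as a Z-score against the wild-type wells of the same
plate (wild-type colonies are placed on every plate to cancel positional
effects, so no cross-plate pooling is done).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["WellGeometry", "to_grayscale", "quantify_wells", "growth_z_scores"]

#: Rec. 601 luminance weights, the common image-software grayscale default.
REC601 = (0.299, 0.587, 0.114)


@dataclass
class WellGeometry:
    """Regular grid of circular sampling areas.

    Well centers sit at ``(origin + index * pitch)`` pixels; the sampling
    area of each well is the full disk of ``radius_px``.
    """

    origin_row: float
    origin_col: float
    pitch_row: float
    pitch_col: float
    radius_px: float

    def center(self, row: int, col: int) -> tuple[float, float]:
        return (self.origin_row + row * self.pitch_row,
                self.origin_col + col * self.pitch_col)


def to_grayscale(image: np.ndarray, weights=REC601) -> np.ndarray:
    """Collapse an 8-bit RGB image to grayscale luminance (0–255 floats)."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return img
    if img.ndim != 3 or img.shape[-1] < 3:
        raise ValueError("expected an RGB image (H, W, 3) or a grayscale array")
    w = np.asarray(weights, dtype=float)
    return img[..., :3] @ w


def quantify_wells(
    image: np.ndarray,
    layout: pd.DataFrame,
    geometry: WellGeometry,
    weights=REC601,
) -> pd.DataFrame:
    """Mean grayscale intensity per well over its full disk sampling area.

    ``layout`` needs columns ``row, col, genotype, is_wt`` plus an optional
    boolean ``excluded`` (wells with bubbles or irregular clamping); excluded
    wells are absent from the output.
    """
    gray = to_grayscale(image, weights)
    h, w = gray.shape
    yy, xx = np.mgrid[:h, :w]
    if "excluded" not in layout.columns:
        layout = layout.assign(excluded=False)

    rows = []
    for _, well in layout.iterrows():
        if bool(well["excluded"]):
            continue
        cy, cx = geometry.center(int(well["row"]), int(well["col"]))
        if not (0 <= cy < h and 0 <= cx < w):
            raise ValueError(f"well ({well['row']},{well['col']}) outside the image")
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= geometry.radius_px**2
        if not mask.any():
            raise ValueError("well sampling area contains no pixels")
        rows.append(
            {
                "row": int(well["row"]),
                "col": int(well["col"]),
                "genotype": well["genotype"],
                "is_wt": bool(well["is_wt"]),
                "intensity": float(gray[mask].mean()),
            }
        )
    return pd.DataFrame(rows)


def growth_z_scores(
    intensities: pd.DataFrame,
    per_well: bool = False,
) -> pd.DataFrame:
    """Z-score each genotype's growth against same-plate wild-type wells.

    Z = (mean of the genotype's replicate wells − mean of wild-type wells)
    / sample SD (ddof=1) of the wild-type wells.  Replicate wells are
    averaged before scoring unless ``per_well=True``.
    """
    wt = intensities[intensities["is_wt"]]
    if len(wt) < 2:
        raise ValueError("need at least 2 wild-type wells with intensities")
    mu = wt["intensity"].mean()
    sd = wt["intensity"].std(ddof=1)
    if sd == 0:
        # a perfectly flat plate (every well at the wild-type mean) is the
        # degenerate all-equal case and scores 0 by convention; any actual
        # difference is unscorable without wild-type variance
        if np.allclose(intensities["intensity"], mu):
            sd = 1.0
        else:
            raise ValueError("wild-type wells have zero variance; plate not scorable")

    if per_well:
        out = intensities.copy()
        out["z"] = (out["intensity"] - mu) / sd
        return out[["row", "col", "genotype", "is_wt", "intensity", "z"]]

    agg = (
        intensities.groupby("genotype", sort=True)
        .agg(n_wells=("intensity", "size"), mean_intensity=("intensity", "mean"),
             is_wt=("is_wt", "any"))
        .reset_index()
    )
    agg["z"] = (agg["mean_intensity"] - mu) / sd
    return agg
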