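"""Compactness indices and sigmoid compactness profiles from binary bone
cross-sections.

A bone cross-section is a binary raster whose foreground is mineralized
tissue.  The analysis mirrors the classical compactness-profile approach for
long-bone sections: the hole-filled section defines the reference area; the
radial occupancy profile (fraction of mineralized pixels per relative-radius
bin, pooled over angular sectors) is summarized by a four-parameter sigmoid

    C(x) = Min + (Max - Min) / (1 + exp((P - x) / S))

where ``P`` locates the medulla-to-cortex transition (a proxy for relative
medullary cavity size) and ``S`` is the relative width of that transition
zone.  Whole-section, central and peripheral compactness (Cg, Cc, Cp) and
the maximal Feret diameter MD complete the index set.

Radial position is normalized per angular sector by that sector's boundary
distance, so elongated (rib-like) sections get a sensible [0, 1] radial
coordinate; the reference centre is the centroid of the hole-filled section,
which cavities cannot shift.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage import measure

from .errors import FitError, InvalidInputError

__all__ = [
    "BoneSection",
    "CompactnessProfile",
    "SigmoidFit",
    "CompactnessIndices",
    "load_section",
    "radial_profile",
    "fit_sigmoid_profile",
    "compactness_indices",
    "sigmoid",
    "DEGENERATE_VAR",
]

#: profile variance below this is treated as "no transition to estimate"
DEGENERATE_VAR = 1e-4


def sigmoid(x, S, P, cmin, cmax):
    """The compactness-profile model Min + (Max-Min)/(1+exp((P-x)/S))."""
    return cmin + (cmax - cmin) / (1.0 + np.exp((P - np.asarray(x, float)) / S))


@dataclass
class BoneSection:
    """A binary bone cross-section plus its metadata.

    ``mask`` is boolean, foreground = mineralized tissue.  ``pixel_size`` is
    edge length of one pixel in mm (None leaves MD in pixels).  Validity
    requires at least one foreground pixel and exactly one connected
    component after hole-filling.
    """

    mask: np.ndarray
    pixel_size: float | None = None
    species_id: str = ""
    bone_type: str = ""

    def __post_init__(self):
        self.mask = np.asarray(self.mask, bool)
        if self.mask.ndim != 2:
            raise InvalidInputError("mask must be 2-D")
        if not self.mask.any():
            raise InvalidInputError("empty mask: no foreground pixels")
        filled = ndimage.binary_fill_holes(self.mask)
        lbl, n = ndimage.label(filled)
        if n != 1:
            # porous cortices shed isolated one-to-few-pixel specks; those are
            # still bone, not a second fragment.  Reject only when more than
            # one component is non-negligible (>= 1% of the largest).
            areas = np.bincount(lbl.ravel())[1:]
            major = int(np.sum(areas >= 0.01 * areas.max()))
            if major != 1:
                raise InvalidInputError(
                    f"disconnected section: {major} fragments after hole-filling"
                )
        self._filled = filled

    @property
    def filled(self) -> np.ndarray:
        """Hole-filled section mask (the reference area)."""
        return self._filled


def load_section(
    path,
    pixel_size: float | None = None,
    species_id: str = "",
    bone_type: str = "",
    invert: bool = False,
    threshold: float = 0.5,
) -> BoneSection:
    """Read a PNG/TIFF image and binarize at ``threshold`` of dynamic range.

    Foreground is white by default; ``invert=True`` for dark-on-light scans.
    Anti-aliased grayscale edges are handled by the threshold.
    """
    from PIL import Image

    img = np.asarray(Image.open(path).convert("L"), float)
    lo, hi = img.min(), img.max()
    mask = img > lo + threshold * (hi - lo) if hi > lo else img > 0
    if invert:
        mask = ~mask
    return BoneSection(mask, pixel_size=pixel_size, species_id=species_id,
                       bone_type=bone_type)


@dataclass
class CompactnessProfile:
    """Radial compactness curve: mean occupancy per relative-radius bin."""

    radii: np.ndarray  # bin centres, strictly increasing, in [0, 1]
    compactness: np.ndarray  # in [0, 1]; NaN for empty bins
    counts: np.ndarray  # pixels per bin (the aggregation weights)
    n_sectors: int
    n_bins: int


def _relative_radius(section: BoneSection, n_sectors: int):
    """Per-pixel relative radius of the filled mask, normalized per sector.

    Returns (rel_radius flat array, foreground flat bool array) over the
    filled-mask pixels.
    """
    filled = section.filled
    ys, xs = np.nonzero(filled)
    cy, cx = ys.mean(), xs.mean()  # centroid of the hole-filled section
    dy, dx = ys - cy, xs - cx
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)  # [-pi, pi]
    sector = np.clip(
        ((theta + np.pi) / (2 * np.pi) * n_sectors).astype(int), 0, n_sectors - 1
    )
    rmax = np.zeros(n_sectors)
    np.maximum.at(rmax, sector, r)
    rmax[rmax == 0] = 1.0  # sector holding only the centroid pixel
    rel = r / rmax[sector]
    fg = section.mask[ys, xs]
    return rel, fg


def radial_profile(
    section: BoneSection, n_sectors: int = 60, n_bins: int = 51
) -> CompactnessProfile:
    """Radial occupancy profile of a bone section.

    For each relative-radius bin, compactness is the fraction of foreground
    pixels among hole-filled-section pixels falling in the bin, pooled over
    angular sectors (i.e. sectors weighted by their pixel counts).
    """
    if n_sectors < 8:
        raise InvalidInputError("n_sectors must be >= 8")
    if n_bins < 10:
        raise InvalidInputError("n_bins must be >= 10")
    rel, fg = _relative_radius(section, n_sectors)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(rel, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    hits = np.bincount(idx, weights=fg.astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        comp = np.where(counts > 0, hits / np.maximum(counts, 1), np.nan)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return CompactnessProfile(
        radii=centres, compactness=comp, counts=counts,
        n_sectors=n_sectors, n_bins=n_bins,
    )


@dataclass
class SigmoidFit:
    """Fitted compactness-profile model parameters."""

    S: float  # transition-zone relative width; NaN for degenerate profiles
    P: float  # transition position in [0, 1]; NaN for degenerate profiles
    Min: float
    Max: float
    rss: float
    converged: bool
    degenerate: bool = False


# deterministic multi-start grid for the transition position
_P_STARTS = (0.2, 0.4, 0.6, 0.8)
_S_START = 0.1
_S_BOUNDS = (1e-4, 1.0)


def fit_sigmoid_profile(profile: CompactnessProfile) -> SigmoidFit:
    """Bounded least-squares fit of the sigmoid model to a radial profile.

    Bins are weighted by pixel count.  Five deterministic starts (P on a
    grid with S = 0.1, plus a moment-based start at the mid-compactness
    crossing) guard against the local optima of logistic fits; the best
    weighted RSS wins, ties broken by smallest S.  Profiles with (weighted)
    variance below ``DEGENERATE_VAR`` have no transition to estimate and are
    returned with S and P missing and Min = Max = mean compactness.
    """
    ok = np.isfinite(profile.compactness) & (profile.counts > 0)
    x = profile.radii[ok]
    c = profile.compactness[ok]
    w = profile.counts[ok]
    if len(x) < 10:
        raise InvalidInputError("profile needs >= 10 populated bins")
    wmean = float(np.average(c, weights=w))
    wvar = float(np.average((c - wmean) ** 2, weights=w))
    if wvar < DEGENERATE_VAR:
        return SigmoidFit(S=math.nan, P=math.nan, Min=wmean, Max=wmean,
                          rss=float(np.sum(w * (c - wmean) ** 2)),
                          converged=False, degenerate=True)

    sw = np.sqrt(w)
    lo, hi = float(c.min()), float(c.max())

    def residuals(theta):
        S, P, cmin, cmax = theta
        return sw * (sigmoid(x, S, P, cmin, cmax) - c)

    # moment-based start: first crossing of the mid-compactness level
    mid = 0.5 * (lo + hi)
    above = c >= mid
    cross = x[np.argmax(above)] if above.any() and not above.all() else 0.5
    starts = [(_S_START, p, lo, hi) for p in _P_STARTS]
    starts.append((_S_START, float(np.clip(cross, 0.05, 0.95)), lo, hi))

    bounds = ([_S_BOUNDS[0], 0.0, 0.0, 0.0], [_S_BOUNDS[1], 1.0, 1.0, 1.0])
    best = None
    for theta0 in starts:
        try:
            res = optimize.least_squares(residuals, theta0, bounds=bounds,
                                         method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        rss = float(2 * res.cost)
        key = (round(rss, 12), res.x[0])  # ties broken by smallest S
        if best is None or key < best[0]:
            best = (key, res)
    if best is None:
        return SigmoidFit(S=math.nan, P=math.nan, Min=wmean, Max=wmean,
                          rss=math.inf, converged=False)
    res = best[1]
    S, P, cmin, cmax = (float(v) for v in res.x)
    return SigmoidFit(S=S, P=P, Min=cmin, Max=cmax, rss=float(2 * res.cost),
                      converged=bool(res.success))


@dataclass
class CompactnessIndices:
    """The per-section index set used in the comparative analyses."""

    Cg: float  # whole-section compactness
    Cc: float  # central compactness (trabecular signal)
    Cp: float  # peripheral compactness (cortical porosity signal)
    S: float
    P: float
    MD: float  # maximal Feret diameter (pixels, or mm when pixel_size given)
    species_id: str = ""
    bone_type: str = ""
    converged: bool = True


def compactness_indices(
    section: BoneSection,
    fit: SigmoidFit | None = None,
    center_frac: float = 1.0 / 3.0,
    periphery_frac: float = 2.0 / 3.0,
    n_sectors: int = 60,
) -> CompactnessIndices:
    """Cg/Cc/Cp/MD for a section, with S and P copied from ``fit``.

    Cg is foreground over hole-filled pixels; Cc restricts to relative radius
    <= ``center_frac`` and Cp to >= ``periphery_frac`` (defaults: symmetric
    thirds, approximating medulla and cortex).
    """
    if not 0.0 < center_frac < periphery_frac < 1.0:
        raise InvalidInputError("need 0 < center_frac < periphery_frac < 1")
    rel, fg = _relative_radius(section, n_sectors)
    cg = float(fg.mean())
    centre = rel <= center_frac
    periph = rel >= periphery_frac
    if not centre.any():
        raise InvalidInputError("central region contains no section pixels")
    if not periph.any():
        raise InvalidInputError("peripheral region contains no section pixels")
    cc = float(fg[centre].mean())
    cp = float(fg[periph].mean())
    lbl = measure.label(section.filled)
    md = float(measure.regionprops(lbl)[0].feret_diameter_max)
    if section.pixel_size is not None:
        md *= section.pixel_size
    return CompactnessIndices(
        Cg=cg, Cc=cc, Cp=cp,
        S=fit.S if fit else math.nan,
        P=fit.P if fit else math.nan,
        MD=md,
        species_id=section.species_id,
        bone_type=section.bone_type,
        converged=fit.converged if fit else True,
    )


def profile_sections(
    manifest: pd.DataFrame,
    n_sectors: int = 60,
    n_bins: int = 51,
    center_frac: float = 1.0 / 3.0,
    periphery_frac: float = 2.0 / 3.0,
    invert: bool = False,
) -> pd.DataFrame:
    """Batch pipeline: manifest (path, species_id, bone_type, pixel_size_mm)
    to an indices table, one row per section."""
    rows = []
    for _, m in manifest.iterrows():
        px = m.get("pixel_size_mm")
        section = load_section(
            m["path"],
            pixel_size=float(px) if pd.notna(px) else None,
            species_id=str(m.get("species_id", "")),
            bone_type=str(m.get("bone_type", "")),
            invert=invert,
        )
        prof = radial_profile(section, n_sectors=n_sectors, n_bins=n_bins)
        fit = fit_sigmoid_profile(prof)
        idx = compactness_indices(
            section, fit, center_frac=center_frac,
            periphery_frac=periphery_frac, n_sectors=n_sectors,
        )
        rows.append(
            dict(species_id=idx.species_id, bone_type=idx.bone_type,
                 Cg=idx.Cg, Cc=idx.Cc, Cp=idx.Cp, S=idx.S, P=idx.P,
                 MD=idx.MD, converged=idx.converged)
        )
    return pd.DataFrame(rows)
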