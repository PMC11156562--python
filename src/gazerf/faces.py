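"""Face-selectivity analysis: fixation categorization, FSI, matched controls.

A fixation is a "face" fixation for a unit when the disc of radius one RF
s.d., centered at the fixation point plus the unit's RF-center offset (in
image coordinates), intersects any face ROI of the image; it is "nonface"
only on images that contain at least one face (to match stimulus
statistics across conditions); fixations on faceless images are excluded.

The face-selectivity index is FSI = (a - b) / (a + b), with a and b the
mean responses over face and nonface fixations in the 150-ms window
following the unit's latency.  Face fixations that are the target of a
face-to-face saccade are excluded from a (response adaptation).  Zeroth
fixations (image onset to first eye movement, analogous to passive
viewing) and nonzeroth fixations are analyzed separately; units with
zeroth-fixation FSI >= 0.2 (responses at least 50% higher to faces) are
called face neurons.

Matched-saccade comparisons ask whether apparent prefixation face
responses survive controlling the presaccadic stimulus: for each
nonface-to-face template saccade a nonface-to-nonface match starting <= 1
dva away with a >= 4-dva divergent endpoint provides a paired control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consistency import BinSpec
from .stats import bky_fdr, rank_tests

__all__ = [
    "FaceSelectivityResult",
    "disc_intersects_rect",
    "categorize_fixations",
    "compute_fsi",
    "saccade_categories",
    "saccade_category_timecourses",
    "matched_category_test",
]

FACE_NEURON_FSI = 0.2


@dataclass
class FaceSelectivityResult:
    a: float  # mean face-fixation response
    b: float  # mean nonface-fixation response
    fsi: float
    n_face: int
    n_nonface: int
    context: str = "nonzeroth"
    valid: bool = True


def disc_intersects_rect(
    cx: np.ndarray, cy: np.ndarray, radius: float,
    x0: float, y0: float, x1: float, y1: float,
) -> np.ndarray:
    """True where the disc at (cx, cy) intersects the axis-aligned rectangle."""
    dx = np.clip(x0 - np.asarray(cx, float), 0, None) + np.clip(np.asarray(cx, float) - x1, 0, None)
    dy = np.clip(y0 - np.asarray(cy, float), 0, None) + np.clip(np.asarray(cy, float) - y1, 0, None)
    return np.hypot(dx, dy) <= radius


def categorize_fixations(
    fixations: pd.DataFrame,
    rois: pd.DataFrame,
    rf_center: tuple[float, float],
    rf_radius: float,
) -> pd.DataFrame:
    """Label each valid fixation face / nonface / excluded for one unit.

    ``fixations`` needs image_id and image-coordinate centroids (x, y);
    ``rois`` is the face-ROI table (image_id, x0, y0, x1, y1).  The RF is
    (center offset dva, radius = 1 s.d.).  Returns the fixation table
    plus ``label`` and ``exclusion_reason`` columns.
    """
    if rf_radius is None or not np.isfinite(rf_radius):
        raise ValueError("unit RF missing; impute before categorizing fixations")
    out = fixations.copy()
    cx = out["x"].to_numpy(float) + rf_center[0]
    cy = out["y"].to_numpy(float) + rf_center[1]
    face_imgs = set(rois["image_id"].unique())
    label = np.full(len(out), "excluded", object)
    reason = np.full(len(out), "", object)
    on_face_img = out["image_id"].isin(face_imgs).to_numpy()
    reason[~on_face_img] = "no-face-image"
    hit = np.zeros(len(out), bool)
    for image_id, grp in rois.groupby("image_id"):
        sel = (out["image_id"] == image_id).to_numpy()
        if not sel.any():
            continue
        h = np.zeros(sel.sum(), bool)
        for _, roi in grp.iterrows():
            h |= disc_intersects_rect(cx[sel], cy[sel], rf_radius,
                                      roi["x0"], roi["y0"], roi["x1"], roi["y1"])
        hit[sel] = h
    label[on_face_img & hit] = "face"
    label[on_face_img & ~hit] = "nonface"
    invalid = ~out["valid"].to_numpy(bool)
    label[invalid] = "excluded"
    reason[invalid] = "invalid-fixation"
    out["label"] = label
    out["exclusion_reason"] = reason
    return out


def _previous_label(labeled: pd.DataFrame) -> np.ndarray:
    """Label of the immediately preceding fixation (same presentation)."""
    key = labeled.set_index(["presentation", "ordinal"])["label"]
    prev = []
    for _, row in labeled.iterrows():
        k = (row["presentation"], row["ordinal"] - 1)
        prev.append(key.loc[k] if k in key.index else "")
    return np.asarray(prev, object)


def compute_fsi(
    labeled: pd.DataFrame,
    responses: np.ndarray,
    context: str = "nonzeroth",
) -> FaceSelectivityResult:
    """Face-selectivity index FSI = (a - b) / (a + b) for one unit.

    ``responses`` aligns with the rows of ``labeled`` (rates in the
    150-ms window following the unit's latency; for the zeroth context,
    image-onset aligned with the image-onset latency).  Face fixations
    that are targets of face-to-face saccades are excluded from a.
    """
    if context not in ("zeroth", "nonzeroth", "all"):
        raise ValueError(f"unknown context: {context!r}")
    resp = np.asarray(responses, float)
    lab = labeled["label"].to_numpy(object)
    prev = _previous_label(labeled)
    ordin = labeled["ordinal"].to_numpy()
    if context == "zeroth":
        scope = ordin == 0
    elif context == "nonzeroth":
        scope = ordin > 0
    else:
        scope = np.ones(len(labeled), bool)
    ok = scope & np.isfinite(resp)
    face = ok & (lab == "face") & (prev != "face")  # drop face-to-face targets
    nonface = ok & (lab == "nonface")
    if face.sum() == 0 or nonface.sum() == 0:
        return FaceSelectivityResult(float("nan"), float("nan"), float("nan"),
                                     int(face.sum()), int(nonface.sum()),
                                     context, valid=False)
    a = float(resp[face].mean())
    b = float(resp[nonface].mean())
    if a + b == 0:
        return FaceSelectivityResult(a, b, float("nan"), int(face.sum()),
                                     int(nonface.sum()), context, valid=False)
    return FaceSelectivityResult(a, b, (a - b) / (a + b), int(face.sum()),
                                 int(nonface.sum()), context, valid=True)


# ---------------------------------------------------------------------------
# Saccade categories
# ---------------------------------------------------------------------------

CATEGORIES = ("face->face", "face->nonface", "nonface->face", "nonface->nonface")


def saccade_categories(labeled: pd.DataFrame) -> pd.DataFrame:
    """Category of the saccade *into* each nonzeroth fixation.

    Returns rows (fixation, onset, category, amplitude) for fixations
    whose own and preceding labels are both face/nonface.
    """
    prev = _previous_label(labeled)
    key = labeled.set_index(["presentation", "ordinal"])[["x", "y"]]
    rows = []
    for i, (_, row) in enumerate(labeled.iterrows()):
        if row["ordinal"] == 0 or row["label"] not in ("face", "nonface"):
            continue
        if prev[i] not in ("face", "nonface"):
            continue
        k = (row["presentation"], row["ordinal"] - 1)
        px, py = key.loc[k, "x"], key.loc[k, "y"]
        rows.append((
            row["fixation"], row["onset"], f"{prev[i]}->{row['label']}",
            float(np.hypot(row["x"] - px, row["y"] - py)),
        ))
    return pd.DataFrame(rows, columns=["fixation", "onset", "category", "amplitude"])


def saccade_category_timecourses(
    categories: pd.DataFrame,
    binned: np.ndarray,
    fixations: pd.DataFrame,
    bins: BinSpec,
    min_amplitude: float | None = None,
) -> dict:
    """Mean fixation-onset-aligned rate per saccade category, min-max normalized.

    ``binned`` is (n_fixations, n_bins) for the rows of ``fixations``.
    Normalization maps the minimum and maximum of the unit's mean rates
    over time *across the four categories* to 0 and 1.  Missing
    categories are flagged and returned as NaN curves.
    """
    idx = pd.Index(fixations["fixation"])
    cat = categories
    if min_amplitude is not None:
        cat = cat[cat["amplitude"] >= min_amplitude]
    curves = {}
    missing = []
    for c in CATEGORIES:
        ids = cat.loc[cat["category"] == c, "fixation"].to_numpy()
        loc = idx.get_indexer(ids)
        loc = loc[loc >= 0]
        if len(loc) == 0:
            curves[c] = np.full(bins.n_bins, np.nan)
            missing.append(c)
        else:
            curves[c] = np.nanmean(binned[loc], axis=0)
    allvals = np.concatenate([v for v in curves.values()])
    lo = np.nanmin(allvals)
    hi = np.nanmax(allvals)
    span = hi - lo if hi > lo else 1.0
    normalized = {c: (v - lo) / span for c, v in curves.items()}
    return {"curves": normalized, "raw": curves, "missing": missing,
            "centers": bins.centers}


def matched_category_test(
    binned_templates: dict[str, np.ndarray],
    binned_matches: dict[str, np.ndarray],
    binned_candidates: dict[str, np.ndarray] | None = None,
    q: float = 0.01,
    tail: str = "greater",
) -> dict:
    """Per-unit, per-bin significance of face vs nonface target responses.

    binned_templates[unit]: (n_templates, n_bins) responses aligned to
    the fixation onsets of nonface-to-face (template) saccades;
    binned_matches: same shape, the matched nonface-to-nonface saccades
    (row-aligned with templates, signed-rank paired test);
    binned_candidates: optional unpaired nonface-to-nonface pool for the
    unmatched rank-sum comparison.  P-values are FDR-corrected across
    bins and units jointly (two-stage BKY at q).  Returns the fraction of
    significant units per bin for each comparison.
    """
    units = sorted(binned_templates)
    if not units or all(binned_templates[u].size == 0 for u in units):
        return {"valid": False}
    n_bins = next(iter(binned_templates.values())).shape[1]

    def run(pairs: bool, other: dict[str, np.ndarray]) -> np.ndarray:
        P = np.full((len(units), n_bins), np.nan)
        for i, u in enumerate(units):
            T = binned_templates[u]
            O = other[u]
            for b in range(n_bins):
                x = T[:, b]
                y = O[:, b]
                ok = np.isfinite(x) & (np.isfinite(y) if pairs else True)
                if pairs:
                    xs, ys = x[ok], y[ok]
                    if len(xs) < 2 or np.all(xs - ys == 0):
                        continue
                    P[i, b] = rank_tests(xs, ys, paired=True, tail=tail)["p"]
                else:
                    xs = x[np.isfinite(x)]
                    ys = y[np.isfinite(y)]
                    if len(xs) < 2 or len(ys) < 2:
                        continue
                    P[i, b] = rank_tests(xs, ys, paired=False, tail=tail)["p"]
        return P

    out: dict = {"valid": True, "units": units}
    for name, pairs, other in [
        ("matched", True, binned_matches),
        ("unmatched", False, binned_candidates),
    ]:
        if other is None:
            continue
        P = run(pairs, other)
        flat = P.ravel()
        ok = np.isfinite(flat)
        flags = np.zeros(len(flat), bool)
        if ok.sum():
            flags[ok] = bky_fdr(flat[ok], q=q)
        F = flags.reshape(P.shape)
        with np.errstate(invalid="ignore"):
            frac = np.where(np.isfinite(P).any(axis=0),
                            F.sum(axis=0) / np.maximum(np.isfinite(P).sum(axis=0), 1),
                            np.nan)
        out[f"{name}_p"] = P
        out[f"{name}_flags"] = F
        out[f"{name}_frac"] = frac
    return out
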