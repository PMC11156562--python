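"""Fixation/saccade detection and the pair/match structures built on them.

Detection follows the ClusterFix recipe: clip outliers at 3 s.d., low-pass
and downsample the trace to 30 Hz, compute distance, velocity, acceleration
and angular velocity per frame, run k-means (k = 2) on the standardized
parameters, and call the lower-velocity cluster "fixation".  Contiguous
runs of one label become events, re-expanded to the native time base.

Downstream structures:

* return-fixation pairs ("current return": two fixations on the same image
  within a distance threshold, default 1 dva, within or across
  presentations) and "previous return" pairs (fixations whose immediately
  preceding fixations form a current-return pair);
* decorrelation flags that drop pairs whose nonpaired neighboring
  fixations are within 4 dva, removing correlation inherited from
  consecutive fixations;
* matched saccades: template/control pairs starting <= 1 dva apart with
  endpoints >= 4 dva apart, controlling for the presaccadic stimulus.

All geometry is in image coordinates (image position shifts between
presentations are corrected before any distance is computed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import Presentation, Session

__all__ = [
    "PairSet",
    "detect_events",
    "detect_session",
    "select_fixations",
    "attach_images",
    "build_pairs",
    "decorrelate_pairs",
    "match_saccades",
]

FIX_COLUMNS = ["fixation", "presentation", "ordinal", "onset", "offset", "x", "y", "valid"]
SACC_COLUMNS = ["saccade", "presentation", "onset", "offset", "start_fix", "end_fix",
                "dx", "dy", "amplitude"]

PAIR_RULES = ("current_return", "previous_return", "same_image", "distant")
PAIR_SCOPES = ("within", "between", "both")


@dataclass
class PairSet:
    """Fixation pairs under one pairing rule.

    ``pairs`` holds (fixation id A, fixation id B) with A strictly earlier;
    ``decorrelated`` flags pairs that survive the 4-dva nonpaired-fixation
    exclusion (all True until :func:`decorrelate_pairs` runs).
    """

    rule: str
    threshold: float
    pairs: np.ndarray  # (n, 2) int fixation ids
    scope: str = "both"
    decorrelated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, int).reshape(-1, 2)
        if self.decorrelated is None:
            self.decorrelated = np.ones(len(self.pairs), bool)

    def __len__(self) -> int:
        return len(self.pairs)

    def active(self, decorrelate: bool = False) -> np.ndarray:
        return self.pairs[self.decorrelated] if decorrelate else self.pairs


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _frame_params(fx: np.ndarray, fy: np.ndarray, dt_s: float):
    """Distance, velocity, acceleration, angular velocity per 30-Hz frame."""
    dx = np.diff(fx)
    dy = np.diff(fy)
    dist = np.hypot(dx, dy)
    vel = dist / dt_s
    acc = np.abs(np.diff(vel, prepend=vel[0])) / dt_s
    ang = np.arctan2(dy, dx)
    dang = np.abs(np.angle(np.exp(1j * np.diff(ang, prepend=ang[0]))))
    angvel = dang / dt_s
    # per-frame value: motion into the frame (prepend a copy for frame 0)
    def pad(a):
        return np.concatenate([[a[0]], a])
    return pad(dist), pad(vel), pad(acc), pad(angvel)


def detect_events(
    session: Session,
    presentation: Presentation,
    frame_hz: float = 30.0,
    random_state: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment the eye trace of one presentation into fixations and saccades.

    Returns (fixations, saccades) with :data:`FIX_COLUMNS` /
    :data:`SACC_COLUMNS`; positions are image-coordinate centroids.  Less
    than 300 ms of trace yields empty tables with a warning.
    """
    t0, t1 = presentation.onset, presentation.offset
    i0 = int(np.searchsorted(session.eye_t, t0))
    i1 = int(np.searchsorted(session.eye_t, t1))
    if (i1 - i0) / session.eye_rate_hz * 1000.0 < 300.0:
        warnings.warn(f"presentation {presentation.presentation}: trace too short")
        return (pd.DataFrame(columns=FIX_COLUMNS), pd.DataFrame(columns=SACC_COLUMNS))
    x = session.eye_x[i0:i1].astype(float)
    y = session.eye_y[i0:i1].astype(float)
    dec = max(int(round(session.eye_rate_hz / frame_hz)), 1)
    n_frames = len(x) // dec
    # low-pass by averaging within each frame (boxcar at the frame rate)
    fx = x[: n_frames * dec].reshape(n_frames, dec).mean(axis=1)
    fy = y[: n_frames * dec].reshape(n_frames, dec).mean(axis=1)
    dt_s = dec / session.eye_rate_hz
    span_x = fx.max() - fx.min()
    span_y = fy.max() - fy.min()
    if max(span_x, span_y) < 0.1:  # still gaze: one fixation, no saccade
        labels = np.ones(n_frames, bool)
    else:
        params = np.stack(_frame_params(fx, fy, dt_s), axis=1)
        clipped = params.copy()
        for j in range(clipped.shape[1]):
            c = clipped[:, j]
            hi = c.mean() + 3 * c.std()
            clipped[:, j] = np.minimum(c, hi)
        z = (clipped - clipped.mean(axis=0)) / (clipped.std(axis=0) + 1e-12)
        km = KMeans(n_clusters=2, n_init=10, random_state=random_state).fit(z)
        vel = params[:, 1]
        means = [vel[km.labels_ == k].mean() for k in (0, 1)]
        fix_label = int(np.argmin(means))
        labels = km.labels_ == fix_label
        # a single isolated fixation frame inside a saccade is noise
        for i in range(1, n_frames - 1):
            if labels[i] and not labels[i - 1] and not labels[i + 1]:
                labels[i] = False
    # contiguous runs -> events; saccade boundaries refined at the native
    # rate (frame labels are only 33-ms-accurate)
    frame_ms = dec / session.eye_rate_hz * 1000.0
    edges = np.flatnonzero(np.diff(labels.astype(int))) + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [n_frames]])
    n_native = len(x)
    vel_native = np.hypot(np.diff(x, prepend=x[0]), np.diff(y, prepend=y[0]))
    if n_native >= 5:  # 5-ms boxcar smoothing of sample-to-sample speed
        kernel = np.ones(5) / 5.0
        vel_native = np.convolve(vel_native, kernel, mode="same")
    sacc_native = np.zeros(n_native, bool)
    for s, e in zip(starts, ends):
        if labels[s]:
            continue
        j0 = max((s - 1) * dec, 0)
        j1 = min((e + 1) * dec, n_native)
        win = vel_native[j0:j1]
        peak = win.max()
        if peak <= 0:
            continue
        # contiguous run above 25% of peak, expanded from the peak sample
        kp = int(np.argmax(win))
        thr = 0.25 * peak
        k0 = kp
        while k0 > 0 and win[k0 - 1] >= thr:
            k0 -= 1
        k1 = kp + 1
        while k1 < len(win) and win[k1] >= thr:
            k1 += 1
        sacc_native[j0 + k0 : j0 + k1] = True
    if not sacc_native.any() and not labels.all():
        sacc_native[: n_frames * dec] = np.repeat(~labels, dec)
    lab_native = ~sacc_native
    edges_n = np.flatnonzero(np.diff(lab_native.astype(int))) + 1
    starts_n = np.concatenate([[0], edges_n])
    ends_n = np.concatenate([edges_n, [n_native]])
    fix_rows = []
    sacc_rows = []
    events = []  # (is_fix, onset, offset, cx, cy)
    for s, e in zip(starts_n, ends_n):
        on = t0 + s * 1000.0 / session.eye_rate_hz
        off = t0 + e * 1000.0 / session.eye_rate_hz
        cx = float(x[s:e].mean()) - presentation.center_x
        cy = float(y[s:e].mean()) - presentation.center_y
        events.append((bool(lab_native[s]), on, off, cx, cy))
    ordinal = 0 if (events and events[0][0]) else 1
    fix_of_event: dict[int, int] = {}
    for k, (is_fix, on, off, cx, cy) in enumerate(events):
        if is_fix:
            fix_of_event[k] = len(fix_rows)
            fix_rows.append((len(fix_rows), presentation.presentation, ordinal,
                             on, off, cx, cy, True))
            ordinal += 1
    for k, (is_fix, on, off, cx, cy) in enumerate(events):
        if is_fix:
            continue
        prev_fix = fix_of_event.get(k - 1, -1)
        next_fix = fix_of_event.get(k + 1, -1)
        if prev_fix >= 0 and next_fix >= 0:
            dx = fix_rows[next_fix][5] - fix_rows[prev_fix][5]
            dy = fix_rows[next_fix][6] - fix_rows[prev_fix][6]
        else:
            dx = dy = np.nan
        sacc_rows.append((len(sacc_rows), presentation.presentation, on, off,
                          prev_fix, next_fix, dx, dy, float(np.hypot(dx, dy))))
    return (
        pd.DataFrame(fix_rows, columns=FIX_COLUMNS),
        pd.DataFrame(sacc_rows, columns=SACC_COLUMNS),
    )


def detect_session(session: Session, **kwargs) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run :func:`detect_events` over every presentation with global event ids."""
    fixes = []
    saccs = []
    n_fix = n_sacc = 0
    for pres in session.presentations():
        f, s = detect_events(session, pres, **kwargs)
        if len(f):
            s = s.copy()
            s["start_fix"] = np.where(s["start_fix"] >= 0, s["start_fix"] + n_fix, -1)
            s["end_fix"] = np.where(s["end_fix"] >= 0, s["end_fix"] + n_fix, -1)
            f = f.copy()
            f["fixation"] += n_fix
            s["saccade"] += n_sacc
            n_fix += len(f)
            n_sacc += len(s)
            fixes.append(f)
            saccs.append(s)
    if not fixes:
        return (pd.DataFrame(columns=FIX_COLUMNS), pd.DataFrame(columns=SACC_COLUMNS))
    return (pd.concat(fixes, ignore_index=True), pd.concat(saccs, ignore_index=True))


# ---------------------------------------------------------------------------
# Selection and pairing
# ---------------------------------------------------------------------------

def select_fixations(
    fixations: pd.DataFrame, schedule: pd.DataFrame, min_duration_ms: float = 100.0
) -> pd.DataFrame:
    """Flag valid fixations: duration >= 100 ms and centroid inside the image."""
    out = fixations.copy()
    geo = schedule.set_index("presentation")[["width", "height"]]
    w = geo.loc[out["presentation"], "width"].to_numpy()
    h = geo.loc[out["presentation"], "height"].to_numpy()
    dur = out["offset"] - out["onset"]
    inside = (out["x"].abs() <= w / 2) & (out["y"].abs() <= h / 2)
    out["valid"] = (dur >= min_duration_ms) & inside
    return out


def attach_images(fixations: pd.DataFrame, schedule: pd.DataFrame) -> pd.DataFrame:
    """Add the image id of each fixation's presentation."""
    img = schedule.set_index("presentation")["image_id"]
    out = fixations.copy()
    out["image_id"] = img.loc[out["presentation"]].to_numpy()
    return out


def build_pairs(
    fixations: pd.DataFrame,
    rule: str,
    threshold_dva: float = 1.0,
    scope: str = "both",
    distant_dva: float = 8.0,
) -> PairSet:
    """Enumerate fixation pairs under a pairing rule.

    Rules: ``current_return`` (same image, centroid distance <=
    threshold), ``previous_return`` (the immediately preceding fixations,
    same presentation, form a current-return pair), ``same_image`` (any
    same-image pair) and ``distant`` (same image, > ``distant_dva``
    apart).  ``scope`` restricts pairs to within one presentation,
    between presentations, or both.  Fixations must carry ``image_id``
    (see :func:`attach_images`); only valid fixations pair.
    """
    if rule not in PAIR_RULES:
        raise ValueError(f"unknown pairing rule: {rule!r}")
    if scope not in PAIR_SCOPES:
        raise ValueError(f"unknown pair scope: {scope!r}")
    if "image_id" not in fixations.columns:
        raise ValueError("fixations need an image_id column (attach_images)")
    fx = fixations
    valid = fx[fx["valid"]].copy()
    # previous fixation (same presentation, ordinal - 1) for every fixation
    key = fx.set_index(["presentation", "ordinal"])["fixation"]
    pos = fx.set_index("fixation")[["x", "y", "image_id", "presentation", "onset", "ordinal"]]
    pairs = []
    for image_id, grp in valid.groupby("image_id"):
        g = grp.sort_values("onset").reset_index(drop=True)
        n = len(g)
        if n < 2:
            continue
        xy = g[["x", "y"]].to_numpy(float)
        d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
        same_pres = g["presentation"].to_numpy()[:, None] == g["presentation"].to_numpy()[None, :]
        iu, ju = np.triu_indices(n, k=1)
        if scope == "within":
            keep_scope = same_pres[iu, ju]
        elif scope == "between":
            keep_scope = ~same_pres[iu, ju]
        else:
            keep_scope = np.ones(len(iu), bool)
        if rule == "current_return":
            keep = (d[iu, ju] <= threshold_dva) & keep_scope
        elif rule == "distant":
            keep = (d[iu, ju] > distant_dva) & keep_scope
        elif rule == "same_image":
            keep = keep_scope
        else:  # previous_return
            ids = g["fixation"].to_numpy()
            prev_id = np.full(n, -1)
            for a in range(n):
                k = (g.loc[a, "presentation"], g.loc[a, "ordinal"] - 1)
                if k in key.index:
                    prev_id[a] = key.loc[k]
            has_prev = prev_id >= 0
            keep = np.zeros(len(iu), bool)
            ok = has_prev[iu] & has_prev[ju] & keep_scope
            if ok.any():
                pa = pos.loc[prev_id[iu[ok]]]
                pb = pos.loc[prev_id[ju[ok]]]
                dprev = np.hypot(pa["x"].to_numpy() - pb["x"].to_numpy(),
                                 pa["y"].to_numpy() - pb["y"].to_numpy())
                same_img = pa["image_id"].to_numpy() == pb["image_id"].to_numpy()
                keep[np.flatnonzero(ok)] = (dprev <= threshold_dva) & same_img
        ids = g["fixation"].to_numpy()
        pairs.extend(zip(ids[iu[keep]], ids[ju[keep]]))
    arr = np.asarray(pairs, int).reshape(-1, 2)
    # chronological order within a pair (grouping sorted by onset already)
    return PairSet(rule=rule, threshold=threshold_dva, pairs=arr, scope=scope)


def decorrelate_pairs(
    pairset: PairSet, fixations: pd.DataFrame, limit_dva: float = 4.0
) -> PairSet:
    """Flag out pairs whose nonpaired neighboring fixations are nearby.

    For current-return pairs the nonpaired fixations are the ones
    *preceding* each member (same presentation); for previous-return
    pairs, the ones *following*.  A pair is flagged out when both
    nonpaired fixations exist and are within ``limit_dva`` of each other
    (and on the same image); pairs lacking a nonpaired fixation (e.g.,
    zeroth fixations) are kept.
    """
    if pairset.rule not in ("current_return", "previous_return"):
        raise ValueError("decorrelation applies to current_return/previous_return pairs")
    step = -1 if pairset.rule == "current_return" else 1
    key = fixations.set_index(["presentation", "ordinal"])["fixation"]
    pos = fixations.set_index("fixation")
    flags = np.ones(len(pairset), bool)
    for i, (a, b) in enumerate(pairset.pairs):
        na = _neighbor(pos, key, a, step)
        nb = _neighbor(pos, key, b, step)
        if na is None or nb is None:
            continue
        ra, rb = pos.loc[na], pos.loc[nb]
        if ra["image_id"] != rb["image_id"]:
            continue
        if np.hypot(ra["x"] - rb["x"], ra["y"] - rb["y"]) <= limit_dva:
            flags[i] = False
    return replace(pairset, decorrelated=pairset.decorrelated & flags)


def _neighbor(pos: pd.DataFrame, key: pd.Series, fix_id: int, step: int):
    row = pos.loc[fix_id]
    k = (row["presentation"], row["ordinal"] + step)
    return int(key.loc[k]) if k in key.index else None


def saccade_endpoints(saccades: pd.DataFrame, fixations: pd.DataFrame) -> pd.DataFrame:
    """Attach image id and start/end fixation-point coordinates to saccades.

    Adds columns image_id, x1, y1 (start fixation centroid), x2, y2 (end
    fixation centroid) and end_onset (the postsaccadic fixation onset);
    saccades lacking either fixation are dropped.
    """
    fx = fixations.set_index("fixation")
    out = saccades[(saccades["start_fix"] >= 0) & (saccades["end_fix"] >= 0)].copy()
    for col, src_col, fid in [("x1", "x", "start_fix"), ("y1", "y", "start_fix"),
                              ("x2", "x", "end_fix"), ("y2", "y", "end_fix")]:
        out[col] = fx.loc[out[fid], src_col].to_numpy()
    if "image_id" in fx.columns:
        out["image_id"] = fx.loc[out["start_fix"], "image_id"].to_numpy()
    out["end_onset"] = fx.loc[out["end_fix"], "onset"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# Matched saccades
# ---------------------------------------------------------------------------

def match_saccades(
    templates: pd.DataFrame,
    candidates: pd.DataFrame,
    max_start_dva: float = 1.0,
    min_divergence_dva: float = 4.0,
    extra_exclusions: set[tuple[int, int]] | None = None,
    require_same_image: bool = True,
) -> dict:
    """Greedy template-to-candidate saccade matching.

    Both tables need columns saccade, image_id, x1, y1, x2, y2 (start/end
    fixation points, image coords).  Templates are processed in time
    order (column ``onset`` if present); each receives the unused
    candidate with the smallest start distance among those with start
    distance <= 1 dva and end divergence >= 4 dva (ties: earlier
    candidate), skipping the template itself and any (template,
    candidate) in ``extra_exclusions``.  Returns a dict with the match
    table and the unmatched template ids.
    """
    excl = extra_exclusions or set()
    cols = ["saccade", "image_id", "x1", "y1", "x2", "y2"]
    for df, name in [(templates, "templates"), (candidates, "candidates")]:
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{name} missing columns: {missing}")
    rows = []
    unmatched = []
    if len(candidates) == 0:
        return {
            "matches": pd.DataFrame(columns=["template", "match", "start_distance", "end_divergence"]),
            "unmatched": list(templates["saccade"]),
        }
    used: set[int] = set()
    order = templates.sort_values("onset") if "onset" in templates.columns else templates
    cand = candidates.reset_index(drop=True)
    cx1 = cand["x1"].to_numpy(float)
    cy1 = cand["y1"].to_numpy(float)
    cx2 = cand["x2"].to_numpy(float)
    cy2 = cand["y2"].to_numpy(float)
    conset = cand["onset"].to_numpy(float) if "onset" in cand.columns else np.arange(len(cand), dtype=float)
    for _, trow in order.iterrows():
        tid = int(trow["saccade"])
        start_d = np.hypot(cx1 - trow["x1"], cy1 - trow["y1"])
        end_d = np.hypot(cx2 - trow["x2"], cy2 - trow["y2"])
        ok = (start_d <= max_start_dva) & (end_d >= min_divergence_dva)
        if require_same_image:
            ok &= cand["image_id"].to_numpy() == trow["image_id"]
        ok &= cand["saccade"].to_numpy() != tid
        for j in np.flatnonzero(ok):
            cid = int(cand.loc[j, "saccade"])
            if cid in used or (tid, cid) in excl:
                ok[j] = False
        if not ok.any():
            unmatched.append(tid)
            continue
        idx = np.flatnonzero(ok)
        best = idx[np.lexsort((conset[idx], start_d[idx]))][0]
        cid = int(cand.loc[best, "saccade"])
        used.add(cid)
        rows.append((tid, cid, float(start_d[best]), float(end_d[best])))
    return {
        "matches": pd.DataFrame(rows, columns=["template", "match", "start_distance", "end_divergence"]),
        "unmatched": unmatched,
    }
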