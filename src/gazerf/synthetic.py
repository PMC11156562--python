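"""Synthetic free-viewing sessions with ground-truth retinotopic responses.

The generator emulates the statistical structure the analyses assume:
fixation durations ~ 276 +/- 49 ms (lognormal), saccade durations
~ 50 +/- 5 ms and amplitudes ~ 5.4 +/- 0.9 dva (normal, resampled at the
positive support), minimum-jerk saccade trajectories, 1.5-s presentations
of 16 x 16-dva images repeated in pseudorandom blocks with per-presentation
position shifts, and frequent return fixations (with probability
``p_return`` a saccade targets a previously visited location on the same
image, plus Gaussian jitter).

Responses are weighted sums of image-patch features over a ground-truth
Gaussian RF: the RF is discretized into offsets on a 2-dva grid, weighted
by a Gaussian decay profile truncated at 2 sigma (normalized to sum 1), and
the weighted feature sum at each 1-kHz eye sample -- delayed by the
response lag -- is the deterministic rate.  Optional Poisson spiking and
within-presentation exponential adaptation.  The simulation extractor is
deliberately different from the analysis extractor used in RF-mapping
tests, so encoding models cannot fit trivially.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import ROI_COLUMNS, SCHEDULE_COLUMNS, UNIT_COLUMNS, Session
from .rfmap import RF_GRID, FeatureGrid, extract_patch_features, get_extractor

__all__ = [
    "GazeParams",
    "GroundTruthRF",
    "SyntheticSession",
    "make_image_set",
    "simulate_gaze",
    "simulate_responses",
    "make_benchmark_session",
    "BENCHMARK_PRESETS",
]


@dataclass(frozen=True)
class GazeParams:
    """Parameters of the gaze simulation (durations ms, geometry dva)."""

    fix_dur_mean: float = 276.0
    fix_dur_sd: float = 49.0
    sacc_dur_mean: float = 50.0
    sacc_dur_sd: float = 5.0
    sacc_amp_mean: float = 5.4
    sacc_amp_sd: float = 0.9
    p_return: float = 0.3
    return_jitter_sd: float = 0.3
    presentation_ms: float = 1500.0
    image_size_dva: float = 16.0
    shift_range_dva: float = 2.0
    iti_ms: float = 250.0
    edge_margin_dva: float = 1.0
    tracker_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in [
            "fix_dur_mean", "fix_dur_sd", "sacc_dur_mean", "sacc_dur_sd",
            "sacc_amp_mean", "sacc_amp_sd", "presentation_ms",
            "image_size_dva", "iti_ms",
        ]:
            if getattr(self, name) <= 0:
                raise ValueError(f"GazeParams.{name} must be positive")
        if not 0.0 <= self.p_return <= 1.0:
            raise ValueError("p_return must be in [0, 1]")


@dataclass(frozen=True)
class GroundTruthRF:
    """Ground-truth RF of one simulated unit.

    center_x/center_y: retinotopic offset of the RF center from the
    fixation point (dva); sigma: Gaussian s.d. (dva); lag_ms: response
    delay; channel: which feature dimension of the simulation extractor
    the unit reads out; noise: 'none' (deterministic rate trace) or
    'poisson' (spikes); adaptation_tau: optional within-presentation
    exponential decay constant (ms); face_selective units multiply their
    stimulus drive by ``face_boost`` whenever a face ROI intersects the
    1-sigma RF disc.
    """

    center_x: float = 0.0
    center_y: float = 0.0
    sigma: float = 1.0
    lag_ms: float = 0.0
    gain: float = 1.0
    baseline: float = 0.0
    channel: int = 0
    noise: str = "none"
    adaptation_tau: float | None = None
    rectify: bool = False
    normalize: str | None = None  # None or 'minmax' (session-wise drive scaling)
    face_selective: bool = False
    face_boost: float = 3.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("RF sigma must be > 0")
        if self.lag_ms < 0:
            raise ValueError("RF lag must be >= 0")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise model: {self.noise!r}")


@dataclass
class SyntheticSession:
    """A Session plus its ground-truth tables."""

    session: Session
    true_fixations: pd.DataFrame
    true_saccades: pd.DataFrame
    true_rfs: pd.DataFrame
    params: GazeParams
    preset: str = ""
    grids: dict[str, FeatureGrid] | None = None


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def make_image_set(
    n_images: int,
    size_dva: float = 16.0,
    face_fraction: float = 0.0,
    seed: int = 0,
    pixels_per_dva: float = 8.0,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Procedural textured images with optional synthetic 'face' ROIs.

    Textures are mixtures of band-passed noise whose mixing weights vary
    smoothly across the image, so local patch statistics differ across
    locations.  The first ``round(face_fraction * n_images)`` images carry
    one or two ring-and-dots face patterns with stored bounding boxes
    (image dva, x0 < x1 and y0 < y1, y upward).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if not 0.0 <= face_fraction <= 1.0:
        raise ValueError("face_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    px = int(round(size_dva * pixels_per_dva))
    n_faces = int(round(face_fraction * n_images))
    images: dict[str, np.ndarray] = {}
    roi_rows = []
    for i in range(n_images):
        image_id = f"img{i:03d}"
        layers = []
        weights = []
        for sig in (1.0, 3.0, 8.0):
            n = gaussian_filter(rng.standard_normal((px, px)), sig)
            n = (n - n.mean()) / (n.std() + 1e-12)
            layers.append(n)
            w = gaussian_filter(rng.standard_normal((px, px)), px / 6.0)
            weights.append(np.abs(w))
        W = np.stack(weights)
        W /= W.sum(axis=0, keepdims=True) + 1e-12
        img = sum(w * l for w, l in zip(W, layers))
        lo, hi = np.percentile(img, [1, 99])
        img = np.clip((img - lo) / (hi - lo + 1e-12), 0, 1) * 0.9 + 0.05
        if i < n_faces:
            for _ in range(int(rng.integers(1, 3))):
                r = float(rng.uniform(1.2, 2.2))
                cx = float(rng.uniform(-size_dva / 2 + r + 1, size_dva / 2 - r - 1))
                cy = float(rng.uniform(-size_dva / 2 + r + 1, size_dva / 2 - r - 1))
                _draw_face(img, cx, cy, r, size_dva, pixels_per_dva)
                roi_rows.append((image_id, cx - 1.2 * r, cy - 1.2 * r,
                                 cx + 1.2 * r, cy + 1.2 * r))
        images[image_id] = img.astype(np.float64)
    rois = pd.DataFrame(roi_rows, columns=ROI_COLUMNS)
    return images, rois


def _draw_face(img: np.ndarray, cx: float, cy: float, r: float,
               size_dva: float, ppd: float) -> None:
    """Ring-and-dots face pattern, contrast comparable to the texture."""
    px = img.shape[0]
    xs = (np.arange(px) + 0.5) / ppd - size_dva / 2
    ys = size_dva / 2 - (np.arange(px) + 0.5) / ppd
    X, Y = np.meshgrid(xs, ys)
    d = np.hypot(X - cx, Y - cy)
    ring = np.abs(d - r) < 0.12 * r
    img[ring] = 0.75
    for ex, ey, er, val in [
        (cx - 0.35 * r, cy + 0.3 * r, 0.13 * r, 0.2),
        (cx + 0.35 * r, cy + 0.3 * r, 0.13 * r, 0.2),
        (cx, cy - 0.35 * r, 0.16 * r, 0.3),
    ]:
        img[np.hypot(X - ex, Y - ey) < er] = val


# ---------------------------------------------------------------------------
# Gaze
# ---------------------------------------------------------------------------

def _min_jerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def simulate_gaze(
    image_order: list[str],
    params: GazeParams,
    rng: np.random.Generator | None = None,
) -> dict:
    """Simulate the eye trace and schedule for a sequence of presentations.

    Returns a dict with eye_t/eye_x/eye_y (screen dva, 1 kHz), the
    schedule DataFrame, and ground-truth fixation/saccade tables (image
    coordinates).  With probability ``p_return`` a saccade targets a
    previously visited location on the same image (any repeat, the target
    whose distance best matches the drawn amplitude), plus Gaussian
    jitter; otherwise a fresh location at the drawn amplitude.
    """
    rng = rng or np.random.default_rng(params.seed)
    half = params.image_size_dva / 2 - params.edge_margin_dva
    if half <= 2 * params.sacc_amp_sd:
        import warnings

        warnings.warn("image too small relative to saccade amplitude spread")
    # lognormal parameters matched to the requested mean and s.d.
    cv2 = (params.fix_dur_sd / params.fix_dur_mean) ** 2
    ln_sigma = math.sqrt(math.log1p(cv2))
    ln_mu = math.log(params.fix_dur_mean) - ln_sigma**2 / 2

    def draw_fix_dur() -> float:
        return float(rng.lognormal(ln_mu, ln_sigma))

    def draw_pos(lo: float = 0.0) -> tuple[float, float]:
        return (float(rng.uniform(-half, half)), float(rng.uniform(-half, half)))

    def draw_sacc() -> tuple[float, float]:
        dur = amp = -1.0
        while dur <= 1.0:
            dur = float(rng.normal(params.sacc_dur_mean, params.sacc_dur_sd))
        while amp <= 0.1:
            amp = float(rng.normal(params.sacc_amp_mean, params.sacc_amp_sd))
        return dur, amp

    visited: dict[str, list[tuple[float, float]]] = {}
    repeat_count: dict[str, int] = {}
    sched_rows = []
    fix_rows = []
    sacc_rows = []
    segments: list[tuple[float, float, np.ndarray, np.ndarray]] = []  # t0, t1, x(t), y(t)

    t = 0.0
    prev_screen = (0.0, 0.0)
    fix_id = 0
    sacc_id = 0
    for p, image_id in enumerate(image_order):
        shift = params.shift_range_dva
        center = (float(rng.uniform(-shift, shift)), float(rng.uniform(-shift, shift)))
        onset = t + params.iti_ms
        offset = onset + params.presentation_ms
        rep = repeat_count.get(image_id, 0)
        repeat_count[image_id] = rep + 1
        sched_rows.append((p, image_id, onset, offset, center[0], center[1],
                           params.image_size_dva, params.image_size_dva, rep))
        vis = visited.setdefault(image_id, [])
        # zeroth fixation target: always a fresh location
        cur = draw_pos()
        # inter-trial interval: min-jerk travel to the zeroth target
        iti_n = int(round(params.iti_ms))
        tau = _min_jerk(np.linspace(0, 1, iti_n, endpoint=False))
        tgt_screen = (cur[0] + center[0], cur[1] + center[1])
        segments.append((t, onset,
                         prev_screen[0] + (tgt_screen[0] - prev_screen[0]) * tau,
                         prev_screen[1] + (tgt_screen[1] - prev_screen[1]) * tau))
        t_cursor = onset
        ordinal = 0
        while t_cursor < offset - 1:
            dur = draw_fix_dur()
            fix_end = t_cursor + dur
            truncated = fix_end >= offset
            fix_end = min(fix_end, offset)
            n = int(round(fix_end - t_cursor))
            if n > 0:
                segments.append((t_cursor, fix_end,
                                 np.full(n, cur[0] + center[0]),
                                 np.full(n, cur[1] + center[1])))
            fix_rows.append((fix_id, p, ordinal, t_cursor, fix_end,
                             cur[0], cur[1], dur, truncated))
            vis.append(cur)
            t_cursor = fix_end
            fix_id += 1
            ordinal += 1
            if truncated or t_cursor >= offset - 1:
                break
            sdur, amp = draw_sacc()
            is_return = False
            nxt = None
            if rng.random() < params.p_return and len(vis) > 1:
                cands = np.asarray(vis[:-1], float)
                dists = np.hypot(cands[:, 0] - cur[0], cands[:, 1] - cur[1])
                k = int(np.argmin(np.abs(dists - amp)))
                if dists[k] > 0.1:
                    base = cands[k]
                    jit = rng.normal(0.0, params.return_jitter_sd, 2) \
                        if params.return_jitter_sd > 0 else np.zeros(2)
                    nxt = (float(np.clip(base[0] + jit[0], -half, half)),
                           float(np.clip(base[1] + jit[1], -half, half)))
                    is_return = True
            if nxt is None:
                for _ in range(40):
                    th = rng.uniform(0, 2 * math.pi)
                    cand = (cur[0] + amp * math.cos(th), cur[1] + amp * math.sin(th))
                    if abs(cand[0]) <= half and abs(cand[1]) <= half:
                        nxt = cand
                        break
                else:
                    nxt = draw_pos()
            sacc_end = min(t_cursor + sdur, offset)
            n = int(round(sacc_end - t_cursor))
            if n > 0:
                tau = _min_jerk(np.arange(n) / sdur)
                segments.append((t_cursor, sacc_end,
                                 cur[0] + center[0] + (nxt[0] - cur[0]) * tau,
                                 cur[1] + center[1] + (nxt[1] - cur[1]) * tau))
            actual_amp = math.hypot(nxt[0] - cur[0], nxt[1] - cur[1])
            sacc_rows.append((sacc_id, p, t_cursor, sacc_end, cur[0], cur[1],
                              nxt[0], nxt[1], actual_amp, is_return))
            sacc_id += 1
            t_cursor = sacc_end
            cur = nxt
        prev_screen = (cur[0] + center[0], cur[1] + center[1])
        t = offset

    total = int(round(t))
    eye_x = np.empty(total)
    eye_y = np.empty(total)
    eye_x[:] = np.nan
    eye_y[:] = np.nan
    for t0, t1, xs, ys in segments:
        i0 = int(round(t0))
        eye_x[i0 : i0 + len(xs)] = xs
        eye_y[i0 : i0 + len(ys)] = ys
    # fill any 1-sample rounding gaps by forward fill
    for arr in (eye_x, eye_y):
        mask = np.isnan(arr)
        if mask.any():
            idx = np.where(~mask, np.arange(total), 0)
            np.maximum.accumulate(idx, out=idx)
            arr[mask] = arr[idx[mask]]
    if params.tracker_noise_sd > 0:
        eye_x += rng.normal(0, params.tracker_noise_sd, total)
        eye_y += rng.normal(0, params.tracker_noise_sd, total)
    return {
        "eye_t": np.arange(total, dtype=float),
        "eye_x": eye_x,
        "eye_y": eye_y,
        "schedule": pd.DataFrame(sched_rows, columns=SCHEDULE_COLUMNS),
        "fixations": pd.DataFrame(
            fix_rows,
            columns=["fixation", "presentation", "ordinal", "onset", "offset",
                     "x", "y", "drawn_duration", "truncated"],
        ),
        "saccades": pd.DataFrame(
            sacc_rows,
            columns=["saccade", "presentation", "onset", "offset",
                     "x1", "y1", "x2", "y2", "amplitude", "is_return"],
        ),
    }


# ---------------------------------------------------------------------------
# Responses
# ---------------------------------------------------------------------------

def rf_offsets_and_weights(rf: GroundTruthRF, step: float = 2.0):
    """Discretize the RF into grid offsets with Gaussian weights truncated at 2 sigma."""
    reach = 2.0 * rf.sigma
    k = int(math.floor(reach / step + 1e-9))
    ax = np.arange(-k, k + 1) * step
    OX, OY = np.meshgrid(ax, ax)
    d = np.hypot(OX, OY)
    keep = d <= reach + 1e-9
    w = np.exp(-(d[keep] ** 2) / (2 * rf.sigma**2))
    w /= w.sum()
    return OX[keep], OY[keep], w


def simulate_responses(
    session: Session,
    rfs: dict[str, GroundTruthRF],
    grids: dict[str, FeatureGrid],
    rng: np.random.Generator | None = None,
) -> Session:
    """Fill a session's rate traces / spikes from ground-truth RFs.

    For each 1-kHz eye sample during a presentation the stimulus drive is
    the weighted sum over RF offsets (2-dva grid, Gaussian weights
    truncated at 2 sigma, normalized to sum 1) of the cached patch feature
    at eye + RF center + offset, for the unit's feature channel.  The
    output rate is ``baseline + gain * drive`` delayed by the lag;
    'poisson' units emit spikes from the rectified rate.
    """
    rng = rng or np.random.default_rng(0)
    n = len(session.eye_t)
    for unit, rf in rfs.items():
        if rf.channel >= next(iter(grids.values())).dim:
            raise ValueError(f"unit {unit}: feature channel {rf.channel} out of range")
        ox, oy, w = rf_offsets_and_weights(rf)
        drive = np.zeros(n)
        presented = np.zeros(n, bool)
        inface_all = np.zeros(n, bool)
        for _, pres in session.schedule.iterrows():
            i0, i1 = int(pres["onset"]), int(pres["offset"])
            presented[i0:i1] = True
            g = grids[pres["image_id"]]
            ex = session.eye_x[i0:i1] - pres["center_x"] + rf.center_x
            ey = session.eye_y[i0:i1] - pres["center_y"] + rf.center_y
            q = np.zeros(i1 - i0)
            for k in range(len(w)):
                # bilinear sampling keeps the drive continuous in eye position
                q += w[k] * g.channel_bilinear(ex + ox[k], ey + oy[k], rf.channel)
            if rf.face_selective:
                rois = session.rois[session.rois["image_id"] == pres["image_id"]]
                if len(rois):
                    inface = np.zeros(i1 - i0, bool)
                    for _, roi in rois.iterrows():
                        ddx = np.clip(roi["x0"] - ex, 0, None) + np.clip(ex - roi["x1"], 0, None)
                        ddy = np.clip(roi["y0"] - ey, 0, None) + np.clip(ey - roi["y1"], 0, None)
                        inface |= np.hypot(ddx, ddy) <= rf.sigma
                    inface_all[i0:i1] = inface
            drive[i0:i1] = q
        if rf.normalize == "minmax":
            lo = drive[presented].min()
            hi = drive[presented].max()
            drive = np.where(presented, (drive - lo) / (hi - lo + 1e-12), 0.0)
        if rf.rectify:
            drive = np.maximum(drive, 0.0)
        if rf.face_selective:
            drive = np.where(inface_all, drive * rf.face_boost, drive)
        if rf.adaptation_tau:
            for _, pres in session.schedule.iterrows():
                i0, i1 = int(pres["onset"]), int(pres["offset"])
                drive[i0:i1] *= np.exp(-np.arange(i1 - i0, dtype=float) / rf.adaptation_tau)
        lag = int(round(rf.lag_ms))
        if lag > 0:
            drive = np.concatenate([np.zeros(lag), drive[:-lag]])
        rate = rf.baseline + rf.gain * drive
        if rf.noise == "poisson":
            lam = np.maximum(rate, 0.0) / 1000.0
            counts = rng.poisson(lam)
            times = np.repeat(session.eye_t, counts) + 0.5
            session.spikes[unit] = np.sort(times)
        else:
            session.rates[unit] = rate
    return session


# ---------------------------------------------------------------------------
# Benchmark sessions
# ---------------------------------------------------------------------------

BENCHMARK_PRESETS = {
    "noiseless-retinotopic": "deterministic rate traces, lag 0, no faces",
    "poisson": "Poisson spiking, lag 100 ms, no faces",
    "face-selective": "half the units boosted by face-ROI overlap, lag 50 ms",
    "lagged-L": "noiseless with response lag L ms, e.g. 'lagged-100'",
}

_RF_CENTERS = [(0.0, 0.0), (2.0, 0.0), (0.0, 2.0), (-2.0, 0.0),
               (0.0, -2.0), (2.0, 2.0), (-2.0, -2.0), (1.0, -1.0)]
_RF_SIGMAS = [1.0, 2.0]


def make_benchmark_session(
    preset: str = "noiseless-retinotopic",
    seed: int = 0,
    n_images: int = 30,
    n_presentations: int = 150,
    n_units: int = 8,
    extractor: str = "random-projection",
    params: GazeParams | None = None,
    keep_grids: bool = True,
) -> SyntheticSession:
    """Compose images, gaze and responses into one loadable session.

    Presets (see :data:`BENCHMARK_PRESETS`): 'noiseless-retinotopic',
    'poisson', 'face-selective', and 'lagged-L' with L a lag in ms.
    Units are spread over 2 arrays x 2 banks with one electrode each and
    read out distinct feature channels of the simulation extractor at
    distinct RF centers/sizes.
    """
    lag = None
    m = re.fullmatch(r"lagged-(\d+)", preset)
    if m:
        lag = float(m.group(1))
    elif preset not in BENCHMARK_PRESETS:
        raise ValueError(f"unknown preset: {preset!r} (have {sorted(BENCHMARK_PRESETS)})")
    rng = np.random.default_rng(seed)
    face_fraction = 0.5 if preset == "face-selective" else 0.0
    params = params or GazeParams(seed=seed)
    images, rois = make_image_set(
        n_images, params.image_size_dva, face_fraction, seed=seed + 1
    )
    image_ids = sorted(images)
    order: list[str] = []
    while len(order) < n_presentations:
        block = list(image_ids)
        rng.shuffle(block)
        order.extend(block)
    order = order[:n_presentations]
    gaze = simulate_gaze(order, params, rng)

    unit_rows = []
    rfs: dict[str, GroundTruthRF] = {}
    for i in range(n_units):
        unit = f"u{i:02d}"
        arr = f"a{i * 2 // max(n_units, 1) + 1}"
        bank = f"{arr}b{(i * 4 // max(n_units, 1)) % 2 + 1}"
        unit_rows.append((unit, f"e{i:02d}", bank, arr, "CIT", "M1"))
        cx, cy = _RF_CENTERS[i % len(_RF_CENTERS)]
        sigma = _RF_SIGMAS[i % len(_RF_SIGMAS)]
        kw = dict(center_x=cx, center_y=cy, sigma=sigma, channel=i)
        if lag is not None:
            rfs[unit] = GroundTruthRF(lag_ms=lag, **kw)
        elif preset == "noiseless-retinotopic":
            rfs[unit] = GroundTruthRF(lag_ms=0.0, **kw)
        elif preset == "poisson":
            rfs[unit] = GroundTruthRF(
                lag_ms=100.0, noise="poisson", normalize="minmax",
                baseline=5.0, gain=40.0, **kw,
            )
        elif preset == "face-selective":
            rfs[unit] = GroundTruthRF(
                lag_ms=50.0, normalize="minmax", baseline=1.0, gain=10.0,
                face_selective=(i < n_units // 2), face_boost=3.0, **kw,
            )
    units = pd.DataFrame(unit_rows, columns=UNIT_COLUMNS)
    session = Session(
        eye_t=gaze["eye_t"],
        eye_x=gaze["eye_x"],
        eye_y=gaze["eye_y"],
        spikes={},
        schedule=gaze["schedule"],
        images=images,
        units=units,
        subject="M1",
        rates={},
        rois=rois,
    )
    grids = extract_patch_features(
        images, RF_GRID, get_extractor(extractor), session.pixels_per_dva
    )
    simulate_responses(session, rfs, grids, rng)
    rf_table = pd.DataFrame(
        [
            dict(unit=u, center_x=r.center_x, center_y=r.center_y, sigma=r.sigma,
                 lag_ms=r.lag_ms, gain=r.gain, baseline=r.baseline,
                 channel=r.channel, noise=r.noise,
                 face_selective=r.face_selective, face_boost=r.face_boost)
            for u, r in rfs.items()
        ]
    )
    return SyntheticSession(
        session=session,
        true_fixations=gaze["fixations"],
        true_saccades=gaze["saccades"],
        true_rfs=rf_table,
        params=params,
        preset=preset,
        grids=grids if keep_grids else None,
    )


def save_synthetic_session(synth: SyntheticSession, path) -> None:
    """Write the session plus ground-truth tables (delimited text)."""
    from pathlib import Path

    from .core import save_session

    path = Path(path)
    save_session(synth.session, path)
    synth.true_fixations.to_csv(path / "true_fixations.tsv", sep="\t", index=False)
    synth.true_saccades.to_csv(path / "true_saccades.tsv", sep="\t", index=False)
    synth.true_rfs.to_csv(path / "true_rfs.tsv", sep="\t", index=False)
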