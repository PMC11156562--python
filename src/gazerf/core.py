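"""Core domain types, session container, coordinate conventions and I/O.

A *session* bundles everything one free-viewing recording provides: a
1-kHz eye-position trace in screen degrees of visual angle (dva), per-unit
spike times (and, for simulated data, deterministic rate traces), the
image-presentation schedule, the image pixel data, optional face ROIs and
per-unit metadata.

Coordinate conventions
----------------------
Screen coordinates are dva with x rightward and y upward, origin at the
screen center.  Because image position is shifted between presentations,
all analyses of gaze geometry use *image coordinates*: dva relative to the
image center of the presentation during which a point was recorded.  A
screen point maps to image coordinates by subtracting the presentation's
image center; the inverse transform adds it back.

Time base: milliseconds from session start (floats).  The eye trace is
regularly sampled at ``Session.eye_rate_hz`` (default 1000 Hz).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd
import yaml
from PIL import Image

__all__ = [
    "Presentation",
    "UnitMeta",
    "Session",
    "SessionValidationError",
    "SessionLoadError",
    "to_image_coords",
    "to_screen_coords",
    "filter_units",
    "save_session",
    "load_session",
    "validate_session",
]

# Schedule / unit table columns used throughout the package.
SCHEDULE_COLUMNS = [
    "presentation",
    "image_id",
    "onset",
    "offset",
    "center_x",
    "center_y",
    "width",
    "height",
    "repeat_index",
]
UNIT_COLUMNS = ["unit", "electrode", "bank", "array", "area", "monkey"]
ROI_COLUMNS = ["image_id", "x0", "y0", "x1", "y1"]


class SessionValidationError(ValueError):
    """A session violates one of its structural invariants."""


class SessionLoadError(IOError):
    """A session directory is missing a required component."""


@dataclass(frozen=True)
class Presentation:
    """One image presentation: identity, timing, and on-screen geometry."""

    presentation: int
    image_id: str
    onset: float
    offset: float
    center_x: float
    center_y: float
    width: float
    height: float
    repeat_index: int = 0

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise SessionValidationError(
                f"presentation {self.presentation}: offset {self.offset} <= onset {self.onset}"
            )
        if not (self.width > 0 and self.height > 0):
            raise SessionValidationError(
                f"presentation {self.presentation}: nonpositive image size"
            )


@dataclass(frozen=True)
class UnitMeta:
    """Recording-hierarchy metadata for one unit (unit -> electrode -> bank -> array)."""

    unit: str
    electrode: str
    bank: str
    array: str
    area: str = "CIT"
    monkey: str = "M1"


@dataclass
class Session:
    """A complete free-viewing session.

    Attributes
    ----------
    eye_t, eye_x, eye_y
        Regularly sampled eye trace; times in ms, positions in screen dva.
    spikes
        Mapping unit id -> sorted spike times (ms).
    rates
        Optional mapping unit id -> deterministic rate trace (spikes/s)
        sampled on ``eye_t``.  Present for noiseless simulated sessions.
    schedule
        DataFrame with :data:`SCHEDULE_COLUMNS`.
    images
        Mapping image id -> 2-D float array in [0, 1] (grayscale).
    units
        DataFrame with :data:`UNIT_COLUMNS`.
    rois
        Face-ROI rectangles per image, in image dva (x0 < x1, y0 < y1).
    """

    eye_t: np.ndarray
    eye_x: np.ndarray
    eye_y: np.ndarray
    spikes: dict[str, np.ndarray]
    schedule: pd.DataFrame
    images: dict[str, np.ndarray]
    units: pd.DataFrame
    subject: str = "M1"
    eye_rate_hz: float = 1000.0
    pixels_per_dva: float = 8.0
    rates: dict[str, np.ndarray] = field(default_factory=dict)
    rois: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=ROI_COLUMNS)
    )

    # -- convenience accessors -------------------------------------------------
    def presentation(self, idx: int) -> Presentation:
        row = self.schedule.loc[self.schedule["presentation"] == idx].iloc[0]
        return Presentation(**{k: row[k] for k in SCHEDULE_COLUMNS})

    def presentations(self):
        for _, row in self.schedule.iterrows():
            yield Presentation(**{k: row[k] for k in SCHEDULE_COLUMNS})

    @property
    def unit_ids(self) -> list[str]:
        return list(self.units["unit"])

    @property
    def duration_ms(self) -> float:
        return float(self.eye_t[-1]) if len(self.eye_t) else 0.0

    def copy(self) -> "Session":
        return Session(
            eye_t=self.eye_t.copy(),
            eye_x=self.eye_x.copy(),
            eye_y=self.eye_y.copy(),
            spikes={u: s.copy() for u, s in self.spikes.items()},
            schedule=self.schedule.copy(),
            images={k: v.copy() for k, v in self.images.items()},
            units=self.units.copy(),
            subject=self.subject,
            eye_rate_hz=self.eye_rate_hz,
            pixels_per_dva=self.pixels_per_dva,
            rates={u: r.copy() for u, r in self.rates.items()},
            rois=self.rois.copy(),
        )


def validate_session(session: Session) -> list[str]:
    """Check all session invariants; raise on violation, return a report.

    The report lists the checks performed (one line per check).
    """
    report: list[str] = []
    t = np.asarray(session.eye_t, float)
    if len(t) and not np.all(np.diff(t) > 0):
        raise SessionValidationError("eye-trace timestamps are not strictly increasing")
    report.append(f"eye trace: {len(t)} samples, strictly increasing timestamps")

    for unit, st in session.spikes.items():
        st = np.asarray(st, float)
        if len(st) and (np.any(np.diff(st) < 0) or st[0] < 0):
            raise SessionValidationError(f"unit {unit}: spike times unsorted or negative")
    report.append(f"spikes: {len(session.spikes)} units, sorted nonnegative times")

    missing = set(session.schedule["image_id"]) - set(session.images)
    if missing:
        raise SessionValidationError(
            f"schedule references unknown image ids: {sorted(missing)}"
        )
    for pres in session.presentations():
        pass  # Presentation.__post_init__ enforces offset > onset and size > 0
    report.append(f"schedule: {len(session.schedule)} presentations, all image ids resolved")

    u = session.units
    # hierarchy consistency: an electrode belongs to one bank, a bank to one array
    if len(u):
        for child, parent in [("electrode", "bank"), ("bank", "array")]:
            n_parents = u.groupby(child)[parent].nunique()
            bad = n_parents[n_parents > 1]
            if len(bad):
                raise SessionValidationError(
                    f"{child} {list(bad.index)} mapped to multiple {parent}s"
                )
    report.append(f"units: {len(u)} rows, hierarchy consistent")
    return report


# ---------------------------------------------------------------------------
# Coordinate transforms
# ---------------------------------------------------------------------------

def to_image_coords(x, y, presentation: Presentation):
    """Map screen-dva point(s) to image coordinates (dva relative to image center)."""
    return np.asarray(x) - presentation.center_x, np.asarray(y) - presentation.center_y


def to_screen_coords(x, y, presentation: Presentation):
    """Inverse of :func:`to_image_coords`."""
    return np.asarray(x) + presentation.center_x, np.asarray(y) + presentation.center_y


# ---------------------------------------------------------------------------
# Unit-quality filtering
# ---------------------------------------------------------------------------

def filter_units(
    session: Session, check_halves: bool = True, eps: float = 1e-9
) -> tuple[Session, pd.DataFrame]:
    """Remove putative-artifact units by comparing session halves.

    A unit is removed if it fires no spikes in the second half of the
    session, or if its mean firing rate differs by more than 50% between
    the two halves: ``|r2 - r1| / max(r1, eps) > 0.5``.  The split point
    is the midpoint of total session duration (wall clock).  Units with a
    deterministic rate trace instead of spikes are kept (the criterion
    targets recording artifacts).

    Returns the filtered session copy and a removal report with one row
    per unit (kept flag, rates per half, reason).
    """
    if len(session.schedule) < 2:
        raise SessionValidationError("filter_units requires a session spanning >= 2 presentations")
    half = session.duration_ms / 2.0
    rows = []
    keep: list[str] = []
    for unit in session.unit_ids:
        if unit in session.rates and unit not in session.spikes:
            rows.append((unit, True, np.nan, np.nan, "rate-trace"))
            keep.append(unit)
            continue
        st = np.asarray(session.spikes.get(unit, np.empty(0)), float)
        n1 = int(np.searchsorted(st, half))
        n2 = len(st) - n1
        r1 = n1 / (half / 1000.0)
        r2 = n2 / (max(session.duration_ms - half, eps) / 1000.0)
        if n2 == 0:
            rows.append((unit, False, r1, r2, "no spikes in second half"))
            continue
        if abs(r2 - r1) / max(r1, eps) > 0.5:
            rows.append((unit, False, r1, r2, "half-rate change > 50%"))
            continue
        rows.append((unit, True, r1, r2, ""))
        keep.append(unit)
    report = pd.DataFrame(rows, columns=["unit", "kept", "rate_half1", "rate_half2", "reason"])
    out = session.copy()
    out.units = out.units[out.units["unit"].isin(keep)].reset_index(drop=True)
    out.spikes = {u: s for u, s in out.spikes.items() if u in keep}
    out.rates = {u: r for u, r in out.rates.items() if u in keep}
    return out, report


# ---------------------------------------------------------------------------
# Session I/O: manifest.yaml + delimited event tables + HDF5 traces + PNGs
# ---------------------------------------------------------------------------

def save_session(session: Session, path) -> None:
    """Write a session to ``path`` in the package layout.

    Layout: ``manifest.yaml``, ``presentations.tsv``, ``units.tsv``,
    ``rois.tsv``, ``traces.h5`` (eye trace, spikes, optional rates) and
    ``images/<id>.png`` (8-bit grayscale).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subject": session.subject,
        "eye_rate_hz": float(session.eye_rate_hz),
        "pixels_per_dva": float(session.pixels_per_dva),
        "images": sorted(session.images),
    }
    (path / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    session.schedule.to_csv(path / "presentations.tsv", sep="\t", index=False)
    session.units.to_csv(path / "units.tsv", sep="\t", index=False)
    session.rois.to_csv(path / "rois.tsv", sep="\t", index=False)
    with h5py.File(path / "traces.h5", "w") as f:
        eye = f.create_group("eye")
        eye.create_dataset("t", data=np.asarray(session.eye_t, np.float64))
        eye.create_dataset("x", data=np.asarray(session.eye_x, np.float64))
        eye.create_dataset("y", data=np.asarray(session.eye_y, np.float64))
        sp = f.create_group("spikes")
        for unit, st in session.spikes.items():
            sp.create_dataset(unit, data=np.asarray(st, np.float64))
        if session.rates:
            ra = f.create_group("rates")
            for unit, r in session.rates.items():
                ra.create_dataset(unit, data=np.asarray(r, np.float64))
    img_dir = path / "images"
    img_dir.mkdir(exist_ok=True)
    for image_id, arr in session.images.items():
        a8 = np.clip(np.asarray(arr, float) * 255.0, 0, 255).round().astype(np.uint8)
        Image.fromarray(a8, mode="L").save(img_dir / f"{image_id}.png")


def load_session(path) -> Session:
    """Load and validate a session saved by :func:`save_session`."""
    path = Path(path)
    for name in ["manifest.yaml", "presentations.tsv", "units.tsv", "traces.h5"]:
        if not (path / name).exists():
            raise SessionLoadError(f"session at {path} is missing component: {name}")
    manifest = yaml.safe_load((path / "manifest.yaml").read_text())
    schedule = pd.read_csv(path / "presentations.tsv", sep="\t")
    units = pd.read_csv(path / "units.tsv", sep="\t", dtype=str)
    if (path / "rois.tsv").exists():
        rois = pd.read_csv(path / "rois.tsv", sep="\t")
        if rois.empty:
            rois = pd.DataFrame(columns=ROI_COLUMNS)
    else:
        rois = pd.DataFrame(columns=ROI_COLUMNS)
    spikes: dict[str, np.ndarray] = {}
    rates: dict[str, np.ndarray] = {}
    with h5py.File(path / "traces.h5", "r") as f:
        eye_t = f["eye/t"][...]
        eye_x = f["eye/x"][...]
        eye_y = f["eye/y"][...]
        for unit in f["spikes"]:
            spikes[unit] = f[f"spikes/{unit}"][...]
        if "rates" in f:
            for unit in f["rates"]:
                rates[unit] = f[f"rates/{unit}"][...]
    images: dict[str, np.ndarray] = {}
    for image_id in manifest.get("images", []):
        p = path / "images" / f"{image_id}.png"
        if not p.exists():
            raise SessionLoadError(f"session at {path} is missing component: images/{image_id}.png")
        images[image_id] = np.asarray(Image.open(p), dtype=np.float64) / 255.0
    session = Session(
        eye_t=eye_t,
        eye_x=eye_x,
        eye_y=eye_y,
        spikes=spikes,
        schedule=schedule,
        images=images,
        units=units,
        subject=manifest.get("subject", "M1"),
        eye_rate_hz=float(manifest.get("eye_rate_hz", 1000.0)),
        pixels_per_dva=float(manifest.get("pixels_per_dva", 8.0)),
        rates=rates,
        rois=rois,
    )
    validate_session(session)
    return session
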