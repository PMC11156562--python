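"""Per-event responses and return-fixation self-consistency.

Self-consistency is the Pearson correlation of a unit's single-trial
(per-fixation) responses across return-fixation pairs: if a neuron
responds selectively to retinotopic features, revisits of the same image
location should evoke similar responses.  It is computed in fixed windows,
in 50-ms sliding bins (25-ms steps) around fixation onset, as a function
of the return-distance threshold, and across presentation time in 200-ms
bins (50-ms steps).

Responses are rates: spike counts in the window divided by window length,
or the mean of a deterministic rate trace for noiseless simulated units.
Windows extending beyond the recording yield NaN entries, never errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Session
from .events import PairSet, attach_images, build_pairs

__all__ = [
    "BinSpec",
    "ResponseSource",
    "event_responses",
    "SelfConsistencyResult",
    "SCTimecourse",
    "nan_corr_cols",
    "self_consistency",
    "pair_self_consistency",
    "sc_timecourse",
    "distance_profile",
    "presentation_timecourse",
    "visual_selectivity_screen",
]


@dataclass(frozen=True)
class BinSpec:
    """Sliding bins relative to an event anchor (ms)."""

    start: float = -200.0
    end: float = 300.0
    width: float = 50.0
    step: float = 25.0

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.start, self.end - self.width + self.step / 2, self.step)

    @property
    def centers(self) -> np.ndarray:
        return self.starts + self.width / 2

    @property
    def n_bins(self) -> int:
        return len(self.starts)


SACCADE_BINS = BinSpec(start=-375.0, end=375.0, width=50.0, step=25.0)


class ResponseSource:
    """Windowed event-aligned rates from a session's spikes or rate traces."""

    def __init__(self, session: Session):
        self.session = session
        self._cumrate: dict[str, np.ndarray] = {}

    def _rate_cumsum(self, unit: str) -> np.ndarray:
        if unit not in self._cumrate:
            r = np.asarray(self.session.rates[unit], float)
            self._cumrate[unit] = np.concatenate([[0.0], np.cumsum(r)])
        return self._cumrate[unit]

    def window_rates(
        self, unit: str, anchors: np.ndarray, start: float, end: float
    ) -> np.ndarray:
        """Rate (spikes/s) of ``unit`` in [anchor+start, anchor+end) per anchor.

        NaN where the window extends beyond the recorded span.
        """
        anchors = np.asarray(anchors, float)
        t0 = float(self.session.eye_t[0])
        t_end = float(self.session.eye_t[-1]) + 1000.0 / self.session.eye_rate_hz
        a = anchors + start
        b = anchors + end
        out = np.full(len(anchors), np.nan)
        ok = (a >= t0) & (b <= t_end)
        if unit in self.session.rates:
            cs = self._rate_cumsum(unit)
            scale = self.session.eye_rate_hz / 1000.0
            i = np.clip(np.round((a - t0) * scale).astype(int), 0, len(cs) - 1)
            j = np.clip(np.round((b - t0) * scale).astype(int), 0, len(cs) - 1)
            with np.errstate(invalid="ignore"):
                vals = (cs[j] - cs[i]) / np.maximum(j - i, 1)
            out[ok] = vals[ok]
        else:
            st = np.asarray(self.session.spikes.get(unit, np.empty(0)), float)
            counts = np.searchsorted(st, b) - np.searchsorted(st, a)
            out[ok] = counts[ok] / ((end - start) / 1000.0)
        return out

    def binned(self, unit: str, anchors: np.ndarray, bins: BinSpec) -> np.ndarray:
        """(n_anchors, n_bins) rates for sliding bins around each anchor."""
        cols = [
            self.window_rates(unit, anchors, s, s + bins.width) for s in bins.starts
        ]
        return np.stack(cols, axis=1)


def event_responses(
    session: Session,
    anchors: np.ndarray,
    window: tuple[float, float],
    units: list[str] | None = None,
) -> np.ndarray:
    """(n_units, n_events) firing rates in a fixed event-aligned window."""
    src = ResponseSource(session)
    units = units if units is not None else session.unit_ids
    return np.stack(
        [src.window_rates(u, anchors, window[0], window[1]) for u in units]
    )


# ---------------------------------------------------------------------------
# Self-consistency
# ---------------------------------------------------------------------------

@dataclass
class SelfConsistencyResult:
    r: float
    n_pairs: int
    rule: str = ""
    threshold: float = float("nan")
    valid: bool = True


@dataclass
class SCTimecourse:
    centers: np.ndarray
    r: np.ndarray
    n: np.ndarray
    rule: str = ""
    decorrelated: bool = False


def self_consistency(resp_a: np.ndarray, resp_b: np.ndarray,
                     rule: str = "", threshold: float = float("nan")) -> SelfConsistencyResult:
    """Pearson r between the earlier and later responses across pairs.

    Invalid (r = NaN) with fewer than 2 finite pairs or when either margin
    has zero variance.
    """
    a = np.asarray(resp_a, float)
    b = np.asarray(resp_b, float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = len(a)
    if n < 2 or a.std() == 0 or b.std() == 0:
        return SelfConsistencyResult(float("nan"), n, rule, threshold, valid=False)
    r = float(np.corrcoef(a, b)[0, 1])
    return SelfConsistencyResult(r, n, rule, threshold, valid=True)


def nan_corr_cols(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Pearson r between A and B (n, m), NaN-aware.

    Returns (r, n) per column; r is NaN for columns with < 2 finite pairs
    or zero variance in either margin.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    ok = np.isfinite(A) & np.isfinite(B)
    n = ok.sum(axis=0)
    Az = np.where(ok, A, 0.0)
    Bz = np.where(ok, B, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = Az.sum(axis=0) / n
        mb = Bz.sum(axis=0) / n
        Ac = np.where(ok, A - ma, 0.0)
        Bc = np.where(ok, B - mb, 0.0)
        va = (Ac**2).sum(axis=0)
        vb = (Bc**2).sum(axis=0)
        r = (Ac * Bc).sum(axis=0) / np.sqrt(va * vb)
    bad = (n < 2) | (va <= 0) | (vb <= 0)
    r = np.where(bad, np.nan, r)
    return r, n


def _gather(responses: np.ndarray, fix_index: pd.Index, ids: np.ndarray) -> np.ndarray:
    loc = fix_index.get_indexer(ids)
    out = np.full(len(ids), np.nan)
    ok = loc >= 0
    out[ok] = responses[loc[ok]]
    return out


def pair_self_consistency(
    pairset: PairSet,
    responses: np.ndarray,
    fixations: pd.DataFrame,
    decorrelate: bool = False,
) -> SelfConsistencyResult:
    """Self-consistency of a response vector (aligned to ``fixations`` rows)."""
    idx = pd.Index(fixations["fixation"])
    pairs = pairset.active(decorrelate)
    a = _gather(responses, idx, pairs[:, 0])
    b = _gather(responses, idx, pairs[:, 1])
    return self_consistency(a, b, pairset.rule, pairset.threshold)


def sc_timecourse(
    pairset: PairSet,
    binned: np.ndarray,
    fixations: pd.DataFrame,
    bins: BinSpec,
    decorrelate: bool = False,
) -> SCTimecourse:
    """Self-consistency per sliding time bin.

    ``binned`` is (n_fixations, n_bins) event-aligned rates for the rows
    of ``fixations`` (see :meth:`ResponseSource.binned`).
    """
    idx = pd.Index(fixations["fixation"])
    pairs = pairset.active(decorrelate)
    la = idx.get_indexer(pairs[:, 0])
    lb = idx.get_indexer(pairs[:, 1])
    ok = (la >= 0) & (lb >= 0)
    A = binned[la[ok]]
    B = binned[lb[ok]]
    r, n = nan_corr_cols(A, B)
    return SCTimecourse(bins.centers, r, n, pairset.rule, decorrelate)


def distance_profile(
    fixations: pd.DataFrame,
    responses: np.ndarray,
    thresholds: np.ndarray | None = None,
    scope: str = "both",
) -> pd.DataFrame:
    """Self-consistency of current-return pairs per distance threshold."""
    if thresholds is None:
        thresholds = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0])
    thresholds = np.asarray(thresholds, float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for th in thresholds:
        ps = build_pairs(fixations, "current_return", threshold_dva=th, scope=scope)
        res = pair_self_consistency(ps, responses, fixations)
        rows.append((th, res.r, res.n_pairs, res.valid))
    return pd.DataFrame(rows, columns=["threshold", "r", "n_pairs", "valid"])


def presentation_timecourse(
    fixations: pd.DataFrame,
    source: ResponseSource,
    unit: str,
    schedule: pd.DataFrame,
    presentation_ms: float | None = None,
    bin_width: float = 200.0,
    bin_step: float = 50.0,
    return_threshold: float = 1.0,
    distant_threshold: float = 8.0,
) -> pd.DataFrame:
    """Self-consistency across repeats as a function of presentation time.

    For each presentation-time bin and each rule (return <= 1 dva, same
    image, distant > 8 dva), two repeats of an image are paired in that
    bin when any two of their fixations overlapping the bin satisfy the
    rule; the correlated values are the unit's rates in the absolute bin.
    Returns a tidy frame (bin center, rule, r, n_pairs, valid).
    """
    sched = schedule.copy()
    if presentation_ms is None:
        presentation_ms = float((sched["offset"] - sched["onset"]).median())
    sched = sched[(sched["offset"] - sched["onset"]).round() == round(presentation_ms)]
    bin_starts = np.arange(0.0, presentation_ms - bin_width + bin_step / 2, bin_step)
    onsets = sched.set_index("presentation")["onset"]
    # unit responses per presentation per bin
    resp = np.stack(
        [
            source.window_rates(unit, onsets.to_numpy() + s, 0.0, bin_width)
            for s in bin_starts
        ],
        axis=1,
    )  # (n_pres, n_bins)
    pres_pos = {p: i for i, p in enumerate(onsets.index)}
    fx = fixations[fixations["valid"] & fixations["presentation"].isin(pres_pos)]
    rel_on = fx["onset"].to_numpy() - onsets.loc[fx["presentation"]].to_numpy()
    rel_off = fx["offset"].to_numpy() - onsets.loc[fx["presentation"]].to_numpy()
    rows = []
    rules = [("return", return_threshold), ("same_image", None), ("distant", distant_threshold)]
    for b, s in enumerate(bin_starts):
        e = s + bin_width
        in_bin = (rel_on < e) & (rel_off > s)
        fb = fx[in_bin]
        for rule, th in rules:
            xs, ys = [], []
            for image_id, grp in fb.groupby("image_id"):
                pres_list = sorted(grp["presentation"].unique())
                for i in range(len(pres_list)):
                    for j in range(i + 1, len(pres_list)):
                        gi = grp[grp["presentation"] == pres_list[i]]
                        gj = grp[grp["presentation"] == pres_list[j]]
                        d = np.hypot(
                            gi["x"].to_numpy()[:, None] - gj["x"].to_numpy()[None, :],
                            gi["y"].to_numpy()[:, None] - gj["y"].to_numpy()[None, :],
                        )
                        if rule == "return":
                            hit = bool((d <= th).any())
                        elif rule == "distant":
                            hit = bool((d > th).any())
                        else:
                            hit = True
                        if hit:
                            xs.append(resp[pres_pos[pres_list[i]], b])
                            ys.append(resp[pres_pos[pres_list[j]], b])
            res = self_consistency(xs, ys)
            rows.append((s + bin_width / 2, rule, res.r, res.n_pairs, res.valid))
    return pd.DataFrame(rows, columns=["center", "rule", "r", "n_pairs", "valid"])


def visual_selectivity_screen(
    r: float, p: float, r_min: float = 0.1, p_max: float = 0.01
) -> bool:
    """Feature-selective unit screen: self-consistency r >= 0.1 and permutation p < 0.01."""
    return bool(np.isfinite(r) and r >= r_min and p < p_max)
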