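"""Test helpers: a benchmark session processed through the standard front end."""

from __future__ import annotations

import gazerf as gz
from gazerf.events import saccade_endpoints
from gazerf.rfmap import RF_GRID, extract_patch_features, get_extractor


class ProcessedSession:
    """A benchmark session with detected events and cached analysis features."""

    def __init__(self, preset: str, seed: int, n_images: int = 30,
                 n_presentations: int = 150, n_units: int = 8,
                 with_grids: bool = True):
        self.synth = gz.make_benchmark_session(
            preset, seed=seed, n_images=n_images,
            n_presentations=n_presentations, n_units=n_units,
        )
        self.session = self.synth.session
        fix, sacc = gz.detect_session(self.session)
        fix = gz.select_fixations(fix, self.session.schedule)
        self.fixations = gz.attach_images(fix, self.session.schedule)
        self.saccades = sacc
        self.endpoints = saccade_endpoints(sacc, self.fixations)
        self.source = gz.ResponseSource(self.session)
        # analysis-side features: deliberately a different extractor than
        # the one that generated the responses
        self.grids = (
            extract_patch_features(
                self.session.images, RF_GRID, get_extractor("gabor-bank"),
                self.session.pixels_per_dva,
            )
            if with_grids
            else None
        )

    @property
    def valid_fixations(self):
        return self.fixations[self.fixations["valid"]].reset_index(drop=True)
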