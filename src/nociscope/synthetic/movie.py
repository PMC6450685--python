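"""Render a synthetic session into a one-photon movie (TIFF stack).

Each neuron becomes an isotropic 2-D Gaussian footprint placed at its
centroid with a minimum-spacing guarantee; the pixel series is the
footprint-weighted sum of the fluorescence traces plus sensor noise.  At
zero noise the movie is exactly the linear mixture of footprints and
traces, which the extraction stage is tested against.
"""

from __future__ import annotations

import numpy as np

from .._rng import substream
from ..types import SessionRecording
from .generate import _place_centroids

__all__ = ["render_movie", "gaussian_footprint"]


def gaussian_footprint(height: int, width: int, center: np.ndarray,
                       radius: float) -> np.ndarray:
    """Unit-peak isotropic Gaussian with sigma = radius/2, truncated at 3 sigma."""
    yy, xx = np.mgrid[0:height, 0:width]
    sigma = radius / 2.0
    d2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2
    fp = np.exp(-0.5 * d2 / sigma ** 2)
    fp[d2 > (3.0 * sigma) ** 2] = 0.0
    return fp


def render_movie(session: SessionRecording, width: int, height: int,
                 cell_radius: float, seed: int, noise_sd: float = 1.0,
                 spacing: float | None = None):
    """Render ``session`` as (movie[frames, H, W], footprints[n, H, W],
    centroids[n, 2]).

    Centroids are re-placed inside the requested frame with minimum spacing
    (default 3x the cell radius) so footprints do not overlap; the session's
    own centroids refer to the generator's field of view, which need not
    match the requested movie size.
    """
    rng = substream(seed, "movie")
    n = session.n_neurons
    spacing = 3.0 * cell_radius if spacing is None else spacing
    centroids = _place_centroids(rng, n, (width, height), spacing, None)

    footprints = np.stack([gaussian_footprint(height, width, c, cell_radius)
                           for c in centroids])
    flat = footprints.reshape(n, -1)
    movie = session.traces.T @ flat          # frames x pixels
    if noise_sd > 0:
        movie = movie + rng.standard_normal(movie.shape) * noise_sd
    movie = movie.reshape(session.n_frames, height, width)
    return movie, footprints, centroids
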