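"""Trailing (causal) rolling-window statistics on per-frame series."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import _fill_undefined

ROLLING_STATS = ("mean", "sum", "std")
ROLLING_SPANS_S = (0.1, 1.0, 2.0)


def span_to_frames(span_s: float, fps: float) -> int:
    """Window length in frames for a span in seconds: ``max(1, round(span*fps))``."""
    if span_s <= 0:
        raise ValueError(f"span_s must be > 0, got {span_s}")
    return max(1, round(span_s * fps))


def rolling_stat(values: np.ndarray, stat: str, span_s: float, fps: float) -> np.ndarray:
    """Trailing rolling mean / sum / population-std over ``span_s`` seconds.

    The window of ``w = max(1, round(span_s * fps))`` frames ends at the
    current frame; windows at the start of the series shrink to the frames
    available, so the std of a single-frame window is 0.
    """
    if stat not in ROLLING_STATS:
        raise ValueError(f"stat must be one of {ROLLING_STATS}, got {stat!r}")
    w = span_to_frames(span_s, fps)
    s = pd.Series(np.asarray(values, dtype=float))
    r = s.rolling(window=w, min_periods=1)
    if stat == "mean":
        out = r.mean()
    elif stat == "sum":
        out = r.sum()
    else:
        out = r.std(ddof=0)
    return out.to_numpy()


def pup_centroid_longwindow(
    pup_coords: np.ndarray,
    span_s: float,
    fps: float,
    fallback: tuple[float, float],
) -> np.ndarray:
    """Likelihood-weighted pup centroid over a long trailing window.

    ``pup_coords`` is the pup block ``(n, max_pups, 9, 3)``; the centroid at
    frame *t* pools every pup slot point of the trailing ``span_s`` seconds,
    weighted by likelihood.  Frames whose window contains no point with
    positive likelihood inherit the nearest preceding defined value, else
    the first defined value, else ``fallback`` (conventionally the cage
    centre).  Long windows (30 or 60 min) bridge stretches where the litter
    is fully occluded by bedding or the dam.
    """
    c = np.asarray(pup_coords, dtype=float)
    n = c.shape[0]
    flat = c.reshape(n, -1, 3)
    w = flat[..., 2]
    sw = w.sum(axis=1)
    swx = (w * flat[..., 0]).sum(axis=1)
    swy = (w * flat[..., 1]).sum(axis=1)
    win = span_to_frames(span_s, fps)

    def _trailing_sum(a: np.ndarray) -> np.ndarray:
        cs = np.concatenate([[0.0], np.cumsum(a)])
        lo = np.maximum(np.arange(n) + 1 - win, 0)
        return cs[1:] - cs[lo]

    tw = _trailing_sum(sw)
    defined = tw > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        x = _trailing_sum(swx) / tw
        y = _trailing_sum(swy) / tw
    xy = np.column_stack([x, y])
    return _fill_undefined(xy, defined, fallback)
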