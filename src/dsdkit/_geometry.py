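"""Small geometric helpers shared by the synthetic generator and the
disconnectome filter."""

from __future__ import annotations

import numpy as np


def densify_polyline(points: np.ndarray, max_spacing: float) -> np.ndarray:
    """Resample a polyline so consecutive points are <= ``max_spacing`` apart.

    Linear interpolation along arclength; original vertices are preserved as
    a subset up to floating error at segment boundaries.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return pts.copy()
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    out = [pts[0]]
    for i, d in enumerate(seg):
        if d <= max_spacing:
            out.append(pts[i + 1])
            continue
        n = int(np.ceil(d / max_spacing))
        t = np.linspace(0.0, 1.0, n + 1)[1:]
        out.extend(pts[i] + t[:, None] * (pts[i + 1] - pts[i]))
    return np.asarray(out)


def polyline_length(points: np.ndarray) -> float:
    pts = np.asarray(points, dtype=float)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
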