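"""Singular spectrum analysis of motor-neuron activity.

A univariate series of length p is stacked into a q x (p - q + 1) Hankel
matrix by a sliding window of q samples; its SVD, H = U S V^T, yields a
hierarchy of eigen-time-series.  Each column of U is a *singular spectrum*
(the shape of the component within the window) and the matching column of V
is the *magnitude series* (how strongly that shape is expressed as the
window slides).  Oscillatory components appear as sinusoid-shaped spectra
in quadrature pairs; a component whose spectrum is flat within the window
carries the slow, non-oscillatory content -- the part of motor-neuron
activity through which persistent sensory signals travel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import hankel

#: window length in seconds used for motor-neuron decomposition
DEFAULT_WINDOW_S = 4.0

#: spectra with coefficient of variation below this count as "constant"
FLATNESS_THRESHOLD = 0.2


def hankel_embed(series, q: int) -> np.ndarray:
    """Hankel (trajectory) matrix: column j holds series[j : j + q]."""
    series = np.asarray(series, dtype=float).ravel()
    p = series.size
    if not 1 < q < p:
        raise ValueError(f"window q={q} must satisfy 1 < q < p={p}")
    return hankel(series[:q], series[q - 1 :])


@dataclass
class SSAResult:
    """SVD of the Hankel embedding with per-component flatness scores.

    ``spectra`` (U) has one q-sample eigen-time-series per column, ordered
    by decreasing singular value; ``magnitudes`` (V) has the matching
    length p - q + 1 magnitude series per column.  ``flatness`` is the
    coefficient of variation of each spectrum: ~0 for a constant spectrum,
    large for oscillatory ones.
    """

    q: int
    spectra: np.ndarray  # U, (q, k)
    singular_values: np.ndarray  # descending, length k
    magnitudes: np.ndarray  # V, (p - q + 1, k)
    flatness: np.ndarray
    dt: float = 1.0
    t0: float = 0.0

    @property
    def n_components(self) -> int:
        return self.singular_values.size

    def reconstruct_hankel(self) -> np.ndarray:
        return (self.spectra * self.singular_values) @ self.magnitudes.T

    def is_constant(self, j: int, threshold: float = FLATNESS_THRESHOLD) -> bool:
        return bool(self.flatness[j] < threshold)

    def constant_components(self, threshold: float = FLATNESS_THRESHOLD) -> np.ndarray:
        return np.nonzero(self.flatness < threshold)[0]

    def to_dir(self, path, channel: str = "") -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.spectra).to_csv(path / "spectra_U.csv", index=False)
        pd.DataFrame({"singular_value": self.singular_values}).to_csv(
            path / "singular_values.csv", index=False
        )
        pd.DataFrame(self.magnitudes).to_csv(path / "magnitudes_V.csv", index=False)
        with open(path / "ssa.json", "w") as fh:
            json.dump(
                {"q": int(self.q), "dt": self.dt, "t0": self.t0,
                 "channel": channel,
                 "flatness": [float(f) for f in self.flatness]},
                fh, indent=2,
            )
            fh.write("\n")


def ssa(series, q: int, dt: float = 1.0, t0: float = 0.0) -> SSAResult:
    """Decompose a series into eigen-time-series via Hankel SVD.

    The number of components is min(q, p - q + 1) and the squared singular
    values partition the Frobenius energy of the Hankel matrix exactly.
    """
    H = hankel_embed(series, q)
    U, s, Vt = np.linalg.svd(H, full_matrices=False)
    flat = np.empty(s.size)
    for j in range(s.size):
        col = U[:, j]
        mu = np.abs(col.mean())
        sd = col.std()
        flat[j] = sd / mu if mu > 0 else np.inf
    return SSAResult(
        q=int(q), spectra=U, singular_values=s, magnitudes=Vt.T,
        flatness=flat, dt=float(dt), t0=float(t0),
    )


def align_magnitudes(result: SSAResult) -> tuple[np.ndarray, np.ndarray]:
    """Time-stamp each magnitude sample at the center of its window.

    Column j of V summarizes samples j .. j + q - 1 of the source series,
    so it is stamped at t0 + (j + (q - 1)/2) dt.  Returns (times, V); the
    stamps let V be paired frame-by-frame with AFD activity y1(t) or
    steering curvature Psi(t).
    """
    n = result.magnitudes.shape[0]
    times = result.t0 + (np.arange(n) + (result.q - 1) / 2.0) * result.dt
    return times, result.magnitudes
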