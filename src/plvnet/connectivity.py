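"""Instantaneous phase extraction and phase-locking-value connectivity.

The PLV of a channel pair is the modulus of the time-averaged unit phasor
of their instantaneous phase difference, computed per epoch over its
samples and then averaged across epochs (``pooling="epoch"``, the default).
``pooling="pooled"`` instead averages the phasors over all epochs' samples
jointly before taking the modulus; it is the direct estimator of the
population mean resultant and is free of the per-epoch small-sample bias
(epoch-mean-of-moduli >= modulus-of-pooled-mean by the triangle inequality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .preprocess import EpochedRecording

__all__ = [
    "PhaseArray",
    "PLVMatrix",
    "instantaneous_phase",
    "plv_pair",
    "plv_matrix",
    "group_mean_plv",
]


@dataclass(frozen=True)
class PhaseArray:
    """Instantaneous phases in radians, wrapped to (-pi, pi]."""

    phases: np.ndarray  # (epochs, channels, samples)
    channel_labels: tuple[str, ...]
    band: str = ""
    condition: str = ""
    participant: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.phases, dtype=float)
        object.__setattr__(self, "phases", p)
        if p.ndim != 3:
            raise ValueError("phases must be (epochs, channels, samples)")
        if not np.isfinite(p).all():
            raise ValueError("phases contain non-finite values")


@dataclass(frozen=True)
class PLVMatrix:
    """Symmetric channel x channel PLV matrix, diagonal fixed to 1."""

    values: np.ndarray
    channel_labels: tuple[str, ...]
    band: str = ""
    condition: str = ""
    participant: str = ""
    n_epochs: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("PLV matrix must be square")
        if v.shape[0] != len(self.channel_labels):
            raise ValueError("label count does not match matrix size")

    def pair_values(self) -> np.ndarray:
        """Unique off-diagonal values (upper triangle, row-major)."""
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]

    def to_csv(self, path) -> None:
        """Write the full matrix with labeled rows and columns."""
        pd.DataFrame(
            self.values, index=self.channel_labels, columns=self.channel_labels
        ).to_csv(path)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: chan_a, chan_b, band, condition, plv."""
        iu = np.triu_indices(self.values.shape[0], k=1)
        labels = self.channel_labels
        return pd.DataFrame(
            {
                "chan_a": [labels[i] for i in iu[0]],
                "chan_b": [labels[j] for j in iu[1]],
                "band": self.band,
                "condition": self.condition,
                "participant": self.participant,
                "plv": self.values[iu],
            }
        )


def instantaneous_phase(ep: EpochedRecording) -> PhaseArray:
    """Phase of the analytic signal of each epoch-channel trace."""
    if np.any(ep.data.std(axis=2) == 0):
        raise ValueError("zero-variance trace: instantaneous phase undefined")
    analytic = hilbert(ep.data, axis=2)
    return PhaseArray(
        phases=np.angle(analytic),
        channel_labels=ep.channel_labels,
        band=ep.band,
        condition=ep.condition,
        participant=ep.participant,
    )


def plv_pair(phix: np.ndarray, phiy: np.ndarray, pooling: str = "epoch") -> float:
    """PLV of two phase traces shaped (epochs, samples) or (samples,)."""
    phix = np.atleast_2d(np.asarray(phix, dtype=float))
    phiy = np.atleast_2d(np.asarray(phiy, dtype=float))
    if phix.shape != phiy.shape:
        raise ValueError(f"shape mismatch: {phix.shape} vs {phiy.shape}")
    if phix.shape[0] < 1 or phix.shape[1] < 1:
        raise ValueError("need at least one epoch and one sample")
    z = np.exp(1j * (phix - phiy))
    if pooling == "epoch":
        return float(np.abs(z.mean(axis=1)).mean())
    if pooling == "pooled":
        return float(np.abs(z.mean()))
    raise ValueError(f"unknown pooling {pooling!r}")


def plv_matrix(ph: PhaseArray, pooling: str = "epoch") -> PLVMatrix:
    """All-pairs PLV matrix from an (epochs, channels, samples) phase array."""
    e, c, s = ph.phases.shape
    if c < 2:
        raise ValueError("need at least 2 channels")
    z = np.exp(1j * ph.phases)
    if pooling == "epoch":
        acc = np.zeros((c, c))
        for k in range(e):
            g = z[k] @ z[k].conj().T  # (c, c) sums of pair phasors
            acc += np.abs(g) / s
        values = acc / e
    elif pooling == "pooled":
        g = np.einsum("ecs,eds->cd", z, z.conj())
        values = np.abs(g) / (e * s)
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return PLVMatrix(
        values=values,
        channel_labels=ph.channel_labels,
        band=ph.band,
        condition=ph.condition,
        participant=ph.participant,
        n_epochs=e,
    )


def group_mean_plv(matrices: list[PLVMatrix]) -> tuple[PLVMatrix, np.ndarray]:
    """Entrywise mean and SD of PLV matrices across participants."""
    if not matrices:
        raise ValueError("empty list of PLV matrices")
    first = matrices[0]
    for m in matrices[1:]:
        if m.channel_labels != first.channel_labels:
            raise ValueError("channel labels differ across matrices")
        if m.band != first.band or m.condition != first.condition:
            raise ValueError("band/condition differ across matrices")
    stack = np.stack([m.values for m in matrices])
    mean = PLVMatrix(
        values=stack.mean(axis=0),
        channel_labels=first.channel_labels,
        band=first.band,
        condition=first.condition,
        participant="GROUP",
        n_epochs=0,
    )
    return mean, stack.std(axis=0, ddof=0)
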