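"""Sampling-quality diagnostics for omega trajectories.

Frames are mapped to binary isomer states (1 = trans, 0 = cis) with a
configurable labeling halfwidth: 90 deg assigns every frame (the octant
convention used for integration), 45 deg leaves intermediate frames
unassigned (the convention used to filter trajectories by state).  On top
of the binary series the module provides the running mean of isomer
states (values near 0.5 indicate balanced cis/trans sampling), cis/trans
transition rates, and Pearson correlations between the residues' states
(near-zero values show that the residues isomerize independently rather
than in lockstep).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import RESIDUES, wrap_angle

UNASSIGNED = -1


@dataclass
class BinaryStateSeries:
    """Per-frame isomer state of one residue: 1 trans, 0 cis, -1 unassigned."""

    values: np.ndarray
    residue: int
    halfwidth: float = 90.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 1:
            raise ValueError("binary state series must be one-dimensional")

    @property
    def assigned(self) -> np.ndarray:
        return self.values != UNASSIGNED

    def __len__(self) -> int:
        return len(self.values)


def label_states(series, halfwidth: float = 90.0):
    """Label every frame of an omega series per residue and as a whole.

    Returns ``(binaries, labels)`` where ``binaries`` is one
    :class:`BinaryStateSeries` per residue and ``labels`` is a per-frame
    array of three-letter state strings (``None`` where any residue is
    unassigned).  Halfwidth 90 labels every frame; the boundary at exactly
    +-90 deg goes to trans.
    """
    frames = np.asarray(getattr(series, "frames", series), dtype=float)
    if frames.ndim != 2 or frames.shape[1] != 3:
        raise ValueError("expected an (N, 3) array of angle triples")
    if not 0 < halfwidth <= 90:
        raise ValueError("halfwidth must lie in (0, 90] degrees")
    d_trans = np.abs(wrap_angle(frames - 180.0))
    d_cis = np.abs(wrap_angle(frames))
    state = np.full(frames.shape, UNASSIGNED, dtype=np.int8)
    state[d_trans <= halfwidth] = 1
    state[d_cis < halfwidth] = 0
    binaries = [BinaryStateSeries(state[:, a], residue=r, halfwidth=halfwidth)
                for a, r in enumerate(RESIDUES)]
    labels = np.empty(len(frames), dtype=object)
    all_assigned = (state != UNASSIGNED).all(axis=1)
    letters = np.where(state == 1, "T", "C")
    for i in np.flatnonzero(all_assigned):
        labels[i] = "".join(letters[i])
    labels[~all_assigned] = None
    return binaries, labels


def running_mean_states(binary: BinaryStateSeries, window: int = 100) -> np.ndarray:
    """Centered running mean of the 0/1 state over ``window`` frames.

    Windows at the series edges are truncated to the available frames;
    unassigned frames are excluded from the local mean.  Values near 0.5
    indicate balanced cis/trans sampling around that time point.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    vals = pd.Series(np.where(binary.assigned, binary.values, np.nan))
    return vals.rolling(window, center=True, min_periods=1).mean().to_numpy()


def transition_rate(binary: BinaryStateSeries, frames_per_time: float = 1.0) -> float:
    """Cis/trans transitions per unit time.

    Counts label changes between consecutive frames that are both
    assigned (no transition is scored across an unassigned gap) and
    divides by the time spanned by the series.
    """
    if frames_per_time <= 0:
        raise ValueError("frames_per_time must be positive")
    if len(binary) < 2:
        return 0.0
    v = binary.values
    both = (v[:-1] != UNASSIGNED) & (v[1:] != UNASSIGNED)
    n_trans = int(np.count_nonzero((v[:-1] != v[1:]) & both))
    spanned = (len(v) - 1) / frames_per_time
    return n_trans / spanned


def state_correlation(binaries) -> np.ndarray:
    """Pearson correlation matrix of the residues' 0/1 states.

    Computed over frames where all residues are assigned; the diagonal is
    exactly one.  Low off-diagonal magnitudes indicate that the residues'
    isomerization events are not linearly coupled in time.
    """
    mats = [np.asarray(b.values) for b in binaries]
    if len({len(m) for m in mats}) != 1:
        raise ValueError("all binary series must have the same length")
    stacked = np.stack(mats)
    common = (stacked != UNASSIGNED).all(axis=0)
    if common.sum() < 2:
        raise ValueError("need at least two commonly assigned frames")
    sub = stacked[:, common].astype(float)
    if np.any(sub.std(axis=1) == 0):
        raise ValueError("a constant state series has undefined correlation")
    corr = np.corrcoef(sub)
    np.fill_diagonal(corr, 1.0)
    return corr


def diagnostics_report(series, halfwidth: float = 90.0, window: int = 100,
                       frames_per_time: float = 1.0) -> dict:
    """Bundle running means, transition rates and the correlation matrix."""
    binaries, labels = label_states(series, halfwidth)
    return {
        "running_mean": {f"Pro{b.residue}": running_mean_states(b, window) for b in binaries},
        "transition_rate": {f"Pro{b.residue}": transition_rate(b, frames_per_time)
                            for b in binaries},
        "pearson_r": state_correlation(binaries),
        "labels": labels,
    }
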