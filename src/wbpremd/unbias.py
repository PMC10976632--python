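"""Unbiasing and free-energy analysis of replica-1 omega samples.

The replica-1 trajectory samples the physical Hamiltonian augmented by the
one-fold trans-penalizing bias.  The biased probability density P~ over
the three-torus (binned, 50 bins per axis by default) is converted to the
physical density by pointwise reweighting

    P(w) = P~(w) * exp(+beta * U_bias(w)) / Z

where the additive free-energy constants of the biased and unbiased
ensembles are absorbed into the normalization Z.  State probabilities are
Simpson integrals of P over the eight +-90 deg octants; Boltzmann
inversion G = -kT ln P gives state free energies, one-dimensional
potentials of mean force, and marginal/conditional cis->trans
isomerization free energies.

Sign convention: dG_cis->trans = -kT ln(P_trans / P_cis) = G_trans - G_cis,
so a negative value means the trans isomer is favored.

Statistical errors are standard errors of the mean over statistics
computed on five equally sized contiguous subsets of the frames.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.integrate import simpson

from .model import (KB, DEFAULT_TEMPERATURE, RESIDUES, STATE_ORDER, StateLabel)

#: Axis index of each proline residue in the (omega2, omega3, omega7) triple.
AXIS_OF_RESIDUE = {2: 0, 3: 1, 7: 2}

#: Sentinel used in place of +inf free energies when writing tables.
INF_SENTINEL = 999.0


@dataclass
class Density3D:
    """Binned probability density over the three-torus (per deg^3).

    Bin edges sit at -180 + k * (360 / n_bins) on every axis; the default
    50 bins per axis give a 7.2 deg bin width.
    """

    values: np.ndarray
    biased: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or len(set(self.values.shape)) != 1:
            raise ValueError("density values must form an (n, n, n) cube")
        if np.any(self.values < 0):
            raise ValueError("density values must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def bin_width(self) -> float:
        return 360.0 / self.n_bins

    @property
    def bin_centers(self) -> np.ndarray:
        return -180.0 + (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def integral(self) -> float:
        return float(self.values.sum() * self.bin_width ** 3)

    def normalize(self) -> "Density3D":
        total = self.integral
        if total <= 0:
            raise ValueError("cannot normalize a density with zero total weight")
        return Density3D(self.values / total, biased=self.biased)


@dataclass
class Marginal:
    """One- or two-dimensional projected density (per deg^k)."""

    values: np.ndarray
    residues: tuple[int, ...]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != len(self.residues):
            raise ValueError("one residue per density axis is required")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def bin_width(self) -> float:
        return 360.0 / self.n_bins

    @property
    def bin_centers(self) -> np.ndarray:
        return -180.0 + (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def integral(self) -> float:
        return float(self.values.sum() * self.bin_width ** len(self.residues))


@dataclass
class FreeEnergyReport:
    """Eight-state probabilities and relative free energies with block SEMs."""

    probabilities: dict[str, float]
    free_energies: dict[str, float]
    temperature: float
    probability_sem: dict[str, float] | None = None
    free_energy_sem: dict[str, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in STATE_ORDER:
            rows.append({
                "state": s,
                "probability": self.probabilities[s],
                "probability_sem": (self.probability_sem or {}).get(s, np.nan),
                "free_energy": self.free_energies[s],
                "free_energy_sem": (self.free_energy_sem or {}).get(s, np.nan),
            })
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        def clean(x):
            return None if x is None or not np.isfinite(x) else float(x)
        payload = {
            "temperature": self.temperature,
            "states": {
                s: {
                    "probability": clean(self.probabilities[s]),
                    "probability_sem": clean((self.probability_sem or {}).get(s, np.nan)),
                    "free_energy": clean(self.free_energies[s]),
                    "free_energy_sem": clean((self.free_energy_sem or {}).get(s, np.nan)),
                }
                for s in STATE_ORDER
            },
        }
        return json.dumps(payload, indent=2)


@dataclass
class ConditionalDG:
    """Conditional cis->trans isomerization free energy of one residue.

    ``condition`` maps the other two residues to their fixed isomer
    letters, e.g. residue=7, condition={2: 'C', 3: 'T'}.
    """

    residue: int
    condition: dict[int, str]
    dg_cis_to_trans: float
    sem: float = np.nan

    def __post_init__(self):
        if self.residue not in RESIDUES:
            raise ValueError(f"residue must be one of {RESIDUES}")
        if set(self.condition) != set(RESIDUES) - {self.residue}:
            raise ValueError("condition must fix exactly the other two residues")

    @property
    def labels(self) -> tuple[str, str]:
        """(trans octant, cis octant) labels of the two involved states."""
        out = []
        for letter in ("T", "C"):
            letters = {self.residue: letter, **self.condition}
            out.append("".join(letters[r] for r in RESIDUES))
        return tuple(out)


def histogram3d(series, n_bins: int = 50, biased: bool | None = None) -> Density3D:
    """Bin omega triples into an (n, n, n) normalized probability density."""
    frames = np.asarray(getattr(series, "frames", series), dtype=float)
    if frames.size == 0:
        raise ValueError("cannot histogram an empty series")
    if biased is None:
        biased = bool(getattr(series, "biased", False))
    counts, _ = np.histogramdd(frames, bins=n_bins, range=[(-180.0, 180.0)] * 3)
    width = 360.0 / n_bins
    return Density3D(counts / (counts.sum() * width ** 3), biased=biased)


def unbias_density(biased: Density3D, bias_force_constant: float,
                   temperature: float = DEFAULT_TEMPERATURE) -> Density3D:
    """Remove the one-fold trans bias by reweighting at bin centers.

    Each bin is multiplied by exp(+beta * U_bias(center)); renormalization
    absorbs the additive free-energy constants of the two ensembles.
    """
    if bias_force_constant < 0:
        raise ValueError("bias force constant must be non-negative")
    dens = biased.normalize()
    if bias_force_constant == 0.0:
        return Density3D(dens.values.copy(), biased=False)
    beta = 1.0 / (KB * temperature)
    b = bias_force_constant * (1.0 - np.cos(np.radians(dens.bin_centers)))
    log_w = beta * (b[:, None, None] + b[None, :, None] + b[None, None, :])
    log_w -= log_w.max()  # guard against overflow; normalization absorbs it
    values = dens.values * np.exp(log_w)
    total = values.sum() * dens.bin_width ** 3
    if total <= 0:
        raise ValueError("reweighted density has zero total weight")
    return Density3D(values / total, biased=False)


@lru_cache(maxsize=32)
def _octant_weights(n_bins: int, trans: bool) -> np.ndarray:
    """Per-bin Simpson weights for integrating one axis over a half-torus.

    Ordinates are the bin-center values inside the octant plus boundary
    ordinates at +-90 deg obtained by linear interpolation of the two
    adjacent bin centers (an even split when the boundary bisects a bin,
    as with 50 bins).  The trans half wraps periodically through 180 deg.
    """
    width = 360.0 / n_bins
    centers = -180.0 + (np.arange(n_bins) + 0.5) * width
    if trans:
        coords = np.where(centers >= 0.0, centers, centers + 360.0)
        lo, hi = 90.0, 270.0
    else:
        coords = centers.copy()
        lo, hi = -90.0, 90.0
    order = np.argsort(coords)
    coords_sorted = coords[order]

    # node list: (position, {bin_index: coefficient})
    nodes: list[tuple[float, dict[int, float]]] = []

    def boundary_node(pos: float):
        exact = np.flatnonzero(np.isclose(coords_sorted, pos))
        if exact.size:
            return pos, {int(order[exact[0]]): 1.0}
        right = int(np.searchsorted(coords_sorted, pos))
        left = (right - 1) % n_bins
        right = right % n_bins
        c_left, c_right = coords_sorted[left], coords_sorted[right]
        if c_right < c_left:
            c_right += 360.0
        frac = (pos - c_left) / (c_right - c_left)
        return pos, {int(order[left]): 1.0 - frac, int(order[right]): frac}

    nodes.append(boundary_node(lo))
    interior = (coords_sorted > lo + 1e-9) & (coords_sorted < hi - 1e-9)
    for j in np.flatnonzero(interior):
        nodes.append((coords_sorted[j], {int(order[j]): 1.0}))
    nodes.append(boundary_node(hi))

    x = np.array([pos for pos, _ in nodes])
    weights = np.zeros(n_bins)
    for k, (_, coeffs) in enumerate(nodes):
        unit = np.zeros(len(nodes))
        unit[k] = 1.0
        w_k = simpson(unit, x=x)
        for bin_idx, coeff in coeffs.items():
            weights[bin_idx] += coeff * w_k
    return weights


def state_probabilities(density: Density3D) -> dict[str, float]:
    """Simpson-integrated probabilities of the eight +-90 deg octant states.

    The eight values are renormalized to unit sum (the normalization
    condition of the reweighted density), so they sum to one exactly.
    """
    n = density.n_bins
    w = {"T": _octant_weights(n, True), "C": _octant_weights(n, False)}
    raw = np.empty(8)
    for i, label in enumerate(STATE_ORDER):
        raw[i] = np.einsum("i,j,k,ijk->", w[label[0]], w[label[1]], w[label[2]],
                           density.values)
    total = raw.sum()
    if total <= 0:
        raise ValueError("density has zero total octant weight")
    return dict(zip(STATE_ORDER, raw / total))


def state_probability(density: Density3D, state) -> float:
    """Probability of one isomerization state (octant integral)."""
    label = StateLabel(state)
    return state_probabilities(density)[label]


def free_energy_table(density: Density3D,
                      temperature: float = DEFAULT_TEMPERATURE) -> FreeEnergyReport:
    """Boltzmann inversion of the eight state probabilities, G(TTT) = 0."""
    probs = state_probabilities(density)
    kT = KB * temperature
    if probs["TTT"] <= 0:
        raise ValueError("the TTT reference state has zero probability")
    empty = [s for s, p in probs.items() if p <= 0]
    if empty:
        warnings.warn(f"empty octant(s) {empty}: free energy set to +inf", RuntimeWarning)
    with np.errstate(divide="ignore"):
        g = {s: (-kT * np.log(p / probs["TTT"]) if p > 0 else np.inf)
             for s, p in probs.items()}
    return FreeEnergyReport(probabilities=probs, free_energies=g, temperature=temperature)


def project_density(density: Density3D, keep_residues) -> Marginal:
    """Project onto one or two residues by summing over the dropped axes."""
    keep = tuple(int(r) for r in np.atleast_1d(keep_residues))
    if not 1 <= len(keep) <= 2 or len(set(keep)) != len(keep):
        raise ValueError("keep one or two distinct residues")
    if any(r not in AXIS_OF_RESIDUE for r in keep):
        raise ValueError(f"residues must be among {RESIDUES}")
    keep = tuple(sorted(keep, key=lambda r: AXIS_OF_RESIDUE[r]))
    keep_axes = [AXIS_OF_RESIDUE[r] for r in keep]
    drop_axes = tuple(a for a in range(3) if a not in keep_axes)
    values = density.normalize().values.sum(axis=drop_axes) * density.bin_width ** len(drop_axes)
    return Marginal(values=values, residues=keep)


def pmf_1d(marginal: Marginal, temperature: float = DEFAULT_TEMPERATURE) -> np.ndarray:
    """Potential of mean force -kT ln P per bin, minimum shifted to zero.

    Empty bins get +inf (never smoothed).
    """
    if marginal.values.ndim != 1:
        raise ValueError("pmf_1d expects a one-dimensional marginal")
    kT = KB * temperature
    with np.errstate(divide="ignore"):
        g = -kT * np.log(marginal.values)
    finite = np.isfinite(g)
    if not finite.any():
        raise ValueError("marginal density is empty everywhere")
    return g - g[finite].min()


def _half_probabilities(marginal: Marginal) -> tuple[float, float]:
    n = marginal.n_bins
    p_trans = float(_octant_weights(n, True) @ marginal.values)
    p_cis = float(_octant_weights(n, False) @ marginal.values)
    return p_trans, p_cis


def isomerization_dG(marginal: Marginal,
                     temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Marginal cis->trans free energy -kT ln[P(180+-90) / P(0+-90)].

    Averages implicitly over the isomer states of the other residues;
    negative values mean trans is favored.
    """
    if marginal.values.ndim != 1:
        raise ValueError("isomerization_dG expects a one-dimensional marginal")
    p_trans, p_cis = _half_probabilities(marginal)
    if p_trans <= 0 or p_cis <= 0:
        warnings.warn("empty cis or trans half: infinite isomerization free energy",
                      RuntimeWarning)
        return np.inf if p_trans <= 0 else -np.inf
    return float(-KB * temperature * np.log(p_trans / p_cis))


def conditional_dG(density: Density3D, residue_i: int, s_j: str, s_k: str,
                   temperature: float = DEFAULT_TEMPERATURE) -> ConditionalDG:
    """Conditional cis->trans free energy of residue i, others fixed.

    ``s_j`` and ``s_k`` are the isomer letters of the other two residues in
    ascending residue order (e.g. residue_i=7 fixes Pro2 then Pro3).
    Equals G(cis octant) subtracted from G(trans octant) of the two
    involved states.
    """
    others = sorted(set(RESIDUES) - {int(residue_i)})
    condition = {others[0]: str(s_j).upper(), others[1]: str(s_k).upper()}
    for letter in condition.values():
        if letter not in ("T", "C"):
            raise ValueError("condition letters must be 'T' or 'C'")
    entry = ConditionalDG(residue=int(residue_i), condition=condition,
                          dg_cis_to_trans=np.nan)
    trans_label, cis_label = entry.labels
    probs = state_probabilities(density)
    p_t, p_c = probs[trans_label], probs[cis_label]
    if p_t <= 0 or p_c <= 0:
        warnings.warn(f"empty conditioned octant for residue {residue_i} | {condition}",
                      RuntimeWarning)
        entry.dg_cis_to_trans = np.inf if p_t <= 0 else -np.inf
        return entry
    entry.dg_cis_to_trans = float(-KB * temperature * np.log(p_t / p_c))
    return entry


def conditional_dG_table(density: Density3D,
                         temperature: float = DEFAULT_TEMPERATURE) -> list[ConditionalDG]:
    """All twelve conditional free energies (3 residues x 4 conditions)."""
    out = []
    for residue in RESIDUES:
        for s_j in "TC":
            for s_k in "TC":
                out.append(conditional_dG(density, residue, s_j, s_k, temperature))
    return out


def conditionals_to_frame(entries: list[ConditionalDG]) -> pd.DataFrame:
    rows = []
    for e in entries:
        cond = " ".join(f"Pro{r}={e.condition[r]}" for r in sorted(e.condition))
        rows.append({"residue": f"Pro{e.residue}", "condition": cond,
                     "dG_cis_to_trans": e.dg_cis_to_trans, "sem": e.sem})
    return pd.DataFrame(rows)


def block_sem(per_frame_stream, statistic, n_blocks: int = 5) -> float:
    """SEM of a statistic over equally sized contiguous frame subsets.

    The stream is truncated to a multiple of ``n_blocks`` frames, the
    statistic is evaluated on each contiguous block, and the standard
    error of the block values is returned.
    """
    data = np.asarray(per_frame_stream)
    if len(data) < n_blocks:
        raise ValueError(f"need at least {n_blocks} frames for {n_blocks} blocks")
    usable = (len(data) // n_blocks) * n_blocks
    blocks = np.split(data[:usable], n_blocks)
    values = np.array([statistic(b) for b in blocks], dtype=float)
    return float(values.std(ddof=1) / np.sqrt(n_blocks))


def cycle_closure(probabilities: dict[str, float],
                  temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Max thermodynamic-cycle residual over residue pairs.

    For residues (i, j) with the third residue fixed, the change of the
    conditional free energy of i when j flips must equal the change of the
    conditional free energy of j when i flips; both reduce to the same
    four-octant combination, so the residual vanishes identically on exact
    densities and within sampling error otherwise.
    """
    kT = KB * temperature
    g = {s: -kT * np.log(max(p, 1e-300)) for s, p in probabilities.items()}
    worst = 0.0
    pos = {r: i for i, r in enumerate(RESIDUES)}
    for i in RESIDUES:
        for j in RESIDUES:
            if j <= i:
                continue
            (k,) = set(RESIDUES) - {i, j}
            for s_k in "TC":
                def octant(si, sj):
                    letters = {i: si, j: sj, k: s_k}
                    return "".join(letters[r] for r in RESIDUES)
                # dG_i(j=T) - dG_i(j=C) vs dG_j(i=T) - dG_j(i=C)
                lhs = (g[octant("T", "T")] - g[octant("C", "T")]) \
                    - (g[octant("T", "C")] - g[octant("C", "C")])
                rhs = (g[octant("T", "T")] - g[octant("T", "C")]) \
                    - (g[octant("C", "T")] - g[octant("C", "C")])
                worst = max(worst, abs(lhs - rhs))
    return worst
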