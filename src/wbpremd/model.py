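"""Reduced three-dihedral model of coupled prolyl cis-trans isomerization.

The peptide bond preceding a proline can populate both the trans
(omega ~ 180 deg) and cis (omega ~ 0 deg) isomer.  For a peptide with three
proline residues (positions 2, 3 and 7 in bradykinin) the isomer combination
defines eight metastable states, labeled e.g. ``TTC`` (Pro2 trans, Pro3
trans, Pro7 cis).  This module defines a reduced Hamiltonian over the three
omega dihedral angles only:

* a physical prolyl torsion potential per residue, the sum of four
  two-fold cosine terms over the four dihedrals that co-rotate with the
  peptide bond, giving equal-depth wells at 0 and 180 deg separated by a
  20 kcal/mol barrier at the physical force constant of 2.5 kcal/mol;
* a smooth periodic state-coupling term that assigns each of the eight
  octant states an energy offset, standing in for the solvated-peptide
  environment that makes the states inequivalent.

An exact quadrature oracle integrates the Boltzmann factor over each
octant, and :func:`calibrate_model` adjusts the offsets until the
quadrature state free energies match a prescribed eight-state table.
Angles are in degrees throughout (canonical interval [-180, 180)),
energies in kcal/mol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

#: Boltzmann constant in kcal mol^-1 K^-1.
KB = 0.0019872

DEFAULT_TEMPERATURE = 300.0

#: Residue positions carrying a prolyl peptide bond, in axis order.
RESIDUES = (2, 3, 7)

#: Canonical ordering of the eight isomerization states.
STATE_ORDER = ("TTT", "TTC", "TCT", "CTT", "TCC", "CTC", "CCT", "CCC")


class CalibrationError(RuntimeError):
    """Raised when offset calibration does not converge; carries residuals."""

    def __init__(self, message: str, residuals: dict[str, float]):
        super().__init__(message)
        self.residuals = residuals


def wrap_angle(omega):
    """Wrap angle(s) in degrees to the canonical interval [-180, 180)."""
    return (np.asarray(omega, dtype=float) + 180.0) % 360.0 - 180.0


class StateLabel(str):
    """Three-letter cis/trans label, positions (Pro2, Pro3, Pro7).

    ``T`` marks the trans isomer (omega within ``halfwidth`` of 180 deg),
    ``C`` the cis isomer (omega within ``halfwidth`` of 0 deg).  The
    halfwidth is context dependent: 90 deg for octant integration, 45 deg
    for trajectory filtering.
    """

    def __new__(cls, letters: str):
        letters = str(letters).upper()
        if len(letters) != 3 or any(ch not in "TC" for ch in letters):
            raise ValueError(f"state label must be 3 characters over {{T,C}}, got {letters!r}")
        return super().__new__(cls, letters)

    @property
    def trans_mask(self) -> tuple[bool, bool, bool]:
        return tuple(ch == "T" for ch in self)

    @classmethod
    def from_omegas(cls, omegas, halfwidth: float = 90.0):
        """Label a single (omega2, omega3, omega7) triple; None if unassigned."""
        letters = []
        for w in np.atleast_1d(np.asarray(omegas, dtype=float)):
            d_cis = np.abs(wrap_angle(w))
            d_trans = np.abs(wrap_angle(w - 180.0))
            if d_trans <= halfwidth:
                letters.append("T")
            elif d_cis < halfwidth:
                letters.append("C")
            else:
                return None
        return cls("".join(letters))


@dataclass(frozen=True)
class TorsionTerm:
    """One cosine dihedral term V * [1 + cos(n*(omega + offset) - phase)].

    ``dihedral_offset`` is the offset of this dihedral from the peptide
    bond omega under rigid co-rotation of the planar peptide unit.
    """

    force_constant: float
    multiplicity: int = 2
    phase: float = 180.0
    dihedral_offset: float = 0.0

    def __post_init__(self):
        if self.force_constant < 0:
            raise ValueError(f"force constant must be >= 0, got {self.force_constant}")
        if self.multiplicity not in (1, 2):
            raise ValueError(f"multiplicity must be 1 or 2, got {self.multiplicity}")
        if not 0.0 <= self.phase < 360.0:
            raise ValueError(f"phase must lie in [0, 360), got {self.phase}")

    def energy(self, omega):
        phi = np.radians(np.asarray(omega, dtype=float) + self.dihedral_offset)
        return self.force_constant * (
            1.0 + np.cos(self.multiplicity * phi - np.radians(self.phase))
        )


#: Offsets of the four co-rotating dihedrals (CA-C-N-CA, O-C-N-CA, O-C-N-H,
#: CA-C-N-H) from omega for a planar peptide unit.
PHYSICAL_OFFSETS = (0.0, 180.0, 180.0, 0.0)


@dataclass(frozen=True)
class ProlylTorsion:
    """The four torsion-energy terms surrounding one prolyl peptide bond."""

    terms: tuple[TorsionTerm, ...]

    def __post_init__(self):
        if len(self.terms) != 4:
            raise ValueError(f"a prolyl torsion has exactly four terms, got {len(self.terms)}")

    @classmethod
    def physical(cls, force_constant: float) -> "ProlylTorsion":
        """Physical form: four two-fold terms, phase 180, planar offsets.

        Under two-fold multiplicity the four co-rotating terms coincide, so
        the profile is 4*V*[1 + cos(2*omega - 180)] with minima of equal
        depth at 0 and 180 deg and a barrier of 8*V at +-90 deg.
        """
        return cls(tuple(
            TorsionTerm(force_constant, multiplicity=2, phase=180.0, dihedral_offset=off)
            for off in PHYSICAL_OFFSETS
        ))

    @property
    def force_constant(self) -> float:
        return self.terms[0].force_constant

    def energy(self, omega):
        return sum(term.energy(omega) for term in self.terms)


def eval_physical_torsion(omega, ladder_force_constant: float):
    """Physical prolyl torsion energy at ``omega`` for one ladder level.

    Sums the four co-rotating two-fold dihedral terms; the barrier height
    (max - min) equals 8 * force_constant.
    """
    return ProlylTorsion.physical(ladder_force_constant).energy(omega)


def trans_weight(omega):
    """Smooth periodic weight of the trans isomer: sin^2(omega/2).

    Equals 1 at omega = 180 deg, 0 at omega = 0 deg; the cis weight is its
    complement.  Products of these per-residue weights switch the eight
    state-coupling offsets on and off continuously over the three-torus.
    """
    return 0.5 * (1.0 - np.cos(np.radians(np.asarray(omega, dtype=float))))


@dataclass(frozen=True)
class ModelPotential:
    """Total reduced Hamiltonian: three prolyl torsions + state coupling.

    ``coupling_offsets`` holds one energy per octant state in
    :data:`STATE_ORDER`; the TTT offset is the zero reference.  The offsets
    enter through a product-of-switching-functions weight per state, so the
    total energy is smooth and periodic on the three-torus.
    """

    torsions: tuple[ProlylTorsion, ProlylTorsion, ProlylTorsion]
    coupling_offsets: tuple[float, ...] = (0.0,) * 8
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        if len(self.torsions) != 3:
            raise ValueError("a model has exactly three prolyl torsions")
        if len(self.coupling_offsets) != 8:
            raise ValueError("one coupling offset per octant state is required")
        if abs(self.coupling_offsets[0]) > 1e-9:
            raise ValueError("the TTT coupling offset is the zero reference")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @classmethod
    def physical(cls, force_constant: float = 2.5, coupling_offsets=None,
                 temperature: float = DEFAULT_TEMPERATURE) -> "ModelPotential":
        offsets = (0.0,) * 8 if coupling_offsets is None else tuple(float(c) for c in coupling_offsets)
        return cls(
            torsions=tuple(ProlylTorsion.physical(force_constant) for _ in range(3)),
            coupling_offsets=offsets,
            temperature=temperature,
        )

    @property
    def offsets_dict(self) -> dict[str, float]:
        return dict(zip(STATE_ORDER, self.coupling_offsets))

    @property
    def coupling_tensor(self) -> np.ndarray:
        """Offsets as a (2, 2, 2) tensor indexed by (cis=0 / trans=1) per residue."""
        c = np.zeros((2, 2, 2))
        for label, value in zip(STATE_ORDER, self.coupling_offsets):
            idx = tuple(1 if ch == "T" else 0 for ch in label)
            c[idx] = value
        return c

    def coupling_energy(self, omegas):
        omegas = np.asarray(omegas, dtype=float)
        wt = trans_weight(omegas)
        wc = 1.0 - wt
        energy = 0.0
        for label, offset in zip(STATE_ORDER, self.coupling_offsets):
            if offset == 0.0:
                continue
            weight = np.ones_like(wt[..., 0])
            for axis, ch in enumerate(label):
                weight = weight * (wt[..., axis] if ch == "T" else wc[..., axis])
            energy = energy + offset * weight
        return energy

    def energy(self, omegas):
        """Total potential energy at (..., 3) angle triples in degrees."""
        omegas = np.asarray(omegas, dtype=float)
        if omegas.shape[-1] != 3:
            raise ValueError("expected angle triples in the last axis")
        total = self.coupling_energy(omegas)
        for axis, torsion in enumerate(self.torsions):
            total = total + torsion.energy(omegas[..., axis])
        return total

    def __call__(self, omegas):
        return self.energy(omegas)


def eval_model_energy(omegas, model: ModelPotential):
    """Total reduced-model energy; periodic in each angle with period 360."""
    return model.energy(omegas)


def _axis_energies(model: ModelPotential, centers: np.ndarray,
                   bias_force_constant: float = 0.0) -> list[np.ndarray]:
    """Per-axis separable energy (torsion + trans-penalizing bias)."""
    out = []
    for torsion in model.torsions:
        e = torsion.energy(centers)
        if bias_force_constant:
            e = e + bias_force_constant * (1.0 - np.cos(np.radians(centers)))
        out.append(np.asarray(e, dtype=float))
    return out


def _boltzmann_grid(model: ModelPotential, centers: np.ndarray, kT: float,
                    bias_force_constant: float = 0.0) -> np.ndarray:
    """Unnormalized Boltzmann factor exp(-U/kT) on the tensor grid of centers."""
    e1, e2, e3 = _axis_energies(model, centers, bias_force_constant)
    u = e1[:, None, None] + e2[None, :, None] + e3[None, None, :]
    wt = trans_weight(centers)
    wc = 1.0 - wt
    for label, offset in zip(STATE_ORDER, model.coupling_offsets):
        if offset == 0.0:
            continue
        f1, f2, f3 = ((wt if ch == "T" else wc) for ch in label)
        u = u + offset * (f1[:, None, None] * f2[None, :, None] * f3[None, None, :])
    u -= u.min()
    return np.exp(-u / kT)


def quadrature_state_probabilities(model: ModelPotential, temperature: float | None = None,
                                   grid_points: int = 120,
                                   bias_force_constant: float = 0.0) -> np.ndarray:
    """Exact (quadrature) octant probabilities of the model Boltzmann density.

    Integrates exp(-U/kT) over each +-90 deg octant on a regular midpoint
    grid aligned with the octant boundaries.  Returns the eight
    probabilities in :data:`STATE_ORDER`; they sum to one by construction.
    An optional trans-penalizing one-fold bias can be folded into U to
    obtain the biased reference density.
    """
    if temperature is None:
        temperature = model.temperature
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    if grid_points < 8 or grid_points % 4:
        raise ValueError("grid_points must be a multiple of 4 (octant-aligned), >= 8")
    width = 360.0 / grid_points
    centers = -180.0 + (np.arange(grid_points) + 0.5) * width
    boltz = _boltzmann_grid(model, centers, KB * temperature, bias_force_constant)
    is_trans = np.abs(centers) > 90.0  # no center sits at +-90 for multiples of 4
    probs = np.empty(8)
    for i, label in enumerate(STATE_ORDER):
        masks = [is_trans if ch == "T" else ~is_trans for ch in label]
        probs[i] = boltz[np.ix_(*masks)].sum()
    return probs / probs.sum()


def quadrature_density(model: ModelPotential, n_bins: int = 50, oversample: int = 4,
                       temperature: float | None = None,
                       bias_force_constant: float = 0.0) -> np.ndarray:
    """Bin-averaged normalized reference density on an (n, n, n) grid.

    Each bin value is the Boltzmann density averaged over an
    ``oversample``^3 subgrid of the bin, so the result is directly
    comparable to a histogram of samples (units: probability per deg^3).
    """
    if temperature is None:
        temperature = model.temperature
    n_fine = n_bins * oversample
    width = 360.0 / n_fine
    centers = -180.0 + (np.arange(n_fine) + 0.5) * width
    boltz = _boltzmann_grid(model, centers, KB * temperature, bias_force_constant)
    shape = (n_bins, oversample, n_bins, oversample, n_bins, oversample)
    coarse = boltz.reshape(shape).mean(axis=(1, 3, 5))
    bin_volume = (360.0 / n_bins) ** 3
    return coarse / (coarse.sum() * bin_volume)


def free_energies_from_probabilities(probabilities, temperature: float = DEFAULT_TEMPERATURE) -> np.ndarray:
    """Boltzmann inversion -kT ln P, shifted so the first (TTT) entry is zero."""
    p = np.asarray(probabilities, dtype=float)
    kT = KB * temperature
    with np.errstate(divide="ignore"):
        g = -kT * np.log(p)
    return g - g[0]


def calibrate_model(target_free_energies, temperature: float = DEFAULT_TEMPERATURE,
                    grid_points: int = 120, barrier_force_constant: float = 2.5,
                    tol: float = 0.002, max_iter: int = 80) -> ModelPotential:
    """Build a model whose quadrature state free energies match a target table.

    ``target_free_energies`` is a mapping or array of eight energies
    (kcal/mol) relative to TTT, ordered as :data:`STATE_ORDER`.  The octant
    offsets are iterated by the current free-energy residual until the
    quadrature free energies match each target to ``tol`` (default well
    inside the 0.01 kcal/mol contract).
    """
    if isinstance(target_free_energies, dict):
        targets = np.array([float(target_free_energies[s]) for s in STATE_ORDER])
    else:
        targets = np.asarray(target_free_energies, dtype=float)
    if targets.shape != (8,):
        raise ValueError("exactly eight target free energies are required")
    if abs(targets[0]) > 1e-9:
        raise ValueError("the TTT target must be zero (reference state)")
    if not np.all(np.isfinite(targets)):
        raise ValueError("target free energies must be finite")

    offsets = targets.copy()
    for _ in range(max_iter):
        model = ModelPotential.physical(barrier_force_constant, offsets, temperature)
        probs = quadrature_state_probabilities(model, temperature, grid_points)
        residual = targets - free_energies_from_probabilities(probs, temperature)
        if np.max(np.abs(residual)) < tol:
            return model
        offsets = offsets + residual
        offsets = offsets - offsets[0]
    raise CalibrationError(
        f"calibration did not converge to {tol} kcal/mol in {max_iter} iterations",
        residuals=dict(zip(STATE_ORDER, residual)),
    )


def save_model(model: ModelPotential, path) -> None:
    """Write a model definition as a YAML config."""
    payload = {
        "temperature": float(model.temperature),
        "force_constant": float(model.torsions[0].force_constant),
        "coupling_offsets": {s: float(v) for s, v in model.offsets_dict.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_model(path) -> ModelPotential:
    """Read a model definition written by :func:`save_model`."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    for key in ("temperature", "force_constant", "coupling_offsets"):
        if key not in payload:
            raise KeyError(f"model config is missing required key {key!r}")
    return ModelPotential.physical(
        force_constant=float(payload["force_constant"]),
        coupling_offsets=[float(payload["coupling_offsets"][s]) for s in STATE_ORDER],
        temperature=float(payload["temperature"]),
    )
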