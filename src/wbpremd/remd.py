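"""Bias-potential Hamiltonian replica exchange over the three omega dihedrals.

The replica ladder scales the force constant of the prolyl torsion
potentials from the physical value (replica 1) down to zero (replica n),
so cis/trans transitions become unhindered at the top of the ladder and
propagate into replica 1 through Metropolis exchanges of configurations
between neighboring replicas.  A one-fold cosine bias that penalizes the
trans isomer of every residue is present in all replicas; it balances
cis/trans sampling and is removed afterwards by reweighting
(:mod:`wbpremd.unbias`).

Dynamics is Metropolis Monte Carlo with wrapped-Gaussian single-angle
proposals (one sweep = one proposed move per angle), which is exactly
Boltzmann for each replica's Hamiltonian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import model as _model
from ._kernel import remd_sweep_kernel
from .model import KB, DEFAULT_TEMPERATURE, ModelPotential, wrap_angle


@dataclass(frozen=True)
class ReplicaLadder:
    """Equidistant ladder of torsion force constants, replica 1 highest.

    The default mirrors the production setup: 12 replicas spanning
    2.5 -> 0 kcal/mol, with a one-fold trans-penalizing bias of
    1 kcal/mol (multiplicity 1, phase 180 deg) in every replica.
    """

    n_replicas: int = 12
    max_force_constant: float = 2.5
    bias_force_constant: float = 1.0
    bias_multiplicity: int = field(default=1, repr=False)
    bias_phase: float = field(default=180.0, repr=False)

    def __post_init__(self):
        if self.n_replicas < 1:
            raise ValueError("at least one replica is required")
        if self.max_force_constant < 0 or self.bias_force_constant < 0:
            raise ValueError("force constants must be non-negative")
        if self.bias_multiplicity != 1 or self.bias_phase != 180.0:
            raise ValueError("the trans-penalizing bias is one-fold with phase 180")

    @property
    def force_constants(self) -> np.ndarray:
        """Per-replica torsion force constants, strictly decreasing to 0."""
        if self.n_replicas == 1:
            return np.array([self.max_force_constant])
        return np.linspace(self.max_force_constant, 0.0, self.n_replicas)


@dataclass
class OmegaSeries:
    """Saved (omega2, omega3, omega7) frames of one replica, in degrees."""

    frames: np.ndarray
    replica_index: int = 1
    save_stride: int = 1
    seed: int = 0
    level_force_constant: float = np.nan
    bias_force_constant: float = 0.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2 or self.frames.shape[1] != 3:
            raise ValueError("frames must be an (N, 3) array of angle triples")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def biased(self) -> bool:
        return self.bias_force_constant > 0

    def to_table(self, path) -> None:
        """Write as plain tabular text: step, omega2, omega3, omega7."""
        steps = np.arange(1, len(self) + 1) * self.save_stride
        df = pd.DataFrame({"step": steps, "omega2": self.frames[:, 0],
                           "omega3": self.frames[:, 1], "omega7": self.frames[:, 2]})
        df.to_csv(path, sep="\t", index=False, float_format="%.4f")

    @classmethod
    def from_table(cls, path, **meta) -> "OmegaSeries":
        df = pd.read_csv(path, sep="\t")
        frames = df[["omega2", "omega3", "omega7"]].to_numpy()
        stride = int(df["step"].iloc[0]) if "step" in df and len(df) else 1
        meta.setdefault("save_stride", max(stride, 1))
        return cls(frames=frames, **meta)


@dataclass
class ExchangeStats:
    """Attempt/acceptance bookkeeping per neighboring replica pair."""

    attempts: np.ndarray
    accepted: np.ndarray

    @property
    def acceptance(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.attempts > 0, self.accepted / np.maximum(self.attempts, 1), np.nan)

    def to_frame(self) -> pd.DataFrame:
        pairs = [f"{i + 1}-{i + 2}" for i in range(len(self.attempts))]
        return pd.DataFrame({"pair": pairs, "attempts": self.attempts,
                             "accepted": self.accepted, "acceptance": self.acceptance})


def eval_bias_potential(omegas, bias_force_constant: float):
    """One-fold trans-penalizing bias: sum_i V * [1 + cos(omega_i - 180)].

    Maximal (2V per residue) in the trans well, zero in the cis well.
    """
    if bias_force_constant < 0:
        raise ValueError("bias force constant must be non-negative")
    omegas = np.asarray(omegas, dtype=float)
    return bias_force_constant * np.sum(1.0 - np.cos(np.radians(omegas)), axis=-1)


def exchange_probability(config_a, config_b, hamiltonian_a, hamiltonian_b,
                         temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Metropolis probability of swapping two configurations between Hamiltonians."""
    beta = 1.0 / (KB * temperature)
    delta = (hamiltonian_a(config_b) + hamiltonian_b(config_a)
             - hamiltonian_a(config_a) - hamiltonian_b(config_b))
    return float(min(1.0, np.exp(-beta * delta)))


def mc_propagate(start, hamiltonian, n_steps: int, step_sigma: float = 20.0,
                 temperature: float = DEFAULT_TEMPERATURE, seed: int = 0,
                 save_stride: int = 1) -> OmegaSeries:
    """Single-chain Metropolis random walk with wrapped-Gaussian proposals.

    ``hamiltonian`` is any callable mapping a (3,) degree triple to an
    energy.  One step is one sweep (one proposed move per angle).  The
    chain satisfies detailed balance w.r.t. exp(-U/kT) and is
    deterministic given the seed.  This is the plain reference sampler;
    the replica-exchange production loop uses a compiled kernel.
    """
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    if step_sigma <= 0:
        raise ValueError("step_sigma must be positive")
    rng = np.random.default_rng(seed)
    beta = 1.0 / (KB * temperature)
    x = wrap_angle(np.asarray(start, dtype=float)).copy()
    if x.shape != (3,):
        raise ValueError("start must be a triple of angles")
    energy = float(hamiltonian(x))
    n_save = n_steps // save_stride
    frames = np.empty((n_save, 3))
    isave = 0
    for step in range(1, n_steps + 1):
        for axis in range(3):
            proposal = x.copy()
            proposal[axis] = wrap_angle(x[axis] + step_sigma * rng.normal())
            new_energy = float(hamiltonian(proposal))
            if rng.random() < np.exp(-beta * min(new_energy - energy, 700.0 / beta)):
                x = proposal
                energy = new_energy
        if step % save_stride == 0:
            frames[isave] = x
            isave += 1
    return OmegaSeries(frames=frames, replica_index=0, save_stride=save_stride, seed=seed)


def replica_hamiltonian(model: ModelPotential, ladder: ReplicaLadder, replica_index: int):
    """Callable Hamiltonian of one replica: scaled torsions + coupling + bias."""
    level = ladder.force_constants[replica_index - 1]
    scaled = ModelPotential.physical(level, model.coupling_offsets, model.temperature)

    def hamiltonian(omegas):
        return scaled.energy(omegas) + eval_bias_potential(omegas, ladder.bias_force_constant)

    return hamiltonian


def run_wbp_remd(model: ModelPotential, ladder: ReplicaLadder, n_sweeps: int,
                 exchange_every: int = 250, save_stride: int = 10,
                 step_sigma: float = 20.0, seed: int = 0,
                 start=None) -> tuple[list[OmegaSeries], ExchangeStats]:
    """Run the full replica-exchange simulation.

    Every replica's Hamiltonian combines its ladder-level torsion scaling
    with the model's state-coupling offsets and the one-fold bias (present
    in all replicas).  Neighbor exchange attempts alternate between even
    and odd pairs every ``exchange_every`` sweeps and swap configurations.
    Returns one :class:`OmegaSeries` per replica (replica 1 first -- the
    analysis input) plus exchange statistics.  Set ``exchange_every=0`` to
    disable exchanges.
    """
    if n_sweeps <= 0:
        raise ValueError("n_sweeps must be positive")
    if exchange_every and ladder.n_replicas < 2:
        raise ValueError("exchanges require at least two replicas")
    if exchange_every < 0:
        raise ValueError("exchange_every must be >= 0 (0 disables exchanges)")

    n_rep = ladder.n_replicas
    if start is None:
        start_deg = np.full((n_rep, 3), 180.0)  # all-trans start
    else:
        start_deg = np.broadcast_to(np.asarray(start, dtype=float), (n_rep, 3)).copy()
    omega0 = np.radians(wrap_angle(start_deg))

    traj, attempts, accepted = remd_sweep_kernel(
        omega0, ladder.force_constants.astype(float), model.coupling_tensor,
        float(ladder.bias_force_constant), KB * model.temperature,
        float(np.radians(step_sigma)), int(n_sweeps), int(exchange_every),
        int(save_stride), int(seed),
    )
    frames_deg = wrap_angle(np.degrees(traj))
    levels = ladder.force_constants
    series = [
        OmegaSeries(frames=frames_deg[:, r, :], replica_index=r + 1,
                    save_stride=save_stride, seed=seed,
                    level_force_constant=float(levels[r]),
                    bias_force_constant=ladder.bias_force_constant)
        for r in range(n_rep)
    ]
    return series, ExchangeStats(attempts=attempts, accepted=accepted)
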