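"""Structural observables on geometric time series.

Operates on precomputed per-frame interatomic distances (Angstrom) and
donor-H-acceptor angles (degrees), typically extracted from an atomistic
trajectory by an external tool.  Provides:

* NOE upper-bound violations: the inverse-6th-power ensemble-averaged
  interproton distance minus the experimental upper bound (3 / 3.5 / 4 /
  4.5 A for strong / medium / weak / very weak intensities); positive
  values flag ensemble-restraint inconsistency;
* geometric hydrogen-bond detection (angle >= 135 deg, donor-acceptor
  distance < 3 A, or a looser 3.5 A criterion) with per-state occupancies;
* the (d - 1.8 A)^2 distance scaling that upweights short contacts before
  learning;
* random-forest feature-importance ranking of scaled distances against
  the eight isomerization-state classes;
* hierarchical density-based (HDBSCAN) conformational clustering with a
  minimum cluster size of 500.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN
from sklearn.ensemble import RandomForestClassifier

#: Experimental NOE upper bound per intensity class, in Angstrom.
NOE_BOUNDS = {"s": 3.0, "m": 3.5, "w": 4.0, "vw": 4.5}

HBOND_ANGLE_MIN = 135.0
HBOND_DIST_MAX = 3.0
HBOND_DIST_MAX_LOOSE = 3.5


@dataclass
class GeomSeries:
    """Frame-aligned named distance and angle channels with state labels."""

    distances: pd.DataFrame
    angles: pd.DataFrame
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.distances = pd.DataFrame(self.distances)
        self.angles = pd.DataFrame(self.angles)
        if len(self.angles) and len(self.distances) != len(self.angles):
            raise ValueError("distance and angle channels must be frame-aligned")
        if (self.distances.to_numpy() <= 0).any():
            raise ValueError("distances must be positive")
        a = self.angles.to_numpy()
        if a.size and ((a < 0) | (a > 180)).any():
            raise ValueError("donor-H-acceptor angles must lie in [0, 180] degrees")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != len(self.distances):
                raise ValueError("labels must be frame-aligned")

    def __len__(self) -> int:
        return len(self.distances)

    def to_tables(self, dist_path, angle_path) -> None:
        self.distances.to_csv(dist_path, sep="\t", index=False)
        self.angles.to_csv(angle_path, sep="\t", index=False)


@dataclass(frozen=True)
class NOERestraint:
    """One interproton NOE restraint: pair id and intensity class."""

    pair_id: str
    intensity_class: str

    def __post_init__(self):
        if self.intensity_class not in NOE_BOUNDS:
            raise ValueError(
                f"intensity class must be one of {sorted(NOE_BOUNDS)}, got {self.intensity_class!r}")

    @property
    def upper_bound(self) -> float:
        return NOE_BOUNDS[self.intensity_class]


def read_restraints(path) -> list[NOERestraint]:
    """Read a whitespace-separated restraint table: pair id, intensity class."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", names=["pair_id", "intensity_class"])
    return [NOERestraint(str(r.pair_id), str(r.intensity_class)) for r in df.itertuples()]


def noe_violation(distances, restraint: NOERestraint) -> float:
    """NOE upper-bound violation Delta = <r^-6>^(-1/6) - bound, in Angstrom.

    The inverse-6th-power average weights short-distance frames the way
    the NOE intensity does; positive values are violations.  Equals
    r - bound for a constant series and is monotone non-decreasing in
    every frame distance.
    """
    r = np.asarray(distances, dtype=float)
    if r.size == 0:
        raise ValueError("cannot average an empty distance series")
    if np.any(r <= 0):
        raise ValueError("distances must be positive")
    effective = np.mean(r ** -6.0) ** (-1.0 / 6.0)
    return float(effective - restraint.upper_bound)


def violation_report(geom: GeomSeries, restraints: list[NOERestraint]) -> pd.DataFrame:
    """Per-restraint, per-state violation table (states from geom.labels)."""
    if geom.labels is None:
        raise ValueError("geometry series carries no state labels")
    states = [s for s in pd.unique(geom.labels) if s is not None]
    rows = []
    for restraint in restraints:
        if restraint.pair_id not in geom.distances:
            raise KeyError(f"no distance channel named {restraint.pair_id!r}")
        channel = geom.distances[restraint.pair_id].to_numpy()
        for state in states:
            mask = geom.labels == state
            rows.append({
                "state": state, "pair": restraint.pair_id,
                "intensity": restraint.intensity_class,
                "violation": noe_violation(channel[mask], restraint),
            })
    return pd.DataFrame(rows)


def detect_hbonds(geom: GeomSeries, angle_min: float = HBOND_ANGLE_MIN,
                  dist_max: float = HBOND_DIST_MAX):
    """Per-frame hydrogen-bond contact flags and occupancy fractions.

    A contact requires a donor-H-acceptor angle of at least ``angle_min``
    and a donor-acceptor distance below ``dist_max``.  Channels present in
    both the distance and angle tables are treated as candidate bonds.
    Returns ``(flags, occupancy)``.
    """
    bonds = [c for c in geom.distances.columns if c in geom.angles.columns]
    if not bonds:
        raise ValueError("no channel appears in both the distance and angle tables")
    flags = pd.DataFrame({
        b: (geom.angles[b].to_numpy() >= angle_min)
        & (geom.distances[b].to_numpy() < dist_max)
        for b in bonds
    })
    return flags, flags.mean(axis=0)


def occupancy_by_state(flags: pd.DataFrame, labels) -> pd.DataFrame:
    """Hydrogen-bond occupancy per isomerization-state subset."""
    labels = np.asarray(labels, dtype=object)
    states = [s for s in pd.unique(labels) if s is not None]
    return pd.DataFrame({s: flags[labels == s].mean(axis=0) for s in states}).T


def scale_distances(d):
    """Quadratic short-contact emphasis: (d - 1.8 A)^2, elementwise."""
    d = np.asarray(d, dtype=float) if not isinstance(d, (pd.Series, pd.DataFrame)) else d
    return (d - 1.8) ** 2


def rank_features(features, labels, seed: int = 0,
                  n_estimators: int = 200) -> pd.DataFrame:
    """Rank features by how well they discriminate the isomer states.

    Trains a random-forest classifier on the state labels (unlabeled
    frames dropped, classes weighted inversely to their frequency) and
    returns the features sorted by decreasing impurity-based importance.
    Deterministic given ``seed``.
    """
    X = pd.DataFrame(features)
    labels = np.asarray(labels, dtype=object)
    mask = np.array([lab is not None for lab in labels])
    y = labels[mask].astype(str)
    if len(np.unique(y)) < 2:
        raise ValueError("feature ranking requires at least two state classes")
    forest = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                    class_weight="balanced", n_jobs=1)
    forest.fit(X.to_numpy()[mask], y)
    ranking = pd.DataFrame({"feature": X.columns, "importance": forest.feature_importances_})
    return ranking.sort_values("importance", ascending=False, kind="stable",
                               ignore_index=True)


def cluster_conformations(features, min_cluster_size: int = 500) -> np.ndarray:
    """Hierarchical density-based clustering of frames in feature space.

    Returns one integer label per frame; ``-1`` marks outliers (points in
    no sufficiently dense region).  Clusters smaller than
    ``min_cluster_size`` are never reported.
    """
    X = pd.DataFrame(features).to_numpy()
    if len(X) < min_cluster_size:
        return np.full(len(X), -1)
    return HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(X)


def cluster_summary(labels, state_labels=None) -> pd.DataFrame:
    """Cluster membership counts, optionally broken down by isomer state."""
    labels = np.asarray(labels)
    clusters = sorted(c for c in np.unique(labels) if c >= 0)
    if state_labels is None:
        rows = [{"cluster": c, "members": int((labels == c).sum())} for c in clusters]
        rows.append({"cluster": "outliers", "members": int((labels == -1).sum())})
        return pd.DataFrame(rows)
    state_labels = np.asarray(state_labels, dtype=object)
    states = [s for s in pd.unique(state_labels) if s is not None]
    rows = []
    for s in states:
        mask = state_labels == s
        row = {"state": s}
        for c in clusters:
            row[f"C{c + 1}"] = int((labels[mask] == c).sum())
        row["outliers"] = int((labels[mask] == -1).sum())
        rows.append(row)
    return pd.DataFrame(rows)
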