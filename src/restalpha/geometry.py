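"""Electrode montage geometry.

Electrode positions live on a unit sphere centred in the head. Spherical
coordinates follow the convention: ``theta`` is the polar angle in degrees
measured from the superior (vertex) axis, ``phi`` is the azimuth in degrees
measured from the right-lateral axis rotating toward the anterior axis.
The derived Cartesian axes are the model covariates:

* ML — medial-lateral, +1 at the right ear
* AP — anterior-posterior, +1 at the nasion
* IS — inferior-superior, +1 at the vertex

so ``(ml, ap, is) = (sin θ cos φ, sin θ sin φ, cos θ)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ElectrodeLayout",
    "NeighborGraph",
    "spherical_to_cartesian",
    "great_circle_distance",
    "build_default_layout",
    "nearest_neighbors",
    "read_montage",
]


def spherical_to_cartesian(theta: float, phi: float) -> tuple[float, float, float]:
    """Convert spherical montage angles (degrees) to a unit ML/AP/IS vector.

    Parameters
    ----------
    theta : polar angle from the vertex, in [0, 180] degrees.
    phi : azimuth from the right-lateral axis toward the nasion,
        in [-180, 180] degrees.
    """
    if not 0.0 <= theta <= 180.0:
        raise ValueError(f"theta must lie in [0, 180] degrees, got {theta!r}")
    if not -180.0 <= phi <= 180.0:
        raise ValueError(f"phi must lie in [-180, 180] degrees, got {phi!r}")
    th = np.deg2rad(theta)
    ph = np.deg2rad(phi)
    return (
        float(np.sin(th) * np.cos(ph)),
        float(np.sin(th) * np.sin(ph)),
        float(np.cos(th)),
    )


def cartesian_to_spherical(ml: float, ap: float, is_: float) -> tuple[float, float]:
    """Inverse of :func:`spherical_to_cartesian`; returns (theta, phi) degrees."""
    theta = float(np.rad2deg(np.arctan2(np.hypot(ml, ap), is_)))
    phi = float(np.rad2deg(np.arctan2(ap, ml)))
    return theta, phi


def great_circle_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Angular distance (radians) between unit vectors on the sphere."""
    return float(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0)))


@dataclass(frozen=True)
class ElectrodeLayout:
    """Montage: channel labels with spherical and Cartesian coordinates."""

    labels: tuple[str, ...]
    theta: np.ndarray  # degrees from vertex
    phi: np.ndarray  # degrees from right ear toward nasion
    ml: np.ndarray
    ap: np.ndarray
    is_: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        norms = self.ml**2 + self.ap**2 + self.is_**2
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("electrode coordinates must lie on the unit sphere")

    @classmethod
    def from_angles(cls, labels, theta, phi) -> "ElectrodeLayout":
        xyz = np.array([spherical_to_cartesian(t, p) for t, p in zip(theta, phi)])
        return cls(
            labels=tuple(labels),
            theta=np.asarray(theta, dtype=float),
            phi=np.asarray(phi, dtype=float),
            ml=xyz[:, 0],
            ap=xyz[:, 1],
            is_=xyz[:, 2],
        )

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown electrode label {label!r}") from None

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) array of unit ML/AP/IS vectors."""
        return np.column_stack([self.ml, self.ap, self.is_])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": list(self.labels),
                "theta_deg": self.theta,
                "phi_deg": self.phi,
                "ml": self.ml,
                "ap": self.ap,
                "is": self.is_,
            }
        )


@dataclass(frozen=True)
class NeighborGraph:
    """k nearest scalp neighbors per electrode, by great-circle distance."""

    k: int
    neighbors: np.ndarray  # (n, k) int indices
    distances: np.ndarray  # (n, k) radians, ascending per row

    def __post_init__(self) -> None:
        n = self.neighbors.shape[0]
        if np.any(self.neighbors == np.arange(n)[:, None]):
            raise ValueError("neighbor lists must exclude the electrode itself")
        if np.any(self.distances < 0):
            raise ValueError("distances must be nonnegative")
        if np.any(np.diff(self.distances, axis=1) < -1e-12):
            raise ValueError("distances must be sorted ascending")


def _slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    """Spherical linear interpolation between unit vectors a and b."""
    omega = np.arccos(np.clip(np.dot(a, b), -1.0, 1.0))
    if omega < 1e-12:
        return a.copy()
    return (np.sin((1 - t) * omega) * a + np.sin(t * omega) * b) / np.sin(omega)


# Outer 10% ring: 20 positions at polar angle 72 deg, azimuth steps of 18 deg
# starting at the nasion (phi=90) and walking over the right hemisphere.
_RING = [
    ("Fpz", 90.0),  # placeholder: not in montage, used as arc anchor only
    ("Fp2", 72.0),
    ("AF8", 54.0),
    ("F8", 36.0),
    ("FT8", 18.0),
    ("T8", 0.0),
    ("TP8", -18.0),
    ("P8", -36.0),
    ("PO8", -54.0),
    ("O2", -72.0),
    ("Oz", -90.0),
    ("O1", -108.0),
    ("PO7", -126.0),
    ("P7", -144.0),
    ("TP7", -162.0),
    ("T7", 180.0),
    ("FT7", 162.0),
    ("F7", 144.0),
    ("AF7", 126.0),
    ("Fp1", 108.0),
]

# Midline electrodes: polar angle in 18 deg (10%) steps along the sagittal arc.
_MIDLINE = {
    "Fz": (36.0, 90.0),
    "FCz": (18.0, 90.0),
    "Cz": (0.0, 0.0),
    "CPz": (18.0, -90.0),
    "Pz": (36.0, -90.0),
    "POz": (54.0, -90.0),
    "Oz": (72.0, -90.0),
}

# Electrodes 10% below the outer ring (on the equator), under 7/8 positions.
_LOWER = {
    "FT9": (90.0, 162.0),
    "FT10": (90.0, 18.0),
    "TP9": (90.0, -162.0),
    "TP10": (90.0, -18.0),
    "PO9": (90.0, -126.0),
    "PO10": (90.0, -54.0),
}

# Interior rows: evenly spaced along the arc from the midline electrode to the
# matching outer-ring electrode (quarter steps for rows of three per side,
# halves for rows of one per side).
_ROWS = {
    # row: (midline label, left ring anchor, right ring anchor, inner labels L, R)
    "AF": ("AFz", "AF7", "AF8", ["AF3"], ["AF4"]),
    "F": ("Fz", "F7", "F8", ["F1", "F3", "F5"], ["F2", "F4", "F6"]),
    "FC": ("FCz", "FT7", "FT8", ["FC1", "FC3", "FC5"], ["FC2", "FC4", "FC6"]),
    "C": ("Cz", "T7", "T8", ["C1", "C3", "C5"], ["C2", "C4", "C6"]),
    "CP": ("CPz", "TP7", "TP8", ["CP1", "CP3", "CP5"], ["CP2", "CP4", "CP6"]),
    "P": ("Pz", "P7", "P8", ["P1", "P3", "P5"], ["P2", "P4", "P6"]),
    "PO": ("POz", "PO7", "PO8", ["PO3"], ["PO4"]),
}

def _default_angle_table() -> list[tuple[str, float, float]]:
    pos: dict[str, np.ndarray] = {}
    for label, az in _RING:
        pos[label] = np.asarray(spherical_to_cartesian(72.0, az))
    for label, (th, ph) in _MIDLINE.items():
        pos[label] = np.asarray(spherical_to_cartesian(th, ph))
    pos["AFz"] = np.asarray(spherical_to_cartesian(54.0, 90.0))
    pos["Fpz"] = np.asarray(spherical_to_cartesian(72.0, 90.0))
    for label, (th, ph) in _LOWER.items():
        pos[label] = np.asarray(spherical_to_cartesian(th, ph))
    for mid, left, right, inner_l, inner_r in _ROWS.values():
        for anchors, inner in (((mid, left), inner_l), ((mid, right), inner_r)):
            a, b = pos[anchors[0]], pos[anchors[1]]
            step = 1.0 / (len(inner) + 1)
            for i, label in enumerate(inner, start=1):
                p = _slerp(a, b, i * step)
                pos[label] = p / np.linalg.norm(p)

    order = (
        ["Fp1", "Fp2", "AF7", "AF3", "AF4", "AF8"]
        + ["F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8"]
        + ["FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10"]
        + ["T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8"]
        + ["TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10"]
        + ["P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8"]
        + ["PO9", "PO7", "PO3", "POz", "PO4", "PO8", "PO10"]
        + ["O1", "Oz", "O2"]
    )
    table = []
    for label in order:
        th, ph = cartesian_to_spherical(*pos[label])
        table.append((label, th, ph))
    return table


#: Channels recorded by the 64-channel cap; the online reference FCz is
#: recovered during re-referencing, giving the 65-electrode analysis montage.
REFERENCE_CHANNEL = "FCz"


def build_default_layout() -> ElectrodeLayout:
    """Deterministic 65-electrode montage (64 recorded + reference FCz).

    Positions are an idealized extended 10-20 arrangement on the unit
    sphere: the outer ring at polar angle 72 deg in 18 deg azimuth steps,
    the sagittal midline in 18 deg steps, interior rows evenly spaced along
    great-circle arcs between midline and ring, and the 9/10 electrodes on
    the equator.
    """
    table = _default_angle_table()
    labels = [t[0] for t in table]
    theta = [t[1] for t in table]
    phi = [t[2] for t in table]
    return ElectrodeLayout.from_angles(labels, theta, phi)


def recorded_labels(layout: ElectrodeLayout) -> list[str]:
    """The 64 cap channels (montage minus the online reference)."""
    return [lab for lab in layout.labels if lab != REFERENCE_CHANNEL]


def nearest_neighbors(layout: ElectrodeLayout, k: int = 4) -> NeighborGraph:
    """k nearest neighbors per electrode by great-circle distance.

    Ties in distance are broken by label order (ascending index).
    """
    n = len(layout)
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must lie in [1, {n - 1}], got {k}")
    pos = layout.positions
    dots = np.clip(pos @ pos.T, -1.0, 1.0)
    dist = np.arccos(dots)
    np.fill_diagonal(dist, np.inf)
    # stable argsort => ties broken by index (= label) order
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    d = np.take_along_axis(dist, order, axis=1)
    return NeighborGraph(k=k, neighbors=order, distances=d)


def read_montage(path_or_buf) -> ElectrodeLayout:
    """Read a montage from delimited text with columns label, theta_deg, phi_deg."""
    df = pd.read_csv(path_or_buf, sep=None, engine="python")
    required = {"label", "theta_deg", "phi_deg"}
    if not required.issubset(df.columns):
        raise ValueError(f"montage file must have columns {sorted(required)}")
    if df["label"].duplicated().any():
        dups = df.loc[df["label"].duplicated(), "label"].tolist()
        raise ValueError(f"duplicate electrode labels: {dups}")
    return ElectrodeLayout.from_angles(
        df["label"].tolist(), df["theta_deg"].to_numpy(), df["phi_deg"].to_numpy()
    )


def write_montage(layout: ElectrodeLayout, path) -> None:
    layout.to_frame()[["label", "theta_deg", "phi_deg"]].to_csv(
        path, sep="\t", index=False
    )
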