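"""Re-referencing: average reference and REST (infinity) reference.

The REST estimator (reference electrode standardization technique)
re-references scalp EEG to a point at infinity by passing the data through
a volume-conductor model: with G the lead field of a dense equivalent
source layer referenced at infinity and G_avg its average-referenced
counterpart, the infinity-referenced data are estimated as

    V_rest = G @ pinv(G_avg) @ V_avg.

The volume conductor is the classical three-concentric-sphere head (brain,
skull, scalp). The forward solution is the analytic Legendre series: per
spherical-harmonic degree n the layered boundary conditions (potential and
radial current continuity at the brain/skull and skull/scalp interfaces, no
current through the scalp) give a 5x5 linear system whose solution yields
the scalp potential coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EEGRecording
from .montage import LabelingError, electrode_positions, normalize_labels

__all__ = [
    "HeadModel",
    "average_reference",
    "linked_mastoid_reference",
    "build_head_model",
    "rest_reference",
]


class NumericalConditioningError(RuntimeError):
    """The average-referenced lead field is too ill-conditioned to invert."""


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous mean across channels from every channel."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return EEGRecording(data, rec.fs, list(rec.labels), reference="average")


def linked_mastoid_reference(rec: EEGRecording, mastoids=("A1", "A2")) -> EEGRecording:
    """Re-reference to the mean of the two mastoid channels (utility; not on
    the analysis path, which assumes average-referenced input)."""
    labels = normalize_labels(mastoids)
    missing = [m for m in labels if m not in rec.labels]
    if missing:
        raise LabelingError(f"mastoid channels not in recording: {missing}")
    idx = [rec.labels.index(m) for m in labels]
    ref = rec.data[idx].mean(axis=0, keepdims=True)
    return EEGRecording(
        rec.data - ref, rec.fs, list(rec.labels), reference="linked-mastoid"
    )


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately evenly distributed unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


@dataclass
class HeadModel:
    """Three-shell spherical volume conductor with a radial source layer.

    ``radii`` are the outer radii of brain, skull and scalp shells (scalp
    normalized to 1); ``conductivities`` the relative shell conductivities;
    ``source_positions`` the unit-direction vectors of the radial dipoles at
    ``source_radius``; ``lead_field`` the (n_electrodes x n_sources)
    infinity-referenced scalp potentials.
    """

    labels: list[str]
    electrode_pos: np.ndarray
    radii: tuple[float, float, float]
    conductivities: tuple[float, float, float]
    source_positions: np.ndarray
    source_radius: float
    lead_field: np.ndarray

    def __post_init__(self):
        r_brain, r_skull, r_scalp = self.radii
        if not (0 < r_brain < r_skull < r_scalp):
            raise ValueError("radii must increase: brain < skull < scalp")
        if any(c <= 0 for c in self.conductivities):
            raise ValueError("conductivities must be positive")
        if not (0 < self.source_radius < r_brain):
            raise ValueError("source layer must lie strictly inside the brain shell")


def _scalp_series_coefficients(radii, sigmas, b, n_terms) -> np.ndarray:
    """Per-degree scalp potential coefficients t_n for a unit radial dipole
    at eccentricity ``b``: V(e) = sum_n t_n P_n(cos gamma).

    Solves, for each degree n, the 5x5 layered-sphere boundary-value system
    in the unknown harmonic coefficients (A1; A2, B2; A3, B3).
    """
    r1, r2, r3 = radii
    s1, s2, s3 = sigmas
    t = np.zeros(n_terms + 1)
    for n in range(1, n_terms + 1):
        c_n = n * b ** (n - 1) / (4 * np.pi * s1)  # primary (source) term
        A = np.zeros((5, 5))
        rhs = np.zeros(5)
        # potential continuity at brain/skull boundary r1
        A[0] = [r1**n, -(r1**n), -(r1 ** -(n + 1)), 0, 0]
        rhs[0] = -c_n * r1 ** -(n + 1)
        # radial current continuity at r1
        A[1] = [
            s1 * n * r1 ** (n - 1),
            -s2 * n * r1 ** (n - 1),
            s2 * (n + 1) * r1 ** -(n + 2),
            0,
            0,
        ]
        rhs[1] = s1 * (n + 1) * c_n * r1 ** -(n + 2)
        # potential continuity at skull/scalp boundary r2
        A[2] = [0, r2**n, r2 ** -(n + 1), -(r2**n), -(r2 ** -(n + 1))]
        # radial current continuity at r2
        A[3] = [
            0,
            s2 * n * r2 ** (n - 1),
            -s2 * (n + 1) * r2 ** -(n + 2),
            -s3 * n * r2 ** (n - 1),
            s3 * (n + 1) * r2 ** -(n + 2),
        ]
        # insulating outer surface at r3
        A[4] = [0, 0, 0, n * r3 ** (n - 1), -(n + 1) * r3 ** -(n + 2)]
        sol = np.linalg.solve(A, rhs)
        A3, B3 = sol[3], sol[4]
        t[n] = A3 * r3**n + B3 * r3 ** -(n + 1)
    return t


def _legendre_sum(coef: np.ndarray, x: np.ndarray) -> np.ndarray:
    """sum_n coef[n] P_n(x), evaluated by the three-term recurrence."""
    p_prev = np.ones_like(x)  # P_0
    p_curr = x.copy()  # P_1
    acc = coef[0] * p_prev + coef[1] * p_curr
    for n in range(1, len(coef) - 1):
        p_next = ((2 * n + 1) * x * p_curr - n * p_prev) / (n + 1)
        acc += coef[n + 1] * p_next
        p_prev, p_curr = p_curr, p_next
    return acc


def build_head_model(
    labels,
    radii=(0.87, 0.92, 1.0),
    conductivities=(1.0, 0.0125, 1.0),
    n_sources: int = 300,
    source_radius: float = 0.86,
    n_terms: int = 80,
) -> HeadModel:
    """Construct the spherical head model and its lead field.

    Defaults: relative radii 0.87/0.92/1.0, relative conductivities
    1/0.0125/1 (standard skull attenuation), 300 radial dipoles evenly
    spread at radius 0.86. The series is truncated at ``n_terms`` Legendre
    degrees (the terms decay like (source_radius)^n).
    """
    labels = normalize_labels(labels)
    elec = electrode_positions(labels)  # raises LabelingError for unknowns
    src = _fibonacci_sphere(n_sources)
    t = _scalp_series_coefficients(radii, conductivities, source_radius, n_terms)
    cosg = np.clip(elec @ src.T, -1.0, 1.0)
    lead = _legendre_sum(t, cosg)
    return HeadModel(
        labels=labels,
        electrode_pos=elec,
        radii=tuple(radii),
        conductivities=tuple(conductivities),
        source_positions=src,
        source_radius=source_radius,
        lead_field=lead,
    )


def _truncated_pinv(mat: np.ndarray, rtol: float) -> np.ndarray:
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    keep = s > rtol * s[0]
    if keep.sum() < min(mat.shape) - 1:
        raise NumericalConditioningError(
            f"average-referenced lead field rank {int(keep.sum())} "
            f"(expected {min(mat.shape) - 1}); model is degenerate"
        )
    return (vt[keep].T / s[keep]) @ u[:, keep].T


def rest_transform(model: HeadModel, rtol: float = 1e-6) -> np.ndarray:
    """The (n_channels x n_channels) matrix mapping average-referenced data
    to the REST (infinity-reference) estimate."""
    G = model.lead_field
    G_avg = G - G.mean(axis=0, keepdims=True)
    return G @ _truncated_pinv(G_avg, rtol)


def rest_reference(rec: EEGRecording, model: HeadModel, rtol: float = 1e-6
                   ) -> EEGRecording:
    """Re-reference a recording to infinity with the REST estimator.

    The recording is average-referenced first if it is not already; the
    model's electrodes must match the recording's labels.
    """
    if model.labels != rec.labels:
        if sorted(model.labels) == sorted(rec.labels):
            rec = rec.pick(model.labels)
        else:
            raise LabelingError(
                f"model/recording channel mismatch: "
                f"{sorted(set(model.labels) ^ set(rec.labels))}"
            )
    if rec.reference != "average":
        rec = average_reference(rec)
    data = rest_transform(model, rtol) @ rec.data
    return EEGRecording(data, rec.fs, list(rec.labels), reference="REST")
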