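"""Scalp electrode nomenclature and geometry for the 10-20 system.

The analysis uses the legacy temporal-chain names (T3/T4/T5/T6) internally;
modern 10-10 equivalents (T7/T8/P7/P8) are mapped onto them on input.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)


class LabelingError(ValueError):
    """Channel labels cannot be resolved or collide after normalization."""


#: canonical 19-channel 10-20 montage, in conventional anterior-to-posterior order
CHANNELS_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

# extra names we recognize without warning (references, midline extensions)
_EXTRA_KNOWN = ("A1", "A2", "Fpz", "Oz", "M1", "M2")

#: modern 10-10 name -> legacy 10-20 name used throughout this package
MODERN_TO_LEGACY = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}

_CANONICAL = {name.lower(): name for name in CHANNELS_1020 + _EXTRA_KNOWN}
_CANONICAL.update({k.lower(): v for k, v in MODERN_TO_LEGACY.items()})


FRONTAL_ELECTRODES = frozenset({"Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz"})
TEMPORAL_ELECTRODES = frozenset({"T3", "T4", "T5", "T6"})


class LobeMap:
    """Frontal and temporal electrode sets used for lobar averaging.

    Defaults follow the 10-20 convention: frontal = {Fp1, Fp2, F3, F4, F7,
    F8, Fz}, temporal = {T3, T4, T5, T6}.
    """

    def __init__(self, frontal=FRONTAL_ELECTRODES, temporal=TEMPORAL_ELECTRODES):
        frontal = frozenset(frontal)
        temporal = frozenset(temporal)
        if frontal & temporal:
            raise ValueError(
                f"frontal and temporal sets overlap: {sorted(frontal & temporal)}"
            )
        self.frontal = frontal
        self.temporal = temporal

    def lobe_of(self, label: str) -> str:
        """Return 'F', 'T' or 'other' for a channel label."""
        if label in self.frontal:
            return "F"
        if label in self.temporal:
            return "T"
        return "other"

    def electrodes(self, lobe: str):
        if lobe == "F":
            return sorted(self.frontal)
        if lobe == "T":
            return sorted(self.temporal)
        raise ValueError(f"unknown lobe {lobe!r}; expected 'F' or 'T'")

    def __repr__(self):  # pragma: no cover
        return f"LobeMap(frontal={sorted(self.frontal)}, temporal={sorted(self.temporal)})"


def normalize_label(label: str) -> str:
    key = label.strip().lower()
    if key in _CANONICAL:
        return _CANONICAL[key]
    logger.warning("unrecognized channel label %r passed through unchanged", label)
    return label.strip()


def normalize_labels(labels) -> list[str]:
    """Normalize channel names to canonical legacy 10-20 spelling.

    Case-insensitive; T7/T8/P7/P8 map to T3/T4/T5/T6. Unknown labels pass
    through (with a logged warning). Raises :class:`LabelingError` if two
    inputs collide on the same canonical name.
    """
    out = [normalize_label(lab) for lab in labels]
    seen: dict[str, str] = {}
    for orig, canon in zip(labels, out):
        if canon in seen:
            raise LabelingError(
                f"labels {seen[canon]!r} and {orig!r} both normalize to {canon!r}"
            )
        seen[canon] = orig
    return out


def electrode_positions(labels) -> np.ndarray:
    """Unit-sphere positions (n_channels, 3) for 10-20 labels.

    Positions come from the standard 10-20 spherical layout (via mne's
    ``standard_1020`` montage), re-centered and projected onto the unit
    sphere — adequate for a concentric-sphere volume conductor.
    """
    import warnings

    import mne

    with warnings.catch_warnings():
        # montage naming is in flux across mne versions; the layout is stable
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1020")
    pos_map = montage.get_positions()["ch_pos"]
    lookup = {k.lower(): np.asarray(v, float) for k, v in pos_map.items()}
    legacy_to_modern = {v: k for k, v in MODERN_TO_LEGACY.items()}

    raw = []
    for lab in labels:
        canon = normalize_label(lab)
        key = legacy_to_modern.get(canon, canon).lower()
        if key not in lookup:
            raise LabelingError(f"no standard 10-20 position for channel {lab!r}")
        raw.append(lookup[key])
    pos = np.array(raw)

    # the montage's head frame has its origin near the sphere center;
    # radial projection onto the unit sphere
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return pos
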