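"""Schematic 34-channel EEG montage (32 scalp + HEOG/VEOG).

The montage is deliberately schematic: the pipeline only relies on
left/right mirror symmetry and smooth spatial neighbourhood structure,
not on true electrode coordinates.  Positions are unitless 2-D
coordinates with x < 0 on the left hemisphere and y increasing toward
the front; every left-hemisphere scalp channel has an exact mirror
partner at (-x, y), midline channels are their own mirror.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

SCALP = "scalp"
HEOG = "heog"
VEOG = "veog"

# 10-20 style names chosen so the posterior-lateral pair PO7/PO8 used for
# the N2pc difference waveform is present.  (x, y) schematic positions.
_SCALP_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.30, 0.95), "Fp2": (0.30, 0.95),
    "F7": (-0.80, 0.60), "F3": (-0.40, 0.60), "Fz": (0.00, 0.60),
    "F4": (0.40, 0.60), "F8": (0.80, 0.60),
    "FC5": (-0.70, 0.30), "FC1": (-0.25, 0.30),
    "FC2": (0.25, 0.30), "FC6": (0.70, 0.30),
    "T7": (-1.00, 0.00), "C3": (-0.50, 0.00), "Cz": (0.00, 0.00),
    "C4": (0.50, 0.00), "T8": (1.00, 0.00),
    "CP5": (-0.70, -0.30), "CP1": (-0.25, -0.30),
    "CP2": (0.25, -0.30), "CP6": (0.70, -0.30),
    "P7": (-0.80, -0.60), "P3": (-0.40, -0.60), "Pz": (0.00, -0.60),
    "P4": (0.40, -0.60), "P8": (0.80, -0.60),
    "PO7": (-0.65, -0.80), "PO3": (-0.30, -0.80), "POz": (0.00, -0.80),
    "PO4": (0.30, -0.80), "PO8": (0.65, -0.80),
    "O1": (-0.30, -0.95), "O2": (0.30, -0.95),
}
_EOG_POSITIONS = {"HEOG": (1.30, 0.90), "VEOG": (0.00, 1.25)}


@dataclass(frozen=True)
class ChannelMontage:
    """Channel names, schematic positions and role flags.

    Parameters
    ----------
    names
        Channel names in data order (scalp channels first by convention).
    positions
        Mapping name -> (x, y) schematic position.
    roles
        Mapping name -> one of ``"scalp"``, ``"heog"``, ``"veog"``.
    """

    names: tuple[str, ...]
    positions: dict[str, tuple[float, float]]
    roles: dict[str, str]
    _mirror: dict[str, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ConfigurationError("channel names must be unique")
        for name in self.names:
            if name not in self.positions or name not in self.roles:
                raise ConfigurationError(f"channel {name!r} lacks position/role")
        mirror: dict[str, str] = {}
        by_pos = {
            (round(x, 6), round(y, 6)): n
            for n, (x, y) in self.positions.items()
            if self.roles[n] == SCALP
        }
        for name in self.scalp_channels:
            x, y = self.positions[name]
            partner = by_pos.get((round(-x, 6), round(y, 6)))
            if partner is None:
                raise ConfigurationError(
                    f"scalp channel {name!r} has no mirror partner"
                )
            mirror[name] = partner
        # EOG channels map to themselves under the mirror.
        for name in self.names:
            if self.roles[name] != SCALP:
                mirror[name] = name
        object.__setattr__(self, "_mirror", mirror)

    @property
    def scalp_channels(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if self.roles[n] == SCALP)

    @property
    def n_scalp(self) -> int:
        return len(self.scalp_channels)

    @property
    def scalp_indices(self) -> np.ndarray:
        return np.array(
            [i for i, n in enumerate(self.names) if self.roles[n] == SCALP]
        )

    def channels_with_role(self, role: str) -> tuple[str, ...]:
        return tuple(n for n in self.names if self.roles[n] == role)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def mirror(self, name: str) -> str:
        """Return the left/right mirror partner of a channel."""
        return self._mirror[name]

    def mirror_permutation(self) -> np.ndarray:
        """Index permutation mapping each channel to its mirror partner.

        ``data[..., perm, :]`` swaps left and right hemispheres.
        """
        return np.array([self.index(self._mirror[n]) for n in self.names])

    def scalp_mirror_permutation(self) -> np.ndarray:
        """Mirror permutation restricted to (and indexed within) scalp channels."""
        scalp = self.scalp_channels
        return np.array([scalp.index(self._mirror[n]) for n in scalp])

    def position_array(self) -> np.ndarray:
        """(n_channels, 2) array of schematic positions in data order."""
        return np.array([self.positions[n] for n in self.names], dtype=float)


def default_montage() -> ChannelMontage:
    """The standard 32-scalp + HEOG/VEOG schematic montage."""
    names = tuple(_SCALP_POSITIONS) + tuple(_EOG_POSITIONS)
    positions = {**_SCALP_POSITIONS, **_EOG_POSITIONS}
    roles = {n: SCALP for n in _SCALP_POSITIONS}
    roles["HEOG"] = HEOG
    roles["VEOG"] = VEOG
    return ChannelMontage(names=names, positions=positions, roles=roles)
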