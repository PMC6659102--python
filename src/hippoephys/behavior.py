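"""Three-chamber social scores and open-field locomotion metrics.

The three-chamber assay scores sociability as (time investigating the novel
mouse) - (time investigating the novel object), and social novelty as (time
with the novel mouse) - (time with the familiar mouse), both over a 10-min
session. Investigation times are consumed as tracker outputs, not recomputed
from positions.

The open field is a 60 x 60 cm arena tiled by 12-cm blocks; the inner zone is
the central 3 x 3 blocks and the outer zone the 16 perimeter blocks. (A
60-cm side forces a 5 x 5 = 25-block tiling, hence 16 perimeter blocks even
though descriptions of the assay sometimes quote 12; the inner/outer
classification is unaffected.) Ambulatory distance is the path integral of
the track and velocity its time average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DataError, ParameterError

__all__ = [
    "ChamberSession",
    "OpenFieldTrack",
    "sociability_score",
    "novelty_score",
    "open_field_metrics",
]

ARENA_CM = 60.0
BLOCK_CM = 12.0
SESSION_LENGTH_S = 600.0


@dataclass(frozen=True)
class ChamberSession:
    """One animal-phase of the three-chamber test.

    For ``phase="sociability"`` the compartment times are (mouse, object);
    for ``phase="novelty"`` they are (novel, familiar).
    """

    phase: str
    time_a_s: float  # mouse (sociability) or novel (novelty)
    time_b_s: float  # object (sociability) or familiar (novelty)
    session_length_s: float = SESSION_LENGTH_S
    animal_id: str = ""

    def __post_init__(self) -> None:
        if self.phase not in ("sociability", "novelty"):
            raise ParameterError(f"unknown phase {self.phase!r}")
        if self.time_a_s < 0 or self.time_b_s < 0:
            raise DataError("compartment times must be >= 0")
        if self.time_a_s + self.time_b_s > self.session_length_s + 1e-9:
            raise DataError("compartment times exceed session length")


@dataclass(frozen=True)
class OpenFieldTrack:
    """Tracked positions (cm) at a fixed sampling rate in the 60 x 60 arena."""

    positions: np.ndarray  # (n, 2) in cm
    sampling_rate: float  # Hz

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.float64)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 2:
            raise DataError("positions must be an (n>=2, 2) array")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be > 0")
        if np.any(pos < -1e-9) or np.any(pos > ARENA_CM + 1e-9):
            raise DataError("positions outside the 60 x 60 cm arena")

    @property
    def duration_s(self) -> float:
        return self.positions.shape[0] / self.sampling_rate


def sociability_score(session: ChamberSession) -> float:
    """Seconds: investigation of the novel mouse minus the novel object."""
    if session.phase != "sociability":
        raise ParameterError(f"expected sociability phase, got {session.phase!r}")
    return session.time_a_s - session.time_b_s


def novelty_score(session: ChamberSession) -> float:
    """Seconds: investigation of the novel minus the familiar mouse."""
    if session.phase != "novelty":
        raise ParameterError(f"expected novelty phase, got {session.phase!r}")
    return session.time_a_s - session.time_b_s


def open_field_metrics(track: OpenFieldTrack) -> dict[str, float]:
    """Distance (m), velocity (mm/s), and inner/outer zone occupancy (s)."""
    pos = track.positions
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)  # cm
    distance_m = float(steps.sum() / 100.0)
    duration = track.duration_s
    velocity_mm_s = distance_m * 1000.0 / duration
    # inner zone: central 3x3 of the 5x5 block grid, i.e. 12 cm <= coord < 48 cm
    lo, hi = BLOCK_CM, ARENA_CM - BLOCK_CM
    inner = (
        (pos[:, 0] >= lo) & (pos[:, 0] < hi) & (pos[:, 1] >= lo) & (pos[:, 1] < hi)
    )
    dt = 1.0 / track.sampling_rate
    inner_s = float(inner.sum() * dt)
    return {
        "distance_m": distance_m,
        "velocity_mm_s": velocity_mm_s,
        "inner_s": inner_s,
        "outer_s": duration - inner_s,
        "duration_s": duration,
    }
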