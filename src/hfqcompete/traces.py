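"""Per-molecule intensity time series and the two-colour excitation scheme.

A competition movie records a Cy3-labelled resident sRNA and Cy5-labelled
competitors at the same immobilised Hfq.  The first second and the last
second of the movie excite both dyes every frame; in between, the lasers
alternate (green on even frames, red on odd frames) so each channel is
sampled every other frame -- an effective 0.2 s resolution per channel --
which limits photobleaching over the 5 min observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["IntensityTrace", "alternating_excitation", "traces_to_frame", "frame_to_traces"]


def alternating_excitation(n_frames: int, n_both_start: int = 10, n_both_end: int = 10) -> dict[str, np.ndarray]:
    """Per-frame excitation masks for the standard acquisition scheme.

    Both lasers are on for the first ``n_both_start`` and last ``n_both_end``
    frames; in between Cy3 is excited on even frames and Cy5 on odd frames.

    Returns a dict ``{"cy3": bool[n_frames], "cy5": bool[n_frames]}``.
    """
    if n_frames < n_both_start + n_both_end:
        raise ValueError("movie shorter than the two both-excited segments")
    frames = np.arange(n_frames)
    middle = (frames >= n_both_start) & (frames < n_frames - n_both_end)
    cy3 = ~middle | (frames % 2 == 0)
    cy5 = ~middle | (frames % 2 == 1)
    return {"cy3": cy3, "cy5": cy5}


@dataclass
class IntensityTrace:
    """Integrated intensity of one AOI in one channel over a whole movie.

    Attributes
    ----------
    molecule_id : identifier of the AOI / molecule.
    channel : ``"cy3"`` (resident) or ``"cy5"`` (competitor).
    intensity : per-frame integrated intensity, arbitrary units, length
        equals the number of movie frames.
    excited : per-frame boolean mask; the channel's dye is excited on these
        frames only, so binding analysis uses this sub-grid.
    frame_interval : seconds per frame.
    """

    molecule_id: str
    channel: str
    intensity: np.ndarray
    excited: np.ndarray
    frame_interval: float = 0.1

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.excited = np.asarray(self.excited, dtype=bool)
        if self.intensity.shape != self.excited.shape:
            raise ValueError("intensity and excitation mask lengths differ")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.intensity.size

    @property
    def duration(self) -> float:
        """Movie length in seconds."""
        return self.n_frames * self.frame_interval

    @property
    def times(self) -> np.ndarray:
        """Start time of each frame, seconds (frame f covers [f*dt, (f+1)*dt))."""
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def excited_frames(self) -> np.ndarray:
        """Indices of the frames on which this channel is excited."""
        return np.flatnonzero(self.excited)


def traces_to_frame(traces: list[IntensityTrace]) -> pd.DataFrame:
    """Long-format table (molecule_id, frame, time_s, channel, intensity, excited)."""
    parts = []
    for tr in traces:
        parts.append(
            pd.DataFrame(
                {
                    "molecule_id": tr.molecule_id,
                    "frame": np.arange(tr.n_frames),
                    "time_s": tr.times,
                    "channel": tr.channel,
                    "intensity": tr.intensity,
                    "excited": tr.excited,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def frame_to_traces(df: pd.DataFrame, frame_interval: float | None = None) -> list[IntensityTrace]:
    """Inverse of :func:`traces_to_frame`."""
    out: list[IntensityTrace] = []
    for (mol, channel), grp in df.groupby(["molecule_id", "channel"], sort=False):
        grp = grp.sort_values("frame")
        dt = frame_interval
        if dt is None:
            t = grp["time_s"].to_numpy()
            dt = float(t[1] - t[0]) if t.size > 1 else 0.1
        out.append(
            IntensityTrace(
                molecule_id=str(mol),
                channel=str(channel),
                intensity=grp["intensity"].to_numpy(dtype=float),
                excited=grp["excited"].to_numpy(dtype=bool),
                frame_interval=dt,
            )
        )
    return out
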