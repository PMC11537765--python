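"""Trajectory container shared by the deterministic and stochastic engines."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import TransferEvent

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Time series of (N, I0, Im) plus any recorded transfer events.

    ``event_states`` holds, for each applied jump epoch, the (I0, Im) pair
    immediately before and after the jump — used to verify that transfer
    conserves the introduced total.
    """

    times: np.ndarray
    N: np.ndarray
    I0: np.ndarray
    Im: np.ndarray
    events: list[TransferEvent] = field(default_factory=list)
    event_states: list[tuple[float, float, float, float]] = field(default_factory=list)
    seed: int | None = None
    extinct: dict = field(default_factory=dict)

    @property
    def I_total(self) -> np.ndarray:
        """Total introduced population I = I0 + Im."""
        return self.I0 + self.Im

    @property
    def state(self) -> np.ndarray:
        """(n_times, 3) array of [N, I0, Im]."""
        return np.column_stack([self.N, self.I0, self.Im])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "N": self.N, "I0": self.I0, "Im": self.Im})

    def to_csv(self, path) -> None:
        """Tidy CSV with columns t, N, I0, Im at full round-trip precision."""
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    def events_to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.t, e.channel, e.count) for e in self.events],
            columns=["t", "channel", "count"],
        )

    def events_to_csv(self, path) -> None:
        self.events_to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(
            times=df["t"].to_numpy(),
            N=df["N"].to_numpy(),
            I0=df["I0"].to_numpy(),
            Im=df["Im"].to_numpy(),
        )
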