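"""Piecewise demographic histories for the one-population diffusion engine.

Sizes are relative to the ancestral (reference) size ``N_anc`` and durations
are in units of ``2 N_anc`` generations, the natural time scale of the
diffusion.  A history is an ordered list of epochs, each either constant size
or exponential interpolation between a start and end size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["Epoch", "EpochModel", "default_european_demography"]

_MODES = ("constant", "exponential")


@dataclass(frozen=True)
class Epoch:
    """One epoch: relative sizes ``nu = N/N_anc`` and duration (2*N_anc gens)."""

    nu_start: float
    duration: float
    mode: str = "constant"
    nu_end: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.nu_start <= 0:
            raise ValueError("relative size nu must be positive")
        if self.duration < 0:
            raise ValueError("epoch duration must be non-negative")
        if self.mode == "exponential":
            if self.nu_end is None or self.nu_end <= 0:
                raise ValueError("exponential epoch needs a positive nu_end")
        elif self.nu_end is None:
            object.__setattr__(self, "nu_end", self.nu_start)

    def nu_at(self, tau: float) -> float:
        """Relative size a time ``tau`` into the epoch."""
        if self.mode == "constant" or self.duration == 0:
            return self.nu_start
        frac = min(max(tau / self.duration, 0.0), 1.0)
        return self.nu_start * (self.nu_end / self.nu_start) ** frac


@dataclass
class EpochModel:
    """Ordered epochs after the ancestral equilibrium, oldest first."""

    epochs: list[Epoch] = field(default_factory=list)
    N_anc: float | None = None

    @property
    def total_duration(self) -> float:
        return float(sum(e.duration for e in self.epochs))

    def is_equilibrium(self) -> bool:
        """True when the history never departs from the ancestral size."""
        return all(
            e.nu_start == 1.0 and e.nu_end == 1.0 for e in self.epochs
        )

    def as_array(self) -> np.ndarray:
        """(n_epochs, 4) float array: nu_start, nu_end, duration, exponential?"""
        rows = [
            (e.nu_start, e.nu_end, e.duration, 1.0 if e.mode == "exponential" else 0.0)
            for e in self.epochs
            if e.duration > 0
        ]
        if not rows:
            return np.zeros((0, 4))
        return np.array(rows, dtype=float)

    def key(self) -> tuple:
        """Hashable identity used for cache lookup."""
        return tuple(
            (e.nu_start, e.nu_end, e.duration, e.mode) for e in self.epochs
        )

    def to_yaml(self, path) -> None:
        data = {
            "N_anc": self.N_anc,
            "epochs": [
                {
                    "nu_start": e.nu_start,
                    "nu_end": e.nu_end,
                    "duration": e.duration,
                    "mode": e.mode,
                }
                for e in self.epochs
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "EpochModel":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        epochs = [
            Epoch(
                nu_start=d["nu_start"],
                duration=d["duration"],
                mode=d.get("mode", "constant"),
                nu_end=d.get("nu_end"),
            )
            for d in data.get("epochs", [])
        ]
        return cls(epochs=epochs, N_anc=data.get("N_anc"))


def default_european_demography(N_anc: float | None = 10_000.0) -> EpochModel:
    """Three-epoch out-of-Africa style European history.

    Bottleneck, recovery at the ancestral size, then recent exponential
    growth.  The sizes and times are round numbers of the magnitude inferred
    for European-ancestry samples; they serve as the default generating model
    for synthetic spectra (the real-data maximum-likelihood values are fit
    from a synonymous SFS, not assumed).
    """
    return EpochModel(
        epochs=[
            Epoch(nu_start=0.15, duration=0.05),
            Epoch(nu_start=1.0, duration=0.04),
            Epoch(nu_start=1.0, nu_end=25.0, duration=0.012, mode="exponential"),
        ],
        N_anc=N_anc,
    )
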