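"""Non-equidistant discretization of the m/z axis.

Two measured masses can never be compared for exact equality, so the m/z
range covered by training and query spectra is cut into bins whose widths
grow with m/z following the instrument's error model: each bin spans twice
the combined absolute (mzabs, Da) and relative (mzppm, ppm of the bin's
lower boundary) mass deviation. A mass is represented by the central value
of its bin; two masses are equal iff they discretize to the same center.
The same binning serves fragment peaks and neutral losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MassBinning", "build_binning", "discretize"]


@dataclass(frozen=True)
class MassBinning:
    b0: float
    mzabs: float
    mzppm: float
    boundaries: np.ndarray = field(repr=False)  # ascending, half-open [b_i, b_{i+1})

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        object.__setattr__(self, "boundaries", b)
        if b[0] != self.b0 or np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must start at b0 and be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.boundaries) - 1

    def centers(self) -> np.ndarray:
        return 0.5 * (self.boundaries[:-1] + self.boundaries[1:])

    def covers(self, m: float) -> bool:
        return self.boundaries[0] <= m < self.boundaries[-1]

    def to_dict(self) -> dict:
        return {"b0": self.b0, "mzabs": self.mzabs, "mzppm": self.mzppm,
                "max_mass": float(self.boundaries[-1])}

    @classmethod
    def from_dict(cls, d: dict) -> "MassBinning":
        # rebuild from the recurrence; bit-identical because the construction
        # is deterministic in (b0, mzabs, mzppm, max_mass)
        return build_binning(d["b0"], d["max_mass"], d["mzabs"], d["mzppm"],
                             _exclusive_max=True)


def build_binning(min_mass: float, max_mass: float, mzabs: float, mzppm: float,
                  *, _exclusive_max: bool = False) -> MassBinning:
    """Generate bin boundaries b_{i+1} = b_i + 2*(b_i*mzppm/1e6 + mzabs)
    from ``min_mass`` until ``max_mass`` is covered."""
    if not 0 < min_mass < max_mass:
        raise ValueError("need 0 < min_mass < max_mass")
    if mzabs < 0 or mzppm < 0:
        raise ValueError("tolerances must be non-negative")
    if mzabs == 0 and mzppm == 0:
        raise ValueError("mzabs and mzppm cannot both be zero (zero-width bins)")
    bounds = [float(min_mass)]
    # strict < on reload (max_mass is then itself the stored last boundary)
    while (bounds[-1] < max_mass) if _exclusive_max else (bounds[-1] <= max_mass):
        b = bounds[-1]
        bounds.append(b + 2.0 * (b * mzppm / 1e6 + mzabs))
    return MassBinning(b0=float(min_mass), mzabs=mzabs, mzppm=mzppm,
                       boundaries=np.array(bounds))


def discretize(m: float, binning: MassBinning) -> float:
    """Map a mass to the central value of its (half-open) bin."""
    b = binning.boundaries
    if not b[0] <= m < b[-1]:
        raise ValueError(f"mass {m} outside binned range [{b[0]}, {b[-1]})")
    i = int(np.searchsorted(b, m, side="right")) - 1
    return float(0.5 * (b[i] + b[i + 1]))
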