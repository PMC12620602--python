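"""Stepwise isolation-window acquisition schedules.

The acquisition sweeps a narrow isolation window across a targeted nominal
mass x: fragmentation events start at (x + start_offset), move in uniform
``step`` increments and stop at (x + end_offset). With the default offsets
(-0.7, +0.9) and a 0.02 Th step this yields 81 fragmentation events per
measurement cycle.

The event count is always derived arithmetically as
``floor((end_offset - start_offset) / step) + 1`` with the final center
clipped to the end offset; offsets for non-default window widths are plain
configuration values, never derived from the width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScanPlan", "build_plan", "centers", "PlanValidationError"]

# guard against float rounding in (end-start)/step when the range is an
# exact multiple of the step (e.g. 1.6/0.02)
_REL_EPS = 1e-9


class PlanValidationError(ValueError):
    """Invalid acquisition-plan parameters."""


@dataclass(frozen=True)
class ScanPlan:
    """Stepped isolation-window schedule around one nominal mass.

    Parameters
    ----------
    nominal_mass:
        The isobars' nominal m/z (Th) the sweep is centred on.
    start_offset, end_offset:
        Signed offsets (Th) of the first and last isolation center relative
        to ``nominal_mass``. Defaults -0.7 / +0.9.
    step:
        Centre-to-centre increment between consecutive events (Th),
        default 0.02.
    isolation_width:
        Full isolation-window width (Th), default 1.0.
    nce:
        Collision energy setting carried into each scan (metadata).
    """

    nominal_mass: float
    start_offset: float = -0.7
    end_offset: float = 0.9
    step: float = 0.02
    isolation_width: float = 1.0
    nce: float = 35.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise PlanValidationError(f"step must be > 0, got {self.step}")
        if self.end_offset <= self.start_offset:
            raise PlanValidationError(
                "end_offset must exceed start_offset "
                f"({self.end_offset} <= {self.start_offset})"
            )
        if self.isolation_width <= 0:
            raise PlanValidationError("isolation_width must be > 0")

    @property
    def n_events(self) -> int:
        """Number of fragmentation events in one measurement cycle."""
        span = self.end_offset - self.start_offset
        return int(np.floor(span / self.step + _REL_EPS)) + 1

    def centers(self) -> np.ndarray:
        """Ordered isolation-window centers c_i = x + start_offset + i*step."""
        i = np.arange(self.n_events, dtype=float)
        c = self.nominal_mass + self.start_offset + i * self.step
        # clip the last center to the end offset against float overshoot
        hi = self.nominal_mass + self.end_offset
        c[-1] = min(c[-1], hi)
        return c


def build_plan(
    nominal_mass: float,
    start_offset: float = -0.7,
    end_offset: float = 0.9,
    step: float = 0.02,
    isolation_width: float = 1.0,
    nce: float = 35.0,
) -> ScanPlan:
    """Validate parameters and return a :class:`ScanPlan`."""
    return ScanPlan(
        nominal_mass=nominal_mass,
        start_offset=start_offset,
        end_offset=end_offset,
        step=step,
        isolation_width=isolation_width,
        nce=nce,
    )


def centers(plan: ScanPlan) -> np.ndarray:
    """Ordered isolation centers of ``plan`` (strictly increasing)."""
    return plan.centers()
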