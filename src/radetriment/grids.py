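"""Five-year age-group axis used throughout the pipeline.

Cancer registries publish counts on abridged age axes: contiguous closed
groups of constant width (here 5 years) topped by an open-ended group
(85+ by default).  The open group has no natural midpoint, so a nominal one
is part of the grid definition; mean-age arithmetic needs it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError

#: Observation-window width in years. The rate denominators assume counts are
#: reported per single calendar year; this is a convention, not a parameter.
DELTA_T = 1.0


@dataclass(frozen=True)
class AgeGrid:
    """Contiguous 5-year (by default) age groups with an optional open top.

    Parameters
    ----------
    lower_bounds : tuple of float
        Lower age bound of each group, starting at 0, strictly increasing
        and equally spaced.
    width : float
        Common width ``dA`` of the closed groups, in years.
    open_top : bool
        Whether the last group is open-ended (e.g. "85+").
    top_midpoint : float
        Nominal mean age assigned to the open top group, in years.  Ignored
        for a closed top group.
    """

    lower_bounds: tuple[float, ...] = tuple(float(a) for a in range(0, 90, 5))
    width: float = 5.0
    open_top: bool = True
    top_midpoint: float = 87.5

    def __post_init__(self) -> None:
        lb = np.asarray(self.lower_bounds, dtype=float)
        if lb.size < 2:
            raise DomainError("an age grid needs at least two groups")
        if lb[0] != 0.0:
            raise DomainError("the first age group must start at age 0")
        if self.width <= 0:
            raise DomainError("age-group width must be positive")
        diffs = np.diff(lb)
        if not np.allclose(diffs, self.width, rtol=0, atol=1e-9) or np.any(diffs <= 0):
            raise DomainError(
                "age-group lower bounds must be contiguous with constant width "
                f"{self.width}"
            )
        if self.open_top and self.top_midpoint < lb[-1]:
            raise DomainError("open-top midpoint must lie at or above the top lower bound")

    # -- derived geometry ---------------------------------------------------

    @property
    def m(self) -> int:
        """Number of age groups."""
        return len(self.lower_bounds)

    @property
    def midpoints(self) -> np.ndarray:
        """Mean age of each group (nominal for the open top group)."""
        mids = np.asarray(self.lower_bounds, dtype=float) + self.width / 2.0
        if self.open_top:
            mids[-1] = self.top_midpoint
        return mids

    @property
    def nominal_upper(self) -> float:
        """Nominal upper age bound ``A_m`` of the grid."""
        return self.lower_bounds[-1] + self.width

    def group_of(self, age: float) -> int:
        """1-based index of the group whose half-open interval holds ``age``.

        Intervals are ``[lower, lower + width)``; ages at or above the top
        lower bound map to the top group.
        """
        if age < 0:
            raise DomainError(f"age must be non-negative, got {age}")
        if age >= self.lower_bounds[-1]:
            return self.m
        return int(np.searchsorted(self.lower_bounds, age, side="right"))

    def check_group(self, i: int) -> int:
        """Validate a 1-based group index."""
        if not 1 <= i <= self.m:
            raise DomainError(f"group index {i} outside 1..{self.m}")
        return int(i)
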