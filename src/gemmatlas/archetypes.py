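"""Expression-domain archetypes along the normalized notch axis.

A gemma is profiled along the axis through its two apical notches; positions
are expressed on [0, 1] with the landmarks (start, notch1, notch2, end)
mapped to (0, r, 1 - r, 1).  An archetype is a nonnegative template curve on
that axis describing where a reporter class is active:

``scz-narrow``
    sharp peaks at both notches — activity confined to the stem-cell zone
    and the dividing/differentiating cells around it.
``notch-broad``
    wider notch peaks — activity spreading through the transition zone.
``axis-decay``
    exponential decay away from each notch — peripheral-zone-weighted
    expression that fades toward the gemma center.
``center-peak``
    a broad maximum at the gemma center (central zone).
``flat``
    uniform expression across the gemma.

These templates are the ground truth planted by the synthetic generators and
the reference the clustering/domain-labeling rules are calibrated on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DomainArchetype", "standard_archetypes", "ARCHETYPE_NAMES"]

ARCHETYPE_NAMES = ("scz-narrow", "notch-broad", "axis-decay", "center-peak", "flat")

# default notch landmark on the normalized axis; the second notch sits at 1 - NOTCH
DEFAULT_NOTCH = 0.2


@dataclass(frozen=True)
class DomainArchetype:
    """A nonnegative template curve on the normalized notch axis [0, 1].

    Parameters
    ----------
    name:
        One of :data:`ARCHETYPE_NAMES`.
    peaks:
        Peak position(s) in normalized axis units, each in [0, 1].
    width:
        Gaussian sigma (peaked forms) or exponential decay length
        (``axis-decay``), in axis units; must be positive for non-flat forms.
    baseline:
        Constant floor added to the curve (>= 0).
    """

    name: str
    peaks: tuple[float, ...] = ()
    width: float = 0.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in ARCHETYPE_NAMES:
            raise ValueError(f"unknown archetype name: {self.name!r}")
        for p in self.peaks:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"peak position {p} outside [0, 1]")
        if self.name != "flat" and self.width <= 0:
            raise ValueError("width must be > 0 for non-flat archetypes")
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")

    def __call__(self, x: np.ndarray | float) -> np.ndarray:
        """Evaluate the template at normalized axis positions ``x``.

        Positions outside [0, 1] are clipped to the boundary value, which
        keeps the curve defined for nuclei lying just beyond the start/end
        landmarks of a synthetic image.
        """
        x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
        if self.name == "flat":
            base = 1.0 if self.baseline == 0 else self.baseline
            return np.full_like(x, base)
        y = np.full_like(x, self.baseline)
        for p in self.peaks:
            if self.name == "axis-decay":
                y = y + np.exp(-np.abs(x - p) / self.width)
            else:
                y = y + np.exp(-0.5 * ((x - p) / self.width) ** 2)
        return y


def standard_archetypes(notch: float = DEFAULT_NOTCH) -> dict[str, DomainArchetype]:
    """The five standard archetypes with notches at ``notch`` and ``1 - notch``.

    Widths: 0.03 for the narrow stem-cell-zone peak, 0.10 for the broad notch
    peak, decay length 0.30 for the peripheral-zone form and sigma 0.12 for
    the central-zone peak; all in normalized axis units.
    """
    if not 0.0 < notch < 0.5:
        raise ValueError("notch landmark must lie in (0, 0.5)")
    notches = (notch, 1.0 - notch)
    return {
        "scz-narrow": DomainArchetype("scz-narrow", notches, width=0.03, baseline=0.05),
        "notch-broad": DomainArchetype("notch-broad", notches, width=0.10, baseline=0.05),
        "axis-decay": DomainArchetype("axis-decay", notches, width=0.30),
        "center-peak": DomainArchetype("center-peak", (0.5,), width=0.12, baseline=0.10),
        "flat": DomainArchetype("flat"),
    }
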