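"""Normalization of raw notch-axis profiles into comparable curves.

Raw plot-profiles differ in length, landmark spacing and brightness.  The
normalization pipeline makes them comparable in four fixed steps:

1. ``smooth_profile`` — cubic smoothing spline (default spar = 0.4) to damp
   cell-to-cell signal granularity;
2. ``landmark_align`` — a piecewise-linear axis map sending the measured
   (start, notch1, notch2, end) onto common reference positions on [0, 1],
   followed by linear resampling onto a uniform grid;
3. ``fold_symmetric`` — averaging of the two mirror halves about the axis
   midpoint, removing left/right notch asymmetry;
4. ``normalize_max`` — division by the profile maximum.

The reference landmarks default to the dataset means of the three landmark
segment lengths, symmetrized so the two notches sit at r and 1 - r; they can
be fixed explicitly for reproducibility across datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .imaging import IntensityProfile
from .smoothing import smooth_series

__all__ = [
    "NormalizationConfig",
    "NormalizedProfile",
    "smooth_profile",
    "landmark_align",
    "axis_map",
    "fold_symmetric",
    "normalize_max",
    "normalize_profiles",
    "reference_from_landmarks",
    "profile_matrix_to_csv",
]

DEFAULT_REFERENCE = (0.0, 0.2, 0.8, 1.0)


@dataclass(frozen=True)
class NormalizationConfig:
    """Parameters of the profile-normalization pipeline.

    ``spar`` is the smoothing parameter (0 < spar < 1.5); ``grid_n`` the
    number of points of the uniform output grid on [0, 1]; ``reference`` the
    normalized positions of (start, notch1, notch2, end), strictly increasing
    with start = 0 and end = 1.  Folding about the midpoint requires the two
    reference notches to be symmetric (notch2 = 1 - notch1), which
    :func:`reference_from_landmarks` guarantees.
    """

    spar: float = 0.4
    grid_n: int = 500
    reference: tuple[float, float, float, float] = DEFAULT_REFERENCE

    def __post_init__(self) -> None:
        if not (0.0 < self.spar < 1.5):
            raise ValueError("spar must lie in (0, 1.5)")
        if self.grid_n < 64:
            raise ValueError("grid_n must be >= 64")
        ref = np.asarray(self.reference, dtype=float)
        if ref[0] != 0.0 or ref[-1] != 1.0 or np.any(np.diff(ref) <= 0):
            raise ValueError(
                "reference landmarks must be strictly increasing with start=0, end=1"
            )


@dataclass
class NormalizedProfile:
    """Profile resampled onto a uniform grid of the normalized axis.

    ``grid`` spans [0, 1] before folding and [0, ~0.5] after; ``max_value``
    records the maximum removed by :func:`normalize_max` (0 when the profile
    was identically zero, in which case ``zero_flag`` is set).
    """

    grid: np.ndarray
    values: np.ndarray
    reference: tuple[float, float, float, float]
    folded: bool = False
    max_value: float | None = None
    zero_flag: bool = False

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values differ in length")


def smooth_profile(profile: IntensityProfile, spar: float = 0.4) -> IntensityProfile:
    """Smoothing-spline denoising of a raw profile (negatives clipped to 0)."""
    fitted = smooth_series(profile.positions, profile.intensities, spar=spar)
    return IntensityProfile(
        profile.positions,
        np.clip(fitted, 0.0, None),
        profile.landmarks,
        background_subtracted=profile.background_subtracted,
        smoothed=True,
    )


def axis_map(landmarks: Sequence[float], config: NormalizationConfig):
    """The piecewise-linear map sending measured landmarks onto the reference.

    Returns forward and inverse callables; the forward map is strictly
    increasing and sends each landmark exactly onto its reference position.
    """
    src = np.asarray(landmarks, dtype=float)
    ref = np.asarray(config.reference, dtype=float)
    if src.shape != (4,):
        raise ValueError("expected four landmarks")
    if np.any(np.diff(src) <= 0):
        raise ValueError("degenerate landmark segment (zero or negative length)")

    def forward(x):
        return np.interp(x, src, ref)

    def inverse(u):
        return np.interp(u, ref, src)

    return forward, inverse


def landmark_align(
    profile: IntensityProfile, config: NormalizationConfig | None = None
) -> NormalizedProfile:
    """Resample a profile onto the uniform reference grid on [0, 1].

    For each grid position the inverse axis map gives the source position and
    the intensity is linearly interpolated there; intensity values at the
    landmarks are therefore preserved exactly.
    """
    config = config or NormalizationConfig()
    marks = profile.landmarks
    if marks[0] < profile.positions[0] - 0.5 or marks[-1] > profile.positions[-1] + 0.5:
        raise ValueError("profile does not span all landmarks")
    _, inverse = axis_map(marks, config)
    grid = np.linspace(0.0, 1.0, config.grid_n)
    src_pos = inverse(grid)
    values = np.interp(src_pos, profile.positions, profile.intensities)
    return NormalizedProfile(grid, values, tuple(config.reference))


def fold_symmetric(profile: NormalizedProfile) -> NormalizedProfile:
    """Average the two mirror halves of an unfolded profile about x = 0.5.

    output(x) = (input(x) + input(1 - x)) / 2 for x in [0, 0.5].  On an
    even-length grid the output keeps the first half of the grid; on an odd
    grid the exact midpoint is kept as its own (self-paired) value.
    """
    if profile.folded:
        raise ValueError("profile is already folded")
    ref = profile.reference
    if abs((ref[1] + ref[2]) - 1.0) > 1e-9:
        raise ValueError("reference notches are not symmetric about 0.5")
    v = profile.values
    n = v.size
    half = (n + 1) // 2
    folded = (v[:half] + v[::-1][:half]) / 2.0
    return NormalizedProfile(
        profile.grid[:half],
        folded,
        ref,
        folded=True,
        max_value=profile.max_value,
        zero_flag=profile.zero_flag,
    )


def normalize_max(profile: NormalizedProfile) -> NormalizedProfile:
    """Divide by the profile maximum; identically-zero profiles are flagged."""
    v = profile.values
    if np.any(v < 0):
        raise ValueError("negative intensities: background subtraction failed upstream")
    m = float(v.max()) if v.size else 0.0
    if m == 0.0:
        warnings.warn("profile is identically zero; returning it flagged", stacklevel=2)
        return replace(profile, max_value=0.0, zero_flag=True)
    if profile.max_value == 1.0 and np.isclose(m, 1.0):
        return profile
    return NormalizedProfile(
        profile.grid,
        v / m,
        profile.reference,
        folded=profile.folded,
        max_value=m if profile.max_value is None else profile.max_value,
        zero_flag=False,
    )


def reference_from_landmarks(
    landmark_sets: Iterable[Sequence[float]],
) -> tuple[float, float, float, float]:
    """Symmetric reference landmarks from the dataset mean segment lengths.

    The mean start->notch1 and notch2->end distances are averaged into a
    common edge segment so the reference notches sit at r and 1 - r, the
    symmetry the folding step relies on.
    """
    segs = np.asarray(
        [np.diff(np.asarray(lm, dtype=float)) for lm in landmark_sets], dtype=float
    )
    if segs.size == 0:
        raise ValueError("no landmark sets supplied")
    if np.any(segs <= 0):
        raise ValueError("landmark sets must be strictly increasing")
    d1, d2, d3 = segs.mean(axis=0)
    edge = (d1 + d3) / 2.0
    total = 2.0 * edge + d2
    r = edge / total
    return (0.0, float(r), float(1.0 - r), 1.0)


def normalize_profiles(
    profiles: Sequence[IntensityProfile],
    config: NormalizationConfig | None = None,
    ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Run the full pipeline (smooth -> align -> fold -> max-normalize).

    Returns a DataFrame of folded normalized profiles, one row per input,
    columns = folded grid positions.  When no config is given the reference
    landmarks are the symmetrized dataset means (recomputed per run).
    """
    if len(profiles) == 0:
        raise ValueError("no profiles supplied")
    if config is None:
        ref = reference_from_landmarks([p.landmarks for p in profiles])
        config = NormalizationConfig(reference=ref)
    rows = []
    for prof in profiles:
        smoothed = smooth_profile(prof, spar=config.spar)
        aligned = landmark_align(smoothed, config)
        folded = fold_symmetric(aligned)
        rows.append(normalize_max(folded))
    grid = rows[0].grid
    index = list(ids) if ids is not None else [f"profile_{i}" for i in range(len(rows))]
    return pd.DataFrame(
        np.vstack([r.values for r in rows]), index=index, columns=np.round(grid, 6)
    )


def normalize_matrix(
    matrix: pd.DataFrame,
    config: NormalizationConfig | None = None,
    landmarks: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Full pipeline over a matrix of raw profiles sharing one position axis.

    Columns are axis positions; ``landmarks`` are the four landmark positions
    on that shared axis (defaulting to the reference itself, as for synthetic
    profile sets generated directly on the normalized axis).
    """
    config = config or NormalizationConfig()
    marks = np.asarray(landmarks if landmarks is not None else config.reference, float)
    x = matrix.columns.to_numpy(dtype=float)
    profs = [
        IntensityProfile(x, row, marks) for row in matrix.to_numpy(dtype=float)
    ]
    return normalize_profiles(profs, config, ids=[str(i) for i in matrix.index])


def profile_matrix_to_csv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, index_label="reporter_id")
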