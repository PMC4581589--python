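"""Restricted cubic spline bases (Harrell parameterization).

Used for the interval-specific intercepts of the pooled logistic switch and
outcome models and for the current-CD4 term of the switch model. A spline
with K knots contributes one linear column plus K-2 nonlinear columns; the
function is linear beyond the boundary knots and has continuous second
derivatives everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class SplineSpecError(ValueError):
    """Raised for invalid knot specifications."""


@dataclass(frozen=True)
class SplineSpec:
    """Knot locations for a restricted cubic spline.

    Parameters
    ----------
    knots
        Strictly increasing sequence of at least 3 distinct values.
    variable_name
        Label used to name the basis columns.
    """

    knots: tuple[float, ...]
    variable_name: str = "x"

    def __post_init__(self) -> None:
        knots = tuple(float(k) for k in self.knots)
        if len(knots) < 3:
            raise SplineSpecError("restricted cubic spline needs >= 3 knots")
        if any(b <= a for a, b in zip(knots, knots[1:])):
            raise SplineSpecError(f"knots must be strictly increasing, got {knots}")
        object.__setattr__(self, "knots", knots)

    @property
    def n_terms(self) -> int:
        return len(self.knots) - 1

    @property
    def column_names(self) -> list[str]:
        v = self.variable_name
        return [v] + [f"{v}_rcs{j}" for j in range(1, len(self.knots) - 1)]


def rcs_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate the restricted cubic spline basis at ``x``.

    Returns an array of shape ``(len(x), len(knots) - 1)``: the first column
    is ``x`` itself, the remaining columns are the restricted truncated-power
    terms, scaled by ``(t_K - t_1)**2`` so all columns share the scale of
    ``x``.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    t = np.asarray(spec.knots, dtype=float)
    K = len(t)
    scale = (t[-1] - t[0]) ** 2

    out = np.empty((x.shape[0], K - 1), dtype=float)
    out[:, 0] = x

    def cub(u: np.ndarray) -> np.ndarray:
        return np.clip(u, 0.0, None) ** 3

    denom = t[-1] - t[-2]
    for j in range(K - 2):
        term = (
            cub(x - t[j])
            - cub(x - t[-2]) * (t[-1] - t[j]) / denom
            + cub(x - t[-1]) * (t[-2] - t[j]) / denom
        )
        out[:, j + 1] = term / scale
    return out


def percentile_knots(values, percentiles=(10.0, 50.0, 90.0)) -> tuple[float, ...] | None:
    """Knots at the given percentiles of ``values``.

    Returns ``None`` when the percentiles do not yield at least three
    distinct knots (degenerate distributions), in which case callers fall
    back to a plain linear term.
    """
    values = np.asarray(values, dtype=float)
    knots = tuple(np.percentile(values, list(percentiles)))
    if len(set(knots)) < 3:
        return None
    return knots
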