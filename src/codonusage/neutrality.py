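"""Neutrality-plot regression: GC12 against GC3 across isolates.

First and second codon positions are under functional constraint
(mutations there usually change the amino acid) while third positions
are largely free, so regressing GC12 on GC3 across sequences separates
directional mutation pressure from selection: a slope near 1 means
composition at constrained and free positions drifts together (mutation
pressure dominates), a slope near 0 means constrained positions resist
the compositional drift of the third positions (selection dominates).
The slope multiplied by 100 is reported as the percentage of variation
attributable to mutation pressure, its complement to selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import UndefinedRegressionError

LABEL_MUTATION = "mutation-dominant"
LABEL_SELECTION = "selection-dominant"
LABEL_EQUIPOISE = "equipoise"


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least squares fit of GC12 ~ GC3 with Pearson correlation."""

    slope: float
    intercept: float
    r: float
    p_value: float
    n: int
    stderr: float

    @property
    def mutation_pct(self) -> float:
        return self.slope * 100.0

    @property
    def selection_pct(self) -> float:
        return 100.0 - self.mutation_pct


def neutrality_regression(
    points: Sequence[tuple[float, float]],
) -> RegressionResult:
    """OLS of GC12 on GC3 over per-isolate points.

    The p-value is the two-sided test of zero slope (equivalently zero
    Pearson correlation for simple OLS).
    """
    if len(points) < 3:
        raise UndefinedRegressionError(
            f"need >= 3 points for the neutrality regression, got {len(points)}"
        )
    gc3 = np.asarray([p[0] for p in points], dtype=float)
    gc12 = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(gc3) == 0:
        raise UndefinedRegressionError("GC3 values are all identical")
    fit = stats.linregress(gc3, gc12)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=len(points),
        stderr=float(fit.stderr),
    )


def interpret_slope(result: RegressionResult) -> str:
    """Advisory dominant-force label; 0.5 is the boundary.

    The numeric mutation/selection percentages on ``result`` are the
    primary output — this label is a convenience reading of them.
    """
    if result.slope > 0.5:
        return LABEL_MUTATION
    if result.slope < 0.5:
        return LABEL_SELECTION
    return LABEL_EQUIPOISE
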