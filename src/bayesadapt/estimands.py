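"""Marginal estimand definitions shared by the DGM and G-computation layers."""

from __future__ import annotations

import enum


class EstimandKind(str, enum.Enum):
    """A marginal treatment-effect contrast γ = f(μ₁, μ₀).

    ``DIFF_MEANS`` contrasts expected outcomes (identity scale), ``RELATIVE_RISK``
    and ``ODDS_RATIO`` contrast marginal event risks, and ``HAZARD_RATIO``
    contrasts marginal survival probabilities at a fixed time t via
    log S₁(t) / log S₀(t) (exact under proportional hazards at the conditional
    level only up to non-collapsibility).

    Superiority is one-sided: the alternative is γ below the null value
    (0 for a difference, 1 for a ratio).
    """

    DIFF_MEANS = "diff_means"
    RELATIVE_RISK = "relative_risk"
    ODDS_RATIO = "odds_ratio"
    HAZARD_RATIO = "hazard_ratio"

    @property
    def null_value(self) -> float:
        return 0.0 if self is EstimandKind.DIFF_MEANS else 1.0

    @property
    def direction(self) -> str:
        """Direction of the alternative hypothesis relative to the null value."""
        return "less"
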