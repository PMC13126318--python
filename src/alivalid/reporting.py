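"""Presentation-scale conversions for fitted coefficients.

The model is linear in the index (0-1 scale) and age in decades, so the
natural reporting quantities are the baseline odds ``exp(b0)`` (index 0 at
the age origin, i.e. an 18-year-old), the odds ratio per 0.1-point
(one-component) index increase ``exp(0.1 * b1)``, and the odds ratio per
decade of age ``exp(b2)``.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

__all__ = ["baseline_odds", "or_per_tenth_ali", "or_per_decade_age",
           "report_coefficients"]


def baseline_odds(beta0: float) -> float:
    """Odds of the outcome at index 0 and the age origin."""
    return float(np.exp(beta0))


def or_per_tenth_ali(beta1: float) -> float:
    """Odds ratio for a 0.1-point (one-component) index increase."""
    return float(np.exp(0.1 * beta1))


def or_per_decade_age(beta2: float) -> float:
    """Odds ratio for a 10-year age increase (age coded in decades)."""
    return float(np.exp(beta2))


def report_coefficients(beta: Sequence[float],
                        se: Sequence[float] | None = None
                        ) -> Mapping[str, object]:
    """Reporting dictionary for a three-coefficient fit (with 95% CIs when
    standard errors are available)."""
    b = np.asarray(beta, dtype=float)
    if b.shape != (3,):
        raise ValueError("expected three coefficients")
    out: dict[str, object] = {
        "beta": b.tolist(),
        "baseline_odds": baseline_odds(b[0]),
        "or_per_tenth_ali": or_per_tenth_ali(b[1]),
        "or_per_decade_age": or_per_decade_age(b[2]),
    }
    if se is not None:
        s = np.asarray(se, dtype=float)
        lo, hi = b - 1.96 * s, b + 1.96 * s
        out["se"] = s.tolist()
        out["ci_beta"] = np.column_stack([lo, hi]).tolist()
        out["ci_baseline_odds"] = [baseline_odds(lo[0]), baseline_odds(hi[0])]
        out["ci_or_per_tenth_ali"] = [or_per_tenth_ali(lo[1]),
                                      or_per_tenth_ali(hi[1])]
        out["ci_or_per_decade_age"] = [or_per_decade_age(lo[2]),
                                       or_per_decade_age(hi[2])]
    return out
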