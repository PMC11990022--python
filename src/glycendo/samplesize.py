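"""Matched case-control sample-size calculation.

The number of matched pairs needed to detect a difference between the
exposure probability in cases (p1) and controls (p0) rests on the
discordant-pair probabilities of the McNemar framework.  With within-pair
correlation phi (default 0, independence between pair members):

    p10 = p1 (1 - p0) - cov,   p01 = (1 - p1) p0 - cov,
    cov = phi * sqrt(p1 (1-p1) p0 (1-p0))

    m = [ z_{1-a/2} sqrt(p10 + p01)
          + z_{1-b} sqrt(p10 + p01 - (p10 - p01)^2) ]^2 / (p10 - p01)^2

rounded up to whole pairs; with an r:1 case-to-control ratio the control
requirement is ceil(m / r).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm


@dataclass(frozen=True)
class SampleSizeSpec:
    """Design parameters of the matched case-control calculation."""

    alpha: float = 0.05      # two-sided significance level
    power: float = 0.90      # 1 - beta
    p_case: float = 0.434    # exposure probability in cases
    p_control: float = 0.164  # exposure probability in controls
    ratio: float = 2.0       # cases per control
    phi: float = 0.0         # within-pair correlation of exposure

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        for name in ("p_case", "p_control"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.p_case == self.p_control:
            raise ValueError("p_case must differ from p_control (zero effect needs infinite n)")
        if self.ratio <= 0:
            raise ValueError("ratio must be > 0")
        if not -1 < self.phi < 1:
            raise ValueError("phi must be in (-1, 1)")


@dataclass(frozen=True)
class SampleSizeResult:
    n_cases: int
    n_controls: int
    raw_cases: float          # unrounded pair requirement
    p10: float                # P(case exposed, control unexposed)
    p01: float                # P(case unexposed, control exposed)


def matched_case_control_n(spec: SampleSizeSpec) -> SampleSizeResult:
    """Required cases and controls for a matched case-control design."""
    p1, p0 = spec.p_case, spec.p_control
    cov = spec.phi * math.sqrt(p1 * (1 - p1) * p0 * (1 - p0))
    p10 = p1 * (1 - p0) - cov
    p01 = (1 - p1) * p0 - cov
    if p10 <= 0 or p01 < 0:
        raise ValueError("discordant probabilities degenerate under the given phi")
    diff = p10 - p01
    psum = p10 + p01
    z_a = norm.ppf(1 - spec.alpha / 2)
    z_b = norm.ppf(spec.power)
    m = (z_a * math.sqrt(psum) + z_b * math.sqrt(psum - diff * diff)) ** 2 / (diff * diff)
    n_cases = math.ceil(m - 1e-12)
    n_controls = math.ceil(n_cases / spec.ratio - 1e-12)
    return SampleSizeResult(n_cases=n_cases, n_controls=n_controls,
                            raw_cases=m, p10=p10, p01=p01)
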