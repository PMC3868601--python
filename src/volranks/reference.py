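"""Published reference coefficients for the normal and AD samples.

These are the reported quadratic regression coefficients (intercept,
beta on age-group code, beta on code squared) for normalized brain
tissue volume in a pooled ADNI+OASIS cohort of 227 normal-ageing and
219 Alzheimer's disease subjects aged 55–89 years: one mean (least
squares) model and one model per percentile rank (5th, 25th, 50th,
75th, 95th) in each sample, printed to 4–5 significant figures.

They serve as desk-scale inputs: the raw subject images cannot ship
with this package, but evaluating these coefficients through the
parallel-shift construction reproduces the reported comparison tables
cell by cell.

One reporting quirk is preserved deliberately: the AD sample's overall
mean change was reported as 0.0222, while the printed AD mean
coefficients evaluate to 0.0220 — the source worked at internal
precision beyond the printed digits. :data:`AD_DELTA_MU_PRINTED` carries
the reported value; :func:`ad_reference_table` lets the caller choose.
"""

from __future__ import annotations

from typing import Dict

from .divergence import RankComparisonTable, table_from_trends
from .trends import QuadraticTrend

__all__ = [
    "NORMAL_MEAN_TREND",
    "NORMAL_RANK_TRENDS",
    "AD_MEAN_TREND",
    "AD_RANK_TRENDS",
    "AD_DELTA_MU_PRINTED",
    "normal_reference_table",
    "ad_reference_table",
]


def _rank(c: float, b1: float, b2: float, tau: float) -> QuadraticTrend:
    return QuadraticTrend(c=c, b1=b1, b2=b2, kind="rank", tau=tau)


#: Normal sample (n=227): mean model.
NORMAL_MEAN_TREND = QuadraticTrend(c=0.7584, b1=0.0007, b2=-0.0011, kind="mean")

#: Normal sample: percentile-rank models keyed by quantile fraction.
NORMAL_RANK_TRENDS: Dict[float, QuadraticTrend] = {
    0.05: _rank(0.7397, -0.0089, 0.0002, 0.05),
    0.25: _rank(0.7545, -0.0049, -0.0002, 0.25),
    0.50: _rank(0.7533, 0.0036, -0.0014, 0.50),
    0.75: _rank(0.7674, 0.0038, -0.0016, 0.75),
    0.95: _rank(0.7747, 0.0067, -0.0016, 0.95),
}

#: AD sample (n=219): mean model (intercept reported to 5 figures).
AD_MEAN_TREND = QuadraticTrend(c=0.73638, b1=0.0035, b2=-0.0015, kind="mean")

#: AD sample: percentile-rank models keyed by quantile fraction.
AD_RANK_TRENDS: Dict[float, QuadraticTrend] = {
    0.05: _rank(0.6950, 0.0072, -0.0020, 0.05),
    0.25: _rank(0.7186, 0.0062, -0.0019, 0.25),
    0.50: _rank(0.7474, -0.0060, 0.0000, 0.50),
    0.75: _rank(0.7399, 0.0098, -0.0025, 0.75),
    0.95: _rank(0.7794, -0.0016, -0.0009, 0.95),
}

#: Reported AD overall mean change (vs 0.0220 from the printed betas).
AD_DELTA_MU_PRINTED = 0.0222


def normal_reference_table() -> RankComparisonTable:
    """Comparison table rebuilt from the normal-sample coefficients.

    Δ_μ is computed from the mean trend (0.0236, matching the report).
    """
    return table_from_trends("normal", NORMAL_MEAN_TREND, NORMAL_RANK_TRENDS)


def ad_reference_table(delta_mu: str = "printed") -> RankComparisonTable:
    """Comparison table rebuilt from the AD-sample coefficients.

    ``delta_mu`` selects the normalizer: "printed" uses the reported
    0.0222; "computed" evaluates the printed mean coefficients (0.0220).
    """
    if delta_mu == "printed":
        override = AD_DELTA_MU_PRINTED
    elif delta_mu == "computed":
        override = None
    else:
        raise ValueError("delta_mu must be 'printed' or 'computed'")
    return table_from_trends("AD", AD_MEAN_TREND, AD_RANK_TRENDS, delta_mu=override)
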