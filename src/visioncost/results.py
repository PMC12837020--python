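"""Headline results: totals, currency conversion, GDP share.

Direct and indirect breakdowns are assembled into a single result with
the grand total in SAR and international dollars (SAR / PPP rate), the
direct/indirect shares, and the burden as a share of GDP.  The PPP rate
itself can be derived from paired SAR / I$ unit-cost printings as the
median of their ratios.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

from .cascade import build_cascade
from .config import EconomyInputs, ModelParameters
from .direct import ComponentBreakdown, direct_costs
from .indirect import IndirectBreakdown, indirect_costs


def convert_currency(amount_sar: float, ppp: float) -> float:
    """SAR → international dollars at a PPP exchange rate (SAR per I$)."""
    if ppp <= 0:
        raise ValueError(f"PPP rate must be positive, got {ppp}")
    return amount_sar / ppp


def derive_ppp_rate(pairs: list[tuple[float, float]]) -> float:
    """PPP rate (SAR per I$) as the median ratio over printed cost pairs.

    The median is robust to the odd mis-rounded pair.
    """
    ratios = [sar / intl for sar, intl in pairs if intl != 0]
    if not ratios:
        raise ValueError("need at least one pair with a nonzero I$ value")
    return statistics.median(ratios)


@dataclass(frozen=True)
class CoiResult:
    """Aggregated one-year burden in SAR and international dollars."""

    direct_sar: float
    indirect_sar: float
    total_sar: float
    direct_intl: float
    indirect_intl: float
    total_intl: float
    direct_share: float
    indirect_share: float
    gdp_share: float
    direct_components: ComponentBreakdown
    indirect_components: IndirectBreakdown
    #: True when the total is zero, in which case shares are reported as 0.
    degenerate: bool = False

    def to_dict(self) -> dict:
        """Summary fields for JSON export (numbers unrounded)."""
        return {
            "total_sar": self.total_sar,
            "direct_sar": self.direct_sar,
            "indirect_sar": self.indirect_sar,
            "total_intl": self.total_intl,
            "direct_intl": self.direct_intl,
            "indirect_intl": self.indirect_intl,
            "direct_share": self.direct_share,
            "indirect_share": self.indirect_share,
            "gdp_share": self.gdp_share,
            "degenerate": self.degenerate,
            "direct_components_sar": dict(self.direct_components.per_component),
            "indirect_components_sar": {
                "pension": self.indirect_components.pension,
                "patient_productivity": self.indirect_components.patient_productivity,
                "caregiver_productivity": self.indirect_components.caregiver_productivity,
            },
        }

    def summary_lines(self) -> list[str]:
        """Human-readable summary (money to 2 dp, shares to 0 dp)."""
        return [
            f"Total burden: SAR {self.total_sar:,.2f} (I$ {self.total_intl:,.2f})",
            f"  Direct:   SAR {self.direct_sar:,.2f} (I$ {self.direct_intl:,.2f}; "
            f"{self.direct_share:.0%})",
            f"  Indirect: SAR {self.indirect_sar:,.2f} (I$ {self.indirect_intl:,.2f}; "
            f"{self.indirect_share:.0%})",
            f"  Share of GDP: {self.gdp_share:.1%}",
        ]


def aggregate(
    direct: ComponentBreakdown, indirect: IndirectBreakdown, economy: EconomyInputs
) -> CoiResult:
    """Assemble the headline result from the two cost breakdowns."""
    direct_sar = direct.total
    indirect_sar = indirect.total
    total_sar = direct_sar + indirect_sar
    degenerate = total_sar == 0.0
    if degenerate:
        direct_share = indirect_share = 0.0
    else:
        direct_share = direct_sar / total_sar
        indirect_share = indirect_sar / total_sar
    ppp = economy.ppp_rate_sar_per_intl_dollar
    return CoiResult(
        direct_sar=direct_sar,
        indirect_sar=indirect_sar,
        total_sar=total_sar,
        direct_intl=convert_currency(direct_sar, ppp),
        indirect_intl=convert_currency(indirect_sar, ppp),
        total_intl=convert_currency(total_sar, ppp),
        direct_share=direct_share,
        indirect_share=indirect_share,
        gdp_share=total_sar / economy.gdp_sar,
        direct_components=direct,
        indirect_components=indirect,
        degenerate=degenerate,
    )


def run_model(params: ModelParameters) -> CoiResult:
    """Full pipeline: cascade → direct + indirect costing → aggregation."""
    cascade = build_cascade(params.population)
    return aggregate(
        direct_costs(cascade, params),
        indirect_costs(cascade, params),
        params.economy,
    )
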