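"""Closed-form nitrogen budgets around the mixing model.

Three small calculators:

* the isotope mass balance that infers the δ¹⁵N of snow-pack ammonium from
  the inflow and snow nitrate signatures and the snow N speciation,
  assuming inflow δ¹⁵N integrates snow NH₄⁺ + NO₃⁻ with negligible
  fractionation during nitrification;
* the scaling of a global tropospheric NOₓ emission budget (Tg N/yr per
  source) to per-source shares of lake nitrate, via the fitted
  atmospherically-oxidized-nitrate (AON) proportion;
* the anthropogenic roll-up: fertilizer share plus the fossil-fuel slice
  of the AON share.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .corrections import ValidationError
from .mixing import round_half_away

__all__ = [
    "MassBalanceInputs",
    "NOxSource",
    "DEFAULT_NOX_BUDGET",
    "DEFAULT_SNOW_NO3_UM",
    "snow_ammonium_d15N",
    "nox_budget_apportionment",
    "budget_frame",
    "anthropogenic_share",
]

#: Global tropospheric NOx emission budget, Tg N per year by source.
DEFAULT_NOX_BUDGET: list[tuple[str, float]] = [
    ("Fossil fuels", 24.0),
    ("Lightning", 12.0),
    ("Soil emissions", 12.0),
    ("Biomass burning", 8.0),
    ("NH3 oxidation", 3.0),
    ("Transport from stratosphere", 0.4),
    ("Aircraft", 0.4),
]

#: Default snow nitrate concentration (μM N) for the ammonium mass balance,
#: back-derived from the study-area mean snow/inflow signatures; replace
#: with a measured value when available.
DEFAULT_SNOW_NO3_UM = 6.73


@dataclass
class MassBalanceInputs:
    """Group-mean inputs to the snow ammonium δ¹⁵N balance.

    ``d15N_snow`` is the measured snow δ¹⁵N–NO₃⁻, taken to equal the δ¹⁵N
    of total snow nitrate; concentrations are μM N.
    """

    d15N_inflow: float
    d15N_snow: float
    nh4_snow: float
    no3_snow: float

    def __post_init__(self) -> None:
        if self.nh4_snow <= 0:
            raise ValidationError(f"nh4_snow must be > 0, got {self.nh4_snow}")
        if self.no3_snow < 0:
            raise ValidationError(f"no3_snow must be >= 0, got {self.no3_snow}")


@dataclass
class NOxSource:
    """One tropospheric NOx source and its share of lake nitrate."""

    name: str
    tg_per_year: float
    percent_of_nox: float
    contribution_to_lakes: float  # % of total lake nitrate


def snow_ammonium_d15N(mb: MassBalanceInputs) -> float:
    """δ¹⁵N of snow ammonium (‰) from the two-pool mass balance.

    Solves  δ¹⁵N_inflow·[total] = δ¹⁵N_NH₄·[NH₄⁺] + δ¹⁵N_snow·[NO₃⁻]
    for δ¹⁵N_NH₄, where [total] = [NH₄⁺] + [NO₃⁻].
    """
    total = mb.nh4_snow + mb.no3_snow
    return (mb.d15N_inflow * total - mb.d15N_snow * mb.no3_snow) / mb.nh4_snow


def nox_budget_apportionment(
    table: list[tuple[str, float]],
    aon_mpe: float,
) -> list[NOxSource]:
    """Scale an NOx emission budget to shares of lake nitrate.

    Each source's percent of tropospheric NOx is 100·Tg/total; its
    contribution to lake nitrate is that percent of the fitted AON
    proportion (``aon_mpe``, in %).  Unrounded contributions sum exactly
    to ``aon_mpe``.
    """
    if not table:
        raise ValidationError("NOx budget table is empty")
    if not 0.0 <= aon_mpe <= 100.0:
        raise ValidationError(f"aon_mpe must be in [0, 100], got {aon_mpe}")
    total = sum(tg for _, tg in table)
    if total <= 0 or any(tg < 0 for _, tg in table):
        raise ValidationError("Tg values must be >= 0 with a positive total")
    out = []
    for name, tg in table:
        pct = 100.0 * tg / total
        out.append(
            NOxSource(
                name=name,
                tg_per_year=tg,
                percent_of_nox=pct,
                contribution_to_lakes=pct / 100.0 * aon_mpe,
            )
        )
    return out


def _display(x: float) -> float:
    """Budget-table display rounding: ≥1 to integer, <1 to one decimal."""
    return round_half_away(x) if abs(x) >= 1.0 else round_half_away(x, 1)


def budget_frame(
    sources: list[NOxSource],
    rounded: bool = True,
    total_row: bool = True,
) -> pd.DataFrame:
    """Budget report table, optionally display-rounded and with a Total row."""
    rows = [
        {
            "source": s.name,
            "tg_per_year": s.tg_per_year,
            "percent_of_nox": s.percent_of_nox,
            "contribution_to_lakes": s.contribution_to_lakes,
        }
        for s in sources
    ]
    if total_row:
        rows.append(
            {
                "source": "Total",
                "tg_per_year": sum(s.tg_per_year for s in sources),
                "percent_of_nox": sum(s.percent_of_nox for s in sources),
                "contribution_to_lakes": sum(
                    s.contribution_to_lakes for s in sources
                ),
            }
        )
    df = pd.DataFrame(rows)
    if rounded:
        num = df.columns.drop("source")
        df[num] = df[num].map(_display)
    return df


def anthropogenic_share(
    fertilizer_mpe: float,
    aon_mpe: float,
    fossil_fraction_of_nox: float,
) -> float:
    """Anthropogenic percentage of nitrate inputs (unrounded).

    Fertilizer share plus the fossil-fuel fraction of the atmospheric
    (AON) share; the remaining AON slices (lightning, soil emissions, …)
    are natural or mixed and are not counted.
    """
    if not 0.0 <= fertilizer_mpe <= 100.0 or not 0.0 <= aon_mpe <= 100.0:
        raise ValidationError("MPE inputs must be percentages in [0, 100]")
    if not 0.0 <= fossil_fraction_of_nox <= 1.0:
        raise ValidationError("fossil_fraction_of_nox must be in [0, 1]")
    return fertilizer_mpe + fossil_fraction_of_nox * aon_mpe
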