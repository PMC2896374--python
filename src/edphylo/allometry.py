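"""Allometric scaling of embryonic developmental period (EDP) on egg mass.

Across Charadriiform birds the expected incubation time scales with fresh egg
mass as a power law, EDP = a * m^b with a = 17.18 days and b = 0.119.  The
comparative analysis in this package works on *residuals* from that
relationship: observed EDP minus the allometric expectation, in days, so a
positive residual means slower-than-predicted embryonic development.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

__all__ = [
    "AllometricParams",
    "ResidualRecord",
    "predicted_edp",
    "edp_residual",
    "residual_table",
]

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import TraitTable


@dataclass(frozen=True)
class AllometricParams:
    """Power-law parameters: predicted EDP (days) = a * egg_mass_g ** b."""

    a: float = 17.18
    b: float = 0.119

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("coefficient a must be positive")
        if not (self.b == self.b and abs(self.b) != float("inf")):
            raise ValueError("exponent b must be finite")


@dataclass(frozen=True)
class ResidualRecord:
    species: str
    edp_observed: float
    egg_mass: float
    edp_predicted: float
    edp_residual: float


_DEFAULT = AllometricParams()


def predicted_edp(
    egg_mass: float, params: AllometricParams = _DEFAULT
) -> float:
    """Expected EDP in days for a fresh egg mass in grams."""
    if not egg_mass > 0:
        raise ValueError(f"egg mass must be positive, got {egg_mass!r}")
    return params.a * egg_mass ** params.b


def edp_residual(
    edp_observed: float,
    egg_mass: float,
    params: AllometricParams = _DEFAULT,
) -> float:
    """Observed minus allometrically predicted EDP, in days."""
    return edp_observed - predicted_edp(egg_mass, params)


def residual_table(
    traits: "TraitTable", params: AllometricParams = _DEFAULT
) -> list[ResidualRecord]:
    """Per-species residual records, preserving the input species order.

    Raises ``ValueError`` naming every species whose EDP or egg mass is
    missing or non-positive (errors are collected, not reported one at a
    time).
    """
    problems: list[str] = []
    records: list[ResidualRecord] = []
    for row in traits.df.itertuples(index=False):
        edp = getattr(row, "edp_days")
        mass = getattr(row, "egg_mass_g")
        if not (edp == edp and edp > 0):
            problems.append(f"{row.species}: invalid EDP {edp!r}")
            continue
        if not (mass == mass and mass > 0):
            problems.append(f"{row.species}: invalid egg mass {mass!r}")
            continue
        pred = predicted_edp(mass, params)
        records.append(
            ResidualRecord(row.species, float(edp), float(mass), pred, edp - pred)
        )
    if problems:
        raise ValueError(
            "invalid EDP/egg-mass entries:\n  " + "\n  ".join(problems)
        )
    return records
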