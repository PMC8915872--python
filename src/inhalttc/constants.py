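"""Fixed physical and regulatory constants used by the derivation formulas."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Any, Mapping

#: Molar volume of an ideal gas at 25 degC / 1 atm, L/mol, as used in the
#: ppm <-> mg/m3 interconversion.  Fixed by convention, never recomputed.
MOLAR_VOLUME_L_MOL = 24.45


@dataclass(frozen=True)
class DerivationConstants:
    """Constants feeding the TTC derivation chain.

    Attributes
    ----------
    dexp
        Dimensionless exposure-duration adjustment converting a 6 h/day,
        5 day/week study exposure to a continuous equivalent:
        (6/24) * (5/7).
    uf_total
        Total uncertainty factor divisor (composed as 10 x 2.5, stored as
        the single value 25; the decomposition is never used separately).
    vresp
        Human respiratory volume, m3/day.
    bw
        Human body weight, kg.
    molar_volume
        Molar volume for gas-phase unit conversion, L/mol.
    """

    dexp: float = (6.0 / 24.0) * (5.0 / 7.0)
    uf_total: float = 25.0
    vresp: float = 20.0
    bw: float = 60.0
    molar_volume: float = MOLAR_VOLUME_L_MOL

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not value > 0:
                raise ValueError(f"constant {f.name!r} must be > 0, got {value!r}")

    @classmethod
    def from_mapping(cls, overrides: Mapping[str, Any] | None = None) -> "DerivationConstants":
        """Build constants, applying explicit overrides on top of defaults."""
        overrides = dict(overrides or {})
        known = {f.name for f in fields(cls)}
        unknown = set(overrides) - known
        if unknown:
            raise ValueError(f"unknown constant override(s): {sorted(unknown)}")
        return cls(**overrides)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}
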