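"""Relative diffusion coefficients from molecular weights.

Used to argue that a visible dye (methylene blue, MW 374 g/mol) traces the
diffusion field of an infused drug cocktail (glutamatergic agonists and
antagonists, mean MW ~201 g/mol): under Stokes-Einstein scaling the
diffusion coefficient goes as the hydrodynamic radius^-1, and radius
scales roughly as MW^(1/3), so D_i is proportional to MW_i^(-1/3).  The
exponent is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["Compound", "relative_diffusion", "METHYLENE_BLUE", "GLUTAMATERGIC_COCKTAIL_MEAN"]


@dataclass(frozen=True)
class Compound:
    name: str
    molecular_weight: float  # g/mol

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError(f"{self.name}: molecular weight must be positive")


#: The dye used to visualise the infusion field.
METHYLENE_BLUE = Compound("methylene blue", 374.0)
#: Mean molecular weight of the glutamatergic drug cocktail members.
GLUTAMATERGIC_COCKTAIL_MEAN = Compound("glutamatergic cocktail (mean)", 201.0)


def relative_diffusion(
    reference: Compound,
    cocktail: Sequence[Compound] | Compound,
    exponent: float = 1.0 / 3.0,
) -> float:
    """Ratio D_reference / D_cocktail under D ~ MW^(-exponent) scaling.

    The cocktail coefficient is the mean of its members' coefficients.
    A ratio below 1 means the reference compound diffuses more slowly than
    the cocktail average (it is heavier); the ratio is invariant to a
    common rescaling of all molecular weights.
    """
    if isinstance(cocktail, Compound):
        cocktail = [cocktail]
    if not cocktail:
        raise ValueError("cocktail must contain at least one compound")
    if exponent <= 0:
        raise ValueError("scaling exponent must be positive")
    d_ref = reference.molecular_weight ** (-exponent)
    d_mix = sum(c.molecular_weight ** (-exponent) for c in cocktail) / len(cocktail)
    return d_ref / d_mix
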