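"""Spectrophotometric chlorophyll assay arithmetic.

Chlorophyll a and b concentrations (mg/L) follow from the absorbances of
an 80% acetone extract at 663 and 646 nm:

    Ca = 12.21 * A663 - 2.81 * A646
    Cb = 20.13 * A646 - 5.03 * A663

and the content per unit fresh mass (mg/g) is

    C = V * (Ca + Cb) / (1000 * M) = V * (17.32*A646 + 7.18*A663) / (1000 * M)

with V the extraction volume in mL and M the fresh leaf mass in grams.
The combined coefficients are an exact algebraic consequence of the a/b
equations (20.13 - 2.81 = 17.32, 12.21 - 5.03 = 7.18).

M is taken in grams.  Quoting the mass in milligrams would make typical
leaf contents a thousandfold too small, so a 0.2 g aliquot enters as
M = 0.2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .exceptions import ParameterError

CA_A663, CA_A646 = 12.21, 2.81
CB_A646, CB_A663 = 20.13, 5.03
TOTAL_A646 = CB_A646 - CA_A646  # 17.32
TOTAL_A663 = CA_A663 - CB_A663  # 7.18


@dataclass(frozen=True)
class AssayInput:
    """Absorbances and extraction geometry for one sample."""

    A646: float
    A663: float
    V: float = 25.0  # extraction volume, mL
    M: float = 0.2  # fresh leaf mass, g

    def __post_init__(self):
        if self.A646 < 0 or self.A663 < 0:
            raise ParameterError("absorbances must be non-negative")
        if self.V <= 0:
            raise ParameterError("extraction volume V must be positive")
        if self.M <= 0:
            raise ParameterError("fresh mass M must be positive")


def chlorophyll_a(A663: float, A646: float) -> float:
    """Chlorophyll a concentration in mg/L."""
    ca = CA_A663 * A663 - CA_A646 * A646
    if ca < 0:
        warnings.warn("negative chlorophyll a: physically implausible absorbances")
    return ca


def chlorophyll_b(A646: float, A663: float) -> float:
    """Chlorophyll b concentration in mg/L."""
    cb = CB_A646 * A646 - CB_A663 * A663
    if cb < 0:
        warnings.warn("negative chlorophyll b: physically implausible absorbances")
    return cb


def chlorophyll_total(inp: AssayInput) -> float:
    """Total chlorophyll content in mg per g fresh mass."""
    ca = chlorophyll_a(inp.A663, inp.A646)
    cb = chlorophyll_b(inp.A646, inp.A663)
    return inp.V * (ca + cb) / (1000.0 * inp.M)


def absorbances_for_content(content_mg_g: float, V: float = 25.0, M: float = 0.2,
                            ab_ratio: float = 3.0) -> tuple[float, float]:
    """Invert the assay: absorbances that yield a target content.

    Splits total pigment into a/b at ``ab_ratio`` (a:b, ~3 in sun leaves)
    and solves the two concentration equations for (A646, A663).  Used by
    the synthetic generator so its truth values flow through the same
    arithmetic as a laboratory measurement.
    """
    if content_mg_g < 0:
        raise ParameterError("content must be non-negative")
    total_conc = content_mg_g * 1000.0 * M / V  # Ca + Cb, mg/L
    ca = total_conc * ab_ratio / (1.0 + ab_ratio)
    cb = total_conc - ca
    # [ 12.21 -2.81 ] [A663]   [Ca]
    # [ -5.03 20.13 ] [A646] = [Cb]
    det = CA_A663 * CB_A646 - CA_A646 * CB_A663
    a663 = (ca * CB_A646 + cb * CA_A646) / det
    a646 = (ca * CB_A663 + cb * CA_A663) / det
    return a646, a663
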