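"""Chain parameters and small polymer-physics conversions.

Defaults describe T4 bacteriophage dsDNA: contour length ~60 um, persistence
length 50 nm (Kuhn length a_k = 0.1 um), 166 kbp, ~300 bp per Kuhn segment —
hence ~600 Kuhn segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import DomainError

__all__ = ["ChainSpec", "T4_DNA", "LAMBDA_DNA", "swelling_corrected_rg"]


@dataclass(frozen=True)
class ChainSpec:
    """A confined dsDNA chain in the ideal-chain (Kuhn) representation.

    Attributes
    ----------
    contour_length : float
        um.
    kuhn_length : float
        a_k = 2 x persistence length, um.
    basepairs : int
    basepairs_per_kuhn : int
    """

    contour_length: float = 60.0
    kuhn_length: float = 0.1
    basepairs: int = 166_000
    basepairs_per_kuhn: int = 300

    def __post_init__(self) -> None:
        if self.contour_length <= 0 or self.kuhn_length <= 0:
            raise DomainError("contour and Kuhn lengths must be positive")
        if self.basepairs <= 0 or self.basepairs_per_kuhn <= 0:
            raise DomainError("base-pair counts must be positive")
        n_from_length = self.contour_length / self.kuhn_length
        n_from_bp = self.basepairs / self.basepairs_per_kuhn
        if abs(n_from_bp - n_from_length) > 0.2 * n_from_length:
            warnings.warn(
                "base-pair and contour-length Kuhn counts disagree by more "
                f"than 20% ({n_from_bp:.0f} vs {n_from_length:.0f})",
                stacklevel=2,
            )

    @property
    def n_kuhn(self) -> float:
        """Number of Kuhn segments, contour_length / kuhn_length."""
        return self.contour_length / self.kuhn_length


T4_DNA = ChainSpec()
LAMBDA_DNA = ChainSpec(contour_length=16.5, kuhn_length=0.1,
                       basepairs=48_502, basepairs_per_kuhn=300)


def swelling_corrected_rg(rg_measured_nm: float, width_measured_nm: float,
                          width_target_nm: float) -> float:
    """Rescale a coil's gyration radius between ionic conditions.

    For a bulk self-avoiding coil Rg ~ w^(1/5) in the effective chain width
    w, so a radius measured at one salt (hence one w) maps to another as
    Rg * (w_target / w_measured)^(1/5).  E.g. a supercoiled plasmid with
    Rg = 102 nm at w ~ 2 nm (high salt) swells to ~140 nm at w ~ 10 nm
    (10 mM Tris).
    """
    if min(rg_measured_nm, width_measured_nm, width_target_nm) <= 0:
        raise DomainError("radii and widths must be positive")
    return rg_measured_nm * (width_target_nm / width_measured_nm) ** 0.2
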