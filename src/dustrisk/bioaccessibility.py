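"""Oral bioaccessibility of toxic metals in road dust.

The bioaccessible concentration CDBA (mg/kg) is the gastric-phase soluble
fraction of the total concentration CT (mg/kg), as measured by a one-step
in-vitro extraction (SBET).  The bioaccessibility rate RD = CDBA / CT is the
dimensionless fraction that enters the exposure equations in place of the
total concentration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

logger = logging.getLogger(__name__)

__all__ = ["BioaccessibilityRecord", "bioaccessibility_rate", "mean_rd_by_metal"]


@dataclass(frozen=True)
class BioaccessibilityRecord:
    """Total and bioaccessible concentration of one metal in one sample."""

    metal: str
    ct: float      # total concentration, mg/kg
    cdba: float    # bioaccessible concentration, mg/kg

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError(f"{self.metal}: total concentration must be positive, got {self.ct}")
        if self.cdba < 0:
            raise ValueError(f"{self.metal}: bioaccessible concentration must be non-negative, got {self.cdba}")
        if self.cdba > self.ct:
            raise ValueError(
                f"{self.metal}: bioaccessible concentration {self.cdba} exceeds "
                f"total {self.ct} — inconsistent measurement"
            )

    @property
    def rd(self) -> float:
        return bioaccessibility_rate(self.ct, self.cdba)


def bioaccessibility_rate(ct: float, cdba: float) -> float:
    """Bioaccessible fraction RD = CDBA / CT, in [0, 1]."""
    if ct <= 0:
        raise ValueError(f"total concentration must be positive, got {ct}")
    if cdba < 0:
        raise ValueError(f"bioaccessible concentration must be non-negative, got {cdba}")
    if cdba > ct:
        raise ValueError(
            f"bioaccessible concentration {cdba} exceeds total {ct} — "
            "inconsistent measurement"
        )
    return cdba / ct


def mean_rd_by_metal(
    records: Iterable[BioaccessibilityRecord],
) -> Tuple[Dict[str, float], List[str]]:
    """Arithmetic mean per-sample RD for each metal, with descending ordering.

    RD is computed per sample and then averaged (not as a ratio of means).
    Returns ``(means, order)`` where *order* lists metals by decreasing mean
    bioaccessibility.  Metals with no records are simply absent.
    """
    sums: Dict[str, float] = {}
    counts: Dict[str, int] = {}
    for rec in records:
        sums[rec.metal] = sums.get(rec.metal, 0.0) + rec.rd
        counts[rec.metal] = counts.get(rec.metal, 0) + 1
    if not sums:
        logger.warning("no bioaccessibility records supplied; empty RD summary")
    means = {m: sums[m] / counts[m] for m in sums}
    order = sorted(means, key=lambda m: means[m], reverse=True)
    return means, order
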