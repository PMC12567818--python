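"""Fuzzy daily-intake, hazard-quotient/index, and carcinogenic-risk model.

Three exposure pathways link road dust to a receptor (adult or child):
incidental ingestion, inhalation of resuspended particles, and dermal
contact.  The bioaccessible concentration CDBA replaces the total
concentration in all three intake equations:

    intake_ing  = CDBA · ED · EF · IngR / (BW · AT) · 1e-6
    intake_inh  = CDBA · ED · EF · InhR / (BW · AT · PEF)
    intake_derm = CDBA · ED · EF · SA · SSAR · ABS / (BW · AT) · 1e-6

with intakes in mg/(kg·d) and CDBA in mg/kg (the 1e-6 factor converts mg/kg
of dust to kg/kg ingested or adhered mass).  The concentration and the
high-sensitivity receptor parameters (IngR, InhR, BW) are triangular fuzzy
numbers; the remaining parameters are crisp.  At a chosen confidence α every
fuzzy factor is cut into an interval and propagated with non-negative
interval arithmetic, so each intake, hazard quotient HQ = intake / RfD,
hazard index HI = Σ HQ, and carcinogenic risk CR = intake · SF is an
interval.  Per-metal total CR (summed over pathways) is classified against
the risk-level scheme and assigned a level by maximum membership.

The averaging time differs by endpoint: AT_nc = ED · 365 days for
non-carcinogenic quotients, AT_ca = a 70-year lifetime for carcinogenic
risk.  With every fuzzy parameter degenerate (a1 = a2 = a3) each interval
collapses to a point and the model reduces exactly to the classical crisp
risk-assessment equations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .fuzzy import (
    DEFAULT_ALPHA,
    DEFAULT_RISK_SCHEME,
    AlphaCutInterval,
    MembershipVector,
    RiskLevelScheme,
    TriangularFuzzyNumber,
    alpha_cut,
    assign_level,
    classify_interval,
    interval_add,
    interval_div,
    interval_mul,
    interval_scale,
    tfn_from_samples,
)
from .simulate import DustSample

logger = logging.getLogger(__name__)

__all__ = [
    "PATHWAYS",
    "ExposureScenario",
    "ToxicityParameters",
    "GroupRiskResult",
    "intake_ingestion",
    "intake_inhalation",
    "intake_dermal",
    "hazard_quotient",
    "hazard_index",
    "carcinogenic_risk",
    "run_risk_assessment",
]

PATHWAYS: Tuple[str, ...] = ("ingestion", "inhalation", "dermal")
GROUPINGS: Tuple[str, ...] = ("season", "site", "season×site", "pooled")


@dataclass(frozen=True)
class ExposureScenario:
    """Receptor-specific exposure parameters.

    IngR, InhR and BW are fuzzy (TFN); the low-sensitivity parameters are
    crisp scalars.  Units: IngR mg/day, InhR m³/day, BW kg, ED years,
    EF days/year, AT days, SA cm², SSAR mg/(cm²·day), ABS unitless,
    PEF m³/kg.
    """

    receptor: str
    IngR: TriangularFuzzyNumber
    InhR: TriangularFuzzyNumber
    BW: TriangularFuzzyNumber
    ED: float
    EF: float
    AT_nc: float
    AT_ca: float
    SA: float
    SSAR: float
    ABS: float
    PEF: float

    def __post_init__(self) -> None:
        for name in ("ED", "EF", "AT_nc", "AT_ca", "SA", "SSAR", "PEF"):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{self.receptor}: {name} must be positive, got {v}")
        if self.ABS < 0:
            # ABS = 0 is legal: it expresses a pathway with no dermal uptake
            raise ValueError(f"{self.receptor}: ABS must be non-negative, got {self.ABS}")
        if self.EF > 366:
            raise ValueError(
                f"{self.receptor}: exposure frequency EF = {self.EF} exceeds 366 days/yr"
            )
        for name in ("IngR", "InhR", "BW"):
            tfn = getattr(self, name)
            if tfn.a1 <= 0:
                raise ValueError(
                    f"{self.receptor}: {name} must be strictly positive, "
                    f"got minimum {tfn.a1}"
                )


@dataclass(frozen=True)
class ToxicityParameters:
    """Reference doses and slope factors per metal × pathway.

    ``rfd[metal][pathway]`` in mg/(kg·d); ``sf[metal][pathway]`` in
    kg·d/mg.  A metal absent from ``rfd`` contributes no hazard quotient; a
    metal absent from ``sf`` contributes no carcinogenic risk.
    """

    rfd: Mapping[str, Mapping[str, float]]
    sf: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for table_name, table in (("rfd", self.rfd), ("sf", self.sf)):
            for metal, per_path in table.items():
                for pathway, value in per_path.items():
                    if pathway not in PATHWAYS:
                        raise ValueError(
                            f"{table_name}[{metal}]: unknown pathway {pathway!r}"
                        )
                    if value <= 0:
                        raise ValueError(
                            f"{table_name}[{metal}][{pathway}] must be positive, got {value}"
                        )

    def rfd_for(self, metal: str, pathway: str) -> Optional[float]:
        return self.rfd.get(metal, {}).get(pathway)

    def sf_for(self, metal: str, pathway: str) -> Optional[float]:
        return self.sf.get(metal, {}).get(pathway)

    @property
    def hq_metals(self) -> List[str]:
        return [m for m, t in self.rfd.items() if t]

    @property
    def cr_metals(self) -> List[str]:
        return [m for m, t in self.sf.items() if t]


# ---------------------------------------------------------------------------
# Fuzzy intakes
# ---------------------------------------------------------------------------

def _intake_core(
    cdba: TriangularFuzzyNumber,
    rate: TriangularFuzzyNumber,
    scn: ExposureScenario,
    alpha: float,
    averaging_time: float,
    crisp_numerator: float,
) -> AlphaCutInterval:
    """(cut(CDBA) ⊗ cut(rate)) · crisp_numerator / (cut(BW) · averaging_time)."""
    if averaging_time <= 0:
        raise ValueError(f"averaging time must be positive, got {averaging_time}")
    num = interval_scale(crisp_numerator, interval_mul(alpha_cut(cdba, alpha), alpha_cut(rate, alpha)))
    den = interval_scale(averaging_time, alpha_cut(scn.BW, alpha))
    return interval_div(num, den)


def intake_ingestion(
    cdba: TriangularFuzzyNumber,
    scn: ExposureScenario,
    alpha: float = DEFAULT_ALPHA,
    averaging_time: Optional[float] = None,
) -> AlphaCutInterval:
    """Fuzzy ingestion intake, mg/(kg·d).

    *averaging_time* defaults to the non-carcinogenic AT; pass ``scn.AT_ca``
    for the carcinogenic endpoint.
    """
    at = scn.AT_nc if averaging_time is None else averaging_time
    return _intake_core(cdba, scn.IngR, scn, alpha, at, scn.ED * scn.EF * 1e-6)


def intake_inhalation(
    cdba: TriangularFuzzyNumber,
    scn: ExposureScenario,
    alpha: float = DEFAULT_ALPHA,
    averaging_time: Optional[float] = None,
) -> AlphaCutInterval:
    """Fuzzy inhalation intake, mg/(kg·d); the PEF divides the dust mass
    into an inhaled-air basis."""
    at = scn.AT_nc if averaging_time is None else averaging_time
    return _intake_core(cdba, scn.InhR, scn, alpha, at * scn.PEF, scn.ED * scn.EF)


def intake_dermal(
    cdba: TriangularFuzzyNumber,
    scn: ExposureScenario,
    alpha: float = DEFAULT_ALPHA,
    averaging_time: Optional[float] = None,
) -> AlphaCutInterval:
    """Fuzzy dermal-contact intake, mg/(kg·d)."""
    at = scn.AT_nc if averaging_time is None else averaging_time
    crisp = scn.ED * scn.EF * scn.SA * scn.SSAR * scn.ABS * 1e-6
    num = interval_scale(crisp, alpha_cut(cdba, alpha))
    den = interval_scale(at, alpha_cut(scn.BW, alpha))
    return interval_div(num, den)


_INTAKE_FUNCS = {
    "ingestion": intake_ingestion,
    "inhalation": intake_inhalation,
    "dermal": intake_dermal,
}


# ---------------------------------------------------------------------------
# Risk metrics
# ---------------------------------------------------------------------------

def hazard_quotient(intake: AlphaCutInterval, rfd: float) -> AlphaCutInterval:
    """HQ = intake / RfD (componentwise on the interval)."""
    if rfd <= 0:
        raise ValueError(f"reference dose must be positive, got {rfd}")
    return interval_scale(1.0 / rfd, intake)


def hazard_index(
    hqs: Sequence[AlphaCutInterval], alpha: float = DEFAULT_ALPHA
) -> Tuple[AlphaCutInterval, bool]:
    """HI = componentwise sum of hazard quotients.

    Returns ``(interval, below_one)`` where *below_one* reports whether even
    the right endpoint stays under the HI = 1 threshold for non-carcinogenic
    concern.  An empty sum yields [0, 0] with a warning.
    """
    if not hqs:
        logger.warning("hazard index over an empty set of quotients; returning [0, 0]")
        return AlphaCutInterval(0.0, 0.0, alpha), True
    total = hqs[0]
    for hq in hqs[1:]:
        total = interval_add(total, hq)
    return total, total.hi < 1.0


def carcinogenic_risk(intake: AlphaCutInterval, sf: float) -> AlphaCutInterval:
    """CR = intake · SF (componentwise on the interval)."""
    if sf <= 0:
        raise ValueError(f"slope factor must be positive, got {sf}")
    return interval_scale(sf, intake)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class GroupRiskResult:
    """Risk results for one sample group × receptor at one confidence α."""

    group: str
    receptor: str
    alpha: float
    n_samples: int
    #: per metal: CDBA TFN built from the group's samples
    cdba: Dict[str, TriangularFuzzyNumber] = field(default_factory=dict)
    #: per metal × pathway, non-carcinogenic averaging time
    intake_nc: Dict[str, Dict[str, AlphaCutInterval]] = field(default_factory=dict)
    #: per metal × pathway, carcinogenic averaging time
    intake_ca: Dict[str, Dict[str, AlphaCutInterval]] = field(default_factory=dict)
    hq: Dict[str, Dict[str, AlphaCutInterval]] = field(default_factory=dict)
    hq_total: Dict[str, AlphaCutInterval] = field(default_factory=dict)
    hi: Optional[AlphaCutInterval] = None
    hi_below_one: bool = True
    cr: Dict[str, Dict[str, AlphaCutInterval]] = field(default_factory=dict)
    cr_total: Dict[str, AlphaCutInterval] = field(default_factory=dict)
    membership: Dict[str, MembershipVector] = field(default_factory=dict)
    level: Dict[str, str] = field(default_factory=dict)
    dominant_pathway: Dict[str, str] = field(default_factory=dict)


def _group_key(sample: DustSample, grouping: str) -> str:
    if grouping == "season":
        return sample.season
    if grouping == "site":
        return sample.site
    if grouping in ("season×site", "seasonxsite", "season_site"):
        return f"{sample.season}/{sample.site}"
    if grouping == "pooled":
        return "pooled"
    raise ValueError(f"unknown grouping {grouping!r}; use one of {GROUPINGS}")


def run_risk_assessment(
    samples: Sequence[DustSample],
    scenarios: Sequence[ExposureScenario],
    tox: ToxicityParameters,
    scheme: RiskLevelScheme = DEFAULT_RISK_SCHEME,
    grouping: str = "season",
    alpha: float = DEFAULT_ALPHA,
    center_rule: str = "mean",
    normalization: str = "computed_interval",
    fuzzy_concentration: bool = True,
) -> List[GroupRiskResult]:
    """Full fuzzy risk assessment over grouped samples.

    For each group the per-metal bioaccessible concentrations are condensed
    into TFNs (min / centre / max over the group's samples); intakes, HQ/HI
    (with AT_nc) and CR with per-metal pathway totals (with AT_ca) are
    computed per receptor; total CR is classified and assigned a level by
    maximum membership; the dominant pathway is the one with the largest CR
    interval midpoint.

    With ``fuzzy_concentration=False`` each group's CDBA collapses to a
    crisp TFN at its centre (the classical-model treatment of the
    concentration).
    """
    if not samples:
        raise ValueError("cannot run a risk assessment on an empty sample set")
    if not scenarios:
        raise ValueError("at least one exposure scenario is required")

    groups: Dict[str, List[DustSample]] = {}
    for s in samples:
        groups.setdefault(_group_key(s, grouping), []).append(s)

    metals: List[str] = []
    for s in samples:
        for m in s.cdba:
            if m not in metals:
                metals.append(m)

    results: List[GroupRiskResult] = []
    for group_label, group_samples in groups.items():
        cdba_tfns = {
            m: tfn_from_samples([s.cdba[m] for s in group_samples], center_rule)
            for m in metals
        }
        if not fuzzy_concentration:
            cdba_tfns = {
                m: TriangularFuzzyNumber.crisp(t.a2) for m, t in cdba_tfns.items()
            }
        for scn in scenarios:
            res = GroupRiskResult(
                group=group_label,
                receptor=scn.receptor,
                alpha=alpha,
                n_samples=len(group_samples),
                cdba=cdba_tfns,
            )

            hq_totals: List[AlphaCutInterval] = []
            for metal in metals:
                tfn = cdba_tfns[metal]
                res.intake_nc[metal] = {
                    p: _INTAKE_FUNCS[p](tfn, scn, alpha, scn.AT_nc) for p in PATHWAYS
                }
                res.intake_ca[metal] = {
                    p: _INTAKE_FUNCS[p](tfn, scn, alpha, scn.AT_ca) for p in PATHWAYS
                }

                # non-carcinogenic: HQ per pathway with an RfD, summed per metal
                hq_paths: Dict[str, AlphaCutInterval] = {}
                for p in PATHWAYS:
                    rfd = tox.rfd_for(metal, p)
                    if rfd is None:
                        continue
                    hq_paths[p] = hazard_quotient(res.intake_nc[metal][p], rfd)
                if hq_paths:
                    res.hq[metal] = hq_paths
                    total = None
                    for hq in hq_paths.values():
                        total = hq if total is None else interval_add(total, hq)
                    res.hq_total[metal] = total
                    hq_totals.append(total)
                else:
                    logger.info(
                        "group %s/%s: no reference dose for %s on any pathway; "
                        "excluded from HI", group_label, scn.receptor, metal,
                    )

                # carcinogenic: CR per pathway with a slope factor, summed per metal
                cr_paths: Dict[str, AlphaCutInterval] = {}
                for p in PATHWAYS:
                    sf = tox.sf_for(metal, p)
                    if sf is None:
                        continue
                    cr_paths[p] = carcinogenic_risk(res.intake_ca[metal][p], sf)
                if cr_paths:
                    res.cr[metal] = cr_paths
                    total = None
                    for cr in cr_paths.values():
                        total = cr if total is None else interval_add(total, cr)
                    res.cr_total[metal] = total
                    res.membership[metal] = classify_interval(total, scheme, normalization)
                    res.level[metal] = assign_level(res.membership[metal])
                    res.dominant_pathway[metal] = max(
                        cr_paths, key=lambda p: cr_paths[p].midpoint
                    )
                else:
                    logger.info(
                        "group %s/%s: no slope factor for %s on any pathway; "
                        "excluded from CR", group_label, scn.receptor, metal,
                    )

            res.hi, res.hi_below_one = hazard_index(hq_totals, alpha)
            results.append(res)
    return results
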