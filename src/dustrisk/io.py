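"""File formats and configuration: sample tables, YAML configs, run manifests.

Sample tables are comma-delimited text with header columns ``site, season,
replicate`` followed by per-metal pairs ``ct_<metal>`` and ``cdba_<metal>``
(lower-case metal symbol, e.g. ``ct_cd``, ``cdba_cd``), concentrations in
mg/kg.  Seasons are normalised case-insensitively to the four canonical
labels (winter, spring, summer, autumn; "fall" is accepted for autumn).

Exposure scenarios, toxicity parameters and the risk-level scheme are YAML;
bundled standards-derived defaults are used when no path is given.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from .exposure import ExposureScenario, GroupRiskResult, ToxicityParameters
from .fuzzy import RiskLevel, RiskLevelScheme, TriangularFuzzyNumber
from .simulate import DustSample

logger = logging.getLogger(__name__)

__all__ = [
    "CANONICAL_SEASONS",
    "read_samples",
    "write_samples",
    "samples_to_frame",
    "load_scenarios",
    "load_toxicity",
    "load_risk_scheme",
    "dump_risk_scheme",
    "write_manifest",
    "results_to_frames",
]

CANONICAL_SEASONS = ("winter", "spring", "summer", "autumn")
_SEASON_ALIASES = {s: s for s in CANONICAL_SEASONS}
_SEASON_ALIASES["fall"] = "autumn"

PathLike = Union[str, Path]


def normalize_season(label: str) -> str:
    key = str(label).strip().lower()
    if key not in _SEASON_ALIASES:
        raise ValueError(
            f"unknown season label {label!r}; expected one of {CANONICAL_SEASONS}"
        )
    return _SEASON_ALIASES[key]


# ---------------------------------------------------------------------------
# Sample tables
# ---------------------------------------------------------------------------

def samples_to_frame(samples: Sequence[DustSample]) -> pd.DataFrame:
    """Wide table: site, season, replicate, then ct_*/cdba_* per metal (mg/kg)."""
    if not samples:
        raise ValueError("no samples to tabulate")
    metals = list(samples[0].ct)
    rows = []
    for s in samples:
        row = {"site": s.site, "season": s.season, "replicate": s.replicate}
        for m in metals:
            row[f"ct_{m.lower()}"] = s.ct[m]
        for m in metals:
            row[f"cdba_{m.lower()}"] = s.cdba[m]
        rows.append(row)
    return pd.DataFrame(rows)


def write_samples(samples: Sequence[DustSample], path: PathLike) -> None:
    # %.17g round-trips float64 exactly through the text table
    samples_to_frame(samples).to_csv(path, index=False, float_format="%.17g")


def read_samples(path: PathLike) -> List[DustSample]:
    """Read and validate a delimited sample table.

    Errors cite the file row (header is row 1, data start at row 2) and the
    offending column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    if df.empty:
        raise ValueError(f"{path}: no data rows")

    for col in ("site", "season", "replicate"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")

    ct_cols = [c for c in df.columns if c.startswith("ct_")]
    metals = [c[3:] for c in ct_cols]
    if not metals:
        raise ValueError(f"{path}: no ct_<metal> concentration columns found")
    for m in metals:
        if f"cdba_{m}" not in df.columns:
            raise ValueError(f"{path}: missing column cdba_{m} paired with ct_{m}")

    samples: List[DustSample] = []
    for idx, rec in df.iterrows():
        row_no = int(idx) + 2  # header occupies row 1
        season = normalize_season(rec["season"])
        ct: Dict[str, float] = {}
        cdba: Dict[str, float] = {}
        for m in metals:
            metal = m.capitalize()
            for col, target in ((f"ct_{m}", ct), (f"cdba_{m}", cdba)):
                try:
                    target[metal] = float(rec[col])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric value {rec[col]!r} at row {row_no}, "
                        f"column {col!r}"
                    ) from None
            if cdba[metal] > ct[metal]:
                raise ValueError(
                    f"{path}: CDBA > CT for {metal} at row {row_no} "
                    f"({cdba[metal]} > {ct[metal]})"
                )
        try:
            samples.append(
                DustSample(
                    site=str(rec["site"]),
                    season=season,
                    replicate=int(rec["replicate"]),
                    ct=ct,
                    cdba=cdba,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {row_no}: {exc}") from None
    return samples


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def _load_yaml(path: Optional[PathLike], bundled: str) -> dict:
    if path is None:
        text = resources.files("dustrisk.data").joinpath(bundled).read_text()
        return yaml.safe_load(text)
    with open(path) as fh:
        return yaml.safe_load(fh)


def _as_tfn(value, context: str) -> TriangularFuzzyNumber:
    if isinstance(value, (int, float)):
        return TriangularFuzzyNumber.crisp(float(value))
    if isinstance(value, (list, tuple)) and len(value) == 3:
        return TriangularFuzzyNumber(*(float(v) for v in value))
    raise ValueError(
        f"{context}: expected a scalar or a [min, mode, max] triple, got {value!r}"
    )


def load_scenarios(path: Optional[PathLike] = None) -> Dict[str, ExposureScenario]:
    """Exposure scenarios keyed by receptor; bundled defaults if *path* is None."""
    raw = _load_yaml(path, "exposure_defaults.yaml")
    try:
        receptors = raw["receptors"]
    except (KeyError, TypeError):
        raise ValueError("exposure config must contain a 'receptors' mapping") from None
    scenarios = {}
    for receptor, params in receptors.items():
        missing = {"IngR", "InhR", "BW", "ED", "EF", "AT_nc", "AT_ca",
                   "SA", "SSAR", "ABS", "PEF"} - set(params)
        if missing:
            raise ValueError(
                f"exposure config for {receptor!r} is missing {sorted(missing)}"
            )
        scenarios[receptor] = ExposureScenario(
            receptor=receptor,
            IngR=_as_tfn(params["IngR"], f"{receptor}.IngR"),
            InhR=_as_tfn(params["InhR"], f"{receptor}.InhR"),
            BW=_as_tfn(params["BW"], f"{receptor}.BW"),
            ED=float(params["ED"]),
            EF=float(params["EF"]),
            AT_nc=float(params["AT_nc"]),
            AT_ca=float(params["AT_ca"]),
            SA=float(params["SA"]),
            SSAR=float(params["SSAR"]),
            ABS=float(params["ABS"]),
            PEF=float(params["PEF"]),
        )
    return scenarios


def load_toxicity(path: Optional[PathLike] = None) -> ToxicityParameters:
    """RfD/SF tables; bundled standards-derived defaults if *path* is None."""
    raw = _load_yaml(path, "toxicity_defaults.yaml")
    if not isinstance(raw, dict) or ("rfd" not in raw and "sf" not in raw):
        raise ValueError("toxicity config must contain 'rfd' and/or 'sf' mappings")
    return ToxicityParameters(rfd=raw.get("rfd", {}), sf=raw.get("sf", {}))


def load_risk_scheme(path: Optional[PathLike] = None) -> RiskLevelScheme:
    """Risk-level scheme; bundled I–V default if *path* is None."""
    raw = _load_yaml(path, "risk_levels.yaml")
    try:
        levels = raw["levels"]
    except (KeyError, TypeError):
        raise ValueError("risk-level config must contain a 'levels' list") from None
    return RiskLevelScheme(
        levels=tuple(
            RiskLevel(str(lv["label"]), float(lv["lower"]), float(lv["upper"]))
            for lv in levels
        )
    )


def dump_risk_scheme(scheme: RiskLevelScheme, path: PathLike) -> None:
    payload = {
        "levels": [
            {"label": lv.label, "lower": lv.lower, "upper": lv.upper}
            for lv in scheme.levels
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def _sha256(path: Optional[PathLike]) -> Optional[str]:
    if path is None:
        return None
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    out_dir: PathLike,
    inputs: Mapping[str, Optional[PathLike]],
    seed: Optional[int],
    grouping: Optional[str],
    alpha: Optional[float],
) -> Path:
    """Write a provenance manifest into *out_dir* (exactly one per run)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "software": {"name": "dustrisk", "version": __version__},
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": {
            name: {"path": str(p) if p is not None else None, "sha256": _sha256(p)}
            for name, p in inputs.items()
        },
        "seed": seed,
        "grouping": grouping,
        "alpha": alpha,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def results_to_frames(
    results: Sequence[GroupRiskResult], midpoint: bool = False
) -> Dict[str, pd.DataFrame]:
    """Flatten risk results into delimited-text-ready tables.

    Returns ``hi``, ``hq``, ``cr`` and ``membership`` tables.  Intervals are
    reported as left/right endpoints with the α used; an optional midpoint
    column is flagged as derived.
    """
    hi_rows, hq_rows, cr_rows, mem_rows = [], [], [], []
    for r in results:
        hi_rows.append(
            {
                "group": r.group, "receptor": r.receptor, "alpha": r.alpha,
                "n_samples": r.n_samples,
                "hi_left": r.hi.lo, "hi_right": r.hi.hi,
                "below_one": r.hi_below_one,
            }
        )
        for metal, per_path in r.hq.items():
            for pathway, hq in per_path.items():
                hq_rows.append(
                    {
                        "group": r.group, "receptor": r.receptor, "metal": metal,
                        "pathway": pathway, "alpha": r.alpha,
                        "hq_left": hq.lo, "hq_right": hq.hi,
                    }
                )
        for metal, per_path in r.cr.items():
            for pathway, cr in per_path.items():
                cr_rows.append(
                    {
                        "group": r.group, "receptor": r.receptor, "metal": metal,
                        "pathway": pathway, "alpha": r.alpha,
                        "cr_left": cr.lo, "cr_right": cr.hi,
                    }
                )
            total = r.cr_total[metal]
            cr_rows.append(
                {
                    "group": r.group, "receptor": r.receptor, "metal": metal,
                    "pathway": "total", "alpha": r.alpha,
                    "cr_left": total.lo, "cr_right": total.hi,
                }
            )
        for metal, mv in r.membership.items():
            row = {
                "group": r.group, "receptor": r.receptor, "metal": metal,
                "alpha": r.alpha, "level": r.level[metal],
                "dominant_pathway": r.dominant_pathway[metal],
            }
            for label, degree in mv.items():
                row[f"m_{label}"] = degree
            mem_rows.append(row)

    frames = {
        "hi": pd.DataFrame(hi_rows),
        "hq": pd.DataFrame(hq_rows),
        "cr": pd.DataFrame(cr_rows),
        "membership": pd.DataFrame(mem_rows),
    }
    if midpoint:
        for key, left, right in (("hq", "hq_left", "hq_right"), ("cr", "cr_left", "cr_right")):
            df = frames[key]
            if not df.empty:
                df["midpoint_derived"] = 0.5 * (df[left] + df[right])
    return frames
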