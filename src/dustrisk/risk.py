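"""Non-carcinogenic health-risk chain for heavy metals in dust.

The exposure model follows the standard screening-level framework for adult
receptors: an average daily dose (ADD, mg/kg/day) is computed per metal for
three exposure paths — incidental ingestion, inhalation of resuspended
particles, and dermal contact — then divided by the path-specific reference
dose (RfD) to give a hazard quotient (HQ).  Per-metal HQs sum over paths,
and the hazard index (HI) of a site is the sum over metals.  HI > 1 flags a
possible non-carcinogenic effect.

The three dose equations are

    ADD_ing  = c * R_ing * EF * ED / (BW * AT) * 1e-6
    ADD_inh  = c * R_inh * EF * ED / (PEF * BW * AT)
    ADD_derm = c * SA * SL * ABS * EF * ED / (BW * AT) * 1e-6

with c the concentration in mg/kg and the exposure factors documented on
:class:`ExposureFactors`.  The 1e-6 converts mg/kg of dust into kg of dust
per mg ingested/adhered; the inhalation path instead divides by the particle
emission factor PEF (m^3/kg).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

PATHS = ("ing", "inh", "derm")

__all__ = [
    "PATHS",
    "ExposureFactors",
    "ReferenceDoseTable",
    "HazardResult",
    "AddSummary",
    "add_ingestion",
    "add_inhalation",
    "add_dermal",
    "hazard_quotients",
    "hazard_index",
    "summarize_add",
    "invert_ingestion_hq",
]


@dataclass(frozen=True)
class ExposureFactors:
    """Adult exposure factors for dust contact.

    Attributes
    ----------
    R_ing : float
        Dust ingestion rate, mg/day.
    R_inh : float
        Inhalation rate, m^3/day.
    BW : float
        Body weight, kg.
    EF : float
        Exposure frequency, day/year.
    ED : float
        Exposure duration, year.
    AT : float
        Averaging time, day.  For non-carcinogenic screening of a
        continuously exposed adult this is 365 * ED, which makes
        EF*ED/AT dimensionless and equal to 1; it is stored explicitly
        so other averaging conventions remain expressible.
    SA : float
        Exposed skin surface, cm^2.
    SL : float
        Skin adherence factor, mg/cm^2.
    ABS : float
        Dermal absorption factor, dimensionless (<= 1).
    PEF : float
        Particle emission factor, m^3/kg.
    """

    R_ing: float = 100.0
    R_inh: float = 20.0
    BW: float = 70.0
    EF: float = 365.0
    ED: float = 24.0
    AT: float = 365.0 * 24.0
    SA: float = 5700.0
    SL: float = 0.07
    ABS: float = 0.001
    PEF: float = 1.36e9

    def __post_init__(self) -> None:
        for name in ("R_ing", "R_inh", "BW", "EF", "ED", "AT", "SA", "SL", "ABS", "PEF"):
            if not getattr(self, name) > 0:
                raise ValueError(f"exposure factor {name} must be strictly positive")
        if self.ABS > 1:
            raise ValueError("dermal absorption factor ABS must be <= 1")

    @classmethod
    def adult_default(cls) -> "ExposureFactors":
        """The adult exposure profile used throughout this package."""
        return cls()


#: Path-specific reference doses, mg/kg/day: metal -> (ingestion, dermal, inhalation).
_DEFAULT_RFD: dict[str, tuple[float, float, float]] = {
    "Ba": (7e-2, 14e-3, 5e-4),
    "Cd": (5e-4, 5e-6, 2e-5),
    "Co": (3e-2, 5e-6, 6e-6),
    "Cr": (3e-3, 15e-6, 1.4e-4),
    "Cu": (4e-2, 12e-3, 1e-4),
    "Fe": (0.7, 2.2e-4, 7e-3),
    "Mn": (2e-2, 8e-4, 5e-5),
    "Ni": (2e-2, 54e-4, 2e-5),
    "Pb": (14e-4, 42e-5, 1e-4),
    "Zn": (0.300, 0.0600, 0.300),
}


@dataclass(frozen=True)
class ReferenceDoseTable:
    """Reference doses (mg/kg/day) per metal and exposure path.

    ``doses`` maps a metal name to ``{"ing": ..., "derm": ..., "inh": ...}``.
    Metal lookup is case-insensitive.
    """

    doses: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for metal, entry in self.doses.items():
            for path in PATHS:
                if path not in entry:
                    raise ValueError(f"RfD for {metal} missing path {path!r}")
                if not entry[path] > 0:
                    raise ValueError(f"RfD for {metal}/{path} must be strictly positive")

    @classmethod
    def default(cls) -> "ReferenceDoseTable":
        """The literature RfD grid for the ten metals analysed here."""
        return cls(
            {m: {"ing": i, "derm": d, "inh": h} for m, (i, d, h) in _DEFAULT_RFD.items()}
        )

    def _canonical(self, metal: str) -> str:
        folded = {m.lower(): m for m in self.doses}
        try:
            return folded[metal.lower()]
        except KeyError:
            known = ", ".join(sorted(self.doses))
            raise KeyError(f"no reference dose for metal {metal!r}; known metals: {known}") from None

    def get(self, metal: str, path: str) -> float:
        if path not in PATHS:
            raise ValueError(f"unknown exposure path {path!r}; expected one of {PATHS}")
        return float(self.doses[self._canonical(metal)][path])

    def metals(self) -> list[str]:
        return list(self.doses)


def _check_conc(c):
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative (mg/kg)")
    return c


def add_ingestion(c, f: ExposureFactors):
    """Average daily dose via incidental dust ingestion, mg/kg/day."""
    c = _check_conc(c)
    return c * f.R_ing * f.EF * f.ED / (f.BW * f.AT) * 1e-6


def add_inhalation(c, f: ExposureFactors):
    """Average daily dose via inhalation of resuspended dust, mg/kg/day."""
    c = _check_conc(c)
    return c * f.R_inh * f.EF * f.ED / (f.PEF * f.BW * f.AT)


def add_dermal(c, f: ExposureFactors):
    """Average daily dose via dermal contact with adhered dust, mg/kg/day."""
    c = _check_conc(c)
    return c * f.SA * f.SL * f.ABS * f.EF * f.ED / (f.BW * f.AT) * 1e-6


_ADD_FUNCS = {"ing": add_ingestion, "inh": add_inhalation, "derm": add_dermal}


def invert_ingestion_hq(hq_ing: float, metal: str, f: ExposureFactors, rfd: ReferenceDoseTable) -> float:
    """Concentration (mg/kg) whose ingestion hazard quotient equals ``hq_ing``.

    Inverts HQ_ing = c * R_ing * EF * ED / (BW * AT) * 1e-6 / RfD_ing for c.
    Useful for back-calculating a site concentration from a reported HQ.
    """
    if hq_ing < 0:
        raise ValueError("hazard quotient must be non-negative")
    return hq_ing * rfd.get(metal, "ing") * f.BW * f.AT / (f.R_ing * f.EF * f.ED * 1e-6)


@dataclass
class HazardResult:
    """Dose and hazard surfaces for a site x metal concentration table.

    Attributes
    ----------
    ADD : pd.DataFrame
        MultiIndex columns (metal, path); one row per site; mg/kg/day.
    HQ_path : pd.DataFrame
        Same layout; dimensionless hazard quotients per path.
    HQ_metal : pd.DataFrame
        Site x metal, HQ summed over the three paths.
    HI : pd.Series
        Hazard index per site (sum of HQ_metal over metals).
    risk_flag : pd.Series
        Boolean per site, True where HI > 1 (strict).
    """

    ADD: pd.DataFrame
    HQ_path: pd.DataFrame
    HQ_metal: pd.DataFrame
    HI: pd.Series
    risk_flag: pd.Series


def hazard_quotients(
    concentrations: pd.DataFrame,
    f: ExposureFactors | None = None,
    rfd: ReferenceDoseTable | None = None,
) -> HazardResult:
    """Compute ADD, HQ per path, HQ per metal, HI and risk flags.

    Parameters
    ----------
    concentrations : DataFrame
        Site x metal concentrations in mg/kg; index labels the sites.
    f : ExposureFactors, optional
        Defaults to the adult profile.
    rfd : ReferenceDoseTable, optional
        Defaults to the packaged literature grid.  Every metal column must
        have an entry (matched case-insensitively).
    """
    f = f or ExposureFactors.adult_default()
    rfd = rfd or ReferenceDoseTable.default()
    if concentrations.shape[0] < 1 or concentrations.shape[1] < 1:
        raise ValueError("concentration table must have at least one site and one metal")
    _check_conc(concentrations.to_numpy())

    metals = list(concentrations.columns)
    add_cols = {}
    hq_cols = {}
    for metal in metals:
        c = concentrations[metal].to_numpy(dtype=float)
        for path in PATHS:
            add = _ADD_FUNCS[path](c, f)
            add_cols[(metal, path)] = add
            hq_cols[(metal, path)] = add / rfd.get(metal, path)

    idx = concentrations.index
    cols = pd.MultiIndex.from_product([metals, PATHS], names=["metal", "path"])
    ADD = pd.DataFrame(add_cols, index=idx)
    ADD.columns = cols
    HQ_path = pd.DataFrame(hq_cols, index=idx)
    HQ_path.columns = cols
    HQ_metal = HQ_path.T.groupby(level="metal", sort=False).sum().T[metals]
    HI = HQ_metal.sum(axis=1)
    HI.name = "HI"
    flag = HI > 1.0
    flag.name = "risk_flag"
    return HazardResult(ADD=ADD, HQ_path=HQ_path, HQ_metal=HQ_metal, HI=HI, risk_flag=flag)


def hazard_index(result: HazardResult) -> pd.Series:
    """Hazard index per site (sum of per-metal HQs); also stored on the result."""
    return result.HI


@dataclass
class AddSummary:
    """Min / max / mean ADD per metal and path, with arg-min/arg-max sites.

    ``table`` has MultiIndex rows (metal, path) and columns
    ``min, min_site, max, max_site, mean``.  ``scale`` is a purely
    presentational multiplier applied to ``scaled_table`` (the conventional
    report prints ADD x 1e8); the unscaled values are authoritative.
    """

    table: pd.DataFrame
    scale: float = 1e8

    @property
    def scaled_table(self) -> pd.DataFrame:
        out = self.table.copy()
        for col in ("min", "max", "mean"):
            out[col] = out[col] * self.scale
        return out


def summarize_add(result: HazardResult, scale: float = 1e8) -> AddSummary:
    """Summarise the ADD surface per metal x path.

    Ties for the extreme value are resolved to the first site in input
    order.
    """
    rows = []
    for metal, path in result.ADD.columns:
        col = result.ADD[(metal, path)]
        imin = int(np.argmin(col.to_numpy()))
        imax = int(np.argmax(col.to_numpy()))
        rows.append(
            {
                "metal": metal,
                "path": path,
                "min": float(col.iloc[imin]),
                "min_site": col.index[imin],
                "max": float(col.iloc[imax]),
                "max_site": col.index[imax],
                "mean": float(col.mean()),
            }
        )
    table = pd.DataFrame(rows).set_index(["metal", "path"])
    return AddSummary(table=table, scale=scale)
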