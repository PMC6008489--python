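"""Potency transforms: Cheng-Prusoff Ki, pKi, ligand efficiency, and the
single-concentration inhibition model.

An IC50 measured in an ATP-competitive kinase assay depends on the ATP
concentration used; the Cheng-Prusoff relation

    Ki = IC50 / (1 + [ATP]/Km,ATP)

removes that dependence so activities measured under different assay
conditions can be compared on one scale.  Ligand efficiency normalises
binding free energy by molecular size:

    LE = 1.37 * pKi / HAC     (kcal/mol per heavy atom, T = 298 K)

where pKi = -log10(Ki in molar) and HAC is the heavy-atom count.
All concentrations are in micromolar throughout; the molar conversion
happens only inside ``pki``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from ._util import round_half_up

__all__ = [
    "AssayCondition",
    "PotencyRecord",
    "Ic50Estimate",
    "cheng_prusoff_ki",
    "pki",
    "ligand_efficiency",
    "single_point_inhibition",
    "ic50_from_single_point",
    "read_assay_conditions",
    "build_potency_table",
]

#: Free-energy conversion at 298 K: 2.303*R*T in kcal/mol per pKi unit.
LE_KCAL_PER_PKI = 1.37


@dataclass(frozen=True)
class AssayCondition:
    """Per-kinase ATP concentration and ATP Km, both in µM."""

    kinase_id: str
    atp_conc: float
    km_atp: float

    def __post_init__(self) -> None:
        if self.atp_conc < 0:
            raise ValueError(f"{self.kinase_id}: atp_conc must be >= 0")
        if self.km_atp <= 0:
            raise ValueError(f"{self.kinase_id}: km_atp must be > 0")

    @property
    def atp_over_km(self) -> float:
        return self.atp_conc / self.km_atp


def cheng_prusoff_ki(ic50: float, atp_conc: float, km_atp: float) -> float:
    """Convert an IC50 (µM) to Ki (µM) for an ATP-competitive inhibitor.

    Ki = IC50 / (1 + [ATP]/Km).  Ki equals IC50 at [ATP] = 0 and is
    strictly decreasing in [ATP].
    """
    if ic50 <= 0:
        raise ValueError(f"ic50 must be > 0, got {ic50}")
    if km_atp <= 0:
        raise ValueError(f"km_atp must be > 0, got {km_atp}")
    if atp_conc < 0:
        raise ValueError(f"atp_conc must be >= 0, got {atp_conc}")
    return ic50 / (1.0 + atp_conc / km_atp)


def pki(ki_um: float) -> float:
    """-log10 of Ki expressed in molar, for Ki given in µM."""
    if ki_um <= 0:
        raise ValueError(f"ki must be > 0, got {ki_um}")
    return -math.log10(ki_um * 1e-6)


def ligand_efficiency(ki_um: float, heavy_atoms: int) -> float:
    """Binding free energy per heavy atom: 1.37 * pKi / HAC (kcal/mol/HA)."""
    if heavy_atoms < 1:
        raise ValueError(f"heavy_atoms must be >= 1, got {heavy_atoms}")
    return LE_KCAL_PER_PKI * pki(ki_um) / heavy_atoms


def single_point_inhibition(ic50: float, conc: float, hill: float = 1.0) -> float:
    """Expected % inhibition at one concentration for a one-site model.

    100 / (1 + (IC50/conc)^hill); 0 at conc = 0, 50 at conc = IC50.
    """
    if ic50 <= 0:
        raise ValueError(f"ic50 must be > 0, got {ic50}")
    if hill <= 0:
        raise ValueError(f"hill must be > 0, got {hill}")
    if conc < 0:
        raise ValueError(f"conc must be >= 0, got {conc}")
    if conc == 0:
        return 0.0
    return 100.0 / (1.0 + (ic50 / conc) ** hill)


@dataclass(frozen=True)
class Ic50Estimate:
    """IC50 inferred from one %-inhibition point; possibly only a bound.

    ``censor`` is ``None`` for an exact value, ``">"`` when inhibition was
    at/below 0% (IC50 above the bound), ``"<"`` when at/above 100%
    (IC50 below the bound).  The bound is the screening concentration.
    """

    value: float
    censor: Optional[str] = None

    @property
    def censored(self) -> bool:
        return self.censor is not None


def ic50_from_single_point(pct: float, conc: float, hill: float = 1.0) -> Ic50Estimate:
    """Invert the single-point model: IC50 = conc * ((100-pct)/pct)^(1/hill).

    Exact inverse of :func:`single_point_inhibition` on 0 < pct < 100.
    Out-of-range responses (saturated or no inhibition) yield a censored
    bound at the screening concentration rather than an extrapolation.
    """
    if conc <= 0:
        raise ValueError(f"conc must be > 0, got {conc}")
    if hill <= 0:
        raise ValueError(f"hill must be > 0, got {hill}")
    if pct <= 0:
        return Ic50Estimate(conc, censor=">")
    if pct >= 100:
        return Ic50Estimate(conc, censor="<")
    return Ic50Estimate(conc * ((100.0 - pct) / pct) ** (1.0 / hill))


@dataclass
class PotencyRecord:
    """Per compound-kinase potency: IC50, Ki, pKi, LE under stated conditions.

    Censored entries (">100" style) carry the bound in ``ic50``/``ki`` and
    no ligand efficiency, mirroring the "> x (-)" table convention.
    """

    compound_id: str
    kinase_id: str
    ic50: Optional[float]
    ki: Optional[float]
    pki: Optional[float]
    le: Optional[float]
    censored: bool = False

    def render_ki_le(self, dp: int = 2) -> str:
        """Human-readable "Ki (LE)" cell, e.g. ``"94.7 (0.39)"`` or ``">100 (-)"``."""
        if self.censored:
            bound = self.ki if self.ki is not None else self.ic50
            return f">{round_half_up(bound, 1):g} (-)"
        le = "-" if self.le is None else f"{round_half_up(self.le, dp):.{dp}f}"
        return f"{round_half_up(self.ki, 1):g} ({le})"


def read_assay_conditions(path) -> dict[str, AssayCondition]:
    """Read ``kinase_id,atp_conc_uM,km_atp_uM`` delimited text."""
    df = pd.read_csv(path, comment="#")
    need = {"kinase_id", "atp_conc_uM", "km_atp_uM"}
    if not need <= set(df.columns):
        raise ValueError(f"assay-condition table missing columns: {sorted(need - set(df.columns))}")
    out = {}
    for _, row in df.iterrows():
        cond = AssayCondition(str(row["kinase_id"]), float(row["atp_conc_uM"]), float(row["km_atp_uM"]))
        out[cond.kinase_id] = cond
    return out


def _parse_ic50_cell(cell) -> tuple[float, bool]:
    """Parse an IC50 table cell; a ``>`` prefix marks a censored bound."""
    s = str(cell).strip()
    if s.startswith(">"):
        return float(s[1:]), True
    return float(s), False


def build_potency_table(
    ic50_table: pd.DataFrame,
    conditions: dict[str, AssayCondition],
    heavy_atoms: dict[str, int] | None = None,
    warn=None,
) -> list[PotencyRecord]:
    """Turn an IC50 input table into full potency records.

    ``ic50_table`` needs columns ``compound_id,kinase_id,ic50_uM`` (the IC50
    column may carry ``>`` censored entries).  ``heavy_atoms`` maps compound
    id -> HAC; compounds absent from it get Ki/pKi but a blank LE (``warn``
    is called with a message for each).  Censored rows get the Cheng-Prusoff
    scaled bound and no pKi/LE.
    """
    need = {"compound_id", "kinase_id", "ic50_uM"}
    if not need <= set(ic50_table.columns):
        raise ValueError(f"IC50 table missing columns: {sorted(need - set(ic50_table.columns))}")
    records = []
    for _, row in ic50_table.iterrows():
        cid, kid = str(row["compound_id"]), str(row["kinase_id"])
        if kid not in conditions:
            raise KeyError(f"no assay condition for kinase {kid!r}")
        cond = conditions[kid]
        ic50, censored = _parse_ic50_cell(row["ic50_uM"])
        ki = cheng_prusoff_ki(ic50, cond.atp_conc, cond.km_atp)
        if censored:
            records.append(PotencyRecord(cid, kid, ic50, ki, None, None, censored=True))
            continue
        p = pki(ki)
        le = None
        if heavy_atoms is not None and cid in heavy_atoms:
            le = LE_KCAL_PER_PKI * p / heavy_atoms[cid]
        elif warn is not None:
            warn(f"compound {cid!r}: no heavy-atom count, LE left blank")
        records.append(PotencyRecord(cid, kid, ic50, ki, p, le))
    return records


def potency_records_frame(records: list[PotencyRecord]) -> pd.DataFrame:
    """Records as the output table ``compound_id,kinase_id,ic50_uM,ki_uM,pki,le,censored``."""
    return pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "kinase_id": r.kinase_id,
                "ic50_uM": r.ic50,
                "ki_uM": r.ki,
                "pki": r.pki,
                "le": r.le,
                "censored": r.censored,
            }
            for r in records
        ],
        columns=["compound_id", "kinase_id", "ic50_uM", "ki_uM", "pki", "le", "censored"],
    )
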