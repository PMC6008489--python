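"""Panel selectivity scores over a single-point kinase screen.

A compound screened at one concentration against a panel of K kinases gets
the selectivity score

    S_compound(theta) = #{kinases with % inhibition > theta} / #{measured}

ranging from 0 (inactive or perfectly selective) to 1 (hits everything).
The mirror-image S_kinase(theta) scores a kinase by the fraction of library
compounds that inhibit it above threshold.  The comparison is strict
(> theta); missing cells drop out of the denominator, so a compound with an
unmeasured kinase is scored over the cells that exist.

Scores are kept as exact integer ratios (hits, evaluated) and rounded only
for presentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PanelProfile", "SelectivityScore", "s_compound", "s_kinase",
           "selectivity_table", "read_panel_profile", "write_panel_profile"]


@dataclass(frozen=True)
class SelectivityScore:
    """One selectivity score with its counting provenance."""

    subject_type: str  # "compound" or "kinase"
    subject_id: str
    theta: float
    hits: int
    evaluated: int

    def __post_init__(self) -> None:
        if not (0 <= self.hits <= self.evaluated):
            raise ValueError(f"invalid score counts: {self.hits}/{self.evaluated}")

    @property
    def score(self) -> float:
        return self.hits / self.evaluated


@dataclass
class PanelProfile:
    """Compound x kinase matrix of % inhibition at a stated concentration.

    ``inhibition`` is indexed by compound id with one column per kinase;
    NaN marks a missing measurement.  ``screen_conc`` gives each compound's
    screening concentration in µM (compounds with poor solubility are
    commonly screened lower, e.g. 30 instead of 100 µM).
    """

    inhibition: pd.DataFrame
    screen_conc: pd.Series

    def __post_init__(self) -> None:
        mat = self.inhibition
        if mat.index.has_duplicates or mat.columns.has_duplicates:
            raise ValueError("duplicate compound or kinase ids in profile")
        vals = mat.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -100 or finite.max() > 200):
            raise ValueError("% inhibition outside the plausible [-100, 200] range")
        if mat.shape[1] and mat.isna().all(axis=1).any():
            bad = mat.index[mat.isna().all(axis=1)].tolist()
            raise ValueError(f"compounds with no measurements: {bad}")
        conc = self.screen_conc.reindex(mat.index)
        if conc.isna().any() or (conc <= 0).any():
            raise ValueError("every compound needs a positive screen_conc")
        object.__setattr__(self, "screen_conc", conc)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.inhibition.index)

    @property
    def kinase_ids(self) -> list[str]:
        return list(self.inhibition.columns)


def _count(values: np.ndarray, theta: float) -> tuple[int, int]:
    mask = np.isfinite(values)
    return int((values[mask] > theta).sum()), int(mask.sum())


def s_compound(profile: PanelProfile, compound_id: str, theta: float = 50.0) -> SelectivityScore:
    """Fraction of the panel this compound inhibits by more than *theta* %."""
    if compound_id not in profile.inhibition.index:
        raise KeyError(f"unknown compound {compound_id!r}")
    row = profile.inhibition.loc[compound_id].to_numpy(dtype=float)
    hits, evaluated = _count(row, theta)
    if evaluated == 0:
        raise ValueError(f"compound {compound_id!r} has no measured cells")
    return SelectivityScore("compound", compound_id, theta, hits, evaluated)


def s_kinase(profile: PanelProfile, kinase_id: str, theta: float = 50.0) -> SelectivityScore:
    """Fraction of the library that inhibits this kinase by more than *theta* %."""
    if kinase_id not in profile.inhibition.columns:
        raise KeyError(f"unknown kinase {kinase_id!r}")
    col = profile.inhibition[kinase_id].to_numpy(dtype=float)
    hits, evaluated = _count(col, theta)
    if evaluated == 0:
        raise ValueError(f"kinase {kinase_id!r} has no measured cells")
    return SelectivityScore("kinase", kinase_id, theta, hits, evaluated)


def selectivity_table(profile: PanelProfile, thetas=(50.0,), subjects: str = "both") -> pd.DataFrame:
    """All selectivity scores as a tidy table.

    One row per subject per threshold, columns
    ``subject_type,subject_id,theta,hits,evaluated,score``.  For a fixed
    subject the score is non-increasing in theta.
    """
    if subjects not in {"both", "compound", "kinase"}:
        raise ValueError(f"subjects must be both/compound/kinase, got {subjects!r}")
    rows = []
    if subjects in ("both", "compound"):
        for cid in profile.compound_ids:
            for theta in thetas:
                rows.append(s_compound(profile, cid, theta))
    if subjects in ("both", "kinase"):
        for kid in profile.kinase_ids:
            for theta in thetas:
                try:
                    rows.append(s_kinase(profile, kid, theta))
                except ValueError:
                    continue  # all-missing column: nothing to report
    return pd.DataFrame(
        [
            {
                "subject_type": s.subject_type,
                "subject_id": s.subject_id,
                "theta": s.theta,
                "hits": s.hits,
                "evaluated": s.evaluated,
                "score": s.score,
            }
            for s in rows
        ],
        columns=["subject_type", "subject_id", "theta", "hits", "evaluated", "score"],
    )


def read_panel_profile(path) -> PanelProfile:
    """Read a profile table: ``compound_id,screen_conc_uM,<kinase>,...``; blank = missing."""
    df = pd.read_csv(path, comment="#", dtype={0: str})
    if df.columns[0] != "compound_id" or df.columns[1] != "screen_conc_uM":
        raise ValueError("panel profile must start with compound_id,screen_conc_uM columns")
    df = df.set_index("compound_id")
    df.index = df.index.astype(str)
    conc = df.pop("screen_conc_uM").astype(float)
    return PanelProfile(df.astype(float), conc)


def write_panel_profile(profile: PanelProfile, path) -> None:
    out = profile.inhibition.copy()
    out.insert(0, "screen_conc_uM", profile.screen_conc)
    out.index.name = "compound_id"
    out.to_csv(path)
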