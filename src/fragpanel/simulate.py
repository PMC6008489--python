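"""Synthetic kinase panel screens with known ground truth.

The generator emulates the statistical structure of a fragment-library
panel screen: a compound x kinase matrix of true affinities (pKi), pushed
through the assay forward model — Cheng-Prusoff inflation of Ki to IC50
under each kinase's [ATP]/Km, a one-site single-point response at the
screening concentration, additive Gaussian read noise, clipping to the
range real normalised readouts occupy, and optional missing cells — plus
replicated 8-point half-log dose-response curves for chosen pairs.

Compounds come in three archetypes mirroring what a fragment screen
actually yields:

* promiscuous — decent affinity everywhere (pKi ~ N(5.0, 0.5) per kinase),
* selective   — weak baseline (pKi ~ N(3.0, 0.3)) with 1-3 boosted targets
  (+1.5 log units),
* inactive    — uniformly weak (pKi ~ N(2.5, 0.3)).

All randomness flows from one integer seed through independent
``numpy.random.default_rng`` streams; the same seed reproduces every
artefact bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .dose_response import four_pl
from .potency import AssayCondition, single_point_inhibition
from .selectivity import PanelProfile, write_panel_profile

__all__ = ["SimulationConfig", "GroundTruth", "sample_truth", "forward_screen",
           "forward_curves", "expected_s_compound", "write_bundle", "DEFAULT_PANEL"]

#: A 26-kinase panel spanning the TK, CMGC, CAMK, CK1 and AGC branches of
#: the kinome, anchored on the mitotic kinases the analysis focuses on.
DEFAULT_PANEL: tuple[str, ...] = (
    "MPS1", "AURKA", "AURKB", "AKT2", "CHK1", "CHK2", "PKCZ", "PKA",
    "ABL", "GSK3B", "RSK1", "PKD2", "EGFR", "SRC", "LCK", "CDK2",
    "ERK2", "P38A", "JNK1", "CK1D", "CAMK2", "PIM1", "ROCK2", "MET",
    "FGFR1", "INSR",
)

ARCHETYPES = ("promiscuous", "selective", "inactive")


@dataclass
class SimulationConfig:
    """Study-scale defaults: a 26-kinase panel, a ~24-member fragment
    library, 100 µM single-point screen, [ATP] = Km, 5% single-point and
    2% curve read noise, 8-point half-log dilutions from 100 µM in
    triplicate, 2% random dropout."""

    seed: int
    n_kinases: int = 26
    n_compounds: int = 24
    screen_conc: float = 100.0
    atp_over_km: float = 1.0
    noise_sd_single_point: float = 5.0
    noise_sd_curve: float = 2.0
    top_conc: float = 100.0
    dilution_fold: float = 10.0 ** 0.5
    n_points: int = 8
    n_replicates: int = 3
    archetype_mix: tuple[float, float, float] = (0.2, 0.4, 0.4)
    dropout_prob: float = 0.02
    clip_lo: float = -20.0
    clip_hi: float = 120.0
    kinase_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if abs(sum(self.archetype_mix) - 1.0) > 1e-9:
            raise ValueError("archetype_mix fractions must sum to 1")
        if min(self.noise_sd_single_point, self.noise_sd_curve) < 0:
            raise ValueError("noise sds must be >= 0")
        if self.n_compounds < 1 or self.n_kinases < 1:
            raise ValueError("n_compounds and n_kinases must be >= 1")
        if not (0 <= self.dropout_prob < 1):
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.kinase_ids is None:
            if self.n_kinases <= len(DEFAULT_PANEL):
                self.kinase_ids = DEFAULT_PANEL[: self.n_kinases]
            else:
                extra = tuple(f"KIN{i:02d}" for i in range(len(DEFAULT_PANEL), self.n_kinases))
                self.kinase_ids = DEFAULT_PANEL + extra
        elif len(self.kinase_ids) != self.n_kinases:
            raise ValueError("kinase_ids length must equal n_kinases")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream derived from the master seed."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    """True affinities behind a simulated screen.

    ``true_pki`` and ``true_hill`` are compound x kinase DataFrames;
    ``assay_conditions`` maps kinase id to its [ATP]/Km setting;
    ``archetypes`` records each compound's generating archetype.
    """

    true_pki: pd.DataFrame
    true_hill: pd.DataFrame
    assay_conditions: dict[str, AssayCondition]
    archetypes: pd.Series

    def true_ic50_um(self) -> pd.DataFrame:
        """True IC50 (µM) per cell: Ki * (1 + [ATP]/Km), Ki = 10^(6 - pKi) µM."""
        ki = 10.0 ** (6.0 - self.true_pki)
        factors = pd.Series(
            {k: 1.0 + c.atp_over_km for k, c in self.assay_conditions.items()}
        ).reindex(self.true_pki.columns)
        return ki * factors


def sample_truth(config: SimulationConfig) -> GroundTruth:
    """Draw a ground-truth affinity matrix under the archetype model."""
    rng = config.rng(0)
    n_c, n_k = config.n_compounds, config.n_kinases
    compound_ids = [f"S{i + 1}" for i in range(n_c)]
    archetypes = rng.choice(ARCHETYPES, size=n_c, p=list(config.archetype_mix))

    pki = np.empty((n_c, n_k))
    for i, arch in enumerate(archetypes):
        if arch == "promiscuous":
            pki[i] = rng.normal(5.0, 0.5, n_k)
        elif arch == "selective":
            pki[i] = rng.normal(3.0, 0.3, n_k)
            n_targets = rng.integers(1, 4)  # 1-3 boosted target kinases
            targets = rng.choice(n_k, size=n_targets, replace=False)
            pki[i, targets] += 1.5
        else:
            pki[i] = rng.normal(2.5, 0.3, n_k)

    kinases = list(config.kinase_ids)
    conditions = {
        k: AssayCondition(k, atp_conc=config.atp_over_km, km_atp=1.0) for k in kinases
    }
    return GroundTruth(
        true_pki=pd.DataFrame(pki, index=compound_ids, columns=kinases),
        true_hill=pd.DataFrame(1.0, index=compound_ids, columns=kinases),
        assay_conditions=conditions,
        archetypes=pd.Series(archetypes, index=compound_ids, name="archetype"),
    )


def forward_screen(truth: GroundTruth, config: SimulationConfig) -> PanelProfile:
    """Simulate the single-point panel screen from the ground truth.

    Per cell: % inhibition of the one-site model at the screening
    concentration, plus N(0, noise_sd) read noise, clipped to
    [clip_lo, clip_hi]; cells then drop out independently with
    ``dropout_prob`` (a row is never left empty).
    """
    rng = config.rng(1)
    ic50 = truth.true_ic50_um().to_numpy()
    conc = config.screen_conc
    clean = 100.0 / (1.0 + (ic50 / conc) ** truth.true_hill.to_numpy())
    noisy = clean + rng.normal(0.0, config.noise_sd_single_point, clean.shape) \
        if config.noise_sd_single_point > 0 else clean.copy()
    noisy = np.clip(noisy, config.clip_lo, config.clip_hi)
    if config.dropout_prob > 0:
        drop = rng.random(noisy.shape) < config.dropout_prob
        # keep at least one measured cell per compound
        full_rows = drop.all(axis=1)
        drop[full_rows, 0] = False
        noisy = np.where(drop, np.nan, noisy)
    mat = pd.DataFrame(noisy, index=truth.true_pki.index, columns=truth.true_pki.columns)
    conc_series = pd.Series(conc, index=mat.index, name="screen_conc_uM")
    return PanelProfile(mat, conc_series)


def forward_curves(truth: GroundTruth, config: SimulationConfig,
                   subset: list[tuple[str, str]]) -> pd.DataFrame:
    """Simulate replicated dose-response curves for compound-kinase pairs.

    Returns a long table ``compound_id,kinase_id,conc_uM,response_pct``:
    ``n_points`` concentrations in a ``dilution_fold`` series from
    ``top_conc``, each in ``n_replicates``, responses 4PL(true IC50,
    true hill, 100, 0) + N(0, noise_sd_curve).
    """
    rng = config.rng(2)
    concs = config.top_conc / config.dilution_fold ** np.arange(config.n_points)
    ic50 = truth.true_ic50_um()
    rows = []
    for cid, kid in subset:
        true_ic50 = float(ic50.loc[cid, kid])
        true_hill = float(truth.true_hill.loc[cid, kid])
        clean = four_pl(concs, true_ic50, true_hill, 100.0, 0.0)
        for _ in range(config.n_replicates):
            noise = rng.normal(0.0, config.noise_sd_curve, config.n_points) \
                if config.noise_sd_curve > 0 else 0.0
            resp = clean + noise
            for c, r in zip(concs, resp):
                rows.append({"compound_id": cid, "kinase_id": kid,
                             "conc_uM": c, "response_pct": r})
    return pd.DataFrame(rows, columns=["compound_id", "kinase_id", "conc_uM", "response_pct"])


def expected_s_compound(truth: GroundTruth, config: SimulationConfig,
                        compound_id: str, theta: float = 50.0) -> float:
    """Noise-free S_compound(theta) implied by the ground truth.

    With no read noise, a cell exceeds theta iff its true IC50 satisfies
    the inverted single-point model; this is the analytic value the
    noiseless forward screen must reproduce exactly.
    """
    ic50 = truth.true_ic50_um().loc[compound_id].to_numpy()
    hill = truth.true_hill.loc[compound_id].to_numpy()
    pct = 100.0 / (1.0 + (ic50 / config.screen_conc) ** hill)
    return float((pct > theta).mean())


def write_bundle(outdir, config: SimulationConfig) -> dict[str, str]:
    """Generate a full synthetic dataset and write it as CSV files.

    Writes compounds.csv, assay_conditions.csv, panel_profile.csv,
    dose_response.csv, ground_truth.csv and config.json into *outdir*;
    returns a manifest of SHA-256 digests (also written as manifest.json).
    Dose-response curves cover every pair whose true IC50 lies inside the
    tested dilution range.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = sample_truth(config)
    profile = forward_screen(truth, config)

    rng = config.rng(3)
    hac = rng.integers(8, 27, config.n_compounds)  # fragment-sized molecules
    compounds = pd.DataFrame({
        "compound_id": truth.true_pki.index,
        "name": [f"synthetic fragment {c}" for c in truth.true_pki.index],
        "ion_formula": "",
        "neutral_formula": "",
        "heavy_atoms": hac,
    })

    conditions = pd.DataFrame(
        [{"kinase_id": k, "atp_conc_uM": c.atp_conc, "km_atp_uM": c.km_atp}
         for k, c in truth.assay_conditions.items()]
    )

    ic50 = truth.true_ic50_um()
    c_min = config.top_conc / config.dilution_fold ** (config.n_points - 1)
    subset = [(cid, kid) for cid in ic50.index for kid in ic50.columns
              if c_min <= ic50.loc[cid, kid] <= config.top_conc]
    curves = forward_curves(truth, config, subset)

    gt = truth.true_pki.stack().rename("true_pki").reset_index()
    gt.columns = ["compound_id", "kinase_id", "true_pki"]
    gt["true_hill"] = 1.0
    gt["archetype"] = gt["compound_id"].map(truth.archetypes)

    compounds.to_csv(outdir / "compounds.csv", index=False)
    conditions.to_csv(outdir / "assay_conditions.csv", index=False)
    write_panel_profile(profile, outdir / "panel_profile.csv")
    curves.to_csv(outdir / "dose_response.csv", index=False)
    gt.to_csv(outdir / "ground_truth.csv", index=False)
    cfg = asdict(config)
    cfg["kinase_ids"] = list(config.kinase_ids)
    (outdir / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")

    manifest = {}
    for name in ("compounds.csv", "assay_conditions.csv", "panel_profile.csv",
                 "dose_response.csv", "ground_truth.csv", "config.json"):
        manifest[name] = hashlib.sha256((outdir / name).read_bytes()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
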