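"""Synthetic sequences, activities and halos for end-to-end testing.

The generator emulates the statistical structure the method assumes, so the
whole pipeline (sequences -> PseAAC features -> cross-validated prediction)
can be exercised and its parameter recovery measured without any laboratory
data: residues are drawn i.i.d. (uniform by default, or from a fixed
xylanase-like composition), per-condition activities are a linear function
of the TRUE PseAAC features plus Gaussian noise of standard deviation
``sigma`` (IU ml^-1, clipped at zero), and halo diameters are a monotone
affine map of a latent activity score plus optional noise, labelled through
the halo thresholds.

Defaults mirror the study's scale: 41 strains, sequence lengths 180-230 (a
typical GH11 catalytic domain), activities spanning roughly 0-900 IU ml^-1,
halos 2-8 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import CONDITIONS, StrainRecord, StudyDataset, write_fasta, write_strain_table
from .errors import ParameterError
from .halo import DEFAULT_THRESHOLDS, HaloThresholds, classify_halo
from .pseaac import (
    CANONICAL_RESIDUES,
    EnzymeSequence,
    PseAACParams,
    extract_features,
)

#: A fixed GH11-xylanase-like residue composition (synthetic stand-in for a
#: real family profile: these enzymes are rich in G/S/T/N/Y and poor in
#: C/M). Used by the "xylanase" composition mode.
XYLANASE_LIKE_COMPOSITION = {
    "A": 0.055, "C": 0.003, "D": 0.045, "E": 0.030, "F": 0.040,
    "G": 0.110, "H": 0.015, "I": 0.045, "K": 0.050, "L": 0.045,
    "M": 0.012, "N": 0.085, "P": 0.025, "Q": 0.030, "R": 0.040,
    "S": 0.110, "T": 0.095, "V": 0.055, "W": 0.040, "Y": 0.070,
}


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    sigma is the activity noise SD in IU ml^-1; the activity signal itself
    has an SD of roughly 150-200 IU ml^-1 under the default coefficients, so
    sigma ~ 50 is mild noise and sigma ~ 400 drowns the signal.
    """

    n_sequences: int = 41
    length_range: tuple[int, int] = (180, 230)
    seed: int = 0
    composition: str = "uniform"  # or "xylanase"
    sigma: float = 50.0
    activity_intercept: float = 350.0
    coefficient_scale: float = 2000.0
    halo_range: tuple[float, float] = (2.0, 8.0)
    halo_noise_sd: float = 0.0
    lambda_: int = 7
    weight: float = 0.05
    thresholds: HaloThresholds = field(default_factory=HaloThresholds)

    def __post_init__(self):
        if self.n_sequences < 0:
            raise ParameterError("n_sequences must be >= 0")
        if self.length_range[0] <= self.lambda_:
            raise ParameterError(
                f"minimum length {self.length_range[0]} must exceed "
                f"lambda={self.lambda_}")
        if self.length_range[0] > self.length_range[1]:
            raise ParameterError("length_range must be (min, max) with min <= max")
        if self.sigma < 0 or self.halo_noise_sd < 0:
            raise ParameterError("noise SDs must be >= 0")
        if self.composition not in ("uniform", "xylanase"):
            raise ParameterError(f"unknown composition {self.composition!r}")

    @property
    def pseaac_params(self) -> PseAACParams:
        return PseAACParams(lambda_=self.lambda_, weight=self.weight)


def true_coefficients(cfg: SimConfig) -> dict[str, np.ndarray]:
    """The fixed per-condition linear coefficients over the PseAAC features.

    Drawn once from a constant-seeded generator so they are properties of
    the simulated "world", not of the sampling seed.
    """
    n_feat = 20 + 2 * cfg.lambda_
    out = {}
    for j, cond in enumerate(CONDITIONS):
        rng = np.random.default_rng(7919 * (j + 1) + 1234)
        out[cond] = rng.normal(0.0, cfg.coefficient_scale, size=n_feat)
    return out


def simulate_sequences(cfg: SimConfig) -> list[EnzymeSequence]:
    """Draw i.i.d.-residue sequences with seeded reproducibility."""
    rng = np.random.default_rng(cfg.seed)
    letters = np.array(list(CANONICAL_RESIDUES))
    if cfg.composition == "uniform":
        probs = np.full(20, 0.05)
    else:
        probs = np.array([XYLANASE_LIKE_COMPOSITION[a] for a in CANONICAL_RESIDUES])
        probs = probs / probs.sum()
    lo, hi = cfg.length_range
    seqs = []
    for i in range(cfg.n_sequences):
        L = int(rng.integers(lo, hi + 1))
        residues = "".join(rng.choice(letters, size=L, p=probs))
        seqs.append(EnzymeSequence(f"SYN{i + 1:04d}", residues))
    return seqs


@dataclass
class ActivitySim:
    """Simulated activities with the zero-clip count surfaced."""

    activities: pd.DataFrame  # rows = ids, columns = condition labels
    n_clipped: int


def simulate_activities(features: pd.DataFrame, cfg: SimConfig) -> ActivitySim:
    """y = intercept + features . beta + Normal(0, sigma^2), clipped at 0."""
    betas = true_coefficients(cfg)
    n_feat = 20 + 2 * cfg.lambda_
    if features.shape[1] != n_feat:
        raise ParameterError(
            f"feature matrix has {features.shape[1]} columns, expected {n_feat}")
    rng = np.random.default_rng(cfg.seed + 1)
    F = np.asarray(features, float)
    cols = {}
    clipped = 0
    for cond in CONDITIONS:
        y = cfg.activity_intercept + F @ betas[cond]
        if cfg.sigma > 0:
            y = y + rng.normal(0.0, cfg.sigma, size=len(y))
        clipped += int((y < 0).sum())
        cols[cond] = np.maximum(y, 0.0)
    frame = pd.DataFrame(cols, index=features.index)
    return ActivitySim(activities=frame, n_clipped=clipped)


@dataclass
class HaloSim:
    halo_mm: pd.Series
    labels: pd.Series


def simulate_halos(activities: pd.DataFrame, cfg: SimConfig) -> HaloSim:
    """Monotone affine map from the mean-activity latent score to millimetres.

    The latent score is min-max scaled onto ``cfg.halo_range``; optional
    Gaussian noise (``halo_noise_sd`` mm) is added before labelling through
    the halo thresholds. Halos are floored just above zero to stay in the
    diameter domain.
    """
    latent = activities.mean(axis=1).to_numpy(float)
    lo, hi = cfg.halo_range
    if len(latent) == 0:
        empty = pd.Series(dtype=float, index=activities.index)
        return HaloSim(halo_mm=empty, labels=empty.astype(str))
    span = latent.max() - latent.min()
    scaled = (latent - latent.min()) / span if span > 0 else np.full_like(latent, 0.5)
    halo = lo + scaled * (hi - lo)
    if cfg.halo_noise_sd > 0:
        rng = np.random.default_rng(cfg.seed + 2)
        halo = halo + rng.normal(0.0, cfg.halo_noise_sd, size=len(halo))
    halo = np.maximum(halo, 0.1)
    labels = [classify_halo(h, cfg.thresholds) for h in halo]
    return HaloSim(
        halo_mm=pd.Series(halo, index=activities.index, name="halo_mm"),
        labels=pd.Series(labels, index=activities.index, name="class"),
    )


@dataclass
class SimulatedStudy:
    """A complete synthetic analogue of the study dataset."""

    sequences: list[EnzymeSequence]
    features: pd.DataFrame
    dataset: StudyDataset
    n_clipped: int


def simulate_study(cfg: SimConfig = SimConfig()) -> SimulatedStudy:
    """Run the full generator: sequences, features, activities, halos."""
    seqs = simulate_sequences(cfg)
    features = extract_features(seqs, cfg.pseaac_params)
    act = simulate_activities(features, cfg)
    halos = simulate_halos(act.activities, cfg)
    records = []
    for sid in features.index:
        records.append(StrainRecord(
            accession=sid, strain=sid.lower(),
            halo_mm=float(halos.halo_mm[sid]),
            real_class=str(halos.labels[sid]),
            activity={c: float(act.activities.loc[sid, c]) for c in CONDITIONS},
        ))
    dataset = StudyDataset(records=records, features=features)
    return SimulatedStudy(sequences=seqs, features=features, dataset=dataset,
                          n_clipped=act.n_clipped)


def write_simulated_study(study: SimulatedStudy, outdir) -> dict[str, Path]:
    """Write the synthetic study in the exact real-data formats.

    Emits ``sequences.fasta``, ``strains.csv`` and ``features.csv`` under
    ``outdir`` so every downstream command consumes them unchanged.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "sequences.fasta",
        "strains": outdir / "strains.csv",
        "features": outdir / "features.csv",
    }
    write_fasta(study.sequences, paths["fasta"])
    write_strain_table(study.dataset, paths["strains"])
    study.features.to_csv(paths["features"], index_label="id")
    return paths
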