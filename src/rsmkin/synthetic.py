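"""Synthetic data generators and the bundled reference dataset.

The generators emulate the statistical structure the analysis assumes: a
true quadratic response surface sampled at CCD points with independent
Gaussian replicate noise (replicate standard errors in the 0-1.7 range
observed in the reference design table), and exponential dissipation
curves with additive noise and an optional detection floor.  Everything
is bit-reproducible given a seed.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignTable, Factor, default_factors
from .errors import CorruptedInstallError, InvalidInputError
from .kinetics import DecayCurve
from .rsm import ResponseDataset, quadratic_model_matrix

__all__ = [
    "SurfaceTruth",
    "DecayTruth",
    "simulate_response_surface",
    "simulate_decay",
    "load_reference_study",
    "reference_truth",
]


@dataclass
class SurfaceTruth:
    """Ground-truth quadratic surface for simulation.

    ``coef`` is ordered like the fitted model's terms: intercept, k linear,
    k(k-1)/2 interaction (lexicographic pairs), k squared coefficients.
    """

    coef: np.ndarray
    noise_sd: float = 0.6
    n_replicates: int = 3

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float)
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise InvalidInputError("n_replicates must be >= 1")


@dataclass
class DecayTruth:
    """Ground-truth first-order decay for simulation.

    Defaults mirror the reference kinetics experiment: 50 mg/L initial
    concentration sampled every 24 h up to 144 h, replicate noise of
    about 1 mg/L, and a detection floor below which residues read as 0.
    """

    c0: float = 50.0
    k: float = 0.0193
    times: np.ndarray = field(default_factory=lambda: np.arange(0.0, 145.0, 24.0))
    noise_sd: float = 1.0
    floor: float = 0.5

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.c0 <= 0:
            raise InvalidInputError("c0 must be > 0")
        if self.k < 0 or self.noise_sd < 0 or self.floor < 0:
            raise InvalidInputError("k, noise_sd and floor must be >= 0")
        if len(self.times) < 2:
            raise InvalidInputError("at least 2 sampling times required")


def simulate_response_surface(
    truth: SurfaceTruth, design: DesignTable, seed: int
) -> ResponseDataset:
    """Draw replicate responses from a quadratic truth surface at CCD points.

    Per run: ``n_replicates`` draws of truth(x) + N(0, noise_sd), clipped to
    the [0, 100] percentage range (the number of clipped draws is recorded
    on the returned design as ``n_clipped``).  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    X = quadratic_model_matrix(design.coded)
    if X.shape[1] != len(truth.coef):
        raise InvalidInputError(
            f"truth has {len(truth.coef)} coefficients, design implies {X.shape[1]}"
        )
    mu = X @ truth.coef
    reps = mu[:, None] + rng.normal(
        0.0, truth.noise_sd, size=(design.n_runs, truth.n_replicates)
    )
    n_clipped = int(np.sum((reps < 0) | (reps > 100)))
    reps = np.clip(reps, 0.0, 100.0)
    y_mean = reps.mean(axis=1)
    if truth.n_replicates > 1:
        y_se = reps.std(axis=1, ddof=1) / np.sqrt(truth.n_replicates)
    else:
        y_se = np.zeros(design.n_runs)
    out = design.with_responses(y_mean, y_se, truth.n_replicates)
    out.runs.attrs["n_clipped"] = n_clipped
    out.runs.attrs["seed"] = seed
    return ResponseDataset(out)


def simulate_decay(truth: DecayTruth, seed: int) -> DecayCurve:
    """Draw one noisy exponential decay series.

    ``C0*exp(-k t) + N(0, noise_sd)``; draws below the detection floor are
    recorded as 0 (non-detects).  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    c = truth.c0 * np.exp(-truth.k * truth.times)
    c = c + rng.normal(0.0, truth.noise_sd, size=len(truth.times))
    c = np.where(c < truth.floor, 0.0, c)
    return DecayCurve(times=truth.times.copy(), concentrations=c, c0_nominal=truth.c0)


# -- bundled reference dataset ----------------------------------------------


def _data_text(name: str) -> bytes:
    return (
        importlib.resources.files("rsmkin.data").joinpath(name).read_bytes()
    )


def reference_values() -> dict:
    """The reported headline numbers of the reference study, with the
    comparison tolerances and provenance notes used by the reproduction
    report."""
    return json.loads(_data_text("reference_values.json"))


def load_reference_study() -> tuple[ResponseDataset, dict]:
    """Load the bundled 24-run reference design table and constants record.

    Returns the allethrin-degradation CCD (coded levels as published, run
    order as published, mean +/- SE of three replicates per run) and the
    dictionary of reported headline values.  The bundled table is
    checksum-verified against the constants record.
    """
    consts = reference_values()
    raw = _data_text("allethrin_ccd.csv")
    digest = hashlib.sha256(raw).hexdigest()
    if digest != consts["fixture_sha256"]:
        raise CorruptedInstallError(
            "bundled design table failed its integrity checksum "
            f"({digest} != {consts['fixture_sha256']})"
        )
    from io import StringIO

    runs = pd.read_csv(StringIO(raw.decode()))
    table = DesignTable(default_factors(), runs)
    table.validate()
    return ResponseDataset(table, "degradation", "%"), consts


def reference_truth(noise_sd: float = 0.6, n_replicates: int = 3) -> SurfaceTruth:
    """SurfaceTruth whose coefficients are the refit of the reference table.

    This is the default simulation truth: the quadratic surface actually
    supported by the published design table.
    """
    from .rsm import fit_quadratic

    dataset, _ = load_reference_study()
    fit = fit_quadratic(dataset)
    return SurfaceTruth(fit.beta.copy(), noise_sd=noise_sd, n_replicates=n_replicates)
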