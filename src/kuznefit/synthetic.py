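"""Virtual patient cohorts with known ground truth.

Emulates the statistical structure the analysis assumes: sparse
clinic-style visit schedules (7-12 visits at a fixed re-staging interval),
lesion trajectories generated by the nondimensional tumor-immune dynamics
from log-uniformly sampled parameters, and additive Gaussian measurement
noise on the longest diameter at the 1-2 mm scale of manual CT reads.
Ground truth (parameters, initial effector level, noise-free diameters)
is retained so that estimation and forecasting can be validated by
recovery rather than against external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import Cohort, PatientRecord, cells_to_ld, clean, ld_to_cells, normalize
from .model import NondimParams, PARAM_NAMES, ScaleConstants, SolverConfig, integrate_y

__all__ = ["SyntheticSpec", "GroundTruth", "sample_patient", "add_noise", "generate_cohort"]

# tight integration for generating truth; fitting then uses the production
# solver settings, as it would on real data
TRUTH_SOLVER = SolverConfig(rtol=1e-8, atol=1e-10, mxstep=20000)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition settings of the virtual cohort.

    Visits every 42 days (typical CT re-staging cadence), 7-12 visits so
    every patient survives the net-measurement filter, baseline LD 10-80 mm
    (measurable target lesions), and 1 mm additive LD noise reflecting the
    manual-measurement margin.  Parameters are drawn log-uniform within the
    estimation bounds, except alpha, capped at 6.5 because the normalized
    tumor growth rate saturates well below the generic upper bound.
    """

    n_patients: int = 20
    visit_interval: float = 42.0          # days
    n_visits: tuple[int, int] = (7, 12)   # inclusive range
    baseline_ld: tuple[float, float] = (10.0, 80.0)  # mm
    ld_noise_sd: float = 1.0              # mm
    param_lower: tuple[float, ...] = (1e-2,) * 6     # sigma..alpha
    param_upper: tuple[float, ...] = (1e2,) * 5 + (6.5,)
    x1_range: tuple[float, float] = (1e-2, 1e2)
    y_floor: float = 1e-4                 # reject vanishing tumors
    y_validity: float = 100.0             # reject blow-ups
    min_ld_change: float = 5.0            # mm; reject clinically static lesions
    seed: int = 0
    max_draws: int = 1000

    def __post_init__(self) -> None:
        if self.ld_noise_sd < 0:
            raise ValueError("ld_noise_sd must be >= 0")
        if self.n_visits[0] < 1 or self.n_visits[0] > self.n_visits[1]:
            raise ValueError("invalid n_visits range")
        lo, up = np.asarray(self.param_lower), np.asarray(self.param_upper)
        if np.any(lo <= 0) or np.any(lo >= up):
            raise ValueError("require 0 < param_lower < param_upper")


@dataclass
class GroundTruth:
    """One virtual patient with its generating parameters."""

    patient_id: str
    params: NondimParams
    x1: float
    y1: float
    time_days: np.ndarray
    ld_true: np.ndarray    # noise-free LD, mm
    ld_noisy: np.ndarray   # observed LD, mm
    y_true: np.ndarray     # noise-free normalized tumor burden


class GenerationError(RuntimeError):
    """Rejection budget exhausted while sampling a valid patient."""


def add_noise(ld_mm: Sequence[float], sd: float, rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian LD noise, truncated below 1 mm by redrawing."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    ld = np.asarray(ld_mm, dtype=float)
    if sd == 0:
        return ld.copy()
    noisy = ld + rng.normal(scale=sd, size=ld.shape)
    for _ in range(1000):
        bad = noisy < 1.0
        if not bad.any():
            break
        noisy[bad] = ld[bad] + rng.normal(scale=sd, size=int(bad.sum()))
    else:
        noisy = np.maximum(noisy, 1.0)
    return noisy


def sample_patient(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    patient_id: str = "S000",
    scales: ScaleConstants = ScaleConstants(),
) -> GroundTruth:
    """Draw one virtual patient, rejecting degenerate trajectories.

    A draw is rejected when the noise-free normalized burden leaves
    (y_floor, y_validity) at any visit — vanished or exploded tumors carry
    no usable longitudinal signal at clinic cadence.
    """
    zlo = np.log10(np.asarray(spec.param_lower))
    zup = np.log10(np.asarray(spec.param_upper))
    for _ in range(spec.max_draws):
        n_vis = int(rng.integers(spec.n_visits[0], spec.n_visits[1] + 1))
        time_days = np.arange(n_vis) * spec.visit_interval
        tau = scales.time_scale * time_days
        theta = 10.0 ** rng.uniform(zlo, zup)
        x1 = 10.0 ** rng.uniform(np.log10(spec.x1_range[0]), np.log10(spec.x1_range[1]))
        ld0 = rng.uniform(*spec.baseline_ld)
        y1 = ld_to_cells(ld0, scales) / scales.T0
        out = integrate_y(theta, x1, y1, tau, scales, TRUTH_SOLVER)
        if out is None:
            continue
        y_true = out[:, 1]
        if np.any(y_true <= spec.y_floor) or np.any(y_true >= spec.y_validity):
            continue
        ld_true = cells_to_ld(y_true * scales.T0, scales)
        # static lesions carry no longitudinal signal at the 1-2 mm read
        # precision; trial patients tracked over many visits show measurable
        # response or progression
        if ld_true.max() - ld_true.min() < spec.min_ld_change:
            continue
        ld_noisy = add_noise(ld_true, spec.ld_noise_sd, rng)
        return GroundTruth(
            patient_id=patient_id,
            params=NondimParams.from_array(theta),
            x1=float(x1),
            y1=float(y1),
            time_days=time_days,
            ld_true=ld_true,
            ld_noisy=ld_noisy,
            y_true=y_true,
        )
    raise GenerationError(
        f"could not draw a valid patient in {spec.max_draws} attempts; "
        f"check parameter ranges {spec.param_lower}..{spec.param_upper} and "
        f"validity window ({spec.y_floor}, {spec.y_validity})"
    )


def generate_cohort(
    spec: SyntheticSpec,
    scales: ScaleConstants = ScaleConstants(),
) -> tuple[Cohort, list[GroundTruth]]:
    """Generate a cohort in the standard schema plus its ground truth.

    Records come back cleaned and normalized, ready for fitting; with at
    least 7 visits they pass the net-measurement filter unchanged.
    """
    rng = np.random.default_rng(spec.seed)
    truths: list[GroundTruth] = []
    records: list[PatientRecord] = []
    for i in range(spec.n_patients):
        gt = sample_patient(spec, rng, patient_id=f"S{i:03d}", scales=scales)
        truths.append(gt)
        rec = PatientRecord(
            patient_id=gt.patient_id,
            study_id="SYNTH",
            arm_id="A1",
            treatment="none",
            time_days=gt.time_days,
            ld_mm=gt.ld_noisy,
        )
        records.append(normalize(clean(rec), scales))
    cohort = Cohort(records=records, provenance={"source": "synthetic", "seed": spec.seed})
    return cohort, truths


def truth_table(truths: Sequence[GroundTruth]) -> pd.DataFrame:
    """Ground-truth CSV table (patient_id, parameters, x1, y1)."""
    rows = []
    for gt in truths:
        row = {"patient_id": gt.patient_id}
        row.update({n: getattr(gt.params, n) for n in PARAM_NAMES})
        row.update({"x1": gt.x1, "y1": gt.y1})
        rows.append(row)
    return pd.DataFrame(rows)
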