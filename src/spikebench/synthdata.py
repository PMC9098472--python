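"""Synthetic two-species spike-in benchmark generator.

The generator emulates the statistical structure of a spike-in benchmark for
label-free quantitative proteomics: a heterogeneous human tissue background
measured across four conditions, into three of which a single batch of
*E. coli* peptides is spiked at known ratios (1:25, 1:12, 1:6 relative to the
human peptide amount) while the fourth contains no spike at all
(``humanOnly``).  On the log2 scale the realized intensity of protein *g* in
sample *s* is

    x_gs = baseline_g + shift_g(condition_s) + patient_gs + tech_gs

with a per-protein baseline ``N(base_mean, base_sd)``, a condition shift of 0
for human proteins and of 0 / spike_delta / delta_1to6 for spike proteins in
conditions 1:25 / 1:12 / 1:6, a biological (inter-patient) effect whose SD is
much larger for human than for spike proteins (the spike comes from one
batch), and technical noise.  Spike proteins are physically absent from
``humanOnly`` samples.

Missingness is missing-not-at-random: each sample draws a detection-threshold
location T_s and each cell is censored with probability
``logistic((T_s − x_gs) · detect_slope)``, plus a small uniform (MCAR) rate.
This single mechanism reproduces the two hallmark correlations of real
acquisitions: proteins with larger average intensity have fewer missing
values, and sample-mean intensity correlates with per-sample missingness
(positively when thresholds vary between samples, negatively when they do
not).  Optionally, spike proteins can be spuriously "identified" in
humanOnly samples with probability ``fp_rate`` per cell, emulating
false-positive quantitations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .dataio import ECOLI, HUMAN, IntensityDataset
from .errors import ConfigurationError

HUMAN_ONLY = "humanOnly"
R1_25 = "1:25"
R1_12 = "1:12"
R1_6 = "1:6"
DEFAULT_CONDITIONS = (HUMAN_ONLY, R1_25, R1_12, R1_6)
DEFAULT_PAIR = (R1_25, R1_12)

_STREAMS = ("baseline", "patient", "tech", "thresholds", "mnar", "mcar", "fp", "dropout")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic spike-in benchmark.

    All intensities are on the log2 scale.  ``spike_delta`` is the true log2
    fold-change of spike proteins between the two compared conditions 1:25 and
    1:12 (default 1.11, the benchmark's calibrated constant); ``delta_1to6``
    is the shift of 1:6 relative to 1:25 (default log2(25/6)).
    """

    n_human: int = 1000
    n_spike: int = 200
    n_per_condition: int = 23
    conditions: Sequence[str] = DEFAULT_CONDITIONS
    base_mean: float = 20.0
    base_sd: float = 2.0
    sigma_patient_human: float = 1.0
    sigma_patient_spike: float = 0.25
    tech_sd: float = 0.25
    spike_delta: float = 1.11
    delta_1to6: float = float(np.log2(25.0 / 6.0))
    detect_mu: float = 17.0
    detect_sd: float = 0.5
    detect_slope: float = 1.0
    mcar_rate: float = 0.01
    fp_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_human", "n_spike", "n_per_condition"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in (
            "base_sd",
            "sigma_patient_human",
            "sigma_patient_spike",
            "tech_sd",
            "detect_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("mcar_rate", "fp_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.detect_slope < 0:
            raise ConfigurationError(f"detect_slope must be >= 0, got {self.detect_slope}")
        unknown = set(self.conditions) - set(DEFAULT_CONDITIONS)
        if unknown:
            raise ConfigurationError(f"conditions contains unknown labels {sorted(unknown)}")
        if HUMAN_ONLY not in self.conditions:
            raise ConfigurationError("conditions must contain humanOnly")
        if not {R1_25, R1_12}.issubset(self.conditions):
            raise ConfigurationError("conditions must contain the compared ratios 1:25 and 1:12")
        if len(set(self.conditions)) != len(tuple(self.conditions)):
            raise ConfigurationError("conditions contains duplicate labels")

    @property
    def spike_shifts(self) -> dict[str, float]:
        """Log2 shift of spike proteins per condition, relative to 1:25."""
        return {HUMAN_ONLY: np.nan, R1_25: 0.0, R1_12: self.spike_delta, R1_6: self.delta_1to6}


@dataclass
class GroundTruth:
    """Known differential status of every simulated protein.

    ``true_log2fc`` refers to the compared condition ``pair`` (default
    1:25 → 1:12): 0 for human proteins, ``spike_delta`` for spike proteins.
    ``present_in`` lists the conditions where the protein is physically
    present (spike proteins are absent from humanOnly).
    """

    species: pd.Series
    true_log2fc: pd.Series
    present_in: pd.Series
    pair: tuple[str, str] = DEFAULT_PAIR

    def subset(self, proteins) -> "GroundTruth":
        idx = pd.Index(proteins)
        return GroundTruth(
            species=self.species.loc[idx],
            true_log2fc=self.true_log2fc.loc[idx],
            present_in=self.present_in.loc[idx],
            pair=self.pair,
        )


@dataclass
class WorkflowEnsemble:
    """Pseudo-workflow datasets sharing one underlying simulation.

    Stands in for the multiple acquisition-software datasets of a real
    benchmark: every member shares the sample annotation but may report a
    different protein subset and its own missingness realization.
    """

    members: list[tuple[str, IntensityDataset]]
    truth: GroundTruth

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.members]

    @property
    def protein_sets(self) -> dict[str, set[str]]:
        return {label: set(ds.proteins) for label, ds in self.members}


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    """Independent, purpose-keyed RNG streams derived by stable sub-seeding."""
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


def apply_missingness(
    matrix: np.ndarray,
    config: SimConfig,
    thresholds: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Censor cells of a complete log2 matrix via the MNAR + MCAR mechanism.

    Cell (g, s) is set missing with probability
    ``logistic((T_s − x_gs) · detect_slope)`` and additionally, independently,
    with probability ``mcar_rate``.  ``detect_slope = inf`` degenerates to a
    hard threshold (missing below T_s, kept above, fair coin at equality).
    Lowering a cell's intensity never decreases its missingness probability.
    """
    matrix = np.asarray(matrix, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.shape != (matrix.shape[1],):
        raise ConfigurationError(
            f"thresholds must have one entry per sample, got {thresholds.shape}"
        )
    gap = thresholds[None, :] - matrix
    if np.isinf(config.detect_slope):
        p_mnar = np.where(gap > 0, 1.0, np.where(gap < 0, 0.0, 0.5))
    else:
        p_mnar = expit(gap * config.detect_slope)
    missing = rng.random(matrix.shape) < p_mnar
    if config.mcar_rate > 0:
        missing |= rng.random(matrix.shape) < config.mcar_rate
    out = matrix.copy()
    out[missing] = np.nan
    return out


def _simulate_core(config: SimConfig):
    """Build the complete (pre-missingness) matrix and all labels."""
    rngs = _rngs(config.seed)
    conditions = list(config.conditions)
    n_total = config.n_human + config.n_spike
    proteins = pd.Index(
        [f"HUM{i + 1:04d}_HUMAN" for i in range(config.n_human)]
        + [f"ECO{i + 1:04d}_ECOLI" for i in range(config.n_spike)]
    )
    species = pd.Series(
        [HUMAN] * config.n_human + [ECOLI] * config.n_spike, index=proteins, name="species"
    )
    samples = pd.Index(
        [f"{cond}_{k + 1:02d}" for cond in conditions for k in range(config.n_per_condition)]
    )
    condition = pd.Series(
        [cond for cond in conditions for _ in range(config.n_per_condition)],
        index=samples,
        name="condition",
    )

    baseline = rngs["baseline"].normal(config.base_mean, config.base_sd, size=n_total)
    is_spike = (species == ECOLI).to_numpy()
    shift_per_cond = config.spike_shifts
    shifts = np.zeros((n_total, len(samples)))
    absent = np.zeros((n_total, len(samples)), dtype=bool)
    cond_arr = condition.to_numpy()
    for cond in conditions:
        cols = cond_arr == cond
        value = shift_per_cond[cond]
        if np.isnan(value):  # spike physically absent
            absent[np.ix_(is_spike, cols)] = True
        else:
            shifts[np.ix_(is_spike, cols)] = value

    sd_patient = np.where(is_spike, config.sigma_patient_spike, config.sigma_patient_human)
    patient = rngs["patient"].normal(0.0, 1.0, size=shifts.shape) * sd_patient[:, None]
    tech = rngs["tech"].normal(0.0, config.tech_sd, size=shifts.shape)
    complete = baseline[:, None] + shifts + patient + tech
    thresholds = rngs["thresholds"].normal(config.detect_mu, config.detect_sd, size=len(samples))
    return proteins, species, samples, condition, complete, absent, thresholds, rngs


def _ground_truth(config: SimConfig, species: pd.Series) -> GroundTruth:
    conditions = frozenset(config.conditions)
    spike_present = conditions - {HUMAN_ONLY}
    is_spike = species == ECOLI
    true_fc = pd.Series(
        np.where(is_spike, config.spike_delta, 0.0), index=species.index, name="true_log2fc"
    )
    present = pd.Series(
        [spike_present if s else conditions for s in is_spike],
        index=species.index,
        name="present_in",
    )
    return GroundTruth(species=species.copy(), true_log2fc=true_fc, present_in=present)


def _observe(config: SimConfig, complete, absent, thresholds, rng_mnar, rng_fp):
    """Apply MNAR/MCAR censoring, structural absence and fp injection."""
    observed = apply_missingness(complete, config, thresholds, rng_mnar)
    n_absent = int(absent.sum())
    if n_absent:
        values = np.full(complete.shape, np.nan)
        if config.fp_rate > 0:
            # spurious identifications sit just above the detection limit
            inject = rng_fp.random(n_absent) < config.fp_rate
            fp_values = np.broadcast_to(thresholds, complete.shape)[absent] + np.abs(
                rng_fp.normal(0.0, 0.5, size=n_absent)
            )
            values[absent] = np.where(inject, fp_values, np.nan)
        observed[absent] = values[absent]
    return observed


def simulate_benchmark(config: SimConfig = SimConfig()) -> tuple[IntensityDataset, GroundTruth]:
    """Simulate one labelled spike-in benchmark dataset.

    Returns the intensity dataset — (n_human + n_spike) proteins ×
    (n_per_condition × |conditions|) samples — and the matching ground truth.
    Identical config (including seed) yields bit-identical output.
    """
    proteins, species, samples, condition, complete, absent, thresholds, rngs = _simulate_core(
        config
    )
    observed = _observe(config, complete, absent, thresholds, rngs["mnar"], rngs["fp"])
    values = pd.DataFrame(observed, index=proteins, columns=samples)
    dataset = IntensityDataset(values=values, species=species, condition=condition)
    return dataset, _ground_truth(config, species)


def simulate_workflow_ensemble(
    config: SimConfig, n_workflows: int, dropout_spread: float
) -> WorkflowEnsemble:
    """Emulate several acquisition workflows over one shared simulation.

    Every member applies an independent protein dropout (retention rate drawn
    uniformly from [1 − dropout_spread, 1]) to the shared complete matrix.
    Member 1 reuses the base simulation's missingness realization (so with
    ``dropout_spread = 0`` it equals :func:`simulate_benchmark` output);
    members 2..W re-draw their detection thresholds and censoring,
    reflecting that different software reports different missingness.
    """
    if n_workflows < 1:
        raise ConfigurationError(f"n_workflows must be >= 1, got {n_workflows}")
    if not 0.0 <= dropout_spread < 1.0:
        raise ConfigurationError(f"dropout_spread must be in [0, 1), got {dropout_spread}")
    proteins, species, samples, condition, complete, absent, thresholds, rngs = _simulate_core(
        config
    )
    truth = _ground_truth(config, species)
    rng_drop = rngs["dropout"]
    members: list[tuple[str, IntensityDataset]] = []
    for w in range(n_workflows):
        if w == 0:
            observed = _observe(config, complete, absent, thresholds, rngs["mnar"], rngs["fp"])
        else:
            thresholds_w = rng_drop.normal(config.detect_mu, config.detect_sd, len(samples))
            observed = _observe(config, complete, absent, thresholds_w, rng_drop, rng_drop)
        retention = 1.0 if dropout_spread == 0 else rng_drop.uniform(1.0 - dropout_spread, 1.0)
        keep = rng_drop.random(len(proteins)) < retention if dropout_spread > 0 else np.ones(
            len(proteins), dtype=bool
        )
        values = pd.DataFrame(observed[keep], index=proteins[keep], columns=samples)
        members.append(
            (
                f"workflow_{w + 1:02d}",
                IntensityDataset(
                    values=values, species=species.loc[proteins[keep]], condition=condition
                ),
            )
        )
    return WorkflowEnsemble(members=members, truth=truth)
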