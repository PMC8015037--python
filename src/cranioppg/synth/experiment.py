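"""Whole-experiment simulation: animals x groups x infusion steps x trials.

The printed design is 32 rats in three groups (valproate n=10, sumatriptan
n=11, saline control n=11), each recorded in 3 baseline trials followed by
3 cumulative infusion steps with 3 trials per step (384 trials total),
trials 10 min apart and infusions 30 min apart.

Pharmacology is phenomenological: a per-step time-drift multiplier > 1
(sensitization seen in the saline controls) acts on the stimulation-evoked
APC gain in every group, while drug multipliers <= 1 oppose it from the
matching infusion step onward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..datatypes import SampledTrace
from .kinetics import HemoDynamicsSpec, TrialProtocol
from .traces import TraceSpec, simulate_trial_traces


@dataclass
class DrugEffect:
    """Per-step multipliers on the stimulation-evoked APC gain excess and
    on the OIS volume response (cumulative, step 1..3)."""

    apc: tuple[float, float, float] = (1.0, 1.0, 1.0)
    ois: tuple[float, float, float] = (1.0, 1.0, 1.0)


DEFAULT_DRUG_EFFECTS: dict[str, DrugEffect] = {
    "saline": DrugEffect(),
    "sumatriptan": DrugEffect(apc=(0.8, 0.6, 0.4), ois=(0.9, 0.8, 0.7)),
    "valproate": DrugEffect(apc=(0.85, 0.70, 0.55), ois=(0.95, 0.90, 0.85)),
}


@dataclass
class ExperimentDesign:
    groups: list[tuple[str, int]] = field(default_factory=lambda: [
        ("valproate", 10), ("sumatriptan", 11), ("saline", 11)])
    baseline_trials_per_animal: int = 3
    infusion_steps: int = 3
    trials_per_step: int = 3
    inter_trial_min: float = 10.0
    inter_infusion_min: float = 30.0
    drift_per_step: float = 1.25  # time effect on APC gain excess, all groups
    drug_effect: dict[str, DrugEffect] = field(
        default_factory=lambda: dict(DEFAULT_DRUG_EFFECTS))
    # animal- and trial-level variability (fractional lognormal SDs)
    animal_sd: float = 0.15
    trial_sd: float = 0.10

    def __post_init__(self) -> None:
        if any(n <= 0 for _, n in self.groups):
            raise ValueError("group sizes must be positive")

    @property
    def n_animals(self) -> int:
        return sum(n for _, n in self.groups)

    @property
    def trials_per_animal(self) -> int:
        return self.baseline_trials_per_animal + self.infusion_steps * self.trials_per_step

    @property
    def n_trials(self) -> int:
        return self.n_animals * self.trials_per_animal

    def stage_multipliers(self, group: str, stage: int) -> tuple[float, float]:
        """(APC-gain-excess multiplier, OIS-response multiplier) at a stage
        (0 = baseline, 1..infusion_steps = after that infusion)."""
        if stage == 0:
            return 1.0, 1.0
        eff = self.drug_effect.get(group, DrugEffect())
        return (self.drift_per_step ** stage * eff.apc[stage - 1], eff.ois[stage - 1])


def build_schedule(design: ExperimentDesign) -> pd.DataFrame:
    """One record per trial with timing and ground-truth stage multipliers."""
    records = []
    for group, n in design.groups:
        for a in range(n):
            animal_id = f"{group}-{a + 1:02d}"
            t_min = 0.0
            for stage in range(design.infusion_steps + 1):
                n_trials = (design.baseline_trials_per_animal if stage == 0
                            else design.trials_per_step)
                if stage > 0:
                    # infusions 30 min apart; first falls 30 min after the
                    # previous stage's first trial
                    t_min = stage * design.inter_infusion_min
                apc_mult, ois_mult = design.stage_multipliers(group, stage)
                for trial in range(1, n_trials + 1):
                    records.append({
                        "animal": animal_id, "group": group, "stage": stage,
                        "trial": trial, "t_start_min": t_min,
                        "apc_gain_multiplier": apc_mult,
                        "ois_response_multiplier": ois_mult,
                    })
                    t_min += design.inter_trial_min
    return pd.DataFrame.from_records(records)


@dataclass
class ExperimentDataset:
    schedule: pd.DataFrame
    traces: dict[tuple[str, int, int], dict[str, SampledTrace]]
    ground_truth: pd.DataFrame
    protocol: TrialProtocol
    design: ExperimentDesign


def simulate_experiment(design: ExperimentDesign | None = None,
                        hemo: HemoDynamicsSpec | None = None,
                        protocol: TrialProtocol | None = None,
                        seed: int = 0,
                        trace_spec: TraceSpec | None = None) -> ExperimentDataset:
    """Simulate every trial of the design at the trace level.

    Each animal draws a random baseline APC level and response gain
    (lognormal, fractional SD ``animal_sd``); each trial adds multiplicative
    jitter (``trial_sd``).  Group/stage effects multiply the stimulation
    gain excess per :meth:`ExperimentDesign.stage_multipliers`.
    """
    design = design or ExperimentDesign()
    hemo = hemo or HemoDynamicsSpec()
    protocol = protocol or TrialProtocol()
    trace_spec = trace_spec or TraceSpec()
    rng = np.random.default_rng(seed)

    schedule = build_schedule(design)
    base_excess = hemo.stim_apc_gain - 1.0
    traces: dict[tuple[str, int, int], dict[str, SampledTrace]] = {}
    gt_rows = []
    for animal, sub in schedule.groupby("animal", sort=False):
        animal_gain = float(np.exp(design.animal_sd * rng.standard_normal()))
        animal_apc0 = trace_spec.apc0_pct * float(
            np.exp(design.animal_sd * rng.standard_normal()))
        for row in sub.itertuples():
            trial_jit = float(np.exp(design.trial_sd * rng.standard_normal()))
            excess = base_excess * animal_gain * row.apc_gain_multiplier * trial_jit
            drop = hemo.stim_volume_drop * row.ois_response_multiplier * trial_jit
            hemo_t = replace(hemo, stim_apc_gain=1.0 + excess,
                             stim_volume_drop=min(drop, 0.95))
            spec_t = replace(trace_spec, apc0_pct=animal_apc0)
            traces[(animal, row.stage, row.trial)] = simulate_trial_traces(
                hemo_t, protocol, rng, spec_t)
            gt_rows.append({
                "animal": animal, "group": row.group, "stage": row.stage,
                "trial": row.trial, "apc_gain_excess": excess,
                "volume_drop": drop, "apc0_pct": animal_apc0,
            })
    return ExperimentDataset(schedule=schedule, traces=traces,
                             ground_truth=pd.DataFrame(gt_rows),
                             protocol=protocol, design=design)
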