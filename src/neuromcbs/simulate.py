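"""Seeded synthetic generator for n-of-1 patient records.

Stands in for molecular-tumour-board patient data, which are not public:
it emulates the *structure* of such a cohort (tumour entity, targeted
therapy class, per-patient PFS, best radiographic response category,
duration of clinical benefit, toxicity and QoL flags) with the simplest
models the scales consume - exponential PFS with an entity-specific
median, a categorical best response, and lognormal DoCB.  No claim of
clinical realism is made beyond the qualitative entity ordering.

The default configuration mirrors a 70-patient CNS cohort (meningioma 8,
brain metastases 10, glioblastoma 36, IDH-mutant astrocytoma 8, other 8)
with therapy classes drawn in proportion to published usage counts.
Generation is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .records import (
    AdjustmentFlags,
    BestResponse,
    Design,
    Endpoint,
    ResponseSummary,
    StudyRecord,
    Ternary,
)

__all__ = ["ResponseProbs", "SimulationConfig", "default_config", "generate_cohort",
           "THERAPY_CLASS_WEIGHTS"]

#: published usage counts of targeted-therapy classes in a CNS molecular
#: tumour board cohort; used as sampling weights for therapy_class labels
THERAPY_CLASS_WEIGHTS = {
    "EGFR inhibition": 17,
    "PD-1/PD-L1 inhibition": 13,
    "NTRK inhibition": 2,
    "PARP inhibition": 3,
    "TK inhibition": 7,
    "Multikinase inhibition": 1,
    "FGFR inhibition": 4,
    "mTOR inhibition": 14,
    "VEGF inhibition": 2,
    "IDH inhibition": 5,
    "CDK 4/6 inhibition": 3,
}

_TOL = 1e-9


class ResponseProbs(BaseModel):
    """Best-response category probabilities for one entity."""

    model_config = ConfigDict(frozen=True)

    p_CR: float = 0.0
    p_PR: float = 0.0
    p_MR: float = 0.0
    p_SD: float = 0.0
    p_PD: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "ResponseProbs":
        probs = self.as_tuple()
        if any(p < 0 for p in probs):
            raise ValueError("response probabilities must be non-negative")
        if abs(sum(probs) - 1.0) > _TOL:
            raise ValueError("response probabilities must sum to 1")
        return self

    def as_tuple(self) -> tuple[float, ...]:
        return (self.p_CR, self.p_PR, self.p_MR, self.p_SD, self.p_PD)


class SimulationConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_patients: int = 70
    entity_mix: dict[str, float]
    pfs_median_months: dict[str, float]
    response_probs: dict[str, ResponseProbs]
    docb_lognorm_mean_months: float = 6.0
    docb_lognorm_sigma: float = 0.6
    tox_rate: float = 0.15
    qol_improve_rate: float = 0.2

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if abs(sum(self.entity_mix.values()) - 1.0) > _TOL:
            raise ValueError("entity_mix proportions must sum to 1")
        if any(p < 0 for p in self.entity_mix.values()):
            raise ValueError("entity_mix proportions must be non-negative")
        for ent in self.entity_mix:
            if ent not in self.pfs_median_months:
                raise ValueError(f"no PFS median for entity {ent!r}")
            if self.pfs_median_months[ent] <= 0:
                raise ValueError("PFS medians must be positive")
            if ent not in self.response_probs:
                raise ValueError(f"no response probabilities for entity {ent!r}")
        for rate in (self.tox_rate, self.qol_improve_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        return self


def default_config(seed: int = 0, n_patients: int = 70) -> SimulationConfig:
    """A 70-patient CNS cohort with entity-typical outcome distributions."""
    return SimulationConfig(
        seed=seed,
        n_patients=n_patients,
        entity_mix={
            "meningioma": 8 / 70,
            "brain_metastases": 10 / 70,
            "glioblastoma": 36 / 70,
            "idh_mutant_astrocytoma": 8 / 70,
            "other": 8 / 70,
        },
        pfs_median_months={
            "meningioma": 6.5,
            "brain_metastases": 7.0,
            "glioblastoma": 2.5,
            "idh_mutant_astrocytoma": 4.0,
            "other": 3.5,
        },
        response_probs={
            "meningioma": ResponseProbs(p_PR=0.05, p_MR=0.10, p_SD=0.55, p_PD=0.30),
            "brain_metastases": ResponseProbs(p_CR=0.05, p_PR=0.25, p_MR=0.10, p_SD=0.35, p_PD=0.25),
            "glioblastoma": ResponseProbs(p_PR=0.05, p_MR=0.05, p_SD=0.25, p_PD=0.65),
            "idh_mutant_astrocytoma": ResponseProbs(p_PR=0.05, p_MR=0.10, p_SD=0.40, p_PD=0.45),
            "other": ResponseProbs(p_PR=0.10, p_MR=0.05, p_SD=0.35, p_PD=0.50),
        },
    )


_RESPONSES = (BestResponse.CR, BestResponse.PR, BestResponse.MR, BestResponse.SD, BestResponse.PD)


def generate_cohort(config: SimulationConfig) -> list[StudyRecord]:
    """Draw a deterministic cohort of n-of-1 patient records."""
    rng = np.random.default_rng(config.seed)
    entities = sorted(config.entity_mix)
    entity_p = np.array([config.entity_mix[e] for e in entities])
    entity_p = entity_p / entity_p.sum()
    classes = sorted(THERAPY_CLASS_WEIGHTS)
    class_p = np.array([THERAPY_CLASS_WEIGHTS[c] for c in classes], dtype=float)
    class_p = class_p / class_p.sum()
    # lognormal parameterised by its median
    mu = math.log(config.docb_lognorm_mean_months)
    records = []
    for i in range(config.n_patients):
        entity = entities[rng.choice(len(entities), p=entity_p)]
        therapy = classes[rng.choice(len(classes), p=class_p)]
        median = config.pfs_median_months[entity]
        pfs = float(rng.exponential(median / math.log(2)))
        probs = np.array(config.response_probs[entity].as_tuple())
        probs = probs / probs.sum()
        response = _RESPONSES[rng.choice(len(_RESPONSES), p=probs)]
        docb = None
        if response != BestResponse.PD:
            docb = float(rng.lognormal(mu, config.docb_lognorm_sigma))
        tox = Ternary.yes if rng.random() < config.tox_rate else Ternary.no
        qol = Ternary.yes if rng.random() < config.qol_improve_rate else Ternary.no
        records.append(
            StudyRecord(
                record_id=f"sim-{config.seed}-{i:04d}",
                design=Design.patient_n_of_1,
                primary_endpoint=Endpoint.PFS,
                n_subjects=1,
                single_arm_pfs_months=round(pfs, 2),
                response=None if docb is None else ResponseSummary(docb_months=round(docb, 2)),
                best_response=response,
                flags=AdjustmentFlags(
                    toxicity_ge30pct_grade34=tox,
                    qol_assessed=Ternary.yes,
                    qol_improved=qol,
                ),
                entity=entity,
                therapy_class=therapy,
            )
        )
    return records
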