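"""Seeded Monte-Carlo sampling of virtual-subject physiology records.

The default specification is a documented stand-in for unpublished human
variability distributions: body weight is lognormal (median at the
reference value, CV 20%, truncated at +/-3 SD in log space); volume and
flow fractions are truncated normals (CV 20%, +/-3 SD), with flow fractions
renormalised to sum to one.  Per-subject RNG streams are spawned from a
single seed sequence so the first ``k`` subjects are identical no matter
how large the requested sample is.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import DomainError, ValidationError
from .params_io import TISSUES, VOLUME_COMPARTMENTS, PhysiologyParams


@dataclass(frozen=True)
class ParamDist:
    """One parameter's sampling distribution."""

    family: str  # "normal" | "lognormal"
    location: float  # mean (normal) or median (lognormal)
    cv: float  # coefficient of variation
    bound_sd: float = 3.0  # symmetric truncation, in SD units

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal"):
            raise ValidationError(f"unknown distribution family: {self.family!r}")
        if self.cv < 0:
            raise DomainError("cv must be >= 0")
        if self.bound_sd < 1.0:
            raise DomainError("truncation bound must be >= 1 SD")

    def draw(self, rng: np.random.Generator) -> float:
        if self.cv == 0.0:
            return self.location
        if self.family == "normal":
            sd = self.cv * abs(self.location)
            while True:
                z = rng.standard_normal()
                if abs(z) <= self.bound_sd:
                    return self.location + sd * z
        # lognormal: location is the median; truncate in log space
        sigma = math.sqrt(math.log(1.0 + self.cv**2))
        while True:
            z = rng.standard_normal()
            if abs(z) <= self.bound_sd:
                return self.location * math.exp(sigma * z)


@dataclass(frozen=True)
class PopulationSpec:
    """Sample size, seed, and per-parameter distributions."""

    n: int
    seed: int
    distributions: Mapping[str, ParamDist]
    reference: PhysiologyParams

    def __post_init__(self) -> None:
        if self.n < 0:
            raise DomainError("n must be >= 0")


def default_population_spec(
    reference: PhysiologyParams, n: int = 10_000, seed: int = 42
) -> PopulationSpec:
    """The default spec: BW lognormal CV 20%; fractions/flows normal CV 20%."""
    dists: dict[str, ParamDist] = {
        "body_weight": ParamDist("lognormal", reference.body_weight, 0.20),
        "cardiac_output_c": ParamDist("normal", reference.cardiac_output_c, 0.20),
        "alveolar_ventilation_c": ParamDist("normal", reference.alveolar_ventilation_c, 0.20),
        "skin_area_c": ParamDist("normal", reference.skin_area_c, 0.20),
    }
    for c in VOLUME_COMPARTMENTS:
        dists[f"volume_fraction_{c}"] = ParamDist(
            "normal", reference.volume_fraction[c], 0.20
        )
    for t in TISSUES:
        dists[f"flow_fraction_{t}"] = ParamDist(
            "normal", reference.flow_fraction[t], 0.20
        )
    return PopulationSpec(n=n, seed=seed, distributions=dists, reference=reference)


def _draw_subject(spec: PopulationSpec, rng: np.random.Generator) -> PhysiologyParams:
    ref = spec.reference
    d = spec.distributions
    for _attempt in range(100):
        bw = d["body_weight"].draw(rng)
        vols = {c: d[f"volume_fraction_{c}"].draw(rng) for c in VOLUME_COMPARTMENTS}
        if sum(vols.values()) > 1.0:  # anatomically impossible; redraw
            continue
        flows = {t: d[f"flow_fraction_{t}"].draw(rng) for t in TISSUES}
        total = sum(flows.values())
        flows = {t: f / total for t, f in flows.items()}
        return PhysiologyParams(
            body_weight=bw,
            volume_fraction=vols,
            flow_fraction=flows,
            cardiac_output_c=d["cardiac_output_c"].draw(rng),
            alveolar_ventilation_c=d["alveolar_ventilation_c"].draw(rng),
            skin_area_c=d["skin_area_c"].draw(rng),
            gas_exchange_volume=ref.gas_exchange_volume,
        )
    raise DomainError("could not draw a valid subject in 100 attempts")


def sample_population(spec: PopulationSpec) -> list[PhysiologyParams]:
    """Draw ``spec.n`` virtual subjects; same seed, same sample."""
    children = np.random.SeedSequence(spec.seed).spawn(spec.n)
    return [
        _draw_subject(spec, np.random.Generator(np.random.PCG64(child)))
        for child in children
    ]


def subset(population: list[PhysiologyParams], k: int) -> list[PhysiologyParams]:
    """The first ``k`` subjects, order preserving."""
    if k > len(population):
        raise DomainError(f"k={k} exceeds population size {len(population)}")
    if k < 0:
        raise DomainError("k must be >= 0")
    return population[:k]


def write_population_csv(population: list[PhysiologyParams], path: str | Path) -> None:
    """One row per subject, one column per parameter."""
    if not population:
        Path(path).write_text("")
        return
    keys = list(population[0].to_mapping().keys())
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(keys)
        for subj in population:
            m = subj.to_mapping()
            writer.writerow([repr(m[k]) for k in keys])
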