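from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from tpscreen.pipeline import PipelineInputs
from tpscreen.suspects import KeyMetaboliteRecord, RegistryEntry
from tpscreen.synthetic import ScenarioConfig, generate_scenario


def scenario_inputs(scenario) -> PipelineInputs:
    return PipelineInputs(
        registry=scenario.registry,
        metabolites=scenario.metabolites,
        features=scenario.features,
        library=scenario.library,
        applications=scenario.applications,
        detections=scenario.detections,
        standards=scenario.standards,
        rt_calibrants=scenario.rt_calibrants,
        calibration=pd.DataFrame(scenario.calibration_rows),
    )


SMALL = ScenarioConfig(
    seed=7,
    n_target_parents=4,
    n_additional_parents=1,
    metabolites_per_parent=1,
    n_spiked_tps=4,
    decoys_per_sample=4,
)

NOISELESS = ScenarioConfig(
    seed=11,
    noise_cv=0.0,
    decoys_per_sample=0,
    library_fraction=1.0,
    standard_fraction=1.0,
    mz_jitter_ppm=0.0,
)


@pytest.fixture(scope="session")
def small_scenario():
    return generate_scenario(SMALL)


@pytest.fixture(scope="session")
def default_scenario():
    return generate_scenario(ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def noiseless_scenario():
    return generate_scenario(NOISELESS)


def study_scale_registry() -> tuple[list[RegistryEntry], list[KeyMetaboliteRecord]]:
    """Registry/metabolite fixture at the composition of a national
    monitoring campaign: 142 targets + 16 additional parents, with 214
    and 28 key metabolites respectively (no shared structures)."""
    registry: list[RegistryEntry] = []
    metabolites: list[KeyMetaboliteRecord] = []
    categories = ("newly_registered", "seed_treatment",
                  "tp_only_monitored_parent", "special_concern")

    def formula(i: int) -> str:
        return f"C{6 + i % 12}H{8 + i % 10}N{i % 3}O{1 + i % 4}".replace("N0", "")

    for i in range(142):
        registry.append(
            RegistryEntry(f"T{i:03d}", f"target-{i:03d}", formula(i),
                          "monitored_target", None, ("E", "M"))
        )
    for i in range(16):
        registry.append(
            RegistryEntry(f"A{i:03d}", f"added-{i:03d}", formula(i + 142),
                          "additional_parent", categories[i % 4], ("E",))
        )
    k = 0
    for i in range(214):
        parent = f"T{i % 142:03d}"
        metabolites.append(
            KeyMetaboliteRecord(parent, f"KM{k:03d}", f"tp-{k:03d}",
                                formula(k + 7), 100.0 + k, 1000.0 + k)
        )
        k += 1
    for i in range(28):
        parent = f"A{i % 16:03d}"
        metabolites.append(
            KeyMetaboliteRecord(parent, f"KM{k:03d}", f"tp-{k:03d}",
                                formula(k + 7), 100.0 + k, 1000.0 + k)
        )
        k += 1
    return registry, metabolites
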