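"""Shared fixtures: the pedigree1 scenario is expensive (tens of seconds), so it
is built once per session, at error 0 and at 10% total read error, with the
detection and phasing stages run on top and cached alongside."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from marecs_kit import phaser, pipeline, scenarios, svscan


@dataclass
class DetectedScenario:
    run: scenarios.ScenarioRun
    candidates: list
    retained: list
    reasons: dict
    phased: phaser.PhasedHaplotype


def _build(seed: int, out_dir: str, error_rate: float) -> DetectedScenario:
    run = scenarios.pedigree1(seed, out_dir, error_rate=error_rate)
    candidates, retained, reasons = svscan.detect(run.paths["sam"])
    assert retained, "scenario must yield a retained SV for downstream fixtures"
    reference = pipeline._load_reference(run.paths["reference"])
    phased = pipeline.phase_candidate(
        retained[0], run.paths["sam"], reference, phaser.PhaseConfig()
    )
    return DetectedScenario(run, candidates, retained, reasons, phased)


@pytest.fixture(scope="session")
def ped1_error0(tmp_path_factory) -> DetectedScenario:
    return _build(1, str(tmp_path_factory.mktemp("ped1_e0")), 0.0)


@pytest.fixture(scope="session")
def ped1_error10(tmp_path_factory) -> DetectedScenario:
    return _build(1, str(tmp_path_factory.mktemp("ped1_e10")), 0.10)
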