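"""Shared fixtures.

The phantom + registration runs are the expensive pieces of the suite, so they
are generated once per session and shared across registration, pipeline and
acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from pneumodose.dosimetry import FractionationScheme
from pneumodose.pipeline import EvaluationResult, PipelineConfig, evaluate_patient
from pneumodose.registration import DisplacementField, demons_register
from pneumodose.synthetic import PhantomSpec, PhantomTruth, generate_phantom_pair


@dataclass
class PhantomPack:
    """One generated phantom with (optionally) its registration and evaluation."""

    spec: PhantomSpec
    planning: object
    followup: object
    structures: dict
    dose: object
    truth: PhantomTruth
    field: DisplacementField | None = None
    evaluation: EvaluationResult | None = None


def _build(spec: PhantomSpec, with_field: bool, with_eval: bool) -> PhantomPack:
    planning, followup, structures, dose, truth = generate_phantom_pair(spec)
    pack = PhantomPack(spec, planning, followup, structures, dose, truth)
    if with_field:
        pack.field = demons_register(planning, followup)
    if with_eval:
        pack.evaluation = evaluate_patient(
            planning, structures, dose, followup, structures["PTP_followup"],
            FractionationScheme(spec.n_fractions), PipelineConfig(),
            patient_id="PHANTOM")
    return pack


@pytest.fixture(scope="session")
def deformed_pack() -> PhantomPack:
    """64x64x48 phantom with the default 6 mm peak Gaussian-bump deformation."""
    return _build(PhantomSpec(seed=1), with_field=True, with_eval=True)


@pytest.fixture(scope="session")
def identity_pack() -> PhantomPack:
    """Same phantom family with zero deformation (identity ground truth)."""
    return _build(PhantomSpec(seed=2, deformation_peak_mm=0.0),
                  with_field=False, with_eval=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)
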