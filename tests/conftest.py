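"""Shared fixtures: small synthetic datasets and one session-scoped
demonstration pipeline run reused by the end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest

from mrrecg.pipeline import demo_config, run_pipeline
from mrrecg.synth import GeneratorConfig, generate_dataset


def make_manifest(
    n: int,
    mix: dict[str, float],
    *,
    fs: float = 100.0,
    duration_s: float = 4.0,
    seed: int = 0,
    snr_db: float = 25.0,
    class_names=None,
):
    cfg = GeneratorConfig(
        n_records=n,
        class_mix=mix,
        fs=fs,
        duration_s=duration_s,
        snr_db=snr_db,
        seed=seed,
        **({"class_names": class_names} if class_names else {}),
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_manifest():
    """40 records, two rhythm classes, 100 Hz / 4 s: cheap but labelled."""
    return make_manifest(
        40, {"Sinus bradycardia": 0.5, "Sinus tachycardia": 0.5}, seed=11
    )


@pytest.fixture(scope="session")
def demo_result():
    """One full demonstration pipeline run (5-fold, four families)."""
    return run_pipeline(demo_config(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
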