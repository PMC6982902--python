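"""Shared fixtures: virtual-learner recordings, reference patterns, banks.

Everything is generated programmatically and seeded; session-scoped
fixtures keep the expensive preprocessing shared across test modules.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from motiontutor.patterns import PatternBank, build_pattern_md
from motiontutor.signals import select_signals
from motiontutor.virtual_learner import (
    CLASS_ALPHA,
    CLASS_BETA,
    LearnerConfig,
    simulate,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

#: signal-catalogue indices of the single-sensor setup
ALL_K = (0, 2, 6, 8)  # accel x/z, position x/z
ROLES = {0: ("class", "time"), 2: ("class", "time"), 6: ("shape",), 8: ("shape",)}


def clean_config(mode: str = CLASS_ALPHA, seed: int = 11, duration: float = 8.0) -> LearnerConfig:
    """Expert-demonstration conditions: no noise, no jitter, no wobble."""
    return LearnerConfig(
        class_mode=mode,
        seed=seed,
        duration=duration,
        noise_density=0.0,
        wobble_deg=0.0,
        amplitude_jitter=0.0,
        phase_jitter=0.0,
    )


def smooth_signal(rng: np.random.Generator, n: int, n_harmonics: int = 4) -> np.ndarray:
    """Random band-limited periodic signal (motion-like test material)."""
    k = np.arange(1, n_harmonics + 1)
    phases = rng.uniform(0, 2 * np.pi, n_harmonics)
    amps = rng.normal(size=n_harmonics) / k
    t = np.arange(n) / n
    return sum(a * np.sin(2 * np.pi * q * t + p) for a, q, p in zip(amps, k, phases))


@pytest.fixture(scope="session")
def reference_patterns():
    """Clean expert demonstrations of both classes, preprocessed and
    turned into multi-dimensional patterns (class+time on accel, shape on
    position)."""
    refs = {}
    for mode in (CLASS_ALPHA, CLASS_BETA):
        stream, _ = simulate(clean_config(mode))
        S = select_signals([stream], ALL_K, period_w=200)
        refs[mode] = build_pattern_md(S, roles=ROLES, label=mode)
    return refs


@pytest.fixture(scope="session")
def training_bank():
    """Labelled bank of jittered, noisy repetitions (3 per class)."""
    entries = []
    for mode in (CLASS_ALPHA, CLASS_BETA):
        for seed in (11, 12, 13):
            cfg = dataclasses.replace(
                clean_config(mode, seed=seed),
                amplitude_jitter=0.02,
                phase_jitter=0.01,
                noise_density=0.4,
            )
            stream, _ = simulate(cfg)
            S = select_signals([stream], ALL_K, period_w=200)
            entries.append(build_pattern_md(S, roles=ROLES, label=mode))
    return PatternBank(entries=entries)
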