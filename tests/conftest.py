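"""Shared fixtures: reference geometries and cached expensive solves."""

from __future__ import annotations

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from microswim import (
    AssemblySpec,
    FilamentSpec,
    HeadSpec,
    evaluate_assembly,
    sweep_lengths,
)

# reduced-resolution settings for property tests (qualitative behavior is
# resolution-robust; see docs/methods.md)
COARSE = {"n_head_nodes": 300, "spacing_factor": 2.0}
DEFAULT = {"n_head_nodes": 600, "spacing_factor": 1.0}


@pytest.fixture(scope="session")
def bench_filament() -> FilamentSpec:
    """Two-turn helix, amplitude b=1, pitch 8b, filament radius b/16."""
    return FilamentSpec(amplitude=1.0, pitch=8.0, n_turns=2.0, radius=1.0 / 16)


@pytest.fixture(scope="session")
def bench_assembly(bench_filament) -> AssemblySpec:
    """The benchmark swimmer: head R=2b plus the two-turn helix."""
    return AssemblySpec(HeadSpec(2.0), bench_filament)


@pytest.fixture(scope="session")
def sweep_filament() -> FilamentSpec:
    """Tight-helix family used for length sweeps: pitch 2.42b, r=b/16."""
    return FilamentSpec(amplitude=1.0, pitch=2.42, n_turns=2.0, radius=1.0 / 16)


@pytest.fixture(scope="session")
def sweep_assembly(sweep_filament) -> AssemblySpec:
    return AssemblySpec(HeadSpec(2.0), sweep_filament)


@pytest.fixture(scope="session")
def bench_results(bench_assembly):
    """All four methods on the benchmark swimmer at default resolution."""
    return evaluate_assembly(
        bench_assembly,
        methods=("global", "additive", "rft-gh", "rft-lighthill"),
        **DEFAULT,
    )


@pytest.fixture(scope="session")
def length_sweep(sweep_assembly):
    """Full integer length sweep 1..20 at reduced resolution."""
    return sweep_lengths(
        sweep_assembly,
        list(range(1, 21)),
        methods=("global", "additive"),
        **COARSE,
    )


def split_sweep(df):
    """(global, additive) halves of a sweep table, indexed by n_turns."""
    g = df[(df.method == "global") & df.ok].set_index("n_turns").sort_index()
    a = df[(df.method == "additive") & df.ok].set_index("n_turns").sort_index()
    return g, a
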