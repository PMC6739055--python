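import numpy as np
import pytest

import fatrophic as ft


@pytest.fixture(scope="session")
def three_sources():
    """Three well-separated source groups over the 8-acid PUFA set."""
    return ft.default_source_specs(["diatom", "copepod", "symbiont"])


@pytest.fixture(scope="session")
def source_library(three_sources):
    ps = ft.simulate_sources(three_sources, 15, seed=11)
    return ft.SourceLibrary.from_profiles(ps, ps.fa_labels)


@pytest.fixture(scope="session")
def factorial_set():
    """Study-shaped crossed design: 3 species x 2 tissues x 2 depths, n=60."""
    return ft.simulate_factorial(ft.study_factorial_spec(seed=21))


def make_paired_coral(seed: int = 7) -> ft.ProfileSet:
    """Factorial coral set with colony-paired host/symbiont sample ids."""
    raw = ft.simulate_factorial(ft.study_factorial_spec(seed=seed))
    counters: dict = {}
    fixed = []
    for p in raw:
        key = (p.species, p.depth_m)
        counters.setdefault(key, {"host": 0, "symbiont": 0})
        counters[key][p.tissue] += 1
        colony = f"{p.species}_{p.depth_m:g}m_{counters[key][p.tissue]:02d}"
        fixed.append(
            ft.FAProfile(
                f"{colony}_{p.tissue}", p.proportions, p.species, p.tissue, p.depth_m
            )
        )
    return ft.ProfileSet(fixed, fa_labels=raw.fa_labels)


@pytest.fixture(scope="session")
def paired_coral():
    return make_paired_coral()
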