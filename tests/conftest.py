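import numpy as np
import pytest
from hypothesis import settings

from cistrokit.peakcalling import (PeakCallingConfig, call_peaks,
                                   estimate_fragment_shift)
from cistrokit.simulate import SimulationConfig, generate_world

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: Seed of the shared default synthetic world used across the suite.
WORLD_SEED = 101


@pytest.fixture(scope="session")
def default_world():
    """The default synthetic world: 1 Mb genome, 100 genes, 200 planted
    half-sites, d=152, 39-bp reads."""
    cfg = SimulationConfig(seed=WORLD_SEED)
    genome, genes, truth, treatment, control, expression = generate_world(cfg)
    return {
        "config": cfg,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "treatment": treatment,
        "control": control,
        "expression": expression,
    }


@pytest.fixture(scope="session")
def called_peaks(default_world):
    """Fragment-shift model and peaks called on the default world."""
    cfg = PeakCallingConfig()
    model = estimate_fragment_shift(
        default_world["treatment"], default_world["genome"], cfg
    )
    peaks = call_peaks(
        default_world["treatment"], default_world["control"], model, cfg,
        default_world["genome"],
    )
    return {"model": model, "peaks": peaks, "config": cfg}


def site_in_peak(site, peaks):
    return any(
        p.chrom == site.chrom and p.start < site.end and site.start < p.end
        for p in peaks
    )


def peak_has_site(peak, sites):
    return any(
        peak.chrom == s.chrom and peak.start < s.end and s.start < peak.end
        for s in sites
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
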