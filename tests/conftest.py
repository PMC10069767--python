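import pytest
from hypothesis import settings

from duet import depthdeconv as dd
from duet import synthgen as sg

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

FIG1_PRIVATE = ((600_001, 700_001), (900_001, 950_001))


@pytest.fixture(scope="session")
def fig1_chain():
    """Full deconvolution chain on the 1 Mb two-strain mixture fixture:
    private regions at 600-700 kb and 900-950 kb, titer 0.7, 50x depth."""
    spec = sg.StrainPairSpec(
        backbone_length=1_000_000, private_regions_a=FIG1_PRIVATE,
        titer_a=0.7, seed=42,
    )
    pair = sg.make_strain_pair(spec)
    track = sg.simulate_mixture_depth(
        pair, cov=sg.CoverageSimSpec(mean_depth=50.0, seed=42)
    )
    wt = dd.windowed_normalized_depth(track)
    regions = dd.classify_regions(
        dd.segment_regions(wt), duplication_evidence=17
    )
    est = dd.estimate_titer(regions, wt, seed=42)
    return {"pair": pair, "track": track, "wt": wt,
            "regions": regions, "estimate": est}
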